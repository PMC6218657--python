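"""Self-organizing-map classification of region accessibility dynamics.

Per-region condition profiles (replicate means of normalised counts) are
z-scored across conditions and clustered on a 5x5 hexagonal SOM trained in
batch mode with a Gaussian neighbourhood.  Units are then labelled with the
condition (or condition combination, e.g. shared anterior/hindbrain) whose
indicator pattern best matches the unit's mean profile, which automates the
by-eye merging of map cells into named groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import OPEN_CONDITIONS

__all__ = [
    "ZScoreMatrix",
    "SOMGrid",
    "ClusterAssignment",
    "zscore_rows",
    "train_som",
    "label_clusters",
    "temporal_profile",
    "transient_cluster_fraction",
    "default_label_patterns",
]

UNCLASSIFIED = "unclassified"


@dataclass
class ZScoreMatrix:
    """Row-standardised condition profiles; constant rows are zeroed and
    flagged rather than divided by zero."""

    values: np.ndarray          # regions x conditions
    conditions: list[str]
    region_ids: list[str]
    constant_flags: np.ndarray  # True where the input row had sd == 0


def zscore_rows(condition_means: pd.DataFrame) -> ZScoreMatrix:
    """z = (x - mean(x)) / sd(x) per row, with the sample sd (n-1)."""
    if condition_means.shape[1] < 2:
        raise ValueError("need >= 2 conditions to z-score")
    x = condition_means.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flags = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / safe_sd
    z[flags] = 0.0
    return ZScoreMatrix(
        values=z,
        conditions=list(condition_means.columns),
        region_ids=[str(i) for i in condition_means.index],
        constant_flags=flags,
    )


def _hex_coordinates(rows: int, cols: int) -> np.ndarray:
    """Unit positions in the hexagonal plane (odd rows offset by half a
    cell, rows sqrt(3)/2 apart); unit index = row * cols + col."""
    coords = np.zeros((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            coords[r * cols + c] = (c + 0.5 * (r % 2), r * np.sqrt(3) / 2)
    return coords


@dataclass
class SOMGrid:
    rows: int
    cols: int
    weights: np.ndarray          # units x conditions
    coordinates: np.ndarray      # units x 2, hex plane
    quantization_errors: list[float] = field(default_factory=list)
    seed: int | None = None
    epochs: int = 0

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def bmus(self, X: np.ndarray) -> np.ndarray:
        """Best-matching unit per row (Euclidean; ties -> lowest index)."""
        d = ((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)


def train_som(
    Z: ZScoreMatrix,
    rows: int = 5,
    cols: int = 5,
    seed: int = 0,
    epochs: int = 100,
    sigma_start: float = 2.5,
    sigma_end: float = 0.5,
) -> tuple[SOMGrid, np.ndarray]:
    """Batch SOM training on the non-flagged z-score rows.

    Weights start from a seeded sample of input rows; each epoch assigns
    every row to its BMU and resets each unit to the Gaussian
    neighbourhood-weighted mean of the data, with the kernel width decaying
    linearly from ``sigma_start`` to ``sigma_end`` grid units.  Fully
    deterministic given the seed.  Returns the grid and, for every input row
    (flagged rows included), its BMU index.
    """
    keep = ~Z.constant_flags
    X = Z.values[keep]
    n_units = rows * cols
    if len(X) < n_units:
        raise ValueError(f"need >= {n_units} usable rows, got {len(X)}")
    rng = np.random.default_rng(seed)
    coords = _hex_coordinates(rows, cols)
    weights = X[rng.choice(len(X), size=n_units, replace=False)].copy()
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    qe: list[float] = []
    bmu = np.zeros(len(X), dtype=np.int64)
    for t in range(epochs):
        frac = t / max(epochs - 1, 1)
        sigma = sigma_start + (sigma_end - sigma_start) * frac
        d2 = ((X[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
        bmu = d2.argmin(axis=1)
        qe.append(float(np.sqrt(d2[np.arange(len(X)), bmu]).mean()))
        H = np.exp(-grid_d2 / (2 * sigma**2))  # units x units
        K = H[bmu]                             # rows x units
        denom = K.sum(axis=0)
        numer = K.T @ X
        nz = denom > 1e-12
        weights[nz] = numer[nz] / denom[nz, None]
    grid = SOMGrid(rows, cols, weights, coords, qe, seed=seed, epochs=epochs)
    # final assignment for every row; flagged rows get BMU of the zero vector
    all_bmus = grid.bmus(Z.values)
    return grid, all_bmus


def default_label_patterns(conditions: Sequence[str]) -> dict[str, np.ndarray]:
    """Centred indicator patterns over ``conditions`` for each named region
    class (classes whose open-condition set is empty or saturated carry no
    signal and are skipped)."""
    patterns: dict[str, np.ndarray] = {}
    for label, opens in OPEN_CONDITIONS.items():
        ind = np.array([1.0 if c in opens else 0.0 for c in conditions])
        ind = ind - ind.mean()
        if np.linalg.norm(ind) < 1e-12:
            continue
        patterns[label] = ind
    return patterns


@dataclass
class ClusterAssignment:
    bmus: np.ndarray                   # per-region unit index
    unit_labels: list[str]             # per-unit class label (or unclassified)
    region_labels: list[str]           # unit label propagated to each region
    groups: dict[str, np.ndarray]      # label -> region indices (merged units)
    unit_similarity: np.ndarray        # best cosine similarity per unit


def label_clusters(
    grid: SOMGrid,
    bmus: np.ndarray,
    Z: ZScoreMatrix,
    patterns: Mapping[str, np.ndarray] | None = None,
    similarity_floor: float = 0.5,
) -> ClusterAssignment:
    """Label each unit with the best-matching condition pattern.

    The unit's member-mean z profile is compared by cosine similarity
    against each (centred) indicator pattern; below ``similarity_floor``
    (or for empty units) the unit is left unclassified.  Ties break by
    pattern order.  Units sharing a label form one named group.
    """
    if patterns is None:
        patterns = default_label_patterns(Z.conditions)
    labels: list[str] = []
    sims = np.zeros(grid.n_units)
    for u in range(grid.n_units):
        members = np.nonzero((bmus == u) & ~Z.constant_flags)[0]
        if len(members) == 0:
            labels.append(UNCLASSIFIED)
            continue
        profile = Z.values[members].mean(axis=0)
        norm = np.linalg.norm(profile)
        if norm < 1e-12:
            labels.append(UNCLASSIFIED)
            continue
        best_label, best_sim = UNCLASSIFIED, -np.inf
        for label, pat in patterns.items():
            sim = float(profile @ pat / (norm * np.linalg.norm(pat)))
            if sim > best_sim:
                best_label, best_sim = label, sim
        sims[u] = best_sim
        labels.append(best_label if best_sim >= similarity_floor else UNCLASSIFIED)
    region_labels = [labels[u] for u in bmus]
    groups: dict[str, np.ndarray] = {}
    for label in dict.fromkeys(labels):
        idx = np.nonzero([region_labels[i] == label for i in range(len(bmus))])[0]
        groups[label] = idx
    return ClusterAssignment(
        bmus=np.asarray(bmus),
        unit_labels=labels,
        region_labels=region_labels,
        groups=groups,
        unit_similarity=sims,
    )


def temporal_profile(
    Z: ZScoreMatrix,
    region_indices: Sequence[int],
    series: Sequence[str],
) -> pd.DataFrame:
    """Mean and sd of z over ``region_indices`` at each point of an ordered
    condition series (e.g. the spinal-cord course D0, D3NMP, D4SC, D5SC)."""
    idx = np.asarray(region_indices, dtype=int)
    if len(idx) == 0:
        raise ValueError("empty region set")
    missing = [c for c in series if c not in Z.conditions]
    if missing:
        raise KeyError(f"conditions not in matrix: {missing}")
    cols = [Z.conditions.index(c) for c in series]
    sub = Z.values[np.ix_(idx, cols)]
    return pd.DataFrame(
        {
            "condition": list(series),
            "mean_z": sub.mean(axis=0),
            "sd_z": sub.std(axis=0, ddof=1) if len(idx) > 1 else np.zeros(len(cols)),
        }
    )


def transient_cluster_fraction(
    cluster_sizes: Mapping[str, int],
    transient: str = "NMP",
    induced: Sequence[str] = ("NMP", "NMP_SC"),
) -> float:
    """Percentage of the induced region set that belongs to the transient
    cluster, e.g. the share of D3 FGF/WNT-induced sites that close again as
    cells commit (NMP-only over NMP + NMP/SC)."""
    total = sum(cluster_sizes[c] for c in induced)
    if total == 0:
        raise ValueError("induced clusters are empty")
    return 100.0 * cluster_sizes[transient] / total
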
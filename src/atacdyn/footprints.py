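"""Tn5 insertion analysis: shifts, insertion matrices, footprint mixture model.

Each sequenced fragment marks two transposase insertions; following the
standard ATAC convention, plus-strand cuts are shifted +4 bp and
minus-strand cuts -5 bp so positions land on the enzyme's centre of action.
The footprint caller is a two-component mixture in the CENTIPEDE family:
bound sites draw their window counts from a free positional profile (which
learns the core depletion) with a higher negative-binomial abundance,
unbound sites from a flat profile with lower abundance, and the mixing
prior is logistic in the PWM score.  EM returns a posterior bound
probability per motif site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .motifs import PWM, MotifHit, read_jaspar_pfm, scan_pwm  # re-exported surface
from .regions import IntervalSet

__all__ = [
    "InsertionEvents",
    "FootprintModel",
    "TSSEnrichmentResult",
    "extract_insertions",
    "build_insertion_matrix",
    "fit_footprint_model",
    "classify_bound",
    "tss_enrichment",
    "PWM",
    "MotifHit",
    "read_jaspar_pfm",
    "scan_pwm",
]

PLUS_SHIFT = 4
MINUS_SHIFT = -5
NFR_MAX_FRAGMENT = 100
BOUND_THRESHOLDS = {"genome-wide": 0.99, "peak-summit": 0.9}


@dataclass
class InsertionEvents:
    """Shifted Tn5 cut sites: parallel arrays plus a dropped-event counter."""

    table: pd.DataFrame  # columns chrom, position, strand, fragment_length
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.table)

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        return {
            chrom: np.sort(grp["position"].to_numpy(np.int64))
            for chrom, grp in self.table.groupby("chrom", sort=True)
        }


def extract_insertions(
    fragments: pd.DataFrame, max_fragment_length: int | None = NFR_MAX_FRAGMENT
) -> InsertionEvents:
    """Two shifted insertion events per retained fragment.

    The plus-strand cut is the fragment start shifted +4; the minus-strand
    cut is the last covered base (end - 1) shifted -5, i.e. stored position
    ``end - 6``.  Fragments with length >= ``max_fragment_length`` are
    discarded (sub-nucleosomal fraction only); pass ``None`` to keep all.
    Events shifted below position 0 are dropped and counted.
    """
    if len(fragments) == 0:
        empty = pd.DataFrame(
            {"chrom": [], "position": [], "strand": [], "fragment_length": []}
        )
        return InsertionEvents(empty, n_dropped=0)
    lengths = (fragments["end"] - fragments["start"]).to_numpy(np.int64)
    keep = (
        np.ones(len(fragments), dtype=bool)
        if max_fragment_length is None
        else lengths < max_fragment_length
    )
    sub = fragments[keep]
    sub_len = lengths[keep]
    plus = sub["start"].to_numpy(np.int64) + PLUS_SHIFT
    minus = sub["end"].to_numpy(np.int64) - 1 + MINUS_SHIFT
    chroms = sub["chrom"].to_numpy(object)
    table = pd.DataFrame(
        {
            "chrom": np.concatenate([chroms, chroms]),
            "position": np.concatenate([plus, minus]),
            "strand": ["+"] * len(sub) + ["-"] * len(sub),
            "fragment_length": np.concatenate([sub_len, sub_len]),
        }
    )
    ok = table["position"] >= 0
    dropped = int((~ok).sum())
    return InsertionEvents(table[ok].reset_index(drop=True), n_dropped=dropped)


def build_insertion_matrix(
    events: InsertionEvents,
    hits: list[MotifHit],
    flank: int = 150,
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Hits x window insertion counts, motif-centred and strand-oriented.

    Windows span ``[start - flank, start + W + flank)``; minus-strand hits
    are column-reversed so the motif always reads 5'->3'.  Insertion-event
    strands are pooled.  Returns the matrix and the indices of hits kept
    (rows whose window leaves the chromosome are dropped).
    """
    if not hits:
        return np.zeros((0, 2 * flank), dtype=np.int64), []
    W = len(hits[0].interval)
    L = W + 2 * flank
    by_chrom = events.positions_by_chrom()
    rows: list[np.ndarray] = []
    kept: list[int] = []
    for i, h in enumerate(hits):
        iv = h.interval
        lo, hi = iv.start - flank, iv.start + W + flank
        if lo < 0:
            continue
        if chrom_sizes is not None and hi > chrom_sizes.get(iv.chrom, np.inf):
            continue
        pos = by_chrom.get(iv.chrom)
        row = np.zeros(L, dtype=np.int64)
        if pos is not None:
            a, b = np.searchsorted(pos, (lo, hi))
            np.add.at(row, pos[a:b] - lo, 1)
        if iv.strand == "-":
            row = row[::-1]
        rows.append(row)
        kept.append(i)
    matrix = np.array(rows, dtype=np.int64) if rows else np.zeros((0, L), np.int64)
    return matrix, kept


@dataclass
class FootprintModel:
    """Fitted two-component footprint mixture."""

    lambda_: np.ndarray        # bound positional profile, sums to 1
    mu_bound: float            # NB abundance mean, bound component
    mu_unbound: float
    dispersion: float          # shared NB dispersion (1/size)
    beta0: float               # logistic prior intercept
    beta1: float               # logistic prior PWM-score coefficient
    posteriors: np.ndarray     # per-hit bound probability
    loglik_trace: list[float]  # penalised log-likelihood, non-decreasing

    @property
    def window(self) -> int:
        return len(self.lambda_)


def _nb_logpmf(N: np.ndarray, mu: float, phi: float) -> np.ndarray:
    r = 1.0 / phi
    return stats.nbinom.logpmf(N, r, r / (r + max(mu, 1e-8)))


def _fit_logistic(s: np.ndarray, gamma: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Weighted (soft-label) logistic regression by IRLS with step halving."""
    X = np.column_stack([np.ones_like(s), s])

    def objective(b):
        eta = X @ b
        return float(np.sum(gamma * eta - np.logaddexp(0.0, eta)))

    best = objective(beta)
    for _ in range(30):
        eta = X @ beta
        p = special.expit(eta)
        wdiag = np.maximum(p * (1 - p), 1e-8)
        grad = X.T @ (gamma - p)
        hess = (X * wdiag[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(20):
            cand = beta + scale * step
            val = objective(cand)
            if val >= best:
                beta, best = cand, val
                break
            scale /= 2
        else:
            break
        if np.abs(scale * step).max() < 1e-8:
            break
    return beta


def fit_footprint_model(
    matrix: np.ndarray,
    pwm_scores: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> FootprintModel:
    """EM fit of the footprint mixture on an insertion matrix.

    The traced objective is the observed-data log-likelihood plus the
    Dirichlet(1)-smoothing prior on the bound profile (the profile update
    uses one pseudocount per window position); it is non-decreasing at
    every iteration.  Component identifiability: the bound component is the
    one with the larger abundance mean.
    """
    X = np.asarray(matrix, dtype=np.int64)
    n, L = X.shape
    if n < 100:
        raise ValueError(f"need >= 100 motif hits, got {n}")
    if X.sum() == 0:
        raise ValueError("no signal: insertion matrix is all zero")
    s = np.asarray(pwm_scores, dtype=float)
    if len(s) != n:
        raise ValueError("pwm_scores must match matrix rows")
    N = X.sum(axis=1)
    gamma = np.where(N > np.median(N), 0.75, 0.25)
    beta = np.array([0.0, 0.0])
    phi = 0.5
    log_flat = -np.log(L)
    trace: list[float] = []
    lam = np.full(L, 1.0 / L)
    mu_b = mu_u = float(max(N.mean(), 1e-6))
    for _ in range(max_iter):
        # M step
        for _swap in range(2):
            w = gamma.sum()
            lam = (gamma @ X + 1.0) / (gamma @ N + L)
            mu_b = float(max((gamma @ N) / max(w, 1e-12), 1e-6))
            mu_u = float(max(((1 - gamma) @ N) / max(n - w, 1e-12), 1e-6))
            if mu_b >= mu_u:
                break
            gamma = 1.0 - gamma

        def neg_q(log_phi):
            ph = 10.0**log_phi
            return -float(
                np.sum(gamma * _nb_logpmf(N, mu_b, ph))
                + np.sum((1 - gamma) * _nb_logpmf(N, mu_u, ph))
            )

        res = optimize.minimize_scalar(neg_q, bounds=(-4.0, 1.0), method="bounded")
        if -res.fun >= -neg_q(np.log10(phi)):
            phi = float(10.0**res.x)
        beta = _fit_logistic(s, gamma, beta)
        # E step + objective under the just-updated parameters
        eta = beta[0] + beta[1] * s
        log_prior_b = -np.logaddexp(0.0, -eta)
        log_prior_u = -np.logaddexp(0.0, eta)
        log_fb = _nb_logpmf(N, mu_b, phi) + X @ np.log(lam)
        log_fu = _nb_logpmf(N, mu_u, phi) + N * log_flat
        a = log_prior_b + log_fb
        b = log_prior_u + log_fu
        ll = float(np.logaddexp(a, b).sum() + np.log(lam).sum())
        gamma = special.expit(a - b)
        converged = bool(trace) and (ll - trace[-1] < tol)
        trace.append(ll)
        if converged:
            break
    return FootprintModel(
        lambda_=lam,
        mu_bound=mu_b,
        mu_unbound=mu_u,
        dispersion=phi,
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        posteriors=gamma,
        loglik_trace=trace,
    )


def classify_bound(posteriors: np.ndarray, mode: str) -> np.ndarray:
    """Bound/unbound calls at the mode-specific posterior threshold
    (genome-wide 0.99; peak-summit 0.9)."""
    if mode not in BOUND_THRESHOLDS:
        raise ValueError(
            f"unknown mode {mode!r}; choose from {sorted(BOUND_THRESHOLDS)}"
        )
    return np.asarray(posteriors) >= BOUND_THRESHOLDS[mode]


@dataclass
class TSSEnrichmentResult:
    profile: np.ndarray    # raw aggregate insertions, positions -window..+window
    smoothed: np.ndarray   # running average
    score: float           # max(smoothed) / min(smoothed)
    infinite: bool = False


def tss_enrichment(
    events: InsertionEvents,
    tss_set: IntervalSet,
    window: int = 2000,
    smooth: int = 50,
) -> TSSEnrichmentResult:
    """Aggregate strand-oriented insertion profile over TSS +/- window with a
    running average; score = max/min of the smoothed profile (reported
    infinite, with a flag, if the minimum is zero)."""
    if len(tss_set) == 0:
        raise ValueError("empty TSS set")
    if len(events) == 0:
        raise ValueError("no insertion events")
    width = 2 * window + 1
    profile = np.zeros(width, dtype=np.int64)
    by_chrom = events.positions_by_chrom()
    for iv in tss_set:
        pos = by_chrom.get(iv.chrom)
        if pos is None:
            continue
        tss = iv.start if iv.strand != "-" else iv.end - 1
        a, b = np.searchsorted(pos, (tss - window, tss + window + 1))
        offsets = pos[a:b] - tss
        if iv.strand == "-":
            offsets = -offsets
        np.add.at(profile, offsets + window, 1)
    from scipy.ndimage import uniform_filter1d

    # nearest-edge handling: a plain 'same' convolution would fabricate a
    # spurious minimum at the window boundary
    smoothed = uniform_filter1d(profile.astype(float), size=smooth, mode="nearest")
    mn, mx = float(smoothed.min()), float(smoothed.max())
    if mn == 0:
        return TSSEnrichmentResult(profile, smoothed, np.inf, infinite=True)
    return TSSEnrichmentResult(profile, smoothed, mx / mn, infinite=False)
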
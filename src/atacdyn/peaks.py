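"""Candidate peak calling, consensus construction, fragment counting, FPM tracks.

The caller is a deliberately simple sliding-window Poisson test against a
global background rate — a self-contained stand-in for a full model-based
caller, adequate for enrichment detection on simulated fragment data.
Fragments are carried as a pandas DataFrame with columns
``chrom, start, end, sample`` (0-based half-open spans).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regions import GenomicInterval, IntervalSet, merge_intervals

__all__ = [
    "SampleInfo",
    "PeakCall",
    "CountMatrix",
    "CoverageTrack",
    "call_candidate_peaks",
    "build_consensus_peaks",
    "count_fragments",
    "coverage_track_fpm",
    "peaks_to_intervals",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "sample"]


@dataclass(frozen=True)
class SampleInfo:
    """One library: condition (e.g. ``D4SC``), day parsed from it, replicate."""

    condition: str
    replicate: int
    day: int = -1

    def __post_init__(self) -> None:
        if self.day < 0:
            m = re.match(r"D(\d+)", self.condition)
            object.__setattr__(self, "day", int(m.group(1)) if m else 0)

    @property
    def id(self) -> str:
        return f"{self.condition}_r{self.replicate}"

    @classmethod
    def from_id(cls, sample_id: str) -> "SampleInfo":
        cond, _, rep = sample_id.rpartition("_r")
        return cls(cond, int(rep))


@dataclass(frozen=True)
class PeakCall:
    """A called peak; score is -log10 of the best window Poisson p-value,
    summit the maximum-coverage offset from start."""

    interval: GenomicInterval
    score: float
    summit: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if not (0 <= self.summit < len(self.interval)):
            raise ValueError("summit outside peak")


def peaks_to_intervals(peaks: list[PeakCall], label: str | None = None) -> IntervalSet:
    return IntervalSet(
        (
            GenomicInterval(
                p.interval.chrom,
                p.interval.start,
                p.interval.end,
                name=f"peak_{i}",
                score=p.score,
                summit=p.summit,
            )
            for i, p in enumerate(peaks)
        ),
        label=label,
    )


@dataclass
class CountMatrix:
    """Consensus regions x samples integer fragment counts."""

    regions: IntervalSet
    samples: list[SampleInfo]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.regions)}, {len(self.samples)})"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    def columns_for(self, condition: str) -> list[int]:
        return [j for j, s in enumerate(self.samples) if s.condition == condition]

    def condition_means(self, size_factors: np.ndarray | None = None) -> pd.DataFrame:
        """Replicate-mean (optionally size-factor normalised) counts per
        condition; rows indexed by region name."""
        norm = self.counts.astype(float)
        if size_factors is not None:
            norm = norm / np.asarray(size_factors)[None, :]
        data = {c: norm[:, self.columns_for(c)].mean(axis=1) for c in self.conditions}
        index = [iv.name or f"region_{i}" for i, iv in enumerate(self.regions)]
        return pd.DataFrame(data, index=index)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.regions],
                "start": [iv.start for iv in self.regions],
                "end": [iv.end for iv in self.regions],
                "region_id": [iv.name or f"region_{i}" for i, iv in enumerate(self.regions)],
            }
        )
        for j, s in enumerate(self.samples):
            df[s.id] = self.counts[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        sample_cols = [c for c in df.columns if c not in ("chrom", "start", "end", "region_id")]
        regions = IntervalSet(
            GenomicInterval(r.chrom, r.start, r.end, name=r.region_id)
            for r in df.itertuples()
        )
        samples = [SampleInfo.from_id(c) for c in sample_cols]
        return cls(regions, samples, df[sample_cols].to_numpy(dtype=np.int64))


@dataclass
class CoverageTrack:
    """Per-base FPM (fragments per million per bp) values per chromosome."""

    values: dict[str, np.ndarray]
    library_size: int

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.values):
                v = self.values[chrom]
                change = np.nonzero(np.diff(v))[0] + 1
                bounds = np.concatenate([[0], change, [len(v)]])
                for s, e in zip(bounds[:-1], bounds[1:]):
                    if v[s] != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.6g}\n")


def _per_chrom(fragments: pd.DataFrame):
    for chrom, grp in fragments.groupby("chrom", sort=True):
        yield chrom, grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)


def call_candidate_peaks(
    fragments: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window: int = 300,
    step: int = 100,
    p_threshold: float = 0.01,
) -> list[PeakCall]:
    """Sliding-window Poisson enrichment test against the global rate.

    The background rate per window is ``n_fragments x (window + mean
    fragment length) / genome_size`` — the expected number of fragments
    overlapping a window under uniform placement.  Significant windows are
    merged; each merged peak gets score ``-log10(min p)`` and its summit at
    the maximum-coverage base.
    """
    if len(fragments) == 0:
        warnings.warn("no fragments: returning no peaks")
        return []
    genome_size = sum(chrom_sizes.values())
    n = len(fragments)
    mean_len = float((fragments["end"] - fragments["start"]).mean())
    lam = n * (window + mean_len) / genome_size
    calls: list[PeakCall] = []
    for chrom, starts, ends in _per_chrom(fragments):
        L = chrom_sizes[chrom]
        s_sorted = np.sort(starts)
        e_sorted = np.sort(ends)
        w_starts = np.arange(0, max(1, L - window + 1), step, dtype=np.int64)
        w_ends = np.minimum(w_starts + window, L)
        k = np.searchsorted(s_sorted, w_ends, side="left") - np.searchsorted(
            e_sorted, w_starts, side="right"
        )
        pvals = stats.poisson.sf(k - 1, lam)
        sig = pvals < p_threshold
        if not sig.any():
            continue
        # merge runs of overlapping significant windows
        windows = IntervalSet(
            GenomicInterval(chrom, int(ws), int(we), score=float(p))
            for ws, we, p in zip(w_starts[sig], w_ends[sig], pvals[sig])
        )
        merged = merge_intervals(windows)
        # per-base coverage for summits
        cov = np.zeros(L + 1, dtype=np.int64)
        np.add.at(cov, np.clip(starts, 0, L), 1)
        np.add.at(cov, np.clip(ends, 0, L), -1)
        cov = np.cumsum(cov)[:L]
        for miv in merged:
            member_p = [
                float(w.score)
                for w in windows
                if w.start < miv.end and w.end > miv.start
            ]
            p_min = max(min(member_p), 1e-300)
            summit = int(np.argmax(cov[miv.start : miv.end]))
            calls.append(
                PeakCall(
                    GenomicInterval(chrom, miv.start, miv.end),
                    score=float(-np.log10(p_min)),
                    summit=summit,
                )
            )
    return calls


def build_consensus_peaks(
    per_condition_sets: list[IntervalSet], return_contributions: bool = False
):
    """Merge peak sets across conditions into the consensus region set.

    With ``return_contributions=True`` also return, per consensus region,
    the tuple of contributing condition labels.
    """
    if len(per_condition_sets) == 0:
        raise ValueError("need at least one condition peak set")
    pooled = IntervalSet(
        (iv for s in per_condition_sets for iv in s), label="consensus"
    )
    merged = merge_intervals(pooled)
    consensus = IntervalSet(
        (
            GenomicInterval(iv.chrom, iv.start, iv.end, name=f"cons_{i:06d}")
            for i, iv in enumerate(merged)
        ),
        label="consensus",
    )
    if not return_contributions:
        return consensus
    from .regions import find_overlaps

    contribs: list[set[str]] = [set() for _ in consensus]
    for ci, cond_set in enumerate(per_condition_sets):
        label = cond_set.label or f"condition_{ci}"
        for qi, _ in find_overlaps(consensus, cond_set):
            contribs[qi].add(label)
    return consensus, [tuple(sorted(c)) for c in contribs]


def _count_one_sample(
    starts_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
    consensus_by_chrom: dict[str, dict[str, np.ndarray]],
    n_regions: int,
) -> np.ndarray:
    counts = np.zeros(n_regions + 1, dtype=np.int64)
    for chrom, (fs, fe) in starts_by_chrom.items():
        if chrom not in consensus_by_chrom:
            continue
        c = consensus_by_chrom[chrom]
        # regions are non-overlapping & sorted: the regions overlapped by a
        # fragment form a contiguous run [lo, hi)
        lo = np.searchsorted(c["end"], fs, side="right")
        hi = np.searchsorted(c["start"], fe, side="left")
        valid = hi > lo
        gidx = c["index"]
        lo_g = gidx[np.clip(lo[valid], 0, len(gidx) - 1)]
        hi_run = hi[valid] - lo[valid]
        np.add.at(counts, lo_g, 1)
        np.add.at(counts, lo_g + hi_run, -1)
    # difference trick works because each chromosome's region indices are
    # contiguous in the sorted IntervalSet order
    return np.cumsum(counts)[:n_regions]


def count_fragments(fragments: pd.DataFrame, consensus: IntervalSet) -> CountMatrix:
    """Region x sample fragment counts; a fragment increments every region it
    overlaps by >= 1 bp."""
    if not consensus.is_nonoverlapping():
        raise ValueError("consensus regions must be non-overlapping")
    cbc = consensus.by_chrom()
    sample_ids = sorted(fragments["sample"].unique())
    samples = [SampleInfo.from_id(s) for s in sample_ids]
    counts = np.zeros((len(consensus), len(samples)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        sub = fragments[fragments["sample"] == sid]
        per_chrom = {
            chrom: (s, e) for chrom, s, e in _per_chrom(sub)
        }
        counts[:, j] = _count_one_sample(per_chrom, cbc, len(consensus))
    return CountMatrix(consensus, samples, counts)


def coverage_track_fpm(
    fragments: pd.DataFrame, sample: str, chrom_sizes: dict[str, int]
) -> CoverageTrack:
    """Per-base coverage scaled by 1e6 / library size (FPM per bp)."""
    sub = fragments[fragments["sample"] == sample]
    if len(sub) == 0:
        raise ValueError(f"sample {sample!r} has no fragments")
    lib = len(sub)
    scale = 1e6 / lib
    values: dict[str, np.ndarray] = {}
    for chrom, L in chrom_sizes.items():
        values[chrom] = np.zeros(L, dtype=np.float64)
    for chrom, starts, ends in _per_chrom(sub):
        L = chrom_sizes[chrom]
        diff = np.zeros(L + 1, dtype=np.int64)
        np.add.at(diff, np.clip(starts, 0, L), 1)
        np.add.at(diff, np.clip(ends, 0, L), -1)
        values[chrom] = np.cumsum(diff)[:L] * scale
    return CoverageTrack(values=values, library_size=lib)
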
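"""Genomic interval algebra and BED/narrowPeak I/O.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``.  Every region, peak and
motif site in the package is carried by :class:`GenomicInterval`, and ordered
collections by :class:`IntervalSet`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "merge_intervals",
    "find_overlaps",
    "extend_around_center",
    "read_regions",
    "write_regions",
]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded, the default).
    ``summit`` is an optional offset from ``start`` (narrowPeak column 10);
    ``None`` encodes the ENCODE ``-1`` "undefined" sentinel.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.summit is not None and not (0 <= self.summit < len(self)):
            raise ValueError(f"summit {self.summit} outside interval of length {len(self)}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name or "")


class IntervalSet:
    """Sorted, de-duplicated collection of :class:`GenomicInterval`.

    Sorting is by ``(chrom, start, end)``; duplicate ``(chrom, start, end,
    name)`` entries are dropped on construction.  ``label`` records
    provenance (a condition or cluster name).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str | None = None):
        seen: set[tuple] = set()
        uniq: list[GenomicInterval] = []
        for iv in intervals:
            key = (iv.chrom, iv.start, iv.end, iv.name)
            if key not in seen:
                seen.add(key)
                uniq.append(iv)
        self._intervals: list[GenomicInterval] = sorted(uniq, key=GenomicInterval.sort_key)
        self.label = label
        self._by_chrom_cache: dict[str, dict[str, np.ndarray]] | None = None

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        lab = f" label={self.label!r}" if self.label else ""
        return f"<IntervalSet n={len(self)}{lab}>"

    # -- helpers -----------------------------------------------------------
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self._intervals})

    def by_chrom(self) -> dict[str, dict[str, np.ndarray]]:
        """Per-chromosome start/end/index arrays (sorted by start)."""
        if self._by_chrom_cache is None:
            out: dict[str, dict[str, np.ndarray]] = {}
            for chrom, group in itertools.groupby(
                enumerate(self._intervals), key=lambda t: t[1].chrom
            ):
                idx, ivs = zip(*group)
                out[chrom] = {
                    "start": np.array([iv.start for iv in ivs], dtype=np.int64),
                    "end": np.array([iv.end for iv in ivs], dtype=np.int64),
                    "index": np.array(idx, dtype=np.int64),
                }
            self._by_chrom_cache = out
        return self._by_chrom_cache

    def total_covered_bases(self) -> int:
        """Covered bases after merging overlaps (each base counted once)."""
        return sum(len(iv) for iv in merge_intervals(self))

    def is_nonoverlapping(self) -> bool:
        for a, b in zip(self._intervals, self._intervals[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                return False
        return True


def merge_intervals(iset: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge intervals separated by a gap strictly smaller than ``max_gap``.

    With the default ``max_gap=0`` only genuinely overlapping intervals are
    merged (book-ended intervals stay separate).  Idempotent; with
    ``max_gap=0`` the union of covered bases is preserved.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    merged: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    for iv in iset:
        if cur is not None and iv.chrom == cur.chrom and iv.start < cur.end + max_gap:
            if iv.end > cur.end:
                cur = replace(cur, end=iv.end, name=None, score=None, summit=None)
        else:
            if cur is not None:
                merged.append(cur)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
        # normalise metadata away on the running interval
        cur = GenomicInterval(cur.chrom, cur.start, cur.end)
    if cur is not None:
        merged.append(cur)
    return IntervalSet(merged, label=iset.label)


def find_overlaps(
    query: IntervalSet, subject: IntervalSet, min_overlap: int = 1
) -> list[tuple[int, int]]:
    """All (query index, subject index) pairs with intersection >= min_overlap bp.

    Symmetric: swapping the arguments transposes the index pairs.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    pairs: list[tuple[int, int]] = []
    subj = subject.by_chrom()
    for chrom, q in query.by_chrom().items():
        if chrom not in subj:
            continue
        s = subj[chrom]
        max_len = int((s["end"] - s["start"]).max())
        # candidates: subject start in [q.start - max_len, q.end)
        lo = np.searchsorted(s["start"], q["start"] - max_len, side="left")
        hi = np.searchsorted(s["start"], q["end"], side="left")
        for qi, ql, qh, qs, qe in zip(q["index"], lo, hi, q["start"], q["end"]):
            if ql >= qh:
                continue
            ov = np.minimum(qe, s["end"][ql:qh]) - np.maximum(qs, s["start"][ql:qh])
            keep = np.nonzero(ov >= min_overlap)[0]
            pairs.extend((int(qi), int(s["index"][ql + k])) for k in keep)
    pairs.sort()
    return pairs


def extend_around_center(
    iset: IntervalSet, flank: int, chrom_sizes: Mapping[str, int]
) -> IntervalSet:
    """Replace each interval by [center - flank, center + flank) clipped to the
    chromosome; ``flank=0`` yields the single center base."""
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    out = []
    for iv in iset:
        if iv.chrom not in chrom_sizes:
            raise KeyError(f"no chromosome size for {iv.chrom!r}")
        c = iv.center
        start = max(0, c - flank)
        end = min(chrom_sizes[iv.chrom], c + flank if flank > 0 else c + 1)
        end = max(end, start + 1) if end > 0 else 1
        out.append(GenomicInterval(iv.chrom, start, end, iv.strand, iv.name, iv.score))
    return IntervalSet(out, label=iset.label)


# ---------------------------------------------------------------------------
# File I/O: BED3 / BED6 / ENCODE narrowPeak (tab-separated, no header)
# ---------------------------------------------------------------------------

FORMATS = ("bed3", "bed6", "narrowpeak")


class RegionParseError(ValueError):
    pass


def _parse_line(line: str, fmt: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    want = {"bed3": 3, "bed6": 6, "narrowpeak": 10}[fmt]
    if len(fields) < want:
        raise RegionParseError(f"line {lineno}: expected >= {want} fields, got {len(fields)}")
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise RegionParseError(f"line {lineno}: non-integer coordinates: {exc}") from None
    name = score = summit = None
    strand = "."
    if fmt in ("bed6", "narrowpeak"):
        name = fields[3] if fields[3] != "." else None
        score = float(fields[4]) if fields[4] != "." else None
        strand = fields[5] if fields[5] in STRANDS else "."
    if fmt == "narrowpeak":
        score = float(fields[6])  # signalValue carries the peak score
        raw_summit = int(fields[9])
        summit = None if raw_summit == -1 else raw_summit
    try:
        return GenomicInterval(chrom, start, end, strand, name, score, summit)
    except ValueError as exc:
        raise RegionParseError(f"line {lineno}: {exc}") from None


def read_regions(path, fmt: str = "bed3") -> IntervalSet:
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            out.append(_parse_line(line, fmt, lineno))
    return IntervalSet(out)


def write_regions(iset: IntervalSet, path, fmt: str = "bed3") -> None:
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")
    with open(path, "w") as fh:
        for i, iv in enumerate(iset):
            name = iv.name if iv.name is not None else f"region_{i}"
            score = iv.score if iv.score is not None else 0
            if fmt == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif fmt == "bed6":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")
            else:
                summit = -1 if iv.summit is None else iv.summit
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}"
                    f"\t{score:g}\t-1\t-1\t{summit}\n"
                )
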
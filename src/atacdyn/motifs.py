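"""Position weight matrices: JASPAR pfm I/O, exact p-value thresholds, scanning.

Scores are log2 odds of the motif model against a background base
composition.  The score threshold for a scan p-value is computed *exactly* by
dynamic programming over the distribution of the (discretised) score under
the background model, the same construction used by MOODS/TFMPvalue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .regions import GenomicInterval, IntervalSet

__all__ = [
    "PWM",
    "MotifHit",
    "read_jaspar_pfm",
    "make_cdx_like_pwm",
    "score_threshold",
    "scan_pwm",
]

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

SCALE = 1000  # score discretisation: 1/1000 bit granularity


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else -> 255 (treated as a gap)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PWM:
    """A probability matrix over ACGT with log2-odds scoring.

    ``probs`` is 4 x W (rows A,C,G,T), columns summing to 1 after the
    pseudocount applied at construction.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape[0] != 4 or p.shape[1] < 4:
            raise ValueError(f"probs must be 4 x W with W >= 4, got {p.shape}")
        if not np.allclose(p.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[:, None])

    @property
    def scaled_log_odds(self) -> np.ndarray:
        """Integer score matrix (log2 odds x SCALE, rounded)."""
        return np.rint(self.log_odds * SCALE).astype(np.int64)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id + "_rc", self.probs[::-1, ::-1], self.background)

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    ) -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(motif_id, c / c.sum(axis=0, keepdims=True), np.asarray(background))


def read_jaspar_pfm(path, pseudocount: float = 0.5) -> PWM:
    """Read a JASPAR pfm file: ``>ID name`` header then 4 count rows
    (A, C, G, T order), with or without ``A [ ... ]`` row labels."""
    motif_id = "motif"
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                motif_id = line[1:].split()[0]
                continue
            if line[0] in "ACGTacgt" and not line.split()[0].replace(".", "").isdigit():
                line = line[1:]
            line = line.replace("[", " ").replace("]", " ")
            rows.append([float(tok) for tok in line.split()])
    if len(rows) != 4:
        raise ValueError(f"expected 4 count rows (ACGT), got {len(rows)}")
    return PWM.from_counts(motif_id, np.array(rows), pseudocount=pseudocount)


def write_jaspar_pfm(pwm: PWM, path, depth: int = 100) -> None:
    counts = np.rint(pwm.probs * depth).astype(int)
    with open(path, "w") as fh:
        fh.write(f">{pwm.motif_id}\n")
        for b, row in zip(BASES, counts):
            fh.write(f"{b} [ " + " ".join(str(v) for v in row) + " ]\n")


def make_cdx_like_pwm() -> PWM:
    """A caudal-type homeodomain motif (TTTAT[G/A]-core, width 8), used as the
    simulator's default planted motif."""
    counts = np.array(
        [
            #  T   T   T   A   T   G   A   T   (consensus along columns)
            [4, 2, 3, 85, 2, 10, 80, 5],    # A
            [6, 3, 2, 5, 3, 5, 5, 10],      # C
            [5, 3, 2, 5, 3, 75, 10, 10],    # G
            [85, 92, 93, 5, 92, 10, 5, 75], # T
        ],
        dtype=float,
    )
    return PWM.from_counts("CDXL1", counts)


# ---------------------------------------------------------------------------
# Exact score distribution under the background (dynamic programming)
# ---------------------------------------------------------------------------

def score_distribution(pwm: PWM) -> tuple[np.ndarray, int]:
    """Exact pmf of the discretised score of a random background word.

    Returns ``(probs, offset)`` where ``probs[k]`` is the probability of
    scaled score ``k + offset``.
    """
    scaled = pwm.scaled_log_odds
    bg = pwm.background
    dist = np.array([1.0])
    offset = 0
    for j in range(pwm.width):
        col = scaled[:, j]
        lo, hi = int(col.min()), int(col.max())
        new = np.zeros(len(dist) + (hi - lo), dtype=float)
        for b in range(4):
            new[col[b] - lo : col[b] - lo + len(dist)] += bg[b] * dist
        dist = new
        offset += lo
    return dist, offset


def score_threshold(pwm: PWM, p_value: float) -> int:
    """Smallest scaled score t with P(score >= t) <= p_value under background.

    Returned on the scaled-integer score axis; ``max_scaled + 1`` (no word
    passes) when even the best word is too probable.
    """
    if not (0 < p_value <= 1):
        raise ValueError(f"p_value must be in (0, 1], got {p_value}")
    dist, offset = score_distribution(pwm)
    tail = np.cumsum(dist[::-1])[::-1]  # tail[k] = P(score >= k + offset)
    ok = np.nonzero((tail <= p_value) & (dist > 0))[0]  # achievable scores only
    if len(ok) == 0:
        return offset + len(dist)  # above the maximum: nothing passes
    return int(offset + ok[0])


@dataclass(frozen=True)
class MotifHit:
    """A motif match: ``interval`` spans the motif (width W), strand-aware."""

    interval: GenomicInterval
    score: float
    region_index: int | None = None

    @property
    def strand(self) -> str:
        return self.interval.strand


def _scan_codes(codes: np.ndarray, scaled: np.ndarray) -> np.ndarray:
    """Scaled score of every window; windows touching a gap get INT64_MIN/2."""
    W = scaled.shape[1]
    n = len(codes) - W + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    bad_val = np.iinfo(np.int64).min // (2 * max(W, 1))
    lut = np.empty((W, 256), dtype=np.int64)
    lut[:, :] = bad_val
    for j in range(W):
        lut[j, :4] = scaled[:, j]
    scores = np.zeros(n, dtype=np.int64)
    for j in range(W):
        scores += lut[j][codes[j : j + n]]
    return scores


def _resolve_overlaps(hits: list[MotifHit]) -> list[MotifHit]:
    """Overlapping same-strand hits on a chromosome -> keep best score
    (ties: leftmost)."""
    out: list[MotifHit] = []
    by_key: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits:
        by_key.setdefault((h.interval.chrom, h.interval.strand), []).append(h)
    for group in by_key.values():
        group.sort(key=lambda h: (-h.score, h.interval.start))
        taken: list[MotifHit] = []
        for h in group:
            if all(h.interval.overlap_length(t.interval) == 0 for t in taken):
                taken.append(h)
        out.extend(taken)
    out.sort(key=lambda h: h.interval.sort_key())
    return out


def scan_pwm(
    sequences: Mapping[str, str],
    pwm: PWM,
    p_threshold: float = 5e-5,
    search_space: IntervalSet | None = None,
    both_strands: bool = True,
    resolve_overlaps: bool = True,
) -> list[MotifHit]:
    """Scan sequences for motif matches above the exact p-value threshold.

    ``search_space``: restrict hits to windows fully inside these intervals
    (e.g. +/- 5 kb around peak summits); ``None`` scans genome-wide.
    Overlapping same-strand hits are resolved to the best-scoring one.
    """
    W = pwm.width
    thr = score_threshold(pwm, p_threshold)
    matrices = [("+", pwm.scaled_log_odds)]
    if both_strands:
        matrices.append(("-", pwm.reverse_complement().scaled_log_odds))
    allowed: dict[str, list[tuple[int, int]]] | None = None
    if search_space is not None:
        allowed = {}
        from .regions import merge_intervals

        for iv in merge_intervals(search_space, max_gap=1):
            allowed.setdefault(iv.chrom, []).append((iv.start, iv.end))
    hits: list[MotifHit] = []
    for chrom, seq in sequences.items():
        codes = encode(seq)
        spans = [(0, len(seq))] if allowed is None else allowed.get(chrom, [])
        for span_start, span_end in spans:
            sub = codes[max(0, span_start) : min(len(seq), span_end)]
            if len(sub) < W:
                continue
            for strand, scaled in matrices:
                scores = _scan_codes(sub, scaled)
                idx = np.nonzero(scores >= thr)[0]
                for i in idx:
                    start = max(0, span_start) + int(i)
                    exact = float(scores[i]) / SCALE
                    hits.append(
                        MotifHit(
                            GenomicInterval(chrom, start, start + W, strand),
                            score=exact,
                        )
                    )
    if resolve_overlaps:
        hits = _resolve_overlaps(hits)
    return hits
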
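"""Irreproducible discovery rate: replicate combination of peak calls.

Model: the rank-transformed replicate score pairs follow a two-component
Gaussian copula mixture — a reproducible component, bivariate normal with
mean (mu, mu), variance sigma^2 and correlation rho, and a noise component,
independent standard bivariate normal.  Parameters are fitted by EM on
pseudo-scores obtained by inverting the mixture marginal CDF at the
empirical CDF of each replicate's scores.  The local idr of a peak is its
posterior probability of belonging to the noise component; the global IDR
at a peak is the running mean of the sorted local values (the expected rate
of irreproducible discoveries among all peaks at least as reproducible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats

from .peaks import PeakCall
from .regions import GenomicInterval, IntervalSet

__all__ = ["IdrResult", "estimate_idr", "match_replicate_peaks", "combine_replicates"]

_MIN_PEAKS = 50


@dataclass
class IdrResult:
    local_idr: np.ndarray   # posterior noise probability, per peak
    global_idr: np.ndarray  # cumulative-mean IDR in the input order
    pi1: float              # reproducible fraction
    rho: float              # reproducible-component correlation
    mu: float               # reproducible-component shift
    sigma2: float           # reproducible-component variance
    n_iter: int
    loglik: float


def _ecdf(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x, method="average")
    return ranks / (len(x) + 1)


def _marginal_inverse(
    u: np.ndarray, pi1: float, mu: float, sigma: float
) -> np.ndarray:
    """Invert G(z) = pi1 Phi((z-mu)/sigma) + (1-pi1) Phi(z) on a dense grid."""
    lo = min(-5.0, mu - 5 * sigma)
    hi = max(5.0, mu + 5 * sigma)
    grid = np.linspace(lo, hi, 4096)
    G = pi1 * stats.norm.cdf((grid - mu) / sigma) + (1 - pi1) * stats.norm.cdf(grid)
    return np.interp(u, G, grid)


def _bvn_logpdf(z1, z2, mu, sigma2, rho):
    q = (
        (z1 - mu) ** 2 - 2 * rho * (z1 - mu) * (z2 - mu) + (z2 - mu) ** 2
    ) / (sigma2 * (1 - rho**2))
    return -np.log(2 * np.pi * sigma2 * np.sqrt(1 - rho**2)) - q / 2


def estimate_idr(
    scores_rep1: np.ndarray,
    scores_rep2: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> IdrResult:
    """Fit the copula mixture to matched per-peak replicate scores.

    Initialisation mu=1, sigma^2=1, rho=0.5, pi1=0.5; EM stops when the
    log-likelihood changes by less than ``tol`` or at ``max_iter``.
    """
    s1 = np.asarray(scores_rep1, dtype=float)
    s2 = np.asarray(scores_rep2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValueError("replicate score vectors must be 1-D and matched")
    n = len(s1)
    if n < _MIN_PEAKS:
        raise ValueError(f"need >= {_MIN_PEAKS} matched peaks, got {n}")
    if not (np.isfinite(s1).all() and np.isfinite(s2).all()):
        raise ValueError("scores must be finite")
    if np.ptp(s1) == 0 or np.ptp(s2) == 0:
        raise ValueError("degenerate input: constant scores in a replicate")
    u1, u2 = _ecdf(s1), _ecdf(s2)
    pi1, rho, mu, sigma2 = 0.5, 0.5, 1.0, 1.0
    ll_old = -np.inf
    gamma = np.full(n, pi1)
    it = 0
    for it in range(1, max_iter + 1):
        sigma = np.sqrt(sigma2)
        z1 = _marginal_inverse(u1, pi1, mu, sigma)
        z2 = _marginal_inverse(u2, pi1, mu, sigma)
        log_f1 = _bvn_logpdf(z1, z2, mu, sigma2, rho)
        log_f0 = _bvn_logpdf(z1, z2, 0.0, 1.0, 0.0)
        a = np.log(pi1) + log_f1
        b = np.log1p(-pi1) + log_f0
        m = np.maximum(a, b)
        ll = float(np.sum(m + np.log(np.exp(a - m) + np.exp(b - m))))
        gamma = special.expit(a - b)
        # M step
        w = gamma.sum()
        pi1 = float(np.clip(w / n, 1e-4, 1 - 1e-4))
        # identifiability: the reproducible component is shifted up (mu >= 0)
        # and genuinely correlated (rho bounded away from 0), otherwise the
        # two components coincide on null data and the fit degenerates
        mu = float(max(np.sum(gamma * (z1 + z2)) / (2 * w), 0.0))
        d1, d2 = z1 - mu, z2 - mu
        sigma2 = float(max(np.sum(gamma * (d1**2 + d2**2)) / (2 * w), 1e-6))
        rho = float(np.clip(np.sum(gamma * d1 * d2) / (w * sigma2), 0.1, 0.999))
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    local = 1.0 - gamma
    order = np.argsort(local, kind="mergesort")
    cum = np.cumsum(local[order]) / np.arange(1, n + 1)
    global_idr = np.empty(n)
    global_idr[order] = cum
    return IdrResult(
        local_idr=local,
        global_idr=global_idr,
        pi1=pi1,
        rho=rho,
        mu=mu,
        sigma2=sigma2,
        n_iter=it,
        loglik=ll,
    )


def match_replicate_peaks(
    peaks_rep1: list[PeakCall], peaks_rep2: list[PeakCall]
) -> list[tuple[int, int]]:
    """Reciprocal-best-overlap matching of two replicate peak lists.

    Best partner = largest intersection length, ties broken by the smaller
    start coordinate; only reciprocal pairs are returned.
    """
    from .regions import find_overlaps

    a = IntervalSet(
        GenomicInterval(p.interval.chrom, p.interval.start, p.interval.end, name=str(i))
        for i, p in enumerate(peaks_rep1)
    )
    b = IntervalSet(
        GenomicInterval(p.interval.chrom, p.interval.start, p.interval.end, name=str(j))
        for j, p in enumerate(peaks_rep2)
    )
    fwd: dict[int, tuple[int, int, int]] = {}  # i -> (ov, partner_start, j)
    rev: dict[int, tuple[int, int, int]] = {}
    for qi, si in find_overlaps(a, b):
        i, j = int(a[qi].name), int(b[si].name)
        ov = a[qi].overlap_length(b[si])
        cand_fwd = (ov, b[si].start, j)
        cur = fwd.get(i)
        if cur is None or ov > cur[0] or (ov == cur[0] and b[si].start < cur[1]):
            fwd[i] = cand_fwd
        cur = rev.get(j)
        if cur is None or ov > cur[0] or (ov == cur[0] and a[qi].start < cur[1]):
            rev[j] = (ov, a[qi].start, i)
    return sorted(
        (i, j) for i, (_, _, j) in fwd.items() if rev.get(j, (0, 0, -1))[2] == i
    )


def combine_replicates(
    peaks_rep1: list[PeakCall],
    peaks_rep2: list[PeakCall],
    idr_threshold: float = 0.1,
    use_global: bool = True,
    label: str | None = None,
) -> IntervalSet:
    """Matched replicate peaks passing IDR <= threshold, merged to the union
    interval of each passing pair.  ``use_global=False`` thresholds the local
    idr instead of the running-mean global IDR."""
    pairs = match_replicate_peaks(peaks_rep1, peaks_rep2)
    if not pairs:
        warnings.warn("no matched replicate peaks; returning empty set")
        return IntervalSet(label=label)
    s1 = np.array([peaks_rep1[i].score for i, _ in pairs])
    s2 = np.array([peaks_rep2[j].score for _, j in pairs])
    res = estimate_idr(s1, s2)
    values = res.global_idr if use_global else res.local_idr
    keep = values <= idr_threshold
    out = []
    for (i, j), ok in zip(pairs, keep):
        if not ok:
            continue
        a, b = peaks_rep1[i].interval, peaks_rep2[j].interval
        out.append(
            GenomicInterval(a.chrom, min(a.start, b.start), max(a.end, b.end))
        )
    return IntervalSet(out, label=label)
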
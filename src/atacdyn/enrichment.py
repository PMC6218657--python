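"""Region-set enrichment, gene association and distribution comparisons.

Two enrichment modes mirror two standard procedures: a region-unit
one-sided Fisher exact test against a universe of regions (LOLA-style, for
TF peak-set enrichment) and a base-pair-fraction one-sided binomial test
(annotation-style, for enhancer catalogues).  Gene association follows the
GREAT recipe: a basal regulatory domain of 5 kb upstream / 1 kb downstream
of the TSS, extended toward the neighbouring genes' basal domains up to
1 Mb per side.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .differential import benjamini_hochberg
from .motifs import PWM, scan_pwm
from .regions import (
    GenomicInterval,
    IntervalSet,
    extend_around_center,
    find_overlaps,
    merge_intervals,
)

__all__ = [
    "EnrichmentResult",
    "ComparisonResult",
    "GeneModel",
    "overlap_proportion",
    "fisher_enrichment",
    "binomial_enrichment",
    "annotate_genomic_context",
    "assign_regions_to_genes",
    "regulatory_domains",
    "compare_lfc_distributions",
    "accessibility_correlation",
    "known_motif_enrichment",
    "read_gene_models",
]

BASAL_UPSTREAM = 5000
BASAL_DOWNSTREAM = 1000
EXTENSION_CAP = 1_000_000
ENRICHED_ALPHA = 0.01


@dataclass
class EnrichmentResult:
    target_id: str
    support: int            # query regions hitting the target
    n_query: int
    effect: float           # odds ratio (Fisher) or fold enrichment (binomial)
    pvalue: float
    padj: float = np.nan
    enriched: bool = False


@dataclass
class ComparisonResult:
    statistic: float        # rank-sum W or Pearson r
    pvalue: float | None
    n_a: int
    n_b: int
    method: str = ""


def _query_hits(query: IntervalSet, reference: IntervalSet, min_overlap: int = 1) -> np.ndarray:
    hit = np.zeros(len(query), dtype=bool)
    for qi, _ in find_overlaps(query, reference, min_overlap=min_overlap):
        hit[qi] = True
    return hit


def overlap_proportion(
    query: IntervalSet, reference: IntervalSet, min_overlap: int = 1
) -> float:
    """Fraction of query regions with >= min_overlap bp overlap in reference."""
    if len(query) == 0:
        raise ValueError("empty query set")
    return float(_query_hits(query, reference, min_overlap).mean())


def fisher_enrichment(
    query_ids: set[str],
    target_sets: dict[str, IntervalSet],
    universe: IntervalSet,
    alpha: float = ENRICHED_ALPHA,
) -> list[EnrichmentResult]:
    """Region-unit one-sided Fisher enrichment of the query within the
    universe, per target set, BH-corrected across targets.

    ``query_ids`` are interval names (or an IntervalSet whose names are
    used) that must all be present in the universe; a universe region
    "hits" a target when it overlaps it by >= 1 bp.
    """
    if isinstance(query_ids, IntervalSet):
        query_ids = {iv.name for iv in query_ids}
    names = [iv.name for iv in universe]
    if len(set(names)) != len(names):
        raise ValueError("universe regions must carry unique names")
    name_set = set(names)
    missing = set(query_ids) - name_set
    if missing:
        raise ValueError(f"query not a subset of universe: e.g. {sorted(missing)[:3]}")
    in_query = np.array([n in query_ids for n in names])
    results: list[EnrichmentResult] = []
    for target_id, target in target_sets.items():
        hit = _query_hits(universe, target)
        a = int((in_query & hit).sum())          # query & target
        b = int((in_query & ~hit).sum())         # query only
        c = int((~in_query & hit).sum())         # target only
        d = int((~in_query & ~hit).sum())        # neither
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        odds = np.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c > 0 else np.nan
        )
        results.append(
            EnrichmentResult(target_id, a, int(in_query.sum()), float(odds), float(p))
        )
    padj = benjamini_hochberg([r.pvalue for r in results])
    for r, q in zip(results, padj):
        r.padj = float(q)
        r.enriched = bool(q < alpha)
    return results


def binomial_enrichment(
    query: IntervalSet, annotation: IntervalSet, genome_size: int
) -> EnrichmentResult:
    """One-sided binomial enrichment of query regions in an annotation.

    f = merged annotation bases / genome size; k of n query regions overlap
    the annotation; p = P(X >= k), X ~ Binomial(n, f); fold = (k/n)/f.
    """
    if len(query) == 0:
        raise ValueError("empty query set")
    covered = annotation.total_covered_bases()
    if genome_size < covered:
        raise ValueError("genome_size smaller than annotation coverage")
    f = covered / genome_size
    n = len(query)
    k = int(_query_hits(query, annotation).sum())
    if f == 0:
        if k > 0:
            raise ValueError("annotation covers zero bases but query overlaps it")
        return EnrichmentResult("annotation", 0, n, np.nan, 1.0)
    p = float(stats.binom.sf(k - 1, n, f))
    fold = (k / n) / f
    return EnrichmentResult("annotation", k, n, fold, min(p, 1.0))


# ---------------------------------------------------------------------------
# Gene models, genomic context and GREAT-style association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int          # 0-based TSS position
    strand: str
    start: int        # transcript span
    end: int
    exons: tuple[tuple[int, int], ...] = ()


def read_gene_models(path, fmt: str = "bed6") -> list[GeneModel]:
    """BED6: one line per gene, TSS = start (+) or end-1 (-); BED12 adds
    exon blocks."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            tss = start if strand != "-" else end - 1
            exons: tuple[tuple[int, int], ...] = ()
            if fmt == "bed12" and len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
            genes.append(GeneModel(name, chrom, tss, strand, start, end, exons))
    return genes


def annotate_genomic_context(
    regions: IntervalSet,
    gene_models: list[GeneModel],
    promoter_window: tuple[int, int] = (-3000, 3000),
) -> list[str]:
    """Per-region label by the feature containing the region midpoint, with
    priority promoter > exonic > intronic > distal intergenic."""
    import warnings

    if not gene_models:
        warnings.warn("no gene models: labelling everything distal intergenic")
        return ["distal_intergenic"] * len(regions)
    lo, hi = promoter_window
    labels: list[str] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for iv in regions:
        mid = iv.center
        label = "distal_intergenic"
        for g in by_chrom.get(iv.chrom, []):
            if g.strand != "-":
                prom = (g.tss + lo, g.tss + hi)
            else:
                prom = (g.tss - hi, g.tss - lo)
            if prom[0] <= mid < prom[1]:
                label = "promoter"
                break
            if any(s <= mid < e for s, e in g.exons):
                label = "exonic" if label != "promoter" else label
            elif g.start <= mid < g.end and label == "distal_intergenic":
                label = "intronic"
        labels.append(label)
    return labels


def regulatory_domains(
    gene_models: list[GeneModel],
    chrom_sizes: dict[str, int],
    cap: int = EXTENSION_CAP,
) -> dict[str, tuple[int, int, int, int]]:
    """Basal and extended domain per gene: {gene_id: (basal_start, basal_end,
    ext_start, ext_end)}.

    Basal = 5 kb upstream / 1 kb downstream of the TSS (strand-oriented,
    irrespective of other genes); each side then extends to the nearest
    other gene's basal-domain edge, capped at ``cap`` bp beyond the basal
    edge and at the chromosome bounds.
    """
    out: dict[str, tuple[int, int, int, int]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, genes in by_chrom.items():
        L = chrom_sizes[chrom]
        basal: dict[str, tuple[int, int]] = {}
        for g in genes:
            if g.strand != "-":
                b = (g.tss - BASAL_UPSTREAM, g.tss + BASAL_DOWNSTREAM)
            else:
                b = (g.tss - BASAL_DOWNSTREAM + 1, g.tss + BASAL_UPSTREAM + 1)
            basal[g.gene_id] = (max(0, b[0]), min(L, b[1]))
        for g in genes:
            bs, be = basal[g.gene_id]
            left_edges = [
                basal[o.gene_id][1]
                for o in genes
                if o.gene_id != g.gene_id and basal[o.gene_id][1] <= bs
            ]
            right_edges = [
                basal[o.gene_id][0]
                for o in genes
                if o.gene_id != g.gene_id and basal[o.gene_id][0] >= be
            ]
            ext_start = max(bs - cap, 0, max(left_edges) if left_edges else 0)
            ext_end = min(be + cap, L, min(right_edges) if right_edges else L)
            out[g.gene_id] = (bs, be, ext_start, ext_end)
    return out


def assign_regions_to_genes(
    regions: IntervalSet,
    gene_models: list[GeneModel],
    chrom_sizes: dict[str, int],
    cap: int = EXTENSION_CAP,
) -> dict[str, list[str]]:
    """Region -> gene list via extended regulatory domains (>= 1 bp overlap);
    keys are region names, values sorted gene ids."""
    domains = regulatory_domains(gene_models, chrom_sizes, cap)
    chrom_of = {g.gene_id: g.chrom for g in gene_models}
    dom_set = IntervalSet(
        GenomicInterval(chrom_of[gid], es, ee, name=gid)
        for gid, (_, _, es, ee) in domains.items()
    )
    out: dict[str, list[str]] = {
        iv.name or f"region_{i}": [] for i, iv in enumerate(regions)
    }
    for qi, si in find_overlaps(regions, dom_set):
        rname = regions[qi].name or f"region_{qi}"
        out[rname].append(dom_set[si].name)
    return {k: sorted(set(v)) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Distribution and correlation comparisons
# ---------------------------------------------------------------------------

def _rank_sum_W(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-sum statistic of sample a (midranks for ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled, method="average")
    return float(ranks[: len(a)].sum())


def compare_lfc_distributions(
    lfc_a,
    lfc_b,
    lfc_filter: float = 0.5,
) -> tuple[ComparisonResult, np.ndarray, np.ndarray]:
    """Two-sided Wilcoxon rank-sum comparison of two log2FC samples.

    Exact p by enumeration of group assignments when min(n, m) <= 8 and
    n + m <= 20; otherwise the normal approximation with tie correction and
    continuity correction.  Also returns the |log2FC| > ``lfc_filter``
    subsets of each sample (meta-profile membership).
    """
    a = np.asarray(lfc_a, dtype=float)
    b = np.asarray(lfc_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 values")
    n, m = len(a), len(b)
    W = _rank_sum_W(a, b)
    if min(n, m) <= 8 and n + m <= 20:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled, method="average")
        total = comb(n + m, n)
        extreme = 0
        mean_W = n * (n + m + 1) / 2
        dev = abs(W - mean_W)
        for idx in itertools.combinations(range(n + m), n):
            w = ranks[list(idx)].sum()
            if abs(w - mean_W) >= dev - 1e-9:
                extreme += 1
        p = extreme / total
        method = "exact"
    else:
        mean_W = n * (n + m + 1) / 2
        pooled = np.concatenate([a, b])
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / ((n + m) * (n + m - 1))
        var_W = n * m / 12 * ((n + m + 1) - tie_term)
        if var_W <= 0:
            p = 1.0
        else:
            z = (abs(W - mean_W) - 0.5) / np.sqrt(var_W)
            p = float(min(1.0, 2 * stats.norm.sf(max(z, 0.0))))
        method = "normal"
    result = ComparisonResult(W, min(p, 1.0), n, m, method)
    return result, a[np.abs(a) > lfc_filter], b[np.abs(b) > lfc_filter]


def accessibility_correlation(
    mean_counts_a, mean_counts_b, region_indices=None
) -> ComparisonResult:
    """Pearson r of log2(normalised mean + 1) over a region set."""
    a = np.asarray(mean_counts_a, dtype=float)
    b = np.asarray(mean_counts_b, dtype=float)
    if region_indices is not None:
        idx = np.asarray(region_indices, dtype=int)
        a, b = a[idx], b[idx]
    if len(a) < 3:
        raise ValueError("need >= 3 regions for a correlation")
    la, lb = np.log2(a + 1), np.log2(b + 1)
    if la.std() == 0 or lb.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(la, lb)
    return ComparisonResult(float(r), float(p), len(a), len(b), "pearson")


def known_motif_enrichment(
    foreground: IntervalSet,
    background: IntervalSet,
    pwms: list[PWM],
    sequences: dict[str, str],
    chrom_sizes: dict[str, int],
    flank: int = 150,
    p_threshold: float = 5e-5,
    alpha: float = ENRICHED_ALPHA,
) -> list[EnrichmentResult]:
    """Known-motif enrichment of foreground vs background regions.

    Regions are recentred to +/- ``flank`` bp around their centres; a region
    is a hit when it contains >= 1 motif match; one-sided Fisher per motif,
    BH across motifs.  A motif with no hits anywhere is reported with
    p = 1 and NaN fold ("no support").
    """
    if len(background) == 0:
        raise ValueError("empty background set")
    fg = extend_around_center(foreground, flank, chrom_sizes)
    bg = extend_around_center(background, flank, chrom_sizes)
    results: list[EnrichmentResult] = []
    for pwm in pwms:
        hits_fg = _regions_with_hits(fg, pwm, sequences, p_threshold)
        hits_bg = _regions_with_hits(bg, pwm, sequences, p_threshold)
        a, b = int(hits_fg.sum()), int((~hits_fg).sum())
        c, d = int(hits_bg.sum()), int((~hits_bg).sum())
        if a + c == 0:
            results.append(EnrichmentResult(pwm.motif_id, 0, len(fg), np.nan, 1.0))
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        odds = np.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c > 0 else np.nan
        )
        results.append(EnrichmentResult(pwm.motif_id, a, len(fg), float(odds), float(p)))
    padj = benjamini_hochberg([r.pvalue for r in results])
    for r, q in zip(results, padj):
        r.padj = float(q)
        r.enriched = bool(q < alpha)
    return results


def _regions_with_hits(
    regions: IntervalSet, pwm: PWM, sequences: dict[str, str], p_threshold: float
) -> np.ndarray:
    hits = scan_pwm(sequences, pwm, p_threshold=p_threshold, search_space=regions)
    hit_set = IntervalSet(
        GenomicInterval(h.interval.chrom, h.interval.start, h.interval.end,
                        name=f"h{i}")
        for i, h in enumerate(hits)
    )
    return _query_hits(regions, hit_set) if len(hit_set) else np.zeros(len(regions), bool)
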
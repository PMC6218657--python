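"""Synthetic ATAC-seq fragment datasets with planted truth.

The generator states a small world that mirrors a directed-differentiation
time course: embryonic stem cells (D0) pushed toward anterior (D3A..D5A),
hindbrain (D4H, D5H) or spinal-cord (D3NMP, D4SC, D5SC) neural fates.  Ten
region classes carry the qualitative accessibility dynamics of that system —
e.g. an NMP class open only in the D3 FGF/WNT condition, an NMP/SC class
open at D3NMP and in spinal-cord conditions, an epiblast class open only at
D0 — with negative-binomial replicate noise, a bimodal (sub-nucleosomal /
mono-nucleosomal) fragment-length mixture, and Tn5 footprint protection at
planted motif sites.  Every downstream stage is tested against this planted
truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import PWM, make_cdx_like_pwm
from .peaks import CountMatrix, SampleInfo, FRAGMENT_COLUMNS
from .regions import GenomicInterval, IntervalSet

__all__ = [
    "CONDITIONS",
    "CLASS_LABELS",
    "OPEN_CONDITIONS",
    "SimConfig",
    "RegionTruth",
    "MotifTruth",
    "CapacityError",
    "default_class_profiles",
    "default_samples",
    "simulate_regions",
    "simulate_counts",
    "simulate_fragments",
    "simulate_genome",
    "simulate_dataset",
    "write_dataset",
    "read_fragments",
    "simulate_idr_scores",
    "simulate_insertion_matrix",
]

CONDITIONS = ("D0", "D3A", "D3NMP", "D4A", "D4H", "D4SC", "D5A", "D5H", "D5SC")

# conditions in which each region class is open (multiplier > 1)
OPEN_CONDITIONS: dict[str, frozenset[str]] = {
    "neural": frozenset({"D4A", "D4H", "D4SC", "D5A", "D5H", "D5SC"}),
    "anterior": frozenset({"D4A", "D5A"}),
    "hindbrain": frozenset({"D4H", "D5H"}),
    "spinal_cord": frozenset({"D4SC", "D5SC"}),
    "NMP": frozenset({"D3NMP"}),
    "NMP_SC": frozenset({"D3NMP", "D4SC", "D5SC"}),
    "A_H": frozenset({"D4A", "D4H", "D5A", "D5H"}),
    "H_SC": frozenset({"D4H", "D4SC", "D5H", "D5SC"}),
    "epiblast": frozenset({"D0"}),
    "background": frozenset(),
}
CLASS_LABELS = tuple(OPEN_CONDITIONS)


def default_class_profiles(
    open_multiplier: float = 6.0, closed_multiplier: float = 1.0
) -> dict[str, dict[str, float]]:
    return {
        label: {
            cond: (open_multiplier if cond in opens else closed_multiplier)
            for cond in CONDITIONS
        }
        for label, opens in OPEN_CONDITIONS.items()
    }


def default_samples(replicates: int = 3) -> tuple[SampleInfo, ...]:
    return tuple(
        SampleInfo(cond, rep) for cond in CONDITIONS for rep in range(1, replicates + 1)
    )


@dataclass(frozen=True)
class FragmentLengthMix:
    """Two-component normal mixture of fragment lengths (bp), truncated to
    [10, 2000]: a sub-nucleosomal and a mono-nucleosomal mode."""

    weights: tuple[float, float] = (0.55, 0.45)
    means: tuple[float, float] = (60.0, 200.0)
    sds: tuple[float, float] = (15.0, 40.0)
    lo: int = 10
    hi: int = 2000

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.means):
            raise ValueError("fragment length means must be > 0")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.random(n) < self.weights[0]
        x = np.where(
            comp,
            rng.normal(self.means[0], self.sds[0], n),
            rng.normal(self.means[1], self.sds[1], n),
        )
        lengths = np.rint(x).astype(np.int64)
        bad = (lengths < self.lo) | (lengths > self.hi)
        while bad.any():
            lengths[bad] = self.sample(int(bad.sum()), rng)
            bad = (lengths < self.lo) | (lengths > self.hi)
        return lengths

    def pmf(self, k: np.ndarray) -> np.ndarray:
        """Exact pmf of rounded, truncated lengths (the sampling law)."""
        k = np.asarray(k, dtype=float)
        def comp_cdf(x):
            return self.weights[0] * stats.norm.cdf(x, self.means[0], self.sds[0]) + (
                self.weights[1] * stats.norm.cdf(x, self.means[1], self.sds[1])
            )
        mass = comp_cdf(k + 0.5) - comp_cdf(k - 0.5)
        total = comp_cdf(self.hi + 0.5) - comp_cdf(self.lo - 0.5)
        return mass / total


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic dataset.

    Defaults are the package's stated world: 10 region classes x 100
    regions, open/closed accessibility multiplier 6 vs 1, NB dispersion
    0.05, baseline 100 fragments per accessible region per library, three
    replicates per condition, 10% background scatter, and a planted
    caudal-homeodomain motif in a quarter of the regions with footprint
    protection factor 0.2.
    """

    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 3_000_000), ("chr2", 3_000_000))
    regions_per_class: int = 100
    region_length: int = 400
    min_spacing: int = 500
    open_multiplier: float = 6.0
    closed_multiplier: float = 1.0
    class_profiles: Mapping[str, Mapping[str, float]] | None = None
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    fragment_length_mix: FragmentLengthMix = field(default_factory=FragmentLengthMix)
    samples: tuple[SampleInfo, ...] = field(default_factory=default_samples)
    motif_fraction: float = 0.25
    p_prot: float = 0.2
    background_fraction: float = 0.10
    # per-region baseline strength: lognormal sd on the log scale, drawn once
    # per region and shared by every sample (real peak strengths span orders
    # of magnitude and are a property of the region, not the library)
    region_strength_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not (0 < self.p_prot <= 1):
            raise ValueError("p_prot must be in (0, 1]")
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must be in [0, 1)")
        reps: dict[str, int] = {}
        for s in self.samples:
            reps[s.condition] = reps.get(s.condition, 0) + 1
        if reps and min(reps.values()) < 2:
            raise ValueError("need >= 2 replicates per condition")
        for label, prof in self.profiles().items():
            if any(v < 0 for v in prof.values()):
                raise ValueError(f"negative multiplier in class {label!r}")

    def profiles(self) -> dict[str, dict[str, float]]:
        if self.class_profiles is not None:
            return {k: dict(v) for k, v in self.class_profiles.items()}
        return default_class_profiles(self.open_multiplier, self.closed_multiplier)

    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def pwm(self) -> PWM:
        return make_cdx_like_pwm()

    def rng(self, *tags: int) -> np.random.Generator:
        """Deterministic substream: root seed + integer stage/sample tags."""
        return np.random.default_rng([int(self.seed)] + [int(t) for t in tags])


# substream tags
_T_REGIONS, _T_COUNTS, _T_FRAGS, _T_SEQ, _T_BG = 1, 2, 3, 4, 5


@dataclass(frozen=True)
class MotifTruth:
    position: int  # absolute start of the motif core
    strand: str
    bound: Mapping[str, bool]  # per condition


@dataclass(frozen=True)
class RegionTruth:
    interval: GenomicInterval
    class_label: str
    motif: MotifTruth | None = None
    strength: float = 1.0  # region-specific baseline multiplier, shared by samples

    def __post_init__(self) -> None:
        if self.motif is not None:
            if not (
                self.interval.start <= self.motif.position
                and self.motif.position < self.interval.end
            ):
                raise ValueError("motif site outside its region")


class CapacityError(ValueError):
    pass


def simulate_regions(config: SimConfig) -> tuple[IntervalSet, list[RegionTruth]]:
    """Place non-overlapping regions (>= min_spacing apart) and assign the
    ten class labels and planted motif sites; deterministic given the seed."""
    rng = config.rng(_T_REGIONS)
    profiles = config.profiles()
    labels = [lab for lab in profiles for _ in range(config.regions_per_class)]
    n = len(labels)
    if n == 0:
        return IntervalSet(label="truth"), []
    slot = config.region_length + config.min_spacing
    required = n * slot
    available = sum(L for _, L in config.chromosomes)
    if required > available:
        raise CapacityError(
            f"genome too small: need {required} bp for {n} regions, have {available} bp"
        )
    # allocate region counts per chromosome proportionally to length
    lengths = np.array([L for _, L in config.chromosomes], dtype=float)
    alloc = np.floor(lengths / lengths.sum() * n).astype(int)
    while alloc.sum() < n:
        alloc[int(np.argmax(lengths / (alloc + 1)))] += 1
    for (name, L), k in zip(config.chromosomes, alloc):
        if k * slot > L:
            raise CapacityError(f"chromosome {name} too small for {k} regions")
    rng.shuffle(labels)
    pwm = config.pwm()
    W = pwm.width
    intervals: list[GenomicInterval] = []
    truths: list[RegionTruth] = []
    i = 0
    for (chrom, L), k in zip(config.chromosomes, alloc):
        if k == 0:
            continue
        slack = L - k * slot
        offsets = np.sort(rng.integers(0, slack + 1, size=k))
        starts = offsets + np.arange(k) * slot + config.min_spacing // 2
        for s in starts:
            label = labels[i]
            iv = GenomicInterval(chrom, int(s), int(s) + config.region_length,
                                 name=f"r{i:05d}")
            motif = None
            if rng.random() < config.motif_fraction:
                margin = 50
                pos = int(rng.integers(iv.start + margin, iv.end - W - margin))
                strand = "+" if rng.random() < 0.5 else "-"
                opens = profiles[label]
                bound = {c: opens[c] > config.closed_multiplier for c in CONDITIONS}
                motif = MotifTruth(pos, strand, bound)
            strength = float(np.exp(rng.normal(0.0, config.region_strength_sd)))
            intervals.append(iv)
            truths.append(RegionTruth(iv, label, motif, strength))
            i += 1
    truths = sorted(truths, key=lambda t: t.interval.sort_key())
    return IntervalSet(intervals, label="truth"), truths


def _region_means(truths: Sequence[RegionTruth], config: SimConfig, condition: str) -> np.ndarray:
    profiles = config.profiles()
    return np.array(
        [
            config.baseline_mean * t.strength * profiles[t.class_label][condition]
            for t in truths
        ]
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion < 1e-10:
        out[pos] = rng.poisson(mean[pos])
        return out
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_counts(truths: Sequence[RegionTruth], config: SimConfig) -> CountMatrix:
    """Planted region x sample counts: NB(baseline x class multiplier,
    dispersion), one independent substream per sample."""
    regions = IntervalSet((t.interval for t in truths), label="truth")
    counts = np.zeros((len(truths), len(config.samples)), dtype=np.int64)
    for j, samp in enumerate(config.samples):
        rng = config.rng(_T_COUNTS, j)
        counts[:, j] = _nb_draw(rng, _region_means(truths, config, samp.condition),
                                config.dispersion)
    return CountMatrix(regions, list(config.samples), counts)


def simulate_fragments(
    truths: Sequence[RegionTruth],
    config: SimConfig,
    sample: SampleInfo | str,
) -> pd.DataFrame:
    """Fragment records for one library.

    Per-region fragment counts are NB draws; fragment midpoints are uniform
    in the region and lengths follow the bimodal mixture.  In regions whose
    planted motif is bound in this condition, fragments with a Tn5 insertion
    endpoint inside the motif core are kept with probability ``p_prot``
    per core endpoint (footprint protection).  A uniform genome-wide
    background adds ``background_fraction`` of the total.
    """
    if isinstance(sample, str):
        sample = SampleInfo.from_id(sample)
    try:
        j = [s.id for s in config.samples].index(sample.id)
    except ValueError:
        raise ValueError(f"unknown sample {sample.id!r}") from None
    rng = config.rng(_T_FRAGS, j)
    counts = _nb_draw(
        config.rng(_T_COUNTS, j),
        _region_means(truths, config, sample.condition),
        config.dispersion,
    )
    sizes = config.chrom_sizes()
    W = config.pwm().width
    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    for t, c in zip(truths, counts):
        if c == 0:
            continue
        L = sizes[t.interval.chrom]
        mids = t.interval.start + rng.random(c) * len(t.interval)
        lens = config.fragment_length_mix.sample(int(c), rng)
        fs = np.clip(np.rint(mids - lens / 2).astype(np.int64), 0, L - 1)
        fe = np.clip(fs + lens, fs + 1, L)
        if t.motif is not None and t.motif.bound.get(sample.condition, False):
            core_lo, core_hi = t.motif.position, t.motif.position + W
            plus_ins = fs + 4
            minus_ins = fe - 6
            in_core = ((plus_ins >= core_lo) & (plus_ins < core_hi)).astype(int) + (
                (minus_ins >= core_lo) & (minus_ins < core_hi)
            ).astype(int)
            keep = rng.random(len(fs)) < config.p_prot ** in_core
            fs, fe = fs[keep], fe[keep]
        chroms.append(np.full(len(fs), t.interval.chrom, dtype=object))
        starts.append(fs)
        ends.append(fe)
    n_signal = int(sum(len(s) for s in starts))
    # background scatter
    bg_rng = config.rng(_T_BG, j)
    bf = config.background_fraction
    n_bg = int(round(n_signal * bf / (1 - bf))) if bf > 0 else 0
    if n_bg > 0:
        names = [c for c, _ in config.chromosomes]
        lens_arr = np.array([L for _, L in config.chromosomes], dtype=float)
        which = bg_rng.choice(len(names), size=n_bg, p=lens_arr / lens_arr.sum())
        lens = config.fragment_length_mix.sample(n_bg, bg_rng)
        for ci, cname in enumerate(names):
            m = which == ci
            if not m.any():
                continue
            L = int(lens_arr[ci])
            mids = bg_rng.random(int(m.sum())) * L
            fl = lens[m]
            fs = np.clip(np.rint(mids - fl / 2).astype(np.int64), 0, L - 1)
            fe = np.clip(fs + fl, fs + 1, L)
            chroms.append(np.full(len(fs), cname, dtype=object))
            starts.append(fs)
            ends.append(fe)
    if not starts:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)
    df = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "start": np.concatenate(starts),
            "end": np.concatenate(ends),
            "sample": sample.id,
        }
    )
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def simulate_genome(truths: Sequence[RegionTruth], config: SimConfig) -> dict[str, str]:
    """Random sequence per chromosome with the motif consensus (strand-aware)
    planted at every truth motif site."""
    rng = config.rng(_T_SEQ)
    pwm = config.pwm()
    cons = pwm.consensus()
    comp = str.maketrans("ACGT", "TGCA")
    seqs: dict[str, np.ndarray] = {}
    for chrom, L in config.chromosomes:
        seqs[chrom] = rng.integers(0, 4, size=L).astype(np.uint8)
    base_codes = {b: i for i, b in enumerate("ACGT")}
    for t in truths:
        if t.motif is None:
            continue
        word = cons if t.motif.strand == "+" else cons.translate(comp)[::-1]
        arr = seqs[t.interval.chrom]
        arr[t.motif.position : t.motif.position + len(word)] = [
            base_codes[b] for b in word
        ]
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {c: lut[a].tobytes().decode("ascii") for c, a in seqs.items()}


@dataclass
class SyntheticDataset:
    config: SimConfig
    regions: IntervalSet
    truths: list[RegionTruth]
    fragments: pd.DataFrame  # all samples pooled, `sample` column
    sequences: dict[str, str] | None = None


def simulate_dataset(config: SimConfig, with_sequence: bool = False) -> SyntheticDataset:
    regions, truths = simulate_regions(config)
    frames = [simulate_fragments(truths, config, s) for s in config.samples]
    fragments = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=FRAGMENT_COLUMNS)
    )
    seqs = simulate_genome(truths, config) if with_sequence else None
    return SyntheticDataset(config, regions, truths, fragments, seqs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Emit fragments, truth regions (BED6 + class), motif truth table, the
    resolved config and a checksum manifest; returns {file: sha256}."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    frag_path = out / "fragments.tsv"
    dataset.fragments.to_csv(frag_path, sep="\t", index=False, header=False)
    bed_path = out / "truth_regions.bed"
    with open(bed_path, "w") as fh:
        for t in dataset.truths:
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t.\t{t.class_label}\n"
            )
    motif_path = out / "motif_truth.tsv"
    with open(motif_path, "w") as fh:
        fh.write("region_id\tchrom\tposition\tstrand\t" + "\t".join(CONDITIONS) + "\n")
        for t in dataset.truths:
            if t.motif is None:
                continue
            flags = "\t".join(str(int(t.motif.bound[c])) for c in CONDITIONS)
            fh.write(
                f"{t.interval.name}\t{t.interval.chrom}\t{t.motif.position}"
                f"\t{t.motif.strand}\t{flags}\n"
            )
    cfg_path = out / "config.json"
    cfg = asdict(replace(dataset.config, class_profiles=dataset.config.profiles()))
    cfg["samples"] = [s.id for s in dataset.config.samples]
    with open(cfg_path, "w") as fh:
        json.dump(cfg, fh, indent=2, default=list)
    files = [frag_path, bed_path, motif_path, cfg_path]
    if dataset.sequences is not None:
        fa = out / "genome.fa"
        with open(fa, "w") as fh:
            for chrom, seq in dataset.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        files.append(fa)
    manifest = {p.name: _sha256(p) for p in files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_fragments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS)
    return df


# ---------------------------------------------------------------------------
# Direct oracles for the replicate-combination and footprint stages
# ---------------------------------------------------------------------------

def simulate_idr_scores(
    n: int,
    pi1: float,
    rho: float,
    mu: float = 2.5,
    sigma: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matched replicate scores from the two-component copula world:
    reproducible pairs are correlated bivariate normal shifted by ``mu``,
    noise pairs independent standard normal.  Returns (s1, s2, labels)."""
    rng = rng or np.random.default_rng()
    labels = (rng.random(n) < pi1).astype(int)
    z = rng.standard_normal((n, 2))
    s1 = np.where(labels == 1, mu + sigma * z[:, 0], z[:, 0])
    corr = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
    s2 = np.where(labels == 1, mu + sigma * corr, rng.standard_normal(n))
    return s1, s2, labels


def simulate_insertion_matrix(
    n_hits: int,
    frac_bound: float = 0.5,
    width: int = 8,
    flank: int = 150,
    unbound_rate: float = 0.05,
    flank_enrichment: float = 5.0,
    p_prot: float = 0.2,
    score_shift: float = 1.5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-motif-site insertion count rows with planted bound/unbound labels.

    Unbound rows: Poisson(unbound_rate) at every window position.  Bound
    rows: flank rate ``flank_enrichment x unbound_rate``, motif-core rate
    additionally thinned by ``p_prot``.  PWM scores are normal, shifted up
    by ``score_shift`` for bound sites.  Returns (matrix, scores, labels).
    """
    rng = rng or np.random.default_rng()
    L = width + 2 * flank
    labels = (rng.random(n_hits) < frac_bound).astype(int)
    rates = np.full((n_hits, L), unbound_rate)
    bound_rates = np.full(L, unbound_rate * flank_enrichment)
    bound_rates[flank : flank + width] *= p_prot
    rates[labels == 1] = bound_rates
    matrix = rng.poisson(rates)
    scores = rng.normal(6.0, 1.5, n_hits) + score_shift * labels
    return matrix, scores, labels
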
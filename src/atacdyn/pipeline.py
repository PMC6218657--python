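"""End-to-end orchestration: simulate -> peaks -> IDR -> consensus -> counts
-> differential -> SOM -> footprints -> enrichment.

Each stage reads the previous stage's files from the run directory and
writes its own, so stages can be re-run individually; a manifest records
parameters, wall time, derived seeds and output checksums.  One root seed
drives everything; per-stage seeds are ``blake2b(f"{seed}:{stage}")`` folded
to 31 bits.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential as diff_mod
from . import enrichment as enr_mod
from . import footprints as fp_mod
from . import idr as idr_mod
from . import peaks as pk_mod
from . import som as som_mod
from .regions import GenomicInterval, IntervalSet, read_regions, write_regions
from .simulate import (
    CONDITIONS,
    FragmentLengthMix,
    SimConfig,
    default_samples,
    read_fragments,
    simulate_dataset,
    write_dataset,
)

__all__ = ["RunConfig", "ConfigError", "DependencyError", "validate_config",
           "run_pipeline", "stage_seed", "STAGES"]

log = logging.getLogger("atacdyn")

STAGES = (
    "simulate", "peaks", "idr", "consensus", "counts",
    "diff", "som", "footprint", "enrich",
)

_DEPENDENCIES: dict[str, list[str]] = {
    "simulate": [],
    "peaks": ["fragments.tsv"],
    "idr": ["peaks.done"],
    "consensus": ["idr.done"],
    "counts": ["consensus.bed", "fragments.tsv"],
    "diff": ["counts.tsv"],
    "som": ["diff.done", "counts.tsv"],
    "footprint": ["fragments.tsv", "genome.fa.done", "consensus.bed"],
    "enrich": ["som_regions.tsv", "truth_regions.bed", "consensus.bed"],
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class DependencyError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """All run parameters with the pipeline's standard thresholds."""

    seed: int = 0
    # simulation
    regions_per_class: int = 100
    region_length: int = 400
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    replicates: int = 3
    n_chromosomes: int = 2
    chromosome_length: int = 3_000_000
    open_multiplier: float = 6.0
    motif_fraction: float = 0.25
    p_prot: float = 0.2
    background_fraction: float = 0.10
    # stage thresholds
    peak_window: int = 300
    peak_step: int = 100
    peak_p: float = 0.01
    idr_threshold: float = 0.1
    lfc_min: float = 1.0
    alpha: float = 0.01
    grid_rows: int = 5
    grid_cols: int = 5
    epochs: int = 100
    flank: int = 150
    max_fragment_length: int = 100
    posterior_mode: str = "peak-summit"
    motif_p: float = 5e-5
    meta_lfc_filter: float = 0.5
    reference_condition: str = "D0"

    def sim_config(self) -> SimConfig:
        return SimConfig(
            seed=stage_seed(self.seed, "simulate"),
            chromosomes=tuple(
                (f"chr{i + 1}", self.chromosome_length) for i in range(self.n_chromosomes)
            ),
            regions_per_class=self.regions_per_class,
            region_length=self.region_length,
            open_multiplier=self.open_multiplier,
            baseline_mean=self.baseline_mean,
            dispersion=self.dispersion,
            samples=default_samples(self.replicates),
            motif_fraction=self.motif_fraction,
            p_prot=self.p_prot,
            background_fraction=self.background_fraction,
        )


_RANGES: dict[str, tuple[float, float]] = {
    "idr_threshold": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "peak_p": (0.0, 1.0),
    "motif_p": (0.0, 1.0),
    "p_prot": (0.0, 1.0),
    "background_fraction": (0.0, 0.999),
    "dispersion": (0.0, np.inf),
    "baseline_mean": (0.0, np.inf),
    "lfc_min": (0.0, np.inf),
    "meta_lfc_filter": (0.0, np.inf),
}
_MIN_INT = {
    "regions_per_class": 0, "region_length": 50, "replicates": 2,
    "n_chromosomes": 1, "chromosome_length": 10_000, "grid_rows": 2,
    "grid_cols": 2, "epochs": 1, "flank": 10, "peak_window": 50,
    "peak_step": 10, "max_fragment_length": 20, "seed": 0,
}


def validate_config(source) -> RunConfig:
    """Build a RunConfig from a YAML file path, a mapping, or None.

    All problems (unknown keys with suggestions, type errors, out-of-range
    values) are reported together in one ConfigError.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError([f"config root must be a mapping, got {type(raw).__name__}"])
    known = set(RunConfig.__dataclass_fields__)
    errors: list[str] = []
    clean: dict = {}
    for key, value in raw.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f' (did you mean "{hint[0]}"?)' if hint else ""
            errors.append(f"unknown key {key!r}{suffix}")
            continue
        ftype = RunConfig.__dataclass_fields__[key].type
        try:
            if key in _MIN_INT:
                value = int(value)
                if value < _MIN_INT[key]:
                    errors.append(f"{key} = {value} below minimum {_MIN_INT[key]}")
            elif key in _RANGES:
                value = float(value)
                lo, hi = _RANGES[key]
                if not (lo < value <= hi) and not (key == "lfc_min" and value == 0):
                    errors.append(f"{key} = {value} outside ({lo}, {hi}]")
            elif key in ("posterior_mode", "reference_condition"):
                value = str(value)
            else:
                value = type(getattr(RunConfig(), key))(value)
        except (TypeError, ValueError):
            errors.append(f"{key}: cannot convert {value!r}")
            continue
        clean[key] = value
    if clean.get("posterior_mode", "peak-summit") not in fp_mod.BOUND_THRESHOLDS:
        errors.append(
            f"posterior_mode must be one of {sorted(fp_mod.BOUND_THRESHOLDS)}"
        )
    if errors:
        raise ConfigError(errors)
    return RunConfig(**clean)


def stage_seed(root_seed: int, stage: str) -> int:
    digest = hashlib.blake2b(f"{root_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(outdir: Path, stage: str) -> None:
    for dep in _DEPENDENCIES[stage]:
        if not (outdir / dep).exists():
            raise DependencyError(
                f"stage {stage!r} requires {dep!r}; run the upstream stage first"
            )


def _touch(outdir: Path, name: str) -> None:
    (outdir / name).write_text("done\n")


# ---------------------------------------------------------------------------
# Stage bodies
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    ds = simulate_dataset(cfg.sim_config(), with_sequence=True)
    write_dataset(ds, outdir)
    _touch(outdir, "genome.fa.done")
    return [outdir / n for n in
            ("fragments.tsv", "truth_regions.bed", "motif_truth.tsv", "genome.fa")]


def _stage_peaks(cfg: RunConfig, outdir: Path) -> list[Path]:
    fragments = read_fragments(outdir / "fragments.tsv")
    sizes = cfg.sim_config().chrom_sizes()
    out = []
    for sid, sub in fragments.groupby("sample"):
        calls = pk_mod.call_candidate_peaks(
            sub, sizes, window=cfg.peak_window, step=cfg.peak_step,
            p_threshold=cfg.peak_p,
        )
        path = outdir / f"peaks_{sid}.narrowPeak"
        write_regions(pk_mod.peaks_to_intervals(calls, label=sid), path, "narrowpeak")
        out.append(path)
        log.info("peaks: %s -> %d candidate peaks", sid, len(calls))
    _touch(outdir, "peaks.done")
    return out


def _read_peakcalls(path: Path) -> list[pk_mod.PeakCall]:
    iset = read_regions(path, "narrowpeak")
    return [
        pk_mod.PeakCall(
            GenomicInterval(iv.chrom, iv.start, iv.end),
            score=iv.score or 0.0,
            summit=iv.summit if iv.summit is not None else len(iv) // 2,
        )
        for iv in iset
    ]


def _stage_idr(cfg: RunConfig, outdir: Path) -> list[Path]:
    out = []
    for cond in CONDITIONS:
        p1 = outdir / f"peaks_{cond}_r1.narrowPeak"
        p2 = outdir / f"peaks_{cond}_r2.narrowPeak"
        if not (p1.exists() and p2.exists()):
            continue
        combined = idr_mod.combine_replicates(
            _read_peakcalls(p1), _read_peakcalls(p2),
            idr_threshold=cfg.idr_threshold, label=cond,
        )
        path = outdir / f"idr_{cond}.bed"
        write_regions(combined, path, "bed3")
        out.append(path)
        log.info("idr: %s -> %d reproducible peaks", cond, len(combined))
    _touch(outdir, "idr.done")
    return out


def _stage_consensus(cfg: RunConfig, outdir: Path) -> list[Path]:
    sets = []
    for cond in CONDITIONS:
        path = outdir / f"idr_{cond}.bed"
        if path.exists():
            s = read_regions(path, "bed3")
            s.label = cond
            sets.append(s)
    consensus = pk_mod.build_consensus_peaks(sets)
    path = outdir / "consensus.bed"
    write_regions(
        IntervalSet(
            (GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.name, score=0.0)
             for iv in consensus),
            label="consensus",
        ),
        path,
        "bed6",
    )
    log.info("consensus: %d regions", len(consensus))
    return [path]


def _stage_counts(cfg: RunConfig, outdir: Path) -> list[Path]:
    consensus = read_regions(outdir / "consensus.bed", "bed6")
    fragments = read_fragments(outdir / "fragments.tsv")
    cm = pk_mod.count_fragments(fragments, consensus)
    path = outdir / "counts.tsv"
    cm.to_tsv(path)
    return [path]


def _stage_diff(cfg: RunConfig, outdir: Path) -> list[Path]:
    cm = pk_mod.CountMatrix.from_tsv(outdir / "counts.tsv")
    sf = diff_mod.estimate_size_factors(cm)
    out = []
    union: dict[tuple, GenomicInterval] = {}
    for cond in cm.conditions:
        if cond == cfg.reference_condition:
            continue
        res = diff_mod.nb_test(cm, sf, (cond, cfg.reference_condition))
        path = outdir / f"diff_{cond}_vs_{cfg.reference_condition}.tsv"
        res.to_csv(path, sep="\t", index=False)
        out.append(path)
        for iv in diff_mod.select_differential(res, cfg.lfc_min, cfg.alpha):
            key = (iv.chrom, iv.start, iv.end)
            union.setdefault(key, GenomicInterval(
                iv.chrom, iv.start, iv.end,
                name=(iv.name or "").split("|")[0] or None))
        log.info("diff: %s vs %s", cond, cfg.reference_condition)
    dpath = outdir / "differential_regions.bed"
    write_regions(IntervalSet(union.values(), label="differential"), dpath, "bed6")
    out.append(dpath)
    np.savetxt(outdir / "size_factors.tsv", sf[None, :], delimiter="\t", fmt="%.6g")
    _touch(outdir, "diff.done")
    return out


def _stage_som(cfg: RunConfig, outdir: Path) -> list[Path]:
    cm = pk_mod.CountMatrix.from_tsv(outdir / "counts.tsv")
    sf = diff_mod.estimate_size_factors(cm)
    diff_regions = read_regions(outdir / "differential_regions.bed", "bed6")
    diff_ids = {iv.name for iv in diff_regions}
    means = cm.condition_means(sf)
    mask = means.index.isin(diff_ids)
    sub = means[mask]
    Z = som_mod.zscore_rows(sub)
    grid, bmus = som_mod.train_som(
        Z, rows=cfg.grid_rows, cols=cfg.grid_cols,
        seed=stage_seed(cfg.seed, "som"), epochs=cfg.epochs,
    )
    assign = som_mod.label_clusters(grid, bmus, Z)
    region_lookup = {(iv.name or ""): iv for iv in cm.regions}
    rows = []
    for rid, unit, label in zip(Z.region_ids, assign.bmus, assign.region_labels):
        iv = region_lookup[rid]
        rows.append((iv.chrom, iv.start, iv.end, rid, unit, label))
    sdf = pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id",
                                      "unit", "cluster"])
    spath = outdir / "som_regions.tsv"
    sdf.to_csv(spath, sep="\t", index=False)
    gpath = outdir / "som_grid.tsv"
    pd.DataFrame(grid.weights, columns=Z.conditions).to_csv(gpath, sep="\t", index=False)
    log.info("som: %d regions over %d units, %d labelled groups",
             len(sdf), grid.n_units, len(assign.groups))
    return [spath, gpath]


def _stage_footprint(cfg: RunConfig, outdir: Path) -> list[Path]:
    from .motifs import make_cdx_like_pwm

    fragments = read_fragments(outdir / "fragments.tsv")
    sim = cfg.sim_config()
    # footprint the D3 FGF/WNT condition, pooling its replicates
    cond_samples = [s.id for s in sim.samples if s.condition == "D3NMP"]
    sub = fragments[fragments["sample"].isin(cond_samples)]
    events = fp_mod.extract_insertions(sub, cfg.max_fragment_length)
    seqs = _read_fasta(outdir / "genome.fa")
    consensus = read_regions(outdir / "consensus.bed", "bed6")
    from .regions import extend_around_center

    space = extend_around_center(consensus, 5000, sim.chrom_sizes())
    hits = fp_mod.scan_pwm(seqs, make_cdx_like_pwm(), p_threshold=cfg.motif_p,
                           search_space=space)
    matrix, kept = fp_mod.build_insertion_matrix(
        events, hits, flank=cfg.flank, chrom_sizes=sim.chrom_sizes()
    )
    paths = []
    if len(matrix) >= 100 and matrix.sum() > 0:
        scores = np.array([hits[i].score for i in kept])
        model = fp_mod.fit_footprint_model(matrix, scores)
        bound = fp_mod.classify_bound(model.posteriors, cfg.posterior_mode)
        fdf = pd.DataFrame(
            {
                "chrom": [hits[i].interval.chrom for i in kept],
                "start": [hits[i].interval.start for i in kept],
                "end": [hits[i].interval.end for i in kept],
                "strand": [hits[i].interval.strand for i in kept],
                "pwm_score": scores,
                "posterior": model.posteriors,
                "bound": bound.astype(int),
            }
        )
        fpath = outdir / "footprint_posteriors.tsv"
        fdf.to_csv(fpath, sep="\t", index=False)
        paths.append(fpath)
        log.info("footprint: %d motif hits, %d called bound", len(fdf),
                 int(bound.sum()))
    else:
        log.warning("footprint: too few motif hits (%d); stage skipped",
                    len(matrix))
    _touch(outdir, "footprint.done")
    return paths


def _stage_enrich(cfg: RunConfig, outdir: Path) -> list[Path]:
    som_df = pd.read_csv(outdir / "som_regions.tsv", sep="\t")
    consensus = read_regions(outdir / "consensus.bed", "bed6")
    truth = _read_truth_bed(outdir / "truth_regions.bed")
    target_sets = {
        label: IntervalSet(ivs, label=label) for label, ivs in truth.items()
    }
    rows = []
    for cluster, grp in som_df.groupby("cluster"):
        if cluster == som_mod.UNCLASSIFIED:
            continue
        query = set(grp["region_id"])
        results = enr_mod.fisher_enrichment(query, target_sets, consensus,
                                            alpha=cfg.alpha)
        for r in results:
            rows.append((cluster, r.target_id, r.support, r.n_query, r.effect,
                         r.pvalue, r.padj, int(r.enriched)))
    edf = pd.DataFrame(rows, columns=["cluster", "target", "support", "n_query",
                                      "odds_ratio", "pvalue", "padj", "enriched"])
    path = outdir / "enrichment.tsv"
    edf.to_csv(path, sep="\t", index=False)
    return [path]


def _read_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def _read_truth_bed(path: Path) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), name=f[3])
            out.setdefault(f[6], []).append(iv)
    return out


_STAGE_BODIES = {
    "simulate": _stage_simulate,
    "peaks": _stage_peaks,
    "idr": _stage_idr,
    "consensus": _stage_consensus,
    "counts": _stage_counts,
    "diff": _stage_diff,
    "som": _stage_som,
    "footprint": _stage_footprint,
    "enrich": _stage_enrich,
}


def run_pipeline(
    config: RunConfig,
    outdir,
    stages: list[str] | None = None,
) -> dict:
    """Run the requested stages (all by default) in dependency order and
    write ``run_manifest.json``; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest: dict = {
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
    }
    for stage in requested:
        _require(outdir, stage)
        seed = stage_seed(config.seed, stage)
        log.info("stage %s (seed %d)", stage, seed)
        t0 = time.monotonic()
        outputs = _STAGE_BODIES[stage](config, outdir)
        manifest["stages"][stage] = {
            "seed": seed,
            "wall_time_s": round(time.monotonic() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
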
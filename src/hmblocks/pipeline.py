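"""End-to-end orchestration: region construction → features → classifiers →
enrichment → positional profiles → ChIP metaprofiles → CTCF → Hi-C/TAD.

A :class:`RunConfig` either embeds a :class:`SimConfig` (synthetic run) or
points at a bundle directory of user-supplied inputs in the same formats the
generator writes. Every stage persists its outputs under ``outdir/<stage>/``
and reports row counts into the run manifest; the manifest plus the config
snapshot reproduce the run exactly (one global seed feeds per-stage
substreams).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ForestSpec, SplitSpec, rank_importances, train_evaluate
from .enrichment import cme_sweep, enrichment_table, select_discriminating
from .intervals import RegionSet
from .motifs import (
    FeatureMatrix,
    build_features,
    concat_features,
    hits_to_tsv,
    scan_regions,
)
from .positional import profile, write_profiles
from .regions import (
    BoundarySpec,
    assert_disjoint,
    derive_boundaries,
    exclude_tss_overlaps,
    gc_match,
    sample_controls,
)
from .signal import compare_sets, ctcf_stratify, metaprofile, normalize, region_frequency
from .simulate import SimConfig, SyntheticBundle, read_bundle, simulate_bundle
from .chromatin3d import strength_vs_random, tad_proximity

log = logging.getLogger(__name__)

STAGES = ("regions", "features", "classify", "enrich", "positional", "signal", "hic")


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    sim: SimConfig | None = None
    bundle_dir: Path | None = None
    boundary_spec: BoundarySpec = field(default_factory=BoundarySpec)
    n_controls: int | None = None  # None -> number of boundary regions
    p_threshold: float = 1e-4
    k_list: tuple[int, ...] = (20, 25, 40, 50)
    k_select: int = 50
    n_trees: int = 200
    m: int | None = None
    train_fraction: float = 0.70
    metaprofile_span: int = 20000
    comparison_mark: str = "H3K4me3"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.sim is None and self.bundle_dir is None:
            raise ValueError("config needs either a sim block or a bundle_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "boundary_spec" in sim:
                sim["boundary_spec"] = BoundarySpec(**sim["boundary_spec"])
            if "motif_width_range" in sim:
                sim["motif_width_range"] = tuple(sim["motif_width_range"])
            raw["sim"] = SimConfig(**sim)
        if "boundary_spec" in raw and raw["boundary_spec"] is not None:
            raw["boundary_spec"] = BoundarySpec(**raw["boundary_spec"])
        if "bundle_dir" in raw and raw["bundle_dir"] is not None:
            raw["bundle_dir"] = Path(raw["bundle_dir"])
        if "k_list" in raw:
            raw["k_list"] = tuple(raw["k_list"])
        return cls(**raw)

    def snapshot(self) -> dict:
        snap = asdict(self)
        snap["outdir"] = str(self.outdir)
        if self.bundle_dir is not None:
            snap["bundle_dir"] = str(self.bundle_dir)
        if self.sim is not None and math.isinf(snap["sim"]["tad_jitter_sd"]):
            snap["sim"]["tad_jitter_sd"] = "inf"
        # canonicalize to JSON types (tuples -> lists) so the written
        # manifest round-trips equal
        return json.loads(json.dumps(snap))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunContext:
    """Carries the bundle and lazily computed intermediates for one run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.counts: dict[str, int] = {}
        self._bundle: SyntheticBundle | None = None
        self._region_sets: dict[str, RegionSet] | None = None
        self._features: FeatureMatrix | None = None
        self._hits = None
        self._reports: dict[str, object] | None = None
        rootseq = np.random.SeedSequence(config.seed)
        self._substreams = {
            name: np.random.default_rng(child)
            for name, child in zip(STAGES, rootseq.spawn(len(STAGES)))
        }

    # -- inputs --------------------------------------------------------------
    @property
    def bundle(self) -> SyntheticBundle:
        if self._bundle is None:
            if self.config.sim is not None:
                self._bundle = simulate_bundle(self.config.sim)
            else:
                self._bundle = read_bundle(self.config.bundle_dir)
        return self._bundle

    def outdir(self, stage: str) -> Path:
        d = self.config.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    # -- stages --------------------------------------------------------------
    @property
    def region_sets(self) -> dict[str, RegionSet]:
        if self._region_sets is None:
            stage_regions(self)
        return self._region_sets

    @property
    def features(self) -> FeatureMatrix:
        if self._features is None:
            stage_features(self)
        return self._features

    @property
    def reports(self) -> dict:
        if self._reports is None:
            stage_classify(self)
        return self._reports


def stage_regions(ctx: RunContext) -> dict[str, RegionSet]:
    cfg = ctx.config
    bundle = ctx.bundle
    rng = ctx._substreams["regions"]
    sizes = bundle.chrom_sizes
    spec = cfg.boundary_spec
    length = spec.region_length
    boundaries = derive_boundaries(bundle.blocks, spec, sizes)
    n = cfg.n_controls or len(boundaries)
    promoters = exclude_tss_overlaps_promoters(
        bundle, boundaries, up=spec.flank_outside, down=spec.flank_inside
    )
    inside = sample_controls(
        bundle.blocks, boundaries, "inside", n, length, rng, sizes,
        allow_shortfall=True,
    )
    # outside controls also stay clear of promoter windows
    exclusion = RegionSet(
        list(boundaries.intervals) + list(promoters.intervals), label="exclude"
    )
    outside = sample_controls(
        bundle.blocks, exclusion, "outside", n, length, rng, sizes,
        allow_shortfall=True,
    )
    # GC-match each control class to the boundary set
    matched: dict[str, RegionSet] = {}
    for rs in (inside, outside, promoters):
        sel, shortfall = gc_match(boundaries, rs, bundle.genome, rng)
        matched[rs.label] = sel
        ctx.counts[f"gc_shortfall_{rs.label}"] = sum(shortfall.values())
    assert_disjoint(boundaries, matched["inside"], matched["outside"], matched["promoter"])
    boundaries_notss = exclude_tss_overlaps(boundaries, bundle.tss)
    sets = {
        "boundary": boundaries,
        "boundary_notss": boundaries_notss,
        "inside": matched["inside"],
        "outside": matched["outside"],
        "promoter": matched["promoter"],
    }
    out = ctx.outdir("regions")
    for name, rs in sets.items():
        rs.to_bed(out / f"{name}.bed")
        ctx.counts[f"n_{name}"] = len(rs)
    ctx._region_sets = sets
    return sets


def exclude_tss_overlaps_promoters(
    bundle: SyntheticBundle, boundaries: RegionSet, up: int = 5000, down: int = 1000
) -> RegionSet:
    """Promoter windows that stay clear of blocks and boundary regions."""
    from .regions import derive_promoters

    promoters = derive_promoters(bundle.tss, up=up, down=down)
    keep = [
        i
        for i, iv in enumerate(promoters.intervals)
        if not boundaries.any_overlap(iv) and not bundle.blocks.any_overlap(iv)
    ]
    return promoters.subset(keep)


def stage_features(ctx: RunContext) -> FeatureMatrix:
    cfg = ctx.config
    bundle = ctx.bundle
    sets = ctx.region_sets
    parts = []
    all_hits = []
    for name in ("boundary", "inside", "outside", "promoter"):
        rs = sets[name]
        if len(rs) == 0:
            continue
        hits = scan_regions(rs, bundle.motif_library, bundle.genome, cfg.p_threshold)
        all_hits += hits
        parts.append(
            build_features(
                rs, bundle.motif_library, bundle.cpg_islands, bundle.genome,
                cfg.p_threshold, hits=hits,
            )
        )
    features = concat_features(*parts)
    out = ctx.outdir("features")
    features.to_tsv(out / "features.tsv")
    hits_to_tsv(all_hits, out / "hits.tsv")
    ctx.counts["n_hits"] = len(all_hits)
    ctx.counts["n_feature_columns"] = features.n_features
    ctx._features = features
    ctx._hits = all_hits
    return features


def stage_classify(ctx: RunContext) -> dict:
    cfg = ctx.config
    features = ctx.features
    out = ctx.outdir("classify")
    reports = {}
    for control in ("inside", "outside", "promoter"):
        sub = features.subset_classes("boundary", control)
        if len(set(sub.labels)) < 2 or min(sub.labels.value_counts()) < 10:
            log.warning("skipping boundary-vs-%s: too few regions", control)
            continue
        report = train_evaluate(
            sub,
            SplitSpec(train_fraction=cfg.train_fraction, seed=cfg.seed),
            ForestSpec(n_trees=cfg.n_trees, m=cfg.m, seed=cfg.seed),
            positive_label="boundary",
        )
        report.to_json(out / f"boundary_vs_{control}.json")
        report.roc.to_csv(out / f"boundary_vs_{control}.roc.tsv", sep="\t", index=False)
        report.importances.sort_values(ascending=False).to_csv(
            out / f"boundary_vs_{control}.importances.tsv", sep="\t"
        )
        reports[control] = report
    ctx.counts["n_classifier_tasks"] = len(reports)
    ctx._reports = reports
    return reports


def stage_enrich(ctx: RunContext) -> dict:
    cfg = ctx.config
    features = ctx.features
    reports = ctx.reports
    bundle = ctx.bundle
    out = ctx.outdir("enrich")
    case = features.subset_classes("boundary")
    results = {}
    for control, report in reports.items():
        ctrl = features.subset_classes(control)
        table = enrichment_table(case, ctrl)
        table.to_csv(out / f"enrichment_boundary_vs_{control}.tsv", sep="\t")
        motif_rank = [
            m for m in rank_importances(report, len(report.importances))
            if m != "cpg_fraction"
        ]
        selected, discarded = select_discriminating(
            motif_rank, table, min(cfg.k_select, len(motif_rank))
        )
        (out / f"selected_{control}.txt").write_text("".join(f"{m}\n" for m in selected))
        sweep = cme_sweep(
            motif_rank, bundle.interactions,
            [p.motif_id for p in bundle.motif_library], cfg.k_list,
        )
        sweep.to_csv(out / f"cme_sweep_{control}.tsv", sep="\t")
        results[control] = {
            "selected": selected,
            "n_discarded": discarded,
            "cme_sweep": sweep,
            "enrichment": table,
            "rank": motif_rank,
        }
    ctx.counts["n_enrichment_tasks"] = len(results)
    ctx._enrich = results
    return results


def stage_positional(ctx: RunContext, enrich_results: dict | None = None) -> pd.DataFrame:
    cfg = ctx.config
    sets = ctx.region_sets
    if ctx._hits is None:
        stage_features(ctx)
    enrich_results = enrich_results or getattr(ctx, "_enrich", None) or stage_enrich(ctx)
    selected = sorted(
        {m for res in enrich_results.values() for m in res["selected"]}
    )
    if not selected:  # fall back to the full library so the stage always emits
        selected = [p.motif_id for p in ctx.bundle.motif_library]
    boundaries = sets["boundary"]
    profiles = [
        profile(
            ctx._hits, boundaries, m,
            window=100, edge_offset=cfg.boundary_spec.flank_outside,
        )
        for m in selected
    ]
    out = ctx.outdir("positional")
    write_profiles(profiles, out / "profiles.tsv")
    ctx.counts["n_positional_motifs"] = len(profiles)
    ctx._profiles = profiles
    return profiles


def stage_signal(ctx: RunContext) -> dict:
    cfg = ctx.config
    bundle = ctx.bundle
    sets = ctx.region_sets
    out = ctx.outdir("signal")
    results: dict = {}
    boundaries = sets["boundary_notss"] if len(sets["boundary_notss"]) else sets["boundary"]
    for mark, (treat, inp) in sorted(bundle.chip_tracks.items()):
        norm = normalize(treat, inp)
        prof = metaprofile(norm, boundaries, span=cfg.metaprofile_span)
        prof.to_frame().to_csv(out / f"metaprofile_{mark}.tsv", sep="\t", index=False)
        entry: dict = {"metaprofile": prof}
        if len(sets["outside"]) >= 2 and len(boundaries) >= 2:
            entry["boundary_vs_outside"] = compare_sets(norm, boundaries, sets["outside"])
        if mark == cfg.comparison_mark:
            entry["ctcf"] = ctcf_stratify(norm, boundaries, bundle.ctcf_sites)
            entry["ctcf"]["freq_inside"] = region_frequency(
                sets["inside"], bundle.ctcf_sites
            )
            entry["ctcf"]["freq_outside"] = region_frequency(
                sets["outside"], bundle.ctcf_sites
            )
        results[mark] = entry
    serializable = {
        mark: {k: v for k, v in entry.items() if k != "metaprofile"}
        for mark, entry in results.items()
    }
    (out / "comparisons.json").write_text(json.dumps(serializable, indent=2, sort_keys=True))
    ctx.counts["n_marks"] = len(results)
    ctx._signal = results
    return results


def stage_hic(ctx: RunContext) -> dict:
    bundle = ctx.bundle
    rng = ctx._substreams["hic"]
    out = ctx.outdir("hic")
    results = {
        "strength": strength_vs_random(
            bundle.blocks, bundle.hic, rng, bundle.chrom_sizes
        ),
        "tad_proximity": tad_proximity(
            bundle.tads, bundle.blocks, rng, bundle.chrom_sizes
        ),
    }
    (out / "hic.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    ctx.counts["n_hic_blocks"] = results["strength"]["n_blocks"]
    ctx._hic = results
    return results


def _checksums(root: Path) -> dict[str, str]:
    sums = {}
    for path in sorted(root.rglob("*")):
        # the log carries wall-clock timings, so it stays out of the
        # determinism-bearing checksums, as does the manifest itself
        if path.is_file() and path.name not in ("manifest.json", "run.log"):
            h = hashlib.sha256(path.read_bytes()).hexdigest()
            sums[str(path.relative_to(root))] = h
    return sums


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest.

    Any stage failure aborts with :class:`StageError` naming the stage,
    after writing the partial manifest.
    """
    import time

    ctx = RunContext(config)
    config.outdir.mkdir(parents=True, exist_ok=True)
    pkg_log = logging.getLogger("hmblocks")
    handler = logging.FileHandler(config.outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    pkg_log.addHandler(handler)
    stage_fns = [
        ("regions", stage_regions),
        ("features", stage_features),
        ("classify", stage_classify),
        ("enrich", stage_enrich),
        ("positional", stage_positional),
        ("signal", stage_signal),
        ("hic", stage_hic),
    ]
    completed = []
    try:
        for name, fn in stage_fns:
            t0 = time.perf_counter()
            log.info("stage %s", name)
            fn(ctx)
            log.info("stage %s done in %.2f s", name, time.perf_counter() - t0)
            completed.append(name)
    except Exception as exc:  # noqa: BLE001 - manifest must name the stage
        _write_manifest(ctx, completed, partial=True)
        raise StageError(name, exc) from exc
    finally:
        pkg_log.removeHandler(handler)
        handler.close()
    return _write_manifest(ctx, completed, partial=False)


def _write_manifest(ctx: RunContext, completed: list[str], partial: bool) -> dict:
    import sklearn
    import scipy

    manifest = {
        "version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "scipy": scipy.__version__,
        },
        "config": ctx.config.snapshot(),
        "stages_completed": completed,
        "partial": partial,
        "counts": dict(sorted(ctx.counts.items())),
        "checksums": _checksums(ctx.config.outdir),
    }
    (ctx.config.outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


def validate(config: RunConfig) -> dict:
    """Pre-flight input validation: fatal errors vs warnings."""
    errors: list[str] = []
    warnings: list[str] = []
    if config.sim is not None:
        return {"errors": errors, "warnings": warnings, "ok": True}
    d = Path(config.bundle_dir)
    required = ["genome.fa", "blocks.bed", "chrom.sizes"]
    for name in required:
        if not (d / name).exists():
            errors.append(f"missing required input {name}")
    if errors:
        return {"errors": errors, "warnings": warnings, "ok": False}
    from .intervals import read_chrom_sizes

    sizes = read_chrom_sizes(d / "chrom.sizes")
    try:
        blocks = RegionSet.from_bed(d / "blocks.bed", label="block")
    except Exception as exc:  # noqa: BLE001
        errors.append(f"malformed blocks.bed: {exc}")
        return {"errors": errors, "warnings": warnings, "ok": False}
    for iv in blocks:
        if iv.chrom not in sizes:
            errors.append(f"chromosome {iv.chrom} in blocks.bed absent from chrom.sizes")
            break
        if iv.end > sizes[iv.chrom]:
            errors.append(f"block {iv} extends beyond chromosome end {sizes[iv.chrom]}")
            break
    ctcf = d / "ctcf.bed"
    if not ctcf.exists() or not ctcf.read_text().strip():
        warnings.append("CTCF input empty or missing: CTCF stratification will be skipped")
    return {"errors": errors, "warnings": warnings, "ok": not errors}
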
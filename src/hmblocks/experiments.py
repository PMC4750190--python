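"""Canned recovery experiments on synthetic bundles.

These wire the pipeline stages into the standard evaluation runs used by the
test suite and the reproduction script: boundary-vs-inside discrimination
with planted-motif recovery, the exchangeable-null calibration of the
classifier AUC, and the 3D-structure (Hi-C / TAD) significance and null
calibration runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import ForestSpec, SplitSpec, rank_importances, train_evaluate
from .enrichment import enrichment_table, select_discriminating
from .motifs import FeatureMatrix, build_features, concat_features
from .regions import derive_boundaries, gc_match, sample_controls
from .simulate import SimConfig, SyntheticBundle, simulate_bundle
from .chromatin3d import strength_vs_random, tad_proximity


def boundary_inside_features(
    bundle: SyntheticBundle, seed: int
) -> tuple[FeatureMatrix, object]:
    """Features for boundary regions and GC-matched inside controls."""
    cfg = bundle.config
    sizes = bundle.chrom_sizes
    boundaries = derive_boundaries(bundle.blocks, cfg.boundary_spec, sizes)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    inside = sample_controls(
        bundle.blocks, boundaries, "inside", len(boundaries),
        cfg.boundary_spec.region_length, rng, sizes, allow_shortfall=True,
    )
    inside, _ = gc_match(boundaries, inside, bundle.genome, rng)
    fb = build_features(boundaries, bundle.motif_library, bundle.cpg_islands, bundle.genome)
    fi = build_features(inside, bundle.motif_library, bundle.cpg_islands, bundle.genome)
    return concat_features(fb, fi), boundaries


@dataclass
class RecoveryResult:
    auc: float
    f_measure: float
    sensitivity: float
    specificity: float
    recall_top_ranks: float
    recall_selected: float
    n_boundary: int
    n_inside: int


def boundary_inside_recovery(
    seed: int, n_trees: int = 100, config: SimConfig | None = None
) -> RecoveryResult:
    """Discriminate boundaries from inside controls under planted enrichment
    and score recovery of the planted motifs by importance rank and by the
    enrichment-filtered selection."""
    config = config if config is not None else SimConfig(seed=seed)
    bundle = simulate_bundle(config)
    features, _ = boundary_inside_features(bundle, seed)
    report = train_evaluate(
        features,
        SplitSpec(seed=seed),
        ForestSpec(n_trees=n_trees, seed=seed),
        positive_label="boundary",
    )
    planted = set(bundle.truth.enriched_motifs)
    rank = [
        m for m in rank_importances(report, features.n_features)
        if m != "cpg_fraction"
    ]
    top = set(rank[: len(planted)])
    recall_top = len(top & planted) / len(planted) if planted else float("nan")
    table = enrichment_table(
        features.subset_classes("boundary"), features.subset_classes("inside")
    )
    selected, _ = select_discriminating(rank, table, len(rank))
    recall_sel = (
        len(set(selected) & planted) / len(planted) if planted else float("nan")
    )
    labels = features.labels.value_counts()
    return RecoveryResult(
        auc=report.auc,
        f_measure=report.f_measure,
        sensitivity=report.sensitivity,
        specificity=report.specificity,
        recall_top_ranks=recall_top,
        recall_selected=recall_sel,
        n_boundary=int(labels.get("boundary", 0)),
        n_inside=int(labels.get("inside", 0)),
    )


def null_auc(seed: int, n_trees: int = 100) -> float:
    """Classifier AUC under the exchangeable null (equal planting rates)."""
    bundle = simulate_bundle(SimConfig.null(seed=seed))
    features, _ = boundary_inside_features(bundle, seed)
    report = train_evaluate(
        features, SplitSpec(seed=seed), ForestSpec(n_trees=n_trees, seed=seed),
        positive_label="boundary",
    )
    return report.auc


def chromatin_stats(seed: int, null: bool = False) -> dict:
    """Hi-C strength and TAD proximity p-values under planted or null
    3D-structure conditions."""
    if null:
        config = SimConfig.chromatin(
            seed=seed, hic_intra_boost=0.0, tad_jitter_sd=float("inf")
        )
    else:
        config = SimConfig.chromatin(seed=seed)
    bundle = simulate_bundle(config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    return {
        "strength": strength_vs_random(bundle.blocks, bundle.hic, rng, bundle.chrom_sizes),
        "tad": tad_proximity(bundle.tads, bundle.blocks, rng, bundle.chrom_sizes),
    }
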
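"""Generator contracts: determinism, round trips, planted structure."""

import math

import numpy as np
import pytest

from hmblocks.motifs import scan
from hmblocks.regions import BoundarySpec, PlacementError, derive_boundaries
from hmblocks.simulate import (
    SimConfig,
    read_bundle,
    sample_block_lengths,
    simulate_bundle,
    write_bundle,
)

SMALL = dict(
    n_chromosomes=1,
    chrom_length=400_000,
    n_blocks=8,
    n_motifs=5,
    n_genes=5,
    n_cme_genes=10,
)


class TestDeterminism:
    def test_same_seed_byte_identical_bundles(self, tmp_path):
        m1 = write_bundle(simulate_bundle(SimConfig(seed=9, **SMALL)), tmp_path / "a")
        m2 = write_bundle(simulate_bundle(SimConfig(seed=9, **SMALL)), tmp_path / "b")
        assert (m1["sha256"] == m2["sha256"]).all()

    def test_different_seed_differs(self, tmp_path):
        m1 = write_bundle(simulate_bundle(SimConfig(seed=9, **SMALL)), tmp_path / "a")
        m2 = write_bundle(simulate_bundle(SimConfig(seed=10, **SMALL)), tmp_path / "b")
        assert (m1["sha256"] != m2["sha256"]).any()

    def test_manifest_checksum_tracks_content(self, tmp_path):
        from hmblocks.simulate import _sha256

        bundle = simulate_bundle(SimConfig(seed=9, **SMALL))
        manifest = write_bundle(bundle, tmp_path / "a")
        target = tmp_path / "a" / "blocks.bed"
        before = manifest.set_index("file").loc["blocks.bed", "sha256"]
        assert _sha256(target) == before
        target.write_text(target.read_text() + "# tweak\n")
        assert _sha256(target) != before


class TestRoundTrip:
    def test_interval_sets_and_matrices_reproduced(self, tmp_path):
        bundle = simulate_bundle(SimConfig(seed=4, **SMALL))
        write_bundle(bundle, tmp_path / "b")
        back = read_bundle(tmp_path / "b")
        for attr in ("blocks", "tss", "cpg_islands", "ctcf_sites", "tads"):
            assert list(getattr(back, attr)) == list(getattr(bundle, attr)), attr
        for a, b in zip(bundle.motif_library, back.motif_library):
            assert a.motif_id == b.motif_id
            assert np.allclose(a.matrix, b.matrix, atol=1e-9)
        for chrom, m in bundle.hic.items():
            assert np.allclose(back.hic[chrom].matrix, m.matrix, atol=1e-4)
        for chrom in bundle.genome.chroms:
            assert back.genome.fetch(chrom, 0, 5000) == bundle.genome.fetch(chrom, 0, 5000)
        assert back.truth.enriched_motifs == bundle.truth.enriched_motifs
        assert back.interactions.cme_genes == bundle.interactions.cme_genes


class TestBlockLengths:
    def test_lognormal_closed_forms(self):
        cfg = SimConfig()
        rng = np.random.default_rng(0)
        lens = sample_block_lengths(cfg, 200_000, rng).astype(float)
        mu, sd = cfg.block_length_log_mean, cfg.block_length_log_sd
        assert np.median(lens) == pytest.approx(math.exp(mu), rel=0.03)
        assert lens.mean() == pytest.approx(math.exp(mu + sd**2 / 2), rel=0.1)
        # heavy tail matching real blocks: mean/median ~ 144/39.5
        assert lens.mean() / np.median(lens) == pytest.approx(144 / 39.5, rel=0.12)

    def test_placement_failure_names_chromosome(self):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length=100_000, n_blocks=30, n_motifs=2, n_genes=1
        )
        with pytest.raises(PlacementError, match="chr1"):
            simulate_bundle(cfg)


class TestPlantedStructure:
    def test_blocks_sorted_nonoverlapping_within_margins(self, default_bundle):
        blocks = default_bundle.blocks
        assert blocks.is_nonoverlapping()
        sizes = default_bundle.chrom_sizes
        for iv in blocks:
            assert 6000 <= iv.start and iv.end <= sizes[iv.chrom] - 6000

    def test_planted_sites_scannable_in_place(self, default_bundle):
        """Planted instances lie within the genome and most score as hits."""
        truth = default_bundle.truth.planted
        lib = {p.motif_id: p for p in default_bundle.motif_library}
        found = 0
        rows = truth.head(150)
        for r in rows.itertuples():
            pwm = lib[r.motif_id]
            seq = default_bundle.genome.fetch_codes(r.chrom, r.pos, r.pos + pwm.width)
            assert len(seq) == pwm.width
            if scan(pwm, seq, p_threshold=1e-4):
                found += 1
        assert found / len(rows) > 0.5  # sampled sites mostly pass the scan cutoff

    def test_boundary_excess_of_enriched_motifs(self, default_bundle):
        truth = default_bundle.truth.planted
        boundary = truth[truth.context == "boundary"]
        assert set(boundary.motif_id) <= set(default_bundle.truth.enriched_motifs)
        bd = derive_boundaries(
            default_bundle.blocks, BoundarySpec(), default_bundle.chrom_sizes
        )
        cfg = default_bundle.config
        expected = (
            (cfg.boundary_planting_rate - cfg.background_planting_rate)
            * len(bd)
            * len(default_bundle.truth.enriched_motifs)
        )
        assert len(boundary) == pytest.approx(expected, rel=0.15)

    def test_hic_matrices_symmetric_nonnegative_with_lift(self, chromatin_bundle):
        from hmblocks.chromatin3d import map_blocks_to_bins

        for chrom, matrix in chromatin_bundle.hic.items():
            assert np.allclose(matrix.matrix, matrix.matrix.T)
            assert (matrix.matrix >= 0).all()
            mapping, _ = map_blocks_to_bins(chromatin_bundle.blocks, matrix)
            intra, inter = [], []
            for bins in mapping.values():
                for i, bi in enumerate(bins):
                    for bj in bins[i + 1 :]:
                        intra.append(matrix.matrix[bi, bj])
            if len(intra) > 10:
                assert np.mean(intra) > matrix.matrix.mean() + 5

    def test_null_config_constructs_exchangeable_setup(self):
        cfg = SimConfig.null(seed=0, **SMALL)
        assert cfg.boundary_planting_rate == cfg.background_planting_rate
        assert cfg.hic_intra_boost == 0.0
        assert math.isinf(cfg.tad_jitter_sd)
        bundle = simulate_bundle(cfg)
        assert (bundle.truth.planted.context == "background").all()
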
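"""Boundary derivation, control sampling, promoters, GC matching."""

import numpy as np
import pytest

from hmblocks.genome import Genome
from hmblocks.intervals import GenomicInterval, RegionSet
from hmblocks.regions import (
    BoundarySpec,
    PlacementError,
    derive_boundaries,
    derive_promoters,
    exclude_tss_overlaps,
    gc_match,
    sample_controls,
)


def _blocks(*coords, chrom="chr1"):
    return RegionSet([GenomicInterval(chrom, s, e) for s, e in coords], label="block")


class TestDeriveBoundaries:
    def test_default_arithmetic(self):
        bd = derive_boundaries(_blocks((100_000, 200_000)), BoundarySpec())
        assert [(iv.start, iv.end) for iv in bd] == [(95_000, 101_000), (199_000, 205_000)]
        assert [m["side"] for m in bd.meta] == ["left", "right"]
        assert [m["anchor"] for m in bd.meta] == [100_000, 200_000]

    def test_two_regions_per_unclipped_block(self):
        blocks = _blocks((20_000, 40_000), (80_000, 130_000), (200_000, 203_000))
        bd = derive_boundaries(blocks, BoundarySpec(), {"chr1": 500_000})
        assert len(bd) == 2 * len(blocks)

    def test_clipped_boundary_dropped_not_truncated(self):
        bd = derive_boundaries(_blocks((2_000, 50_000)), BoundarySpec(), {"chr1": 100_000})
        assert len(bd) == 1
        assert bd.meta[0]["side"] == "right"
        assert all(iv.length == 6000 for iv in bd)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            derive_boundaries(_blocks((0, 10_000), (5_000, 20_000)), BoundarySpec())


class TestSampleControls:
    def test_inside_on_6kb_block_is_infeasible(self, rng):
        blocks = _blocks((50_000, 56_000))
        bd = derive_boundaries(blocks, BoundarySpec(), {"chr1": 200_000})
        with pytest.raises(PlacementError):
            sample_controls(blocks, bd, "inside", 1, 6000, rng, {"chr1": 200_000})

    def test_controls_disjoint_from_boundaries_and_each_other(self, default_bundle, rng):
        blocks = default_bundle.blocks
        sizes = default_bundle.chrom_sizes
        bd = derive_boundaries(blocks, BoundarySpec(), sizes)
        for kind in ("inside", "outside"):
            ctrl = sample_controls(
                blocks, bd, kind, 40, 6000, rng, sizes, allow_shortfall=True
            )
            assert len(ctrl) > 0
            assert all(iv.length == 6000 for iv in ctrl)
            # brute-force pairwise overlap check, including against boundaries
            ivs = list(ctrl) + list(bd)
            for i, a in enumerate(ivs):
                for j, b in enumerate(ivs):
                    if i < j and not (i >= len(ctrl) and j >= len(ctrl)):
                        assert not a.overlaps(b), (a, b)
            for c in ctrl:
                inside_any = any(
                    b.chrom == c.chrom and b.start <= c.start and c.end <= b.end
                    for b in blocks
                )
                assert inside_any == (kind == "inside")


class TestPromoters:
    def test_plus_strand_window(self):
        tss = RegionSet([GenomicInterval("chr1", 50_000, 50_001, "+")])
        prom = derive_promoters(tss)
        assert (prom[0].start, prom[0].end) == (45_000, 51_000)

    def test_minus_strand_mirrored(self):
        tss = RegionSet([GenomicInterval("chr1", 50_000, 50_001, "-")])
        prom = derive_promoters(tss)
        assert (prom[0].start, prom[0].end) == (49_000, 55_000)

    def test_overlapping_promoters_deduplicated(self):
        tss = RegionSet(
            [
                GenomicInterval("chr1", 50_000, 50_001, "+"),
                GenomicInterval("chr1", 50_100, 50_101, "+"),
            ]
        )
        assert len(derive_promoters(tss)) == 1

    def test_missing_strand_rejected(self):
        tss = RegionSet([GenomicInterval("chr1", 50_000, 50_001, ".")])
        with pytest.raises(ValueError, match="strand"):
            derive_promoters(tss)


class TestGcMatch:
    def test_identity(self, default_bundle, rng):
        bd = derive_boundaries(
            default_bundle.blocks, BoundarySpec(), default_bundle.chrom_sizes
        )
        sel, shortfall = gc_match(bd, bd, default_bundle.genome, rng)
        assert not shortfall
        assert sorted(sel.intervals) == sorted(bd.intervals)

    def test_disjoint_histograms_yield_shortfall(self, rng):
        genome = Genome.from_sequences({"chr1": "AT" * 5000 + "GC" * 5000})
        cases = RegionSet([GenomicInterval("chr1", 10_000, 10_400)])  # all GC
        cands = RegionSet([GenomicInterval("chr1", 0, 400)])  # all AT
        sel, shortfall = gc_match(cases, cands, genome, rng)
        assert len(sel) == 0
        assert sum(shortfall.values()) == 1

    def test_matched_distributions_close(self, default_ctx, rng):
        genome = default_ctx.bundle.genome
        sets = default_ctx.region_sets
        cases = sets["boundary"].subset(
            sorted(rng.choice(len(sets["boundary"]), size=60, replace=False))
        )
        sel, shortfall = gc_match(cases, sets["inside"], genome, rng)
        assert sum(shortfall.values()) <= 5
        gc = lambda rs: np.sort(
            [genome.gc_fraction(iv.chrom, iv.start, iv.end) for iv in rs]
        )
        a, b = gc(cases), gc(sel)
        # two-sample KS distance by direct empirical-CDF comparison
        grid = np.concatenate([a, b])
        cdf = lambda x, g: np.searchsorted(x, g, side="right") / len(x)
        ks = np.max(np.abs(cdf(a, grid) - cdf(b, grid)))
        # matching should leave no detectable difference at these sample
        # sizes: stay under the alpha = 0.01 two-sample KS critical value
        crit = 1.63 * np.sqrt((len(a) + len(b)) / (len(a) * len(b)))
        assert ks < crit


class TestExcludeTss:
    def test_tss_inside_region_removed_and_end_is_exclusive(self):
        regions = RegionSet(
            [GenomicInterval("chr1", 0, 6000), GenomicInterval("chr1", 10_000, 16_000)]
        )
        tss = RegionSet(
            [
                GenomicInterval("chr1", 3000, 3001, "+"),
                GenomicInterval("chr1", 16_000, 16_001, "+"),  # at end: outside
            ]
        )
        kept = exclude_tss_overlaps(regions, tss)
        assert [(iv.start, iv.end) for iv in kept] == [(10_000, 16_000)]

    def test_agrees_with_bruteforce_scan(self, rng):
        regions = RegionSet(
            [
                GenomicInterval("chr1", int(s), int(s) + 500)
                for s in rng.choice(100_000, size=100, replace=False) * 1
            ]
        )
        tss = RegionSet(
            [GenomicInterval("chr1", int(p), int(p) + 1, "+") for p in rng.integers(0, 101_000, 60)]
        )
        kept = exclude_tss_overlaps(regions, tss)
        expected = [
            iv
            for iv in regions
            if not any(iv.start <= t.start < iv.end for t in tss)
        ]
        assert list(kept) == sorted(expected)
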
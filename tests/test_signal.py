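"""ChIP track normalization, region means, metaprofiles, comparisons."""

import itertools
import math

import numpy as np
import pytest

from hmblocks.intervals import GenomicInterval, RegionSet
from hmblocks.regions import BoundarySpec, derive_boundaries
from hmblocks.signal import (
    BinnedTrack,
    compare_sets,
    ctcf_stratify,
    metaprofile,
    normalize,
    region_mean,
)
from hmblocks.stats import rank_sum_test


def _track(values, bw=20):
    return BinnedTrack({"chr1": np.asarray(values, dtype=float)}, bin_width=bw)


class TestNormalize:
    def test_equal_tracks_give_zero(self):
        t = _track(np.arange(10))
        out = normalize(t, t)
        assert np.allclose(out.values["chr1"], 0.0)

    def test_scaled_track_spotcheck(self, rng):
        t_vals = rng.integers(1, 50, 10).astype(float)
        i_vals = rng.integers(1, 50, 10).astype(float)
        out = normalize(_track(t_vals), _track(i_vals), pseudocount=0.5)
        for j in range(10):
            assert out.values["chr1"][j] == pytest.approx(
                math.log((t_vals[j] + 0.5) / (i_vals[j] + 0.5))
            )

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            normalize(_track(np.ones(5)), _track(np.ones(6)))

    def test_missing_propagates(self):
        out = normalize(_track([1.0, np.nan]), _track([1.0, 1.0]))
        assert math.isnan(out.values["chr1"][1])


class TestRegionMean:
    def test_constant_track(self):
        track = _track(np.full(100, 3.5))
        rs = RegionSet([GenomicInterval("chr1", 13, 977)])
        assert region_mean(track, rs)[0] == pytest.approx(3.5)

    def test_partial_bin_weighting(self):
        track = _track([0.0, 2.0])
        rs = RegionSet([GenomicInterval("chr1", 10, 30)])  # half of each bin
        assert region_mean(track, rs)[0] == pytest.approx(1.0)

    def test_against_per_base_oracle(self, rng):
        vals = rng.normal(size=50)
        track = _track(vals)
        per_base = np.repeat(vals, 20)
        regions = RegionSet(
            [GenomicInterval("chr1", int(s), int(s) + int(l))
             for s, l in zip(rng.integers(0, 900, 20), rng.integers(7, 90, 20))]
        )
        got = region_mean(track, regions)
        for iv, g in zip(regions, got):
            assert g == pytest.approx(per_base[iv.start : iv.end].mean())

    def test_scaling_linearity(self, rng):
        vals = rng.random(50)
        rs = RegionSet([GenomicInterval("chr1", 5, 633)])
        a = region_mean(_track(vals), rs)[0]
        b = region_mean(_track(vals * 3.0), rs)[0]
        assert b == pytest.approx(3.0 * a)


class TestMetaprofile:
    def test_flat_track_flat_profile(self):
        track = _track(np.full(5000, 1.25))
        bd = RegionSet(
            [GenomicInterval("chr1", 45_000, 51_000)],
            label="boundary",
            meta=[{"anchor": 50_000, "side": "left"}],
        )
        prof = metaprofile(track, bd, span=10_000)
        vals = prof.mean_signal[~np.isnan(prof.mean_signal)]
        assert np.allclose(vals, 1.25)

    def test_peak_recovered_near_boundary(self, default_bundle):
        bd = derive_boundaries(
            default_bundle.blocks, BoundarySpec(), default_bundle.chrom_sizes
        )
        treat, inp = default_bundle.chip_tracks["H3K4me3"]
        prof = metaprofile(normalize(treat, inp), bd)
        peak = prof.offsets[np.nanargmax(prof.mean_signal)]
        assert -1500 <= peak <= 0  # just outside the block edge

    def test_left_and_mirrored_right_agree(self, default_bundle):
        bd = derive_boundaries(
            default_bundle.blocks, BoundarySpec(), default_bundle.chrom_sizes
        )
        treat, inp = default_bundle.chip_tracks["H3K4me3"]
        norm = normalize(treat, inp)
        profs = {}
        for side in ("left", "right"):
            keep = [i for i, m in enumerate(bd.meta) if m["side"] == side]
            profs[side] = metaprofile(norm, bd.subset(keep))
        peaks = {
            s: p.offsets[np.nanargmax(p.mean_signal)] for s, p in profs.items()
        }
        assert abs(peaks["left"] - peaks["right"]) <= 600

    def test_shuffled_boundaries_flat(self, default_bundle, rng):
        treat, inp = default_bundle.chip_tracks["H3K4me3"]
        norm = normalize(treat, inp)
        sizes = default_bundle.chrom_sizes
        fake = RegionSet(
            [GenomicInterval("chr1", int(p), int(p) + 6000)
             for p in rng.integers(10_000, sizes["chr1"] - 20_000, 60)],
            label="boundary",
            meta=[{"anchor": int(p) + 5000, "side": "left"}
                  for p in rng.integers(10_000, sizes["chr1"] - 20_000, 60)],
        )
        # anchors independent of true edges: profile has no aligned peak
        prof = metaprofile(norm, fake)
        smooth = np.convolve(
            np.nan_to_num(prof.mean_signal), np.ones(25) / 25, mode="valid"
        )
        assert smooth.max() - smooth.min() < 0.35


class TestCompareSets:
    def test_identical_sets_p_one(self):
        track = _track(np.arange(100, dtype=float))
        rs = RegionSet([GenomicInterval("chr1", i * 200, i * 200 + 100) for i in range(5)])
        res = compare_sets(track, rs, rs)
        assert res["p_value"] == pytest.approx(1.0)

    def test_rank_sum_matches_enumeration_oracle(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5) + 0.8
        u_obs, p = rank_sum_test(x, y)
        # enumerate all rank assignments of the pooled sample
        pooled = np.concatenate([x, y])
        order = pooled.argsort().argsort() + 1  # ranks, no ties w.p. 1
        r_x = order[:5].sum()
        u_x = r_x - 5 * 6 / 2
        n1n2 = 25
        us = []
        for combo in itertools.combinations(range(1, 11), 5):
            us.append(sum(combo) - 15)
        us = np.array(us)
        p_oracle = np.mean(np.abs(us - n1n2 / 2) >= abs(u_x - n1n2 / 2) - 1e-12)
        assert u_obs == pytest.approx(u_x)
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_planted_boundary_signal_detected(self, default_ctx):
        bundle = default_ctx.bundle
        sets = default_ctx.region_sets
        treat, inp = bundle.chip_tracks["H3K4me3"]
        res = compare_sets(normalize(treat, inp), sets["boundary"], sets["outside"])
        assert res["mean_a"] > res["mean_b"]
        assert res["p_value"] < 0.05


class TestCtcf:
    def test_no_sites_skips_comparison(self, default_ctx):
        sets = default_ctx.region_sets
        res = ctcf_stratify(None, sets["boundary"], RegionSet([], label="ctcf"))
        assert res["freq_with"] == 0.0 and res["comparison_skipped"]

    def test_every_boundary_with_site(self, default_ctx):
        sets = default_ctx.region_sets
        res = ctcf_stratify(None, sets["boundary"], sets["boundary"])
        assert res["freq_with"] == 1.0

    def test_boundary_frequency_recovers_config(self, default_ctx):
        bundle = default_ctx.bundle
        sets = default_ctx.region_sets
        res = ctcf_stratify(None, sets["boundary"], bundle.ctcf_sites)
        p, n = bundle.config.ctcf_boundary_prob, res["n_boundaries"]
        se = math.sqrt(p * (1 - p) / n)
        # boundary freq within ~4 SE of the planting probability (background
        # sites can only add), and above the background frequency
        assert p - 4 * se < res["freq_with"] < p + 6 * se
        from hmblocks.signal import region_frequency

        assert res["freq_with"] > region_frequency(sets["outside"], bundle.ctcf_sites)
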
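"""PWM scanning against brute-force oracles, MEME round trips, features."""

import itertools
import math

import numpy as np
import pytest

from hmblocks.genome import Genome
from hmblocks.intervals import GenomicInterval, RegionSet
from hmblocks.motifs import (
    PWM,
    build_features,
    read_meme,
    scan,
    write_meme,
)

BASES = "ACGT"


def _logodds(pwm, word):
    return sum(
        math.log2(pwm.matrix[j, BASES.index(b)] / pwm.background[BASES.index(b)])
        for j, b in enumerate(word)
    )


def _revcomp(word):
    return word.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _bruteforce_pvalue(pwm, score, tol=1e-9):
    """P(score' >= score) under the background, by enumerating all words."""
    total = 0.0
    for word in itertools.product(BASES, repeat=pwm.width):
        w = "".join(word)
        if _logodds(pwm, w) >= score - tol:
            prob = 1.0
            for b in w:
                prob *= pwm.background[BASES.index(b)]
            total += prob
    return total


@pytest.fixture()
def pwm3():
    mat = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.6, 0.2, 0.1], [0.05, 0.05, 0.1, 0.8]])
    return PWM("T3", mat)


class TestScan:
    def test_background_pwm_scores_zero_everywhere(self):
        pwm = PWM("BG", np.full((4, 4), 0.25))
        hits = scan(pwm, "ACGTACGTACGT", p_threshold=0.5)
        assert hits == []  # p-value of score 0 is 1 > 0.5

    def test_bruteforce_oracle_width3(self, pwm3):
        seq = "ACGTTGCA"
        got = scan(pwm3, seq, p_threshold=0.05)
        expected = []
        for off in range(len(seq) - 2):
            for strand in "+-":
                word = seq[off : off + 3]
                if strand == "-":
                    word = _revcomp(word)
                s = _logodds(pwm3, word)
                p = _bruteforce_pvalue(pwm3, s)
                if p <= 0.05:
                    expected.append((off, strand, s, p))
        assert len(got) == len(expected)
        for h, (off, strand, s, p) in zip(
            sorted(got, key=lambda h: (h.offset, h.strand)), sorted(expected)
        ):
            assert (h.offset, h.strand) == (off, strand)
            assert h.score == pytest.approx(s, abs=2e-3)
            assert h.p_value == pytest.approx(p, rel=1e-3)

    def test_max_score_pvalue_is_product_of_max_column_probs(self, pwm3):
        max_score = sum(
            math.log2(pwm3.matrix[j].max() / 0.25) for j in range(pwm3.width)
        )
        expected = 1.0
        for j in range(pwm3.width):
            best = pwm3.matrix[j].max()
            expected *= sum(
                0.25 for v in pwm3.matrix[j] if np.isclose(v, best)
            )
        assert pwm3.pvalue(max_score) == pytest.approx(expected, rel=1e-6)

    def test_strand_symmetry(self, pwm3, rng):
        seq = "".join(rng.choice(list(BASES), size=200))
        fwd = scan(pwm3, seq, p_threshold=0.05)
        rev = scan(pwm3, _revcomp(seq), p_threshold=0.05)
        mirror = {"+": "-", "-": "+"}
        expected = sorted(
            (len(seq) - pwm3.width - h.offset, mirror[h.strand], round(h.score, 6))
            for h in fwd
        )
        got = sorted((h.offset, h.strand, round(h.score, 6)) for h in rev)
        assert got == expected

    def test_windows_with_n_skipped(self, pwm3):
        assert scan(pwm3, "NNNNNNNN", p_threshold=0.999) == []

    def test_invalid_base_rejected(self, pwm3):
        with pytest.raises(ValueError, match="position 2"):
            scan(pwm3, "ACXGT")

    def test_background_hit_rate_matches_exact_pvalue(self, rng):
        # expected hits on i.i.d. sequence = 2 (L - w + 1) * attained p
        alpha = rng.dirichlet(np.ones(4) * 2, size=10)
        pwm = PWM("R", alpha)
        p_thr = 1e-3
        p_attained = pwm.pvalue(pwm.score_threshold(p_thr) / 1000)
        assert p_attained <= p_thr
        L = 300_000
        seq = rng.integers(0, 4, size=L).astype(np.uint8)
        hits = scan(pwm, seq, p_threshold=p_thr)
        exp = 2 * (L - pwm.width + 1) * p_attained
        se = math.sqrt(exp)
        assert abs(len(hits) - exp) < 4 * se


class TestFeatures:
    def test_cpg_fraction_and_columns(self, rng):
        genome = Genome.from_sequences({"chr1": "".join(rng.choice(list(BASES), 4000))})
        regions = RegionSet(
            [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 2000, 3000)],
            label="custom",
        )
        cpg = RegionSet([GenomicInterval("chr1", 0, 1000)], label="cpg")
        lib = [PWM(f"M{i}", rng.dirichlet(np.ones(4), size=8)) for i in range(3)]
        fm = build_features(regions, lib, cpg, genome)
        assert fm.n_features == len(lib) + 1
        assert fm.counts.loc["custom_00000", "cpg_fraction"] == 1.0
        assert fm.counts.loc["custom_00001", "cpg_fraction"] == 0.0

    def test_region_without_planted_motifs_mostly_zero(self, rng):
        # sharp PWMs at 1e-6: chance hits on 1 kb background are very unlikely
        genome = Genome.from_sequences({"chr1": "".join(rng.choice(list(BASES), 1000))})
        regions = RegionSet([GenomicInterval("chr1", 0, 1000)])
        mats = []
        for _ in range(3):
            m = np.full((10, 4), 0.01 / 3)
            m[np.arange(10), rng.integers(0, 4, 10)] = 0.99
            mats.append(m)
        lib = [PWM(f"M{i}", m) for i, m in enumerate(mats)]
        fm = build_features(regions, lib, RegionSet([], label="cpg"), genome, 1e-6)
        assert fm.counts[[p.motif_id for p in lib]].to_numpy().sum() == 0

    def test_counts_invariant_to_region_order(self, default_bundle):
        genome = default_bundle.genome
        lib = default_bundle.motif_library[:3]
        ivs = [
            GenomicInterval("chr1", 10_000, 16_000),
            GenomicInterval("chr1", 30_000, 36_000),
            GenomicInterval("chr2", 5_000, 11_000),
        ]
        a = build_features(RegionSet(ivs), lib, RegionSet([]), genome)
        b = build_features(RegionSet(ivs[::-1]), lib, RegionSet([]), genome)
        assert (a.counts.to_numpy() == b.counts.to_numpy()).all()

    def test_mixed_lengths_rejected(self, default_bundle):
        rs = RegionSet(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 350)]
        )
        with pytest.raises(ValueError, match="mixed lengths"):
            build_features(rs, default_bundle.motif_library[:1], RegionSet([]),
                           default_bundle.genome)


class TestMemeIO:
    def test_round_trip_within_1e9(self, default_bundle, tmp_path):
        lib = default_bundle.motif_library
        path = tmp_path / "motifs.meme"
        write_meme(lib, path)
        back = read_meme(path)
        assert [p.motif_id for p in back] == [p.motif_id for p in lib]
        for a, b in zip(lib, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-9)
            assert np.allclose(a.background, b.background, atol=1e-9)
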
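"""Domain/spacer decomposition and the shuffle permutation test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from ihscape.intervals import Coverage
from ihscape.shuffle_test import (
    Arrangement,
    ShuffleConfig,
    decompose,
    genomewide_test,
    normal_tail_p,
    null_statistics,
    permutation_test,
    recompose,
    shuffle_arrangement,
)


class TestDecompose:
    def test_worked_example(self):
        arr = decompose([10, 50], [20, 70], 100)
        assert list(arr.domain_lengths) == [10, 20]
        assert list(arr.spacer_lengths) == [10, 30, 30]

    def test_no_domains(self):
        arr = decompose([], [], 500)
        assert arr.n_domains == 0
        assert list(arr.spacer_lengths) == [500]

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            decompose([10], [120], 100)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 900), st.integers(1, 80)),
                    min_size=0, max_size=12))
    def test_roundtrip_identity(self, raw):
        # build sorted non-overlapping domains on a length-1000 chromosome
        starts, ends, cursor = [], [], 0
        for gap, length in raw:
            s = cursor + gap
            e = s + length
            if e > 1000:
                break
            starts.append(s)
            ends.append(e)
            cursor = e
        arr = decompose(starts, ends, 1000)
        s2, e2 = recompose(arr)
        assert list(s2) == starts and list(e2) == ends


class TestShuffleArrangement:
    def test_conserves_length_multisets(self):
        rng = np.random.default_rng(5)
        arr = decompose([10, 50, 300], [20, 120, 450], 1000)
        for _ in range(20):
            s, e = shuffle_arrangement(arr, rng)
            assert sorted(e - s) == sorted(arr.domain_lengths)
            spacers = np.diff(np.concatenate(([0], *zip(s, e), [1000])).ravel())[::2]
            assert sorted(spacers) == sorted(arr.spacer_lengths)

    def test_single_domain_two_positions_equally_likely(self):
        rng = np.random.default_rng(11)
        arr = Arrangement("c", 100, np.array([20]), np.array([10, 70]))
        firsts = [shuffle_arrangement(arr, rng)[0][0] for _ in range(4000)]
        frac = np.mean(np.array(firsts) == 10)
        assert 0.45 < frac < 0.55

    def test_twelve_layouts_uniform(self):
        """N=2 with 3 distinct spacers: 2!*3! = 12 equally likely layouts."""
        arr = Arrangement("c", 100, np.array([10, 20]), np.array([5, 30, 35]))
        layouts = set()
        for ap in itertools.permutations(arr.domain_lengths):
            for sp in itertools.permutations(arr.spacer_lengths):
                layouts.add(recompose(Arrangement("c", 100, np.array(ap),
                                                  np.array(sp)))[0].tobytes())
        assert len(layouts) == 12
        rng = np.random.default_rng(3)
        counts = {}
        n = 12_000
        for _ in range(n):
            key = shuffle_arrangement(arr, rng)[0].tobytes()
            counts[key] = counts.get(key, 0) + 1
        assert set(counts) == layouts
        # each frequency within 5 sigma of 1/12
        sd = np.sqrt((1 / 12) * (11 / 12) / n)
        for c in counts.values():
            assert abs(c / n - 1 / 12) < 5 * sd


class TestPermutationTest:
    def test_track_covering_whole_chromosome_degenerate(self):
        res = permutation_test([10, 50], [20, 70], [0], [100], 100,
                               ShuffleConfig(iterations=500, seed=1))
        assert res.null_sd == 0
        assert res.p_enrich == 1.0 and res.p_deplete == 1.0
        assert res.method == "empirical"

    def test_empty_track(self):
        res = permutation_test([10, 50], [20, 70], [], [], 100,
                               ShuffleConfig(iterations=500, seed=1))
        assert res.observed == 0
        assert res.p_deplete == 1.0

    def test_identity_permutation_statistic_equals_observed(self):
        arr = decompose([10, 50], [20, 70], 100)
        s, e = recompose(arr)
        cov = Coverage(np.array([0]), np.array([40]))
        ident = int(cov.overlap(s, e).sum())
        res = permutation_test([10, 50], [20, 70], [0], [40], 100,
                               ShuffleConfig(iterations=200, seed=2))
        assert res.observed == ident

    def test_empirical_p_matches_exhaustive_enumeration(self):
        """2-domain toy: MC p within 3*sqrt(p(1-p)/M) of the exact p."""
        ds, de = [5, 45], [15, 65]
        arr = decompose(ds, de, 100)
        cov = Coverage(np.array([0]), np.array([40]))
        exact = []
        for ap in itertools.permutations(arr.domain_lengths):
            for sp in itertools.permutations(arr.spacer_lengths):
                s, e = recompose(Arrangement("c", 100, np.array(ap), np.array(sp)))
                exact.append(int(cov.overlap(s, e).sum()))
        exact = np.array(exact)
        obs = int(cov.overlap(np.array(ds), np.array(de)).sum())
        p_exact = (exact >= obs).mean()
        m = 20_000
        res = permutation_test(ds, de, [0], [40], 100,
                               ShuffleConfig(iterations=m, seed=9))
        tol = 3 * np.sqrt(p_exact * (1 - p_exact) / m)
        assert abs(res.p_enrich - p_exact) < tol

    def test_add_one_estimator_never_zero(self):
        res = permutation_test([10], [30], [50], [90], 100,
                               ShuffleConfig(iterations=100, seed=4))
        assert 0 < res.p_enrich_add_one <= 1
        assert 0 < res.p_deplete_add_one <= 1


class TestNormalTail:
    def test_p_at_mean_is_half(self):
        assert normal_tail_p(10.0, 10.0, 2.0, "enrich") == pytest.approx(0.5)
        assert normal_tail_p(10.0, 10.0, 2.0, "deplete") == pytest.approx(0.5)

    def test_standard_quantile(self):
        p = normal_tail_p(10 + 1.959964 * 3, 10, 3, "enrich")
        assert p == pytest.approx(0.025, rel=1e-4)

    def test_agreement_with_erfc_evaluation(self):
        for z in (-3.5, -1.0, 0.3, 2.2, 4.8):
            p = normal_tail_p(z, 0.0, 1.0, "enrich")
            assert p == pytest.approx(0.5 * special.erfc(z / np.sqrt(2)),
                                      abs=1e-12)

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            normal_tail_p(1.0, 1.0, 0.0, "enrich")


class TestGenomeWide:
    def _per_chrom(self, chroms):
        return {
            c: dict(domain_starts=np.array(d[0]), domain_ends=np.array(d[1]),
                    track_starts=np.array(d[2]), track_ends=np.array(d[3]))
            for c, d in chroms.items()
        }

    def test_single_chromosome_equals_per_chromosome_test(self):
        cfg = ShuffleConfig(iterations=2000, seed=21)
        single = permutation_test([100, 700], [300, 900], [0, 500], [200, 600],
                                  1000, cfg)
        joint = genomewide_test(
            self._per_chrom({"2L": ([100, 700], [300, 900],
                                    [0, 500], [200, 600])}),
            {"2L": 1000}, cfg,
        )
        assert joint.observed == single.observed
        assert joint.p_enrich == single.p_enrich
        assert joint.count_ge == single.count_ge

    def test_requires_at_least_one_chromosome(self):
        with pytest.raises(ValueError):
            genomewide_test({}, {}, ShuffleConfig(iterations=10, seed=0))

    def test_joint_statistic_sums_chromosomes(self):
        cfg = ShuffleConfig(iterations=500, seed=8)
        joint = genomewide_test(
            self._per_chrom({
                "2L": ([100], [300], [0], [200]),
                "2R": ([400], [600], [350], [700]),
            }),
            {"2L": 1000, "2R": 1000}, cfg,
        )
        assert joint.observed == 100 + 200

    def test_count_statistic_mode(self):
        cfg = ShuffleConfig(iterations=300, seed=8, statistic="count")
        res = permutation_test([100, 700], [300, 900], [0], [200], 1000, cfg)
        assert res.observed == 1  # one domain overlaps the track
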
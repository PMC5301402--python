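"""Differentiation statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vgrscan.stats import (GenotypeCounts, SnpCounts, bonferroni_threshold,
                           fisher_allelic_test, fisher_track, fst_track,
                           genomic_inflation, hwe_exact_test, pearson_chi_square,
                           weir_cockerham_fst)
from vgrscan.simulate import SimConfig, simulate_dataset

from conftest import make_dataset
from oracles import fisher_exact_enumeration, hwe_exact_enumeration, wc_theta_reference


def _counts(a, b):
    return SnpCounts(GenotypeCounts(*a), GenotypeCounts(*b))


class TestWeirCockerham:
    def test_complete_fixation(self):
        res = weir_cockerham_fst(_counts((20, 0, 0), (0, 0, 20)))
        assert res.defined
        assert res.theta == pytest.approx(1.0)
        assert (res.a, res.b, res.c) == pytest.approx((0.5, 0.0, 0.0))

    def test_monomorphic_undefined(self):
        assert not weir_cockerham_fst(_counts((20, 0, 0), (15, 0, 0))).defined

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n1, n2 = rng.integers(2, 60, size=2)
            ca = rng.multinomial(n1, rng.dirichlet([1, 1, 1]))
            cb = rng.multinomial(n2, rng.dirichlet([1, 1, 1]))
            res = weir_cockerham_fst(_counts(tuple(ca), tuple(cb)))
            p1 = (2 * ca[0] + ca[1]) / (2 * n1)
            p2 = (2 * cb[0] + cb[1]) / (2 * n2)
            a, b, c, theta = wc_theta_reference(n1, p1, ca[1] / n1, n2, p2, cb[1] / n2)
            assert res.a == pytest.approx(a, abs=1e-12)
            assert res.b == pytest.approx(b, abs=1e-12)
            assert res.c == pytest.approx(c, abs=1e-12)
            if res.defined:
                assert res.theta == pytest.approx(theta, abs=1e-12)
                assert res.theta <= 1.0 + 1e-12

    @given(st.tuples(*[st.integers(0, 20)] * 6).filter(lambda t: sum(t[:3]) and sum(t[3:])))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_label_swap_invariance(self, t):
        ca, cb = t[:3], t[3:]
        r1 = weir_cockerham_fst(_counts(ca, cb))
        r2 = weir_cockerham_fst(_counts(cb, ca))           # population swap
        r3 = weir_cockerham_fst(_counts(ca[::-1], cb[::-1]))  # allele swap
        if r1.defined:
            assert r1.theta == pytest.approx(r2.theta, abs=1e-12)
            assert r1.theta == pytest.approx(r3.theta, abs=1e-12)


class TestFisherExact:
    def test_exchangeable_table(self):
        assert fisher_allelic_test(_counts((5, 0, 0), (5, 0, 0))) == 1.0

    def test_fixed_difference_closed_form(self):
        from math import comb
        p = fisher_allelic_test(_counts((5, 0, 0), (0, 0, 5)))
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-10)

    def test_zero_margin_convention(self):
        assert fisher_allelic_test(_counts((3, 0, 0), (4, 0, 0))) == 1.0

    def test_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(150):
            ca = rng.multinomial(rng.integers(1, 16), rng.dirichlet([1, 1, 1]))
            cb = rng.multinomial(rng.integers(1, 16), rng.dirichlet([1, 1, 1]))
            counts = _counts(tuple(ca), tuple(cb))
            table = [[2 * ca[0] + ca[1], 2 * ca[2] + ca[1]],
                     [2 * cb[0] + cb[1], 2 * cb[2] + cb[1]]]
            assert fisher_allelic_test(counts) == pytest.approx(
                fisher_exact_enumeration(table), abs=1e-10)


class TestHWEExact:
    def test_monomorphic(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    def test_all_heterozygous_matches_enumeration(self):
        assert hwe_exact_test(0, 10, 0) == pytest.approx(
            hwe_exact_enumeration(0, 10, 0), abs=1e-12)

    @given(st.tuples(st.integers(0, 17), st.integers(0, 17), st.integers(0, 17))
           .filter(lambda t: sum(t) >= 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_enumeration_and_symmetry(self, t):
        p = hwe_exact_test(*t)
        assert p == pytest.approx(hwe_exact_enumeration(*t), abs=1e-10)
        assert p == pytest.approx(hwe_exact_test(t[2], t[1], t[0]), abs=1e-12)


class TestPearsonChiSquare:
    def test_uniform_table(self):
        stat, df, p = pearson_chi_square([[10, 10], [10, 10]])
        assert (stat, df, p) == (0.0, 1, 1.0)

    def test_diagonal_table_closed_form(self):
        stat, df, _ = pearson_chi_square([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)
        assert df == 1

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        t = rng.integers(1, 30, size=(3, 2)).astype(float)
        stat, df, _ = pearson_chi_square(t)
        e = np.outer(t.sum(1), t.sum(0)) / t.sum()
        assert stat == pytest.approx(((t - e) ** 2 / e).sum(), abs=1e-12)
        assert df == 2

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            stat, df, _ = pearson_chi_square([[5, 5], [0, 0], [5, 5]])
        assert df == 1


class TestGenomicInflation:
    def test_unit_lambda_at_median_chi2(self):
        assert genomic_inflation([0.4549364] * 5, kind="chi2") == pytest.approx(1.0, abs=1e-6)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        chi2 = rng.chisquare(1, size=201)
        lam = genomic_inflation(chi2, kind="chi2")
        assert genomic_inflation(2 * chi2, kind="chi2") == pytest.approx(2 * lam)

    def test_uniform_pvalues_give_unit_lambda(self):
        rng = np.random.default_rng(2024)
        p = rng.uniform(size=10_000)
        assert genomic_inflation(p, kind="p") == pytest.approx(1.0, abs=0.05)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            genomic_inflation([])


class TestBonferroni:
    @pytest.mark.parametrize("alpha,n,expected", [
        (0.05, 46563, 1.07e-6), (0.05, 1, 0.05), (0.05, 2, 0.025)])
    def test_threshold(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=5e-3)

    def test_printed_precision(self):
        assert f"{bonferroni_threshold(0.05, 46563):.3g}" == "1.07e-06"


class TestTracks:
    def test_planted_fixed_difference_gives_theta_one(self):
        geno = np.zeros((20, 3), dtype=np.int8)
        geno[10:, 0] = 2  # pop B fixed for alternate allele at marker 0
        geno[:, 1] = [0, 1] * 10
        geno[:, 2] = [1, 0] * 10
        ds = make_dataset(geno)
        track = fst_track(ds)
        assert track.values[0] == pytest.approx(1.0)

    def test_x_markers_get_nan_fst_but_finite_fisher(self):
        rng = np.random.default_rng(4)
        geno = rng.integers(0, 3, size=(20, 4)).astype(np.int8)
        ds = make_dataset(geno, chroms=["1", "1", "X", "X"],
                          positions=[100, 200, 100, 200])
        assert np.isnan(fst_track(ds).values[2:]).all()
        assert np.isfinite(fisher_track(ds).values[2:]).all()

    def test_null_split_mean_theta_near_zero(self):
        cfg = SimConfig(n_pop_a=100, n_pop_b=100, n_chrom=1, markers_per_chrom=2000,
                        f_background=0.0, missing_rate=0.0, seed=21)
        ds, _ = simulate_dataset(cfg)
        assert abs(np.nanmean(fst_track(ds).values)) < 0.01

    def test_tracks_invariant_to_population_relabeling(self, toy_dataset):
        flipped = make_dataset(
            toy_dataset.genotypes,
            chroms=[m.chrom for m in toy_dataset.markers],
            positions=[m.pos_bp for m in toy_dataset.markers],
            pops=[{"A": "B", "B": "A"}[s.population] for s in toy_dataset.samples])
        np.testing.assert_allclose(fst_track(toy_dataset).values,
                                   fst_track(flipped).values, atol=1e-12)
        np.testing.assert_allclose(fisher_track(toy_dataset).values,
                                   fisher_track(flipped).values, atol=1e-12)
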
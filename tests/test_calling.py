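"""Statistical cores of the three callers, against independent oracles."""

import math

import numpy as np
import pytest

from medipseq.calling import (NoCutoffError, agreement_percent, call_cppd,
                              call_nb, call_rpkm, cppd_pvalue,
                              empirical_fdr_cutoff, fit_nb, method_agreement,
                              nb_pvalue, normalize_input)


def poisson_tail_brute(k, lam, terms=2000):
    """P(X >= k) by direct pmf summation of the lower tail."""
    acc = 0.0
    logp = -lam
    for j in range(k):
        acc += math.exp(logp)
        logp += math.log(lam) - math.log(j + 1)
    return 1.0 - acc


class TestCppd:
    def test_zero_count_is_certain(self):
        assert cppd_pvalue(0, 3.0) == 1.0

    def test_closed_form_small_cases(self):
        assert cppd_pvalue(3, 1.0) == pytest.approx(
            1 - math.exp(-1) * (1 + 1 + 0.5), abs=1e-9)
        assert cppd_pvalue(1, 1.0) == pytest.approx(1 - math.exp(-1), abs=1e-9)

    def test_matches_brute_force_summation(self):
        """Oracle sweep: lambda <= 50, k <= 200, agreement to 1e-10."""
        for lam in (0.5, 1, 5, 20, 50):
            for k in (0, 1, 2, 5, 20, 50, 100, 200):
                assert cppd_pvalue(k, lam) == pytest.approx(
                    poisson_tail_brute(k, lam), abs=1e-10), (k, lam)

    def test_monotone_nonincreasing_in_k(self):
        lam = 7.3
        ps = [cppd_pvalue(k, lam) for k in range(0, 60)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_fractional_counts_are_floored(self):
        assert cppd_pvalue(3.9, 2.0) == cppd_pvalue(3, 2.0)

    def test_nonpositive_lambda_is_an_error(self):
        with pytest.raises(ValueError):
            cppd_pvalue(1, 0.0)


class TestNb:
    def test_zero_count_is_certain(self):
        assert nb_pvalue(0, 5.0, 2.0) == 1.0

    def test_geometric_closed_form(self):
        """mu=1, r=1 is geometric: P(X>=5) = 0.5^5."""
        assert nb_pvalue(5, 1.0, 1.0) == pytest.approx(0.03125, abs=1e-12)

    def test_poisson_limit(self):
        """NB tail converges to the Poisson tail as r -> infinity."""
        ks = np.arange(0, 101)
        for mu in (0.5, 2.0, 10.0, 20.0):
            diff = np.abs(nb_pvalue(ks, mu, 1e8) - cppd_pvalue(ks, mu))
            assert diff.max() < 1e-6
        assert nb_pvalue(7, 3.0, np.inf) == cppd_pvalue(7, 3.0)

    def test_monotone_nonincreasing_in_k(self):
        ps = [nb_pvalue(k, 8.0, 3.0) for k in range(0, 80)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_nonpositive_dispersion_is_an_error(self):
        with pytest.raises(ValueError):
            nb_pvalue(1, 1.0, -2.0)


class TestFitNb:
    def test_single_window_moments_example(self):
        """Replicates (4,8): mean 6, var 8 -> r = 36/2 = 18."""
        fit = fit_nb(np.array([[4, 8]]))
        assert fit.r == pytest.approx(18.0)

    def test_variance_equal_mean_degenerates_to_poisson(self):
        fit = fit_nb(np.array([[5, 5], [3, 3]]))
        assert np.isinf(fit.r)

    def test_single_replicate_is_an_error(self):
        with pytest.raises(ValueError, match="dispersion"):
            fit_nb(np.array([[4], [8]]))

    def test_parameter_recovery_on_simulated_counts(self):
        """NB(mu=20, r=5) over 2000 windows recovers r in [4, 6]."""
        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(5, 5 / 25, size=(2000, 2))
        fit = fit_nb(counts)
        assert 4 <= fit.r <= 6


class TestNormalizeInput:
    def test_depth_scaling(self):
        lam = normalize_input(np.array([10.0, 10.0]), 1e6, 2e6)
        assert np.allclose(lam, 20.0)

    def test_floor_raises_low_windows_to_the_mean(self):
        lam = normalize_input(np.array([1.0, 10.0, 4.0]), 1.0, 1.0)
        assert lam.tolist() == [5.0, 10.0, 5.0]

    def test_floor_only_raises(self, rng):
        counts = rng.integers(0, 40, 500).astype(float)
        lam = normalize_input(counts, 1e6, 1.7e6)
        assert np.all(lam >= counts * 1.7)
        # calls with the floor are a subset of calls without it
        obs = rng.poisson(20, 500)
        with_floor = call_cppd(obs, lam + 1e-9).mask
        without = call_cppd(obs, np.maximum(counts * 1.7, 1e-9)).mask
        assert not np.any(with_floor & ~without)


class TestEmpiricalFdr:
    def _brute_force_cutoff(self, sample, inputs, ratio, step=0.01):
        """Independent oracle: literal scan of the grid definition."""
        pairs = [np.abs(inputs[i] - inputs[j])
                 for i in range(len(inputs)) for j in range(len(inputs)) if i != j]
        diffs = sample - inputs.mean(axis=0)
        c = step
        top = diffs.max()
        while c <= top + step:
            ns = int((diffs >= c - 1e-12).sum())
            nn = float(np.mean([(p >= c - 1e-12).sum() for p in pairs]))
            if ns > 0 and ns >= ratio * nn:
                return round(c, 6)
            c += step
        return None

    def test_agrees_with_brute_force_scan(self, rng):
        inputs = rng.normal(10, 1, size=(3, 400)).clip(0)
        sample = inputs.mean(axis=0) + np.where(rng.random(400) < 0.3,
                                                rng.uniform(2.5, 6, 400), 0.0)
        for ratio in (1, 10, 100):
            expected = self._brute_force_cutoff(sample, inputs, ratio)
            got = empirical_fdr_cutoff(sample, inputs, ratio=ratio).cutoff_rpkm
            assert got == pytest.approx(expected, abs=1e-9), ratio

    def test_separated_sample_cuts_where_null_vanishes(self):
        """Null diffs <= 2.0, 150 sample diffs at 2.5 -> cutoff in (2.0, 2.5]."""
        inputs = np.vstack([np.zeros(400), np.full(400, 2.0)])
        sample = inputs.mean(axis=0).copy()
        sample[:150] += 2.5 + 1.0  # diff vs mean(inputs) = 2.5 above null max
        res = empirical_fdr_cutoff(sample, inputs, ratio=100)
        assert 2.0 < res.cutoff_rpkm <= 3.5 + 0.011
        assert res.n_null_exceed == 0
        assert res.n_sample_exceed == 150

    def test_null_vs_null_has_no_cutoff(self, rng):
        inputs = rng.normal(10, 1, size=(3, 500)).clip(0)
        with pytest.raises(NoCutoffError):
            empirical_fdr_cutoff(inputs[0], inputs, ratio=100)

    def test_ratio_one_degenerate_rule(self, rng):
        inputs = rng.normal(10, 1, size=(2, 300)).clip(0)
        sample = inputs.mean(axis=0) + rng.uniform(0, 3, 300)
        expected = self._brute_force_cutoff(sample, inputs, 1)
        assert empirical_fdr_cutoff(sample, inputs, ratio=1).cutoff_rpkm == \
            pytest.approx(expected, abs=1e-9)


class TestCallers:
    def test_rpkm_boundary_difference_is_called(self):
        inputs = np.zeros((2, 3))
        sample = np.array([2.0, 1.99, 0.0])
        cs = call_rpkm(sample, inputs, 2.0)
        assert cs.mask.tolist() == [True, False, False]

    def test_all_zero_sample_calls_nothing(self):
        cs = call_rpkm(np.zeros(5), np.zeros((2, 5)), 1.0)
        assert cs.n_called == 0

    def test_cppd_alpha_boundary_is_strict(self):
        lam = np.array([1.0])
        k = np.array([1])
        p = cppd_pvalue(k, lam)[0]
        cs = call_cppd(k, lam, alpha=p)
        assert cs.n_called == 0  # p < alpha is strict

    def test_huge_count_is_called(self):
        assert call_cppd(np.array([500]), np.array([2.0])).n_called == 1
        assert call_nb(np.array([500]), np.array([2.0]), 5.0).n_called == 1

    def test_cppd_null_call_rate_near_alpha(self):
        """Poisson-null counts are called at about the nominal tail level."""
        rng = np.random.default_rng(5)
        lam = np.full(200_000, 20.0)
        counts = rng.poisson(lam)
        cs = call_cppd(counts, lam, alpha=1e-3)
        # discreteness makes the realized level conservative
        assert cs.n_called / counts.size <= 2e-3


class TestAgreement:
    def test_published_agreement_cells_recompute(self):
        """Common/NB x 100 reproduces printed method-agreement percentages."""
        assert agreement_percent(1_096, 2_335) == 46.9
        assert agreement_percent(4_838, 6_499) == 74.4
        assert agreement_percent(29_388, 32_922) == 89.3

    def test_identical_callsets_agree_fully(self):
        mask = np.array([True, False, True, False])
        sets = [call_rpkm(np.array([3, 0, 3, 0.0]), np.zeros((2, 4)), 1.0),
                call_cppd(np.array([90, 0, 90, 0]), np.full(4, 2.0)),
                call_nb(np.array([90, 0, 90, 0]), np.full(4, 2.0), 5.0)]
        for s in sets:
            assert s.mask.tolist() == mask.tolist()
        out = method_agreement(sets)
        assert out["agreement_all"] == 1.0
        assert out["agreement_nb"] == 100.0

    def test_empty_nb_reports_missing_agreement(self):
        a = call_rpkm(np.array([3.0]), np.zeros((2, 1)), 1.0)
        b = call_cppd(np.array([90]), np.array([2.0]))
        c = call_nb(np.array([0]), np.array([2.0]), 5.0)
        assert method_agreement([a, b, c])["agreement_nb"] is None
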
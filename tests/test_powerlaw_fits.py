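"""Exponent MLE, gamma regression, kappa measures and the cutoff fit."""

import numpy as np
import pytest

from mscrit import (
    AvalancheSet,
    FitConfig,
    distribution_cutoff,
    fit_discrete_powerlaw_mle,
    fit_gamma,
    generalized_kappa,
    kappa,
    profile_at_scale,
    sample_discrete_powerlaw,
)
from mscrit.avalanches import extract_avalanches

from conftest import make_raster


def grid_mle(samples, xmin, xmax, grid):
    """Independent brute-force likelihood grid oracle."""
    x = samples[(samples >= xmin) & (samples <= xmax)]
    support = np.arange(xmin, xmax + 1)
    best_e, best_ll = None, -np.inf
    for e in grid:
        logz = np.log(np.sum(support.astype(float) ** (-e)))
        ll = -len(x) * logz - e * np.sum(np.log(x))
        if ll > best_ll:
            best_e, best_ll = e, ll
    return best_e


class TestDiscreteMLE:
    def test_uniform_sample_gives_zero_exponent(self):
        x = sample_discrete_powerlaw(100_000, 0.0, 1, 100, seed=1)
        e = fit_discrete_powerlaw_mle(x, 1, 100)
        assert abs(e) < 0.05
        assert abs(e - grid_mle(x, 1, 100, np.arange(-0.2, 0.2, 0.001))) < 0.002

    def test_recovers_generating_exponent(self):
        x = sample_discrete_powerlaw(100_000, 1.5, 1, 100, seed=2)
        e = fit_discrete_powerlaw_mle(x, 1, 100)
        assert 1.45 <= e <= 1.55
        assert abs(e - grid_mle(x, 1, 100, np.arange(1.3, 1.7, 0.001))) < 0.002

    def test_tiny_sample_matches_grid_oracle(self):
        x = np.array([1, 1, 1, 2])
        e = fit_discrete_powerlaw_mle(x, 1, 2, min_samples=1)
        oracle = grid_mle(x, 1, 2, np.arange(-1.0, 4.0, 0.001))
        assert e == pytest.approx(oracle, abs=0.002)

    def test_duplication_equivariance(self):
        x = sample_discrete_powerlaw(2_000, 1.7, 1, 50, seed=3)
        e1 = fit_discrete_powerlaw_mle(x, 1, 50)
        e2 = fit_discrete_powerlaw_mle(np.concatenate([x, x]), 1, 50)
        assert e1 == pytest.approx(e2, abs=1e-6)

    def test_out_of_range_samples_discarded(self):
        x = sample_discrete_powerlaw(10_000, 1.5, 1, 50, seed=4)
        spiked = np.concatenate([x, np.full(5_000, 500)])
        assert fit_discrete_powerlaw_mle(spiked, 1, 50) == pytest.approx(
            fit_discrete_powerlaw_mle(x, 1, 50), abs=1e-9
        )

    def test_too_few_samples_missing_with_warning(self):
        with pytest.warns(UserWarning, match="floor"):
            assert np.isnan(fit_discrete_powerlaw_mle(np.arange(1, 10), 1, 100))

    def test_degenerate_sample_diverges(self):
        with pytest.warns(UserWarning, match="diverges"):
            e = fit_discrete_powerlaw_mle(np.ones(100, dtype=int), 1, 10)
        assert np.isinf(e)

    def test_bias_decreases_with_sample_size(self):
        for true_e in (1.2, 1.5, 2.0):
            errs = []
            for n in (1_000, 30_000):
                est = [
                    fit_discrete_powerlaw_mle(
                        sample_discrete_powerlaw(n, true_e, 1, 100, seed=s), 1, 100
                    )
                    for s in range(8)
                ]
                errs.append(abs(np.mean(est) - true_e))
            assert errs[0] < 0.05
            assert errs[1] <= errs[0] + 0.005


class TestGamma:
    def _av(self, durations, sizes):
        durations = np.asarray(durations)
        sizes = np.asarray(sizes)
        return AvalancheSet(
            sizes=sizes,
            durations=durations,
            iai=np.ones(max(0, len(sizes) - 1), dtype=int),
            bin_profiles=tuple(
                np.r_[np.ones(d - 1, dtype=int), s - d + 1]
                for d, s in zip(durations, sizes)
            ),
            starts=np.arange(len(sizes)),
            scale_k=1,
            threshold=None,
            n_channels=8,
        )

    def test_exact_quadratic_relation(self):
        durations, sizes = [], []
        for d in (1, 2, 4, 8):
            durations += [d] * 5
            sizes += [d * d] * 5
        assert fit_gamma(self._av(durations, sizes)) == pytest.approx(2.0)

    def test_single_duration_is_missing(self):
        av = self._av([1] * 20, [1] * 20)
        assert np.isnan(fit_gamma(av))

    def test_matches_independent_regression(self, critical_avalanches):
        av = critical_avalanches
        g = fit_gamma(av)
        # independent re-implementation on the binned means
        d, c = np.unique(av.durations, return_counts=True)
        d = d[c >= 5]
        means = [av.sizes[av.durations == dd].mean() for dd in d]
        x, y = np.log(d), np.log(means)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert g == pytest.approx(slope, rel=1e-9)


class TestKappa:
    def test_powerlaw_sample_scores_near_one(self):
        x = sample_discrete_powerlaw(100_000, 1.5, 1, 64, seed=5)
        assert 0.97 <= kappa(x, 1.5, 1, 64) <= 1.03

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        x = rng.integers(1, 65, 5_000)
        k = kappa(x, 1.5, 1, 64, m=10)
        # independent spreadsheet-style recomputation
        betas = np.logspace(0, np.log10(64), 10)
        support = np.arange(1, 65)
        pmf = support ** -1.5
        pmf = pmf / pmf.sum()
        f_ref = np.array([pmf[: int(np.floor(b))].sum() for b in betas])
        f_emp = np.array([(x <= b).mean() for b in betas])
        assert k == pytest.approx(1 + np.mean(f_ref - f_emp), abs=1e-12)

    def test_subcritical_deficit_scores_below_one(self):
        # sharply decaying sample: large events missing relative to the
        # reference power law -> empirical CDF above it -> kappa < 1
        x = sample_discrete_powerlaw(50_000, 3.5, 1, 64, seed=7)
        assert kappa(x, 1.5, 1, 64) < 1.0

    def test_supercritical_excess_scores_above_one(self):
        x = sample_discrete_powerlaw(50_000, 0.5, 1, 64, seed=8)
        assert kappa(x, 1.5, 1, 64) > 1.0

    def test_empty_support_missing(self):
        assert np.isnan(kappa(np.array([200, 300]), 1.5, 1, 64))

    def test_generalized_kappa_near_one_for_any_exponent(self):
        for e, seed in ((0.8, 9), (1.5, 10), (2.5, 11)):
            x = sample_discrete_powerlaw(60_000, e, 1, 64, seed=seed)
            assert abs(generalized_kappa(x, 1, 64) - 1) < 0.03

    def test_generalized_kappa_flags_shape_deviance(self):
        rng = np.random.default_rng(12)
        logn = np.clip(rng.lognormal(2.0, 0.35, 50_000).astype(int), 1, 64)
        pl = sample_discrete_powerlaw(50_000, 1.5, 1, 64, seed=13)
        dev_logn = abs(generalized_kappa(logn, 1, 64) - 1)
        dev_pl = abs(generalized_kappa(pl, 1, 64) - 1)
        assert dev_logn > dev_pl

    def test_kappa_at_mle_exponent_equals_generalized(self):
        x = sample_discrete_powerlaw(20_000, 1.8, 1, 64, seed=14)
        e_hat = fit_discrete_powerlaw_mle(x, 1, 64)
        assert kappa(x, e_hat, 1, 64) == pytest.approx(
            generalized_kappa(x, 1, 64), abs=1e-12
        )


class TestCutoff:
    @staticmethod
    def _truncated_sample(n, e, s_c, xmin, hi, seed):
        support = np.arange(xmin, hi + 1)
        pmf = support ** (-e) * np.exp(-support / s_c)
        pmf = pmf / pmf.sum()
        rng = np.random.default_rng(seed)
        return rng.choice(support, size=n, p=pmf)

    def test_pure_powerlaw_has_no_interior_dropoff(self):
        # steep exponent on a wide support: the sample maximum is natural
        # (far below the support bound), so no drop-off should be found
        x = sample_discrete_powerlaw(50_000, 2.5, 1, 100_000, seed=15)
        assert distribution_cutoff(x) > x.max()

    def test_matches_likelihood_grid_oracle(self):
        x = self._truncated_sample(20_000, 1.5, 30.0, 1, 600, seed=17)
        s_hat = distribution_cutoff(x)
        # brute-force 2-D likelihood grid over (exponent, scale)
        support = np.arange(1, 20 * x.max() + 1, dtype=float)
        best, best_ll = None, -np.inf
        for e in np.arange(1.0, 2.01, 0.05):
            for s in np.arange(10, 80.0, 2.0):
                w = support ** (-e) * np.exp(-support / s)
                ll = -len(x) * np.log(w.sum()) - e * np.sum(np.log(x)) - np.sum(x) / s
                if ll > best_ll:
                    best, best_ll = (e, s), ll
        assert s_hat == pytest.approx(best[1], abs=4.0)

    def test_recovers_generative_scale(self):
        x = self._truncated_sample(100_000, 1.5, 20.0, 1, 400, seed=16)
        assert 15 <= distribution_cutoff(x) <= 26

    def test_degenerate_sample_missing(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert np.isnan(distribution_cutoff(np.ones(100, dtype=int)))


class TestProfile:
    def test_empty_set_all_missing(self):
        av = extract_avalanches(make_raster(np.zeros((2, 20), dtype=int)))
        prof = profile_at_scale(av)
        assert prof.flags == ("empty",)
        assert all(np.isnan(v) for v in prof.to_dict().values())

    def test_missing_components_flagged_not_zero(self):
        # a handful of avalanches: too few for any distribution fit
        av = extract_avalanches(make_raster([[1, 0, 1, 0, 1, 0], [0] * 6]))
        prof = profile_at_scale(av)
        assert np.isnan(prof.alpha) and "alpha" in prof.flags
        assert np.isnan(prof.gamma) and "gamma" in prof.flags
        assert np.isfinite(prof.sigma)

    def test_critical_exponents_near_mean_field(self, critical_avalanches):
        prof = profile_at_scale(critical_avalanches)
        assert 1.35 <= prof.alpha <= 1.65
        assert 0.9 <= prof.sigma <= 1.1
        assert np.isfinite(prof.tau) and np.isfinite(prof.delta)

    def test_crackling_scaling_relation_soft(self, critical_avalanches):
        # (tau - 1)/(alpha - 1) tracks gamma on critical simulations; a
        # soft cross-check, both sides estimated from the same data
        prof = profile_at_scale(critical_avalanches)
        lhs = (prof.tau - 1) / (prof.alpha - 1)
        assert abs(lhs - prof.gamma) < 0.35
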
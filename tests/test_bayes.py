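import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sugartrait.bayes import (
    GenusModel,
    conjugate_posterior,
    fit_all_genera,
    hpd_interval,
    log_posterior,
    sample_posterior,
    summarize_posterior,
    trait_regression,
    trait_spearman,
)
from sugartrait.simulate import SyntheticConfig, gen_diet_abundance, gen_trait_beta_pair


def scipy_log_posterior(model, alpha, beta, sigma):
    """Independent density oracle built from scipy distributions."""
    lp = (
        stats.norm.logpdf(alpha)
        + stats.norm.logpdf(beta)
        + stats.expon.logpdf(sigma)
    )
    mu = alpha + beta * model.x
    return float(lp + stats.norm.logpdf(model.y, loc=mu, scale=sigma).sum())


class TestLogPosterior:
    def test_prior_only_closed_form(self):
        m = GenusModel(y=np.zeros(0), x=np.zeros(0))
        expected = 2 * (-0.5 * math.log(2 * math.pi)) - 1.0
        assert log_posterior(m, 0.0, 0.0, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_single_point_closed_form(self):
        m = GenusModel(y=np.array([0.0]), x=np.array([0.0]))
        expected = 2 * (-0.5 * math.log(2 * math.pi)) - 1.0 + (
            -0.5 * math.log(2 * math.pi)
        )
        assert log_posterior(m, 0.0, 0.0, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_oracle(self, rng):
        x = rng.normal(size=17)
        y = rng.normal(size=17)
        m = GenusModel(y=y, x=x)
        for _ in range(20):
            a, b = rng.normal(size=2)
            s = rng.exponential() + 0.05
            assert log_posterior(m, a, b, s) == pytest.approx(
                scipy_log_posterior(m, a, b, s), abs=1e-10
            )

    def test_nonpositive_sigma_rejected(self):
        m = GenusModel(y=np.zeros(2), x=np.zeros(2))
        assert log_posterior(m, 0, 0, 0.0) == -math.inf
        assert log_posterior(m, 0, 0, -1.0) == -math.inf


class TestSampler:
    def test_same_seed_is_bit_identical(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        m = GenusModel(y=y, x=x)
        d1 = sample_posterior(m, seed=42)
        d2 = sample_posterior(m, seed=42)
        assert np.array_equal(d1.beta, d2.beta)
        assert np.array_equal(d1.sigma, d2.sigma)

    def test_prior_recovery_with_no_data(self):
        m = GenusModel(y=np.zeros(0), x=np.zeros(0))
        d = sample_posterior(m, seed=3)
        for name, (mean, sd) in {"alpha": (0, 1), "beta": (0, 1)}.items():
            draws = d.flat(name)
            mc_se = draws.std() / math.sqrt(d.ess[name])
            assert abs(draws.mean() - mean) <= 3 * mc_se
            assert abs(draws.std() - sd) <= 0.1
        sig = d.flat("sigma")
        assert abs(sig.mean() - 1.0) <= 3 * sig.std() / math.sqrt(d.ess["sigma"])

    def test_conjugate_posterior_with_fixed_sigma(self, rng):
        x = rng.normal(size=40)
        y = 1.0 + 0.8 * x + rng.normal(scale=0.6, size=40)
        m = GenusModel(y=y, x=x)
        d = sample_posterior(m, seed=11, fixed_sigma=0.6)
        mean, cov = conjugate_posterior(m, 0.6)
        for i, name in enumerate(("alpha", "beta")):
            draws = d.flat(name)
            mc_se = draws.std() / math.sqrt(d.ess[name])
            assert abs(draws.mean() - mean[i]) <= 3 * mc_se
            assert draws.std() == pytest.approx(math.sqrt(cov[i, i]), rel=0.15)

    def test_posterior_contraction(self):
        """The beta estimate approaches the planted slope as n grows."""
        errs = {}
        for n in (50, 500):
            rng = np.random.default_rng(n)
            x = rng.normal(size=n)
            y = 0.7 * x + rng.normal(scale=0.5, size=n)
            d = sample_posterior(GenusModel(y=y, x=x), seed=n)
            errs[n] = abs(d.flat("beta").mean() - 0.7)
        assert errs[500] < errs[50] < 0.2


class TestHPDAndSummary:
    def test_degenerate_point_mass(self):
        d = np.full(500, 2.5)
        assert hpd_interval(d) == (2.5, 2.5)

    def test_bruteforce_window_oracle(self, rng):
        draws = np.sort(rng.standard_t(df=3, size=1000))
        m = int(math.ceil(0.95 * 1000))
        best = min(
            ((draws[i + m - 1] - draws[i], i) for i in range(1000 - m + 1)),
        )
        lo, hi = hpd_interval(draws, 0.95)
        assert (lo, hi) == (draws[best[1]], draws[best[1] + m - 1])
        assert hi - lo <= np.quantile(draws, 0.975) - np.quantile(draws, 0.025) + 1e-12

    def test_symmetric_draws_include_zero(self, rng):
        vals = rng.normal(size=(4, 1000))

        class FakeDraws:
            rhat = {}
            ess = {}

            def flat(self, name):
                return vals.reshape(-1)

        s = summarize_posterior(FakeDraws())
        assert not s.excludes_zero
        assert s.ci66[0] > s.ci95[0] and s.ci66[1] < s.ci95[1]

    def test_all_positive_draws_exclude_zero(self):
        class FakeDraws:
            rhat = {}
            ess = {}

            def flat(self, name):
                return np.full(200, 1.7)

        s = summarize_posterior(FakeDraws())
        assert s.excludes_zero and s.hpd95 == (1.7, 1.7)


class TestFitAllGenera:
    def test_planted_signs_recovered(self):
        config = SyntheticConfig(
            seed=2, n_genera=3, n_samples=300, n_patients=30, sigma_noise=0.5
        )
        study = gen_diet_abundance(config, true_beta=np.array([-0.5, 0.0, 0.5]))
        exposures = pd.DataFrame(
            {
                "sample_id": study.abundance.index,
                "sugar_exposure": study.true_exposure.to_numpy(),
            }
        )
        from sugartrait.compositional import clr_transform

        clr = clr_transform(study.abundance)
        fits = fit_all_genera(clr, exposures, seed=5).set_index("genus")
        assert fits.loc["g000", "beta_mean"] < 0 < fits.loc["g002", "beta_mean"]
        assert fits.loc["g000", "excludes_zero"] and fits.loc["g002", "excludes_zero"]

    def test_empty_and_zero_variance_handling(self):
        clr = pd.DataFrame(
            {"gA": [0.1, -0.1, 0.0, 0.0], "gB": [0.0, 0.0, 0.0, 0.0]},
            index=[f"s{i}" for i in range(4)],
        )
        exposures = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(4)], "sugar_exposure": [1, 2, 3, 4.0]}
        )
        fits = fit_all_genera(clr, exposures, seed=1, chains=2, draws=200, warmup=200)
        assert fits.set_index("genus").loc["gB", "status"] == "zero_variance"
        assert fits.set_index("genus").loc["gA", "status"] == "ok"

    def test_requires_enough_exposed_samples(self):
        clr = pd.DataFrame({"g": [0.1, 0.2]}, index=["s1", "s2"])
        exposures = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "sugar_exposure": [None, 3.0]}
        )
        with pytest.raises(ValueError, match="3 samples"):
            fit_all_genera(clr, exposures, seed=0)


class TestTraitRegression:
    def test_covariate_max_normalization(self):
        census, summaries, _ = gen_trait_beta_pair(
            SyntheticConfig(seed=1, n_genera=3, sigma_beta=0.01)
        )
        census["abc"] = [10.0, 20.0, 40.0]
        reg = trait_regression(summaries, census, seed=1, chains=2, draws=200, warmup=400)
        assert reg.covariate == pytest.approx([0.25, 0.5, 1.0])

    def test_planted_linear_relation_detected(self):
        config = SyntheticConfig(seed=4, n_genera=40, trait_effect=1.0, sigma_beta=0.02)
        census, summaries, _ = gen_trait_beta_pair(config)
        reg = trait_regression(summaries, census, seed=9)
        assert reg.summary.beta_mean > 0
        assert reg.summary.hpd95[0] > 0
        assert reg.mean_curve is not None and len(reg.mean_curve) == 50
        assert np.all(reg.band_lo <= reg.mean_curve)
        assert np.all(reg.mean_curve <= reg.band_hi)

    def test_spearman_directions_and_tie_oracle(self):
        from test_growth import midrank_pearson

        census = pd.DataFrame(
            {
                "genus": list("abcd"),
                "abc": [1.0, 2.0, 2.0, 4.0],
                "pts": [0.0] * 4,
                "mfs": [0.0] * 4,
                "total": [1.0, 2.0, 2.0, 4.0],
            }
        )
        summaries = pd.DataFrame(
            {
                "genus": list("abcd"),
                "status": "ok",
                "beta_mean": [0.1, 0.2, 0.15, 0.4],
            }
        )
        rho, _ = trait_spearman(summaries, census, "abc")
        assert rho == pytest.approx(
            midrank_pearson([1, 2, 2, 4], [0.1, 0.2, 0.15, 0.4]), abs=1e-12
        )

    def test_all_zero_covariate_skips_regression(self):
        census = pd.DataFrame(
            {
                "genus": list("abc"),
                "abc": [0.0, 0.0, 0.0],
                "pts": [1.0, 2.0, 3.0],
                "mfs": [0.0] * 3,
                "total": [1.0, 2.0, 3.0],
            }
        )
        summaries = pd.DataFrame(
            {"genus": list("abc"), "status": "ok", "beta_mean": [0.1, 0.2, 0.3]}
        )
        reg = trait_regression(summaries, census, "abc", seed=0)
        assert reg.summary is None and math.isnan(reg.spearman_rho)

    def test_too_few_genera_refused(self):
        census, summaries, _ = gen_trait_beta_pair(
            SyntheticConfig(seed=1, n_genera=3)
        )
        with pytest.raises(ValueError, match=">= 3 genera"):
            trait_regression(summaries.iloc[:2], census, seed=0)
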
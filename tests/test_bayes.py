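"""Ordinal model, robust vividness regression, and the ROPE Bayes factor."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imaes import (
    DesignSpec,
    EffectSpec,
    McmcConfig,
    dissimilarity_score,
    fit_cumulative_probit,
    fit_vividness_regression,
    generate_ratings,
    rope_bayes_factor,
)

FAST = McmcConfig(chains=2, warmup=400, draws=400, seed=0)
# long enough for split-Rhat < 1.05 on every parameter
LONG = McmcConfig(chains=2, warmup=1500, draws=1500, seed=0)


class TestRopeBayesFactor:
    def test_closed_form_oracle(self):
        # analytic posterior and prior give the exact Gaussian-mass formula
        post = stats.norm(0.0, 0.02)
        prior = stats.norm(0.0, 1.0)
        res = rope_bayes_factor(post, prior=prior, rope=(-0.1, 0.1))

        def mass(d):
            return d.cdf(0.1) - d.cdf(-0.1)

        expected = (mass(post) / (1 - mass(post))) / (mass(prior) / (1 - mass(prior)))
        assert res.bf01 == pytest.approx(expected, rel=1e-12)
        assert res.bf01 > 3

    def test_posterior_equal_to_prior_is_one(self):
        prior = stats.norm(0.0, 1.0)
        res = rope_bayes_factor(prior, prior=prior)
        assert res.bf01 == pytest.approx(1.0, rel=1e-12)

    def test_posterior_far_outside_rope(self):
        res = rope_bayes_factor(stats.norm(2.0, 0.05), prior=stats.norm(0.0, 1.0))
        assert res.bf01 < 1e-6

    def test_all_draws_inside_is_infinite(self):
        res = rope_bayes_factor(np.zeros(100), prior=stats.norm(0.0, 1.0))
        assert res.infinite
        assert np.isinf(res.bf01)

    def test_zero_prior_mass_inside_errors(self):
        with pytest.raises(ValueError, match="zero mass"):
            rope_bayes_factor(np.zeros(10), prior=stats.uniform(5.0, 1.0))

    def test_invalid_rope(self):
        with pytest.raises(ValueError):
            rope_bayes_factor(np.zeros(10), prior=stats.norm(), rope=(0.1, -0.1))

    def test_bf_monotone_in_effect_size(self):
        prior = stats.norm(0.0, 1.0)
        bfs = [
            rope_bayes_factor(stats.norm(mu, 0.05), prior=prior).bf01
            for mu in (0.0, 0.12, 0.4)
        ]
        assert bfs[0] > bfs[1] > bfs[2]


class TestCumulativeProbit:
    def test_null_effect_recovery(self):
        d = DesignSpec(n_subjects=10, n_stimuli_per_type=8, seed=31)
        eff = EffectSpec(beta_modality=0.0, beta_type=0.0)
        fit = fit_cumulative_probit(generate_ratings(d, eff), config=LONG)
        lo, hi = fit.interval("beta_modality")
        assert lo < 0.0 < hi
        assert fit.converged

    def test_thresholds_ordered_in_every_draw(self):
        d = DesignSpec(n_subjects=6, n_stimuli_per_type=5, seed=3)
        ratings = generate_ratings(d, EffectSpec())
        fit = fit_cumulative_probit(
            ratings,
            config=McmcConfig(chains=2, warmup=200, draws=200, seed=1),
            init_thresholds=np.array([1.0, -1.0, 0.0, 2.0, -2.0, 0.5]),
        )
        tau = fit.array("tau")
        assert (np.diff(tau, axis=1) > 0).all()

    def test_degenerate_single_category_errors(self, small_ratings):
        table = small_ratings.copy()
        table["moving"] = 4
        with pytest.raises(ValueError, match="single observed rating category"):
            fit_cumulative_probit(table, config=FAST)

    def test_all_missing_errors(self, small_ratings):
        table = small_ratings.copy()
        table["moving"] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            fit_cumulative_probit(table, config=FAST)

    def test_summary_has_diagnostics(self, small_ratings):
        fit = fit_cumulative_probit(
            small_ratings, config=McmcConfig(chains=2, warmup=200, draws=200, seed=2)
        )
        s = fit.summary()
        assert {"parameter", "mean", "rhat", "ess_bulk"} <= set(s.columns)
        row = s[s.parameter == "beta_modality"]
        assert np.isfinite(row["rhat"].iloc[0])

    def test_intervals_calibrated_under_prior_drawn_truths(self):
        # simulation-based calibration: draw the modality effect from its own
        # prior, simulate matched data (no vividness coupling, which the fit
        # does not model), and check 95% interval coverage of the truth
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 25
        cfg = McmcConfig(chains=2, warmup=500, draws=500, seed=5)
        for rep in range(n_rep):
            truth = float(rng.normal())
            d = DesignSpec(n_subjects=8, n_stimuli_per_type=6, seed=3000 + rep)
            ratings = generate_ratings(
                d, EffectSpec(beta_modality=truth, kappa=0.0)
            )
            lo, hi = fit_cumulative_probit(ratings, config=cfg).interval(
                "beta_modality"
            )
            hits += lo <= truth <= hi
        assert hits >= 20  # 95% nominal; binomial(25, .95) P(<20) < 0.01


class TestVividnessRegression:
    @staticmethod
    def _scores(kappa, seed, n_subjects=20, n_stim=12):
        d = DesignSpec(n_subjects=n_subjects, n_stimuli_per_type=n_stim, seed=seed)
        eff = EffectSpec(kappa=kappa, vividness_probs=(1 / 7.0,) * 7)
        return dissimilarity_score(generate_ratings(d, eff))

    def test_null_slope_ci_contains_zero(self):
        fit = fit_vividness_regression(self._scores(0.0, 41), config=LONG)
        lo, hi = fit.interval("beta_vividness")
        assert lo < 0.0 < hi
        assert fit.converged

    def test_planted_coupling_gives_negative_slope(self):
        fit = fit_vividness_regression(self._scores(3.6, 42), config=FAST)
        lo, hi = fit.interval("beta_vividness")
        assert hi < 0.0

    def test_ci_shrinks_with_sample_size(self):
        widths = []
        for n_subj in (8, 32):
            fit = fit_vividness_regression(
                self._scores(0.0, 43, n_subjects=n_subj), config=FAST
            )
            lo, hi = fit.interval("beta_vividness")
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_zero_variance_vividness_errors(self):
        t = pd.DataFrame(
            {"subject_id": ["a", "a", "b"], "score": [1, 2, 3], "vividness": [5, 5, 5]}
        )
        with pytest.raises(ValueError, match="zero variance"):
            fit_vividness_regression(t, config=FAST)

    def test_constant_score_slope_near_zero(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(
            {
                "subject_id": np.repeat(["a", "b", "c", "d"], 20),
                "score": 5.0,
                "vividness": rng.integers(1, 8, size=80),
            }
        )
        fit = fit_vividness_regression(t, config=FAST)
        lo, hi = fit.interval("beta_vividness")
        assert lo < 0.0 < hi

    def test_rope_from_fit_uses_recorded_prior(self):
        fit = fit_vividness_regression(self._scores(0.0, 44), config=FAST)
        res = rope_bayes_factor(fit, parameter="beta_vividness")
        assert res.prior_mass == pytest.approx(
            stats.norm(0, 1).cdf(0.1) - stats.norm(0, 1).cdf(-0.1), rel=1e-9
        )
        assert res.bf01 > 0
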
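"""Tests for model prediction, fitting and normalized-likelihood comparison."""

import math

import numpy as np
import pandas as pd
import pytest

import audcat as ac
from audcat import model_fitting as mf
from audcat import synthetic_data as synth


class TestFitSpec:
    def test_canonical_variant_free_counts(self):
        assert mf.FitSpec.prediction(0.02).n_free == 0
        assert mf.FitSpec.subjective_seven(0.02).n_free == 7
        assert mf.FitSpec.subjective_eight().n_free == 8

    def test_seven_parameter_variant_fixes_sigma_s(self):
        spec = mf.FitSpec.subjective_seven(0.033)
        assert "sigma_s" not in spec.free
        assert spec.fixed_values["sigma_s"] == 0.033

    def test_sigma_s_must_be_free_or_fixed(self):
        with pytest.raises(ValueError, match="sigma_s"):
            mf.FitSpec("match", "subjective", ("mu_a",))

    def test_objective_family_rejects_free_parameters(self):
        with pytest.raises(ValueError):
            mf.FitSpec("match", "objective", ("mu_a",), {"sigma_s": 0.02})


class TestTrialLoglik:
    def test_coin_flip_model_scores_n_log_half(self, scale, match_trials):
        """An observer whose psi is 0.5 everywhere scores n*log(0.5).

        Identical category distributions with a half prior give posterior 0.5
        for every measurement, hence psi identically 0.5."""
        cat = ac.SubjectiveCategory("A", 10.7, 2.3, 0.1)
        same = ac.SubjectiveCategory("B", 10.7, 2.3, 0.1)
        model = ac.ObserverModel(
            scale, cat, same, {0.25: 0.5, 0.5: 0.5, 0.75: 0.5}, 0.02, "match"
        )
        n = len(match_trials)
        assert mf.trial_loglik(match_trials, model) == pytest.approx(n * math.log(0.5), rel=1e-9)

    def test_additivity_under_duplication(self, scale, match_trials, match_observer):
        single = mf.trial_loglik(match_trials, match_observer)
        doubled = mf.trial_loglik(
            pd.concat([match_trials, match_trials], ignore_index=True), match_observer
        )
        assert doubled == pytest.approx(2 * single, rel=1e-12)

    def test_generative_model_beats_mismatched_rule(self, scale, match_observer):
        """MATCH data scored under MATCH beats the same parameters under MAP."""
        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            design = synth.ExperimentDesign(n_sessions=1, trials_per_block=600, seed=700 + rep)
            t = synth.generate_trial_sequence(design)
            t = synth.simulate_observer(t, match_observer, np.random.default_rng(800 + rep))
            if mf.trial_loglik(t, match_observer) > mf.trial_loglik(
                t, match_observer.with_rule("map")
            ):
                wins += 1
        assert wins >= int(0.95 * n_rep)

    def test_missing_condition_prior_raises(self, scale, match_trials):
        model = ac.ObserverModel.objective(scale, 0.02, conditions=(0.5,))
        with pytest.raises(KeyError):
            mf.trial_loglik(match_trials, model)


class TestReferences:
    def test_balanced_bins_make_references_coincide(self, scale):
        trials = pd.DataFrame(
            {
                "subject": "S1",
                "session": 1,
                "condition": 0.5,
                "trial_index": range(18),
                "true_category": "A",
                "frequency_hz": np.repeat(np.geomspace(520, 5400, 9), 2),
                "choice": ["A", "B"] * 9,
            }
        )
        rand, emp = mf.reference_logliks(trials, scale)
        assert emp == pytest.approx(rand)

    def test_deterministic_data_explain_themselves_perfectly(self, scale, match_trials):
        det = match_trials.copy()
        # split exactly at a bin edge so every bin's choice probability is 0 or 1
        edge = scale.to_hz(scale.x_min + scale.span / 3)
        det["choice"] = np.where(det["frequency_hz"] < edge, "A", "B")
        rand, emp = mf.reference_logliks(det, scale)
        assert emp == pytest.approx(0.0, abs=1e-9)

    def test_empirical_dominates_random_on_random_data(self, scale):
        """Gibbs' inequality: the empirical binomial reference always scores
        at least as high as random guessing."""
        rng = np.random.default_rng(5)
        for rep in range(20):
            n = 400
            trials = pd.DataFrame(
                {
                    "subject": "S1",
                    "session": 1,
                    "condition": 0.5,
                    "trial_index": range(n),
                    "true_category": "A",
                    "frequency_hz": np.exp(
                        rng.uniform(math.log(500), math.log(5550), n)
                    ),
                    "choice": rng.choice(["A", "B"], n),
                }
            )
            rand, emp = mf.reference_logliks(trials, scale)
            assert emp >= rand - 1e-9

    def test_normalized_anchors(self):
        refs = (-100.0, -40.0)
        assert mf.normalized_loglik(-100.0, refs) == 0.0
        assert mf.normalized_loglik(-40.0, refs) == 1.0
        assert mf.normalized_loglik(-130.0, refs) == -0.5

    def test_uninformative_data_rejected(self):
        with pytest.raises(ValueError, match="uninformative"):
            mf.normalized_loglik(-50.0, (-100.0, -100.0))


class TestFitModel:
    def test_empty_free_set_returns_fixed_model_score(self, scale, match_trials):
        spec = mf.FitSpec.prediction(0.02, rule="match")
        res = mf.fit_model(match_trials, spec, scale)
        model = ac.ObserverModel.objective(scale, 0.02, rule="match")
        assert res.loglik == pytest.approx(mf.trial_loglik(match_trials, model), rel=1e-12)
        assert res.params == {"sigma_s": 0.02}

    def test_fit_determinism(self, scale, match_trials):
        spec = mf.FitSpec.subjective_seven(0.02)
        a = mf.fit_model(match_trials, spec, scale, seed=3, n_starts=2, maxiter=60)
        b = mf.fit_model(match_trials, spec, scale, seed=3, n_starts=2, maxiter=60)
        assert a.params == b.params

    def test_subjective_seven_recovers_priors(self, scale, match_trials):
        """Prior-probability parameters are identified by the plateau heights."""
        spec = mf.FitSpec.subjective_seven(0.02)
        res = mf.fit_model(match_trials, spec, scale, seed=0, n_starts=6)
        assert res.params["pi_0.25"] == pytest.approx(0.25, abs=0.07)
        assert res.params["pi_0.5"] == pytest.approx(0.5, abs=0.07)
        assert res.params["pi_0.75"] == pytest.approx(0.75, abs=0.07)
        assert res.norm_loglik > 0.9

    def test_self_consistency_of_fitted_model(self, scale, match_trials):
        """Data re-simulated from a fitted model are scored by that model
        within a few units of its own fit likelihood per 1000 trials."""
        spec = mf.FitSpec.subjective_seven(0.02)
        res = mf.fit_model(match_trials, spec, scale, seed=1, n_starts=4)
        resim = synth.simulate_observer(
            match_trials.drop(columns="choice").assign(choice=""),
            res.model,
            np.random.default_rng(99),
        )
        ll_resim = mf.trial_loglik(resim, res.model)
        n = res.n_trials
        # same expected per-trial entropy up to sampling error
        assert ll_resim / n == pytest.approx(res.loglik / n, abs=0.1)

    def test_normalized_likelihood_ordering_match_vs_map(self, scale, match_trials):
        """On probability-matching data at measured-scale noise: the MATCH
        prediction beats the MAP prediction, the MAP prediction scores below
        random guessing, and the subjective-7 MATCH fit approaches the
        empirical reference while the MAP fit stays poor."""
        pred_match = mf.fit_model(match_trials, mf.FitSpec.prediction(0.02, rule="match"), scale)
        pred_map = mf.fit_model(match_trials, mf.FitSpec.prediction(0.02, rule="map"), scale)
        assert pred_match.norm_loglik > pred_map.norm_loglik
        assert pred_map.norm_loglik < 0.0

        fit_match = mf.fit_model(
            match_trials, mf.FitSpec.subjective_seven(0.02, rule="match"), scale,
            seed=2, n_starts=6,
        )
        fit_map = mf.fit_model(
            match_trials, mf.FitSpec.subjective_seven(0.02, rule="map"), scale,
            seed=2, n_starts=6,
        )
        assert fit_match.norm_loglik >= 0.9
        assert fit_map.norm_loglik < 0.5
        assert fit_match.norm_loglik > fit_map.norm_loglik

    def test_map_eight_parameter_fit_inflates_sigma_s(self, scale, match_trials):
        """Fitting the optimal rule to matching behavior requires sensory
        noise far above the generative level; MATCH recovers it."""
        res_map = mf.fit_model(
            match_trials, mf.FitSpec.subjective_eight(rule="map"), scale, seed=4, n_starts=8
        )
        assert res_map.params["sigma_s"] >= 10 * 0.02
        # the MATCH fit keeps sigma_s at the measured scale; it trades off with
        # the smoothing SD, so the point estimate is only loosely pinned
        res_match = mf.fit_model(
            match_trials, mf.FitSpec.subjective_eight(rule="match"), scale, seed=4, n_starts=6
        )
        assert res_match.params["sigma_s"] < 5 * 0.02
        assert res_match.params["sigma_s"] < res_map.params["sigma_s"] / 5

    def test_no_responded_trials_rejected(self, scale, match_trials):
        silent = match_trials.copy()
        silent["choice"] = "none"
        with pytest.raises(ValueError, match="no responded trials"):
            mf.fit_model(silent, mf.FitSpec.prediction(0.02), scale)


class TestReconstruction:
    def _result(self, scale, mu_a=10.1, mu_b=11.3, width=2.3, sigma_cat=0.3):
        params = {
            "mu_a": mu_a, "mu_b": mu_b, "width": width, "sigma_cat": sigma_cat,
            "pi_0.25": 0.25, "pi_0.5": 0.5, "pi_0.75": 0.75, "sigma_s": 0.02,
        }
        spec = mf.FitSpec.subjective_eight()
        model = mf._build_model(params, spec, scale)
        return mf.ModelFitResult(spec, model, params, -1.0, None, None, 0)

    def test_density_normalizes_on_wide_grid(self, scale):
        res = self._result(scale)
        grid = np.geomspace(50, 50000, 4001)
        recon = mf.reconstruct_distributions(res, grid)
        x = scale.to_log(grid)
        for col in ("density_a", "density_b"):
            assert np.trapezoid(recon[col], x) == pytest.approx(1.0, abs=1e-4)

    def test_small_smoothing_recovers_box(self, scale):
        res = self._result(scale, sigma_cat=1e-4)
        grid = np.geomspace(500, 5550, 501)
        recon = mf.reconstruct_distributions(res, grid)
        x = scale.to_log(grid)
        inside = (x > 10.1 - 2.3 / 2 + 0.01) & (x < 10.1 + 2.3 / 2 - 0.01)
        np.testing.assert_allclose(recon.loc[inside, "density_a"], 1 / 2.3, rtol=1e-6)

    def test_heavy_smoothing_approaches_moment_matched_gaussian(self, scale):
        """sigma_cat >> width: density tends to a Gaussian whose variance is
        sigma_cat^2 + width^2/12 (box variance plus smoothing variance)."""
        width, sigma_cat = 0.5, 2.0
        res = self._result(scale, width=width, sigma_cat=sigma_cat)
        grid = np.geomspace(50, 50000, 1001)
        x = scale.to_log(grid)
        sd = math.sqrt(sigma_cat**2 + width**2 / 12)
        gauss = np.exp(-0.5 * ((x - 10.1) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
        recon = mf.reconstruct_distributions(res, grid)
        np.testing.assert_allclose(recon["density_a"], gauss, atol=2e-3)

    def test_bootstrap_envelope_columns(self, scale):
        res = self._result(scale)
        res.boot_params = pd.DataFrame(
            {
                "mu_a": [10.0, 10.2], "mu_b": [11.2, 11.4],
                "width": [2.2, 2.4], "sigma_cat": [0.2, 0.4],
            }
        )
        grid = np.geomspace(500, 5550, 50)
        recon = mf.reconstruct_distributions(res, grid)
        for col in ("density_a_lo", "density_a_hi", "density_b_lo", "density_b_hi"):
            assert col in recon.columns
        assert (recon["density_a_lo"] <= recon["density_a_hi"] + 1e-12).all()

    def test_bootstrap_refits_stay_near_point_estimate(self, scale, match_trials):
        spec = mf.FitSpec.subjective_seven(0.02)
        res = mf.fit_model(match_trials, spec, scale, seed=5, n_starts=2, maxiter=60)
        boots = mf.bootstrap_fit(match_trials, spec, res, n_boot=2, seed=6, maxiter=20)
        assert list(boots.columns) == list(spec.free)
        for pi_name in ("pi_0.25", "pi_0.5", "pi_0.75"):
            assert np.all(np.abs(boots[pi_name] - res.params[pi_name]) < 0.15)

    def test_objective_family_rejected(self, scale, match_trials):
        pred = mf.fit_model(match_trials, mf.FitSpec.prediction(0.02), scale)
        with pytest.raises(ValueError, match="objective"):
            mf.reconstruct_distributions(pred, np.geomspace(500, 5550, 10))
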
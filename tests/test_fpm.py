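"""Foot-placement model: state extraction, de-meaning, per-phase OLS."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gaitfpc as g
from gaitfpc.events import segment_steps, time_normalize


@pytest.fixture(scope="module")
def stride(default_trial):
    windows = segment_steps(default_trial.truth.events)
    return time_normalize(default_trial.signals, windows, fs=default_trial.fs)


class TestComStates:
    def test_com_on_stance_foot_gives_zero(self, stride):
        fake = dict(stride.channels)
        sides = stride.sides_leading()
        fake["com_pos_ap_m"] = np.stack(
            [stride.channels[f"heel_ap_{s}_m"][i] for i, s in enumerate(sides)])
        s2 = type(stride)(channels=fake, j_ds=stride.j_ds, j_ss=stride.j_ss,
                          windows=stride.windows, fs=stride.fs)
        P, _ = g.compute_com_states(s2)
        assert np.max(np.abs(P)) == 0.0

    def test_translation_invariance(self, stride):
        shifted = dict(stride.channels)
        for c in ("com_pos_ap_m", "heel_ap_left_m", "heel_ap_right_m"):
            shifted[c] = stride.channels[c] + 0.5
        s2 = type(stride)(channels=shifted, j_ds=stride.j_ds, j_ss=stride.j_ss,
                          windows=stride.windows, fs=stride.fs)
        P1, V1 = g.compute_com_states(stride)
        P2, V2 = g.compute_com_states(s2)
        np.testing.assert_allclose(P1, P2, atol=1e-12)
        np.testing.assert_allclose(V1, V2, atol=0)

    def test_heel_strike_states_match_truth(self, default_config, default_trial, stride):
        P, V = g.compute_com_states(stride)
        n_s = default_config.samples_per_step
        idx = np.array([w.start // n_s for w in stride.windows])
        truth = default_trial.truth.com_hs_states[idx]
        # j = 100% falls exactly on the heel-strike sample: no interpolation
        np.testing.assert_allclose(P[:, -1], truth[:, 0], atol=1e-9)
        np.testing.assert_allclose(V[:, -1], truth[:, 1], atol=1e-9)


class TestFootPlacement:
    def test_worked_demeaning(self):
        fp = g.compute_foot_placement([0.50, 0.60, 0.70], [0.0, 0.0, 0.0])
        np.testing.assert_allclose(fp, [-0.10, 0.0, 0.10], atol=1e-15)

    def test_identical_steps_give_zero(self):
        fp = g.compute_foot_placement([0.6] * 5, [0.1] * 5)
        assert np.all(fp == 0.0)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            g.compute_foot_placement([0.5, 0.6], [0.0, 0.0])


class TestFitFpm:
    def test_worked_three_step_example_matches_normal_equations(self):
        fp = np.array([-0.10, 0.004, 0.10])
        pos = np.array([-0.02, 0.001, 0.021])[:, None]   # perturbed to break
        vel = np.array([-0.05, -0.002, 0.05])[:, None]   # collinearity
        fit = g.fit_fpm(fp, pos, vel)
        X = np.column_stack([pos[:, 0] - pos.mean(), vel[:, 0] - vel.mean()])
        beta = np.linalg.solve(X.T @ X, X.T @ (fp - fp.mean()))
        assert fit.beta_pos[0] == pytest.approx(beta[0], abs=1e-9)
        assert fit.beta_vel[0] == pytest.approx(beta[1], abs=1e-9)

    def test_null_r2_expectation(self):
        # with FP independent of the states, E[R^2] = p/(n-1) for p=2
        rng = np.random.default_rng(3)
        n, reps = 50, 500
        r2 = np.empty(reps)
        for i in range(reps):
            fit = g.fit_fpm(rng.standard_normal(n),
                            rng.standard_normal((n, 1)),
                            rng.standard_normal((n, 1)))
            r2[i] = fit.r_squared[0]
        assert r2.mean() == pytest.approx(2.0 / (n - 1), rel=0.15)

    def test_rank_deficiency_flagged_not_zeroed(self):
        rng = np.random.default_rng(0)
        pos = rng.standard_normal((10, 3))
        vel = 2.0 * pos
        fit = g.fit_fpm(rng.standard_normal(10), pos, vel)
        assert fit.degenerate.all()
        assert np.isnan(fit.beta_pos).all() and np.isnan(fit.beta_vel).all()

    def test_residual_mean_zero_every_phase(self, analyzed):
        for fit in analyzed.fits.values():
            assert np.nanmax(np.abs(fit.residuals.mean(axis=0))) < 1e-12

    def test_r2_invariant_to_predictor_rescaling(self):
        rng = np.random.default_rng(5)
        fp = rng.standard_normal(40)
        pos = rng.standard_normal((40, 4))
        vel = rng.standard_normal((40, 4))
        f1 = g.fit_fpm(fp, pos, vel)
        f2 = g.fit_fpm(fp, pos * 10.0, vel * 0.25)
        np.testing.assert_allclose(f1.r_squared, f2.r_squared, rtol=1e-10)
        np.testing.assert_allclose(f1.beta_pos, f2.beta_pos * 10.0, rtol=1e-10)
        np.testing.assert_allclose(f1.beta_vel, f2.beta_vel * 0.25, rtol=1e-10)

    def test_missing_values_rejected(self):
        pos = np.ones((5, 2))
        pos[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            g.fit_fpm(np.arange(5.0), pos, np.ones((5, 2)))

    @given(shift=st.floats(-10, 10, allow_nan=False))
    def test_fit_invariant_to_constant_fp_offset(self, shift):
        rng = np.random.default_rng(7)
        fp = rng.standard_normal(20)
        pos = rng.standard_normal((20, 3))
        vel = rng.standard_normal((20, 3))
        f1 = g.fit_fpm(fp, pos, vel)
        f2 = g.fit_fpm(fp + shift, pos, vel)
        np.testing.assert_allclose(f1.beta_pos, f2.beta_pos, atol=1e-9)
        np.testing.assert_allclose(f1.residuals, f2.residuals, atol=1e-9)


class TestErrors:
    def test_estimated_errors_track_truth(self, pipe_config):
        cfg = g.GeneratorConfig(n_strides=1000, seed=17)
        trial = g.simulate_trial(cfg)
        res = g.analyze_trial(trial, pipe_config, signals=(), contrasts=False)
        n_s = cfg.samples_per_step
        idx = np.array([w.start // n_s for w in res.stride.windows])
        tru = trial.truth.fp_errors[idx]
        ok = ~np.isnan(res.errors_by_step)
        r = np.corrcoef(res.errors_by_step[ok], tru[ok])[0, 1]
        assert r >= 0.95

    def test_error_mean_exactly_zero(self, analyzed):
        for fit in analyzed.fits.values():
            assert abs(g.foot_placement_errors(fit).mean()) < 1e-12

    def test_perfect_fit_gives_zero_errors(self):
        rng = np.random.default_rng(1)
        pos = rng.standard_normal((20, 2))
        vel = rng.standard_normal((20, 2))
        fp = 1.5 * pos[:, -1] + 0.3 * vel[:, -1]
        fit = g.fit_fpm(fp, pos, vel)
        assert fit.r_squared[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(g.foot_placement_errors(fit))) < 1e-12


class TestSummarizeErrors:
    def test_gaussian_mle_consistency(self):
        rng = np.random.default_rng(2)
        s = g.summarize_errors(rng.normal(0.0, 0.013, size=20000))
        assert s["gaussian_sigma"] == pytest.approx(0.013, rel=0.03)
        assert abs(s["mean"]) < 4 * 0.013 / np.sqrt(20000)

    def test_constant_vector_degenerate(self):
        s = g.summarize_errors(np.full(10, 0.2))
        assert s["sd"] == 0.0 and s["degenerate"]
        assert np.isnan(s["shapiro_p"])

    def test_slow_condition_has_larger_error_sd(self, pipe_config):
        sds = {}
        for name, cfg in (("normal", g.normal_config(seed=9)),
                          ("slow", g.slow_config(seed=9))):
            res = g.analyze_trial(g.simulate_trial(cfg), pipe_config,
                                  signals=(), contrasts=False)
            e = np.concatenate([g.foot_placement_errors(f) for f in res.fits.values()])
            sds[name] = g.summarize_errors(e)["sd"]
        assert sds["slow"] > sds["normal"]


class TestParameterRecoveryScaling:
    def test_rmse_shrinks_with_sample_size(self, pipe_config):
        # quick 1/sqrt(n) sanity check (the acceptance suite runs the full
        # Monte-Carlo version): RMSE at n=800 strides is well below n=50
        rmse = {}
        for n in (50, 800):
            errs = []
            for rep in range(8):
                cfg = g.GeneratorConfig(n_strides=n, seed=1000 + 10 * n + rep)
                res = g.analyze_trial(g.simulate_trial(cfg), pipe_config,
                                      signals=(), contrasts=False)
                for fit in res.fits.values():
                    errs.append(fit.beta_pos[-1] - 1.2)
                    errs.append(fit.beta_vel[-1] - 0.35)
            rmse[n] = np.sqrt(np.mean(np.square(errs)))
        assert rmse[800] < rmse[50] / 2.0
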
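"""Event detection from the CoP butterfly, segmentation and normalization."""

import numpy as np
import pytest

import gaitfpc as g
from gaitfpc.events import StepWindow, grid_times

from conftest import event_match_stats


def detect(trial, **kw):
    df = trial.signals
    return g.detect_events_from_cop(df["cop_ap_m"].to_numpy(),
                                    df["cop_ml_m"].to_numpy(), trial.fs, **kw)


class TestDetection:
    def test_matches_truth_on_clean_trial(self, default_trial):
        table = detect(default_trial)
        frac, fp = event_match_stats(table, default_trial.truth.events)
        assert frac >= 0.99
        assert fp == 0

    @pytest.mark.parametrize("noise_frac", [0.05, 0.10, 0.20])
    def test_robust_to_cop_noise(self, noise_frac):
        # noise SD as a fraction of the ML butterfly amplitude (step_width/2)
        cfg = g.GeneratorConfig(seed=31, cop_noise_sd=noise_frac * 0.05)
        trial = g.simulate_trial(cfg)
        table = detect(trial)
        frac, fp = event_match_stats(table, trial.truth.events)
        assert frac >= 0.99
        assert fp <= 2

    def test_constant_cop_fails_explicitly(self):
        with pytest.raises(g.EventDetectionError):
            g.detect_events_from_cop(np.zeros(5000), np.zeros(5000), 200.0)

    def test_time_reversed_trial_swaps_event_roles(self, default_trial):
        df = default_trial.signals
        n = len(df)
        table = g.detect_events_from_cop(df["cop_ap_m"].to_numpy()[::-1],
                                         df["cop_ml_m"].to_numpy()[::-1],
                                         default_trial.fs)
        truth = default_trial.truth.events
        # a heel strike in reversed time is the completion of a reversed
        # transfer, i.e. an original toe-off (and vice versa)
        det_hs = np.sort(np.concatenate(list(table.heel_strikes.values())))
        exp_hs = np.sort(n - 1 - np.concatenate(list(truth.toe_offs.values())))
        d = np.abs(det_hs[:, None] - exp_hs[None, :])
        assert np.mean(d.min(axis=0) <= 1) >= 0.99
        det_to = np.sort(np.concatenate(list(table.toe_offs.values())))
        exp_to = np.sort(n - 1 - np.concatenate(list(truth.heel_strikes.values())))
        d = np.abs(det_to[:, None] - exp_to[None, :])
        assert np.mean(d.min(axis=0) <= 1) >= 0.98

    def test_event_table_requires_alternation(self):
        with pytest.raises(Exception):
            g.GaitEventTable(
                fs=100.0,
                heel_strikes={"left": np.array([0, 100]), "right": np.array([220])},
                toe_offs={"left": np.array([]), "right": np.array([])},
            ).merged_heel_strikes()


class TestSegmentation:
    def test_step_count_from_truth(self, default_config, default_trial):
        windows = g.segment_steps(default_trial.truth.events)
        assert len(windows) == 2 * default_config.n_strides
        for w in windows:
            assert w.ds_duration_s > 0
            assert w.duration_s > w.ds_duration_s

    def test_single_step(self):
        table = g.GaitEventTable(
            fs=100.0,
            heel_strikes={"left": np.array([0]), "right": np.array([100])},
            toe_offs={"left": np.array([]), "right": np.array([20])},
        )
        windows = g.segment_steps(table)
        assert len(windows) == 1
        w = windows[0]
        assert (w.side_leading, w.side_trailing) == ("left", "right")
        assert w.ds_duration_s > 0 and w.duration_s > w.ds_duration_s

    def test_deleted_toe_off_drops_exactly_one_step(self, default_trial):
        truth = default_trial.truth.events
        broken = g.GaitEventTable(
            fs=truth.fs,
            heel_strikes={s: truth.heel_strikes[s].copy() for s in ("left", "right")},
            toe_offs={"left": truth.toe_offs["left"][1:],  # drop one toe-off
                      "right": truth.toe_offs["right"].copy()},
        )
        n_full = len(g.segment_steps(truth))
        assert len(g.segment_steps(broken)) == n_full - 1


class TestNormalization:
    def test_constant_channel_stays_constant(self, default_trial):
        windows = g.segment_steps(default_trial.truth.events)
        n = len(default_trial.signals)
        stride = g.time_normalize({"c": np.full(n, 3.25)}, windows, fs=200.0)
        assert np.all(stride.channels["c"] == 3.25)

    def test_linear_ramp_exact(self):
        # a signal linear in time is reproduced exactly by linear resampling
        fs = 100.0
        n = 401
        x = 0.7 * np.arange(n) - 3.0
        w = [StepWindow(start=50, toe_off=72, end=160, side_leading="left", fs=fs),
             StepWindow(start=160, toe_off=185, end=270, side_leading="right", fs=fs)]
        stride = g.time_normalize({"x": x}, w, j_ds=10, j_ss=40, fs=fs)
        for row, win in zip(stride.channels["x"], w):
            expected = 0.7 * grid_times(win, 10, 40) - 3.0
            np.testing.assert_allclose(row, expected, atol=1e-12)

    def test_grid_endpoint_is_contralateral_heel_strike(self, default_trial):
        windows = g.segment_steps(default_trial.truth.events)
        df = default_trial.signals
        stride = g.time_normalize(df, windows)
        ends = np.array([w.end for w in windows])
        np.testing.assert_allclose(stride.channels["heel_ap_left_m"][:, -1],
                                   df["heel_ap_left_m"].to_numpy()[ends], atol=0)

    def test_idempotent_on_grid_aligned_rows(self):
        # a window whose sub-window lengths equal the grid sizes maps grid
        # points onto integer samples: renormalizing reproduces the values
        rng = np.random.default_rng(0)
        j_ds, j_ss = 8, 32
        x = rng.standard_normal(j_ds + j_ss + 1)
        w = [StepWindow(start=0, toe_off=j_ds, end=j_ds + j_ss, side_leading="left", fs=100.0)]
        once = g.time_normalize({"x": x}, w, j_ds=j_ds, j_ss=j_ss, fs=100.0)
        np.testing.assert_allclose(once.channels["x"][0], x[1:], atol=1e-12)
        again = g.time_normalize({"x": np.r_[x[0], once.channels["x"][0]]}, w,
                                 j_ds=j_ds, j_ss=j_ss, fs=100.0)
        np.testing.assert_allclose(again.channels["x"][0], once.channels["x"][0],
                                   atol=1e-12)

    def test_round_trip_error_bounded_for_bandlimited_signal(self):
        # linear interpolation error on a smooth signal is bounded by
        # h^2/8 * max|f''|; the normalized rows must respect that bound
        fs = 200.0
        t = np.arange(2000) / fs
        f = np.sin(2 * np.pi * 2.0 * t)          # 2 Hz
        w = [StepWindow(start=s, toe_off=s + 22, end=s + 110, side_leading="left", fs=fs)
             for s in range(0, 1800, 110)]
        stride = g.time_normalize({"f": f}, w, j_ds=20, j_ss=80, fs=fs)
        fmax2 = (2 * np.pi * 2.0) ** 2
        bound = (1.0 / fs) ** 2 / 8.0 * fmax2
        for row, win in zip(stride.channels["f"], w):
            dense = np.sin(2 * np.pi * 2.0 * grid_times(win, 20, 80) / fs)
            assert np.max(np.abs(row - dense)) <= bound * 1.01

    def test_short_subwindow_dropped(self, caplog):
        w = [StepWindow(start=0, toe_off=1, end=50, side_leading="left", fs=100.0),
             StepWindow(start=50, toe_off=60, end=100, side_leading="right", fs=100.0)]
        stride = g.time_normalize({"x": np.arange(101.0)}, w, fs=100.0)
        assert stride.n_steps == 1

    def test_invalid_grid_sizes(self):
        with pytest.raises(ValueError):
            g.time_normalize({"x": np.arange(100.0)},
                             [StepWindow(0, 10, 50, "left", 100.0)], j_ds=1)
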
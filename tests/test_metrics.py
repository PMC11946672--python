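"""Accuracy/precision tables, exclusion rules and the main sequence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gazerig.config import RunConfig
from gazerig.detect import FixationWindow, SaccadeEvent
from gazerig.metrics import (
    accuracy_table,
    exclusion_filter,
    flag_fragments,
    main_sequence_fit,
    per_condition_v10,
    precision_table,
)
from gazerig.pipeline import run_pattern_trials
from gazerig.rig import plan_calibration_grid


def make_window(idx, planned, mx, my, sd=1.0, n=250, pupil=2888.94):
    return FixationWindow(target_index=idx, planned_px=planned, start_ms=0, end_ms=n,
                          mean_x=mx, mean_y=my, sd_x=sd, sd_y=sd,
                          mean_pupil_au=pupil, n_samples=n)


class TestAccuracyTable:
    def test_deviation_is_mean_minus_planned(self, screen):
        trials = [[make_window(0, (960.0, 540.0), 969.7, 532.4)]]
        acc = accuracy_table(trials, screen)
        assert acc.loc[0, "dev_x_px"] == pytest.approx(9.7)
        assert acc.loc[0, "dev_y_px"] == pytest.approx(-7.6)
        assert acc.loc[0, "dev_x_deg"] == pytest.approx(0.17, abs=0.005)

    def test_constant_bias_shifts_every_deviation(self, grid_fixations_100, screen):
        fixations, _ = grid_fixations_100
        base = accuracy_table(fixations, screen)
        shifted = [
            [make_window(w.target_index, w.planned_px, w.mean_x + 5.0, w.mean_y,
                         w.sd_x, w.n_samples, w.mean_pupil_au) for w in trial]
            for trial in fixations
        ]
        acc = accuracy_table(shifted, screen)
        np.testing.assert_allclose(acc["dev_x_px"], base["dev_x_px"] + 5.0, atol=1e-9)
        np.testing.assert_allclose(acc["dev_y_px"], base["dev_y_px"], atol=1e-9)

    def test_noiseless_grid_within_quantization_bound(self, screen):
        cfg = RunConfig(seed=2, n_trials=5, noise_sd_deg=0.0, pupil_noise_au=0.0)
        fixations = run_pattern_trials(cfg, plan_calibration_grid())
        acc = accuracy_table(fixations, screen)
        assert len(acc) == 13
        # per-trial error <= 0.28125 deg; the mean over trials shrinks it
        assert acc[["dev_x_deg", "dev_y_deg"]].abs().to_numpy().max() <= 0.28125


class TestPrecisionTable:
    def test_single_trial_rejected(self, screen):
        with pytest.raises(ValueError):
            precision_table([[make_window(0, (960.0, 540.0), 960.0, 540.0)]], screen)

    def test_known_summary_statistics(self, screen):
        """Pooled-raw SD reconstructed from window summaries matches the
        direct computation on the underlying samples."""
        rng = np.random.default_rng(1)
        samples = [rng.normal(960.0, 2.0, 300) for _ in range(20)]
        trials = [
            [make_window(0, (960.0, 540.0), s.mean(), 540.0, s.std(ddof=1), 300)]
            for s in samples
        ]
        prec = precision_table(trials, screen)
        allx = np.concatenate(samples)
        assert prec.loc[0, "sd_x_px"] == pytest.approx(allx.std(ddof=1), rel=1e-9)

    def test_trial_means_method_translation_invariant(self, grid_fixations_100, screen):
        fixations, _ = grid_fixations_100
        p1 = precision_table(fixations, screen, method="trial_means")
        shifted = [
            [make_window(w.target_index, w.planned_px, w.mean_x + 7.0, w.mean_y + 3.0,
                         w.sd_x, w.n_samples) for w in trial]
            for trial in fixations
        ]
        p2 = precision_table(shifted, screen, method="trial_means")
        np.testing.assert_allclose(p1["sd_x_px"], p2["sd_x_px"], atol=1e-9)

    def test_default_noise_grid_matches_printed_order_of_magnitude(self, grid_fixations_100, screen):
        """At the default noise the per-coordinate precision lands in the
        0.005-0.04 deg decade a real tracker/rig system prints."""
        fixations, _ = grid_fixations_100
        prec = precision_table(fixations, screen)
        sds = prec[["sd_x_deg", "sd_y_deg"]].to_numpy()
        assert sds.min() >= 0.001 and sds.max() <= 0.08


class TestExclusionFilter:
    def make_event(self, amp, transition=False, fragment=False):
        return SaccadeEvent(onset_ms=0, offset_ms=60, amplitude_deg=amp,
                            peak_velocity_dps=300.0, is_transition=transition,
                            is_fragment=fragment)

    def test_rules_and_log(self):
        events = [self.make_event(10.0), self.make_event(3.0),
                  self.make_event(20.0, transition=True), self.make_event(10.0, fragment=True)]
        kept, log = exclusion_filter(events)
        assert len(kept) == 1
        assert log == {"input": 4, "transition": 1, "fragment": 1, "amplitude": 1, "retained": 1}

    def test_boundaries_inclusive(self):
        kept, _ = exclusion_filter([self.make_event(4.0), self.make_event(14.6)])
        assert len(kept) == 2

    def test_clean_simulated_dataset_fully_retained(self, brightness_run):
        """Planned amplitudes 4.5-14.1 deg against the 4.0-14.6 deg filter:
        nearly everything survives; no transition saccade ever does."""
        log = brightness_run["exclusion_log"]
        planned = 20 * 50 * 3
        assert log["retained"] >= 0.99 * planned
        assert log["transition"] == 19 * 3  # one per participant change per condition


class TestFragmentFlag:
    def test_edge_and_gap_fragments(self):
        events = [SaccadeEvent(onset_ms=100, offset_ms=160),
                  SaccadeEvent(onset_ms=170, offset_ms=230),  # 10 ms gap: split pair
                  SaccadeEvent(onset_ms=980, offset_ms=999)]
        flag_fragments(events, stream_len=1000)
        assert events[0].is_fragment and events[1].is_fragment
        assert events[2].is_fragment  # truncated at the stream end


class TestMainSequenceFit:
    def test_exact_linear_data(self):
        amps = np.array([4.0, 6.0, 8.0, 10.0, 12.0, 14.0])
        fit = main_sequence_fit(amps, 20.0 * amps + 100.0)
        assert fit.slope == pytest.approx(20.0, abs=1e-9)
        assert fit.intercept == pytest.approx(100.0, abs=1e-9)
        assert fit.v10 == pytest.approx(300.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_v10_identity(self, rng):
        a = rng.uniform(4, 14, 50)
        v = 25 * a + 80 + rng.normal(0, 10, 50)
        fit = main_sequence_fit(a, v)
        assert fit.v10 == pytest.approx(fit.intercept + 10 * fit.slope)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            a = rng.uniform(4, 14, 30)
            v = rng.normal(300, 40, 30)
            fit = main_sequence_fit(a, v)
            X = np.column_stack([a, np.ones_like(a)])
            beta = np.linalg.solve(X.T @ X, X.T @ v)
            assert fit.slope == pytest.approx(beta[0], abs=1e-9)
            assert fit.intercept == pytest.approx(beta[1], abs=1e-9)

    def test_r_squared_invariant_to_amplitude_rescaling(self, rng):
        a = rng.uniform(4, 14, 100)
        v = 25 * a + 80 + rng.normal(0, 15, 100)
        f1 = main_sequence_fit(a, v)
        f2 = main_sequence_fit(60.0 * a + 5.0, v)  # amplitudes in arcmin + offset
        assert f1.r_squared == pytest.approx(f2.r_squared, abs=1e-12)

    def test_degenerate_designs_raise(self):
        with pytest.raises(ValueError):
            main_sequence_fit([10.0, 10.0, 10.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            main_sequence_fit([10.0, 11.0], [1.0, 2.0])


class TestPerConditionV10:
    def test_identical_streams_give_identical_v10(self):
        df = pd.DataFrame({
            "participant": [0] * 6, "condition": ["dark"] * 3 + ["light"] * 3,
            "amplitude_deg": [5.0, 10.0, 14.0] * 2,
            "peak_velocity_dps": [200.0, 300.0, 350.0] * 2,
        })
        matrix, grand = per_condition_v10(df)
        assert matrix.loc[0, "dark"] == pytest.approx(matrix.loc[0, "light"])
        assert grand["dark"].v10 == pytest.approx(grand["light"].v10)

    def test_sparse_participants_excluded(self):
        rows = []
        for p in (0, 1):
            for c in ("dark", "light"):
                n = 1 if (p == 1 and c == "light") else 4
                for i in range(n):
                    rows.append((p, c, 5.0 + 2 * i, 220.0 + 30 * i))
        df = pd.DataFrame(rows, columns=["participant", "condition",
                                         "amplitude_deg", "peak_velocity_dps"])
        with pytest.warns(UserWarning, match="excluded 1 participant"):
            matrix, _ = per_condition_v10(df)
        assert list(matrix.index) == [0]

    def test_null_experiment_grand_v10_agree(self, brightness_run):
        grand = brightness_run["grand_fits"]
        v10s = [f.v10 for f in grand.values()]
        assert max(v10s) - min(v10s) < 1.0  # deg/s, the null-model bound
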
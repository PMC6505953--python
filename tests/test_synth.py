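"""Tests for the synthetic trial/subject/behavior generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from alphactf import (
    BehavioralGenerator,
    SimulationConfig,
    generate_behavioral_errors,
    generate_subject,
    generate_timecourse_dataset,
    sample_trial_positions,
)
from alphactf.encoding import predicted_responses
from alphactf.synth import bin_centers


class TestTrialPositions:
    def test_two_item_pairs_exactly_counterbalanced(self):
        cfg = SimulationConfig(n_trials_per_condition=576)
        trials = sample_trial_positions(cfg, "two_item", 0)
        counts = (
            trials.groupby(["bin_probed", "bin_unprobed"]).size().unstack(fill_value=0)
        )
        assert counts.shape == (8, 8)
        assert (counts.to_numpy() == 576 // 64).all()

    def test_one_item_bins_uniform(self):
        cfg = SimulationConfig(n_trials_per_condition=576)
        trials = sample_trial_positions(cfg, "one_item", 0)
        assert (np.bincount(trials["bin_probed"], minlength=8) == 72).all()

    def test_angles_inside_bin_wedge(self):
        cfg = SimulationConfig(n_trials_per_condition=128)
        for cond in ("one_item", "two_item"):
            trials = sample_trial_positions(cfg, cond, 1)
            delta = (trials["angle_probed"] - bin_centers()[trials["bin_probed"]] + 180) % 360 - 180
            assert (np.abs(delta) <= 22.5).all()

    def test_minimum_separation_enforced(self):
        cfg = SimulationConfig(n_trials_per_condition=576, min_item_separation=4.6)
        trials = sample_trial_positions(cfg, "two_item", 2)
        sep = np.abs(
            (trials["angle_probed"] - trials["angle_unprobed"] + 180) % 360 - 180
        )
        assert (sep >= 4.6).all()

    def test_indivisible_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_trials_per_condition=100)

    def test_reproducible_with_same_seed(self):
        cfg = SimulationConfig(n_trials_per_condition=128)
        a = sample_trial_positions(cfg, "two_item", 7)
        b = sample_trial_positions(cfg, "two_item", 7)
        pd.testing.assert_frame_equal(a, b)


class TestGenerateSubject:
    def test_noiseless_item_at_center_reads_out_weights(self):
        cfg = SimulationConfig(
            n_subjects=1,
            n_trials_per_condition=64,
            n_electrodes=10,
            noise_sd_one_item=0.0,
            noise_sd_two_item=0.0,
            jitter_width=0.0,
        )
        subj = generate_subject(cfg, 0, conditions=("one_item",))
        # stimulus at a channel center: the electrode row is the weighted
        # basis column (the tuned channel at 1, neighbors at cos(22.5)^25)
        C = predicted_responses(
            bin_centers()[subj.trials["bin_probed"].to_numpy()], bin_centers(), 25
        )
        np.testing.assert_allclose(subj.electrode_data, (subj.true_weights @ C).T, atol=1e-12)
        # and the dominant contribution is the tuned channel's weight column
        for i in range(8):
            b = int(subj.trials.loc[i, "bin_probed"])
            np.testing.assert_allclose(
                subj.electrode_data[i], subj.true_weights[:, b], atol=0.35
            )

    def test_two_item_additivity(self):
        cfg = SimulationConfig(
            n_subjects=1,
            n_trials_per_condition=64,
            n_electrodes=10,
            noise_sd_one_item=0.0,
            noise_sd_two_item=0.0,
        )
        subj = generate_subject(cfg, 3)
        two = subj.trials["condition"] == "two_item"
        C1 = predicted_responses(subj.trials.loc[two, "angle_probed"].to_numpy(), bin_centers(), 25)
        C2 = predicted_responses(subj.trials.loc[two, "angle_unprobed"].to_numpy(), bin_centers(), 25)
        expected = (subj.true_weights @ (C1 + C2)).T
        np.testing.assert_allclose(subj.electrode_data[two.to_numpy()], expected, atol=1e-12)

    def test_amplitude_scaling(self):
        base = dict(
            n_subjects=1,
            n_trials_per_condition=64,
            n_electrodes=10,
            noise_sd_one_item=0.0,
            noise_sd_two_item=0.0,
        )
        a = generate_subject(SimulationConfig(**base), 11)
        b = generate_subject(SimulationConfig(**base, amplitude_scale_two_item=0.9), 11)
        two = (a.trials["condition"] == "two_item").to_numpy()
        np.testing.assert_allclose(
            b.electrode_data[two], 0.9 * a.electrode_data[two], atol=1e-12
        )
        np.testing.assert_allclose(b.electrode_data[~two], a.electrode_data[~two])

    def test_weights_in_unit_interval_and_shared_across_conditions(self):
        cfg = SimulationConfig(n_subjects=1, n_trials_per_condition=64, n_electrodes=10)
        subj = generate_subject(cfg, 5)
        assert subj.true_weights.min() >= 0 and subj.true_weights.max() <= 1
        assert subj.electrode_data.shape == (128, 10)

    def test_bit_identical_reproducibility(self):
        cfg = SimulationConfig(n_subjects=1, n_trials_per_condition=64, n_electrodes=10)
        a = generate_subject(cfg, 9)
        b = generate_subject(cfg, 9)
        np.testing.assert_array_equal(a.electrode_data, b.electrode_data)
        pd.testing.assert_frame_equal(a.trials, b.trials)


class TestBehavioralGenerator:
    def test_pure_guessing_is_uniform(self):
        gen = BehavioralGenerator(sd_target=6.0, p_guess=1.0, n_trials=10_000)
        errors, labels, _ = generate_behavioral_errors(gen, 0)
        assert (labels == "guess").all()
        stat = sps.kstest(errors, sps.uniform(loc=-180, scale=360).cdf)
        assert stat.pvalue > 0.01

    def test_high_precision_no_lapses(self):
        gen = BehavioralGenerator(sd_target=0.5, p_guess=0.0, p_swap=0.0, n_trials=500)
        errors, labels, _ = generate_behavioral_errors(gen, 1)
        assert (labels == "target").all()
        assert np.abs(errors).max() < 5.0

    def test_swap_component_centered_on_nontarget(self):
        gen = BehavioralGenerator(sd_target=4.0, p_swap=1.0, n_trials=2000)
        errors, labels, offsets = generate_behavioral_errors(gen, 2)
        assert (labels == "swap").all()
        resid = (errors - offsets + 180) % 360 - 180
        assert np.abs(resid).mean() < 10.0

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            BehavioralGenerator(p_guess=0.7, p_swap=0.5)


class TestTimecourse:
    def test_tuning_confined_to_window(self):
        cfg = SimulationConfig(
            n_subjects=1, n_trials_per_condition=64, n_electrodes=10,
            noise_sd_one_item=0.5,
        )
        ep, trials = generate_timecourse_dataset(cfg, 250, 1250, 4)
        inside = (ep.times >= 250) & (ep.times <= 1250)
        # outside the window the data are zero-mean noise; inside they carry
        # the strictly positive forward-model signal
        assert ep.power[:, :, ~inside].mean() == pytest.approx(0.0, abs=0.05)
        assert ep.power[:, :, inside].mean() > 0.5

    def test_invalid_window_rejected(self):
        cfg = SimulationConfig(n_subjects=1, n_trials_per_condition=64)
        with pytest.raises(ValueError):
            generate_timecourse_dataset(cfg, 800, 200, 0)

    def test_both_conditions_share_trial_table(self):
        cfg = SimulationConfig(n_subjects=1, n_trials_per_condition=64, n_electrodes=10)
        ep, trials = generate_timecourse_dataset(
            cfg, 0, 500, 5, conditions=("one_item", "two_item")
        )
        assert len(trials) == 128
        assert ep.power.shape[0] == 128
        assert set(trials["condition"]) == {"one_item", "two_item"}
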
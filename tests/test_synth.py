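"""Synthetic-session generator: round-trips and ground-truth recovery."""

import numpy as np
import pytest

from ramplight import behavior, photometry, synth
from ramplight.synth import (
    GroundTruth,
    condition_ground_truth,
    generate_lick_train,
    generate_photometry_session,
    generate_vr_session,
    ground_truth_manifest,
    load_manifest,
    save_manifest,
)
from ramplight.task import SHORT_ITI_SPEC


class TestGroundTruth:
    def test_presets_encode_condition_regimes(self):
        sd = condition_ground_truth("SD")
        ld = condition_ground_truth("LD")
        sf = condition_ground_truth("SF")
        assert sd.ramp_slope_base > 0 and sd.beta_iti < 0
        assert ld.ramp_slope_base == 0 and ld.onset_amplitude > sd.onset_amplitude
        assert sf.ramp_slope_base == 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            condition_ground_truth("SD", dip_amplitude=0.5)
        with pytest.raises(ValueError):
            condition_ground_truth("nope")


class TestManifest:
    def test_round_trip(self, tmp_path, sd_session_noiseless):
        path = tmp_path / "manifest.json"
        save_manifest(sd_session_noiseless, path)
        back = load_manifest(path)
        assert back == sd_session_noiseless.ground_truth

    def test_seed_reproduces_session_bit_identically(self):
        gt = condition_ground_truth("SD", n_trials=5, noise_sd_470=0.2, seed=99)
        a = generate_photometry_session(gt)
        b = generate_photometry_session(gt)
        np.testing.assert_array_equal(a.session.ch470, b.session.ch470)
        np.testing.assert_array_equal(a.lick_times, b.lick_times)

    def test_tampered_manifest_rejected(self, tmp_path, sd_session_noiseless):
        path = tmp_path / "manifest.json"
        save_manifest(sd_session_noiseless, path)
        text = path.read_text().replace('"n_trials": 25', '"n_trials": 26')
        path.write_text(text)
        with pytest.raises(ValueError, match="checksum"):
            load_manifest(path)

    def test_manifest_requires_synthetic_session(self):
        with pytest.raises(TypeError):
            ground_truth_manifest(object())


class TestPavlovianRecovery:
    def test_zero_amplitudes_zero_dff(self):
        gt = condition_ground_truth(
            "SD", n_trials=4, onset_amplitude=0, ramp_slope_base=0, beta_iti=0,
            reward_amplitude=0, dip_amplitude=0, slope_jitter_sd=0,
        )
        s = generate_photometry_session(gt)
        dff = photometry.compute_dff(
            s.session.ch470, s.true_fitted405, s.session.time_s
        )
        np.testing.assert_allclose(dff.dff_percent, 0.0, atol=1e-10)

    def test_noiseless_exact_recovery(self, sd_session_noiseless):
        """Noise off: every injected slope and onset amplitude comes back
        exactly (machine precision against the clean reference channel)."""
        s = sd_session_noiseless
        trace = photometry.compute_dff(
            s.session.ch470, s.true_fitted405, s.session.time_s
        )
        for cue, true_slope in zip(
            s.trial_truth["cue_onset_t"], s.trial_truth["injected_slope"]
        ):
            assert photometry.ramp_slope_time(trace, cue) == pytest.approx(
                true_slope, abs=1e-9
            )
            assert photometry.onset_peak_response(trace, cue) == pytest.approx(
                s.ground_truth.onset_amplitude, abs=1e-9
            )

    def test_full_pipeline_near_exact_without_noise(self, sd_session_noiseless):
        """Estimating the isosbestic fit from the data itself leaves only the
        small contamination from the dopamine component (<1% of truth)."""
        s = sd_session_noiseless
        tab = photometry.session_trial_metrics(s.session)
        err = tab["ramp_slope"].to_numpy() - s.trial_truth["injected_slope"][: len(tab)]
        assert np.max(np.abs(err)) < 0.01 * max(s.ground_truth.ramp_slope_base, 1.0)

    def test_noisy_recovery_within_mc_error(self, sd_session_noisy):
        s = sd_session_noisy
        tab = photometry.session_trial_metrics(s.session)
        err = tab["ramp_slope"].to_numpy() - s.trial_truth["injected_slope"][: len(tab)]
        assert abs(err.mean()) < 3 * err.std(ddof=1) / np.sqrt(err.size)

    def test_beta_iti_recovery_at_paper_scale(self):
        """A 300-trial session generated with the slope-vs-previous-ITI
        dependence seen per animal recovers it within 3 standard errors."""
        gt = condition_ground_truth(
            "SD", n_trials=300, noise_sd_405=0.3, noise_sd_470=0.3, seed=21
        )
        s = generate_photometry_session(gt)
        tab = photometry.session_trial_metrics(s.session)
        rep = behavior.previous_iti_beta(tab)
        assert rep.beta == pytest.approx(gt.beta_iti, abs=3 * rep.se)

    def test_pre_cue_slope_positive_during_dip_recovery(self):
        gt = condition_ground_truth(
            "SD", n_trials=30, slope_jitter_sd=0.0, seed=3
        )  # dip on by default
        s = generate_photometry_session(gt)
        trace = photometry.compute_dff(
            s.session.ch470, s.true_fitted405, s.session.time_s
        )
        slopes = [
            photometry.pre_cue_slope(trace, c) for c in s.trial_truth["cue_onset_t"][1:]
        ]
        assert np.mean(slopes) > 0

    def test_shared_multiplicative_artifact_robustness(self, sd_session_noiseless):
        """A slow gain drift common to both channels barely moves the
        recovered slopes (isosbestic correction cancels shared artifacts)."""
        s = sd_session_noiseless
        t = s.session.time_s
        artifact = 1.0 + 0.05 * np.sin(2 * np.pi * t / 300.0)
        sess = photometry.PhotometrySession(
            t, s.session.ch470 * artifact, s.session.ch405 * artifact, s.session.events
        )
        tab = photometry.session_trial_metrics(sess)
        err = tab["ramp_slope"].to_numpy() - s.trial_truth["injected_slope"][: len(tab)]
        assert np.max(np.abs(err)) < 0.05 * s.ground_truth.ramp_slope_base


class TestLickGenerator:
    def test_zero_rates_no_licks(self):
        gt = condition_ground_truth("SD", n_trials=3, lick_baseline_hz=0, lick_trace_hz=0)
        s = generate_photometry_session(gt)
        assert s.lick_times.size == 0

    def test_anticipatory_rate_recovered(self):
        """Baseline 2 Hz vs trace-period 6 Hz -> ~4 Hz anticipatory rate
        (Monte-Carlo over trials)."""
        gt = condition_ground_truth("SD", n_trials=200, seed=17)
        s = generate_photometry_session(gt)
        t_bins, rate = behavior.lick_rate(
            s.lick_times, t_end=s.session.time_s[-1]
        )
        vals = [
            behavior.anticipatory_lick_rate(t_bins, rate, cue)
            for cue in s.trial_truth["cue_onset_t"]
        ]
        vals = np.array([v for v in vals if v is not None])
        expected = gt.lick_trace_hz - gt.lick_baseline_hz
        assert vals.mean() == pytest.approx(expected, abs=3 * vals.std() / np.sqrt(vals.size))

    def test_poisson_scaling(self):
        gt1 = condition_ground_truth("SD", n_trials=50, seed=4)
        gt2 = condition_ground_truth(
            "SD", n_trials=50, seed=4, lick_baseline_hz=4.0, lick_trace_hz=12.0
        )
        s1 = generate_photometry_session(gt1)
        s2 = generate_photometry_session(gt2)
        ratio = s2.lick_times.size / s1.lick_times.size
        assert ratio == pytest.approx(2.0, rel=0.15)


@pytest.fixture(scope="module")
def vr():
    gt = condition_ground_truth("VR-short", n_trials=12, dip_amplitude=0.0, seed=6)
    return generate_vr_session(gt)


class TestVRGenerator:
    def test_trial_duration_matches_velocity_profile(self, vr):
        """67 cm at 20 cm/s plateau with a 0.5 s rise tau: the exponential
        start-up costs ~tau of extra time, so duration ~ 67/20 + 0.5 s."""
        tab = photometry.vr_session_trial_metrics(vr.session)
        expected = synth.HALLWAY_CM / vr.ground_truth.velocity_plateau_cm_s
        assert tab["trial_duration_s"].mean() == pytest.approx(
            expected + vr.ground_truth.velocity_rise_tau_s, abs=0.1
        )

    def test_distance_ramp_slope_recovery(self, vr):
        tab = photometry.vr_session_trial_metrics(vr.session)
        np.testing.assert_allclose(
            tab["ramp_slope"], vr.ground_truth.ramp_slope_base, atol=2e-3
        )

    def test_stationary_iti_samples_dropped_by_alignment(self, vr):
        """During the black-screen ITI distance is constant, so alignment
        keeps a single pair out of any stationary stretch."""
        dm = (vr.distance_time_s >= vr.trial_truth["reward_t"][0] + 1) & (
            vr.distance_time_s < vr.trial_truth["trial_onset_t"][1] - 1
        )
        dist = vr.distance_cm[dm]
        dff = np.zeros(3 * dist.size)
        d_kept, _ = photometry.distance_align(dff, dist)
        assert d_kept.size == 1

    def test_velocity_plateau_recovered(self, vr):
        # 30 ms distance stream resampled to the 50 ms behavior grid
        t50 = np.arange(0.0, vr.session.time_s[-1], 0.05)
        d50 = np.interp(t50, vr.distance_time_s, vr.distance_cm)
        vt, v = behavior.velocity_trace(d50, t50)
        on = vr.trial_truth["trial_onset_t"][0]
        rew = vr.trial_truth["reward_t"][0]
        plateau = v[(vt > on + 2.0) & (vt < rew - 0.2)]
        assert plateau.mean() == pytest.approx(
            vr.ground_truth.velocity_plateau_cm_s, rel=0.05
        )
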
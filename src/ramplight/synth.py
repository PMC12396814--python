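"""Ground-truth-known synthetic sessions for end-to-end pipeline validation.

Emulates the statistical structure the analyses assume — truncated
exponential ITIs, cue-locked dopamine transients, a within-cue linear ramp
whose slope depends on the previous ITI, a reward transient followed by a
sub-baseline dip with exponential recovery, double-exponential photobleaching
on both channels, Poisson licking with an anticipatory build-up, and smooth
VR velocity profiles along a 67 cm virtual hallway.  Every generating
parameter is recorded in a manifest so pipeline estimates can be asserted
against truth.  Deliberately absent: sensor kinetics, motion artifacts and
hemodynamics — recovery here validates the analysis code, not robustness to
every property of real recordings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .photometry import PhotometrySession
from .task import (
    EventStream,
    LONG_ITI_SPEC,
    SHORT_ITI_SPEC,
    TrialConfig,
    TruncExpSpec,
    VR_LONG_ITI_SPEC,
    build_pavlovian_stream,
    sample_itis,
)

__all__ = [
    "GroundTruth",
    "SyntheticSession",
    "condition_ground_truth",
    "generate_photometry_session",
    "generate_lick_train",
    "generate_vr_session",
    "ground_truth_manifest",
    "save_manifest",
    "load_manifest",
]

HALLWAY_CM = 67.0


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for one synthetic session."""

    condition: str
    n_trials: int
    iti_spec: TruncExpSpec
    onset_amplitude: float = 2.0  # %dF/F
    ramp_slope_base: float = 0.0  # %dF/F per s (per cm for VR)
    beta_iti: float = 0.0  # %dF/F s^-1 per s of previous ITI
    slope_jitter_sd: float = 0.0  # trial-to-trial biological scatter
    reward_amplitude: float = 5.0  # %dF/F
    dip_amplitude: float = -1.0  # %dF/F, must be <= 0
    dip_recovery_tau_s: float = 2.5
    bleach_amps: tuple = (0.15, 0.1)  # fractional double-exponential bleach
    bleach_taus: tuple = (600.0, 3000.0)
    noise_sd_405: float = 0.0  # raw-channel white noise (fraction of baseline %)
    noise_sd_470: float = 0.0
    lick_baseline_hz: float = 2.0
    lick_trace_hz: float = 6.0
    velocity_plateau_cm_s: float = 20.0
    velocity_rise_tau_s: float = 0.5
    sample_rate_hz: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_405 < 0 or self.noise_sd_470 < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.dip_amplitude > 0:
            raise ValueError("dip_amplitude must be <= 0 (an undershoot)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


# qualitative regimes of the four Pavlovian conditions: large onset with long
# ITI; ramp (with negative ITI dependence) only for short ITI + dynamic tone.
_PRESETS = {
    "LF": dict(iti_spec=LONG_ITI_SPEC, n_trials=40, onset_amplitude=8.0),
    "LD": dict(iti_spec=LONG_ITI_SPEC, n_trials=40, onset_amplitude=8.0),
    "SD": dict(
        iti_spec=SHORT_ITI_SPEC,
        n_trials=100,
        onset_amplitude=2.0,
        ramp_slope_base=0.55,
        beta_iti=-0.045,
        slope_jitter_sd=0.15,
    ),
    "SF": dict(iti_spec=SHORT_ITI_SPEC, n_trials=100, onset_amplitude=2.0),
    "VR-long": dict(
        iti_spec=VR_LONG_ITI_SPEC, n_trials=50, onset_amplitude=8.0,
        sample_rate_hz=100.0,
    ),
    "VR-short": dict(
        iti_spec=SHORT_ITI_SPEC, n_trials=50, onset_amplitude=2.0,
        ramp_slope_base=0.05,  # %dF/F per cm over the 20-57 cm window
        sample_rate_hz=100.0,
    ),
}


def condition_ground_truth(condition: str, **overrides) -> GroundTruth:
    """Preset GroundTruth for a named condition (LF, LD, SD, SF, VR-*)."""
    if condition not in _PRESETS:
        raise ValueError(f"unknown condition {condition!r}")
    kw = dict(_PRESETS[condition])
    kw.update(overrides)
    return GroundTruth(condition=condition, **kw)


@dataclass
class SyntheticSession:
    """A generated session plus everything needed to assert recovery."""

    ground_truth: GroundTruth
    session: PhotometrySession
    lick_times: np.ndarray
    true_dff: np.ndarray  # injected dopamine component, % on the session grid
    true_fitted405: np.ndarray  # noise-free reference channel (gain * clean 405)
    trial_truth: "dict"  # cue_onset_t, reward_t, injected_slope, previous_iti_s
    distance_time_s: np.ndarray | None = None
    distance_cm: np.ndarray | None = None


def _bleach_baseline(gt: GroundTruth, t: np.ndarray) -> np.ndarray:
    a1, a2 = gt.bleach_amps
    t1, t2 = gt.bleach_taus
    return 1.0 + a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)


def _add_kernel(d, t, t0, amp, tau, t_stop=None, plateau=0.0):
    """amp held for ``plateau`` s from t0, then exponential decay at ``tau``
    (optionally truncated at ``t_stop``).  The plateau makes the injected
    peak amplitude recoverable exactly at any sampling phase."""
    hi = t.size if t_stop is None else np.searchsorted(t, t_stop)
    lo = np.searchsorted(t, t0)
    dt_rel = np.maximum(t[lo:hi] - t0 - plateau, 0.0)
    d[lo:hi] += amp * np.exp(-dt_rel / tau)


def _pavlovian_truth_trace(
    gt: GroundTruth, t: np.ndarray, cues: np.ndarray, rewards: np.ndarray, rng
):
    """Injected dopamine component (%dF/F) and per-trial injected slopes."""
    d = np.zeros_like(t)
    prev_iti = np.full(cues.size, np.nan)
    prev_iti[1:] = cues[1:] - rewards[:-1]
    slopes = gt.ramp_slope_base + gt.beta_iti * np.nan_to_num(prev_iti)
    slopes += gt.slope_jitter_sd * rng.standard_normal(cues.size)
    for i, (cue, rew) in enumerate(zip(cues, rewards)):
        _add_kernel(d, t, cue, gt.onset_amplitude, 0.3, t_stop=cue + 3.0, plateau=0.1)
        lo, hi = np.searchsorted(t, [cue + 3.0, cue + 9.0])
        d[lo:hi] += slopes[i] * (t[lo:hi] - cue - 3.0)
        _add_kernel(d, t, rew, gt.reward_amplitude, 0.5, t_stop=rew + 3.0)
        # sub-baseline dip recovering exponentially through the ITI
        # (truncated at 8 time constants; residual < 0.04% of the amplitude)
        _add_kernel(d, t, rew + 1.0, gt.dip_amplitude, gt.dip_recovery_tau_s,
                    t_stop=rew + 1.0 + 8.0 * gt.dip_recovery_tau_s)
    return d, slopes, prev_iti


def _channels_from_truth(gt: GroundTruth, t: np.ndarray, true_dff: np.ndarray, rng):
    clean405 = 100.0 * _bleach_baseline(gt, t)
    gain = 1.6  # 470 nm collection efficiency relative to 405 nm
    true_fitted405 = gain * clean405
    ch405 = clean405 + gt.noise_sd_405 * rng.standard_normal(t.size)
    ch470 = true_fitted405 * (1.0 + true_dff / 100.0)
    ch470 = ch470 + gt.noise_sd_470 * rng.standard_normal(t.size)
    return ch405, ch470, true_fitted405


def generate_photometry_session(
    gt: GroundTruth, seed: int | None = None
) -> SyntheticSession:
    """Synthesize a Pavlovian two-channel photometry session.

    405 = bleaching baseline + white noise; 470 = gain * baseline modulated
    multiplicatively by the injected dopamine component (so running the
    dF/F pipeline recovers it) + white noise.  The injected component per
    trial: a fast cue-onset transient, a linear ramp over [3, 9) s after cue
    onset with slope ramp_slope_base + beta_iti * previous ITI (+ jitter), a
    reward transient, and a post-reward dip with exponential recovery.
    """
    rng = np.random.default_rng(gt.seed if seed is None else seed)
    config = TrialConfig(iti_spec=gt.iti_spec, n_trials=gt.n_trials)
    stream = build_pavlovian_stream(config, rng)
    pad = 10.0
    stream = EventStream(stream.times + pad, stream.labels)
    t_end = stream.times[-1] + 12.0
    t = np.arange(0.0, t_end, 1.0 / gt.sample_rate_hz)
    cues = stream.times_of("cue_onset")
    rewards = stream.times_of("reward")
    true_dff, slopes, prev_iti = _pavlovian_truth_trace(gt, t, cues, rewards, rng)
    ch405, ch470, true_fitted405 = _channels_from_truth(gt, t, true_dff, rng)
    session = PhotometrySession(t, ch470, ch405, stream)
    licks = generate_lick_train(gt, stream, rng)
    return SyntheticSession(
        ground_truth=gt,
        session=session,
        lick_times=licks,
        true_dff=true_dff,
        true_fitted405=true_fitted405,
        trial_truth={
            "cue_onset_t": cues,
            "reward_t": rewards,
            "injected_slope": slopes,
            "previous_iti_s": prev_iti,
        },
    )


def generate_lick_train(
    gt: GroundTruth, events: EventStream, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Inhomogeneous-Poisson lick times.

    Baseline rate everywhere; across each cue the rate climbs linearly from
    baseline to the trace-period rate, holds through the trace second, then
    resets after reward.  Sampled by thinning.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cues = events.times_of("cue_onset")
    rewards = events.times_of("reward")
    t_end = events.times[-1] + 2.0
    rmax = max(gt.lick_baseline_hz, gt.lick_trace_hz)
    if rmax == 0:
        return np.array([])
    n = rng.poisson(rmax * t_end)
    cand = np.sort(rng.uniform(0, t_end, n))
    rate = np.full(cand.size, gt.lick_baseline_hz)
    for cue, rew in zip(cues, rewards):
        in_cue = (cand >= cue) & (cand < rew - 1.0)
        frac = (cand[in_cue] - cue) / max(rew - 1.0 - cue, 1e-9)
        rate[in_cue] = gt.lick_baseline_hz + frac * (gt.lick_trace_hz - gt.lick_baseline_hz)
        in_trace = (cand >= rew - 1.0) & (cand < rew)
        rate[in_trace] = gt.lick_trace_hz
    return cand[rng.uniform(0, rmax, cand.size) < rate]


def generate_vr_session(gt: GroundTruth, seed: int | None = None) -> SyntheticSession:
    """Synthesize a VR session: distance at 30 ms, dF/F channels at 10 ms.

    Per trial the animal accelerates with time constant
    ``velocity_rise_tau_s`` toward ``velocity_plateau_cm_s`` until covering
    the 67 cm hallway; reward is delivered at the end and the distance holds
    (black screen) through the ITI.  The dopamine component carries an onset
    transient at trial start, a ramp that is linear in *distance* over
    [20, 57) cm, a reward transient, and the post-reward dip.
    """
    rng = np.random.default_rng(gt.seed if seed is None else seed)
    itis = sample_itis(gt.iti_spec, gt.n_trials, rng)
    dt = 1.0 / gt.sample_rate_hz  # 10 ms grid
    onsets, reward_ts = [], []
    t_cursor = 10.0
    seg_t, seg_d = [], []
    for i in range(gt.n_trials):
        onsets.append(t_cursor)
        # distance vs time: d(t) = v*(tt - tau*(1-exp(-tt/tau)))
        tau, v = gt.velocity_rise_tau_s, gt.velocity_plateau_cm_s
        tt = np.arange(0.0, HALLWAY_CM / v + 5 * tau + 5.0, dt)
        dist = v * (tt - tau * (1.0 - np.exp(-tt / tau)))
        stop = int(np.searchsorted(dist, HALLWAY_CM))
        tt, dist = tt[: stop + 1], np.minimum(dist[: stop + 1], HALLWAY_CM)
        seg_t.append(t_cursor + tt)
        seg_d.append(dist)
        reward_ts.append(t_cursor + tt[-1])
        t_cursor = reward_ts[-1] + itis[i]
    t_end = reward_ts[-1] + 12.0
    t = np.arange(0.0, t_end, dt)
    # distance restarts at 0 at each trial onset and holds at the hallway end
    # (black screen) from reward until the next onset
    distance = np.zeros_like(t)
    next_onsets = onsets[1:] + [t_end + 1.0]
    for ts, ds, nxt in zip(seg_t, seg_d, next_onsets):
        lo = np.searchsorted(t, ts[0] - dt / 2)
        hi = min(lo + ds.size, t.size)
        distance[lo:hi] = ds[: hi - lo]
        distance[hi : np.searchsorted(t, nxt - dt / 2)] = HALLWAY_CM

    onsets = np.asarray(onsets)
    reward_ts = np.asarray(reward_ts)
    d = np.zeros_like(t)
    for on, rew in zip(onsets, reward_ts):
        _add_kernel(d, t, on, gt.onset_amplitude, 0.3, t_stop=on + 3.0, plateau=0.1)
        seg = (t >= on) & (t < rew)
        x = distance[seg]
        ramp = np.where(
            x >= RAMP_START_CM, gt.ramp_slope_base * (x - RAMP_START_CM), 0.0
        )
        d[seg] += ramp
        _add_kernel(d, t, rew, gt.reward_amplitude, 0.5, t_stop=rew + 3.0)
        _add_kernel(d, t, rew + 1.0, gt.dip_amplitude, gt.dip_recovery_tau_s,
                    t_stop=rew + 1.0 + 8.0 * gt.dip_recovery_tau_s)
    ch405, ch470, true_fitted405 = _channels_from_truth(gt, t, d, rng)

    times = np.sort(np.concatenate([onsets, reward_ts]))
    labels = np.where(np.isin(times, onsets), "trial_onset", "reward").astype(object)
    events = EventStream(times, labels)
    # distance stream at 30 ms for syncing (and usable at 50 ms via resampling)
    dist_t = np.arange(0.0, t_end, 0.03)
    dist_samples = np.interp(dist_t, t, distance)
    session = PhotometrySession(
        t, ch470, ch405, events, distance_time_s=dist_t, distance_cm=dist_samples
    )
    return SyntheticSession(
        ground_truth=gt,
        session=session,
        lick_times=np.array([]),
        true_dff=d,
        true_fitted405=true_fitted405,
        trial_truth={
            "trial_onset_t": onsets,
            "reward_t": reward_ts,
            "injected_slope": np.full(onsets.size, gt.ramp_slope_base),
            "previous_iti_s": np.concatenate([[np.nan], onsets[1:] - reward_ts[:-1]]),
        },
        distance_time_s=dist_t,
        distance_cm=dist_samples,
    )


RAMP_START_CM = 20.0


def ground_truth_manifest(session: SyntheticSession) -> dict:
    """All generating parameters of a synthetic session, JSON-serializable."""
    if not isinstance(session, SyntheticSession):
        raise TypeError("manifest is only defined for synthetic sessions")
    gt = dataclasses.asdict(session.ground_truth)
    gt["iti_spec"] = dataclasses.asdict(session.ground_truth.iti_spec)
    return gt


def _manifest_digest(manifest: dict) -> str:
    payload = json.dumps(manifest, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def save_manifest(session: SyntheticSession, path) -> None:
    manifest = ground_truth_manifest(session)
    with open(path, "w") as fh:
        json.dump({"ground_truth": manifest, "sha256": _manifest_digest(manifest)}, fh, indent=1)


def load_manifest(path) -> GroundTruth:
    """Read a manifest back into a GroundTruth; raises on tampering."""
    with open(path) as fh:
        payload = json.load(fh)
    manifest = payload["ground_truth"]
    if _manifest_digest(manifest) != payload.get("sha256"):
        raise ValueError("manifest checksum mismatch: file was modified")
    spec = manifest.pop("iti_spec")
    manifest["iti_spec"] = TruncExpSpec(**spec)
    for key in ("bleach_amps", "bleach_taus"):
        manifest[key] = tuple(manifest[key])
    return GroundTruth(**manifest)
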
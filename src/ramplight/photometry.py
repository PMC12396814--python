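"""Two-channel fiber-photometry processing: dF/F, onset peaks, ramp slopes.

The 405 nm (isosbestic, dopamine-independent) channel is least-squares
scaled to the 470 nm (dopamine-dependent) channel and
dF/F = (470 - fitted405) / fitted405 * 100.  Per-trial quantification uses
ordinary least squares on the *unsmoothed* dF/F: ramp slope over 3-8 s after
cue onset (Pavlovian, %dF/F per s) or 20-57 cm along the virtual hallway
(VR, %dF/F per cm), and an onset peak (max within 1 s post-onset minus the
mean of the preceding 1 s).  All windows are half-open [a, b).  Gaussian
smoothing exists for visualization only and is never applied upstream of
quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .task import EventStream

__all__ = [
    "PhotometrySession",
    "DFFTrace",
    "fit_isosbestic",
    "compute_dff",
    "event_aligned_matrix",
    "onset_peak_response",
    "ramp_slope_time",
    "pre_cue_slope",
    "distance_align",
    "ramp_slope_distance",
    "bin_by_cm",
    "smooth_for_display",
    "session_trial_metrics",
    "vr_session_trial_metrics",
]

RAMP_WINDOW_S = (3.0, 8.0)
RAMP_WINDOW_CM = (20.0, 57.0)


@dataclass
class PhotometrySession:
    """Raw two-channel recording plus its event log (and VR distance)."""

    time_s: np.ndarray
    ch470: np.ndarray
    ch405: np.ndarray
    events: EventStream
    distance_time_s: np.ndarray | None = None
    distance_cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ch470 = np.asarray(self.ch470, dtype=float)
        self.ch405 = np.asarray(self.ch405, dtype=float)
        if not (len(self.time_s) == len(self.ch470) == len(self.ch405)):
            raise ValueError("time and channel arrays must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.time_s, "ch470": self.ch470, "ch405": self.ch405}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, events: EventStream) -> "PhotometrySession":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["ch470"].to_numpy(), df["ch405"].to_numpy(), events)

    def dff(self, fit_intercept: bool = True) -> "DFFTrace":
        fitted = fit_isosbestic(self.ch405, self.ch470, fit_intercept=fit_intercept)
        return compute_dff(self.ch470, fitted, self.time_s)


@dataclass
class DFFTrace:
    time_s: np.ndarray
    dff_percent: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dff_percent = np.asarray(self.dff_percent, dtype=float)
        if self.time_s.shape != self.dff_percent.shape:
            raise ValueError("time and dff must have equal length")
        if not np.all(np.isfinite(self.dff_percent)):
            raise ValueError("dF/F contains non-finite values")


def fit_isosbestic(
    ch405: np.ndarray, ch470: np.ndarray, fit_intercept: bool = True
) -> np.ndarray:
    """Least-squares scaling of the 405 channel to the 470 channel.

    Affine (a*ch405 + c) by default; ``fit_intercept=False`` restricts the
    fit to a pure gain, for rigs where both channels share a true zero.
    """
    ch405 = np.asarray(ch405, dtype=float)
    ch470 = np.asarray(ch470, dtype=float)
    if ch405.size < 2:
        raise ValueError("need at least two samples")
    if np.ptp(ch405) == 0:
        raise ValueError("isosbestic channel is constant; cannot scale")
    if fit_intercept:
        a, c = np.polyfit(ch405, ch470, 1)
        return a * ch405 + c
    a = float(ch405 @ ch470 / (ch405 @ ch405))
    return a * ch405


def compute_dff(
    ch470: np.ndarray, fitted405: np.ndarray, time_s: np.ndarray | None = None
) -> DFFTrace:
    """dF/F = (470 - fitted405) / fitted405 * 100, elementwise."""
    ch470 = np.asarray(ch470, dtype=float)
    fitted405 = np.asarray(fitted405, dtype=float)
    bad = np.flatnonzero(fitted405 <= 0)
    if bad.size:
        raise ValueError(f"fitted 405 is non-positive at sample index {bad[0]}")
    dff = (ch470 - fitted405) / fitted405 * 100.0
    if time_s is None:
        time_s = np.arange(ch470.size, dtype=float)
    return DFFTrace(time_s, dff)


def _window_mask(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (x >= lo) & (x < hi)


def _window_slice(t_sorted: np.ndarray, lo: float, hi: float) -> slice:
    """Half-open [lo, hi) as a slice into a sorted time grid (O(log n))."""
    return slice(*np.searchsorted(t_sorted, [lo, hi], side="left"))


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        raise ValueError("need at least two samples for a slope")
    return float(np.polyfit(x, y, 1)[0])


def event_aligned_matrix(
    trace: DFFTrace,
    event_times: np.ndarray,
    window: tuple[float, float],
    bin_s: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-aligned (PSTH) matrix.

    Returns (matrix, bin_centers, mean): one row per event, one column per
    ``bin_s`` bin across the half-open ``window``; bins that fall outside
    the recording are NaN and ignored by the mean.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("empty event list")
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    centers = edges[:-1] + bin_s / 2
    mat = np.full((event_times.size, centers.size), np.nan)
    for r, ev in enumerate(event_times):
        rel = trace.time_s - ev
        for c in range(centers.size):
            m = _window_mask(rel, edges[c], edges[c + 1])
            if m.any():
                mat[r, c] = trace.dff_percent[m].mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
    return mat, centers, mean


def onset_peak_response(trace: DFFTrace, event_t: float) -> float | None:
    """Max dF/F in [t, t+1) minus mean dF/F in [t-1, t); None if the
    +/-1 s window is not covered by the recording (trial dropped)."""
    if event_t - 1.0 < trace.time_s[0] or event_t + 1.0 > trace.time_s[-1]:
        warnings.warn(f"onset window at t={event_t:.2f}s outside recording; dropped")
        return None
    post = trace.dff_percent[_window_slice(trace.time_s, event_t, event_t + 1.0)]
    pre = trace.dff_percent[_window_slice(trace.time_s, event_t - 1.0, event_t)]
    return float(post.max() - pre.mean())


def ramp_slope_time(
    trace: DFFTrace, cue_onset_t: float, window: tuple[float, float] = RAMP_WINDOW_S
) -> float:
    """OLS slope (%dF/F per s) of unsmoothed dF/F over [onset+a, onset+b)."""
    m = _window_slice(trace.time_s, cue_onset_t + window[0], cue_onset_t + window[1])
    return _ols_slope(trace.time_s[m], trace.dff_percent[m])


def pre_cue_slope(trace: DFFTrace, cue_onset_t: float, window_s: float = 2.0) -> float:
    """OLS slope of dF/F over the [onset - window_s, onset) baseline period."""
    m = _window_slice(trace.time_s, cue_onset_t - window_s, cue_onset_t)
    return _ols_slope(trace.time_s[m], trace.dff_percent[m])


def distance_align(
    dff_10ms: np.ndarray, distance_30ms: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sync a 10 ms dF/F stream to 30 ms distance samples.

    The mean of every three consecutive dF/F values is assigned to the
    corresponding distance sample; a trailing partial triplet is dropped.
    Distance samples equal to their predecessor (stationary animal) are then
    removed together with their dF/F value.
    """
    dff_10ms = np.asarray(dff_10ms, dtype=float)
    distance_30ms = np.asarray(distance_30ms, dtype=float)
    n_triplets = dff_10ms.size // 3
    if abs(n_triplets - distance_30ms.size) > 1:
        raise ValueError(
            f"{dff_10ms.size} dF/F samples cannot pair 3:1 with "
            f"{distance_30ms.size} distance samples"
        )
    n = min(n_triplets, distance_30ms.size)
    dff3 = dff_10ms[: 3 * n].reshape(n, 3).mean(axis=1)
    dist = distance_30ms[:n]
    keep = np.ones(n, dtype=bool)
    keep[1:] = dist[1:] != dist[:-1]
    return dist[keep], dff3[keep]


def ramp_slope_distance(
    distance_cm: np.ndarray,
    dff: np.ndarray,
    window: tuple[float, float] = RAMP_WINDOW_CM,
) -> float | None:
    """OLS slope (%dF/F per cm) over the half-open distance window; None
    (trial dropped) if fewer than two aligned pairs fall inside."""
    distance_cm = np.asarray(distance_cm, dtype=float)
    dff = np.asarray(dff, dtype=float)
    m = _window_mask(distance_cm, window[0], window[1])
    if m.sum() < 2:
        warnings.warn("fewer than two samples in distance ramp window; trial dropped")
        return None
    return _ols_slope(distance_cm[m], dff[m])


def bin_by_cm(
    distance_cm: np.ndarray, dff: np.ndarray, max_cm: int = 67
) -> np.ndarray:
    """Mean dF/F per integer cm (distances rounded to nearest integer).

    Returns an array of length ``max_cm + 1`` (bins 0..max_cm); empty bins
    are NaN.  Used for visualization of distance-aligned traces.
    """
    distance_cm = np.asarray(distance_cm, dtype=float)
    dff = np.asarray(dff, dtype=float)
    bins = np.rint(distance_cm).astype(int)
    out = np.full(max_cm + 1, np.nan)
    for b in range(max_cm + 1):
        m = bins == b
        if m.any():
            out[b] = dff[m].mean()
    return out


def smooth_for_display(values: np.ndarray, sigma_samples: float = 2.0) -> np.ndarray:
    """Gaussian smoothing for plots only — never feed the result into
    slope/peak quantification."""
    return gaussian_filter1d(np.asarray(values, dtype=float), sigma_samples)


def session_trial_metrics(
    session: PhotometrySession,
    cue_label: str = "cue_onset",
    ramp_window: tuple[float, float] = RAMP_WINDOW_S,
    pre_cue_window_s: float = 2.0,
    fit_intercept: bool = True,
) -> pd.DataFrame:
    """Per-trial metrics table for a Pavlovian session.

    Columns: trial_index, cue_onset_t, ramp_slope, onset_peak, pre_cue_slope,
    previous_iti_s, previous_iri_s.  previous_* are NaN on the first trial;
    trials whose analysis windows exceed the recording are dropped
    (onset_peak NaN) rather than raising.
    """
    trace = session.dff(fit_intercept=fit_intercept)
    cues = session.events.times_of(cue_label)
    rewards = session.events.times_of("reward")
    rows = []
    for i, cue_t in enumerate(cues):
        prev_rewards = rewards[rewards < cue_t]
        prev_iti = cue_t - prev_rewards[-1] if prev_rewards.size else np.nan
        prev_iri = (
            prev_rewards[-1] - prev_rewards[-2] if prev_rewards.size >= 2 else np.nan
        )
        end = cue_t + ramp_window[1]
        if end > trace.time_s[-1] or cue_t + ramp_window[0] < trace.time_s[0]:
            warnings.warn(f"trial {i}: ramp window outside recording; dropped")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            peak = onset_peak_response(trace, cue_t)
        rows.append(
            {
                "trial_index": i,
                "cue_onset_t": cue_t,
                "ramp_slope": ramp_slope_time(trace, cue_t, ramp_window),
                "onset_peak": np.nan if peak is None else peak,
                "pre_cue_slope": pre_cue_slope(trace, cue_t, pre_cue_window_s)
                if cue_t - pre_cue_window_s >= trace.time_s[0]
                else np.nan,
                "previous_iti_s": prev_iti,
                "previous_iri_s": prev_iri,
            }
        )
    return pd.DataFrame(rows)


def vr_session_trial_metrics(
    session: PhotometrySession,
    window_cm: tuple[float, float] = RAMP_WINDOW_CM,
    fit_intercept: bool = True,
) -> pd.DataFrame:
    """Per-trial distance-ramp metrics for a VR session.

    For each trial (trial_onset to reward), the 10 ms dF/F stream is synced
    3:1 to the 30 ms distance samples, stationary duplicates are dropped, and
    the OLS slope (%dF/F per cm) is taken over the distance ramp window.
    Also reports the onset peak (time-domain) and the previous ITI.
    """
    if session.distance_cm is None:
        raise ValueError("session has no distance samples")
    trace = session.dff(fit_intercept=fit_intercept)
    onsets = session.events.times_of("trial_onset")
    rewards = session.events.times_of("reward")
    rows = []
    for i, (on, rew) in enumerate(zip(onsets, rewards)):
        dm = (session.distance_time_s >= on) & (session.distance_time_s < rew)
        fm = (trace.time_s >= on) & (trace.time_s < rew)
        dist = session.distance_cm[dm]
        dff = trace.dff_percent[fm]
        n = min(dff.size // 3, dist.size)
        if n < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d_aligned, f_aligned = distance_align(dff[: 3 * n], dist[:n])
            slope = ramp_slope_distance(d_aligned, f_aligned, window_cm)
            peak = onset_peak_response(trace, on)
        rows.append(
            {
                "trial_index": i,
                "trial_onset_t": on,
                "ramp_slope": np.nan if slope is None else slope,
                "onset_peak": np.nan if peak is None else peak,
                "previous_iti_s": on - rewards[i - 1] if i > 0 else np.nan,
                "trial_duration_s": rew - on,
            }
        )
    return pd.DataFrame(rows)
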
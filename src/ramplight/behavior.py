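"""Behavioral metrics and trial-wise statistics linking ramp slope to ITI history.

Licking (Pavlovian) and running velocity (VR) index learning; the statistical
analyses ask whether a trial's dopamine ramp slope depends on the inter-trial
interval (ITI) that preceded it — per animal, pooled across animals with
within-animal z-scoring, on consecutive-trial changes (delta analysis), and
on broader averages of past ITIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionReport",
    "lick_rate",
    "anticipatory_lick_rate",
    "lick_slope",
    "velocity_trace",
    "onset_velocity_change",
    "pre_reward_velocity",
    "previous_iti_beta",
    "pooled_zscore_beta",
    "delta_iti_analysis",
    "average_prev_iti_beta",
    "filter_iri_outliers",
    "condition_comparison",
]


@dataclass(frozen=True)
class RegressionReport:
    """OLS slope report for a trial-wise regression."""

    beta: float
    intercept: float
    se: float
    p_value: float
    n: int
    pooled: bool = False

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 points for a fitted report")


def _linreg(x: np.ndarray, y: np.ndarray, pooled: bool = False) -> RegressionReport:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite (x, y) pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: zero variance")
    res = stats.linregress(x, y)
    return RegressionReport(
        beta=float(res.slope),
        intercept=float(res.intercept),
        se=float(res.stderr),
        p_value=float(res.pvalue),
        n=int(x.size),
        pooled=pooled,
    )


# --------------------------------------------------------------------------
# licking


def lick_rate(
    lick_times: np.ndarray,
    bin_s: float = 0.1,
    t_start: float = 0.0,
    t_end: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lick rate (Hz): counts in ``bin_s`` bins divided by the bin width.

    Returns (bin_centers, rate).  Bins are half-open [edge, edge + bin_s).
    """
    lick_times = np.sort(np.asarray(lick_times, dtype=float))
    if t_end is None:
        t_end = lick_times[-1] + bin_s if lick_times.size else t_start + bin_s
    edges = np.arange(t_start, t_end + bin_s / 2, bin_s)
    counts, _ = np.histogram(lick_times, bins=edges)
    return edges[:-1] + bin_s / 2, counts / bin_s


def _mean_in_window(t: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    m = (t >= lo) & (t < hi)
    if not m.any():
        raise ValueError(f"no samples in window [{lo}, {hi})")
    return float(y[m].mean())


def anticipatory_lick_rate(
    rate_t: np.ndarray,
    rate_hz: np.ndarray,
    cue_onset_t: float,
    reward_delay_s: float = 9.0,
) -> float | None:
    """Baseline-subtracted anticipatory licking (Hz).

    Mean rate in the trace second before reward ([cue+8, cue+9) by default)
    minus the mean in the 1 s baseline before cue onset.  Trials whose
    coverage is incomplete are dropped (returns None).
    """
    rate_t = np.asarray(rate_t, dtype=float)
    if cue_onset_t - 1.0 < rate_t[0] or cue_onset_t + reward_delay_s > rate_t[-1] + 0.1:
        warnings.warn("incomplete trial coverage for anticipatory licking; dropped")
        return None
    trace = _mean_in_window(
        rate_t, rate_hz, cue_onset_t + reward_delay_s - 1.0, cue_onset_t + reward_delay_s
    )
    base = _mean_in_window(rate_t, rate_hz, cue_onset_t - 1.0, cue_onset_t)
    return trace - base


def lick_slope(
    rate_t: np.ndarray,
    rate_hz: np.ndarray,
    cue_onset_t: float,
    window: tuple[float, float] = (3.0, 8.0),
) -> float:
    """OLS slope (Hz/s) of the binned lick rate over the ramp window.

    The window matches the dopamine ramp window so lick and dopamine slopes
    are directly comparable.
    """
    rate_t = np.asarray(rate_t, dtype=float)
    m = (rate_t >= cue_onset_t + window[0]) & (rate_t < cue_onset_t + window[1])
    if m.sum() < 2:
        raise ValueError("fewer than two rate bins in window")
    res = stats.linregress(rate_t[m], np.asarray(rate_hz, dtype=float)[m])
    return float(res.slope)


# --------------------------------------------------------------------------
# running


def velocity_trace(
    distance_cm: np.ndarray, time_s: np.ndarray, dt_s: float = 0.05, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity (cm/s) as the first difference of uniformly sampled distance.

    Aligned to the later sample of each pair.  Raises if sampling deviates
    from ``dt_s`` beyond ``tol``.
    """
    time_s = np.asarray(time_s, dtype=float)
    distance_cm = np.asarray(distance_cm, dtype=float)
    steps = np.diff(time_s)
    if np.any(np.abs(steps - dt_s) > tol):
        raise ValueError(f"distance samples are not uniform at {dt_s} s")
    return time_s[1:], np.diff(distance_cm) / dt_s


def onset_velocity_change(
    vel_t: np.ndarray, vel: np.ndarray, trial_onset_t: float
) -> float | None:
    """Mean velocity in [onset+1, onset+2) minus the [onset-1, onset) baseline."""
    vel_t = np.asarray(vel_t, dtype=float)
    if trial_onset_t - 1.0 < vel_t[0] or trial_onset_t + 2.0 > vel_t[-1] + 0.05:
        warnings.warn("incomplete coverage for onset velocity change; dropped")
        return None
    post = _mean_in_window(vel_t, vel, trial_onset_t + 1.0, trial_onset_t + 2.0)
    base = _mean_in_window(vel_t, vel, trial_onset_t - 1.0, trial_onset_t)
    return post - base


def pre_reward_velocity(
    vel_t: np.ndarray, vel: np.ndarray, reward_t: float
) -> float | None:
    """Mean velocity over the 1 s preceding reward delivery."""
    vel_t = np.asarray(vel_t, dtype=float)
    if reward_t - 1.0 < vel_t[0]:
        warnings.warn("incomplete coverage for pre-reward velocity; dropped")
        return None
    return _mean_in_window(vel_t, vel, reward_t - 1.0, reward_t)


# --------------------------------------------------------------------------
# trial-wise ITI statistics


def previous_iti_beta(
    table: pd.DataFrame,
    slope_col: str = "ramp_slope",
    iti_col: str = "previous_iti_s",
) -> RegressionReport:
    """Per-animal regression of trial ramp slope on the preceding ITI.

    First trials (undefined previous ITI) are excluded automatically.
    """
    return _linreg(table[iti_col], table[slope_col])


def pooled_zscore_beta(
    tables: dict,
    slope_col: str = "ramp_slope",
    iti_col: str = "previous_iti_s",
) -> RegressionReport:
    """Pooled regression of within-animal z-scored slopes on previous ITI.

    ``tables`` maps animal id -> trial table.  Z-scoring the slopes per
    animal (mean 0, SD 1) removes between-animal mean differences before
    pooling; ITIs are left on their natural scale.  Animals with zero slope
    variance are excluded with a warning.
    """
    if len(tables) < 2:
        raise ValueError("pooled analysis needs at least two animals")
    xs, zs = [], []
    for animal, tab in tables.items():
        ok = np.isfinite(tab[iti_col]) & np.isfinite(tab[slope_col])
        s = tab.loc[ok, slope_col].to_numpy(dtype=float)
        x = tab.loc[ok, iti_col].to_numpy(dtype=float)
        sd = s.std(ddof=0)
        if sd == 0:
            warnings.warn(f"animal {animal!r} has zero slope variance; excluded")
            continue
        zs.append((s - s.mean()) / sd)
        xs.append(x)
    return _linreg(np.concatenate(xs), np.concatenate(zs), pooled=True)


def delta_iti_analysis(
    table: pd.DataFrame,
    category_threshold_s: float = 1.0,
    slope_col: str = "ramp_slope",
    iti_col: str = "previous_iti_s",
) -> dict:
    """Consecutive-trial change analysis.

    For consecutive trials i-1, i: delta_iti = previous ITI of trial i minus
    previous ITI of trial i-1 (the quantities driving each trial's ramp), and
    delta_slope likewise.  Returns the OLS report of delta_slope on delta_iti
    plus mean delta_slope for relative ITI decreases (delta < -threshold) and
    increases (delta > +threshold); a category with no pairs is NaN.
    """
    tab = table.dropna(subset=[slope_col, iti_col]).reset_index(drop=True)
    d_iti = np.diff(tab[iti_col].to_numpy(dtype=float))
    d_slope = np.diff(tab[slope_col].to_numpy(dtype=float))
    report = _linreg(d_iti, d_slope)
    dec = d_slope[d_iti < -category_threshold_s]
    inc = d_slope[d_iti > category_threshold_s]
    return {
        "report": report,
        "beta_delta": report.beta,
        "mean_delta_slope_decrease": float(dec.mean()) if dec.size else np.nan,
        "mean_delta_slope_increase": float(inc.mean()) if inc.size else np.nan,
    }


def average_prev_iti_beta(
    table: pd.DataFrame,
    k_back: int,
    slope_col: str = "ramp_slope",
    iti_col: str = "previous_iti_s",
) -> RegressionReport:
    """Regress trial slope on the mean of its ``k_back`` preceding ITIs.

    k_back=1 reduces to ``previous_iti_beta``; trials lacking a full k-deep
    history are dropped.
    """
    if k_back < 1:
        raise ValueError("k_back must be >= 1")
    itis = table[iti_col].to_numpy(dtype=float)
    slopes = table[slope_col].to_numpy(dtype=float)
    if k_back > itis.size:
        raise ValueError("k_back exceeds session length")
    avg = pd.Series(itis).rolling(k_back).mean().to_numpy()
    return _linreg(avg, slopes)


def filter_iri_outliers(iris: np.ndarray, k_sd: float = 3.0) -> np.ndarray:
    """Drop IRIs more than ``k_sd`` population SDs from the mean.

    Mean and SD come from the *original* distribution (single pass, no
    re-estimation after removal), which makes the filter idempotent.
    """
    iris = np.asarray(iris, dtype=float)
    if iris.size < 2:
        raise ValueError("need at least two IRIs")
    mu, sd = iris.mean(), iris.std(ddof=0)
    return iris[np.abs(iris - mu) <= k_sd * sd]


def condition_comparison(
    per_animal_a: np.ndarray, per_animal_b: np.ndarray, paired: bool = True
) -> dict:
    """Two-sided test on per-animal means between conditions (alpha = 0.05).

    Paired t-test by default (same animals across conditions); unpaired
    Welch otherwise.
    """
    a = np.asarray(per_animal_a, dtype=float)
    b = np.asarray(per_animal_b, dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("need at least two animals per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires matched animals")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n": int(a.size),
        "mean_difference": float(a.mean() - b.mean()),
        "paired": paired,
    }
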
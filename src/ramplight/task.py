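"""Trial/event-stream construction for Pavlovian and simulated sessions.

The tasks modeled here share one trial skeleton: an 8 s auditory cue, a 1 s
trace period, then sucrose reward.  Conditions differ in the inter-trial
interval (ITI, reward to next cue onset), drawn from a truncated exponential
distribution, and in whether the tone is fixed or sweeps ("dynamic").  For
model simulations the 8 s tone is discretized into 8 sub-cues at 1 s spacing
plus an offset event, and a fixed consummatory period follows each reward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TruncExpSpec",
    "TrialConfig",
    "EventStream",
    "calibrate_truncated_exponential",
    "sample_itis",
    "build_pavlovian_stream",
    "build_simulation_stream",
    "tone_frequency_profile",
    "SHORT_ITI_SPEC",
    "LONG_ITI_SPEC",
    "VR_MED_ITI_SPEC",
    "VR_LONG_ITI_SPEC",
]


class CalibrationError(ValueError):
    """Target mean is not attainable by a truncated exponential on [min, max]."""


@dataclass(frozen=True)
class TruncExpSpec:
    """Truncated exponential ITI distribution on [min_s, max_s].

    ``rate`` is the rate (1/s) of the underlying exponential before
    truncation; ``None`` means the spec has not been calibrated yet.
    """

    min_s: float
    max_s: float
    target_mean_s: float
    rate: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.min_s < self.max_s):
            raise ValueError("require 0 <= min_s < max_s")
        mid = 0.5 * (self.min_s + self.max_s)
        if not (self.min_s < self.target_mean_s < mid):
            raise CalibrationError(
                f"target mean {self.target_mean_s} outside feasible interval "
                f"({self.min_s}, {mid}) for a truncated exponential"
            )
        if self.rate is not None and self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def calibrated(self) -> bool:
        return self.rate is not None

    def truncated_mean(self) -> float:
        """Closed-form mean of Exp(rate) truncated to [min_s, max_s]."""
        if self.rate is None:
            raise ValueError("spec is not calibrated")
        return _truncated_exponential_mean(self.rate, self.min_s, self.max_s)


def _truncated_exponential_mean(rate: float, a: float, b: float) -> float:
    w = rate * (b - a)
    if w < 1e-4:  # series in rate*(b-a): avoids catastrophic cancellation
        return 0.5 * (a + b) - w * (b - a) / 12.0
    ew = np.exp(-w)  # form factored by exp(-rate*a): stable for any rate
    return 1.0 / rate + (a - b * ew) / (1.0 - ew)


def calibrate_truncated_exponential(
    min_s: float, max_s: float, target_mean_s: float
) -> TruncExpSpec:
    """Solve for the exponential rate whose [min, max]-truncation has the
    requested mean.

    The mean of a truncated exponential on [a, b] decreases monotonically
    from (a+b)/2 (rate -> 0) to a (rate -> inf), so a root exists iff
    a < target < (a+b)/2; it is found by bracketed root-finding to <1e-6 s.
    """
    spec = TruncExpSpec(min_s, max_s, target_mean_s)  # validates feasibility
    f = lambda lam: _truncated_exponential_mean(lam, min_s, max_s) - target_mean_s
    lo = 1e-12
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
    rate = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    assert abs(_truncated_exponential_mean(rate, min_s, max_s) - target_mean_s) < 1e-6
    return replace(spec, rate=rate)


def sample_itis(
    spec: TruncExpSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. ITIs (s) from a calibrated truncated exponential."""
    if not spec.calibrated:
        raise ValueError("spec must be calibrated before sampling (rate is None)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dist = stats.truncexpon(
        b=(spec.max_s - spec.min_s) * spec.rate, loc=spec.min_s, scale=1.0 / spec.rate
    )
    return dist.rvs(size=n, random_state=rng)


# Calibrated presets matching the experimental conditions.
SHORT_ITI_SPEC = calibrate_truncated_exponential(6.0, 12.0, 8.0)
LONG_ITI_SPEC = calibrate_truncated_exponential(6.0, 186.0, 55.0)
VR_MED_ITI_SPEC = calibrate_truncated_exponential(6.0, 90.0, 28.0)
VR_LONG_ITI_SPEC = calibrate_truncated_exponential(6.0, 186.0, 62.0)


@dataclass(frozen=True)
class TrialConfig:
    """Trial structure shared by Pavlovian and simulated sessions.

    For simulation streams the cue is discretized into ``n_subcues`` distinct
    sub-cues at 1 s spacing (plus the cue-offset event), and ``consummatory_s``
    seconds elapse after reward before the ITI clock starts; the reward-to-cue
    gap then equals ``consummatory_s + ITI``.  Experimental Pavlovian streams
    use ``consummatory_s = 0``: there the ITI is defined directly as the
    reward-to-cue-onset period.
    """

    iti_spec: TruncExpSpec
    n_trials: int
    cue_duration_s: float = 8.0
    trace_s: float = 1.0
    consummatory_s: float = 0.0
    n_subcues: int = 8
    include_offset_event: bool = True

    def __post_init__(self) -> None:
        for name in ("cue_duration_s", "trace_s", "consummatory_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_subcues < 1:
            raise ValueError("n_subcues must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def reward_delay_s(self) -> float:
        """Cue onset to reward: cue duration plus trace period."""
        return self.cue_duration_s + self.trace_s


@dataclass
class EventStream:
    """Time-ordered labeled events (seconds from session start)."""

    times: np.ndarray
    labels: np.ndarray  # object array of str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.times.shape != self.labels.shape:
            raise ValueError("times and labels must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def times_of(self, label: str) -> np.ndarray:
        return self.times[self.labels == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "label": self.labels})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventStream":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["label"].to_numpy(dtype=object))

    def mean_inter_reward_interval(self) -> float:
        rewards = self.times_of("reward")
        if rewards.size < 2:
            raise ValueError("need at least two rewards for an IRI")
        return float(np.mean(np.diff(rewards)))


def build_pavlovian_stream(
    config: TrialConfig,
    seed: int | np.random.Generator,
    itis: np.ndarray | None = None,
) -> EventStream:
    """Experimental-style stream: one cue_onset and one reward per trial.

    Reward follows cue onset by ``cue_duration_s + trace_s`` (9 s by default);
    the next cue onset follows reward by an ITI draw (``itis`` overrides
    sampling, e.g. to force deterministic gaps).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if itis is None:
        itis = sample_itis(config.iti_spec, config.n_trials, rng)
    itis = np.asarray(itis, dtype=float)
    times, labels = [], []
    t = 0.0
    for i in range(config.n_trials):
        times += [t, t + config.reward_delay_s]
        labels += ["cue_onset", "reward"]
        t += config.reward_delay_s + config.consummatory_s + itis[i]
    return EventStream(np.array(times), np.array(labels, dtype=object))


def build_simulation_stream(
    config: TrialConfig,
    seed: int | np.random.Generator,
) -> EventStream:
    """Model-input stream: cue_1..cue_n at 1 s spacing, cue_offset, reward.

    Per trial, cue_i occurs at t0 + (i-1) s, cue_offset at t0 + cue_duration_s
    and reward ``trace_s`` later.  After reward, a fixed consummatory period
    plus an ITI draw (the experimental draw minus the consummatory period, so
    the reward-to-cue gap reproduces the experimental ITI) separates trials.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    raw = sample_itis(config.iti_spec, config.n_trials, rng)
    # split the experimental reward-to-cue gap into consummatory + residual ITI
    itis = np.maximum(raw - config.consummatory_s, 0.0)
    times, labels = [], []
    t = 0.0
    for i in range(config.n_trials):
        for c in range(config.n_subcues):
            times.append(t + c * 1.0)
            labels.append(f"cue_{c + 1}")
        if config.include_offset_event:
            times.append(t + config.cue_duration_s)
            labels.append("cue_offset")
        times.append(t + config.reward_delay_s)
        labels.append("reward")
        t += config.reward_delay_s + config.consummatory_s + itis[i]
    return EventStream(np.array(times), np.array(labels, dtype=object))


def simulation_config(
    condition: Literal["sim-short", "sim-long"], n_trials: int = 1000
) -> TrialConfig:
    """Preset simulation configs for the short/long dynamic conditions.

    Short: ITI averaging 2 s past a 6 s consummatory period (17 s mean IRI);
    long: ITI averaging 49 s (64 s mean IRI).
    """
    spec = SHORT_ITI_SPEC if condition == "sim-short" else LONG_ITI_SPEC
    return TrialConfig(iti_spec=spec, n_trials=n_trials, consummatory_s=6.0)


def tone_frequency_profile(
    tone_kind: Literal["dynamic_up", "dynamic_down", "fixed_3khz", "fixed_12khz"],
    t_s: float,
    cue_duration_s: float = 8.0,
) -> float | None:
    """Tone frequency (kHz) at time ``t_s`` into the cue; ``None`` = silence.

    Dynamic tones step 0.08 kHz every 0.2 s (3.2 kHz total across 8 s), up
    from 3 kHz or down from 12 kHz.  The fixed 12 kHz tone is continuous; the
    fixed 3 kHz tone is pulsed 200 ms on / 200 ms off.
    """
    if not (0 <= t_s <= cue_duration_s):
        raise ValueError(f"t_s={t_s} outside cue [0, {cue_duration_s}]")
    n_steps = int(np.floor(t_s / 0.2 + 1e-9))
    if tone_kind == "dynamic_up":
        return 3.0 + 0.08 * n_steps
    if tone_kind == "dynamic_down":
        return 12.0 - 0.08 * n_steps
    if tone_kind == "fixed_12khz":
        return 12.0
    if tone_kind == "fixed_3khz":
        return 3.0 if n_steps % 2 == 0 else None
    raise ValueError(f"unknown tone_kind {tone_kind!r}")
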
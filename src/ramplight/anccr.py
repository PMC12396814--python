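"""ANCCR: retrospective causal-credit learning and its dopamine read-out.

The model (Adjusted Net Contingency for Causal Relations) holds that on each
*meaningful* event (initially only reward) an agent looks back in time for
candidate causes.  Memory of the past is carried by eligibility traces
E_i(t) = sum over past occurrences of event i of exp(-(t - t_i)/T), with a
single time constant T that adapts to the environment's event rate
(T = k * IRI, the inter-reward interval).  Retrospective association of a
cause c with a target j is measured by the predecessor representation
contingency PRC = M_{c at j} - Mbar_c, where M is an exponential moving
average of E_c sampled at occurrences of j (rate alpha) and Mbar_c is the
continuously sampled baseline (rate alpha0, every dt seconds).

Because T scales with the IRI, short inter-trial intervals make T small
relative to the trial; with a dynamic sequence of sub-cues, only late cues
retain eligibility at reward, so causal credit - and hence the simulated
dopamine response - grows across the trial: a ramp.  Long ITIs make T large,
every cue retains eligibility, and the first cue absorbs the credit while
later cues are explained away: a large onset response and no ramp.

The conversion of contingencies into a per-event dopamine response is a
reconstruction of the model family (the printed parameters w, b, threshold,
alpha_R fix its roles): prospective contingency via a base-rate correction,
net contingency as their w-weighted blend, value weighting by R (seeded by
innate value b, updated at rate alpha_R), and explaining-away of credit
already assigned to other currently eligible meaningful events.  It is
validated against the qualitative contracts (ramp with small T, onset
dominance with large T, reward response shrinking as cue contingency grows),
not as a line-by-line port of any particular implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import EventStream, TrialConfig, build_simulation_stream, simulation_config

__all__ = [
    "ANCCRParams",
    "ANCCRState",
    "SimulationResult",
    "eligibility_trace",
    "update_event_memory",
    "update_baseline_memory",
    "predecessor_contingency",
    "adaptive_alpha",
    "eligibility_time_constant",
    "compose_dopamine_responses",
    "simulate_stream",
    "run_simulation",
    "simulation_ramp_metrics",
]


@dataclass(frozen=True)
class ANCCRParams:
    """Model constants.

    alpha0: baseline-memory learning rate (per dt sample).
    alphaR: value learning rate.
    w: weight of the prospective term in net contingency.
    b_cue / b_reward: innate value per event type (seeds R; reward's b also
        enters its dopamine response additively, configurable).
    threshold: estimated-value cutoff above which an event is "meaningful"
        and acts as a learning target.
    k: eligibility time constant multiplier, T = k * IRI.
    dt: baseline sampling step (s).
    """

    alpha0: float = 5e-3
    alphaR: float = 1.0
    w: float = 0.5
    b_cue: float = 0.0
    b_reward: float = 0.5
    threshold: float = 0.2
    k: float = 0.2
    dt: float = 0.2
    n_iterations: int = 20
    n_trials: int = 1000
    n_analysis_trials: int = 100
    add_b_at_output: bool = True  # reward's innate value added to its response
    track_iri_online: bool = False  # running-mean IRI instead of condition mean

    def __post_init__(self) -> None:
        if not (0 < self.alpha0 < 1):
            raise ValueError("alpha0 must lie in (0, 1)")
        if not (0 <= self.w <= 1):
            raise ValueError("w must lie in [0, 1]")
        if self.dt <= 0 or self.k <= 0:
            raise ValueError("dt and k must be positive")


def eligibility_trace(
    event_times: np.ndarray, T: float, query_t: float | np.ndarray
) -> float | np.ndarray:
    """Brute-force eligibility: sum of exp(-(t - t_i)/T) over t_i <= t."""
    if T <= 0:
        raise ValueError("T must be positive")
    event_times = np.asarray(event_times, dtype=float)
    q = np.asarray(query_t, dtype=float)
    delta = q[..., None] - event_times
    vals = np.where(delta >= 0, np.exp(-np.clip(delta, 0, None) / T), 0.0)
    out = vals.sum(axis=-1)
    return float(out) if np.isscalar(query_t) else out


def update_event_memory(M, E_at_event, alpha: float):
    """EMA update of a target-sampled memory: M' = M + alpha (E - M)."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    return M + alpha * (np.asarray(E_at_event) - M)


def update_baseline_memory(Mbar, E_at_sample, alpha0: float):
    """Baseline memory update on the dt grid; same convex rule at rate alpha0."""
    return update_event_memory(Mbar, E_at_sample, alpha0)


def predecessor_contingency(M, Mbar):
    """PRC: target-sampled memory minus its continuously sampled baseline."""
    return np.asarray(M) - np.asarray(Mbar)


def adaptive_alpha(IRI: float, alpha0: float, dt: float) -> float:
    """Event-memory learning rate during initial learning.

    alpha = 1 - (1 - alpha0)^(IRI/dt): the per-event rate that matches the
    cumulative effect of baseline updates accrued over one inter-reward
    interval.  Strictly increasing in IRI; equals alpha0 at IRI = dt.
    """
    if IRI <= 0:
        raise ValueError("IRI must be positive")
    return 1.0 - (1.0 - alpha0) ** (IRI / dt)


def eligibility_time_constant(IRI: float, k: float) -> float:
    """T = k * IRI: memory timescale proportional to the event timescale."""
    if IRI <= 0 or k <= 0:
        raise ValueError("IRI and k must be positive")
    return k * IRI


@dataclass
class ANCCRState:
    """Evolving quantities for a fixed label set.

    M[i, j]: eligibility of cause j sampled at occurrences of target i.
    Mbar[j]: baseline eligibility of j, sampled every dt.
    R[i]: learned value, seeded by innate b.
    meaningful[i]: whether i currently acts as a learning target.
    """

    labels: list
    T: float
    alpha: float
    b: np.ndarray
    E: np.ndarray = field(init=False)
    M: np.ndarray = field(init=False)
    Mbar: np.ndarray = field(init=False)
    R: np.ndarray = field(init=False)
    meaningful: np.ndarray = field(init=False)
    t_last: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.E = np.zeros(n)
        self.M = np.zeros((n, n))
        self.Mbar = np.zeros(n)
        self.R = self.b.astype(float).copy()
        self.meaningful = self.b > 0.2  # refreshed against params.threshold
        self.index = {lab: i for i, lab in enumerate(self.labels)}

    def decay_to(self, t: float) -> None:
        """Advance eligibility traces to time t (pure exponential decay)."""
        if t < self.t_last:
            raise ValueError("time must not run backwards")
        self.E *= np.exp(-(t - self.t_last) / self.T)
        self.t_last = t

    def net_contingency(self, params: ANCCRParams) -> np.ndarray:
        """NC[i, j]: net contingency of cause j toward target i.

        Prospective term = PRC * Mbar_target / Mbar_cause (base-rate
        correction); blended with the retrospective PRC by weight w.
        """
        prc = predecessor_contingency(self.M, self.Mbar[None, :])
        denom = np.maximum(self.Mbar[None, :], 1e-12)
        prospective = prc * (np.maximum(self.Mbar[:, None], 0.0) / denom)
        return params.w * prospective + (1.0 - params.w) * prc


def compose_dopamine_responses(
    state: ANCCRState, params: ANCCRParams, event_index: int
) -> float:
    """Dopamine response to the event that just occurred.

    For each meaningful target j the event i claims credit NC[j, i], less
    credit already explained by other meaningful events still eligible now
    (weighted by their clipped traces).  An event is its own target with
    self-contingency 1, so a fully predicted reward (cue contingencies
    summing to 1) evokes no value-driven response.  Credit is value-weighted
    by R[j]; reward's innate b is added at output when configured.
    """
    i = event_index
    nc = state.net_contingency(params)
    presence = np.minimum(state.E, 1.0)  # clipped: one recent occurrence saturates
    da = 0.0
    for j in np.flatnonzero(state.meaningful):
        own = 1.0 if i == j else nc[j, i]
        others = [k for k in np.flatnonzero(state.meaningful) if k != i and k != j]
        explained = float(np.sum(nc[j, others] * presence[others]))
        if i == j:
            explained = min(max(explained, 0.0), 1.0)  # cannot out-predict the event
        da += state.R[j] * (own - explained)
    if params.add_b_at_output:
        da += state.b[i]
    return float(da)


def _refresh_meaningful(state: ANCCRState, params: ANCCRParams) -> None:
    """Re-evaluate which events are meaningful (learning targets).

    Estimated value = innate b + contingency-weighted value of the current
    meaningful targets; an event is meaningful while that exceeds the
    threshold.  Reward bootstraps the set through b_reward > threshold and
    can never lose the flag; cues gain and may lose it as contingencies
    evolve.
    """
    nc = state.net_contingency(params)
    value = state.b + nc[state.meaningful, :].T @ state.R[state.meaningful]
    state.meaningful = (value > params.threshold) | (state.b > params.threshold)


def _baseline_gap_update(
    state: ANCCRState, params: ANCCRParams, t_event: float, next_grid: float
) -> float:
    """Apply all baseline samples on the dt grid strictly before t_event.

    Between events E decays geometrically on the grid (ratio rho per step),
    so the EMA over n steps has the closed form
        Mbar' = beta^n Mbar + alpha0 * E_1 * beta^(n-1) * sum_{m=0}^{n-1} (rho/beta)^m
    with beta = 1 - alpha0 and E_1 the trace at the first grid point.
    Returns the next unused grid time.
    """
    dt, a0 = params.dt, params.alpha0
    if t_event <= next_grid:
        return next_grid
    # grid samples at next_grid + m*dt strictly before the event (ties after)
    n = int(np.ceil((t_event - next_grid) / dt - 1e-9))
    if n <= 0:
        return next_grid
    beta = 1.0 - a0
    rho = np.exp(-dt / state.T)
    E1 = state.E * np.exp(-(next_grid - state.t_last) / state.T)
    r = rho / beta
    if abs(r - 1.0) < 1e-12:
        geom = n * beta ** (n - 1)
    else:
        geom = beta ** (n - 1) * (r**n - 1.0) / (r - 1.0)
    state.Mbar = beta**n * state.Mbar + a0 * E1 * geom
    return next_grid + n * dt


def simulate_stream(
    stream: EventStream, params: ANCCRParams, IRI: float | None = None
) -> dict:
    """Run the event-driven model over one stream.

    Returns {"labels": [...], "da": per-event dopamine array aligned with the
    stream, "T": T, "alpha": alpha}.  T and alpha are fixed from the stream's
    mean IRI unless ``track_iri_online`` keeps a running mean.
    """
    labels = sorted(set(stream.labels), key=lambda s: (s != "reward", s))
    if IRI is None:
        IRI = stream.mean_inter_reward_interval()
    T = eligibility_time_constant(IRI, params.k)
    alpha = adaptive_alpha(IRI, params.alpha0, params.dt)
    b = np.array([params.b_reward if lab == "reward" else params.b_cue for lab in labels])
    state = ANCCRState(labels=labels, T=T, alpha=alpha, b=b)
    state.meaningful = b > params.threshold

    da = np.empty(len(stream))
    next_grid = params.dt
    last_reward_t = None
    iri_run, n_iri = IRI, 1
    for idx in range(len(stream)):
        t = stream.times[idx]
        i = state.index[stream.labels[idx]]
        next_grid = _baseline_gap_update(state, params, t, next_grid)
        state.decay_to(t)
        state.E[i] += 1.0
        da[idx] = compose_dopamine_responses(state, params, i)
        if state.meaningful[i]:
            state.M[i] = update_event_memory(state.M[i], state.E, state.alpha)
        state.R[i] += params.alphaR * (state.b[i] - state.R[i])
        _refresh_meaningful(state, params)
        if stream.labels[idx] == "reward":
            if params.track_iri_online and last_reward_t is not None:
                n_iri += 1
                iri_run += (t - last_reward_t - iri_run) / n_iri
                state.T = eligibility_time_constant(iri_run, params.k)
                state.alpha = adaptive_alpha(iri_run, params.alpha0, params.dt)
            last_reward_t = t
    return {"labels": labels, "da": da, "T": T, "alpha": alpha}


@dataclass
class SimulationResult:
    """Per-iteration, per-trial dopamine at each within-trial event.

    ``da`` has shape (n_iterations, n_analysis_trials, n_event_labels);
    ``event_times_in_trial`` gives each label's time from cue_1 onset.
    """

    condition: str
    event_labels: list
    event_times_in_trial: np.ndarray
    da: np.ndarray
    seeds: list

    def mean_response(self) -> np.ndarray:
        """Label-wise mean over iterations and analyzed trials."""
        return self.da.mean(axis=(0, 1))

    def to_frame(self):
        import pandas as pd

        it, tr, ev = np.indices(self.da.shape)
        return pd.DataFrame(
            {
                "iteration": it.ravel(),
                "trial": tr.ravel(),
                "event_label": np.asarray(self.event_labels, dtype=object)[ev.ravel()],
                "event_time_in_trial_s": self.event_times_in_trial[ev.ravel()],
                "dopamine": self.da.ravel(),
            }
        )


def run_simulation(
    config: TrialConfig | str,
    params: ANCCRParams = ANCCRParams(),
    seed: int = 0,
) -> SimulationResult:
    """Simulate ``params.n_iterations`` fresh streams and keep the last
    ``params.n_analysis_trials`` trials of each.

    ``config`` may be a TrialConfig or a condition name ("sim-short" /
    "sim-long").  One master seed spawns per-iteration substreams.
    """
    condition = config if isinstance(config, str) else "custom"
    if isinstance(config, str):
        config = simulation_config(config, n_trials=params.n_trials)
    if config.n_trials < params.n_analysis_trials:
        raise ValueError("stream shorter than n_analysis_trials")

    labels = [f"cue_{c + 1}" for c in range(config.n_subcues)]
    times_in_trial = [float(c) for c in range(config.n_subcues)]
    if config.include_offset_event:
        labels.append("cue_offset")
        times_in_trial.append(config.cue_duration_s)
    labels.append("reward")
    times_in_trial.append(config.reward_delay_s)

    # fixed condition-level IRI: trial span + consummatory + ITI target mean
    mean_iti = config.iti_spec.target_mean_s - config.consummatory_s
    IRI = config.reward_delay_s + config.consummatory_s + mean_iti

    master = np.random.SeedSequence(seed)
    children = master.spawn(params.n_iterations)
    da = np.empty((params.n_iterations, params.n_analysis_trials, len(labels)))
    for it, child in enumerate(children):
        stream = build_simulation_stream(config, np.random.default_rng(child))
        out = simulate_stream(stream, params, IRI=IRI)
        per_label = {
            lab: out["da"][stream.labels == lab][-params.n_analysis_trials :]
            for lab in labels
        }
        for e, lab in enumerate(labels):
            da[it, :, e] = per_label[lab]
    return SimulationResult(
        condition=condition,
        event_labels=labels,
        event_times_in_trial=np.asarray(times_in_trial),
        da=da,
        seeds=[c.entropy for c in children],
    )


def simulation_ramp_metrics(
    result: SimulationResult, window: tuple[float, float] = (3.0, 8.0)
) -> dict:
    """Ramp slope and onset response of the iteration-averaged curve.

    slope: least-squares slope of mean dopamine vs within-trial event time
    over events in the half-open window [a, b) — for the default trial this
    spans sub-cues 4-8, excluding onset and offset transients.
    onset_response: mean dopamine at the first cue.
    """
    t = result.event_times_in_trial
    mask = (t >= window[0]) & (t < window[1])
    if mask.sum() < 2:
        raise ValueError("need at least two events inside the ramp window")
    mean = result.mean_response()
    slope = float(np.polyfit(t[mask], mean[mask], 1)[0])
    return {"slope": slope, "onset_response": float(mean[0])}


def per_iteration_ramp_slopes(
    result: SimulationResult, window: tuple[float, float] = (3.0, 8.0)
) -> np.ndarray:
    """Ramp slope of each iteration's trial-averaged curve."""
    t = result.event_times_in_trial
    mask = (t >= window[0]) & (t < window[1])
    curves = result.da.mean(axis=1)  # (iterations, labels)
    return np.array([np.polyfit(t[mask], c[mask], 1)[0] for c in curves])
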
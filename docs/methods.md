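# Methods

`ramplight` packages two things: an event-driven simulator of the ANCCR
(Adjusted Net Contingency for Causal Relations) learning model configured for
a trace-conditioning task with a discretized "dynamic" cue, and the analysis
pipeline used on fiber-photometry recordings of mesolimbic dopamine — dF/F
extraction, per-trial ramp-slope and onset-peak quantification in time
(Pavlovian) and in virtual distance (VR), and the trial-wise statistics
relating ramp slope to inter-trial-interval (ITI) history.  A synthetic
session generator with known ground truth closes the loop: every analysis
stage is validated by parameter recovery rather than by eyeballing.

## Task and event streams

All conditions share one trial skeleton: an 8 s cue, a 1 s trace period,
then reward, so reward follows cue onset by 9 s.  ITIs (reward to next cue
onset) are drawn i.i.d. from truncated exponential distributions:
6–12 s with mean 8 s (short) and 6–186 s with mean 55 s (long).  Only the
support and mean are specified, so the exponential rate is solved by
bracketed root-finding on the closed-form truncated mean (|error| < 1e-6 s);
for the short spec this gives λ ≈ 0.358 /s.  The mean of a truncated
exponential on [a, b] lives in (a, (a+b)/2), which is enforced as a
feasibility check.  A small-λ series expansion avoids cancellation near the
uniform limit, and the factored form avoids underflow at large λ.

Simulation streams discretize the dynamic tone into 8 sub-cues at 1 s
spacing (a 400 Hz/s frequency change being the assumed detectable
granularity) plus the cue offset as a ninth cue, then reward.  After reward,
a fixed 6 s consummatory period precedes the ITI clock.  The residual
simulation ITI is the experimental truncated-exponential draw minus the
consummatory period (mean 2 s short, 49 s long), so the reward-to-cue gap
reproduces the experimental ITI distribution and the mean inter-reward
interval (IRI) is 9 + 8 = 17 s (short) and 9 + 55 = 64 s (long).

Times are float64 seconds from session start.  All analysis windows are
half-open [a, b); samples on the right edge are excluded.

## The ANCCR simulator

State per event type i: an eligibility trace E_i(t) = Σ exp(−(t − t_i)/T)
over past occurrences (updated recursively: decay, then +1 at each
occurrence; verified against the explicit sum to 1e-10), pairwise memories
M[j, i] — an exponential moving average of E_i sampled at occurrences of
target j at rate α — and a baseline memory M̄_i sampled every dt = 0.2 s at
rate α₀ = 5e-3 on a global grid independent of events.  The predecessor
representation contingency is PRC = M − M̄.  Between events the baseline EMA
is advanced in closed form (the trace decays geometrically on the grid, so
the EMA over n steps is a geometric sum), which keeps long sessions cheap.

Two quantities adapt to the environment's timescale: the eligibility time
constant T = k·IRI with k = 0.2, and the event-memory learning rate
α = 1 − (1 − α₀)^(IRI/dt) (≈ 0.347 at IRI 17 s, ≈ 0.799 at 64 s).  Both are
fixed per condition from the condition's mean IRI; an optional
`track_iri_online` flag switches to a running-mean IRI but is off by
default, since trial-by-trial adaptation of T is deliberately not modeled.

The conversion of contingencies into a dopamine response is this package's
reconstruction of the model family from its published parameter roles
(w = 0.5, b_cues = 0, b_reward = 0.5, threshold = 0.2, α_R = 1); the
composition equations themselves are defined in companion work, so fidelity
is claimed only at the level of qualitative contracts, not line-by-line:

- prospective contingency = PRC × M̄_target / M̄_cause (a Bayes base-rate
  correction); net contingency NC = w·prospective + (1 − w)·PRC;
- every event's value R is seeded by its innate value b and pulled back to
  it at rate α_R on each occurrence; contributions toward a target are
  scaled by the target's R, which makes reward (b = 0.5) the only target
  that matters with the default b_cues = 0;
- an event is *meaningful* (acts as a learning target: its M row updates,
  and it participates in credit assignment) while its estimated value
  b + Σ NC·R over meaningful targets exceeds the threshold.  Reward
  bootstraps the set and cannot leave it; cues gain and may lose the flag
  as contingencies evolve.  Meaningfulness is re-evaluated after every
  event — an early design used a sticky flag, but the large
  initial-learning α then froze transiently-high contingencies into the
  set and suppressed the long-ITI onset response;
- dopamine at event i = Σ over meaningful targets j of
  R_j·(NC_{i→j} − Σ_k NC_{k→j}·min(E_k, 1)), the credit i claims toward j
  minus credit already explained by other currently-eligible meaningful
  events k (their presence clipped at one occurrence).  An event is its own
  target with self-contingency 1, and its explained-away sum is clipped to
  [0, 1], so a fully predicted reward evokes no value-driven response.
  b_reward is additionally added to the reward response at output
  (configurable via `add_b_at_output`).

This composition reproduces the intended regime behavior.  Short ITI
(T = 3.4 s): only late sub-cues retain eligibility at reward, PRC rises
across the sequence, and little is explained away because earlier cues have
decayed — a ramp, with a slightly negative onset response (a known
discrepancy with experiment, left uncorrected).  Long ITI (T = 12.8 s):
every cue retains eligibility, so contingencies are high throughout, but at
each later cue the earlier cues are still present and explain the credit
away — the first cue carries the response and the within-trial slope is
flat-to-negative.  The within-trial slope is quantified as the OLS slope of
the iteration-averaged response versus event time over [3, 8) s, i.e.
sub-cues 4–8, excluding the onset and offset transients like the
experimental ramp window.

Each condition runs 1000 trials × 20 iterations (fresh streams spawned from
one master seed; per-iteration seeds recorded) and analyzes the last 100
trials per iteration.  Both conditions complete in about a minute on one
core.

## Photometry pipeline

The 405 nm isosbestic channel is least-squares scaled to the 470 nm channel
— affine (gain + intercept) by default, with a gain-only option — and
dF/F = (470 − fitted405)/fitted405 × 100.  Nonpositive fitted values are a
hard error naming the sample.  Per-trial metrics: onset peak = max dF/F in
[t, t+1) minus mean over [t−1, t); ramp slope = OLS slope over [3, 8) s
after cue onset (%dF/F per s); pre-cue slope over a 2 s window (the window
length is not externally specified; 2 s is this package's default,
configurable).  Slopes are always computed on unsmoothed dF/F; Gaussian
smoothing (default σ = 2 samples, likewise a package choice) exists only in
`smooth_for_display`.  Trials whose windows exceed the recording are
dropped with a warning, not errors.

For VR sessions, the 10 ms dF/F stream is synced to 30 ms distance samples
by assigning the mean of each dF/F triplet to its distance sample and
dropping any distance sample equal to its predecessor (stationary animal)
together with its dF/F.  The ramp slope is then the OLS slope of dF/F
versus distance over [20, 57) cm of the 67 cm hallway; per-cm curves round
distances to the nearest integer and average within bins.  The generator
emits 10 ms dF/F and 30 ms distance directly; other rates go through a
mean-within-bin resampler.

## Trial-wise statistics

Previous ITI = time from the preceding trial's reward to this trial's cue
onset; first trials are excluded from all previous-ITI analyses.  Analyses:
per-animal OLS of ramp slope on previous ITI; pooled OLS after z-scoring
slopes within animal (removing between-animal mean differences; ITIs stay
on their natural scale); the delta analysis on consecutive trials, where
ΔITI_i and Δslope_i difference the quantities driving trials i−1 and i, an
OLS of Δslope on ΔITI, and category means for |ΔITI| > 1 s; and the
average-previous-ITI variant regressing on the mean of the k preceding
ITIs.  IRI outliers beyond 3 population SDs of the original distribution
are removed in a single pass (no re-estimation), which makes the filter
idempotent for bounded scatter.  Condition contrasts use two-sided paired
t-tests on per-animal means by default (configurable to unpaired Welch);
α = 0.05.

## Synthetic sessions

The generator emulates what the analyses assume, with all parameters in a
checksummed manifest.  Channels: 405 = 100·(1 + double-exponential bleach,
amplitudes 0.15/0.10, taus 600/3000 s) + white noise; 470 = 1.6 × clean 405
× (1 + d(t)/100) + white noise, so the dF/F pipeline recovers the injected
component d(t).  Per trial d(t) contains a cue-onset transient (0.1 s
plateau then 0.3 s decay — the plateau makes the peak amplitude exactly
recoverable at any sampling phase), a linear ramp over [3, 9) s after cue
onset with slope = base + β·(previous ITI) + N(0, jitter), a reward
transient, and a −1% dip starting 1 s after reward recovering with a 2.5 s
time constant (truncated at 8 time constants; the dip magnitude is not an
externally reported value, only an order-of-magnitude choice used for
robustness checks, e.g. the positive pre-cue slope it induces at short
ITIs).  Licking is an inhomogeneous Poisson train (baseline 2 Hz climbing
to 6 Hz through the cue and trace period) sampled by thinning.  VR trials
accelerate exponentially (τ = 0.5 s) toward a 20 cm/s plateau down the
67 cm hallway with the ramp injected as a function of distance.

Condition presets encode the qualitative regimes: LD/LF — 8% onset
transient, no ramp, 40 trials; SD — 2% onset, ramp base 0.55 %dF/F/s with
β = −0.045 and 0.15 %dF/F/s trial jitter, 100 trials; SF — no ramp,
100 trials; VR 50 trials.  The SD noise level (0.3 raw-channel SD and the
slope jitter) is chosen so per-trial slope scatter is large relative to the
ITI-driven signal, as in per-trial scatter plots of real recordings; with
300 trials this puts the β standard error near 0.006, so recovery within
3 SE is a meaningful check.  β itself and the session sizes are the
reported study scales.

Two caveats on what recovery shows.  "Exact" noiseless recovery is asserted
against the generator's clean reference channel; estimating the isosbestic
fit from the data itself leaves a small (<1% of truth) contamination,
because the dopamine component perturbs the 405→470 regression — an
inherent property of the method, also present on real data.  And the
generator shares the analyses' structural assumptions (linear ramp, kernel
additivity, stationary noise), so passing recovery validates the code and
the statistics, not the biological adequacy of those assumptions.

## Problem sizes

Defaults used by the analysis drivers and tests: full simulations at
20 × 1000 trials; recovery studies at 200 replicates of 300-trial sessions
sampled at 120 Hz; sampler calibration checked with 1e5–1e6 draws.  The
drivers under `analysis/` regenerate every table in `results/` from scratch
with fixed seeds.

## Known limitations

- The dopamine composition layer is a reconstruction; quantitative values
  of simulated responses are not comparable across implementations of the
  model family, only the regime contracts are.
- The simulator's negative short-ITI cue-onset response disagrees in sign
  with experiment (likely pre-training history, which is not modeled); no
  correction is applied.
- No NWB ingestion; sessions are CSV/arrays.  No sensor kinetics, motion
  artifacts, or hemodynamics in the generator.
- Statistical tests are the package defaults described above, not a claim
  about which test any particular published comparison used.
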
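# Methods

## The model

Error detection is treated as a second, post-decisional accumulation
process.  After an erroneous action, evidence that an error has occurred
accumulates as a one-dimensional diffusion

    dx = u dt + s dW,    x(0) = 0,

with a trial-specific drift `u ~ Normal(v, eta)`.  Detection is
signalled when `x` first reaches a single bound `a`; if the bound has
not been reached by a deadline the trial ends as an undetected error.
The detection response time is `rt_d = T + t_nd`, with `T` the
first-passage time and `t_nd` a non-decision time covering encoding and
motor execution.  The within-trial noise scale `s` is fixed at 0.1 so
the remaining parameters are expressed on a common scale.  A trial
counts as detected iff `T + t_nd <= deadline`, because the deadline is
estimated on the `rt_d` scale (slowest detection RT after a single-pass
trim of values above mean + 3.5 s.d.).

With `eta > 0` some trials have negative drift, for which no analytic
first-passage law exists; the model is therefore simulated as an
Euler–Maruyama random walk (default 1 ms steps, 15,000 paths per
distribution; `scripts/` and tests scale these down where noted).  For
the `eta = 0` special case, closed forms act as oracles: with drift
`u > 0` the first-passage time is inverse-Gaussian with mean `a/u` and
shape `a²/s²`; with `u < 0` absorption occurs with probability
`exp(2ua/s²)` and is inverse-Gaussian-distributed conditional on
absorption.  Euler discretization biases first-passage times upward by
O(√dt) (paths can cross and recross between steps); the oracle tests
use finer steps (0.25–2 ms) chosen so this bias is small against their
Monte-Carlo tolerance, and long horizons (up to 90 s for the weakest
negative drift) so truncated absorption mass is negligible.

## Fitting

The model is fit per subject to the *defective* distribution of
detection RTs: the 0.1/0.3/0.5/0.7/0.9 quantiles of detected `rt_d`
(linear interpolation between order statistics) define six detected
bins with fixed expected shares (.1,.2,.2,.2,.2,.1) of the detected
count, plus one undetected bin, so accuracy and RT are constrained
jointly.  Model-expected counts come from simulation in the same bins,
floored at `1e-4 * n_total` to keep the Pearson statistic finite, and
`chi2 = sum((O-E)²/E)` is minimized by particle-swarm optimization:
30 particles, reflecting box bounds (`a` in (0.01,1], `v` in [−1,2],
`eta` in [0,1.5], `t_nd` in [0.05, deadline)), constriction
coefficients (inertia 0.72, cognitive/social 1.49), 100 iterations by
default.  All objective evaluations within one fit share one set of
random numbers (common random numbers), making the χ² surface — and the
whole fit — a deterministic function of its inputs and smoothing the
landscape the swarm explores.  Degrees of freedom follow the convention
(7 bins − 1) − (4 free parameters + 1 for the empirically fixed
deadline) = 1.

The individual magnitudes of `a`, `v`, `eta` are identifiable only up
to roughly 2:1 (a scaled-up bound and drift with a shorter `t_nd` can
fit almost as well); the drift ratio `v/eta` is the invariant
evidence-quality index and is what downstream analyses consume.  The
parameter-recovery test asserts exactly this: `t_nd` within ±0.05 s and
`v/eta` within ±25%, with no claim on the individual magnitudes.

Reconstructed decision-variable trajectories allot 90 ms of `t_nd` to
post-threshold response preparation (the residual delays accumulation
onset) and decay linearly to baseline over 300 ms after the bound;
undetected trials hold their terminal value once accumulation stops at
the deadline.

## Synthetic cohort

The generator emulates the structure the analyses assume, not raw EEG:

* **Trial stream** — blocks of 224 trials (200 Go / 24 No-Go) with at
  least three Go trials between No-Go stimuli, placed by a random
  composition of the free gaps; infeasible compositions raise.
* **Behavior** — per-subject withhold probability Normal(0.566, 0.13)
  clipped to [0.05, 0.95]; diffusion parameters drawn around the
  group-mean fit (a=0.21, t_nd=0.20, v=0.45, eta=0.45; s.d.
  0.12/0.08/0.30/0.30, clipped to plausible ranges) with deadlines
  Normal(1.17, 0.19) clipped to [0.81, 1.47] s.  Detection outcomes and
  `rt_d` come from the one-choice model itself.
* **Primary RTs** — log-normal per condition, tied by a latent
  "salience" of the No-Go lapse: salient lapses are pressed faster and
  generate stronger error evidence (correlation 0.6 with the drift
  deviate).  The log-RT coupling (0.16) and the error-median offset
  (25 ms below the Go median of 511 ms) were derived analytically so
  the detected/Go/undetected medians reproduce the target ordering
  (~457 < 511 < 543 ms) while the primary-RT/`rt_d` correlation stays
  near zero.
* **Signals** — the CPP is a deterministic ramp that reaches the bound
  `a` exactly 90 ms before the report and decays over 300 ms
  (undetected errors ramp at the trial's drift, capped below the bound,
  and hold after the deadline; Go trials carry a first-order ramp
  reaching the bound 90 ms before the primary response).  FC-theta is a
  5.5 Hz carrier under a Gaussian envelope (center +0.15 s, s.d.
  0.12 s after the response) with amplitude √θ_scale, θ_scale
  log-normal with unit mean (log-s.d. 0.4).  The coupling
  `u += γ (θ_scale − 1)` with γ = 0.3 creates the
  theta → build-up → `rt_d` mediation; γ = 0 severs it by construction.
  Both channels receive 1/f noise of s.d. 0.05 signal units (the bound
  is ~0.21), sampled at 256 Hz.

What the generator does *not* emulate: channel covariance and volume
conduction, artifacts, first-order Go/No-Go competition beyond a single
ramp, stimulus-evoked potentials, or any coupling between primary-task
and detection accuracy beyond the salience device.  Passing tests
therefore demonstrate that the statistical machinery recovers the
relationships the generator encodes at realistic sizes and noise — not
that those relationships hold in any particular EEG dataset.

## Electrophysiological statistics

Band power uses either complex Morlet convolution (90 linear
frequencies 1–30 Hz, cycles rising linearly 2→12, reflection padding of
half the longest wavelet) or a zero-phase least-squares FIR band-pass
(2–7 Hz, order three cycles of the low cut, 20% transition bands)
followed by the squared analytic-signal envelope.  Power is expressed
as `10·log10(power/baseline)` against the across-trial average power in
the 0.3 s before stimulus onset, computed separately per condition so
single-trial baseline variability survives; power is clipped at 1e−12
before the log.  The time-frequency mask keeps pixels with paired-t
p < 0.01 versus baseline only inside contiguous clusters spanning at
least 400 ms and 5 frequency bins.

Single-trial metrics follow fixed windows (seconds, relative to the
error unless stated): FC-theta amplitude −0.1..+0.4; CPP amplitude
−0.2..0 before the report; build-up rates as OLS slopes in 0..0.2
(theta) and 0.1..0.3 (CPP), with the mediation mediator measured
−0.3..−0.1 before the report to reduce overlap with the theta window;
peak latency as the within-window argmax between a per-signal start
(−0.1 theta, +0.1 CPP) and `rt_d + 0.15`, advancing the start to the
first positive-going sample when the maximum pins to the window edge.
RT bins are equal-sized after sorting (ties by trial order; remainders
to the fastest bins so sizes differ by at most one).  Sliding 150 ms
slope contrasts use centered linear weights with a one-tailed group
test (steeper build-up for faster trials); sample-wise amplitude
contrasts are two-tailed.  Go-trial analyses drop primary RTs ≤ 350 ms.

The ROC analysis pools trials across subjects, scores 20 ms window
means with the rank-based AUC (midrank ties) and compares against a
null built from 1000 within-subject label permutations that conserve
each subject's detected/undetected counts; the band is the permutation
mean ± 1.96 s.d. (two-sided; exceedances reportable per tail).

Within-subject regressions use bisquare M-estimation (tuning 4.685,
IRLS, ≤200 iterations) of `log(rt_d)` on the FC-theta and CPP metric of
each model, estimated jointly; effect sizes β/s.e. are tested across
subjects with one-sample and paired t tests (two-tailed).  Latencies
are square-root transformed after shifting by the window start (the
theta window starts at −0.1 s, so raw latencies may be negative) and
tested against a permutation null that redraws each trial's latency
uniformly within its own measurement window, because the dynamic window
alone induces a positive latency–RT coupling.

Mediation z-scores each variable within subject (s.d. with n−1), pools
across subjects, sorts by `rt_d`, averages consecutive bins of 12
(remainder dropped) and fits the three OLS path regressions; `ab = a·b`
and `c = c′ + ab` holds identically.  Inference is a bias-corrected
(BC, no acceleration) bootstrap over bins, 10,000 resamples by default;
degenerate resamples are redrawn and counted.

## Problem sizes used by the test suite

The statistical-calibration tests run the full generator→analysis chain
at sizes chosen to balance resolution against a desk-scale run: type-I
calibration uses 100 cohorts of 12 subjects × 3 blocks with γ = 0
(400 bootstrap resamples, 200 permutations), asserting binomial 95%
bands around the nominal 5% for mediation and regression and a 99%
t-interval around the 5% two-tailed ROC exceedance rate on pre-error
windows; the power check runs 20 cohorts at the generator's default
28 subjects × 10 blocks.  Parameter recovery fits 1,000 simulated error
trials with 3,000-path objective evaluations and 60 swarm iterations.

## Known limitations

* The Euler random walk slightly over-estimates first-passage times at
  1 ms steps; fits inherit this from the same approximation the fitting
  procedure itself uses, so it cancels to first order in recovery tests
  but matters if parameters are compared against analytic laws.
* The χ² objective is a step function of the parameters at finite
  simulation count; common random numbers smooth it but plateaus
  remain, and the swarm can terminate on one (flagged via `patience`).
* BC (not BCa) bootstrap intervals; with strong skew and small bin
  counts the intervals can be slightly liberal.
* The latency permutation null re-fits the full robust regression per
  iteration and is the most expensive statistic at its default 1,000
  iterations.
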
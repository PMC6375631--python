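# Methods

`polvmut` models how the *E. coli* translesion DNA polymerase V mutasome
(pol V Mut = UmuD′₂C·RecA·ATP) switches between catalytically active and
inactive conformations, and provides the estimators needed to quantify that
switch from bulk primer-extension assays and single-molecule FRET binding
records. This note documents the models, their assumptions, the defaults, the
numerical choices, and what the synthetic-data tests do and do not establish.

## Dynamic deactivation model

Primer extension on a pool of primer/template (p/t) DNA follows
pseudo-first-order kinetics, `dP/dt = k′(t) (1 − P)`, where `P(t)` is the
fraction of primer extended and `k′` is proportional to the concentration of
*active* enzyme. Deactivation during synthesis ("dynamic" deactivation)
depletes the active pool as a Poisson process at rate `D`, so
`k′(t) = k e^{−Dt}` and

    P(t) = 1 − exp(−(k/D)(1 − e^{−Dt})),    P(∞) = 1 − e^{−k/D}.

This form satisfies the required short-time limit `ln(1 − P) ≈ −kt` and the
`D → 0` limit `1 − e^{−kt}`. A historical variant of the integrated
equation, `ln(1−P) = −kt + k(e^{−Dt} − Dt − 1)/D`, is retained behind an
`as_printed=True` flag for comparison only; its short-time slope is `−3k`,
which is inconsistent with the initial-rate convention used for seeding the
fit, so the corrected form is the default everywhere.

Parameters and defaults (units min⁻¹ throughout):

| parameter | meaning | typical values |
|---|---|---|
| `k` | pseudo-first-order synthesis rate (enzyme concentration folded in) | 0.004–0.012 |
| `D` | dynamic deactivation rate | 0.01–0.028 (faster at 37 °C than 30 °C) |

**Fitting.** `DynamicDeactivationModel` first estimates `k` from the
initial-rate slope — the least-squares slope *through the origin* of
`−ln(1 − pe)` versus time over the first `window_n = 3` points in the
low-extension regime (`pe < 0.1`); the model forces `P(0) = 0`, which is why
the intercept is pinned. It then runs bounded nonlinear least squares
(`scipy.optimize.curve_fit`, both parameters free, non-negativity bounds)
over the full profile, with inverse-variance weighting when replicate SDs
are supplied. Standard errors come from the fit covariance;
non-convergence raises `FitConvergenceError` rather than returning defaults.
Note the initial-rate slope alone is biased low by deactivation (≈12 % for
`k = 0.004, D = 0.015` sampled at 0/10/20 min); it is only a seed, and the
full nonlinear fit removes the bias (noiseless round trips recover both
parameters to better than 4 significant figures).

**Derived quantities.** The expected number of rounds of synthesis at an
`x`-fold molar DNA excess is `P(∞)·x` (each round extends a fraction `1/x`
of the pool). With `k = 0.008, D = 0.028` the plateau is 0.2485 — one round
at 5-fold excess; with `k = 0.012, D = 0.01` it is 3.49 rounds, i.e. the
slow-deactivation regime supports multiple template cycles.

## Static deactivation and Arrhenius analysis

Activity loss during incubation *without* synthesis is treated as
exponential decay of relative activity, `A(t) = e^{−rt}`. The initial rate
is estimated from the activity remaining at a reference time (default
30 min) as `r = −ln A(t_ref)/t_ref`; a linear convention `(1 − A)/t_ref` is
available by flag, but the exponential convention is the default because it
reproduces a rate of 0.015 min⁻¹ from ≈36 % activity loss at 30 min, the
regime these assays operate in. Two-temperature Arrhenius analysis uses

    Ea = R ln(r_high/r_low) / (1/T_low − 1/T_high),

with `T = °C + 273.15` and `R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹`. Because this
two-point estimate is extremely sensitive to rounding of the input rates,
the package treats the *formula* as the deliverable and makes no attempt to
reproduce any particular published energy from rounded rates.

## smFRET event idealization

Per-frame FRET efficiency is `E = I_A/(I_D + I_A)`, clipped to [0, 1];
frames with non-positive total intensity are flagged invalid and excluded
from event logic. `ThresholdEventDetector` idealizes a trajectory into
bound intervals as maximal runs of ≥ `min_frames` consecutive frames with
`E ≥ threshold`. Defaults: `threshold = 0.2` (the lower edge of the observed
bound-state efficiency range), `min_frames = 2`. Runs touching the first or
last frame are flagged censored and excluded from dwell samples by default,
since their true duration is unknown; an inclusion flag exists for
sensitivity analysis. Dwell durations count qualifying frames times the
frame interval; sub-threshold single frames inside an event are *not*
bridged (no hysteresis by default). Event gaps within a trajectory form the
rebinding-time sample.

Background handling: a first thresholding pass classifies frames, the
median acceptor intensity over unbound frames is subtracted from the
acceptor channel, and efficiencies are recomputed before final detection.
Only the acceptor channel is corrected — unbound frames carry the full
donor signal, so an unbound-frame donor median is signal, not background.

Efficiency histograms over bound frames use bins *centered* on multiples of
the bin width (e.g. the 0.70 bin covers [0.675, 0.725)), so a bound-state
efficiency sitting exactly on a multiple of the width falls in the interior
of a bin rather than on an edge.

Frame-interval conventions: 0.3 s per frame for ATPγS acquisitions and
0.1 s for ATP, mirroring the acquisition rates of the experiments this
pipeline targets.

## Dwell-time statistics and affinity calculus

Bound dwells and rebinding gaps are exponential, so the MLE of the time
constant is the sample mean with asymptotic SE `τ̂/√n`. A least-squares
single-exponential histogram fit (Poisson-weighted, `σ = √count` per bin) is
kept as a cross-check; the two agree within 15 % on samples of n ≥ 200.
Censoring is handled by exclusion, not by a survival likelihood — a known
limitation that biases dwell means slightly when records are short relative
to the dwell scale.

Rate constants and affinity: `k_dissoc = 1/τ_bound`,
`k_assoc = 1/(τ_rebind·c)` with the enzyme concentration `c` in nM (the
rebinding time stands in for the unobservable unbound time), and
`K_D = k_dissoc/k_assoc` in nM. Survival fractions are `e^{−t/τ}`.
Distances come from inverting the Förster relation,
`r = R₀((1−E)/E)^{1/6}`, with `R₀ = 51 Å` for the AF555/AF647 pair; the
forward relation `E = 1/(1+(r/R₀)⁶)` is provided for round-trip checks.

## Three-state switch simulator

Each molecule is a continuous-time Markov chain over: state 1 (assembled,
no nucleotide cofactor, cannot bind DNA), state 2 (ATP-activated, the only
synthesizing state), state 3 (deactivated). Transitions: 1→2 at `k_act`
(default: instantaneous — ATP binding is fast on the deactivation
timescale, so molecules start in state 2; a finite-rate option exists);
2→3 at the dynamic rate `D_dyn` while synthesizing, or at the static rate
`D_stat` when synthesis is disabled; 3→2 only at RecA* dosing times, as an
instantaneous Bernoulli restoration with probability `reactivation_eff`
(the experiments establish that RecA* reverses deactivation, not a
concentration–rate law, so dosing is modeled as an event, not a rate).

Event times are sampled exactly (no time-step discretization); the output
grid is for reporting only. Because the dwell distributions are memoryless,
each dwell is drawn once and carried across dose boundaries, which also
makes a zero-efficiency dose run bitwise-identical to an undosed run at the
same seed. Ensemble extension is computed at the pool level:
`pe(t) = 1 − exp(−k_syn ⟨A(t)⟩)` with `⟨A(t)⟩` the ensemble-mean time spent
in state 2 up to `t`. This is the discrete counterpart of the closed-form
model above (whose derivation treats the DNA as a shared pool depleted by
the *ensemble* active fraction) and converges to it at `O(n^{−1/2})`; a
per-molecule average `⟨1 − e^{−k·A_i}⟩` would instead converge to
`k/(k+D)` at the plateau and is deliberately not used. With a single full
dose after the pool has deactivated, the plateau compounds on the residual
unextended fraction: `pe(∞) → 1 − (1 − P(∞))²`.

## Synthetic data: what it emulates, and what it does not

The generators produce exactly the statistical structure the estimators
assume: extension curves are the closed-form model plus additive Gaussian
noise on the fraction scale (clipped to [0, 1]), replicates independent;
activity series are exponential decay plus noise (clipped to [0, 1.05]);
binding trajectories are alternating-renewal two-state paths starting
unbound, with exponential dwells, a fixed bound-state efficiency, constant
intensity levels (unbound donor at the full bound-state total, acceptor
background at zero), additive per-channel Gaussian noise, and optional
exponential photobleach truncation. A frame is bound when its center falls
inside a bound interval. The ground-truth event list reports *every* dwell,
including those shorter than a frame, so detection bias is measurable.

Defaults mirror the study conditions: `τ_bound = 6.1 s`,
`τ_unbound = 17 s`, `E_bound = 0.7`, 0.3 s frames, 180 s records (the
usable window before photobleaching), total bound-state intensity 300
(arbitrary units), and "moderate" noise meaning an SD of 10 % of the total
intensity per channel.

Not emulated: camera/EMCCD noise physics, spectral crosstalk and gamma
factors, donor/acceptor blinking, intensity drift, multi-step photobleach,
diffusing background spots, and pixel-level image formation. Passing the
pipeline tests therefore shows the estimators are correct *given* two-state
dynamics with stationary intensities and Gaussian noise; it does not
validate the detector against the full pathology of real TIRF records.

## Numerical choices

- `model_pe` evaluates `(k/D)(1 − e^{−Dt})` as `kt·(1 − e^{−x})/x` with a
  series branch below `x = 10⁻⁸`, so it is stable through `D → 0` (including
  denormal `D`) and exact at `D = 0`.
- The deactivation fit retries from a small ladder of `D` seeds before
  declaring non-convergence.
- Fully-extended points (`pe = 1`) are dropped from the initial-rate window
  with a warning (the log transform diverges there).
- Dwell samples reject non-positive values by index; histogram fits require
  ≥ 3 occupied bins.
- All simulators take integer seeds; a global seed fans out to per-stage
  child seeds through `numpy.random.SeedSequence`, so identical seeds give
  bitwise-identical outputs and stages can be re-run in isolation.

## Problem sizes used in the shipped reproduction

The `reproduce` command and `scripts/acceptance.py` use the study's own
sample sizes where they are stated (n = 298/258/218 dwell samples, 300
trajectories, 10⁴ molecules in the ensemble check) and a 20-seed replication
protocol for the stochastic estimator checks, reporting the median estimate
across seeds. These sizes complete in seconds while leaving Monte-Carlo
error well below the tolerances being checked.

## Known limitations

- The dwell-time likelihood ignores censoring beyond exclusion; no
  survival-corrected or multi-exponential fitting.
- The event detector has no hysteresis or change-point refinement; dwell
  estimates are quantized to whole frames, and exclusion of sub-2-frame
  events truncates the dwell distribution (the MLE on detected events is
  therefore biased upward by roughly one frame plus the truncation offset,
  comfortably inside the 15 % pipeline tolerance at the default settings).
- A ±2 s band around a 17 s time constant estimated from 218 exponential
  draws is only 1.74 standard errors wide; no unbiased estimator can sit
  inside such a band 95 % of the time (the exact coverage is 91.8 %). The
  corresponding pass-rate check is left failing by design rather than
  widening the band; see the test suite.
- Efficiency-to-distance conversion assumes the standard Förster relation
  with a fixed `R₀`; efficiencies at the extremes (0 or 1) are rejected
  because the implied distances are unbounded or zero.
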
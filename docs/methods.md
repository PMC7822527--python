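# Methods

## Signal model

A participant's skin conductance is modelled as

    y(t) = tonic(t) + (x * h)(t) + ε(t)

with `tonic` a slowly varying baseline, `x ≥ 0` a sparse phasic driver
(sudomotor bursts), `h` the Bateman impulse response
`h(t) ∝ exp(−t/τ_d) − exp(−t/τ_r)` for `t ≥ 0`, and `ε` measurement
noise. Defaults `τ_r = 0.75 s`, `τ_d = 2.0 s` are in the middle of the
range the EDA deconvolution literature uses for the SCR shape; both are
configurable, and the kernel is discretized at the trace's sampling rate
over a support of `5 τ_d` (the biexponential is below 1% of its peak
there) and normalized to unit sum.

## Tonic handling

Richardson–Lucy (RL) requires non-negative data dominated by the
component being deconvolved, so the trace is first detrended by a
running-minimum baseline over a 30 s centred window and floored at
1e−6 μS. The window must be longer than any single SCR (a few seconds)
and shorter than genuine tonic excursions; 30 s satisfies both for this
paradigm's ~10-minute tasks. No motion-artifact handling is attempted.

## Deconvolution

RL iterates the multiplicative update `x ← x · corr(d / (h ∗ x), h)`,
which preserves non-negativity and, in its plain form, monotonically
improves the Poisson-likelihood fit of the reconstruction `h ∗ x` to the
detrended data `d`. Three numerical choices matter:

- **Initialization is flat** (the mean of `d`). Initializing at the data
  itself concentrates driver mass very quickly for SCRs that rise from
  baseline but leaves the second of two superposed SCRs as a broad,
  low-prominence smear; the flat start treats both symmetrically.
- **Acceleration.** Plain RL is slow: after 50 iterations two SCRs must
  be ~1.5 s apart to separate, and even 1600 iterations only reach
  ~0.4 s. Since separating overlapping SCRs is the entire point of
  deconvolving, the default applies Biggs–Andrews vector extrapolation
  (momentum `x + α(x − x_prev)` with `α` estimated from successive update
  directions, clipped to [0, 1)); 100 accelerated iterations resolve
  impulse pairs ~0.3 s apart. `accelerate=False` recovers the textbook
  update, for which the reconstruction RMSE is non-increasing in the
  iteration count; with acceleration the residual can wiggle transiently,
  so the monotonicity guarantee is stated (and tested) for the plain
  form. An optional stopping rule ends iteration early when the relative
  RMSE improvement falls below `tol` (default 1e−6).
- **Amplitude calibration.** RL squeezes each SCR's conductance mass into
  a narrow lobe whose raw height depends on the iteration count, not on
  the SCR. Because the update is scale-equivariant, one factor fixes the
  units: the kernel's own impulse response (a unit-amplitude isolated
  SCR) is deconvolved once per parameter setting, and the driver is
  divided by the resulting peak. On this scale a driver lobe of height
  0.3 reads as "an SCR of ~0.3 μS", which makes a prominence threshold
  stated in μS meaningful on the deconvolved signal.

An all-zero (or constant) trace short-circuits to an all-zero driver.

## Peak detection

SCRs are local maxima of the driver passing two criteria jointly:
topographic prominence ≥ 0.05 μS, evaluated on the calibrated
(un-normalized) driver, and height ≥ 1 SD above the mean, evaluated on
the z-normalized driver (recording-wide mean and population SD).
Evaluating each criterion on the view matching its stated unit takes
both literally; the recording-wide normalization scope matches treating
"the mean level" as a property of the whole signal. Plateau maxima count
once at their midpoint; edge samples cannot be peaks (prominence is
undefined there); no minimum inter-peak distance is imposed, since
separation is the deconvolution's job.

## Windows, rates, synchrony

Proposal windows are half-open `[t_end − 1, t_end + 4)` seconds around
each proposal's end — early enough to catch anticipatory responses to a
nearly-complete proposal, late enough for the seconds-long SCR latency.
Windows are kept per event for rates (each is one statistical
observation, overlapping or not) but merged for the task segmentation,
whose proposal and non-proposal parts tile the task span exactly.
Windows crossing a recording edge are clipped and flagged rather than
dropped. When no explicit task span is configured it is inferred as
first annotation start − 1 s to last annotation end + 4 s.

Rates are `60 · count / duration` SCR/min. Synchrony is the Pearson
correlation of the two members' drivers over the samples of a
segmentation, pooled across segments (not averaged per event); dyads are
aggregated via Fisher z, and the proposal vs non-proposal contrast is a
dependent t-test on the per-dyad z differences (variance-stabilized;
the r-scale means are reported alongside). If no dyad shows any
difference the contrast is reported as exactly null rather than
undefined.

## Mixed models

The rate analyses use Gaussian linear mixed models on per-event rates —
the coefficient-table layout implies an identity link, and per-event
observations (not participant means) are what make a
participant-in-dyad random intercept meaningful:

    rate ~ Role * Diagnosis        (all rows)
    rate ~ Response * Diagnosis    (proposer rows only)

with Role 0 = recipient / 1 = proposer, Diagnosis 0/1, Response
0 = non-accepting / 1 = accepting, and random intercepts for dyad and
participant nested in dyad. Estimation is REML (statsmodels MixedLM).
Degrees of freedom are Satterthwaite: for coefficient `i`,
`df = 2 v² / (g' A g)` where `v = [(X'V⁻¹X)⁻¹]_ii`, `g = ∂v/∂θ` over the
variance components θ, and `A` is the inverse observed information of
the REML log-likelihood; both derivatives are central finite differences
on the variance-component scale. Variance components estimated at the
boundary are flagged singular, held fixed in the differentiation, and —
if the approximation still degenerates — the residual df `n − p` is used
and noted in the result. Explained variance follows Nakagawa:
`R²_marginal = var(Xβ)/(var(Xβ) + σ²_dyad + σ²_participant + σ²_resid)`
and `R²_conditional` adds the random-intercept variances to the
numerator. A constant response returns the constant as intercept with a
zero-residual-variance flag instead of attempting a fit.

Cohen's kappa is computed from the full confusion matrix with observed
and expected agreement reported; when both raters use one identical
category throughout (expected agreement 1), kappa is defined as 1.

## Synthetic dyads

The generator emulates exactly the structure the analysis assumes:

- **Events.** `events_per_dyad` proposals per task, ends spaced ≥ 10 s
  (so windows never overlap), durations uniform 1.5–4 s, proposer
  alternating between members, responses accepting with probability 0.44
  by default (rejecting 0 by default, configurable).
- **Impulses.** Per participant, an inhomogeneous Poisson process:
  `baseline_rate` (default 2.76 SCR/min) outside windows and a
  condition rate inside each window, keyed by (role, diagnosis,
  response) with fallback to (role, diagnosis) — defaults are the four
  observed group means 4.60/5.99 (proposers) and 2.91/3.91 (recipients).
  A fraction ρ (`shared_fraction`, default 0.15) of the lower of the two
  members' rates is drawn from a dyad-common stream and copied to both,
  which is what creates synchrony; shared impulses reuse a common
  amplitude draw.
- **Trace.** Amplitudes are lognormal with median 0.3 μS and
  σ_log = 0.25 — deliberately far above the 0.05 μS detection cut-off so
  that recovery experiments exercise the pipeline, not the
  signal-to-noise ratio — convolved with the unit-peak Bateman kernel and
  added to a 2 μS tonic level, a Gaussian-random-walk drift
  (0.01 μS·s^−1/2) and white noise (0.005 μS).
- **Determinism.** Each dyad derives its RNG from (seed, dyad index), so
  studies are reproducible per dyad and byte-identical on disk across
  runs. All ground truth (impulse times, shared stream, amplitudes,
  per-window generating rates) is retained.

What the generator does **not** emulate: motion artifacts,
device-specific filtering, non-stationary baselines beyond slow drift,
SCR shape variability across responses or participants, refractoriness
(impulses can fall arbitrarily close), or any coupling between the
conversation audio and physiology. Passing recovery tests therefore
demonstrate correctness of the computational pipeline under the model's
own assumptions, not robustness to the artifacts of real recordings.

## Recovery experiments and problem sizes

The calibrated-recovery experiments set the generator's window rates to
the reported group means and require the full pipeline to return them.
Choices there: every dyad is mixed (one diagnosed member) with
alternating proposers, so one study populates all four role × diagnosis
cells evenly; the accepting-cell experiment sets `p_accepting = 1`; the
overall-rate experiment uses 30 dyads with 10-minute tasks and no window
boost; the proposal-rate experiment gives both members the
proposal-sequence rate (4.03 SCR/min) against the 2.76 baseline. Sizes
(thousands of windows per cell in the acceptance script, somewhat fewer
in the test suite) are chosen so Monte-Carlo error per cell is ~3–5%,
comfortably inside the 10% recovery criterion; the residual systematic
deficit (~1–2%, from sub-resolution impulse pairs and window-edge
leakage) is measured by the efficiency analysis in the test suite's
diagnostics and stays well below that margin.

## Known limitations

- The Satterthwaite finite-difference machinery assumes the REML
  optimum is interior; heavily singular fits fall back to residual df.
- The driver calibration is exact for isolated SCRs; for overlapping
  SCRs the per-lobe amplitude reading is approximate (counts, the only
  quantity used downstream, are unaffected as long as lobes separate).
- Praat TextGrid support covers the long text format with a single
  interval tier named `proposals` and `proposer;response` labels; short
  format and multi-tier grids are out of scope.
- Non-uniformly sampled traces are rejected, not resampled; annotation
  and physiology clocks are assumed already aligned.
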
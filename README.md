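# dyadeda

Event-related skin-conductance (electrodermal activity, EDA) analysis for
dyadic joint decision-making conversations.

When two people negotiate a series of small decisions, each proposal and
its response is a charged interactional moment. This package quantifies
that moment physiologically: it takes both participants' raw skin
conductance (μS, sampled at 128 Hz), isolates the phasic sympathetic
responses (SCRs), and asks how SCR rates and dyadic physiological
synchrony depend on the conversational context — proposal windows vs the
rest of the task, proposer vs recipient role, depression diagnosis, and
whether the proposal was accepted.

It is written for psychophysiology researchers who have per-participant
conductance traces plus Praat TextGrid (or CSV) annotations of proposal
sequences, and for anyone who wants a fully synthetic, ground-truth-known
test bed for event-related EDA pipelines.

## The analysis

1. **Phasic driver extraction.** The conductance trace is modelled as a
   slow tonic level plus `driver * h`, where `h` is the Bateman SCR
   impulse response `h(t) ∝ exp(−t/τ_d) − exp(−t/τ_r)` (defaults
   τ_r = 0.75 s, τ_d = 2.0 s). After running-minimum detrending, the
   non-negative driver is recovered by Richardson–Lucy deconvolution
   (Biggs–Andrews accelerated, 100 iterations by default), which
   separates SCRs that overlap into a single visible hump. The driver is
   calibrated so an isolated SCR of amplitude *a* μS appears as a driver
   lobe of peak ≈ *a*, and z-normalized over the recording.
2. **SCR detection.** Local maxima of the driver with topographic
   prominence ≥ 0.05 μS and height ≥ 1 SD above the recording mean.
3. **Event-locked rates.** Each proposal contributes a half-open window
   `[t_end − 1 s, t_end + 4 s)`; the SCR rate in a window is
   `60 · count / duration` (SCR/min), one observation per participant per
   proposal. Outright rejections are excluded.
4. **Synchrony.** Pearson correlation of the two dyad members' drivers
   over proposal vs non-proposal time, aggregated across dyads on the
   Fisher z = atanh(r) scale and contrasted with a dependent t-test
   (Cohen's d = mean(diff)/SD(diff)).
5. **Mixed models.** Gaussian linear mixed models on the per-event rates:
   `rate ~ Role * Diagnosis` and, on proposer rows,
   `rate ~ Response * Diagnosis`, each with random intercepts for dyad and
   participant nested in dyad; REML estimation, Satterthwaite degrees of
   freedom, Nakagawa marginal/conditional R².
6. **Synthetic dyads.** An inhomogeneous-Poisson SCR generator with
   condition-dependent rates inside proposal windows, a dyad-shared
   impulse stream controlling synchrony, lognormal SCR amplitudes, tonic
   drift and measurement noise — with full ground truth retained for
   recovery testing.

## Worked example

```bash
dyadeda simulate --out study --n-dyads 2 --events-per-dyad 8 \
    --task-duration 220 --seed 123
dyadeda run --input study --out report
```

prints (abridged):

```json
{
  "n_dyads": 2,
  "n_participants": 4,
  "n_rate_records": 32,
  "mean_window_rate": 6.0,
  "overall_rate_mean_of_dyad_means": 3.12,
  "synchrony": {
    "mean_r_proposal": 0.158,
    "mean_r_nonproposal": 0.082,
    "n_dyads": 2
  }
}
```

Read: across the 16 simulated proposals (32 participant × event
observations) the mean SCR rate inside proposal windows is 6.0 per
minute versus 3.1 over the whole task (a tiny study — two dyads' worth
of windows is a noisy estimate of the generating cell means), and the
dyad members' driver signals correlate more strongly during proposal
windows (r ≈ 0.16) than elsewhere (r ≈ 0.08) — the generator plants
exactly this structure (elevated window rates per role/diagnosis, a
shared impulse stream), and the pipeline recovers it from the raw
traces. `report/` holds the per-participant
drivers, the peak table, the segmentation, the rate table, per-dyad
synchrony and a JSON stats report with both mixed-model coefficient
tables.

The same stages are available as `dyadeda deconvolve / detect / rates /
synchrony / stats` on individual files, and from Python via
`dyadeda.analyze_study(...)`.

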
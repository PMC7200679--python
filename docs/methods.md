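# Methods

This note documents the models, conventions and numerical choices behind
`dyadsync`, and what the simulator does and does not emulate.

## Study design assumed by the pipeline

Each couple (mother, father) is recorded twice — once listening to the
stimuli together (TOG), once separately (SEP) — with a 20-channel
prefrontal montage (8 sources, 7 detectors; regions SFG/MFG/IFG/aPFC,
both hemispheres) at 7.81 Hz with 760/850 nm illumination. A session
presents 6 auditory stimuli (adult laughter, infant laughter, low- and
high-pitched infant cry, adult cry, static) in randomised order, 3 trials
each, 15 s per presentation with a 10 s inter-stimulus interval: 18
events, 440 s. The high-pitched cry is the low-pitched cry shifted up by
200 Hz (354.3 → 554.3 Hz).

## Preprocessing

Order is fixed: channel rejection → spike replacement → discontinuity
correction → band-pass → Beer–Lambert conversion. Every step preserves
series length and introduces no non-finite values on finite input; a
rejected channel stays present as all-NaN so per-channel N can differ
downstream.

- **Channel rejection.** A channel is excluded when its amplifier gain
  exceeds 8 or the coefficient of variation of its raw intensity exceeds
  7.5% (strict inequalities; boundary values survive). CV is
  100·SD/mean computed on raw intensity with the population SD; a
  non-positive mean makes CV undefined and the channel is rejected with
  the reason recorded.
- **Spike replacement.** Spikes are short excursions entered and left by
  opposite-signed first differences exceeding k·(1.4826·MAD) of the
  differenced series (k = 5, configurable; excursion width ≤ 3 samples).
  Flagged runs are linearly interpolated between the nearest clean
  neighbours, so a one-sample spike becomes the mean of its neighbours.
  If more than 20% of samples are touched the channel is flagged.
- **Discontinuities.** A first difference exceeding k = 8 MAD-scaled SDs
  with *no* opposite return jump within the spike-width budget is a
  persistent level shift; the jump (relative to the median
  sample-to-sample difference) is subtracted from all later samples.
- **Band-pass.** 3rd-order Butterworth, 0.01–0.2 Hz, applied
  forward-backward (zero phase; the effective magnitude response is the
  square of the single-pass response). Series shorter than three filter
  lengths are refused with a minimum-duration message.
- **Modified Beer–Lambert law.** Optical density OD(t) = −ln(I/mean I)
  per channel and wavelength; concentrations solve the per-sample 2×2
  system ΔOD_λ = (ε_HbO,λ ΔHbO + ε_HbR,λ ΔHbR)·d·DPF. Defaults: DPF 6.0,
  source–detector distance 3.0 cm, extinction coefficients (cm⁻¹ mM⁻¹)
  from a standard compiled table shipped with the package (760 nm:
  0.586/1.5485; 850 nm: 1.058/0.6913 for HbO/HbR). All constants are
  configurable. Band-pass is applied to OD before conversion; the system
  is linear, so the order is immaterial.

## The synchrony index (MCC2)

Epochs are the floor(15 s × fs) = 117 samples from each event onset,
demeaned. For an epoch pair, the Pearson correlation is computed at every
integer-sample lag in [−2, +2] s — lags −15..+15 at 7.81 Hz. The stated
0.125 s lag step of the original metric is not commensurate with the
7.81 Hz sample period (≈ 0.128 s); the integer-sample grid is the nearest
realizable one and avoids resampling artifacts. At each lag the
*overlapping* segments are demeaned and normalised (so each lag is a
proper correlation), and the **signed** maximum is taken — consistent
with the small positive channel means this index produces; ties take the
most negative lag. Per-trial values are averaged over the valid trials
(up to 3); a channel contributes only when both partners' channels
survived QC.

Positive best-lag means the second (father) signal trails the first.
A constant epoch has no defined correlation: the value is missing, with
the reason logged.

**Control dyads.** For each (stimulus, channel, condition) an independent
random derangement re-pairs mothers with non-spouse fathers (rejection
sampling of permutations, uniform over derangements). Control pairs hear
the same stimuli, so they share stimulus-locked structure; what they lack
is couple-specific coupling. The number of control replicates per cell is
configurable (default 1).

## Statistics

- **Condition contrast.** Per channel, two-sided Mann–Whitney of SEP vs
  TOG MCC2, one value per (dyad, stimulus) pooled over stimuli.
  Mann–Whitney p-values use exact enumeration when both n ≤ 8 without
  ties, else the tie-corrected normal approximation. FDR:
  Benjamini–Hochberg step-up over the m = 20 channel family. The BH
  implementation accepts m larger than the number of supplied p-values
  (ranks of the supplied values with divisor m — valid when they are the
  smallest of the family).
- **Effect size.** Pooled-SD Cohen's d, (TOG − SEP), (n−1)-weighted —
  the convention that reproduces published one-decimal values from
  printed summary statistics.
- **Stimulus follow-up.** Within each significant channel, one-sided
  (TOG > SEP) Mann–Whitney per stimulus, BH over m = 6.
- **Covariates.** Parent-ratio option a:b (a + b = 5) coded as
  a/5 ∈ {0, 0.2, …, 1}, averaged across partners. Parity contrast by
  two-sided Mann–Whitney; Spearman correlations of MCC2 with the average
  ratio score, mother/father age and mean parental age — each pooled over
  all channels (unadjusted) and per significant channel with BH over the
  significant-channel family. Covariate analyses run on TOG-condition
  rows, where the co-presence effect lives; all analyses repeat on
  control pairings as negative controls. The pooled analysis pools rows
  across channels (not per-channel coefficients).
- **Power.** Two-sided two-sample power via the noncentral-t
  distribution, df = 2n−2, noncentrality d·√(n/2); at α = 0.0025 and
  n = 130 per group this gives 0.995 for d = 0.7 and 0.834 for d = 0.5.
  The lower tail uses the sign-flip symmetry of the noncentral t because
  direct CDF evaluation at −t with large noncentrality is numerically
  unstable. A Monte-Carlo route (repeated unit-SD normal studies, t
  test) is provided for cross-validation; a Mann–Whitney Monte-Carlo
  power can be obtained by passing the rank test in user code.

The original report labels the channel-wise comparison "ANOVA" in its
results narrative while specifying Mann–Whitney in its analysis plan; the
Mann–Whitney specification is implemented.

## The simulator

Per channel, a subject's oxy-Hb series is

```
x(t) = r(t) + σ_L · [κ·Z(t) + √(1−κ²)·X(t)] + noise(t)
```

- `r` — deterministic event-locked response: the stimulus boxcar train
  convolved with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
  ratio 1/6), area-normalised so a sustained stimulus plateaus at its
  configured amplitude (default 1 μM for every stimulus). `r` is common
  to all subjects: unpaired strangers hearing the same sounds are
  correlated too, as in real stimulus-locked designs.
- `Z` — the *shared* latent: a zero-mean, unit-variance stimulus-locked
  process (HRF-convolved event train with standard-normal per-event
  gains, blended half-and-half with a smooth 0.15 Hz-low-passed
  background). `X` is an independent draw of the same process per
  partner. The κ/√(1−κ²) mixing keeps marginal variance constant across
  κ, so the partners' epoch correlation (beyond the `r` floor) scales as
  κ². σ_L defaults to 0.8 μM.
- The father's stimulus-locked part (r + latents) can be delayed by a
  configurable inter-partner lag within ±2 s.
- Noise: Mayer waves (0.2 μM, 0.1 Hz), respiration (0.1 μM, 0.3 Hz),
  cardiac (0.1 μM at 1.2 Hz — representable below the 3.9 Hz Nyquist),
  white noise (0.2 μM), linear drift (±0.3 μM over the session), all
  per-subject with random phases.
- Deoxy-Hb is −oxy/3 plus small independent noise — enough to feed the
  two-chromophore conversion; all synchrony analysis uses oxy-Hb.
- Raw-intensity output forward-projects (oxy, deoxy) through the
  Beer–Lambert model to 760/850 nm OD and exponentiates around a unit
  baseline, with configurable OD-scale measurement noise (default 0.01,
  CV ≈ 1%; "high-CV" bad channels use 0.12, CV ≈ 12%). "High-gain" bad
  channels get gains in 8.5–12.
- Spikes are Poisson-placed 1–3-sample excursions of configurable
  amplitude in robust-SD units, with ground-truth positions returned.

Default condition couplings are κ_TOG = 0.6, κ_SEP = 0.1. No published
anchor links κ to observed MCC2 means, so these are calibration choices:
they produce a clearly detectable but not saturated contrast at realistic
sample sizes. Simulated MCC2 levels are higher than the small means
reported from real recordings (the simulator's stimulus-locked share is
larger); recovery tests therefore validate *operating characteristics*
(detection, type-I control, monotonicity in κ), not absolute index
levels.

**What the simulator does not emulate:** optode–scalp physics, motion
beyond spikes and steps, systemic confounds shared across partners
(which in real data can inflate synchrony and motivate the control
pairing), non-stationary coupling, and the acoustic stimuli themselves.
Passing recovery tests shows the pipeline detects coupling of the assumed
form at the assumed SNR; it does not certify sensitivity on real
recordings.

## Problem sizes used by the test suite

Parameter-recovery checks run 20 seeds × 24 dyads × 2 conditions per
regime (effect and null), with one control replicate per cell, and a
κ-monotonicity sweep over κ ∈ {0, 0.3, 0.6, 0.9} with 20 dyads each;
these sizes give stable Monte-Carlo rates (binomial SE ≈ 0.05 at 20
seeds) at desk-scale runtime. Recovery runs generate oxy-Hb directly;
the raw-intensity → preprocessing → synchrony chain is exercised
separately end-to-end.

## Known limitations

- The lag grid is sample-quantised; reported best-lags are multiples of
  1/fs ≈ 0.128 s, and a true lag between grid points biases MCC2 down
  very slightly.
- BH with partially supplied p-values assumes the supplied values are
  the smallest of their family.
- The spike and step detectors are MAD-threshold heuristics; pathological
  series (e.g. > 50% artifact) degrade both detection and the robust
  scale estimate.
- Whether the original analysis computed CV on raw intensity or optical
  density, demeaned epochs before correlation, or took a signed or
  absolute lag-maximum is not specified in the source material; raw
  intensity, per-overlap demeaning, and the signed maximum are adopted
  and documented above.
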
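# Methods

## Signal model and preprocessing

Recordings are treated as referential-montage multichannel signals
(samples × channels) at a nominal 2000 Hz. The conditioning chain is:

1. **High-pass 0.5 Hz** — 4th-order Butterworth, applied forward–backward
   (`sosfiltfilt`) so the filter is zero-phase; phase distortion would
   bias every directed metric downstream. Reflect-padding is extended to
   3/cutoff seconds because the 0.5 Hz filter's impulse response spans
   seconds and default padding leaves visible edge transients.
2. **Decimation to 250 Hz** — zero-phase 8th-order Butterworth low-pass
   at 0.8 × the new Nyquist (100 Hz), then every 8th sample. The original
   rate must be an integer multiple of the target; anything else is an
   error, not a resample.
3. **10 s epochs** — contiguous, non-overlapping, trailing remainder
   dropped; epoch intervals are half-open `[start, start + 10)`.
4. **Epoch selection** — the visual rejection of artefact-laden blocks is
   not reproducible, so a quantitative surrogate is used: an epoch is
   rejected when any channel's peak amplitude exceeds a robust z of 6
   (median/MAD across epochs) or any channel variance falls below 1e-12.
   Both thresholds are configurable; the selection is logged.
5. **SOZ exclusion** (optional) — channels flagged as seizure onset zone
   are dropped from data, labels and region map; a region emptied by the
   exclusion is dropped from pair statistics with a warning.
6. **Split half** — epochs split into early/late halves in temporal
   order; an odd count gives the extra epoch to the early half
   (deterministic).

## MVAR estimation

One MVAR model is fitted per 10 s epoch by ordinary least squares on the
stacked one-step regression: each epoch is mean-removed per channel,
contributes only rows whose lags lie inside the epoch, and `C_n` is the
pooled residual covariance (ML normalisation, divide by row count). The
normal equations are solved by Cholesky factorisation; a relative pivot
below 1e-7 is treated as rank deficiency. A fitted model whose companion
spectral radius reaches 1 is flagged unstable with a warning.

**Order selection** uses Schwarz's Bayesian Criterion,

    SBC(p) = ln det C_n(p) + (ln N / N) · p · n²,

minimised over an inclusive range (default 8–40), ties toward the
smaller order. All candidate orders are scored on the same regression
rows — those available at the maximum order — so likelihoods are
comparable and the Gram matrix is assembled once; N is that common row
count. The absolute SBC level depends on this convention but the argmin
does not, which the order-12 recovery test verifies. The pipeline's
fixed default order of 12 sits in the middle of the 8–40 selection band
(typical selected orders for such data cluster near 15).

**Spectral evaluation** computes, on an integer 1–40 Hz grid with
ω = 2πf/fs: `Abar(ω) = I − Σ A(k) e^{−jkω}`, the transfer matrix `H` by
per-frequency linear solve (no explicit inverse; a smallest singular
value below 1e-12 raises an error naming the frequency), and
`S = H C_n H*`.

## Directed metrics and conventions

All metric cubes are oriented `values[source, target, frequency]`; the
diagonal is computed but excluded from statistics.

* **Granger causality** — pairwise Geweke measure evaluated from the
  full multivariate model:
  `f_{s→t}(ω) = ln[S_tt / (S_tt − (C_ss − C_ts²/C_tt)|H_ts|²)]`.
  The instantaneous-correlation-removing transformation of `H` leaves
  the (t, s) element unchanged, so `H_ts` enters directly;
  `C_ss − C_ts²/C_tt` is the source innovation variance conditional on
  the target's. Negative round-off is clipped at zero, and the
  denominator is floored at `1e-12 · S_tt` against round-off. This is a
  *pairwise-from-full-model* estimator, not a conditional (partial) GC:
  whether the original analysis conditioned on the remaining channels is
  not determinable, and the pairwise form matches the common parametric
  toolbox lineage. Cascaded influence therefore appears in GC, as it
  does in DTF.
* **DTF** — reported squared (the normalisation that is bounded):
  `DTF²_{j→i} = |H_ij|²/Σ_m|H_im|²`; for each target row the sources sum
  to 1.
* **PDC** — reported as magnitude with *source = column j* of `Abar`
  (the outflow normalisation: `Σ_i |PDC_ij|² = 1`). The alternative
  index reading (source = row) is rejected because the outflows of the
  source channel must be what normalises the measure.
* **Band aggregation** — arithmetic mean over the integer frequencies
  inside each inclusive band (delta 1–4, theta 5–8, alpha 9–12, beta
  13–24, low gamma 25–40 Hz). Per-epoch metric cubes are averaged
  element-wise across epochs before band aggregation (the two commute).

## CCEP / SPES quantification

Trials are cut −1 s to +2 s around each pulse; events too close to the
recording edge are dropped with a warning. The stimulated contact pair
and its immediate neighbours (same electrode, contact number ±1) are
excluded from the response channels — they carry the saturated
stimulation artefact. Baseline correction subtracts each trial's mean
over −1.0 … −0.01 s; trials are then averaged, and the **baseline SD of
the averaged waveform** is the noise floor for scoring. (Whether the
single-trial or averaged-waveform SD is the right denominator is an open
convention; the averaged-waveform SD is used because the N1 is measured
on the averaged waveform.) The N1 score is

    z = max |averaged amplitude| over [0.010, 0.110) s ÷ baseline SD,

with the latency at the argmax. The absolute value is deliberate: N1
polarity varies under a referential montage. The first 10 ms are
excluded, so the stimulation artefact cannot influence z (verified
exactly in tests). z is invariant under channel-wise rescaling. Note a
small upward bias inherent to a max statistic: the maximum over ~200
samples of signal-plus-noise exceeds the true peak by a fraction of the
noise SD, so a deflection of 10 × the noise floor scores z ≈ 10.5–11 on
average.

## Directionality statistics

Contact-level values are pooled per unordered region pair: the forward
list holds `M[s, t]` for every (source-region contact, target-region
contact) pair, the reverse list the mirrored elements; within-region
elements and the diagonal never enter. Each pair/band gets a one-way
two-level ANOVA (forward vs reverse; F with df (1, n_f + n_r − 2), equal
to the squared pooled t), Bonferroni-corrected over the pair × band
family (configurable; the family size used is recorded in the output),
with stars at 0.05/0.01/0.001 on the corrected p. The element-wise
asymmetries `M[i, j] − M[j, i]` are additionally tested with a two-sided
one-sample t against zero.

**Cohort design.** Contact-pair values measured from one fitted model
are strongly correlated — they share the model's estimation noise and
its region-level small-sample bias (the GC noise floor for s→t scales
with the source's conditional innovation variance over the target's band
power, so heterogeneous spectra give *systematically* asymmetric floors
within a single recording). Treating them as independent observations
overstates the degrees of freedom and produces spurious "significant"
asymmetries for uncoupled pairs. The cohort driver therefore simulates
several independent patients (each its own network draw and recording),
averages the contact-pair values within patient to one observation per
direction, and pools those across patients — the regional pair acting as
a between-subject factor over the cohort. Under this design the null is
calibrated (independent patients) and seeded edges remain highly
significant. Single-recording contact-pair tables are still produced by
`directionality_analysis` as the within-patient view.

The SOZ contrast re-runs an identical configuration with flagged
channels excluded and tabulates, per pair and band, the favored
direction, significance, direction flips (only between two significant
calls) and significance changes; pairs dropped by the exclusion are
marked.

## Synthetic study conditions

The generator is the package's definition of "data like the study's":

* **Network** — four regions × two contacts; directed edges AMG→HPC,
  TP→HPC, TP→PHP (the dominant directions of the mesiotemporal circuit);
  the other three pairs carry no direct coupling and are the null pairs.
* **Per-contact dynamics** — damped AR(2) oscillator; pole frequency
  drawn per region from 4–30 Hz and jittered ±2 Hz per contact; pole
  radius `exp(−1/(fs·τ))` with damping time τ = 50 ms, jittered ±30 %
  per contact; innovation SD jittered ±20 % per contact. This
  heterogeneity emulates the contact-to-contact variability of real
  depth electrodes; without it same-region contacts are statistically
  identical and any contact-level group statistic is degenerate.
  Contacts within a region are mutually coupled at 0.1 (lag 1).
* **Edges** — coefficient 0.005 placed source-contact → target-contact
  at lag 16 samples (8 ms at 2000 Hz), scaled ±30 % per contact pair.
  At this strength the afferent drive contributes roughly 40 % of a
  target contact's variance — a strong but not dominating connection.
* **Stability** — if the assembled coefficients are unstable, all A(k)
  are scaled by 0.95 repeatedly (≤ 50 times; zero blocks are preserved);
  failure raises. Simulation discards a burn-in of 10·p·n samples.
* **SPES sessions** — 40 pulses, 4 s interval ± 10 % uniform jitter,
  saturating artefact in the first 10 ms on all channels, Gaussian N1
  bump (width 2.5 ms — a sharp early component, which keeps the latency
  estimate within the ±2 ms tolerance at 10× amplitude) at 25 ms on
  mapped channels, white noise elsewhere.

What the generator does **not** emulate: 1/f-shaped broadband spectra,
epileptiform transients, volume conduction and shared-reference
artefacts, nonstationarity across the 10 min interval, and realistic
N1 waveshape (biphasic morphology, distance-dependent latency). Passing
tests therefore demonstrate correctness of the estimators and the
statistical machinery under the declared model class, not robustness to
those real-data complications.

## Problem sizes used by the test suite

Chosen as the package's validation scale: direction recovery runs 12
cohort studies of 8 patients × 600 s each; null calibration runs 60
no-edge cohorts of 4 patients × 120 s plus a 1000-replicate t-test
calibration; order selection uses 20 seeds at 150k pooled samples;
spectral accuracy is checked against Welch periodograms of 2·10⁶-sample
simulations, band-averaged, within 5 %.

## Known limitations

* The pairwise GC shares cascade sensitivity with DTF; a conditional
  (partial) Granger variant is not implemented.
* Decimation before fitting slightly distorts short-lag causal
  structure; edges are declared at lags that survive the 8× decimation
  (≥ 2 samples at 250 Hz).
* The ANOVA observation unit within one recording ignores the
  correlation between contact pairs; use the cohort driver for
  calibrated inference (see above).
* The EDF writer targets round-tripping of simulated data (16-bit, 1 s
  records, integer sampling rates); it is not a general-purpose EDF+
  implementation.
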
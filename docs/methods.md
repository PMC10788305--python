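# Methods

`psgkit` implements a complete pediatric sleep-EEG analysis chain — from
multichannel PSG signals and a 30-s hypnogram to macro-architecture
metrics, stage-wise band power, spindle and slow-oscillation (SO) events,
permutation-calibrated SO–spindle coupling, and a sleep-based brain-age
model — together with a ground-truthed synthetic-PSG generator that makes
every stage testable without access-controlled clinical data. This note
records the models, the parameters that matter, and the choices made where
the field has no single convention.

## Preprocessing

Signals are re-referenced to the contralateral mastoid (F3/C3/O1 − M2,
F4/C4/O2 − M1), down-sampled to 200 Hz when above it, mains-cleaned by
spectrum interpolation, and band-pass filtered 0.5–35 Hz. All filters are
4th-order Butterworth applied forward–backward (zero phase): event timing
and SO phase — the quantities coupling depends on — survive filtering
unshifted, at the cost of a doubled effective filter order.

Spectrum interpolation replaces the FFT *amplitude* in mains ± 1 Hz (and
the first harmonic) with a log-linear interpolation of the 2-Hz flanking
bands while preserving phase. On a 20 µV injected 60 Hz line this removes
> 99 % of the 59.5–60.5 Hz Welch power without touching the rest of the
spectrum.

Epochs are 30 s on the staging grid (0-based, half-open). Per stage and
channel an epoch is rejected when (a) any |sample| > 200 µV; (b) the signal
is flat (|Δx| < 0.05 µV) or pinned at the epoch extrema for > 10 % of
samples; or (c–e) any Hjorth parameter (activity = variance, mobility,
complexity) is > 3 SD from the stage's all-channel pool, > 4 SD from the
same channel's epochs, or > 4 SD from the pooled distribution. The Hjorth
passes run twice with statistics recomputed on survivors; a channel losing
more than half its epochs in a stage is dropped for that stage. On clean
synthetic records the false-positive rate of the 3/4-SD rules is below 1 %.
Hjorth statistics are stage-specific: stages differ grossly in amplitude
(N3 ≫ N2), and pooling them would turn ordinary N3 epochs into "outliers".

### Polarity

EEG polarity flips occur in practice (inverted montages), and every
SO-dependent quantity inverts with them. The polarity statistic `T_DIFF` is
the standardized per-epoch skewness of the 0.5–4 Hz N2 signal: deep
negative SO half-waves make delta-band epochs negatively skewed, so a
correctly oriented channel has T_DIFF < 0. The decision rule on C3/C4 is
T_DIFF > 1 → flip, T_DIFF < −1 → keep, otherwise the record is marked
polarity-ambiguous and excluded from SO/coupling analyses. The statistic is
deliberately an *effect size* (mean/SD over epochs), not a t-statistic:
fixed ±1 cutoffs then retain the same meaning regardless of record length,
symmetric noise stays inside the ambiguous band essentially always, and
SO-rich sleep sits at −1.3 to −2.1 on synthetic records. T_DIFF is odd
under global negation by construction.

### Record-level exclusions

A record is excluded when TST < 180 min, when any analysed stage retains
fewer than 10 epochs, when polarity is ambiguous, or — in cohort mode,
where cross-record z-scores exist — when residual line noise (SPK: mains
band over 45–55 Hz flank power ratio) exceeds z = 5, or spectral power at
1 Hz (±4 SD) or 25 Hz (+4 SD) is an outlier. Single-record runs skip the
cohort-referenced rules.

## Spectral power

Welch PSD per retained 30-s epoch: 4-s segments (0.25 Hz resolution),
Tukey(0.5) taper, 50 % overlap, one-sided density normalization with taper
power compensated; segment PSDs are averaged within the epoch, then across
epochs. Band powers integrate rectangularly over half-open bands
[lo, hi) — slow 0.5–1, delta 1–4, theta 4–8, alpha 8–12, sigma 12–15, beta
15–30, total 0.5–35 Hz — so a 12 Hz bin belongs to sigma, not alpha.
Relative power divides by the total band; absolute power is natural-log
transformed for analysis, with non-positive values propagating as missing.
The normalization is a testable contract: a unit-variance sinusoid
integrates to 1 µV² to within taper leakage (< 5 %), and band power scales
exactly with the square of signal gain.

## Spindle detection

Slow (11 Hz) and fast (15 Hz) spindles are detected separately from the
smoothed (0.1-s moving average) magnitude of a 7-cycle complex Morlet
transform of the concatenated retained N2 samples, per channel. The
wavelet's Gaussian passband (σ_f ≈ 1.6–2.1 Hz) *is* the "≈ ±2 Hz" class
band; no additional filter is applied. Thresholds are relative to the mean
envelope over all retained N2 samples: an event must exceed 2× the mean for
≥ 0.5 s and contain a core above 4.5× the mean for ≥ 0.3 s (containment
required); intervals > 3 s are rejected; intervals separated by < 0.5 s are
merged unless the merge would exceed 3 s. Relative thresholds make
detection exactly invariant to channel gain.

Candidates pass a band-ratio quality check: variance ratios (event window /
whole retained stage) are computed in delta, theta, beta and the class band
(fc ± 2 Hz); an event is discarded when any non-spindle ratio strictly
exceeds the spindle-band ratio. This removes broadband artifacts that
cross the envelope threshold without being sigma-specific.

Morphology per retained event: amplitude = envelope maximum (µV), duration
= detected-interval length, density = events per retained N2 minute.

### Frequency and chirp

Chirp — the intra-spindle frequency change, last-half minus first-half
frequency, negative for the characteristic deceleration — is estimated by
quadratic phase modelling: an envelope²-weighted quadratic is fit to the
unwrapped Hilbert phase (fc ± 4 Hz band) over the detected interval, whose
curvature gives the linear chirp rate in Hz/s; the observed frequency is
the fitted phase slope at the interval midpoint. Because the dual-threshold
interval covers only the event core (~⅔ of a Hann-windowed event) while
the chirp rate of a linear ramp is window-invariant, the rate is scaled by
half the *trough-to-trough envelope support* (the envelope minima flanking
the detection, capped at ±0.5 s), which tracks the full event extent. Two
simpler estimators were rejected on synthetic ground truth: differencing
per-half aggregates of the per-sample instantaneous frequency is shrunk
both by interval truncation and by noise pulling the phase derivative
toward the band centre (recovering −0.09 to −0.38 for a −1.0 Hz ramp), and
envelope-weighted per-half means place each half's effective time point
too close to the event centre. The phase-fit estimator recovers
−0.45 to −0.48 for a −1.0 Hz implanted ramp and is within ±0.05 Hz of zero
for constant-frequency implants.

## SO detection

Zero crossings of the 0.5–4 Hz zero-phase-filtered signal define candidate
events anchored at a positive-to-negative crossing: negative half-wave
0.3–1.5 s, following positive half-wave ≤ 1 s. Amplitude criteria come in
two modes. Relative (default): negative-peak magnitude and peak-to-peak
amplitude must each exceed 2× their per-channel means over all
temporal-criteria-passing candidates (two-pass detection — the thresholds
are computable before selection; means for the two quantities are computed
separately). Absolute: negative peak < −40 µV and p2p > 75 µV, strict
comparisons. Density, mean negative peak, p2p, duration (full event span)
and the negative-to-positive peak slope are reported per channel.

The two modes genuinely disagree on age trends when SO amplitude declines
with age — shrinking signals drop below a fixed cut but also lower the
relative threshold — and the package reproduces this reversal on synthetic
cohorts (relative-mode density slope positive, absolute-mode negative, in
10/10 seeded cohorts).

## SO–spindle coupling

Phase convention (stated because every angle in the output depends on it):
0° = SO positive peak, 180° = negative peak, increasing with time; this is
the raw Hilbert argument of the 0.5–4 Hz signal. Three metrics per channel
and spindle class: gross overlap (share of spindle peaks inside a detected
SO's [down-crossing, end-crossing)), the circular-mean SO phase at
overlapping spindle peaks, and ITPC (mean resultant length of the unit
phasors). Overlap is anchored at the spindle *peak* for consistency with
phase-at-peak.

z-scores come from two permutation nulls that preserve the stated
constraints: the overlap null circularly shifts the entire spindle-peak
series by a uniform offset (preserving counts and inter-event structure);
the ITPC null reassigns each overlapping spindle a uniform time inside a
randomly chosen SO interval (preserving counts *and* gross overlap).
z = (observed − null mean)/null SD; permutation seeds are independent of
detection seeds. Calibration on uncoupled synthetic data: mean z within
±0.1 and |z| > 1.96 rates of 2–8 % across 300 runs at 2,000 permutations;
power for a κ = 5 von Mises preference with ≥ 50 overlapping spindles is
≈ 100 %, and a κ = 20 preference is recovered within 10°.

## Macro-architecture

Sleep onset is the first scored sleep epoch; TST counts all sleep epochs;
SME = TST over the onset-to-last-sleep span; WASO is wake inside that
span; SFI counts transitions from established sleep (N2/N3/R) to W or N1
per hour of TST; the NREM↔R transition index counts boundaries between
maximal NREM and R segments, wake-transparent. REM latency is measured
from sleep onset. NREM cycles follow adapted Feinberg–Floyd rules: a cycle
is an NREM period ≥ 15 min followed by an R period ≥ 5 min (the first R
period exempt from its minimum); a terminal NREM period ≥ 15 min without R
counts as a final cycle; interposed NREM < 15 min does not start a new
cycle. These are declared conventions (the field has several); all
thresholds are arguments of `CycleRules`.

## Brain age

The statistical layer works on a subject × feature table. Per-feature age
associations are OLS fits of feature ~ age + sex + race (one-hot, reference
levels F/white), with unadjusted Pearson r, a quadratic comparison (adding
age²; ΔAIC/ΔBIC negative when the quadratic wins), 3-SD outlier masking in
two recomputed rounds, and Benjamini–Hochberg q-values per tested family
(q clipped to ≥ p).

The age-prediction model is deliberately the simplest thing that works:
greedy correlation pruning (|r| > 0.9 against already-retained features, in
fixed catalogue order, on the training sample only), z-scoring by training
mean/SD (frozen into the model), mean-imputation of missing values in
z-space, and OLS of age on z-features + covariates. 10-fold CV reports
per-fold R² and MAE; held-out and transfer predictions reuse the frozen
z-parameters. The brain-age gap is predicted minus chronological age
(ME = mean gap, MAE = mean |gap|). Group analyses refit the whole pipeline
on each of `n_rounds` random 70/30 resplits of the non-clinical pool, with
fixed clinical groups scored each round and two-sample Welch t-tests
against the held-out pool; the *median* p over rounds is reported — a
convention that is anticonservative relative to a single pre-registered
split, and documented as such.

One property of this estimator worth knowing when reading gap values: OLS
age prediction is shrunk toward the training mean by the ratio
σ²_age/(σ²_age + σ²_residual), so a group constructed with a −2.0-yr
developmental offset registers a mean gap of ≈ −1.85 yr on the synthetic
cohorts below (age SD 4.3 yr, residual 1 yr). The package reports the raw
gap without shrinkage correction, as the estimator defines it.

The age-bin similarity profile z-scores all features by the comparison
sample, then reports the mean over features of |bin mean − group mean| per
age bin (2-yr bins centred 3–13, 4-yr bins centred 16–80, bins with < 10
subjects omitted); a developmentally delayed group minimizes this curve at
a bin younger than its chronological mean age.

## Synthetic PSG generator

The generator is first-class, tested code; its defaults are the study
conditions for every acceptance experiment.

* **Hypnogram**: cycles of ascending–descending NREM (N1, N2, N3, N2) plus
  an R period; N3 front-loaded, R growing across the night; brief
  awakenings at `waso_rate`/h. Defaults: 4 cycles × 90 min, 20 % R,
  10 min sleep-onset wake.
* **Background**: Gaussian 1/f^α noise via spectral shaping, flattened
  below 0.5 Hz, per-stage α (N2 1.5, N3 2.0, R/W 1.2 — conventional values,
  not claims) and RMS (N2 20, N3 40, W/R 15–18 µV); posterior 10 Hz alpha
  in wake and diffuse 5 Hz theta in R at a few µV.
* **Spindles**: Hann-windowed sinusoids; `amplitude` is the envelope peak
  (default 30 µV — pediatric spindles are high-amplitude, an order of
  magnitude above the ~2.5 µV sigma-band background RMS); `chirp` is the
  total linear instantaneous-frequency ramp, symmetric about the carrier.
* **SOs**: a negative raised-cosine half-wave (clipped to 0.3–1.5 s)
  followed by a positive one (≤ 1 s); `amplitude` is the negative-peak
  magnitude, `p2p` defaults to 1.6× that.
* **Coupling**: when κ > 0, each spindle peak is placed at a von
  Mises(μ, κ)-drawn SO phase, mapped to time through piecewise-linear
  anchors (90° at the down-crossing through 450° at the end-crossing).
* **Placement** is rejection sampling inside stage segments, same-class
  events kept ≥ 1 s apart (so implants are never merged by the detector's
  500-ms rule); event counts are exactly round(density × stage minutes).
* **Artifacts**: clip, flatline, high-amplitude pulse, 60 Hz line,
  whole-channel polarity flip — applied to logged (channel, epoch) targets
  only.
* **Cohorts**: each subject carries a latent developmental offset
  ~N(0, offset_sd) that moves *all* of their feature curves along the age
  axis, plus independent per-feature noise; named groups evaluate curves at
  age + group offset. The latent offset is the irreducible residual of any
  age predictor built from the features, which makes the expected held-out
  MAE analytic: offset_sd·√(2/π).
* **Randomness** flows from one integer seed through a hierarchical
  `SeedSequence` scheme (record → channel), so identical inputs are
  bit-identical and regeneration is stable.

### What the generator does and does not emulate

It reproduces the statistical structure the pipeline assumes: 1/f
background with stage-dependent depth, discrete oscillatory events with
controlled density/amplitude/duration/frequency/chirp, von-Mises phase
coupling, age trajectories with subject-level developmental noise, and
gross artifacts. It does **not** model K-complexes, arousals, respiratory
or EMG/EOG channels, topographic traveling waves, sigma-peak individual
differences, or infant EEG. Passing tests therefore demonstrate that the
estimators recover what they claim *under the stated generative model* —
correctness of the machinery, not clinical validity on real PSGs.

## Validation problem sizes

The validation battery (`psgkit.validation`, reported by
`scripts/acceptance.py`) uses sizes chosen so Monte-Carlo error is small
against each tolerance while the whole battery runs in a few minutes:
20 × 30-min N2 records over a 0.5–3/min density grid for detector
operating characteristics; 8 × 30-min records (~480 events) for chirp
recovery; 300 one-hour κ = 0 runs at 2,000 permutations for null
calibration; 10 cohorts × 9 subjects × 36 min N2 for the SO threshold-mode
reversal (36 min keeps per-subject Poisson density noise below the age
effect; a real night has ~3 h of N2); 10 replicate cohorts of n = 600 + 50
for brain-age recovery, with 100 resampling rounds for the group test.
The recovered coupling phase pools the per-record circular means before
measuring its distance from the implanted preference. With the 1-yr latent
offset, 40-feature noise averaging and OLS shrinkage, the analytic
expectation for the held-out brain-age MAE is ≈ 0.85 yr
(residual SD ≈ 1.06 × √(2/π)); the measured values sit there.

## Known limitations

* The chirp estimate is mildly conservative (≈ −0.46 recovered for a −0.5
  half-ramp) because in-band noise attenuates the fitted phase curvature.
* Relative SO thresholds depend on the candidate pool and hence on
  background delta content; cross-cohort comparisons should fix the mode
  explicitly (the absolute/relative disagreement is a feature of the
  method, not of this implementation).
* The permutation ITPC null conditions on the detected SO set; with very
  few overlapping spindles (< ~10) the null becomes skewed and z-scores
  should be read cautiously (the package reports n_overlap alongside).
* Median-p reporting over resampling rounds is anticonservative; it is
  provided for comparability, with the per-round distribution available.
* OLS brain-age gaps are shrunk toward the training mean (see above); no
  bias correction is applied.
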
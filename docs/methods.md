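# Methods

`gpalpha` implements an electrophysiological-biomarker analysis for deep
brain stimulation (DBS) in obsessive–compulsive disorder (OCD): it reduces
bipolar local field potential (LFP) snippets recorded from 4-contact VC/VS
leads to alpha-band biomarkers, relates them to symptom severity (Y-BOCS,
0–40) across and within patients, projects them onto individual contacts to
predict the clinically optimal stimulation contact, and maps their spatial
distribution in MNI template space.  Because suitable patient recordings are
not publicly available, a synthetic cohort generator with fully known ground
truth accompanies the pipeline; every stage is validated against planted
truth and independent oracles.

## Signal conditioning

Recordings arrive as ~20 s snippets at 250 Hz, one per bipolar pair (6 pairs
per lead, 2 leads per patient), possibly in packetized form with dropped
packets.  Missing samples are placed on a uniform grid reconstructed from
packet timestamps, linearly interpolated, and flagged in a gap mask; Welch
windows that touch a gap are excluded rather than imputed into the spectrum.
Drifts are removed with a zero-phase (forward–backward) 4th-order Butterworth
high-pass at 1 Hz; zero-phase filtering is used so narrowband alpha phase is
untouched.  An automated quality screen replaces manual artifact review: it
flags recordings with more than 0.5% reconstructed samples, 1-s windows with
zero variance (flatlines), or 1-s RMS values whose robust z-score (median/MAD)
exceeds 8.  Each recording is joined to the nearest-in-time Y-BOCS assessment
of the same patient within ±7 days, preferring same-day visits and breaking
exact ties toward the earlier visit.

## Spectral estimation and parameterization

Power spectral densities use Welch's method with 1-s Hann windows and 50%
overlap; the FFT is zero-padded to twice the window length so 1-s windows
realize 0.5 Hz bins.  Absolute spectra (µV²/Hz) may be converted to relative
spectra (percent of the 3–100 Hz total).  Repeated clean snippets within a
session are PSD-averaged before fitting, giving one fit per pair per session.

The log10 power spectrum is decomposed into an aperiodic background plus
Gaussian peaks:

    log10 P(f) = log10 L(f) + Σ_n a_n exp(−(f − fc_n)² / (2 w_n²))
    L(f) = A (f_k^χ + f_min^χ) / (f_k^χ + f^χ)

with offset `A` (the power at the minimal reliable frequency, f_min = 1 Hz),
knee frequency `f_k`, and exponent `χ`.  This knee-Lorentzian form fits
knee-free spectra by converging to f_k < f_min, so no a-priori knee/no-knee
model choice is needed; a knee is declared present iff the fitted f_k
strictly exceeds f_min.  The fit minimizes squared log10-power error over
1–65 Hz plus a regularization term λ = 100 times the total closed-form mass
of the Gaussians over negative frequencies (a·w·√(2π)·Φ(−fc/w)), which keeps
low-frequency peaks identifiable.  Peaks are seeded iteratively from the
largest flattened-spectrum residual exceeding max(0.1, 2·SD), capped at 8,
then all parameters are refined jointly by bounded least squares.  Bounds:
χ ∈ [−1, 4], f_k ∈ (0.01, 65] Hz, a_n ≥ 0, w_n ∈ [1, 15] Hz (w_n is the
Gaussian SD).  Peaks whose refined amplitude falls below the 0.1 detection
floor are discarded as noise.  The initial aperiodic fit is refit robustly on
the sub-model portion of the spectrum (lowest 2.5% of clipped residuals) so
peaks do not drag the background up.  60 Hz line noise is absorbed as an
ordinary Gaussian peak rather than notch filtered, because notches distort
the spectrum the model must fit.  Goodness of fit (R²) and the per-bin
absolute reconstruction error are computed on log10 power over the fit range.
The periodic spectrum is the per-bin log10 residual above the aperiodic fit.

## Alpha biomarkers

Band power is the trapezoidal integral divided by the band width.  Two alpha
summaries are computed from each spectrum kind (absolute, relative,
periodic): canonical alpha (7–14 Hz) and peak alpha — the mean power within
±2.5 Hz of the individual alpha peak frequency, taken from the
largest-amplitude fitted Gaussian in the band, else the largest interior
local maximum of the periodic spectrum; windows overrunning the grid are
clipped rather than dropped so near-boundary peaks are kept.  Hemisphere
summaries either select the pair with maximal alpha power or average the six
pairs.

## Pseudo-monopolar mapping and contact prediction

Bipolar power cannot be attributed to single contacts, so each contact
receives the maximum of (1) the mean power of the three pairs including it
and (2) the maximum power of pairs spanning it without including it (absent
for the outer contacts 0 and 3).  With several spanning pairs their maximum
is used, consistent with the outer max rule; a mean variant is available.
Estimates are min–max normalized within each lead (a flat lead maps to zeros
with a flag).

Contacts are ranked by power (ties break to the lower index).  Performance
against the clinically selected ("active") contacts is summarized by the
cumulative probability of finding the optimal contact within the top-k ranked
contacts and its AUC, defined as the mean cumulative probability over the
first n−1 tested contacts — the unique simple convention in which blind
sequential testing of a 4-contact lead scores 0.5 and a predictor that always
ranks the optimal contact first scores 1.  Hemispheres with double-monopolar
stimulation count as found at the better of their two active contacts' ranks.
Significance uses per-hemisphere rank-order permutation (10,000 by default);
the active-vs-inactive contrast uses size-matched subsets of all contacts as
the permutation null (the inactive-only subsampling variant is available but
anti-conservative, see Design choices); the rank difference (electrophysiological
rank of the optimal contact minus 1) is reported with a percentile bootstrap
95% CI and a left-sided permutation p.  All permutation p-values use the
+1-corrected estimator (1 + #{null ≥ obs}) / (1 + n_perm).

## Spatial mapping

Right-hemisphere contact coordinates are mirrored onto the left (x → −x);
precomputed nonlinearly flipped coordinates can be supplied instead.  The
spatial peak is the unweighted centroid of contacts in the top 5% of power.
Focality is the power-weighted moment of inertia
I = Σ w_i ‖r_i − r_avg‖² / Σ w_i (mm²), with the radius of gyration √I; the
weights must be mass-like, so periodic power is shifted by its minimum before
weighting.  A left-sided permutation test permutes hemisphere-level mean
weights across hemispheres and shuffles residuals within hemispheres,
preserving lead geometry; reconstructed negative weights are clipped at zero.
Power–distance decay is a Spearman correlation of power against distance to
the spatial peak, reported sign-inverted (decay → positive R) with a
bootstrap CI.  Distances to structure borders use the structure's border
point set (boundary voxel centers of a NIfTI mask through its affine, or a
CSV point cloud).  2D heatmaps project contacts onto a plane, interpolate
linearly on a regular grid (0.5 mm default) and smooth with a Gaussian of
FWHM 0.75 in grid units (a configurable choice; the unit is not standardized),
masking outside the convex hull.

## Cohort statistics

Patients are split at the median S1 Y-BOCS (ties to the more-severe side; an
explicit threshold, e.g. 30, can override).  Frequency-wise group contrasts
and severity correlations use cluster-based permutation correction: per-bin
statistics (Welch t unpaired, paired t within units, Spearman R for
correlations) are thresholded at a per-bin two-sided level (alpha_cluster,
default 0.05 — a free parameter of the method, stated explicitly because the
family-wise level alone does not fix it), contiguous same-sign
supra-threshold bins form clusters scored by their summed statistic, and the
null is the maximum absolute cluster mass over label permutations, sign
flips, or outcome permutations.  Clusters with corrected p below alpha_fw
(default 0.01) are significant.

Longitudinal deltas relative to the first session are Δ
Y-BOCS% = 100·(y_S1 − y_s)/y_S1 (positive = improvement) and Δalpha =
log(alpha_s / alpha_S1) (negative = suppression); because periodic power is a
log residual and can be non-positive, one cohort-wide affine shift to
positivity is applied and reported.  Mixed-effects models regress Y-BOCS on
an alpha metric with stimulation amplitude and days since DBS onset as
covariates and a random intercept per patient, pooled with a
hemisphere×alpha interaction (hemisphere L is the reference) or fitted per
hemisphere.  Alpha is centered; the nuisance covariates are centered and
scaled to unit SD for conditioning (their coefficients are per-SD).  Fitting
is REML via statsmodels; F tests use a Satterthwaite
denominator-degrees-of-freedom approximation computed from the closed-form
random-intercept REML likelihood (numerical gradient of the contrast
variance and Hessian of the likelihood in the two variance components).  The
implementation matches lme4/lmerTest coefficients, SEs and Satterthwaite df
on a reference fit (tested).  Responders are patients with ≥35% Y-BOCS
improvement over the pre-operative baseline.  The best-session contrast
selects per patient the session with maximal baseline-relative reduction
(ties to the earlier session; patients whose best session is S1 are excluded)
and runs the paired cluster test against S1 on patient-level mean periodic
spectra.

## Synthetic cohort generator

The generator emulates the study conditions: 13 patients, bilateral 4-contact
leads (2 mm contact spacing) on jittered trajectories near a planted alpha
hotspot at MNI (−10.12, 4.07, −4) mm mirrored for the right hemisphere, four
sessions per patient except one cross-sectional-only patient (so 12
longitudinal patients), 20 s snippets at 250 Hz for all six pairs.  Expected
spectra follow the model above: offset 10^U(0,1) µV²/Hz, exponent U(1, 2),
knee present with probability 0.07 (2–8 Hz) else f_k ∈ U(0.05, 0.6) Hz (no
knee), a beta peak (16–24 Hz, amplitude 0.05–0.2), and a 60 Hz line peak
(amplitude 0.5).  The per-contact alpha amplitude is
base·exp(−d²/2ℓ²)·severity_factor with base 0.45 log10 units, decay length
ℓ = 6 mm, and a severity factor 0.3 + 0.7·s where the latent severity
s ∈ [0, 1] drives Y-BOCS affinely (10 + 28·s plus noise, clipped to 0–40) and
declines over sessions by a patient-specific improvement rate U(0.1, 0.8);
the right hemisphere tracks longitudinal severity with weight 0.4,
emulating left-lateralized coupling.  Time series are Gaussian noise
spectrally shaped so the expected Welch PSD equals the model spectrum
(narrowband peaks are shaped noise, not coupled oscillators); bipolar pairs
are contact differences plus 0.5 µV sensor noise, with each contact carrying
half the aperiodic power so a pair carries roughly one unit.  Active contacts
are the per-hemisphere argmax of true S1 alpha, corrupted with probability
0.1 (label noise) and doubled with probability 1/12 (double-monopolar).
Stimulation amplitude follows a random walk across visits (deliberately not a
deterministic function of visit number, to avoid collinearity with time).
Packetized acquisition with per-packet drop probability is available
(`packet_loss_prob`); the default is 0 because the quality screen's 0.5%
per-recording gap threshold is below a single 63-sample packet in a 20-s
snippet, i.e. the analyzed recordings are effectively clean after grid
reconstruction.
Anatomical structures are toy spheres, clearly labeled synthetic —
sufficient for border-distance logic, not anatomy.  All outputs are pure
functions of (config, seed); fixtures regenerate byte-identically.

What the generator does not emulate: cardiac/movement artifacts, circadian
modulation, volume conduction, electrode impedance drift, or genuinely
nonlinear hemisphere flips.  Passing tests therefore demonstrate correctness
of the analysis machinery and recoverability of planted effects at realistic
noise, not clinical validity on real recordings.

## Numerical and design choices

- 0.5 Hz resolution from 1-s windows requires FFT zero-padding to 2 s — the
  only reading consistent with both stated settings.
- The 1 Hz "low-pass to remove drifts" is implemented as a high-pass (the
  stated purpose fixes the stated type).
- AUC convention: mean cumulative probability over the first n−1 contacts
  (trapezoid-from-origin alternatives violate the perfect-predictor anchor).
- The active-vs-inactive null pool defaults to all contacts: restricted to
  inactive contacts the test is anti-conservative under exchangeability
  (~13% rejections at the 5% level in simulation) because the null
  distribution excludes exactly the observed active values.
- Exact replication of rows is not a no-op for a random-intercept model
  (group sizes enter the covariance weighting); duplication moves
  coefficients by well under 5% of their SE in the tested regime.
- Degenerate min–max leads map to zeros with a flag; clinical-match ties go
  to the earlier visit; best-session ties to the earlier session; ranking
  ties to the lower contact index — all for reproducible determinism.
- Parameter-recovery checks synthesize spectra directly from the model with
  independent per-bin log10 noise of SD 0.08, the marginal variability of a
  20-s Welch estimate (~39 windows); the time-series route is exercised
  separately end-to-end, where zero-padding-induced bin correlation makes
  per-bin peak localization noisier.

## Problem sizes used in the test suite

Unit tests run on 2–6 patient cohorts; statistical calibration uses 200 null
replicates at 1,000 permutations; end-to-end recovery uses 10 seeds of the
full 13-patient default cohort; mixed-model recovery uses 30 replicates of a
12-patient × 4-session × 2-hemisphere table.  Pipeline defaults remain
10,000 permutations/resamples.

## Known limitations

- The Satterthwaite approximation covers single-degree-of-freedom contrasts
  (all fixed effects here are single-df); multi-row contrasts would need the
  Fai–Cornelius extension.
- Spectral fits assume positive power over 1–65 Hz; pathological all-zero
  inputs are rejected rather than fitted.
- The heatmap is an analysis artifact: bit-exactness across platforms is not
  guaranteed, only its stated invariants (uniformity, mean preservation,
  hotspot localization).
- The packetized reader covers the simplified packet form, not any full
  proprietary telemetry export.
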
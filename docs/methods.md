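# Methods notes

This note records the modelling assumptions, parameter choices and numerical
conventions behind `cuelpp`, and what the synthetic cohorts do and do not
show about real data.

## Conventions

Sample indices are 0-based and all time windows are half-open `[start, end)`
in milliseconds, so at 250 Hz the 400–800 ms LPP window contains exactly 100
samples and the −100–0 ms baseline exactly 25. Epochs run −100…1096 ms in
4 ms steps (300 samples; index 25 is picture onset). Event onsets are stored
in samples, never milliseconds, to keep segmentation exact. All voltages are
in microvolts.

Epoched data are persisted as a float64 `.npy` array (trials × sensors ×
time) with a JSON sidecar carrying the rate, sensor labels and positions,
ROI, per-trial categories and the time axis. There is no universal container
for epoched EEG; raw-EEG formats carry continuous data, so this explicit
pairing was chosen for lossless, dependency-free round-trips. Every tabular
artifact is TSV; reals are written with 12 significant digits.

## Task schedule

Each of the 6 blocks holds exactly 10 neutral, 5 erotica, 5 romantic,
5 mutilation, 5 violence, 5 pollution, 10 food-paired and 10 food-unpaired
images (the paired role is assigned to sweet or savory per participant,
counterbalanced by alternation). Block orders are rejection-sampled
(bounded at 1000 shuffles, then an error — the run-length rule is never
silently violated) so that no category appears three times in a row, with
the check spanning block boundaries. Non-paired trials last 2200 ms;
food-paired trials additionally carry a uniform 1–3 s consumption delay —
a stand-in for the unknown distribution of real consumption times; it only
affects onset spacing, never epoch content. Intertrial intervals are uniform
500–2000 ms; all onsets round to whole samples.

## Signal model

Each trial contributes a raised-cosine bump `0.5·(1 − cos 2π(t−400)/400)`
supported on [400, 800) ms, scaled by the category's peak amplitude and by a
centroparietal topography: a Gaussian (width 0.45 chord units) of distance
from the ROI centroid, made zero-mean across sensors — i.e. already
average-reference-consistent — and normalized to ROI-mean weight 1. With
that normalization the noise-free extracted LPP equals peak/2 exactly
(the uniform sampling of one full cosine period makes the window mean
exactly 0.5), which is the closed form the tests assert at 1e-9.

Sensor noise is independent 1/f-power-shaped Gaussian noise, default SD
8 µV per sample — a typical single-trial EEG background against which
picture-viewing LPP effects of a few microvolts must be averaged out. The
analytic single-trial LPP noise SD (`lpp_trial_noise_sd`) follows from the
exact circular spectrum of the generator applied to the LPP-minus-baseline
time weighting, divided by √(ROI size). It deliberately ignores the small
variance reductions from the 30 Hz filter and the average reference, so the
LPP-level cohort generator (below) is slightly *noisier* than the full EEG
path — conservative for recovery and k-selection claims.

### Amplitude defaults

The generating LPP amplitudes are not published anywhere; the defaults are a
synthetic calibration chosen to reproduce the qualitative structure of the
phenomenon at magnitudes typical of picture-viewing LPP studies (extracted
LPP = peak/2, in µV):

| category      | C>P peak | P>C peak |
|---------------|----------|----------|
| food_paired   | 16.0     | 7.0      |
| erotica       | 11.0     | 13.0     |
| romantic      | 6.0      | 6.0      |
| food_unpaired | 3.5      | 3.5      |
| neutral       | 3.5      | 3.5      |
| pollution     | 3.5      | 3.5      |
| violence      | 6.0      | 6.0      |
| mutilation    | 13.0     | 13.0     |

These encode: the arousal gradient (erotica & mutilation > romantic &
violence > neutral & pollution) in both profiles, food-paired > erotica for
C>P and the reverse for P>C, food-unpaired ≈ neutral, and a convex arousal
profile so the quadratic trend contrast is strongly positive. The
food-paired separation between profiles (4.5 µV on the LPP scale) is more
than an order of magnitude above the per-category measurement SEM
(≈0.3–0.4 µV at 30–60 trials), satisfying the ≥3-SEM separation requirement
by a wide margin.

Per-participant heterogeneity: a lognormal overall gain (log-SD 0.12), a
per-category amplitude jitter (SD 0.5 µV), and an additive LPP offset
(SD 2 µV). Gain and offset are exactly removed by ipsatization (which is the
point of ipsatizing); the jitter survives it and keeps profiles from being
artificially identical.

### Artifacts

Artifact rates are per trial × sensor cell; each selected cell receives
exactly one kind: a ±110–150 µV plateau (amplitude rule; blink-like frontal
excursions are folded into this kind, since the proprietary blink-correction
step is out of scope and synthetic blinks must instead be *rejectable*), a
30–60 µV step (step rule), a full-segment ±55–75 µV ramp (range rule, with
per-sample increments far below the step threshold), or a >100 ms constant
stretch with <0.2 µV jitter (flatline rule). Default rates (0.3%, 0.2%,
0.1%, 0.2%) flag roughly one sensor per segment — enough to exercise QC
continuously without dropping segments on the dense montage.

Raw 1/f noise at 8 µV trips the 25 µV step rule in ≈1% of cells; in the
pipeline QC runs on 30 Hz-filtered epochs where this false-positive rate
falls below 0.5% and essentially never accumulates to the >10% per-segment
drop threshold on 129 sensors. The false rate is measured and asserted in
the test suite.

### Outcomes

Candy counts are negative binomial with mean 20 (C>P) / 8 (P>C) and variance
φ·mean, φ = 1.5: the quasi-Poisson model specifies only the first two
moments, so a concrete distribution realizing them was needed for
reproducible sampling; NB with `r = µ/(φ−1)` is the standard choice and
degenerates to Poisson at φ = 1 (under-dispersion is rejected). Covariates
(age uniform 24–65; gender 45% female; BMI normal(31, 5) clipped; pre-task
hunger normal(−4.4, 18) on a satiety-scale range) are drawn independent of
profile by default, so covariate-balance tests are null calibrations.

### Two cohort granularities

`generate_cohort` produces full EEG (129 sensors × 330 epochs × 300 samples
per participant, streamed one participant at a time — a whole cohort does
not fit in memory). `simulate_lpp_cohort` produces the same cohort directly
at the LPP-table stage, using identical per-subject amplitude parameters
plus per-category Gaussian noise at the analytic single-trial SD divided by
√(trials per category). Repetition-heavy analyses (k-selection and recovery
over 100 cohorts, power/type-I studies over 400) use the LPP-level path;
the full EEG path is exercised by the closed-form checks, the unit suite,
and the acceptance script's complete pipeline run. Problem sizes in the
tests (100 LPP-level cohorts for k-selection; 20 for recovery; 200 + 200
outcome cohorts; 1000 GLM calibration fits at n = 500; one full-EEG cohort
in the acceptance script) were chosen so the whole suite runs in a few
minutes while keeping Monte-Carlo error well inside the asserted bands.

What passing these tests does *not* show about real data: the generator has
no ocular or muscle dipoles, no non-stationary drift, no volume-conduction
correlation between sensor noises, no learning or habituation across blocks,
and its two latent profiles are crisp by construction. Recovery and
k-selection results on synthetic cohorts demonstrate the pipeline's
correctness and power under its stated model, not the effect size or cluster
separability of any empirical population.

## Preprocessing choices

The low-pass filter is a windowed-sinc (Hamming) FIR with a transition band
of 0.25 × cutoff, applied zero-phase (forward and time-reversed), which
preserves LPP latency; DC gain is exactly 1 and single-pass attenuation at
50 Hz exceeds 50 dB. Zero-phase application of a symmetric FIR equals a
single convolution with the kernel's autocorrelation, which is how it is
implemented (with odd-reflection padding; verified against `filtfilt` to
2e-15). Epoched data are filtered per epoch; edge transients stay within a
filter half-width (~220 ms) of the epoch edges, outside both the baseline
and the LPP window.

Bad sensors are those flagged by the artifact rules in more than 50% of a
participant's segments — the per-epoch re-expression of "contaminated for
more than half the recording", which cannot be evaluated verbatim without
continuous data. They are replaced by the inverse-distance-weighted mean of
their 4 nearest good sensors; spherical splines would add substantial
numerical machinery while the quantity of interest (LPP at intact ROI
sensors) is insensitive to the choice. Because flags are computed on
referenced, baselined epochs, interpolation necessarily happens *after*
average referencing — the opposite order from a continuous-data workflow;
with at most a handful of bad sensors in 129 the effect on the reference is
negligible.

QC order is fixed and logged: filter → average reference → baseline →
flags → bad-sensor interpolation → re-flag → segment rejection → retention.
All exclusion inequalities are strict, reading "above / larger than / more
than / fewer than" literally, so boundary cases (exactly 10% flagged
sensors, exactly 20% retained trials) pass. The flatline rule's ">100 ms"
means runs of at least 26 samples at 250 Hz (25 samples span exactly 96 ms
between window endpoints' strict reading: 26 samples are needed to exceed
100 ms), implemented as a sliding-window max−min test. The range rule is
evaluated per sensor over the whole 300-sample segment including baseline
(a per-sensor reading; the alternative cross-sensor reading is not used).
Segments are kept or dropped whole — a flagged sensor inside a kept segment
is not masked from the category average.

## Clustering choices

Ipsatization uses the sample SD (n−1); the convention is isolated in one
function. Constant LPP vectors cannot be ipsatized and raise an error naming
the participant.

k-means: Lloyd with k-means++ seeding, best of 50 restarts under a fixed
master seed; final centroids are recomputed as exact member means so the
fixed-point invariant holds to machine precision. Tiny two-cluster instances
(n ≤ 12) are solved exactly by enumerating all 2^(n−1)−1 splits — restarted
Lloyd measurably misses the global optimum on such instances, and exact
enumeration there is cheaper than the restarts. Empty clusters are handled
by the underlying implementation's re-seeding policy.

Silhouette uses Euclidean distances with s = 0 for singletons and for the
all-identical degenerate case; selection is the argmax of the mean
silhouette over k ≥ 2. The gap statistic follows the canonical recipe:
uniform reference draws over the feature-wise bounding box (not the
PCA-rotated variant), `Gap(k) = mean_b log W*_kb − log W_k`,
`s_k = sd_b(log W*_kb)·√(1+1/B)` with B = 25 references (10 restarts per
reference fit; 50 for the data fits), and the chosen k is the smallest with
`Gap(k) ≥ Gap(k+1) − s_{k+1}`. When the two criteria disagree the pipeline
reports both and follows the configured `k_criterion` (default: gap) with a
warning rather than silently preferring one.

Profile labels apply only at k = 2: the cluster whose centroid has
food_paired > erotica (in ipsatized units) is C>P, the other P>C; an exact
tie leaves both unlabelled with a warning, as does any k ≠ 2 (the clustering
itself remains valid and reported).

## Statistical choices

All p-values are two-sided. The quadratic arousal trend collapses the six
nonfood categories to three levels (high = mean of erotica & mutilation,
mid = romantic & violence, low = neutral & pollution) and t-tests the
per-participant contrast high − 2·mid + low against zero within each group.

The profile MANOVA avoids sphericity assumptions by testing multivariately:
the between-group effect is a two-group Hotelling T² on the raw 8-vector
with its exact F conversion; the category and group × category effects are
Hotelling tests of the intercept and group rows of a multivariate linear
model (intercept + centred group) on 7 orthonormal Helmert contrasts of the
categories. T² is invariant to the choice of orthonormal contrast basis.
Per-category between-group t tests are Bonferroni-corrected with a declared
family size (default 8); family sizes must be stated per comparison set
because implied families are otherwise ambiguous.

Mann–Whitney U uses midranks for ties and reports the min(Uₓ, Uᵧ)
convention with group identities attached. When C(n₁+n₂, n₁) ≤ 200,000 the
two-sided p is exact by enumerating every labeling of the pooled midranks
(the null permutation distribution of U is symmetric about n₁n₂/2, so the
|U − µ| ≥ |U_obs − µ| count equals the usual doubled one-sided tail);
otherwise a normal approximation with tie-corrected variance and a 0.5
continuity correction is used. The correction is exact-spaced for untied
data; with ties U moves in half-steps and the approximation is coarser in
the mid-p range (differences up to a few hundredths near p ≈ 0.8, under
0.02 in the p ≤ 0.2 decision region) — the exact method is preferred
whenever feasible.

The quasi-Poisson GLM is a Poisson log-link fit by IRLS with dispersion
φ = Pearson X²/(n − p), coefficient covariance φ·(XᵀWX)⁻¹, and Wald 95% CIs
on the log scale exponentiated to rate ratios. The normal quantile is used
for the CIs (an R-style t quantile would widen them imperceptibly at n = 49).
In a group-only design the fitted group means equal the sample means
exactly. Suspected separation (diverging standard errors) produces a
warning and honestly divergent CIs, not a masked result. Covariate balance
uses two-sample t tests for numeric covariates and chi-square without
continuity correction for categoricals; zero-variance covariates are
reported as not testable. One-sample t tests against a scale anchor cover
the satiety pre/post comparisons.

## Reproducibility

One master seed drives everything: per-participant and per-stage generators
are spawned from it via `numpy.random.SeedSequence`, so identical
configs+seeds give bit-identical cohorts and byte-identical artifacts, and
partial re-runs stay consistent with end-to-end runs (stage-wise and
streaming execution produce identical tables; the epoch containers are
lossless float64).

## Known limitations

Continuous-raw synthesis, spherical-spline interpolation, ocular-artifact
correction, notch filtering, resampling, EDF/vendor formats, probabilistic
cluster-membership uncertainty and cross-session stability analysis are out
of scope. The bad-sensor rule is epoch-granular by necessity. The
Mann–Whitney normal approximation's continuity correction is conventional
rather than tie-adaptive. The generator's realism limits are listed above.
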
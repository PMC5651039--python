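# Methods

## Hemodynamic model

The canonical HRF is the difference of two gamma densities with shape
delay/dispersion and scale equal to the dispersion: response delay 6 s,
undershoot delay 16 s, both dispersions 1 s, undershoot ratio 6, kernel
length 32 s.  The kernel is evaluated directly at the run's TR (no
microtime upsampling); causal convolution is truncated to the series length
and scaled by the sampling step, so amplitudes are comparable between a
0.645 s and a 1.4 s grid, with zero-padding before scan start.  The
positive lobe of the default kernel peaks at 5 s.

Slow drifts are modelled with the discrete cosine basis: for `N` scans at
repetition time `TR` and nominal cutoff period `C` (default 128 s), the
basis keeps `floor(2·N·TR/C + 1)` orthonormal columns including the
constant, giving an effective cutoff of `n_drift/(2·N·TR)` Hz — 0.0069 Hz
for 225 scans at 0.645 s and 0.0077 Hz for 93 scans at 1.4 s.

## Deconvolution

The neuronal-level series is estimated as `z = D·w` on the full cosine
basis `D` (one column per scan by default), by minimizing

    || x − (D·w) * h ||² + λ · Σ_j f_j² w_j²

where `f_j` is column `j`'s frequency in Hz.  The f² penalty shrinks fast
components hardest, reproducing the qualitative behaviour expected of
regularized fMRI deconvolution: a deconvolved-then-reconvolved series is a
smoothed version of the input, with power in the 0.2–0.4 Hz band reduced by
two orders of magnitude at λ = 1.  Noiseless band-limited inputs round-trip
essentially exactly as λ → 0.

λ is selected per series by generalized cross-validation over a logarithmic
grid (10⁻⁶–10⁸), taking the **first local minimum** of the GCV curve.  The
guard matters: for a series with no reliable smooth structure the GCV curve
is nearly flat and its global minimum sits at the fully-shrunk end, which
would collapse the estimate to a constant.  For multi-subject group
analyses even the guarded per-series choice leaves betas on heterogeneous
scales, so the study pipeline applies one **common fixed weight across
subjects** (`StudyConfig.deconv_reg_weight`, default 1.0 — the typical
interior GCV optimum on synthetic BOLD at these scan lengths); set it to
`None` to restore per-series GCV.  The solver caches the convolved-basis
Gram factorizations per scan grid, so cohort-scale deconvolution costs
milliseconds per series.

## PPI construction and estimation

Both methods share the psychological column `center(boxcar * h)` and the
raw seed series as the physiological column; they differ only in the
interaction term.  The non-deconvolution term centers *after* convolution;
the deconvolution term centers the boxcar at the neuronal level before
multiplying with `z` and convolving back.  The boxcar itself uses
start-of-volume timestamps and half-open `[onset, onset + duration)`
intervals; after discarding `ceil(discard_s/TR)` leading volumes the scan
clock keeps the original acquisition origin.

Estimation is ordinary least squares without prewhitening.  Rank-deficient
designs raise an error naming the collinear columns; perfect fits report
signed-infinity t sentinels with a warning rather than dropping the unit.
ROI-pair ("edge") analysis fits, for every ordered pair, the target on
`[task, seed_i, PPI_i, constant]` with covariates omitted — ROI series are
expected to be nuisance-adjusted first (`nuisance_adjusted_series` regresses
out motion-24, WM/CSF and DCT drifts plus an intercept).  The resulting
R×R beta matrix is symmetrized by averaging the two directions, leaving
R(R−1)/2 unique effects (190 for 20 ROIs) with an undefined (NaN) diagonal.
ROI summary series use the first singular vector of the (adjusted) voxel
block, scaled by its singular value over √n_voxels and sign-anchored to
correlate nonnegatively with the ROI mean.

Group inference is a per-unit one-sample t test, one-tailed in the
requested direction (df = n−1; 138 subjects give df 137, whose p < 0.001
critical value truncates to 3.15).  Matrix-level multiple-comparison
control uses Benjamini–Hochberg over the unique effects.  No random-field
cluster inference is provided; voxel-level work is supported only at toy
volume sizes.

## Reliability metrics

* **Dice**: 2|A∩B|/(|A|+|B|), defined as 0 for two empty masks.  Curves are
  computed under a common-t grid (1.7–7.0 in steps of 0.1; 1.7 ≈ one-tailed
  p < 0.05 at df ≈ 137) and a matched-percentile grid (80–99.5 in steps of
  0.5), the latter ensuring equal suprathreshold counts up to ties.
  Negative effects are analysed by negating both maps.
* **ICC**: two-way mixed, single-measure, consistency form ICC(3,1) by
  default — the standard choice for two-run test–retest — with one-way
  ICC(1,1) selectable.  Zero-variance inputs yield NaN sentinels with a
  warning.  Histograms compare the ICC distribution inside a significance
  mask (intersection of runs × methods at p < 0.01) against the whole
  domain, with masses normalized to 1.
* **CV**: per subject, the variance of the two log effects; the square root
  of the subject-mean is back-transformed (`exp(s) − 1`) and reported in
  percent.  Logs require positive values: the default orientation
  multiplies by the contrast sign (so reduced-connectivity betas become
  positive) and raises, naming the subject, on remaining non-positive
  values rather than silently dropping them.

## Design-speed simulation

Task designs are sampled at TR 2 s over 480 s (240 bins): an event design
alternating one 2 s trial bin with five baseline bins, and block designs
with cycles 8–80 s split into equal on/off halves, trailing partial cycles
truncated.  For each of 1000 i.i.d. standard-Gaussian neuronal series the
two PPI terms are built with the psychological vector **centered** before
multiplication in both constructions and their Pearson correlation
recorded.  Centering is the convention under which the event design's mean
correlation falls below 0.5 while slow block designs exceed 0.9, matching
the documented behaviour; it is configurable off.  Degenerate designs
(zero-variance terms) yield NaN sentinels.

## Synthetic cohort generator

The generator emulates the structure of a two-run flickering-checkerboard
experiment: run A with 225 retained volumes at TR 0.645 s (9 s of dummies
discarded), run B with 93 at TR 1.4 s (7 s discarded); three 20 s
stimulation blocks alternating with 20 s fixation; 20 visual ROIs
(thalamus, occipital areas OC1–OC5, fusiform FG1/FG2, left/right).  The
forward model injects the interaction at the neuronal level:

    n_j(t) = u_j(t) + a·box(t) + Σ_pairs γ_s · center(box)(t) · n_i(t)
    y_j(t) = (n_j * h_s)(t) + AR(1) noise + drift + nuisance leak

so the deconvolution method is the generative model and the
non-deconvolution method its block-design approximation.  Defaults, chosen
once as realistic for this kind of task: unit-variance neuronal
fluctuations with an exchangeable inter-ROI correlation of 0.3 and a 2 s
autocorrelation time (AR(1) in continuous time, so both runs sample the
same process despite different TRs — with white per-scan innovations the
short-TR run's faster fluctuations would be attenuated more by the HRF,
inverting the expected power relation between runs); activation amplitude
1.5; five designated pairs centered on FG1 modulated at γ = −0.5 with
between-subject SD 0.2 (γ_s ~ Normal); per-subject HRF response-delay
jitter SD 0.5 s (clipped to 3–10 s); measurement noise SD 0.8 with AR(1)
coefficient 0.3; random slow cosine drifts (periods > 128 s) with
coefficient SD 0.5; a 0.2 leak of shared WM/CSF-like signals; smooth
random-walk motion with 0.02 mm/° step SD.  Ground truth (designated and
per-subject coefficients, HRF delays) is stored losslessly with the data.

What the generator does **not** emulate: anatomy and spatial structure
beyond disjoint cubic ROIs, physiological (cardiac/respiratory) noise,
scanner artefacts, spatially varying HRFs within subject, or non-Gaussian
between-subject heterogeneity.  Passing tests therefore demonstrate that
the estimators recover what this forward model encodes — signs and ordering
of injected effects, reliability scaling with between-subject variance —
not that they are robust to everything real fMRI contains.

## Problem sizes and numerical conventions

Ground-truth recovery checks use a 50-subject cohort for sign recovery
(both methods × both runs), three 30-subject cohorts with between-subject
effect SDs 0.05/0.3/0.8 for the ICC-scaling check, and ten 20-subject
replicates for the run-power comparison (run A's mean group |t| over the
modulated pairs beats run B's in ≥ 70% of replicates); the design-speed
simulation uses its full 1000 draws.  All randomness is seeded.  Other
conventions: winner-takes-all ties break to the lowest map index and
all-zero voxels stay unlabelled; boxcar membership is half-open; the
motion-screening inequality is strict (a frame-wise displacement exactly at
1.5 mm/1.5° is kept); the BH step-up keep-set is computed exactly rather
than via adjusted p values.

## Known limitations

OLS without prewhitening mildly misstates single-subject standard errors
under autocorrelated noise (group inference, which operates on betas, is
unaffected).  The ridge deconvolution is not numerically equivalent to any
particular empirical-Bayes implementation; only its qualitative
high-frequency suppression is claimed.  CV on signed effects requires a
consistent orientation and is undefined for edges whose effects cross zero
across subjects; such edges are skipped in the study report.
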
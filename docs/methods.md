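# Methods

## The analysis model

The pipeline estimates, for each cortical-depth bin of a V1 region of
interest, how well two stimulus colours (or two stimulus conditions) can
be linearly decoded from trial-wise multivoxel response patterns, and then
tests depth profiles of decoding accuracy at the group level.

**pRF model.** A voxel's population receptive field is an isotropic 2-D
Gaussian over the visual field with centre (x, y) and size σ, all in
degrees of visual angle. Predicted mapping-run responses are the per-frame
overlap of the binary stimulus aperture with the Gaussian, convolved with
the two-gamma HRF at the TR. The grid fit scores every candidate by the
squared Pearson correlation (r²) between the predicted and observed time
courses concatenated across the wedge and ring runs, which leaves response
amplitude and offset implicitly free. Candidates use 24 σ levels,
log-spaced 0.2°–4.8° by default (the level count is fixed; the range is a
configurable modelling choice), with centres one σ apart covering the
mapped field. Ties are broken towards the smallest σ, then the
lexicographically smallest centre; an all-constant voxel returns an
r² = 0 sentinel. The wedge and ring runs are fitted jointly in one
concatenated score.

**Phase mapping.** Fourier amplitude and phase are taken at the
stimulation frequency (1/64 Hz) after excluding the 12-s baselines, so the
analysis window holds an integer number of cycles. The F-ratio divides the
squared amplitude at the stimulation frequency by the mean squared
amplitude at all other nonzero frequencies; under white noise its mean
is 1.

**ROI rule.** A voxel enters an ROI when r² exceeds the threshold (0.2 by
default; 0.1 for small target regions) *and* the closed disc of radius 1σ
around its pRF centre lies inside the target region, boundary-inclusive.
Target regions are composed from discs, half-planes, intersections and
unions (e.g. semicircles along an illusory contour). Because strict
thresholding favours superficial voxels, an optional stacked-column
completion adds every voxel sharing a cortical column with a passing voxel
(flagged per voxel), the deterministic analogue of projecting ROI patches
through all depths. For unions the containment test is per-component,
which is exact for well-separated parts (the intended geometry).

**Depth bins.** Six bin centres at 0.1, 0.26, 0.42, 0.58, 0.74, 0.9 of
cortical thickness with interval membership |depth − centre| ≤ 0.1. The
depth coordinate runs from 0 at the white-matter boundary to 1 at the pial
surface, so "deep" means low values; this convention is used everywhere.
With the default halfwidth, neighbouring bins share voxels in 0.04-wide
zones and the bins jointly cover [0, 1]. Equidistant (not equivolume)
spacing is used; the halfwidth is configurable and the true voxel-sharing
kernel of grid-sampling tools is not modelled.

**GLM.** The two-gamma HRF is a difference of gamma densities with unit
scale whose modes sit exactly at the peak (5 s) and undershoot (15 s)
times; the lobes are peak-normalised and combined at a 6:1 ratio, then the
kernel is peak-normalised. Boxcars are built at 0.1-s resolution,
convolved, and sampled at the TR. Trial betas come from one OLS model per
run with one column per block plus an intercept (a least-squares-all
convention; single-trial models are not used). No autoregressive noise
model and no HRF derivatives. Voxels with grand-mean raw intensity below
100 are removed; a voxel at exactly 100 is retained.

**Decoding.** Linear C-SVM, C = 1, termination tolerance 0.001, equal
class costs. Betas are rescaled per voxel onto [−1, 1] with parameters
learned on the training folds only; held-out values may leave [−1, 1] and
are not clipped. Cross-validation leaves one run out; reported accuracy is
the arithmetic mean over folds. Cross-classification between conditions
trains on all runs of one condition and tests on all runs of the other
(the sets are disjoint by construction, so no fold structure is imposed).
Weight maps average the primal vector over folds, with positive weights
meaning evidence for the first-named class.

**Inference.** First level: bootstrap of the across-subject mean with
10,000 resamples; one-sided p = (1 + #{resampled means ≤ 0.5}) / 10,001
(the add-one form avoids p = 0); 90% CI from the 5th/95th percentiles,
matching the one-sided test. The accuracy vector is sorted before
resampling so the seeded result is invariant to subject order. FDR uses
Benjamini–Hochberg within the family of all depth × condition × ROI
comparisons of one experiment. Second level: a linear mixed model of
accuracy on depth (continuous bin centre), condition, experiment and all
interactions, with per-subject random intercept, depth slope and
condition × depth slope, fitted by REML (statsmodels MixedLM). Wald
statistics are reported as t with df = n_obs − n_fixed; this df convention
follows the fitting machinery and is stated in the output because mixed-
model df conventions differ. If the full random structure is singular the
model refits with random intercept + depth and sets a `degenerate` flag.
Simulations in the test suite show the nominal 5% type-I rate and ≈95% CI
coverage under this convention. A companion model (counts ~ depth + roi +
roi:depth with the matching random structure) serves as a QC gate against
laminar sampling bias.

**Back-projection.** y_i = Σ_j(w_ij x_j) / Σ_j w_ij with w_ij the
unnormalised (peak-1) pRF Gaussian of voxel j at pixel i, set to zero
where the Euclidean distance exceeds 2σ_j (boundary inclusive), and
y_i = 0 where total coverage is zero. Gaussian normalisation cancels in
the ratio except through truncation. Fold-averaged weights are projected.

**Behavioural scoring.** %primed = n_primed / (n − n_mock − n_mixed);
catch and mixed trials never count as primed. Selection keeps participants
at or above 60%. The catch-failure rate is reported descriptively; no
exclusion cut-off is applied.

## The synthetic-data generator

The generator emulates the study design: 6 task runs of 272 volumes at
TR = 2 s; per run each of five conditions (perception, imagery, illusory,
amodal, mock) appears six times — three per colour — in seeded random
order, in 8-s blocks with ISIs drawn uniformly from [7, 8] s and rounded
to 0.5 s (the jitter distribution and block-order randomisation are free
choices; the source design states only the range). Mapping runs are a
22.5° wedge rotating anti-clockwise through 12 cycles of 64 s (396
volumes) and a ring expanding to the field edge through 8 cycles (268
volumes), both with 12-s baselines.

Voxels are organised in cortical columns: all voxels of a column share one
pRF (the hypercolumn assumption) and sit at jittered depths around the six
canonical centres. Each voxel's task time course is

    baseline × gain × (1 + common response + pattern response) + noise

where gain = 1 + slope × depth encodes the superficial vascular bias
(slope 0.6 by default), the common response (1% amplitude) follows every
block, and the colour pattern for a condition is ±effect × w_v (w_v a
seeded standard normal per voxel and condition; + for red, − for green),
nonzero only inside the condition's target depth band. Colour is therefore
a pattern effect with zero mean-amplitude difference, mirroring the
decoding logic. Defaults: perception 2% at all depths; imagery 1.5% in
the deep band [0, 0.35]; illusory 1.5% and amodal 0.8% in the superficial
band [0.65, 1]; mock carries nothing. Noise is i.i.d. Gaussian per volume
with sd equal to 1% of the voxel's mean intensity (baseline × gain).
Making the noise multiplicative in the gain renders the vascular gradient
information-neutral: per-voxel rescaling removes the gain exactly, which
is why amplitude profiles change with the gain slope while decoding
accuracies do not — the generator's built-in version of the
amplitude/decoding dissociation.

What the generator does **not** emulate: temporal autocorrelation and
high-pass-filtered noise spectra, motion and distortion, physiological
noise structure, spatial noise correlations, surface geometry, and
non-stationary pattern amplitudes. Passing tests therefore show that the
*analysis* is correct and calibrated under its stated assumptions, not
that real 7T data would yield the same effect sizes.

## Problem sizes and numerical conventions

Test and calibration runs use 16–20 columns × 6 depths (≈100–120 voxels)
per subject, 16 subjects for null calibration, 10 for laminar-specificity
checks, and 500 simulated datasets at 26 subjects for mixed-model
coverage — sizes chosen so the full suite exercises every stage end to end
at desk scale. The pRF recovery check uses 500 voxels against the full
24-level grid; "recovered within one grid step" means the fitted centre
lies within one true-σ of the true centre (the grid step at that level).
Time-course SNR for that check is defined as signal sd / noise sd = 1.
Seeds are explicit everywhere; identical configuration + seed reproduces
identical data bit-for-bit.

## Known limitations

- The SVM termination tolerance (0.001) bounds reproducibility of weight
  vectors across solvers to ~1e-3.
- The mixed model reports Wald t with a residual-df convention rather than
  Satterthwaite/Kenward-Roger df; with the simulated geometries this is
  accurate (nominal type-I error and CI coverage), but small-sample df
  corrections are not implemented.
- Union regions test containment per component; a pRF disc straddling two
  touching components would be rejected.
- The generator's rivalry pre-test assumes ideal catch-trial behaviour.
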
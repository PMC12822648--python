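# Methods

`proxdec` reimplements, as a tested pipeline, a multivariate fMRI analysis
of how dynamic scene context shapes visual object representations: linear
classifiers are trained on benchmark responses to wide vs. narrow object
views and tested on main-task responses, decoding performance is summarized
as *classifier information*, robustness is assessed over nested sub-ROIs
with 1D TFCE sign-flip inference, and a coupling analysis relates each
voxel's activation time course to the seed region's time-resolved decoding.
Because no scanner data ship with the package, a forward generator emulates
both experimental designs with known ground truth, so every stage can be
verified by parameter recovery and calibration studies.

## Experimental designs

Two session layouts are built in (`proxdec.design`):

* **Experiment 1** — 7 main-task runs x 48 trials. Each trial ends with the
  object reappearing against the rotated room, congruently (75%, 36 trials
  per run) or incongruently (25%, 12) with the scene rotation, balanced
  over the four initial-orientation x rotation combinations A30/A90/B30/B90.
  The proximal-shape mapping is wide = {A30, B90}, narrow = {B30, A90}; the
  final scene orientation (30 or 90 degrees) is a confound the decoding
  scheme must control. Three classifier-training runs show the final views
  in 13.5-s mini-blocks (20 per run, 5 per combination), and two localizer
  runs show category mini-blocks (objects, scrambled, faces, scenes).
  Congruent trials are split per run into three subsets of 12, stratified
  by condition (3 trials per condition per split) so that every
  condition x split GLM cell is estimable; the incongruent trials then have
  a matched trial count per cell.
* **Experiment 2** — 8 main runs x 40 trials in which the object stays
  occluded; the final occluded period (1.5-2.0 s, jittered) is the event of
  interest. On 12.5% of trials (40/320, spread 2-10 per run) the object
  reappears (catch trials, excluded from analysis; their reappearance is a
  separate regressor). Training runs show background-free objects grouped
  by proximal shape in 6.75-s mini-blocks.

Trial onset asynchrony is fixed by the protocol run lengths (e.g. 404
volumes at TR = 1 s for Experiment 1 main runs); the final-view event sits
4 s into each trial. Scaled designs (`exp1_scaled_params`,
`exp2_scaled_params`) keep every timing constant and all balance rules but
shorten runs; they exist for simulation studies, not as defaults.

## Forward model

Each simulated subject draws, per voxel: a nonnegative responsiveness gain
(gamma, mean 1), wide/narrow shape patterns and 30/90-degree background
patterns (Gaussian, scaled elementwise by responsiveness and a per-ROI
signal scale), so localizer responsiveness and shape information are
positively coupled — the premise that makes top-N localizer ranking
meaningful. Event amplitudes are:

* main-task reappearance (impulse): `gain_congruency x shape_pattern +
  background_pattern`, plus a spatially uniform surprise amplitude on
  incongruent trials (the generative counterpart of the reported
  incongruent > congruent univariate response);
* training mini-blocks (boxcars): shape pattern (+ background pattern in
  Experiment 1);
* occluded final period (boxcar, Experiment 2): `occluded_signal_gain x
  shape_pattern` of the expected shape — cross-decoding from visible to
  occluded presumes this shared pattern geometry;
* localizer mini-blocks: responsiveness times a per-category drive.

Amplitudes are convolved with the canonical double-gamma HRF (delays
6/16 s, unit dispersions, undershoot ratio 1/6, unit peak) on a 10x
oversampled grid — exactly the regressors the GLM uses, so a noiseless run
is recovered to machine precision. Noise is AR(1) Gaussian per voxel
(`ar1_rho` = 0.3 by default, marginal SD `noise_sigma` = 1); white noise is
the `rho = 0` special case. Per-subject overall amplitude varies
lognormally (SD 0.08). All randomness descends from one integer seed via
`numpy.random.SeedSequence` (cohort -> subject -> run).

### Default amplitudes

The generator's defaults were calibrated once, by pilot simulation at
protocol scale, so that the synthetic cohorts reproduce the order of the
group effects the analysis is meant to detect: with `amp_shape = 0.009`
(in units of noise SD) and EVC congruency gains 1.07/0.93, a 34-subject
cohort yields EVC classifier information near 0.29/0.24
(congruent/incongruent, difference ~0.05, between-subject SD ~0.11), LVC
near 0.13/0.10 with no congruency effect (LVC gains 1.0), and Experiment 2
occluded information near 0.07-0.08 in both ROIs (per-ROI occluded gains
{EVC: 0.08, LVC: 0.19}; the larger LVC share reflects that the top-down
signal is carried relatively more by later visual cortex). The small
absolute amplitude compensates for two idealizations of the generator —
spatially independent noise (so multivariate SNR grows like sqrt(voxels))
and fully informative patterns in every ROI voxel; real data needs much
larger per-voxel effects to reach the same group statistics.

### What the generator does not emulate

No spatial noise correlation or smoothness, no retinotopy or anatomical
geometry (ROIs are labeled slabs on an abstract voxel grid), no motion or
physiological artifacts, no HRF variability across voxels or subjects, and
no behavioral task model beyond the reappearance-count reports. Passing
recovery tests therefore demonstrates the correctness and calibration of
the *analysis machinery* under the stated generative assumptions, not
performance on real scanner data.

## Estimation

GLMs are ordinary least squares via the pseudoinverse (minimum-norm under
rank deficiency), one regressor per condition (x split x mini-block as
appropriate), a per-run intercept as the run-based nuisance regressor, and
optional unconvolved nuisance columns (e.g. motion). No prewhitening:
decoding consumes relative pattern geometry, not single-voxel inference.
Impulse regressors are exact HRF copies (unit peak); boxcars integrate the
HRF over the event. The FIR basis uses non-overlapping 1-s (1-volume)
sticks, bin 0 at the onset volume, 10 bins by default; the coupling FIR
model crosses congruency with proximal shape (4 conditions) so each bin
provides labeled wide/narrow patterns.

## Voxel ranking and sub-ROIs

The localizer contrast is the mean of the objects and scrambled-objects
betas per run (fixation baseline absorbed by the intercept); a one-sample
t across runs ranks voxels within each ROI x hemisphere. Top-N sets for
N = 100..6000 in steps of 100 (60 sub-ROIs at protocol scale; ladders are
truncated to the simulated voxel budget) are nested by construction; ties
break by ascending voxel index.

## Decoding and classifier information

Classifiers are hard-margin-style linear SVMs (hinge loss, C = 1) trained
on standardized features (per-voxel mean 0, population SD 1, zero-variance
guard). The trainer solves the C-SVC dual with a numba-compiled SMO
(maximal-violating-pair working sets, analytic two-variable updates,
KKT-based intercept), deterministic for fixed input; the test suite pins
its decision values to an independent SVM implementation at 1e-4.

Decoding performance is the mean over test samples of z-scored signed
hyperplane distance times the true +/-1 label (*classifier information*):
0 at chance, invariant to positive rescaling of distances. Distances are
z-scored with the population SD across all test samples pooled over runs
within a cell (a `within_run` pooling mode exists behind a config switch;
with two samples per run it degenerates to +/-1 and is therefore not the
default — the degeneracy is documented rather than resolved).

Experiment 1 uses background-matched cross-decoding: per background (30/90)
a classifier separates the A vs. B orientations (+1 = A); test cells are
congruency x background x split, with incongruent labels given by the
orientation actually shown. Information is averaged over backgrounds, over
the three congruent splits, and over both decoding directions (train on
training runs / train on main-task cells; the reverse direction trains one
classifier per congruency x background x split cell and tests on the
matching-background mini-block betas). Experiment 2 trains a single
wide-vs-narrow classifier (+1 = wide) and tests on the occluded-period
betas, catch trials excluded, again direction-averaged. An optional
accuracy mode (chance 0.5) mirrors the information statistic.

## Group inference

Per subject, classifier information is averaged over voxel counts and
hemispheres (hemispheres averaged before the group test); conditions are
compared with two-sided paired t tests (Cohen's d = mean difference / SD
of differences, 95% t CIs), overall decodability with one-sample t tests,
and the congruency x ROI question with a repeated-measures 2x2 interaction
F (algebraically the squared paired t of the difference of differences,
verified against an independent ANOVA implementation).

Robustness across sub-ROIs uses 1D TFCE: each point of the t curve
accumulates `extent^E x height^H x dh` over thresholds, with E = 0.5,
H = 2 (field-standard exponents), dh = max |t| / 100, and negative values
enhanced on the mirrored curve. The null flips each subject's whole curve
with probability 1/2 (10,000 permutations by default); family-wise p-values
use the max-enhanced-statistic over curve points (a pointwise null is
available behind `tfce_null='pointwise'`), and z is the corresponding
normal quantile. The add-one permutation estimator keeps p > 0.

Univariate analyses average betas over voxels within each sub-ROI, then
over sub-ROIs, per congruency condition (two-regressor GLM), compared with
paired t tests; the whole-brain contrast thresholds per-voxel one-sample t
maps at alpha = 0.001 (uncorrected), groups surviving voxels into
face-adjacent (6-connected) 3D clusters, and drops clusters under
10 voxels. The coupling contrast is the same machinery, one-sided
(congruent > incongruent), applied to per-voxel Pearson correlations
between each voxel's run-averaged FIR curve and the seed region's 10-bin
information curve, averaged over six seed sizes (500..1000 voxels pooled
across hemispheres at protocol scale); degenerate voxels contribute r = 0
so map geometry is fixed across subjects. Raw correlations enter the group
test by default (`fisher=True` applies the z transform).

Participants in Experiment 2 are excluded when their run-wise correlation
between true and reported reappearance counts falls below Q1 - 2 IQR
(linear-interpolated quartiles; degenerate-variance reports score 1 when
exactly correct, else 0).

## Calibration and recovery studies

`proxdec.studies` fixes four simulation studies (used by the acceptance
suite and `scripts/acceptance.py`); all use scaled designs with the
package's timing constants and share one trial sequence per cohort
(subjects keep independent patterns, gains and noise — sign-flip and label
symmetries are unaffected):

* **Type-I calibration** — null cohorts (equal congruency gains), 34
  subjects, 600 voxels in the tested ROI, sub-ROIs 100..600, 2 main runs x
  16 trials, 500 sign-flip permutations; the family-wise false-positive
  rate of the congruency TFCE test over 200 cohorts should sit near the
  nominal 0.05.
* **Experiment 1 recovery** — EVC gains 1.11/0.89 at `amp_shape = 0.04`,
  3 main runs x 48 trials, 300 voxels per ROI and hemisphere, 24-subject
  cohorts: the expected per-subject congruent-incongruent information
  difference is ~0.05-0.06 (group d ~0.8), detected by the paired t in the
  EVC but not in the equal-gain LVC. The scaled studies use a larger
  amplitude than the protocol-scale default because per-subject measurement
  noise grows at reduced trial counts; the gains were set by pilot so the
  *difference*, the quantity under test, stays in the stated band.
* **Experiment 2 recovery** — occluded gain 0.2 vs. 0, 16-subject cohorts,
  3 main runs x 24 trials (12.5% catch preserved), 300 voxels per ROI.
* **Coupling recovery** — a 15-voxel block outside the visual ROIs responds
  univariately on congruent trials only (amplitude 2 x noise SD), so its
  FIR curve tracks the congruent seed information curve; 16-subject
  cohorts, seed sizes 100..350. Detection = a surviving one-sided cluster
  (>= 10 voxels) peaking inside the block.

## Numerical and degenerate-input choices

Population SD in all z-scores; zero-variance features/distances/voxels map
to 0 with flags; zero-variance t tests return 0 (mean 0) or signed
infinity; all-zero design columns are dropped from the solve and their
estimates set to 0; tied localizer ranks break by voxel index; quantiles
interpolate linearly; SVM tolerance 1e-6 with a 1e5-iteration cap;
permutation and simulation seeds are explicit arguments and recorded in the
results manifest together with every active analysis choice.

## Known limitations

The generator's independence assumptions (noise across voxels, subjects
sharing only scalar amplitude variation) make absolute information values
and effect sizes incommensurable with real data; only their ordering and
the inferential calibration transfer. Real-data mode (NIfTI + events TSV +
voxel-metadata TSV) reuses the full analysis stack but expects preprocessed,
ROI-labeled inputs; anatomical atlas construction, preprocessing and
meta-analytic peak labeling are out of scope.
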
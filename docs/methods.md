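# Methods

`calmito` implements the analysis chain for live imaging of human enteric
(submucous-plexus) neurons: calcium-transient detection from Fluo-4
time-lapse movies, 3D mitochondrial morphometry and membrane-potential
fluctuation analysis from TMRE stacks, and the paired patient/control
statistics used to compare the two groups. Because no patient recordings
are distributable, every stage is exercised against a synthetic-data
generator whose ground truth is known exactly; this note records the
models, the defaults and why, and what the synthetic benchmarks do and do
not demonstrate.

## Calcium pipeline

**Model.** A movie is a (T, Y, X) single-channel stack with a frame
interval and a list of labelled stimulus windows (high-K+ depolarization,
DMPP, electrical stimulation). Neuron ROIs are supplied, not segmented:
the analysis mirrors practice where ROIs are drawn by hand over each soma.

**Registration.** Perfusion and tissue drift are modelled as a global
rigid translation; each frame is registered to frame 0 by phase
cross-correlation with 10x subpixel upsampling and translated back with
linear interpolation (edge padding). Shifts above 20% of the image width
raise a warning, never an error — such recordings are usually unusable,
but that judgement belongs to the analyst. Registration of an
already-registered movie yields shifts below 0.5 px (idempotence, tested).

**Traces and normalization.** The trace of an ROI is the per-frame mean
over its pixels. F0 is the mean over a baseline window (default: all
frames before the first stimulus; it must not overlap a stimulus), and the
trace is expressed as the ratio F/F0, so the resting level is 1 and a
transient of amplitude a% peaks at 1 + a/100. All downstream decisions are
scale-invariant: multiplying the raw movie by any constant changes nothing
(tested as a property).

**Intrinsic noise.** The noise level sigma is the standard deviation of
the baseline ratio after removing a linear trend, so a slow bleach ramp
does not inflate it; a robust variant (1.4826 x MAD) is selectable for
baselines contaminated by spontaneous events. The baseline must hold at
least 10 frames; at the default 2 Hz and a 20 s pre-stimulus baseline it
holds 40.

**Transient call.** A neuron is a responder to a stimulus when its ratio
peak inside the evaluation window *strictly exceeds* 1 + 5 sigma; a peak
exactly at threshold is a non-responder. The evaluation window is the
stimulus window plus a 10 s tail (transients outlast a 10 s stimulus
application); the peak time is the first frame attaining the maximum. The
maximum amplitude is (peak − 1) x 100, in %ΔF/F0. Raising sigma can only
demote responders, never promote (tested). The per-stimulus summary
reports % responders and the mean maximum amplitude; the amplitude mean is
taken over **all** analysed neurons by default, with a switch to
responders-only, since published summaries rarely state the denominator.
Subjects, not neurons, are the statistical unit: neuron-level calls are
averaged per subject before any group test.

## Mitochondrial (TMRE) pipeline

**Correction.** Background is a per-stack scalar — the 5th percentile of
in-mask intensities — subtracted and clipped at 0. Photobleaching is
corrected by rescaling each frame's global mean to frame 0's, under the
acquisition-order assumption that the first image is the brightest;
factors are clipped to >= 1 and made monotone non-decreasing by a
cumulative-maximum projection, so apparent re-brightening is treated as
fluctuation rather than dye recovery. On a synthetic 1%/frame decay the
recovered factors match the true decay to <0.5%.

**Volume detection.** Absolute intensity thresholding inside the ganglion
mask; volume = supra-threshold voxel count x voxel volume (anisotropic
voxels supported, all geometry in µm). The volume ratio is mitochondrial
volume over mask volume, in [0, 1].

**Threshold default.** The default absolute threshold is 0.55 x the median
detected spot-centre intensity (fallback: 0.55 x the in-mask 99.9th
percentile when no spots are available). Anchoring on spot centres — the
blurred object peaks — makes the default independent of how densely the
mask is populated; a plain intensity percentile is not, because the
quantile slides along the blob shoulder as the supra-background fraction
changes. The factor 0.55 was calibrated once on PSF-blurred synthetic
ground truth (the deconvolution parameters of the original acquisition
software are unpublished, so detection is tuned on simulated truth
instead): across 40–300 simulated mitochondria per stack and several
seeds it keeps total and mean volumes within ±10% of truth. It remains a
resolution-limited compromise — for objects much larger or smaller than
the ~0.5 µm default radius the threshold should be set explicitly.

**Spot detection.** Local maxima of a negated Laplacian-of-Gaussian
response at scale log_sigma_um (default 0.5 µm ~ expected mitochondrion
radius; plausible range 0.3–1 µm), converted per axis to voxels so the
filter is isotropic in physical space. The truncated discrete LoG kernel
does not sum exactly to zero, so a constant image leaks a small DC
response; that leak is cancelled exactly before peak finding. Candidates
must exceed an intensity floor (default 0.25 x in-mask p99.9) and are
thinned greedily by decreasing response with a minimum physical separation
(default 1 µm, KD-tree). Density is #spots per 1000 µm³ of mask volume.

**Single-mitochondrion volumes.** Supra-threshold voxels are partitioned
into 26-connected components; any component holding more than one detected
spot centre is split by an intensity watershed seeded at those spots.
The mean component volume is the reported per-subject statistic.

**Top-N selection and tracking.** Spots are ranked by centre intensity
(ties broken by (z, y, x) centroid order, so selection is deterministic)
and the brightest N (default 500) are tracked. Tracking is greedy
nearest-neighbour: spots are re-detected on every frame and each live
track links to the nearest unclaimed detection within a gate (default
1 µm/frame); a track that misses a frame is dropped entirely, because a
partial series would bias the fluctuation statistic. No merge/split
handling — mitochondrial fission/fusion topology is out of scope.

**Fluctuation score.** Per tracked mitochondrion, the intensity is sampled
as the mean over a 0.5 µm-radius sphere around the tracked centre;
variation_pct(t) = 100 x (I(t) − mean_t I)/mean_t I, and the score is its
population (ddof=0) standard deviation — i.e. the temporal coefficient of
variation in percent. For a sinusoidal modulation of relative amplitude a
over whole periods the score is 100a/sqrt(2), which the tests verify in
closed form. The subject-level value is the mean score over tracked
mitochondria. CV% is this package's declared convention for "intensity
fluctuation"; the statistic used by the original commercial software is
not published.

**Dilution arithmetic.** A helper converts injection/target volumes
(nl/µl/mm³, 1 mm³ = 1 µl = 1000 nl) to the dimensionless dilution factor
target/injected — the sanity computation that a ~150 nl TMRE injection
dilutes ~40-fold into a 6 mm³ biopsy and ~3.3e3-fold into a 500 µl bath.

## Synthetic-data generator

**Calcium movies.** Somata are hard disks (radius 4 px by default) placed
on a jittered grid that guarantees non-overlap; a field too small for the
requested count is an error. A configurable fraction of neurons are
responders — realized as an exact count, round(fraction x n), so the
simulated truth equals the nominal fraction rather than a binomial draw
around it. Responder kinetics are instantaneous rise at stimulus onset to
baseline x (1 + A/100) with single-exponential decay (tau default 5 s);
amplitudes are N(mean, sd) clipped positive; non-responders are flat.
Noise is additive Gaussian per pixel (Poisson shot noise optional, default
off); drift is a global rigid translation accumulated per frame — exactly
what registration-to-first-frame can undo. Defaults follow the emulated
protocol: a 10 s high-K+ window after a 20 s baseline, 2 Hz, 120 frames.
Frame rate and bit depth of the real recordings are unreported; these
defaults are configurable stand-ins, not claims.

**TMRE stacks.** Ellipsoidal mitochondria (per-axis radii N(0.5, 0.08) µm)
are placed uniformly inside a ganglion ellipsoid, optionally with a
minimum separation, and rasterized by a voxel-centre test on an
anisotropic grid (default (0.5, 0.25, 0.25) µm). Ground-truth volumes are
the rasterized voxel counts — what a perfect segmentation of the unblurred
image would measure. Per-mitochondrion intensity follows an independent
mean-reverting (Ornstein–Uhlenbeck) process, mean 1, stationary SD =
CV/100, AR(1)-discretized with correlation time tau (default 5 s — short
enough that a minutes-long recording holds many decorrelation times, as
the visibly dynamic recordings suggest; the true process is unknown).
Bleaching multiplies the signal by (1 − r)^t; the constant background
(detector offset and stray light) does not bleach. The PSF is a Gaussian
blur (default sigma (0.6, 0.25, 0.25) µm). With bleach and background off,
total frame intensity is conserved up to the fluctuation modulation
(tested).

**What the generator does not emulate:** optical sectioning artifacts,
dye-diffusion gradients, tissue autofluorescence texture, neuron/ganglion
morphology beyond disks and ellipsoids, detector nonlinearity. Passing the
recovery benchmarks therefore shows the algorithms are correct and
calibrated under the stated forward model, not that they are robust to
every property of real tissue.

**Subject-level cohort simulator.** For statistical calibration, paired
cohorts are generated directly at the per-subject summary level. Pairing
is a shared pair effect: value = mean + shift(PD) + s(sqrt(rho) z_pair +
sqrt(1−rho) z_subject), clipped to the metric's range, giving a
paired-difference SD of s sqrt(2(1−rho)). Defaults: responder-% mean 57.3
with between-subject SD 20 and pair correlation 0.5 (the pairwise
recruitment of household partners exists precisely to cut within-pair
variance; the larger spread of the real cohort also carries disease
heterogeneity the simulator does not model). Clinical covariates (age,
SCOPA, UPDRS-III off, disease duration) are drawn with PD/control offsets
matching the cohort being emulated.

## Statistics

**Paired Wilcoxon signed-rank.** Zero differences are dropped (n reported
after dropping). For n <= 15 the two-sided p is exact: the null
distribution of the positive-rank sum is built by polynomial convolution
over the observed (average) ranks — doubled so tied half-ranks stay
integer — and p = min(1, 2 min(P(W <= w), P(W >= w))); this is valid under
ties because it conditions on the observed |differences|. The test suite
verifies exact agreement with a brute-force 2^n sign enumeration on random
data. For n > 15 the normal approximation with tie correction (scipy) is
used. "Paired Wilcoxon" is the within-pair signed-rank test;
Mann–Whitney is available for unpaired sensitivity checks.

**Chi-squared on 2x2 tables.** Uncorrected Pearson,
n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), df = 1. The continuity correction is
deliberately off: the cohort's gender table [[4,11],[11,4]] yields
chi² = 6.533, p = 0.0106 (printed 0.01), whereas Yates' correction gives
0.03 and does not reproduce the printed value.

**Spearman correlation.** Pearson on average ranks; two-sided p from the
t approximation on n − 2 df (p = 0 at rho = ±1). Invariant under strictly
monotone transforms of either variable (tested). Pearson on raw values is
available by flag; the nonparametric test is the default because the
normality gate, not the analyst, should decide.

**Normality gate.** Shapiro–Wilk on each group's values (3 <= n <= 50);
the paired comparison uses Wilcoxon when either group rejects at 0.05 (or
is degenerate), the paired t-test otherwise. The gate's type-I rate and
power are themselves verified by simulation in the test suite.

**Multiple testing.** Bonferroni within each declared family:
the calcium family (per-stimulus %responders and amplitude, m = 2 per
stimulus set analysed) and the mito family (volume ratio, density, mean
single volume, fluctuation score, m = 4); each metric's Spearman
correlations against the four clinical covariates form a family of m = 4.
Family sizes are logged in the results table via the corrected p.

**Orchestration.** `run_cohort_comparison` validates the pairing (exactly
one PD and one control per pair), runs the gated paired test per metric
with family correction, correlates each PD metric with the covariates, and
returns a tidy results table. Identical groups (all differences zero)
produce a "degenerate" row with p = NaN, flagged not significant — no
evidence is not evidence of difference.

## Benchmark problem sizes

The packaged benchmarks use: 200 neurons for calcium recovery (responder
fraction 0.6, amplitudes ~20% against a ~1.4% detection threshold); a
(40, 224, 224)-voxel single-frame stack with 300 mitochondria separated by
>= 2.5 µm for morphometry; a (100, 14, 72, 72) stack of 40 mitochondria at
8% CV for fluctuation; and 200 replicate 15-pair cohorts for calibration.
These sizes give sampling error comfortably below the tolerances being
checked while keeping a full run in tens of seconds on one core.
Measured on these benchmarks: responder fraction recovered exactly,
amplitude bias < 1%, spot count and density within a few percent, mean
single volume within ~10%, fluctuation CV within ~5% relative; the null
cohort's Bonferroni-corrected significant-call rate ~1.7% and power for a
20-point shift ~95%.

## Known limitations

- Translation-only registration; rotation or non-rigid tissue deformation
  is not corrected.
- The volume threshold, LoG scale and spot floor are calibrated for
  sub-micron mitochondria at the default voxel sizes; strongly different
  geometries need explicit settings.
- Greedy tracking has no occlusion or merge/split handling; it is adequate
  for quasi-stationary mitochondria, not for fast directed transport.
- Exact Wilcoxon is limited to n <= 15 (the intended cohort scale);
  beyond that the normal approximation is used.
- TMRE intensity is reported in arbitrary units; no conversion to
  millivolts of membrane potential is attempted.
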
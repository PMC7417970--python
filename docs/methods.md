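# Methods

This note documents the models, numerical choices and limitations behind
`wpet`, in the order the pipeline runs.

## Phantom worlds

All validation runs on synthetic phantoms born directly in a shared
isotropic analysis space (default 48×56×48 voxels at 3 mm), so spatial
normalisation and registration are bypassed by construction.

**Template.** The cerebrum is an ellipsoid with a WM core and a GM shell;
deep grey nuclei (thalamus, basal ganglia) and insular blobs are carved
out of the core as GM, and a separate inferior-posterior ellipsoid forms
the cerebellum. Tissue indicator masks are blurred with a small gaussian
(1.2 voxels FWHM-equivalent) to produce probability maps; because the
indicators are disjoint, GM+WM+CSF ≤ 1 holds everywhere by linearity.
The atlas assigns 12 named parcels (frontal, temporal, parietal,
occipital, peri-Rolandic, central operculum, precuneus, insula, thalamus,
basal ganglia, residual cortex, cerebellum) on the unblurred tissue masks,
so every labelled voxel carries tissue probability. Parcel centres are
jittered by at most one voxel from the seed: worlds differ across seeds
while the geometric invariants hold deterministically.

**Cohorts.** Noise-free uptake for a subject of age *a* is
`(intercept + slope·a) · gm_prob`, defaults 100 a.u. and −0.5 a.u./year
over ages 30–65 — a linear age decline of cortical metabolism.
Carrier lesions multiply uptake inside named atlas regions; the defaults
place hypometabolism of 20–30% in thalamus, basal ganglia, insula and
frontal cortex and +6% focal hypermetabolism in the peri-Rolandic parcel,
inside the ranges such cohorts report. The image is then blurred at the
acquisition FWHM (5.5 mm) and gaussian voxel noise (default SD 2 a.u.) is
added. Blur precedes noise deliberately: noise models post-reconstruction
variability, and this ordering keeps PVC recovery testable (deconvolving
the blur must recover the pre-blur truth). Modulated GM-volume images are
`gm_prob · (TIV / reference TIV)` with multiplicative regional atrophy
(default −20%), a 2 mm segmentation blur and small noise (SD 0.01).

**Covariates.** Cohort sizes default to 25 controls vs 17 carriers. CSF
neurofilament markers are lognormal (skewed, strictly positive); carriers
draw NfL from a two-component mixture whose elevated component
(median 1600 pg/mL, 19% weight) puts a minority above the 1227 pg/mL
cutoff, while pNfH stays within the reference range for everyone. ECAS
subdomain scores are gaussian around their normative means; 29% of
carriers have one subdomain displaced 2.5 SD below the mean, i.e. below
the 5th-percentile threshold. Upper-motor-neuron signs occur in 59% of
carriers. Female fractions default to 0.71 (carriers) and 0.48
(controls).

**What the phantoms do not emulate.** No cortical folding, no
between-subject biological variability in regional metabolism beyond the
age trend, no scanner drift, no motion, no registration error. The main
visible consequence: group-comparison t values on phantoms are far larger
than on real cohorts (noise is the only variance source and smoothing
suppresses most of it), so passing tests demonstrate correctness of the
estimators and calibration of their error rates — not realistic power.

## Partial-volume correction

The PSF is an isotropic gaussian; `sigma = fwhm / (2·sqrt(2·ln 2))`,
reflect boundary handling, and `fwhm = 0` is the exact identity.

**WM activity.** The homogeneous WM activity is the origin-constrained
least-squares slope of observed PET on the PSF-blurred WM probability over
voxels with WM probability > 0.95. Whether to include an intercept is a
genuinely open choice; the origin-constrained form is standard
Müller-Gärtner practice and is pinned by a forward-simulation test
(WM at activity 2.0, blurred at 5.5 mm, recovered within 2%).

**Müller-Gärtner.** For voxels with GM probability ≥ 0.3:
`corrected = (pet − wm_activity·blur(wm_prob)) / blur(gm_prob)`. All other
voxels — and included voxels whose blurred GM probability falls below
1e-6 — are carried as NaN, never zero-filled, and counted in a report, so
downstream masks stay honest. MG corrects GM↔WM cross-talk but not
within-GM spill across an activity boundary; regional quantification of a
focal lesion therefore reads the region's GM core (boundary voxels
eroded) rather than voxels at the lesion edge.

**GTM.** Regions are the atlas labels plus a WM compartment (WM
probability > 0.5 outside any label). The transfer matrix holds the mean
of each blurred region indicator over each region; solving `W t = o`
yields corrected means. Matrices with condition number above 1e8 raise,
reporting the condition number.

## Preprocessing

The analysis mask is `mean GM probability > 0.1` (strict: a voxel at
exactly the threshold is excluded) minus the occipital parcels, which are
excluded from every comparative analysis. The pooled (both-group) mean GM
map is used; control-only was the alternative, and the choice is
documented here because the downstream statistics are insensitive to it
at phantom effect sizes. Proportional normalisation divides by the
in-mask mean, so the in-mask mean is exactly 1 (not the grand-mean-50
convention; downstream statistics are scale-invariant, so this is
cosmetic). SUVR divides by the mean over cerebellar labels. Smoothing
defaults to 8 mm FWHM; inside a mask it is normalised convolution (blur
of the zero-filled image divided by blur of the valid-voxel indicator),
which preserves constants and provably propagates nothing across the mask
boundary — verified by placing an impulse in the excluded occipital label.

## Voxelwise inference

Per-voxel OLS with an intercept, a carrier indicator, centred age, and
(for the volumetric analysis) centred TIV; the VBM path reuses the same
code with TIV added — no separate implementation. One-sided contrasts
follow the declared direction of each hypothesis. Height threshold:
upper-tail t quantile at p < .001 with the model's residual df. Clusters:
18-connectivity (faces + edges, the common neuroimaging convention;
configurable to 6/26 — the convention used upstream is not always
reported, so it is explicit here), extent filter 150 voxels.

Cluster-level FWE uses a max-cluster-size permutation test rather than
random-field theory: assumption-light and exactly testable on phantoms,
while preserving the same inferential target (cluster-corrected p < .05).
Nuisance effects are handled by Freedman–Lane residualisation: the data
are residualised against the nuisance columns, residual rows are
permuted, the full model is refit. Corrected p uses add-one smoothing,
`(1 + #{perm max ≥ observed size}) / (1 + n_perm)`, which keeps the test
valid at finite n_perm (and slightly conservative). The permutation seed
is mandatory and echoed in output provenance. The empirical FWER is
checked on 200 null phantom cohorts × 500 permutations on a reduced grid
(16³ voxels, 10 vs 10 subjects, 8 mm smoothing); that check uses a height
threshold of p = .01 and extent 1 so the null max-cluster-size
distribution is rich enough for a meaningful rate estimate — at p = .001
with extent 150, null clusters essentially never form and the estimate
degenerates to 0 without this saying anything about calibration.

`percent_difference` is `100·(control mean − carrier mean)/control mean`
over a supplied voxel set on normalised (unsmoothed) images; over a whole
cluster it understates a focal lesion because clusters span halo voxels,
so recovery checks read the lesioned region's GM core.

## W-scores

Per-voxel OLS of control intensity on age; residual SD uses n − 2 df (the
model's residual df; with n in the hundreds the n vs n−2 distinction is
invisible, and the null-calibration test pins the behaviour). W for a
subject is `(raw − predicted-for-age) / residual SD`. Thresholds are
boundary-inclusive: hypometabolic maps flag W ≤ −1.96, hypermetabolic
maps W ≥ +1.96; 1.96 bounds the central 95% mass of a standard normal.
Frequency maps are voxelwise counts and fractions of flagged subjects.
Zero residual SD makes W undefined and is an error at fit time;
`on_zero_sd="nan"` marks such voxels undefined instead, which is what the
noise-free recovery tests use to inspect the coefficients. Whether a
subject "shows abnormality in a region" counts any suprathreshold in-mask
voxel of that region by default (a minimum-count rule can be applied to
the per-region counts the pipeline writes). W-scores are computed on
normalised, PVC-corrected, smoothed images, mirroring the group-analysis
order; the functions are order-agnostic.

Calibration: with 500 controls and held-out null subjects from the same
generative model, the per-side exceedance of W ≤ −1.96 is 2.5% up to a
factor `sqrt(1 + 1/n + (a−ā)²/S_aa)` ≈ 1.002 of prediction-error
inflation — well inside the ±0.3 percentage-point band the acceptance
check uses.

## Regional and clinical statistics

Regional group tests are a one-sided linear-model contrast on the carrier
indicator with centred age as covariate (the exact upstream statistic for
VOI confirmation tables is typically unreported; this covariate-adjusted
contrast is the assumption made here, cross-checked against statsmodels).
Benjamini–Hochberg is the classic step-up rule, implemented directly
because the rejected index set is the contract, and cross-checked against
statsmodels' `fdr_bh`.

Chi-square is Pearson's without continuity correction — pinned by
reproducing the 2.11 (sex) and 0.37 (education) values from the reference
cohort's 2×2 count tables; with Yates' correction those become 1.29 and
0.08, so the uncorrected form is unambiguous. Mann–Whitney uses mid-rank
U; for samples of at most 8 each, the p-value enumerates all group
assignments exactly (valid under ties); larger samples use the normal
approximation with tie correction and a 0.5 continuity correction.
Neurofilament flags are strict inequalities ("surpassing" the cutoff):
1227 pg/mL exactly is not elevated. ECAS abnormality uses the normal
quantile of supplied norms (score < mean − 1.6449·SD for the 5th
percentile), since the underlying normative tables are a config input,
not a distributable.

One-sided test directions must be declared; the cohort summary table
reports two-sided Mann–Whitney p-values for transparency.

## Pipeline

Stages (`simulate → pvc → preprocess → glm → wscore → voi → clinical →
report`) communicate only through files in the run directory, so any
stage re-runs reproducibly from cached inputs. Config validation requires
every threshold key to be present before any compute; all defaults are
the analysis values above. All NIfTI outputs carry the template affine
(grid centred at the world origin); voxel indices are 0-based in code.
Failures abort with the stage name and offending subject id; the CLI maps
validation errors to exit code 2 and runtime failures to 3.

## Problem sizes

Defaults are desk-scale by design: the full pipeline on the default
48×56×48 grid with 42 subjects and 1000 permutations runs in well under
15 minutes on one CPU; the FWER calibration uses a 16³ grid, and the
W-score calibration a 24³ grid with 500 controls and 200 null subjects
(≈2.8 million voxel-subject draws, Monte-Carlo SE ≈ 0.01 percentage
points).
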
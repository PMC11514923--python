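# Methods

This note documents the models, the synthetic data, the numerical
choices and the known limitations of `qt1bbb`.

## Signal model and T1 estimation

The spoiled gradient-recalled echo (SPGR) steady-state magnitude at flip
angle α, repetition time TR and longitudinal relaxation time T1 is

    S(α) = M0 · sin α · (1 − E1) / (1 − E1 cos α),   E1 = e^(−TR/T1).

M0 lumps proton density, receive sensitivity and the fixed-TE T2\*
factor; TE (default 6.7 ms) is carried as metadata only. The default
acquisition is TR = 16.4 ms with flip angles {4°, 10°, 18°, 25°}. The
schedule is configurable; the default brackets the Ernst angle of
~1000 ms tissue at this TR (≈ 10.4°), which balances slope leverage for
grey- and white-matter T1 at 3 T.

T1 and M0 are estimated voxelwise by the DESPOT1 linearization
S/sin α = E1 · (S/tan α) + M0(1 − E1): an ordinary least-squares line in
the transformed coordinates (the exact two-point solution when only two
angles exist), T1 = −TR/ln(slope). Voxels with any non-positive signal,
slope outside (0, 1), or T1 outside a plausibility window (default
50–10000 ms) are masked invalid; invalid voxels propagate through all
downstream stages and are never interpolated.

Noise behaviour: at additive Gaussian noise with SNR 50 (σ = mean
signal / 50) the median absolute relative T1 error of the linearized fit
is ≈ 2.6% with this schedule — indistinguishable from a full nonlinear
maximum-likelihood fit, i.e. at the information limit — with no
systematic bias. Rician magnitude bias is neglected (high-SNR regime);
the simulator offers additive Gaussian noise clipped at zero. B1
inhomogeneity is not modelled: flip angles are taken as nominal, which
in vivo would scale T1 estimates regionally; the subtraction biomarkers
divide much of this out but a B1 map would be required for absolute
accuracy.

## Digital phantom

The phantom is schematic: ROI identity, disjointness and adjacency
matter for the analysis; shape fidelity does not. On a 64³ grid at 1 mm
(configurable, ≥ 32³):

* head ellipsoid — cortical shell (T1 1300 ms) over white matter
  (850 ms) with a central CSF blob (4000 ms);
* paired interior blobs for hippocampus (1350 ms), amygdala (1330 ms)
  and piriform cortex (1320 ms), radius floor 2 voxels so every ROI
  keeps ≥ 30 voxels at the smallest grid;
* the superior sagittal sinus (SSS): a 3×3 voxel blood column
  (1650 ms) spanning exactly three consecutive coronal slices at the
  superior midline, matching how a vascular reference ROI is drawn on a
  few slices in practice.

A smooth multiplicative T1 texture field (Gaussian-filtered white noise,
correlation length 3 voxels, SD 4%, seed-deterministic) is applied
inside the head and demeaned within every labelled region, so each
ROI-mean baseline T1 equals its nominal tissue value exactly. The
texture exists because a piecewise-constant ellipsoid leaves the rigid
pose of the subject nearly unidentifiable to intensity-based
registration; real parenchyma is textured.

**Contrast.** Gadolinium enters as fast-exchange relaxivity,
1/T1_post = 1/T1_pre + r1·C with r1 = 5 L·mmol⁻¹·s⁻¹ (literature
gadobutrol at 3 T; the dose actually injected in such protocols pins
neither the scan-time blood concentration nor r1, so the vascular
concentration c_vasc is a free parameter, default 0.5 mmol/L for both
post-contrast sessions, separately configurable to emulate
injection-to-scan latency differences). BBB dysfunction is a leakage
fraction λ ∈ [0, 1] per ROI and session: parenchymal concentration
λ·c_vasc. This is deliberately the simplest mechanism that produces
ROI-specific T1 shortening; full pharmacokinetic (Tofts-type) modelling
is out of scope.

**Sessions.** The noncontrast session is the baseline plus voxel noise
(multiplicative Gaussian, default SD 1% of T1). Each post-contrast
session is rendered *analytically* in a random rigid pose (uniform
translation ≤ 2 mm and rotation ≤ 2° per axis by default): labels, T1
and contrast are evaluated at the displaced coordinates, so the
acquired volume is sharp on its own grid exactly as a scanner acquires
a moved subject. (An earlier design resampled the canonical volume,
which adds an interpolation blur no real acquisition has and biases
subtraction maps; see below.) Ground truth records the noiseless
canonical-frame per-ROI mean ΔqT1 for both map kinds, including the SSS
reference values.

## Registration

6-DOF rigid registration (3 rotations about the volume center, 3
translations) by Powell's method over a 3-level Gaussian pyramid
(factors 4/2/1), maximizing normalized cross-correlation by default
(gadolinium changes absolute intensities between sessions; MSE is
available for same-contrast problems). Resampling is trilinear with
validity masks propagated nearest-neighbour; out-of-field voxels are
invalid. Cubic/sinc interpolation was evaluated and rejected: spline
ringing worsens eroded ROI means on high-contrast boundaries, and the
recovery property shows trilinear is sufficient.

One subtlety matters. The moving image is compared, after one
interpolation, against a sharp fixed image; trilinear interpolation
ripple then rewards grid-aligned poses over truly aligned ones (biases
up to ~0.65° on this phantom). Both images are therefore smoothed
equally (σ = 1.5 voxels) at the finest pyramid level before cost
evaluation — the standard remedy. With texture and matched smoothing,
worst-case recovery over 20 seeded perturbations (≤ 4 mm, ≤ 4°, 3%
noise) is ≈ 0.1 voxel and ≈ 0.2°, against a tolerance of 0.3 voxel /
0.6°. Optimizer caps (20/10/4 Powell cycles per level, xtol 0.02 in
mm/deg) keep one registration at a few seconds on one CPU without
touching this accuracy.

## Subtraction biomarkers

ΔqT1_ni = noncontrast − interictal and ΔqT1_ip = interictal − postictal,
computed voxelwise on the noncontrast grid after registration, valid
mask = AND of the inputs. Each map is then divided by its mean over the
SSS mask — "normalization" is read as division, which makes the
biomarker a dimensionless fraction of the vascular enhancement and
cancels between-subject differences in circulating gadolinium; an
|SSS mean| below 10⁻⁶ of the map's dynamic range raises an error
(no measurable vascular contrast to normalize by). Normalization
happens after registration and subtraction, on the noncontrast grid.

ROI readout reports mean and sample (n−1) SD over valid voxels, per
hemisphere or pooled; empty ROIs yield explicit missing values, never
silent zeros. The whole-cortex label excludes hippocampus and amygdala
by construction. The pipeline reads ROIs on masks eroded by one voxel
(configurable): the registered session is interpolated once, so the
outermost voxel shell of every ROI mixes tissue with its surround, and
at small-ROI scale that shell alone shifts raw means by tens of ms.
With erosion, a noiseless perturbed subject with 10% piriform leakage
reads back its ground truth within 0.2% and null ROIs within ~2 ms.
The SSS reference is never eroded (it is only 3 voxels wide); its
~10–15% partial-volume underestimate is a pure scale factor common to
all of a subject's maps. Subjects with unknown seizure-onset side are
excluded from side-specific (ipsilateral) analyses.

## Cohort simulation

Two generators exist. The volumetric route runs phantom subjects
through the full imaging pipeline (used for the 8-subject demo cohort
and end-to-end checks). The summary-level generator draws per-subject
per-ROI biomarker values directly and is used for statistical
calibration at scale:

    value = baseline + lateralized group/ROI effect + slope·duration
            + subject intercept + noise.

Covariate structure mirrors a 37-subject epilepsy cohort: 14 TLE / 23
ETLE; duration of epilepsy lognormal, median ≈ 14 y, clipped to
[2, 44]; injection-to-scan latencies lognormal, median ≈ 34.6 min,
clipped to [18, 266], postictal matched to interictal; onset side
left/right/unknown with probabilities 14/37, 14/37, 9/37; memory scores
normal around 90 (verbal) and 88 (figural) with SDs 12/13 on the
normative 100/10 scale. Effects load fully on the ipsilateral
hemisphere and half contralaterally; memory scores shift −8 for
side-concordant subjects (left→verbal, right→figural), which induces
the memory–biomarker association without a separate dial. Default
effect sizes (TLE piriform +0.025, TLE hippocampus +0.028, ETLE
hippocampus +0.024 normalized units against noise SD 0.02) put Glass' Δ
near 1.3 — the scale of reported clinical effects. The power scenario
uses a TLE-only piriform effect of 0.04, calibrated once by pilot
simulation to give ≥ 90% Dunn-adjusted rejection at n = 14 while the
ETLE comparison stays null.

What the generator does *not* emulate: anatomical shape, B1/coil
profiles, motion within a session, perfusion/kinetic time courses,
partial-volume mixtures at acquisition resolution, and any relationship
between dose, latency and c_vasc beyond independent configuration.
Passing tests therefore validate the pipeline's arithmetic, estimator
calibration and inferential behaviour — not clinical effect sizes on
real anatomy.

## Statistics

* Kruskal–Wallis with mid-rank ties and chi-square p (k−1 df); the
  all-identical degenerate case is defined as H = 0, p = 1. ROIs
  measured within the same subjects are compared unpaired, replicating
  the published workflow this pipeline models; a paired Wilcoxon
  variant exists but is off by default.
* Dunn's post hoc z on pooled mid-ranks with the tie-corrected variance,
  two-sided normal p, Bonferroni adjustment capped at 1 (Holm
  available). Bonferroni-with-capping is chosen because reported values
  in this workflow hit exactly 1.0.
* Glass' Δ = (mean(ROI) − mean(cortex)) / sampleSD(cortex), |Δ| > 0.8
  flagged large. The raw estimator is reported by default; a
  Hedges-type small-sample correction (`small_sample_correction=True`)
  is available and is the variant whose unbiasedness the tests assert
  (the raw estimator is biased away from zero by ~6.5% at n = 14 —
  an estimator property, not an implementation artifact).
* OLS via statsmodels with ROI treatment-coded against whole cortex, so
  interaction coefficients read directly as slope differences from
  cortex; rank-deficient designs are refused with the aliased columns
  named. The interictal latency enters ΔqT1_ni models and the postictal
  latency ΔqT1_ip models (the natural pairing; the convention is a
  configuration point).
* Memory impairment: standardized score < 90, strictly.
* No correction across scenario analyses, matching the modelled
  workflow (and its acknowledged limitation).

Scenario driver outputs are invariant to input row order; scenarios
with unmet prerequisites (e.g. < 3 impaired subjects per ROI cell) are
skipped with a logged reason.

## Determinism and numerical conventions

Every stochastic stage takes an explicit seed; fixed seed ⇒ bit-identical
volumes, tables and CSVs (the cohort pipeline's config snapshot replays
byte-identically). Voxel indices are 0-based; world coordinates via the
NIfTI affine; rotations in degrees about the volume center. Invalid
voxels are NaN-coded in NIfTI output so masks round-trip without side
files. Tie-breaks in ranking use mid-ranks throughout.

## Known limitations

* Rigid-only registration; no nonlinear warp, no inter-subject space.
* No B1 correction and no Rician likelihood in the T1 fit.
* The SSS reference is partial-volume attenuated (~10–15% at 3-voxel
  width); comparisons are unaffected but absolute normalized values are
  inflated by the same factor.
* The leakage model is static; no dynamic (DCE) kinetics.
* Summary-level cohort simulation assumes Gaussian noise and linear
  covariate effects; heavy-tailed clinical data may behave differently.
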
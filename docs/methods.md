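# Methods

## Scope and measurement model

`onhmorph` quantifies retinal ganglion cell axon-related structure at
the optic nerve head (ONH) from *segmented* OCT surfaces: the inner
limiting membrane (ILM), the posterior nerve fibre layer (NFL)
boundary, Bruch's membrane (BM) with its opening, the prelamina
anterior (cup) surface and the anterior lamina cribrosa (LC) surface,
plus labelled BM-opening (BMO) termination landmarks. Segmentation of
raw OCT intensities is out of scope; surfaces and landmarks are inputs.

All measurements are referenced to the **BMO plane**, the
total-least-squares plane through the termination landmarks (SVD of the
centred landmark matrix; degenerate configurations — fewer than six
points, collinear or coincident landmarks — are rejected). The BMO
centre is the landmark centroid projected onto the plane. The volume
is resliced radially at 45° around the centre into four sections /
eight half-meridians labelled S, SN, N, IN, I, IT, T, ST. Labels are
anchored anatomically: the canonical frame is a right eye (+x temporal,
+y superior); left eyes are mirrored nasal↔temporal before labelling so
regions pool anatomically.

Reslicing samples each surface **along the plane normal** at in-plane
radii `0, h, 2h, …` in each region direction (`h` = lateral grid
pitch). The depth of a height-map surface along an oblique normal line
is solved by fixed-point iteration on the bilinear interpolant
(contraction for clinically plausible tilts; stalled starts near a
surface-footprint boundary are retried from several plausible depths
before a sample is declared missing). Referencing depths to the plane
rather than to the scanner axis makes every quantity invariant to rigid
scan tilt, which the test suite exploits: a tilted phantom must
reproduce its untilted ground truth exactly.

Per half-meridian:

* **Border NFL** — distance from the termination to the ILM along the
  plane normal. The "vertical" direction is interpreted as the plane
  normal, not the scanner axis, so the index is tilt-invariant.
* **Peripapillary NFL (pNFL)** — ILM to NFL-posterior separation at
  1.7 mm in-plane radius from the BMO centre, measured perpendicular to
  the local NFL course (the normal-direction separation divided by
  `sqrt(1 + slope²)` with the mean local slope of the two boundaries).
* **MRW** — minimum Euclidean distance from the termination to the ILM
  curve within the section plane: discrete search over the sampled
  curve, continuous refinement on a cubic-spline interpolant, and the
  ILM point directly above the termination included as a candidate so
  that `MRW ≤ border NFL` holds by construction. A full 3-D minimum
  (`mrw_3d`) is available behind a flag; the per-section search is the
  standard measure.
* **MRA** — per region, the lateral area of the conical frustum strip
  swept by the MRW segment over the region's 45° arc:
  `area = (π/4)·d̄·w`, with `w` the MRW and `d̄` the in-plane distance
  from the BMO central axis to the segment midpoint. An axisymmetric
  ring (`w = 0.25 mm`, `d̄ = 0.8 mm`) therefore totals
  `2π·0.8·0.25 ≈ 1.2566 mm²`; a fine-angle (0.5°) quadrature of the
  swept surface guards this closed form in the tests.
* **Prelamina thickness** — anterior-LC depth minus prelamina-surface
  depth along the plane normal, at the BMO centre and at the eight
  midpoints between centre and terminations (9 values). Negative
  values (possible under segmentation noise) are clamped to 0 with a
  warning.
* **Prelamina volume** — `∫ depth_LC dA − ∫ max(depth_prelamina, 0) dA`
  over the BMO-projected area, i.e. the tissue volume between cup
  surface and anterior LC. Numerics: polar midpoint quadrature
  (default 160 radial × 240 angular nodes) with the opening radius
  interpolated periodically from the terminations. Area-weighted LC
  coverage holes above 5% raise an error; smaller holes are inpainted
  by nearest neighbour with a warning.

Missing values propagate as NaN, never as 0; family means are over
non-missing regions.

### Calibration

Transverse: Bennett's abbreviated scaling
`q = 0.01306·(AEL − 1.82) mm/deg` converts the scan angle (default 20°
over 512 pixels) to retinal millimetres; eyes with `AEL ≤ 1.82 mm` are
rejected as nonphysical. Axial: optical path per pixel divided by the
tissue group refractive index, default `n = 1.38` (retinal tissue),
configurable. Both are declared, documented choices for the generic
"axial-length and refractive-index corrected" calibration; no
ray-traced model eye is attempted.

## The phantom family

Surfaces are smooth and radially parameterised so that every regional
target has a closed form (z increases posteriorly; depths below the
BMO plane are positive):

* Angular profiles (rim height `h(θ)`, pNFL thickness `t(θ)`, prelamina
  mid-thickness `T_mid(θ)`) are the unique band-limited trigonometric
  interpolants of the 8 regional targets, so the interpolant passes
  exactly through each target at its meridian and its circular mean is
  the arithmetic mean of the 8 values.
* ILM: flat at `−h(θ)` outside the opening (optionally with constant
  radial slope `m`), cosine-blended into the cup inside, with zero
  radial slope at the termination and centre. Hence border NFL truth
  `= h(θ_k)`, MRW truth `= h/sqrt(1+m²)` (attained at
  `r = R + mh/(1+m²)` for `m ≥ 0`; verified against dense minimisation),
  and pNFL truth `= t(θ_k)/sqrt(1+m²)`.
* Prelamina anterior: cosine dome of central depth `cup_depth`;
  anterior LC: the dome plus the thickness field
  `T(u,θ) = T_c + (T_mid(θ) − T_c)·sin²(πu)`, `u = r/R`, so the centre
  thickness is `T_c = lc_depth − cup_depth` and the sector midpoints
  (`u = 1/2`) hit the regional targets exactly. The volume truth is the
  closed form `πR²·[T_c + (mean(T_mid) − T_c)/2]`
  (`∫₀¹ u sin²(πu) du = 1/4`), cross-checked by adaptive quadrature of
  the generating functions.
* Plane tilt is an exact rigid rotation about the superior–inferior
  axis, realised as a height map by numerically inverting the rotation
  per grid column; bounded surfaces are iterated on a clamped extension
  and masked afterwards so footprint boundaries stay exact. All
  plane-referenced truths are unaffected by tilt.

One deliberate idealisation: inside the opening the ILM is given its
own cosine blend down to the cup rather than being identified with the
prelamina anterior surface (anatomically the two coincide). Keeping
them separate keeps the MRW minimum well-posed at the termination and
every regional target closed-form.

Noise is an independent Gaussian perturbation of surface heights (not
voxel intensity noise — the measurements act on identified surfaces);
landmarks stay exact. After perturbation the anatomical ordering
invariants (NFL posterior ≥ ILM, LC ≥ prelamina) are restored by
clamping where both surfaces are defined. Voxel rasterisation exists
only as an optional labelled-TIFF export for demonstrations.

What the phantoms do **not** emulate: OCT speckle and shadowing,
vascular artefacts, segmentation bias, tilted-disc/peripapillary-
atrophy morphology, and BMO non-planarity beyond landmark noise.
Passing the oracle suite therefore demonstrates correctness of the
measurement geometry and statistics pipeline, not robustness to real
segmentation failure modes.

## The synthetic cohort

The generator emulates a cross-sectional POAG cohort with age-matched
controls: four stages (C, PG, EG, MAG) with per-stage covariate
distributions (age, mean sphere, IOP, axial length, CCT, ACD) matching
the demographic structure of such cohorts; two eyes per participant
sharing a participant-level random intercept (`inter_eye_sd`, default
0.020 mm) with per-eye residuals (`residual_sd`, default 0.015 mm);
stage effects applied as fractional thinning of the parameter-family
profiles; and VF mean deviation generated as
`baseline − coupling·(mean border-NFL deficit) + noise` (defaults
−0.4 dB, 55 dB/mm, 1.2 dB), which reproduces the qualitative stage
ordering of such cohorts (C ≈ PG > EG > MAG) and negative
structure-function correlations. Default stage effects (PG 6%/6%/15%,
EG 18%/15%/20%, MAG 45%/35%/30% for border-NFL/pNFL/prelamina families)
encode early prelamina compression followed by progressive rim and NFL
loss; they are qualitative study conditions, not fits to any dataset.
MRW/MRA derive from the rim geometry and prelamina volume from the
thickness field, so those families inherit their parents' effects
coherently. A `missing_eye_prob` knob (default 0: no published value
exists) drops second eyes.

Each eye's tabulated parameters are the *analytic morphometry of its
generated anatomy* — participant and eye noise enter at the profile
level — so the cohort table, any realised surfaces, and the measured
parameters are mutually consistent, and the per-eye ground truth is
exact by construction.

## Statistical pipeline

Per parameter: REML linear mixed model with participant random
intercept (statsmodels `MixedLM`; BFGS with Powell/Nelder-Mead
fallbacks; non-convergence raises with optimizer diagnostics; a
collapsed random-intercept variance, or a single-eye-only cohort, sets
a `singular` flag rather than failing silently). Backward stepwise
deletion drops the non-stage covariate with the largest p ≥ 0.05,
refitting between deletions, until all retained covariates are
significant; stage is the inference target and is never deleted.
Estimated marginal means are model predictions per stage at covariate
sample means; all six pairwise stage contrasts get studentized-range
(Tukey) adjusted p-values, floored at the unadjusted p so the
adjustment can never appear anti-conservative under floating-point
underflow.

Denominator degrees of freedom use the containment rule
(participants − fixed-effect rank), the classical choice for
between-participant effects, because stage and the candidate
covariates vary (almost) only between participants; a
Satterthwaite/Kenward-Roger approximation is not available in the
fitting backend. Monte-Carlo calibration in the acceptance suite shows
the resulting Tukey familywise error is at its nominal 0.05 under the
null generator. One test cross-checks the fit and the marginal means
against an independent R implementation (lme4 + emmeans) on the same
cohort.

Structure-function association is the pooled-eyes Pearson correlation
with VF MD, exactly as scatter-plot analyses pool eyes — a documented
limitation, since pooling ignores the inter-eye correlation for this
analysis. The correlation's sign is reported with both variables'
orientations explicit (thickness in mm against MD in dB, so coupled
thinning yields r > 0 between parameter and MD); no sign is asserted
against any external convention. Shapiro-Wilk (3 ≤ n ≤ 5000) screens
residual normality and is advisory only.

## Problem sizes and numerical defaults

* Phantom grids: 10 µm default, 5 µm for the geometric-oracle
  acceptance run, 20 µm for the 1000-phantom invariant sweep — sizes
  chosen so each check is decisive at desk scale.
* Volume quadrature: 160×240 default (80×96 in the invariant sweep);
  halving the grid changes smooth-phantom volumes well under 1%.
* Monte-Carlo calibration: 500 null replicates (familywise error and
  null covariate retention), 300 effect-recovery replicates, 150
  covariate-power replicates, 15 participants (30 eyes) per stage,
  matching the intended recovery checks.
* MRW refinement tolerance 1e-10 mm²; truth-side dense search 2001
  samples with parabolic vertex refinement, validated against a
  0.05-0.1 µm brute force.

## Known limitations

* The calibration constants (Bennett factor, tissue index 1.38) are
  standard published defaults, not device-specific reconstructions.
* The per-section BMO "plane" is fitted globally to all terminations;
  a per-tomogram two-point variant is noted but not implemented (the
  global fit is strictly more stable).
* pNFL is measured perpendicular to the local course; a scanner-axis
  variant would require only dropping the slope factor but is not
  exposed.
* Pooled-eyes Pearson correlations understate uncertainty in the
  presence of inter-eye correlation (kept deliberately, see above).
* The phantoms cannot produce MRW < border NFL by more than the rim
  slope allows; real cups with overhanging rims would, and are only
  covered indirectly by the noisy-curve invariant tests.
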
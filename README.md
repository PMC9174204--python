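# onhmorph

Optic-nerve-head (ONH) axonal morphometry from segmented OCT surfaces,
with a mixed-effects disease-stage analysis — aimed at researchers
quantifying retinal ganglion cell axon loss in glaucoma from
spectral-domain OCT volumes whose surfaces (ILM, posterior NFL
boundary, Bruch's membrane and its opening, prelamina, anterior lamina
cribrosa) have already been segmented.

## What it computes

All measurements are referenced to the Bruch's membrane opening (BMO)
plane — the total-least-squares plane through the BMO termination
landmarks — and the volume is resliced radially at 45° around the BMO
centre into 8 half-meridians (S, SN, N, IN, I, IT, T, ST). Per eye:

| family | definition | regions |
|---|---|---|
| border NFL | termination→ILM distance along the plane normal | 8 + mean |
| pNFL | ILM→NFL-posterior thickness at r = 1.7 mm, ⊥ to local course | 8 + mean |
| MRW | minimum termination→ILM distance in the section plane | 8 + mean |
| MRA | frustum strip (π/4)·d̄·w swept by the MRW segment per 45° arc | 8 + mean |
| prelamina thickness | LC depth − prelamina depth along the normal | 8 midpoints + centre |
| prelamina volume | ∫(depth_LC − max(depth_prelamina,0)) dA over the opening | scalar |

Pixel→mm calibration uses Bennett's abbreviated transverse scaling
q = 0.01306·(AEL − 1.82) mm/deg and an axial tissue refractive-index
correction (default n = 1.38).

The statistics layer mirrors how such cohorts are analysed: per
parameter, a REML linear mixed model `y ~ stage + covariates +
(1 | participant)` accounts for the inter-eye correlation of fellow
eyes; non-stage covariates (age, axial length, ACD, refraction, CCT,
IOP) are removed by backward stepwise deletion at p ≥ 0.05; stage
groups are compared via estimated marginal means with Tukey-adjusted
pairwise contrasts; structure–function association is the pooled-eyes
Pearson correlation with visual-field mean deviation (VF MD); and
Shapiro–Wilk screens residual normality.

Because no real scans ship with the package, a first-class synthetic
module generates parametric ONH phantoms (smooth radial surfaces with
closed-form regional ground truth) and whole two-eyed cohorts with
stage-dependent thinning and VF-MD coupling, so every operation is
testable against analytic oracles. See `docs/methods.md` for the
model, assumptions and numerical choices.

## Worked example

```python
from onhmorph import CohortSpec, StageModel, generate_cohort

spec = CohortSpec()                      # four-stage cohort, 85 participants
cohort, _ = generate_cohort(spec, seed=7)
model = StageModel.from_dataframe(cohort, response="bnfl_mean")
res = model.fit()                        # REML + stepwise deletion + Tukey
print(res.summary())
```

prints

```
Stage analysis: bnfl_mean
============================================================
eyes: 170   participants: 85   denominator df: 81
variance components: participant 3.625e-04, residual 2.597e-04
retained covariates: (none)
...
Estimated marginal means (at covariate means)
stage  emmean        se  ci_low  ci_high
    C   0.298  0.004352  0.2893   0.3067
   PG  0.2803  0.005548  0.2693   0.2914
   EG  0.2491  0.003986  0.2411    0.257
  MAG  0.1678  0.006406  0.1551   0.1806

Tukey-adjusted pairwise stage contrasts
contrast  estimate        se      t    p_unadj    p_tukey
  C - PG   0.01765  0.007051  2.503    0.01432    0.06695
  C - EG   0.04894  0.005901  8.293  1.984e-12  1.185e-11
 C - MAG    0.1301  0.007744  16.81  3.952e-28  3.952e-28
 PG - EG   0.03129  0.006831  4.581  1.659e-05  9.649e-05
PG - MAG    0.1125  0.008474  13.28  5.032e-22  5.032e-22
EG - MAG   0.08121  0.007544  10.76  2.745e-17  2.745e-17

Pearson r vs VF MD: 0.893 (p = 4.05e-60)
Shapiro-Wilk residual normality p: 0.77
```

Reading: mean border NFL in this simulated cohort is 0.298 mm in
controls and thins monotonically with stage; every pairwise contrast
except C–PG survives Tukey adjustment at this sample size; the pooled
Pearson r of +0.89 says thinner border NFL accompanies more negative
(worse) VF MD; and the random-intercept variance (3.6e-4 mm²) shows the
strong inter-eye correlation the mixed model is there to absorb.

The same flow is scriptable from a shell:

```bash
onh-morph simulate --seed 1 --out demo --export-surfaces 1
onh-morph measure  --surfaces demo/surfaces_P0001_OD --out eye.csv
onh-morph analyze  --cohort demo/cohort.csv --params all --out demo/results
onh-morph run      --seed 1 --out demo_full        # all three + manifest
onh-morph selftest                                 # quick oracle checks
```

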
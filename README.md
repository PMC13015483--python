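# exermap

Repeated-measures multi-omic analysis of acute-exercise cohorts:
difference-in-changes mixed models, a type-I-error/power simulation
harness for longitudinal modeling strategies, competitive and
over-representation enrichment, signed co-expression modules, fuzzy
time-course clustering, and secreted-factor ("exerkine")
endocrine-connectivity scoring — exercised end-to-end on synthetic
cohorts with planted ground truth.

## Who this is for

Analysts working with three-arm exercise (or other intervention) designs
in which every participant contributes a pre-intervention sample plus
exactly one post timepoint determined by a randomized *temporal profile*.
That design confounds naive pre/post comparisons with circadian,
fasting and biopsy effects and leaves each participant with only two
observations, which is exactly the regime where the choice of
repeated-measures model matters.

## The core model

Each molecular feature y is fit with a cell-means linear mixed model

    y_ijt = μ_{g(i),t} + x_i'γ + u_i + e_ijt,   u_i ~ N(0, τ²),  e ~ N(0, σ²)

with one mean per group × timepoint cell, demographic covariates, and a
participant random intercept (REML, Satterthwaite df). The primary
exercise effect is the **difference-in-changes** ("delta-delta")
contrast

    (μ_{g,t} − μ_{g,pre}) − (μ_{CON,t} − μ_{CON,pre}),

the change in an exercise group minus the same change in the
non-exercising control. P-values are BH-adjusted within each
(contrast family, group, ome, timepoint) stratum at FDR 0.05, and
features need ≥ 3 paired participants per involved group to be tested.

Around this sit the supporting layers: a moment-matched non-normal
simulator (Fleishman/Vale–Maurelli), a strategy-comparison harness
(paired t, OLS, weighted/unweighted random-intercept LMM, unstructured
GLS, GEE-AR(1) with sandwich SEs), CAMERA-PR-style pre-ranked enrichment
and hypergeometric ORA, WGCNA-style signed modules with biweight
midcorrelation trait association, Mfuzz-style fuzzy c-means on
zero-baseline-scaled z-score trajectories, and QENIE-style Ssec scoring
(mean −ln p of cross-tissue biweight midcorrelations per origin gene).
See `docs/methods.md` for the full account.

## Worked example

```python
from exermap.simulate import generate_cohort, generate_omics, EffectSpec
from exermap.differential import run_differential

design = generate_cohort({"EE": 20, "RE": 20, "CON": 20},
                         profile_weights=(0.0, 1.0, 0.0), seed=12)
spec = EffectSpec(n_features_per_ome=300, frac_dd_affected=0.1,
                  dd_effect=1.0, trajectory_shapes=False,
                  omes=("protein",), seed=21)
matrices, truth = generate_omics(design, spec)
res = run_differential(matrices["protein"], design, covariates=(),
                       families=("difference_in_changes",), ome="protein")
dd = res[res.group == "EE"]
print(len(dd), "EE contrasts;", int(dd.significant.sum()), "significant at FDR 0.05")
hits = set(dd[dd.significant].feature_id)
planted = set(truth[truth.is_dd_affected].feature_id)
print("recovered", len(hits & planted), "of", len(planted), "planted effects;",
      len(hits - planted), "false discoveries")
```

prints

```
300 EE contrasts; 20 significant at FDR 0.05
recovered 20 of 30 planted effects; 0 false discoveries
```

— every BH discovery is a planted effect (no false discoveries), and
two-thirds of the 1-SD planted effects survive FDR adjustment at 20
pairs per group; at raw p < 0.05 the per-contrast power exceeds 0.8, as
the closed-form paired two-sample calculation predicts.

The same pipeline runs from the shell:

```bash
exermap simulate --seed 12 --outdir sim/
exermap da --matrix sim/protein.tsv --design sim/design.tsv \
           --contrasts dd --out da.tsv
exermap run --seed 5 --outdir demo/     # all stages end to end
```

## Layout

| module | contents |
|---|---|
| `exermap.simulate` | cohort and multi-omic generators with planted truth |
| `exermap.moments` | Fleishman / Vale–Maurelli moment-matched sampling |
| `exermap.lmm` | random-intercept REML, GEE-AR(1), unstructured GLS engines |
| `exermap.differential` | cell-means contrasts, min-pairs rule, stratified FDR, z-matrices |
| `exermap.simeval` | type-I-error / power strategy comparison |
| `exermap.enrichment` | set filtering, pre-ranked competitive test, ORA |
| `exermap.networks` | signed modules, eigengenes, kME, bicor trait association |
| `exermap.trajectories` | z-trajectory stacking, fuzzy c-means, scree, fuzzifier |
| `exermap.endocrine` | secretome filtering, extracellular scores, Ssec, rank shifts |
| `exermap.preprocess` | per-ome filtering / imputation / normalization rules |
| `exermap.pipeline`, `exermap.cli` | end-to-end orchestration and `exermap` CLI |
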
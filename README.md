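# jointfactor

Hierarchical sparse non-negative matrix factorization for patterns of
joint involvement in childhood arthritis.

Children with juvenile idiopathic arthritis (JIA) present with arthritis
in characteristic combinations of joints — both knees, the small joints of
the fingers, the ankle–subtalar–midfoot complex — that clinicians
recognize at the bedside but that standard diagnostic categories do not
capture. Given a cohort's binary patient × joint involvement matrix
(recorded on a standardized 71-joint homunculus), this package

* quantifies pairwise **joint co-involvement**: involvement frequencies
  P(x), co-involvement P(x, y), conditional co-involvement P(y | x),
  same-side versus opposite-side skew z-scores per joint-type pair, and a
  permutation test of global left/right mirror symmetry;
* discovers **hierarchical joint patterns** with a two-layer sparse NMF:
  X ≈ W₁H₁ groups frequently co-involved joints into tight low-level
  factors, a second factorization H₁ ≈ W₂H₂ groups those factors into
  broad high-level patterns, and the composite loading C = W₁W₂ defines
  each pattern's **key joints** (strictly positive entries);
* selects the ranks and the L1 penalty by **bi-cross-validation** (BiCV):
  row-block × column-block holdout with the Owen–Perry estimator
  Â = B·D̂⁺·C and held-out Q² = 1 − PRESS/TSS;
* assigns each patient to the **patient group** of their highest-scoring
  high-level factor and computes their **degree of localization** — the
  exact fraction of their active joints that are key joints of their
  group (≥90% localized, 60–90% partially localized, <60% extended);
* analyses **longitudinal outcome**: group trajectories over follow-up
  visits, transition matrices with a label-permutation null
  (Holm–Bonferroni adjusted), and time to zero active joints via Cox
  proportional hazards, log-rank tests and Kaplan–Meier curves
  (through `lifelines`);
* ships a **synthetic cohort generator** with planted hierarchical
  structure, a tunable localization mixture and localization-dependent
  resolution hazards, so the whole pipeline is testable end to end with
  known ground truth.

The model core is fitted by multiplicative updates minimising
½‖X − WH‖²_F + α‖W‖₁ + α/2‖H‖²_F, which never increase the objective;
loadings are max-normalized to read as 0–100% contributions, small
entries are sparsified away, and all scaling is frozen so external
cohorts and follow-up visits can be projected through the fixed model.

## Worked example

```python
import jointfactor as jf

# synthetic cohort: 600 patients on the 71-joint homunculus,
# planted structure with 19 low-level and 7 high-level patterns
cohort, truth, planted = jf.simulate_cohort("homunculus", 600, seed=0)

res = jf.MultilayerNMF.from_cohort(cohort).fit(seed=0)
print(res.summary())

assignment = res.assign_groups()
loc = jf.localize(cohort.baseline_matrix, assignment, res.key_joints)
surv = jf.time_to_zero(cohort).join(loc[["group", "category"]])
cox = jf.fit_cox(surv, ["category"], reference={"category": "localized"})
print(cox.summary())
```

prints

```
Multilayer NMF
================================================
data:        71 joints x 600 patients
layer 1:     k1=19, alpha1=3, threshold=0.1
layer 2:     k2=7, alpha2=2, threshold=0.1
key joints:  G1:4, G2:6, G3:6, G4:6, G5:6, G6:6, G7:4
group sizes: G1:109, G2:83, G3:67, G4:89, G5:84, G6:97, G7:71
training Q2: low=0.547, high=0.403, group=0.297

Cox PH: n=600, events=373; LR chi2=266.61, p=1.28e-58, R2=0.359
                        beta        HR    ci_low   ci_high          z             p
covariate
category[extended] -2.474118  0.084237  0.062424  0.113673 -16.180626  6.908843e-59
category[partial]  -1.114247  0.328162  0.254737  0.422752  -8.622508  6.550316e-18
```

The seven fitted key-joint sets here equal the seven planted ones
exactly; the Q² rows show how much of the binary involvement data each
level of the hierarchy reconstructs (joint-level factors > patterns >
hard groups). The hazard ratios below 1 say that, in this simulated
cohort, patients whose active joints extend beyond their assigned
pattern take markedly longer to reach zero active joints than localized
patients — the planted effect direction.

A command-line interface mirrors the library
(`jointfactor simulate|validate|stats|fit|select|assign|project|trajectories|survival`);
see `jointfactor COMMAND --help`.

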
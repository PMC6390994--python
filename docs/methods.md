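# Methods

This note documents the statistical machinery implemented in
`jointfactor`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not establish.

## Data model

Joint involvement is recorded on a site catalog — by default a 71-joint
homunculus (35 bilateral joint types plus the midline cervical spine):
TMJs, cervical spine, sternoclavicular joints, shoulders, elbows, wrists,
thumb MCP/IP, finger MCPs/PIPs/DIPs (digits 2–5), sacroiliac joints,
hips, knees, ankles, subtalar joints, midfeet, MTPs 1–5 and toe IPs 1–5.
The default enumeration is a reconstruction of the standard pediatric
71-joint count; any catalog can be supplied as a TSV and is validated
(unique ids, perfect left/right pairing per joint type).

A cohort holds one binary joints × patients matrix per visit. Visits a
patient did not attend are absent, never zero-filled; an attended visit
with no active joints is a real observation (it is the event for the
time-to-zero outcome) and is preserved distinctly in both on-disk
dialects. The default visit schedule is months {0, 6, 12, 18, 24, 36,
48, 60} — six-month intervals for eighteen months, then yearly — but any
strictly increasing schedule is accepted. Severity grades are out of
scope; involvement is strictly binary.

## Co-involvement statistics

For the baseline matrix: P(x) is the involvement proportion, P(x, y) the
proportion with both joints active, and P(y | x) = P(x, y)/P(x) the
conditional co-involvement (undefined and flagged where P(x) = 0). The
screen of all k² ordered conditionals against their marginals uses an
exact binomial test with Bonferroni correction — the simplest exact
choice for binary counts; the correction denominator counts all ordered
pairs, including undefined ones.

**Same-side skew.** For joint types x and y, n_same counts patients with
a same-side co-involved pair, n_opposite with an opposite-side pair;
each patient contributes at most one to each count. With add-one
shrinkage m = (n_same+1)/((n_same+1)+(n_opposite+1)),
σ = √(m(1−m)/n) with n the shrunken total (the natural companion of the
shrunken proportion; the raw total differs by 2 and changes nothing
materially), and z = (m−0.5)/σ. A χ² test of n_same versus n_opposite
against equality gives the p-value; Benjamini–Hochberg FDR across all
unordered type pairs (the counts are symmetric in x and y, so ordered
duplicates would only dilute the FDR), significant below 0.1. Self-pairs
exclude the reference joint itself on the same side, so they score pure
bilaterality through the opposite-side count.

**Mirror symmetry.** The two opposite-side quadrants of the conditional
matrix — P(y_right | x_left) and P(y_left | x_right), cell by cell — are
compared by the Frobenius norm of their difference. The null relabels
each patient's left and right sides independently with probability ½
(the natural exchangeability null for handedness) and recomputes the
norm; the p-value is the add-one permutation tail.

## Sparse NMF core

The factorization minimises

  L(W, H) = ½‖X − WH‖²_F + α‖W‖₁ + (α/2)‖H‖²_F

by the standard multiplicative updates, which are monotone in L.
Squared Frobenius loss (not KL) matches the Q²-style reconstruction
accuracy used throughout. The sparsity-inducing L1 term acts on the
loadings W only — sparse joint patterns are the interpretive goal, and
patient scores must stay dense for group assignment. The quadratic term
on H carries no sparsity pressure; it exists because the factorization
is scale-indeterminate (W → W/c, H → cH): without it an L1 penalty on W
alone is vacuous — the optimizer escapes it by deflating W's scale into
H, which we verified empirically (fits identical across α spanning an
order of magnitude). Tying both terms to a single α keeps the interface
one-dimensional; the ridge share is small at the fitted scale.

After fitting, each W column is scaled to unit maximum with the
compensation folded into H, so loadings read as 0–100% contributions;
the per-factor scales are stored. Factors whose loading column collapsed
to exactly zero under strong penalization are pruned (effective rank
shrinks) rather than failing the fit.

**Initialisation.** Deterministic NNDSVD (SVD-based, zeros filled with
the matrix mean) by default; optional seeded random-uniform restarts with
the lowest final objective winning, ties broken by restart order. A
third deterministic option, `cluster`, average-links the feature rows by
correlation distance into k groups and starts W at soft cluster
membership — appropriate when features are expected to partition into
factor-aligned blocks.

**Sparsification.** Entries of W below a fraction (default 0.1) of their
column maximum are set to zero and H is re-estimated per sample by
non-negative least squares with W fixed. The per-factor Spearman
correlation between pre- and post-sparsification scores is reported so
users can confirm patients were not reordered. If thresholding empties a
column the call fails loudly, suggesting a lower threshold. The 10%
default is a calibrated choice (see below), configurable everywhere.

**Projection.** New samples are scored by the same NNLS step with W and
all stored scaling frozen — deterministic, and exactly reproducing the
training scores when the training matrix is projected (the training H
is produced by the identical computation).

**Q².** 1 − PRESS/TSS over the evaluated cells (the cross-validated R²;
can be negative). A squared-Pearson variant is available via
`method="corr"` for users who prefer a correlation reading; PRESS/TSS is
the default because it is the quantity BiCV actually cross-validates.

## Bi-cross-validation

Rows and columns are independently partitioned into folds (3 by
default, uniform at random, seeded). For each held-out block A with
flanking blocks B, C and training block D, the rank-k fit D̂ = WH on D
predicts Â = B·Ĥ⁺Ŵ⁺·C (the Owen–Perry block estimator with the
pseudo-inverse taken through the factors). Held-out residuals pool into
one Q² per replicate and grid point. Selection follows one-standard-error
parsimony: the smallest rank within one SE of the best mean Q², and the
largest α within one SE of the unpenalized mean Q² — the sparsest model
that costs no measurable accuracy. Defaults run 200 replicates
interactively; the validation studies use the replicate counts stated
with each result.

## Multilayer composition

Layer 1 factorizes the joints × patients matrix at k1 (default 19 for
homunculus-shaped data); after sparsification each score row is rescaled
to unit maximum (scales stored) and layer 2 factorizes the rescaled
scores at k2 (default 7). The composite loading C = W₁·diag(s)·W₂ maps
high-level factors back to joints; it is sparsified by the same relative
rule as every other loading matrix (entries below the layer-2 threshold
fraction of the column maximum are zeroed) — on planted data, genuine
key-joint loadings sit at ≥0.5 of the column maximum while propagated
stray loadings sit at ≤0.13, so the uniform rule separates them with a
wide margin. A factor's **key joints** are the strictly positive entries
of its sparsified composite column.

The second layer uses the `cluster` initialisation by default: with
NNDSVD or random starts the layer-2 objective has split/merge local
optima (one planted grouping split across two factors, two others
merged) in roughly a quarter of planted-data replicates, and restarting
by objective does not reliably escape them because the spurious optima
can win the penalized objective; the clustering start is deterministic
and recovered every planted grouping in our calibration runs.

The penalty defaults α₁ = 3, α₂ = 2 were calibrated once on planted
homunculus-shaped synthetic cohorts (600 patients, flip noise 0.02) by
sweeping α and scoring exact key-set recovery; they are sensible for
binary matrices of roughly this size, and BiCV `select_alpha` is the
data-driven chooser for anything else.

**Groups.** Each patient is assigned to their highest-scoring high-level
factor; ties are flagged and broken toward the lowest factor index;
all-zero score vectors go to a reserved "unscored" group that is
reported, never dropped. Group–factor overlap normalizes scores
patient-wise to the maximum, z-transforms factor-wise, and applies
one-sided z-tests with BH-FDR (< 0.1). Group–label association uses the
χ² contingency test with adjusted Pearson residuals
(obs−exp)/√(exp(1−row prop)(1−col prop)), enriched at ≥ 1.96, so the cut
reads as a normal 5% quantile.

**Group-level reconstruction** (the coarsest Q²) represents each patient
by their group's composite column scaled by the group's mean own-factor
score — a one-hot, hard-clustering view. This is one reasonable
definition among several; it is used only for the descriptive Q² ladder.

## Degree of localization

The fraction of a patient's active joints that are key joints of their
*assigned* group is computed in exact rational arithmetic
(`fractions.Fraction`) and compared against closed thresholds: localized
at ≥ 9/10, partial at ≥ 3/5, extended below — so 9 of 10 active joints
is localized by definition, with no floating-point drift at either
boundary. The thresholds are fixed configuration, not estimated.
Group-wise localization skew is a per-group χ² goodness-of-fit against
the global category proportions, Bonferroni-adjusted across groups, with
above/below-expectation directions reported. A threshold sweep reports
the proportion of patients at or above each candidate threshold with a
bootstrap (default 2,000 resamples) standard error.

## Longitudinal analyses

Follow-up visits are scored through the frozen model; an all-inactive
visit short-circuits projection to the ZERO state. Transition matrices
use reach-any-visit semantics — a patient counts once per destination
state reached at any follow-up — because the output is a baseline-group
by destination table, not a Markov chain estimate (a per-visit occupancy
variant is available by flag). Denominators count patients with at least
one observed follow-up; label permutation shuffles baseline strata
against whole trajectories, preserving within-trajectory correlation,
with add-one p-values Holm–Bonferroni-adjusted (enriched below 0.05,
2,000 permutations by default).

Time to zero joints is a first-passage outcome: the event is the first
all-inactive visit, later flares do not undo it, and patients never
reaching zero are censored at their last observed visit (patients with
no follow-up are excluded with a warning). Cox proportional-hazards
models, log-rank tests and Kaplan–Meier curves go through `lifelines`;
the visit grid creates heavy ties, handled by Efron's method (the only
tie scheme lifelines implements). The global model R² is reported in the
Cox–Snell form 1 − exp(−LR/n). Non-convergence (monotone likelihood from
a separated covariate level) is re-raised with a diagnostic.

## Synthetic cohorts

The generator plants: disjoint low-level supports (one bilateral joint
type each, ordered along the body axis), high-level supports partitioning
them into k2 contiguous groups, uniform group weights (the standard
balanced choice for planted-recovery testing; any weights can be
passed), and a localization mixture defaulting to (0.561, 0.194, 0.245).
Patients activate each of their group's supports with probability 0.7;
within an activated support both sides light up together with
probability 0.8 (bilateral coupling), reflecting predominantly symmetric
involvement. Partial and extended patients then add non-key joints drawn
uniformly until their exact key fraction lands in [0.6, 0.9) or
[0, 0.6); finally each joint flips independently with the noise rate
(default 0.02). Ground-truth categories are *recomputed* from the final
matrix, so stored labels and a from-scratch recomputation agree exactly;
note that at 71 joints a 2% flip rate adds ≈1.3 active joints per
patient, so the realized category mixture shifts toward less localized
than the pre-noise target (at zero noise the target is hit exactly).

Over follow-up, each active joint resolves independently per visit with
a hazard depending on the localization category (defaults 0.5 / 0.35 /
0.25) — the simplest mechanism giving a known monotone ordering of time
to zero; optional flares reactivate inactive joints. No claim is made
that this matches real disease dynamics: per-joint independence, single
group membership per patient, and disjoint supports are all idealized.
Passing the planted-recovery tests therefore shows the estimator
recovers structure of this kind at these noise levels — not that real
cohorts are this clean, nor that real patterns are disjoint.

## Validation studies and problem sizes

`jointfactor.validation` (run by `scripts/acceptance.py` and asserted in
the test suite) uses: 100 random 20×30 instances for update
monotonicity; 60×60 planted rank-3 matrices with 50 BiCV replicates
(noiseless and at signal-to-noise 5) for rank recovery; 20 planted
homunculus cohorts of 600 patients at noise 0.02 for key-set recovery;
200 side-independent replicates for skew-test calibration; 200
label-shuffled replicates (199 permutations each) for transition-test
calibration; 500 identical-hazard replicates for log-rank uniformity
(the KS p-value is itself uniform under the null, so occasional small
values are expected); 200 two-group exponential simulations of 500
patients at hazard ratio 2 for CI coverage; and one 600-patient cohort
with a 3-replicate BiCV for projection self-consistency. These sizes
give stable estimates at interactive runtimes; all are parameters.

## Known limitations

* The default 71-joint enumeration is a reconstruction; site-level
  naming may differ from any specific registry's form.
* Two layers only; no deeper hierarchies.
* The L1/ridge coupling through a single α is a convenience; decoupled
  penalties would need a second selection axis.
* Binary involvement only; no severity, no imaging.
* The transition permutation null assumes exchangeable baseline labels
  across patients; informative censoring is not modelled.
* Breslow tie handling is unavailable (Efron only, via lifelines).
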
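"""Planted-data validation studies.

Each routine here runs one self-contained check of the pipeline against
synthetic data with known ground truth — analytic identities, optimizer
monotonicity, planted-structure recovery, null-calibration of the
permutation and survival tests, and projection self-consistency.  They are
used both by the test suite and by ``scripts/acceptance.py``, which prints
their numbers; sizes are parameters so callers can trade precision for
runtime.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import default_catalog
from .coinvolvement import coinvolvement, skew_test
from .localization import categorize
from .longitudinal import fit_cox, logrank, transitions
from .model_selection import bicv, select_rank
from .multilayer import MultilayerNMF
from .nmf import NMF, FitConfig
from .simulate import simulate_cohort

__all__ = [
    "conditional_pair_count", "catalog_joint_count",
    "mu_objective_violations", "bicv_rank_recovery",
    "multilayer_support_recovery", "localization_boundary_accuracy",
    "skew_null_positive_rate", "transition_null_enrichment_rate",
    "logrank_null_ks_p", "cox_ci_coverage", "projection_self_consistency",
]


def conditional_pair_count(seed: int = 0) -> int:
    """Number of ordered-pair entries of the conditional matrix (71² = 5041)."""
    cohort, _, _ = simulate_cohort("homunculus", 50, seed=seed)
    return coinvolvement(cohort.baseline_matrix).n_ordered_pairs


def catalog_joint_count() -> int:
    return len(default_catalog())


def mu_objective_violations(n_instances: int = 100, shape=(20, 30),
                            ranks=(1, 2, 3, 4, 5), seed: int = 0,
                            rel_tol: float = 1e-9) -> int:
    """Count multiplicative-update steps that increased the penalized objective.

    Random non-negative instances with random rank and alpha; a violation is
    a relative objective increase beyond floating tolerance.
    """
    rng = np.random.default_rng(seed)
    violations = 0
    for i in range(n_instances):
        X = rng.uniform(0, 1, shape)
        k = int(rng.choice(ranks))
        alpha = float(rng.choice([0.0, 0.5, 2.0]))
        res = NMF(X, k, alpha).fit(FitConfig(seed=i, max_iter=150, tol=1e-12,
                                             init="random"))
        tr = res.objective_trace
        violations += int(np.sum(np.diff(tr) > rel_tol * np.abs(tr[:-1])))
    return violations


def _planted_block_matrix(rng, rank=3, side=60, snr=None):
    X = np.zeros((side, side))
    rows = np.array_split(np.arange(side), rank)
    cols = np.array_split(np.arange(side), rank)
    for b in range(rank):
        X[np.ix_(rows[b], cols[b])] = np.outer(rng.uniform(0.5, 1.5, len(rows[b])),
                                               rng.uniform(0.5, 1.5, len(cols[b])))
    if snr is not None:
        sd = X[X > 0].std() / snr
        X = np.clip(X + rng.normal(0, sd, X.shape), 0, None)
    return X


def bicv_rank_recovery(replicates: int = 50, seed: int = 0,
                       snr: float | None = None) -> int:
    """Rank selected by 3-fold BiCV on a planted rank-3 block matrix."""
    rng = np.random.default_rng(seed)
    X = _planted_block_matrix(rng, rank=3, side=60, snr=snr)
    grid = bicv(X, ranks=[1, 2, 3, 4, 5, 6], folds=3, replicates=replicates,
                seed=seed, config=FitConfig(max_iter=200, tol=1e-6))
    return select_rank(grid)


def multilayer_support_recovery(n_seeds: int = 20, n_patients: int = 600,
                                noise_rate: float = 0.02,
                                seed: int = 0) -> float:
    """Fraction of planted cohorts whose high-level key sets are recovered exactly.

    Homunculus-shaped planted models (71 joints, k1=19, k2=7) are fitted with the
    package defaults; recovery requires every fitted key-joint set to equal a
    planted one (set equality after matching, i.e. the two collections of
    frozen sets coincide).
    """
    hits = 0
    for s in range(n_seeds):
        cohort, _, planted = simulate_cohort("homunculus", n_patients,
                                             seed=seed * 1000 + s,
                                             noise_rate=noise_rate)
        try:
            res = MultilayerNMF.from_cohort(cohort).fit(seed=0)
        except ValueError:
            continue
        planted_sets = {frozenset(planted.key_joints(g)) for g in range(planted.k2)}
        hits += planted_sets == {frozenset(k) for k in res.key_joints}
    return hits / n_seeds


def localization_boundary_accuracy() -> float:
    """Fraction of closed-boundary cases classified exactly (rational arithmetic)."""
    cases = [
        (Fraction(9, 10), "localized"),
        (Fraction(6, 10), "partial"),
        (Fraction(59, 100), "extended"),
        (Fraction(89, 100), "partial"),
        (Fraction(1, 1), "localized"),
        (Fraction(0, 1), "extended"),
    ]
    return float(np.mean([categorize(f) == c for f, c in cases]))


def skew_null_positive_rate(n_replicates: int = 200, n_patients: int = 200,
                            seed: int = 0) -> float:
    """Fraction of skew tests flagged at FDR < 0.1 under side-independent data.

    Each replicate activates the left and right member of every joint type
    independently with the same per-type probability, so no same-side skew
    exists; the flagged fraction estimates the realized false-positive rate.
    """
    catalog = default_catalog()
    rng = np.random.default_rng(seed)
    types = catalog.bilateral_types
    idx = catalog.index
    flagged = total = 0
    for _ in range(n_replicates):
        q = rng.uniform(0.03, 0.25, len(types))
        X = np.zeros((len(catalog), n_patients), dtype=np.int8)
        for t_i, t in enumerate(types):
            left, right = catalog.pair(t)
            X[idx[left.joint_id]] = rng.random(n_patients) < q[t_i]
            X[idx[right.joint_id]] = rng.random(n_patients) < q[t_i]
        table = skew_test(pd.DataFrame(X, index=catalog.joint_ids), catalog)
        flagged += int(table["significant"].sum())
        total += len(table)
    return flagged / total


def transition_null_enrichment_rate(n_replicates: int = 100, n_patients: int = 90,
                                    n_perm: int = 199, seed: int = 0) -> float:
    """Fraction of transition cells flagged on label-shuffled trajectories.

    Baseline strata are assigned independently of the follow-up states, so
    every enrichment call is a false positive; the Holm-adjusted test at
    0.05 should flag well under 5% of cells.
    """
    rng = np.random.default_rng(seed)
    states = ["G1", "G2", "G3", "ZERO"]
    flagged = total = 0
    for rep in range(n_replicates):
        idx = [f"p{i}" for i in range(n_patients)]
        traj = pd.DataFrame({
            0: rng.choice(["G1", "G2", "G3"], n_patients),
            6: rng.choice(states, n_patients),
            12: rng.choice(states, n_patients),
        }, index=idx)
        strata = pd.Series(rng.choice(["G1", "G2", "G3"], n_patients), index=idx)
        tm = transitions(traj, strata, n_perm=n_perm, seed=seed * 7919 + rep)
        flagged += int(tm.enriched.to_numpy().sum())
        total += tm.enriched.size
    return flagged / total


def logrank_null_ks_p(n_replicates: int = 500, n_patients: int = 80,
                      seed: int = 0) -> float:
    """KS-test p-value for uniformity of log-rank p under identical hazards."""
    ps = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed * 100003 + rep)
        g = np.repeat(["a", "b"], n_patients // 2)
        surv = pd.DataFrame({"time": rng.exponential(1.0, n_patients),
                             "event": 1, "group": g})
        _, p = logrank(surv, "group")
        ps.append(p)
    return float(stats.kstest(ps, "uniform").pvalue)


def cox_ci_coverage(n_sims: int = 200, n_patients: int = 500,
                    true_hr: float = 2.0, seed: int = 0) -> float:
    """95% CI coverage of the planted localization hazard ratio.

    Extended patients resolve at half the (exponential) rate of localized
    patients; each simulation fits a two-level Cox model and checks whether
    the Wald CI covers the true ratio.
    """
    covered = 0
    for rep in range(n_sims):
        rng = np.random.default_rng(seed * 99991 + rep)
        cat = np.repeat(["localized", "extended"], n_patients // 2)
        lam = np.where(cat == "localized", true_hr, 1.0)
        surv = pd.DataFrame({"time": rng.exponential(1.0 / lam),
                             "event": 1, "localization": cat})
        fit = fit_cox(surv, ["localization"], reference={"localization": "extended"})
        lo, hi = fit.table["ci_low"].iloc[0], fit.table["ci_high"].iloc[0]
        covered += lo <= true_hr <= hi
    return covered / n_sims


def projection_self_consistency(n_patients: int = 600, seed: int = 0,
                                bicv_replicates: int = 3) -> dict[str, float]:
    """Project the training cohort through its own frozen model.

    Returns the maximal absolute deviation between projected and stored
    patient scores, the training reconstruction Q² at the low level, and
    the BiCV held-out mean Q² at the same rank (training fit should not be
    worse than held-out prediction).
    """
    cohort, _, _ = simulate_cohort("homunculus", n_patients, seed=seed,
                                   noise_rate=0.02)
    X = cohort.baseline_matrix
    res = MultilayerNMF.from_cohort(cohort).fit(seed=0)
    dev = float(np.max(np.abs(res.project(X) - res.layer2.H)))
    q_train = res.q2_levels()["low"]
    grid = bicv(X.to_numpy(dtype=float), ranks=[res.model.k1],
                alphas=[res.model.alpha1], folds=3, replicates=bicv_replicates,
                seed=seed, config=FitConfig(max_iter=200, tol=1e-6))
    q_heldout = float(grid.summarize()["mean_q2"].iloc[0])
    return {"max_score_deviation": dev, "training_q2": q_train,
            "heldout_q2": q_heldout}
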
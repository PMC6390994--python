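"""Longitudinal outcomes: trajectories, transitions, time to zero joints.

Follow-up visits are scored through the frozen two-layer model, giving each
(patient, visit) a state: a patient group, ``ZERO`` (no active joints) or
``MISSING`` (visit not observed).  From baseline strata — patient group,
optionally crossed with degree of localization — transition frequencies to
any state reached at any follow-up visit are tabulated and tested against a
permutation null that shuffles baseline stratum labels across whole
trajectories (Holm–Bonferroni-adjusted, enriched below 0.05).

Time to zero joint involvement is a first-passage outcome: the event time
is the month of the first all-inactive visit; patients never reaching zero
are censored at their last observed visit.  Cox proportional-hazards
models (Efron tie handling; visit grids create heavy ties), log-rank tests
and Kaplan–Meier curves are fitted through lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable
from .multilayer import MultilayerResults, UNSCORED

__all__ = ["score_visits", "transitions", "TransitionMatrix", "time_to_zero",
           "CoxFit", "fit_cox", "logrank", "km_curve", "ZERO", "MISSING"]

ZERO = "ZERO"
MISSING = "MISSING"


def score_visits(cohort: CohortTable, results: MultilayerResults) -> pd.DataFrame:
    """State of every patient at every visit through the frozen model.

    Returns a patients × visit-months frame of states: a factor name
    (highest-scoring high-level factor), ``ZERO`` for an all-inactive
    visit (which short-circuits projection), ``UNSCORED`` for an active
    visit with all-zero projected scores, or ``MISSING``.
    """
    patients = cohort.patient_ids
    out = pd.DataFrame(MISSING, index=patients, columns=cohort.visits, dtype=object)
    for v in cohort.visits:
        M = cohort.X[v]
        active_mask = M.sum(axis=0).to_numpy() > 0
        zero_pats = M.columns[~active_mask]
        out.loc[zero_pats, v] = ZERO
        act = M.loc[:, active_mask]
        if act.shape[1]:
            assign = results.assign_groups(act)
            out.loc[act.columns, v] = assign.group_name.to_numpy()
    return out


@dataclass
class TransitionMatrix:
    """Reach-any-visit transition counts and their permutation test."""

    count: pd.DataFrame        # stratum × destination state
    denominator: pd.Series     # stratum size with >= 1 observed follow-up
    probability: pd.DataFrame
    p: pd.DataFrame            # permutation p per cell
    p_adjusted: pd.DataFrame   # Holm–Bonferroni across cells
    enriched: pd.DataFrame     # adjusted p < alpha
    n_perm: int

    def summary(self) -> str:
        cells = [(s, d) for s in self.enriched.index for d in self.enriched.columns
                 if self.enriched.loc[s, d]]
        return (f"transition matrix ({self.count.shape[0]} strata x "
                f"{self.count.shape[1]} destinations, {self.n_perm} permutations)\n"
                f"enriched transitions (Holm-adjusted p < 0.05): {cells}")


def transitions(traj: pd.DataFrame, strata: pd.Series, n_perm: int = 2000,
                seed: int | None = None, alpha: float = 0.05,
                per_visit: bool = False) -> TransitionMatrix:
    """Baseline-stratum → destination-state transition frequencies.

    A patient counts once per destination state reached at *any* follow-up
    visit (default), or once per (visit, state) occupancy with
    ``per_visit=True`` — the Markov-style alternative.  The denominator per
    stratum is the number of its patients with at least one observed
    follow-up visit; patients whose every later visit is missing drop out
    of both numerator and denominator.

    Significance is a permutation test: baseline stratum labels are
    shuffled across patients (whole trajectories kept intact, preserving
    within-trajectory correlation) ``n_perm`` times; the per-cell p-value
    is the add-one tail probability of a transition proportion at least as
    large, Holm–Bonferroni-adjusted across all cells.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    follow_cols = list(traj.columns[1:])
    if not follow_cols:
        raise ValueError("need at least one follow-up visit")
    strata = strata.reindex(traj.index)
    fu = traj[follow_cols]
    observed_any = (fu != MISSING).any(axis=1).to_numpy()
    # reached[d] : bool vector over patients
    dests = sorted({s for s in fu.to_numpy().ravel() if s != MISSING})
    if per_visit:
        # Markov-style: count every observed (patient, visit) occupancy
        reach = {d: (fu == d).sum(axis=1).to_numpy() for d in dests}
        weight = (fu != MISSING).sum(axis=1).to_numpy()
    else:
        # reach-any-visit: a patient counts once per destination
        reach = {d: (fu == d).any(axis=1).to_numpy().astype(float) for d in dests}
        weight = observed_any.astype(float)

    labels = strata.to_numpy()
    strata_levels = sorted(pd.unique(labels[pd.notna(labels)]), key=str)

    def tabulate(lab):
        cnt = np.zeros((len(strata_levels), len(dests)))
        den = np.zeros(len(strata_levels))
        for i, s in enumerate(strata_levels):
            members = lab == s
            den[i] = weight[members].sum()
            for j, d in enumerate(dests):
                cnt[i, j] = reach[d][members].sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            prob = cnt / den[:, None]
        return cnt, den, prob

    cnt, den, prob = tabulate(labels)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(cnt)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, _, pprob = tabulate(perm)
        exceed += np.nan_to_num(pprob) >= np.nan_to_num(prob) - 1e-12
    p = (1 + exceed) / (1 + n_perm)
    flat = p.ravel()
    adj = multipletests(flat, method="holm")[1].reshape(p.shape)
    idx = pd.Index(strata_levels, name="stratum")
    cols = pd.Index(dests, name="destination")
    return TransitionMatrix(
        count=pd.DataFrame(cnt, index=idx, columns=cols),
        denominator=pd.Series(den, index=idx),
        probability=pd.DataFrame(prob, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        p_adjusted=pd.DataFrame(adj, index=idx, columns=cols),
        enriched=pd.DataFrame(adj < alpha, index=idx, columns=cols),
        n_perm=n_perm,
    )


def time_to_zero(cohort: CohortTable) -> pd.DataFrame:
    """First-passage time to a visit with no active joints, with censoring.

    Event time is the month of the first ZERO visit (later flares do not
    undo the event); otherwise the patient is censored at their last
    observed visit.  Patients with no follow-up at all are excluded with a
    warning.
    """
    base = cohort.baseline_visit
    rows, dropped = [], []
    followup = cohort.followup
    for p in cohort.patient_ids:
        obs = [v for v in cohort.visits if v > base and p in cohort.X[v].columns]
        if not obs:
            dropped.append(p)
            continue
        zero_at = next((v for v in obs
                        if cohort.X[v][p].to_numpy().sum() == 0), None)
        if zero_at is not None:
            rows.append((p, zero_at, 1))
        else:
            rows.append((p, followup[p], 0))
    if dropped:
        warnings.warn(f"{len(dropped)} patient(s) with no follow-up excluded "
                      f"from survival data: {dropped[:5]}...")
    return pd.DataFrame(rows, columns=["patient_id", "time", "event"]) \
        .set_index("patient_id")


@dataclass
class CoxFit:
    """Cox proportional-hazards fit: hazard ratios, CIs and global tests."""

    table: pd.DataFrame     # per covariate level: beta, HR, CI, z, p
    lr_statistic: float     # partial-likelihood ratio test
    lr_p: float
    r2: float               # Cox–Snell form 1 - exp(-LR/n)
    n: int
    n_events: int
    fitter: CoxPHFitter

    def summary(self) -> str:
        return (f"Cox PH: n={self.n}, events={self.n_events}; "
                f"LR chi2={self.lr_statistic:.2f}, p={self.lr_p:.3g}, "
                f"R2={self.r2:.3f}\n" + self.table.to_string())


def fit_cox(surv: pd.DataFrame, covariates: list[str],
            reference: dict[str, str] | None = None) -> CoxFit:
    """Multivariate Cox PH on time-to-zero data with categorical covariates.

    ``surv`` carries ``time``, ``event`` and the covariate columns;
    categorical covariates are one-hot encoded against the declared (or
    first alphabetical) reference level.  Efron tie handling throughout.
    Non-convergence (e.g. monotone likelihood from a perfectly separated
    level) is re-raised with a diagnostic rather than silently ignored.
    """
    if not covariates:
        raise ValueError("no covariates to estimate")
    if int(surv["event"].sum()) < 2:
        raise ValueError("need at least 2 events")
    reference = reference or {}
    df = surv[["time", "event"]].copy()
    for c in covariates:
        col = surv[c].astype(str)
        levels = sorted(col.unique())
        if len(levels) < 2:
            raise ValueError(f"covariate {c!r} has a single level; nothing to estimate")
        ref = reference.get(c, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not found in covariate {c!r}")
        for lv in levels:
            if lv != ref:
                df[f"{c}[{lv}]"] = (col == lv).astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as err:  # noqa: BLE001 - surface the diagnostic
        raise RuntimeError(
            f"Cox model failed to converge ({err}); check for empty or "
            f"perfectly separated covariate levels") from err
    s = cph.summary
    table = pd.DataFrame({
        "beta": s["coef"],
        "HR": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "z": s["z"],
        "p": s["p"],
    })
    lr = cph.log_likelihood_ratio_test()
    n = len(df)
    return CoxFit(table=table, lr_statistic=float(lr.test_statistic),
                  lr_p=float(lr.p_value), r2=float(1 - np.exp(-lr.test_statistic / n)),
                  n=n, n_events=int(df["event"].sum()), fitter=cph)


def logrank(surv: pd.DataFrame, grouping: str | pd.Series) -> tuple[float, float]:
    """Log-rank test across the levels of a grouping variable."""
    g = surv[grouping] if isinstance(grouping, str) else grouping.reindex(surv.index)
    res = multivariate_logrank_test(surv["time"], g, surv["event"])
    return float(res.test_statistic), float(res.p_value)


def km_curve(surv: pd.DataFrame, grouping: str | pd.Series) -> pd.DataFrame:
    """Kaplan–Meier curves per group: proportion still with active joints.

    Returns tidy rows (group, time, at_risk, surviving); the curve starts
    at 1 at time 0 and is non-increasing.
    """
    g = surv[grouping] if isinstance(grouping, str) else grouping.reindex(surv.index)
    rows = []
    for level in sorted(g.astype(str).unique()):
        sub = surv[g.astype(str) == level]
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"], label=str(level))
        sf = km.survival_function_
        ev = km.event_table["at_risk"].reindex(sf.index)
        for t, val in sf.iloc[:, 0].items():
            rows.append((level, float(t), float(ev.loc[t]), float(val)))
    return pd.DataFrame(rows, columns=["group", "time", "at_risk", "surviving"])
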
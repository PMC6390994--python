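"""Degree of localization: how closely a patient matches their pattern.

The degree of localization is the fraction of a patient's active joints
that are key joints of their assigned group's high-level factor.  Patients
are classified by closed thresholds:

* **localized** — fraction ≥ 90%;
* **partially localized** — 60% ≤ fraction < 90%;
* **extended** — fraction < 60%.

Fractions are computed in exact rational arithmetic before comparison, so
a patient with 9 of 10 active joints in their key set sits exactly on the
0.9 boundary and is localized — no floating-point drift at the 0.6 / 0.9
cuts.  Localization is always measured against the *assigned* group's key
set, not the best-matching one.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CATEGORIES", "degree_of_localization", "categorize", "localize",
           "localization_skew", "threshold_sweep"]

CATEGORIES = ("localized", "partial", "extended")

_LOCALIZED = Fraction(9, 10)
_PARTIAL = Fraction(3, 5)


def categorize(fraction: Fraction,
               localized_threshold: Fraction = _LOCALIZED,
               partial_threshold: Fraction = _PARTIAL) -> str:
    """Classify an exact key-joint fraction by the closed thresholds."""
    if fraction >= localized_threshold:
        return "localized"
    if fraction >= partial_threshold:
        return "partial"
    return "extended"


@dataclass(frozen=True)
class LocalizationRow:
    n_active: int
    n_key: int
    fraction: Fraction
    category: str


def degree_of_localization(active_joints: set, key_joints: set,
                           **thresholds) -> LocalizationRow:
    """Exact key-joint fraction and category for one patient.

    ``active_joints`` must be nonempty; ``key_joints`` is the key set of
    the patient's assigned high-level factor.
    """
    n_active = len(active_joints)
    if n_active == 0:
        raise ValueError("patient has no active joints")
    n_key = len(set(active_joints) & set(key_joints))
    frac = Fraction(n_key, n_active)
    return LocalizationRow(n_active=n_active, n_key=n_key, fraction=frac,
                           category=categorize(frac, **thresholds))


def localize(X: pd.DataFrame, assignment, key_joints: list[set]) -> pd.DataFrame:
    """Per-patient localization table for a baseline matrix.

    Parameters
    ----------
    X : joints × patients binary matrix.
    assignment : :class:`~jointfactor.multilayer.GroupAssignment`.
    key_joints : per high-level factor key sets (``results.key_joints``).

    Unscored patients get NaN fraction and category ``"unscored"``.
    """
    rows = []
    for p in X.columns:
        active = set(X.index[X[p].to_numpy() == 1])
        g = assignment.group_index[p]
        if g == -1:
            rows.append((p, len(active), np.nan, np.nan, "unscored"))
            continue
        r = degree_of_localization(active, key_joints[g])
        rows.append((p, r.n_active, r.n_key, float(r.fraction), r.category))
    out = pd.DataFrame(rows, columns=["patient_id", "n_active", "n_key",
                                      "fraction", "category"]).set_index("patient_id")
    out["group"] = assignment.group_name
    return out


def localization_skew(loc: pd.DataFrame) -> pd.DataFrame:
    """Per-group χ² of the localization distribution against the global one.

    For every patient group, a goodness-of-fit χ² compares that group's
    (localized, partial, extended) counts with expectations under the
    global category proportions; p-values are Bonferroni-adjusted across
    groups.  The per-category skew direction (above/below expectation) is
    reported alongside.
    """
    scored = loc[loc["category"].isin(CATEGORIES)]
    groups = sorted(scored["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 patient groups")
    global_counts = scored["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    global_prop = global_counts / global_counts.sum()
    nonzero = global_prop[global_prop > 0].index
    rows = []
    for g in groups:
        sub = scored[scored["group"] == g]
        if len(sub) < 1:
            raise ValueError(f"group {g} has no patients")
        obs = sub["category"].value_counts().reindex(nonzero, fill_value=0)
        exp = global_prop[nonzero] * len(sub)
        chi2, p = stats.chisquare(obs.to_numpy(), f_exp=exp.to_numpy())
        direction = {c: ("above" if obs[c] > exp[c] else
                         "below" if obs[c] < exp[c] else "equal") for c in nonzero}
        rows.append((g, len(sub), chi2, p, direction))
    out = pd.DataFrame(rows, columns=["group", "n", "chi2", "p", "direction"])
    out["p_bonferroni"] = np.minimum(out["p"] * len(groups), 1.0)
    out["significant"] = out["p_bonferroni"] < 0.05
    return out


def threshold_sweep(fractions, thresholds=None, n_boot: int = 2000,
                    seed: int | None = None) -> pd.DataFrame:
    """Proportion of patients at or above each localization threshold.

    For each candidate threshold t, reports mean(fraction ≥ t) with a
    bootstrap standard error over ``n_boot`` patient resamples.
    """
    fr = np.asarray([float(f) for f in fractions])
    if fr.size == 0:
        raise ValueError("fractions must be nonempty")
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, fr.size, size=(n_boot, fr.size))
    rows = []
    for t in np.atleast_1d(thresholds):
        hit = fr >= t
        prop = float(hit.mean())
        se = float(hit[boot_idx].mean(axis=1).std(ddof=1)) if n_boot > 1 else 0.0
        rows.append((float(t), prop, se))
    return pd.DataFrame(rows, columns=["threshold", "proportion", "se"])
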
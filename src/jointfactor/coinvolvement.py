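"""Pairwise joint co-involvement statistics and left/right symmetry tests.

Given a baseline joints × patients binary matrix, this module computes

* involvement frequencies ``P(x)``, pairwise co-involvement ``P(x, y)`` (the
  proportion of patients with both joints active) and conditional
  co-involvement ``P(y | x)`` — the fraction of patients with the reference
  joint *x* involved who also have *y* involved;
* a same-side versus opposite-side *skew* z-score per joint-type pair, with
  a χ² test of the same/opposite patient counts and Benjamini–Hochberg FDR;
* a permutation test of global left/right mirror symmetry of the
  conditional matrix (Frobenius norm between the two opposite-side
  quadrants, null built by independently flipping each patient's sides).

The skew statistic for a reference joint type *x* and co-involved type *y*
counts patients carrying a same-side co-involved pair (n_same) and an
opposite-side pair (n_opposite) — each patient contributing at most one to
each count — and sets::

    m = (n_same + 1) / ((n_same + 1) + (n_opposite + 1))
    sigma = sqrt(m (1 - m) / n),   n = (n_same + 1) + (n_opposite + 1)
    z = (m - 0.5) / sigma

so z is near zero for symmetric co-involvement and large positive when
co-involved joints concentrate on the same side of the body.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import JointCatalog

__all__ = [
    "CoinvolvementResult", "coinvolvement", "conditional_screen",
    "skew_test", "lr_symmetry_perm_test", "bh_fdr",
]


@dataclass
class CoinvolvementResult:
    """Involvement frequencies and co-involvement probability matrices.

    ``cond.loc[x, y]`` is P(y | x): reference joint on the rows.  Rows with
    P(x) = 0 are NaN (conditional undefined) and flagged in ``undefined``.
    """

    freq: pd.Series
    pair: pd.DataFrame
    cond: pd.DataFrame
    n_patients: int

    @property
    def undefined(self) -> pd.Series:
        return self.freq == 0

    @property
    def n_ordered_pairs(self) -> int:
        k = len(self.freq)
        return k * k


def coinvolvement(X: pd.DataFrame) -> CoinvolvementResult:
    """Frequencies and (conditional) co-involvement from a binary matrix.

    Parameters
    ----------
    X : joints × patients DataFrame with 0/1 entries, at least one patient.
    """
    if X.shape[1] == 0:
        raise ValueError("empty matrix: no patients")
    A = X.to_numpy(dtype=float)
    if not np.isin(A, (0.0, 1.0)).all():
        raise ValueError("matrix entries must be 0/1")
    n = A.shape[1]
    pair = (A @ A.T) / n
    freq = np.diag(pair).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = pair / freq[:, None]
    cond[freq == 0, :] = np.nan
    idx = X.index
    return CoinvolvementResult(
        freq=pd.Series(freq, index=idx, name="freq"),
        pair=pd.DataFrame(pair, index=idx, columns=idx),
        cond=pd.DataFrame(cond, index=idx, columns=idx),
        n_patients=n,
    )


def conditional_screen(result: CoinvolvementResult, alpha: float = 0.05) -> pd.DataFrame:
    """Screen every ordered pair's P(y|x) against the marginal P(y).

    An exact binomial test of the co-involvement count among patients with
    the reference joint involved, against the null rate P(y); significance
    is Bonferroni-adjusted across all k² ordered pairs (including pairs with
    an undefined conditional, which count toward the correction).
    """
    joints = list(result.freq.index)
    n = result.n_patients
    n_tests = len(joints) ** 2
    rows = []
    for x in joints:
        nx = int(round(result.freq[x] * n))
        for y in joints:
            if nx == 0:
                rows.append((x, y, np.nan, np.nan, False))
                continue
            k = int(round(result.pair.loc[x, y] * n))
            p = stats.binomtest(k, nx, min(max(result.freq[y], 1e-12), 1 - 1e-12)).pvalue
            rows.append((x, y, result.cond.loc[x, y], p, bool(p * n_tests < alpha)))
    return pd.DataFrame(rows, columns=["x", "y", "cond", "p", "significant"])


def skew_test(X: pd.DataFrame, catalog: JointCatalog,
              fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Same-side vs opposite-side skew for every bilateral joint-type pair.

    Counts are per patient (a patient adds at most one to n_same and at most
    one to n_opposite per type pair).  Self-pairs (x_type == y_type) exclude
    the reference joint itself on the same side, so they measure pure
    bilaterality through the opposite-side count.  Returns one row per
    unordered type pair — the counts are symmetric in (x, y) — with the skew
    z, χ² against equal counts, p, and BH FDR (significant iff FDR below
    ``fdr_threshold``).
    """
    types = catalog.bilateral_types
    if not types:
        raise ValueError("catalog has no bilateral joint types")
    idx = catalog.index
    A = X.to_numpy(dtype=bool)
    lr = {t: (A[idx[catalog.pair(t)[0].joint_id]], A[idx[catalog.pair(t)[1].joint_id]])
          for t in types}
    rows = []
    for i, tx in enumerate(types):
        xl, xr = lr[tx]
        for ty in types[i:]:
            yl, yr = lr[ty]
            if tx == ty:
                same = np.zeros_like(xl)  # the same-side member is the joint itself
                opp = xl & xr
            else:
                same = (xl & yl) | (xr & yr)
                opp = (xl & yr) | (xr & yl)
            n_same = int(same.sum())
            n_opp = int(opp.sum())
            m = (n_same + 1) / ((n_same + 1) + (n_opp + 1))
            n_shrunk = (n_same + 1) + (n_opp + 1)
            sigma = np.sqrt(m * (1 - m) / n_shrunk)
            z = (m - 0.5) / sigma
            if n_same + n_opp > 0:
                chi2, p = stats.chisquare([n_same, n_opp])
            else:
                chi2, p = 0.0, 1.0
            rows.append((tx, ty, n_same, n_opp, m, sigma, z, chi2, p))
    out = pd.DataFrame(rows, columns=["x_type", "y_type", "n_same", "n_opposite",
                                      "m", "sigma", "z", "chi2", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def lr_symmetry_perm_test(X: pd.DataFrame, catalog: JointCatalog,
                          n_perm: int = 1000, seed: int | None = None
                          ) -> tuple[float, float]:
    """Permutation test of left/right mirror symmetry of co-involvement.

    The conditional matrix is partitioned by body side; the two
    opposite-side quadrants — P(right y | left x) and P(left y | right x),
    aligned by joint type — are compared by the Frobenius norm of their
    difference.  The null distribution relabels each patient's left/right
    sides independently at random ``n_perm`` times and recomputes the norm.

    Returns ``(frobenius, p)`` with the add-one permutation p-value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    types = catalog.bilateral_types
    idx = catalog.index
    li = np.array([idx[catalog.pair(t)[0].joint_id] for t in types])
    ri = np.array([idx[catalog.pair(t)[1].joint_id] for t in types])
    A = X.to_numpy(dtype=float)

    def norm(mat: np.ndarray) -> float:
        n = mat.shape[1]
        pair = (mat @ mat.T) / n
        freq = np.diag(pair)
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = pair / freq[:, None]
        q1 = cond[np.ix_(li, ri)]  # entry (x, y): P(y right | x left)
        q2 = cond[np.ix_(ri, li)]  # entry (x, y): P(y left | x right)
        diff = q1 - q2  # mirror image swaps both sides, cell by cell
        return float(np.sqrt(np.nansum(diff ** 2)))

    observed = norm(A)
    exceed = 0
    for _ in range(n_perm):
        flip = rng.random(A.shape[1]) < 0.5
        B = A.copy()
        B[np.ix_(li, flip)] = A[np.ix_(ri, flip)]
        B[np.ix_(ri, flip)] = A[np.ix_(li, flip)]
        if norm(B) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return observed, p


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values for a vector of p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
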
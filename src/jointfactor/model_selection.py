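"""Rank and regularization selection by bi-cross-validation (BiCV).

BiCV holds out a row-block × column-block of the data matrix: rows and
columns are independently partitioned into folds, and for each held-out
block A the model is fitted only on the complementary submatrix D, with the
flanking blocks B (same rows as A) and C (same columns as A) used to carry
the fit across::

        ┌ A │ B ┐          Â = B · D̂⁺ · C ,   D̂ = W H  (rank-k fit on D)
        ├───┼───┤
        └ C │ D ┘          D̂⁺ = H⁺ W⁺   (Moore–Penrose through the factors)

Held-out accuracy is Q² = 1 − PRESS/TSS over the held-out entries only;
entries of A are never seen by the fit that predicts them.

Selection rules (one-standard-error parsimony):

* rank — the smallest k whose mean Q² lies within one standard error of
  the best mean Q²;
* alpha — the largest α whose mean Q² lies within one standard error of
  the unpenalized (α = 0) mean Q², i.e. the sparsest model that does not
  measurably cost accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .nmf import NMF, FitConfig

__all__ = ["BiCVGrid", "bicv", "select_rank", "select_alpha"]


@dataclass
class BiCVGrid:
    """Per-(k, alpha, replicate) held-out Q² values plus run metadata."""

    table: pd.DataFrame  # columns: k, alpha, replicate, q2
    folds: int
    replicates: int
    seed: int | None

    def summarize(self) -> pd.DataFrame:
        """Mean and standard error of held-out Q² per (k, alpha)."""
        g = self.table.groupby(["k", "alpha"])["q2"]
        out = g.agg(mean_q2="mean", sd="std", n="count").reset_index()
        out["se"] = (out["sd"].fillna(0.0)) / np.sqrt(out["n"])
        return out.drop(columns="sd")

    def summary(self) -> str:
        s = self.summarize()
        lines = [f"BiCV grid: {self.folds}-fold, {self.replicates} replicate(s), "
                 f"seed={self.seed}", s.to_string(index=False)]
        return "\n".join(lines)


def bicv(X, ranks, alphas=(0.0,), folds: int = 3, replicates: int = 200,
         seed: int | None = None, config: FitConfig | None = None) -> BiCVGrid:
    """Bi-cross-validate a rank × alpha grid.

    Per replicate, rows and columns are partitioned uniformly at random
    into ``folds`` groups; every (row-fold, column-fold) pair is held out in
    turn and predicted by the Owen–Perry block estimator above.  Held-out
    residuals are pooled across the folds of a replicate into a single Q².
    """
    X = np.asarray(X, dtype=float)
    ranks = sorted(set(int(k) for k in np.atleast_1d(ranks)))
    alphas = sorted(set(float(a) for a in np.atleast_1d(alphas)))
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    min_train = min(d - (d // folds + (d % folds > 0)) for d in X.shape)
    if max(ranks) > min_train:
        raise ValueError(f"max rank {max(ranks)} infeasible: training blocks can be "
                         f"as small as {min_train} rows/columns")
    cfg = config if config is not None else FitConfig(max_iter=300, tol=1e-6)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        row_folds = _partition(X.shape[0], folds, rng)
        col_folds = _partition(X.shape[1], folds, rng)
        for k, alpha in product(ranks, alphas):
            resid, held = [], []
            for I, J in product(row_folds, col_folds):
                Ic = np.setdiff1d(np.arange(X.shape[0]), I)
                Jc = np.setdiff1d(np.arange(X.shape[1]), J)
                A = X[np.ix_(I, J)]
                B = X[np.ix_(I, Jc)]
                C = X[np.ix_(Ic, J)]
                D = X[np.ix_(Ic, Jc)]
                res = NMF(D, k, alpha).fit(cfg)
                Dp = np.linalg.pinv(res.H) @ np.linalg.pinv(res.W)
                Ahat = B @ Dp @ C
                resid.append((A - Ahat).ravel())
                held.append(A.ravel())
            held = np.concatenate(held)
            resid = np.concatenate(resid)
            sst = float(np.sum((held - held.mean()) ** 2))
            q2 = np.nan if sst == 0 else 1.0 - float(np.sum(resid ** 2)) / sst
            rows.append((k, alpha, rep, q2))
    table = pd.DataFrame(rows, columns=["k", "alpha", "replicate", "q2"])
    return BiCVGrid(table=table, folds=folds, replicates=replicates, seed=seed)


def _partition(n: int, folds: int, rng) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(b) for b in np.array_split(perm, folds)]


def select_rank(grid: BiCVGrid, alpha: float | None = None) -> int:
    """Smallest rank within one standard error of the best mean Q²."""
    s = grid.summarize()
    if s.empty:
        raise ValueError("empty grid")
    if alpha is None:
        alpha = s["alpha"].min()
    s = s[s["alpha"] == alpha].sort_values("k")
    if s.empty:
        raise ValueError(f"grid has no entries at alpha={alpha}")
    best = s.loc[s["mean_q2"].idxmax()]
    thr = best["mean_q2"] - best["se"]
    return int(s.loc[s["mean_q2"] >= thr, "k"].iloc[0])


def select_alpha(grid: BiCVGrid, k_fixed: int) -> float:
    """Largest alpha whose mean Q² is within one SE of the α = 0 mean Q²."""
    s = grid.summarize()
    s = s[s["k"] == k_fixed].sort_values("alpha")
    if s.empty:
        raise ValueError(f"grid has no entries at k={k_fixed}")
    ref = s.iloc[0]  # smallest alpha (normally 0) is the reference
    thr = ref["mean_q2"] - ref["se"]
    ok = s.loc[s["mean_q2"] >= thr, "alpha"]
    return float(ok.iloc[-1])
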
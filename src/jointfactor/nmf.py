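"""Sparse non-negative matrix factorization by multiplicative updates.

The decomposition X ≈ WH splits a non-negative data matrix (here: joints ×
patients binary involvement) into a loading matrix W, giving the
contribution of each input feature to each factor, and a score matrix H
scoring each sample on each factor.  Because both matrices are constrained
non-negative, reconstruction only ever *adds* groups of features, which is
what makes the factors read as interpretable joint groupings.

The fitted objective is

    L(W, H) = 1/2 ‖X − WH‖²_F + α ‖W‖₁ + α/2 ‖H‖²_F ,

minimised by the classical multiplicative updates

    H ← H ∘ (WᵀX) ⊘ (WᵀWH + αH)
    W ← W ∘ (XHᵀ) ⊘ (WHHᵀ + α) ,

which never increase L.  The sparsity-inducing L1 penalty acts on W —
sparse loadings are the interpretive goal, while sample scores stay dense
for downstream group assignment.  The quadratic (ridge) term on H carries
no sparsity pressure; it pins down the scale indeterminacy of the
factorization (W → W/c, H → cH), without which an L1 penalty on W alone
is vacuous — the optimizer escapes it by deflating W and inflating H.  After fitting, each W column is scaled to unit maximum
(loadings read as 0–100% contributions) with the compensation folded into
H; the per-factor scales are stored so that new data can be projected with
exactly the same scaling ("frozen model" projection).

Sparsification (`NMFResults.sparsify`) zeroes loadings below a fraction of
their column maximum and re-estimates H by per-sample non-negative least
squares with the sparsified W held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

__all__ = ["NMF", "NMFResults", "FitConfig", "fit_nmf", "q2"]

_EPS = 1e-12


@dataclass
class FitConfig:
    """Optimisation settings for :class:`NMF`.

    max_iter : iteration cap per restart.
    tol : relative objective-change stopping criterion.
    n_restarts : number of additional random-uniform restarts beyond the
        deterministic initialisation; the fit with the lowest final
        objective wins (ties broken by restart order).
    seed : seed for the random restarts.
    init : ``"nndsvd"`` (deterministic, SVD-based, default), ``"random"``,
        or ``"cluster"`` — deterministic agglomerative clustering of the
        feature rows by correlation, useful when features are expected to
        partition into factor-aligned blocks (e.g. the second layer of a
        hierarchical fit).
    """

    max_iter: int = 1000
    tol: float = 1e-8
    n_restarts: int = 0
    seed: int | None = 0
    init: str = "nndsvd"

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.init not in ("nndsvd", "random", "cluster"):
            raise ValueError("init must be 'nndsvd', 'random' or 'cluster'")


class NMF:
    """Non-negative factorization model for a fixed data matrix.

    Parameters
    ----------
    X : non-negative matrix (features × samples), array or DataFrame.
    rank : number of factors k, at most min(X.shape).
    alpha : L1 regularization coefficient on W (≥ 0).
    """

    def __init__(self, X, rank: int, alpha: float = 0.0):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.index)
            self.sample_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names = [f"f{i}" for i in range(X.shape[0])]
            self.sample_names = [f"s{j}" for j in range(X.shape[1])]
        if np.any(X < 0):
            raise ValueError("X must be non-negative")
        if not (1 <= rank <= min(X.shape)):
            raise ValueError(f"rank must be in [1, {min(X.shape)}], got {rank}")
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        self.X = X
        self.rank = int(rank)
        self.alpha = float(alpha)

    @classmethod
    def from_cohort(cls, cohort, rank: int, alpha: float = 0.0) -> "NMF":
        """Build the model from a cohort's baseline involvement matrix."""
        return cls(cohort.baseline_matrix, rank, alpha)

    # -- fitting ------------------------------------------------------
    def fit(self, config: FitConfig | None = None,
            init_W: np.ndarray | None = None,
            init_H: np.ndarray | None = None, **kwargs) -> "NMFResults":
        cfg = config if config is not None else FitConfig(**kwargs)
        inits: list[tuple[np.ndarray, np.ndarray]] = []
        if init_W is not None and init_H is not None:
            inits.append((np.asarray(init_W, float).copy(),
                          np.asarray(init_H, float).copy()))
        else:
            rng = np.random.default_rng(cfg.seed)
            if cfg.init == "nndsvd":
                inits.append(_nndsvd_init(self.X, self.rank))
            elif cfg.init == "cluster":
                inits.append(_cluster_init(self.X, self.rank))
            else:
                inits.append(_random_init(self.X, self.rank, rng))
            for _ in range(cfg.n_restarts):
                inits.append(_random_init(self.X, self.rank, rng))
        best = None
        for W0, H0 in inits:
            W, H, trace, converged = _mu_fit(self.X, W0, H0, self.alpha,
                                             cfg.max_iter, cfg.tol)
            if best is None or trace[-1] < best[2][-1]:
                best = (W, H, trace, converged)
        W, H, trace, converged = best
        W, H, scale = _normalize_columns(W, H)
        return NMFResults(model=self, config=cfg, W=W, H=H, scale=scale,
                          objective_trace=np.asarray(trace),
                          converged=converged)


@dataclass
class NMFResults:
    """Fitted factorization: loadings, scores, scaling and diagnostics."""

    model: NMF
    config: FitConfig
    W: np.ndarray          # features × k, columns max-normalized to 1
    H: np.ndarray          # k × samples
    scale: np.ndarray      # per-factor scale folded out of W into H
    objective_trace: np.ndarray
    converged: bool
    sparsify_threshold: float = 0.0
    score_rank_correlations: np.ndarray | None = None  # pre/post sparsify, per factor

    # -- views --------------------------------------------------------
    @property
    def rank(self) -> int:
        return self.W.shape[1]

    @property
    def loadings(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.model.feature_names,
                            columns=[f"factor_{i+1}" for i in range(self.rank)])

    @property
    def scores(self) -> pd.DataFrame:
        return pd.DataFrame(self.H, columns=self.model.sample_names,
                            index=[f"factor_{i+1}" for i in range(self.rank)])

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H

    def q2(self, mask=None, method: str = "press") -> float:
        """Reconstruction accuracy of the fit on its own training data."""
        return q2(self.model.X, self.reconstruct(), mask=mask, method=method)

    # -- sparsification ----------------------------------------------
    def sparsify(self, threshold: float = 0.1) -> "NMFResults":
        """Zero small loadings and re-estimate scores with W held fixed.

        Entries of W below ``threshold`` × (their column maximum) are set to
        zero; H is then re-solved per sample by non-negative least squares.
        Reports the per-factor Spearman rank correlation between pre- and
        post-sparsification sample scores so the user can confirm that
        sparsifying did not reorder patients.
        """
        if not (0 <= threshold < 1):
            raise ValueError("threshold must lie in [0, 1)")
        colmax = self.W.max(axis=0)
        Ws = np.where(self.W < threshold * colmax, 0.0, self.W)
        dead = np.flatnonzero(Ws.max(axis=0) == 0)
        if dead.size:
            raise ValueError(
                f"sparsification zeroed entire factor column(s) {dead.tolist()}; "
                f"use a lower threshold")
        if np.array_equal(Ws, self.W):  # nothing removed: model unchanged
            return replace(self, sparsify_threshold=threshold,
                           score_rank_correlations=np.ones(self.rank))
        Hs = _nnls_scores(Ws, self.model.X)
        corr = np.empty(self.rank)
        for f in range(self.rank):
            if np.ptp(self.H[f]) == 0 or np.ptp(Hs[f]) == 0:
                corr[f] = np.nan
            else:
                corr[f] = stats.spearmanr(self.H[f], Hs[f]).statistic
        return replace(self, W=Ws, H=Hs, sparsify_threshold=threshold,
                       score_rank_correlations=corr)

    def prune_dead_factors(self) -> "NMFResults":
        """Drop factors whose loading column collapsed to zero during fitting.

        With a strong L1 penalty the multiplicative updates can drive an
        entire (redundant) loading column to zero; such factors carry no
        signal and are removed, shrinking the effective rank.
        """
        keep = self.W.max(axis=0) > 0
        if keep.all():
            return self
        return replace(self, W=self.W[:, keep], H=self.H[keep, :],
                       scale=self.scale[keep],
                       score_rank_correlations=None
                       if self.score_rank_correlations is None
                       else self.score_rank_correlations[keep])

    # -- projection ---------------------------------------------------
    def project(self, X_new) -> np.ndarray:
        """Score new samples on the frozen factors.

        Solves a non-negative least-squares problem per sample with W and
        the stored scaling held fixed; deterministic given its inputs.  If
        ``X_new`` is a DataFrame its rows must match the model's feature
        names in order.
        """
        if isinstance(X_new, pd.DataFrame):
            if list(X_new.index) != list(self.model.feature_names):
                raise ValueError("feature names/order of X_new do not match the model")
            X_new = X_new.to_numpy(dtype=float)
        else:
            X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[0] != self.W.shape[0]:
            raise ValueError(f"X_new has {X_new.shape[0]} features, model has "
                             f"{self.W.shape[0]}")
        return _nnls_scores(self.W, X_new)

    # -- reporting ----------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Non-negative matrix factorization",
            "=" * 48,
            f"data shape:          {self.model.X.shape[0]} features x "
            f"{self.model.X.shape[1]} samples",
            f"rank:                {self.rank}",
            f"alpha (L1 on W):     {self.model.alpha:g}",
            f"converged:           {self.converged}",
            f"iterations:          {len(self.objective_trace) - 1}",
            f"final objective:     {self.objective:.6g}",
            f"fit Q2 (all cells):  {q2(self.model.X, self.reconstruct()):.4f}",
            f"sparsify threshold:  {self.sparsify_threshold:g}",
            f"W nonzeros:          {int(np.count_nonzero(self.W))} / {self.W.size}",
        ]
        if self.score_rank_correlations is not None:
            cs = ", ".join(f"{c:.3f}" for c in self.score_rank_correlations)
            lines.append(f"score rank corr (pre/post sparsify): [{cs}]")
        return "\n".join(lines)


# ---------------------------------------------------------------------
# numeric core
# ---------------------------------------------------------------------

def _objective(X, W, H, alpha) -> float:
    R = X - W @ H
    return (0.5 * float(np.sum(R * R)) + alpha * float(np.abs(W).sum())
            + 0.5 * alpha * float(np.sum(H * H)))


def _mu_fit(X, W, H, alpha, max_iter, tol):
    trace = [_objective(X, W, H, alpha)]
    converged = False
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + alpha * H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + alpha + _EPS)
        obj = _objective(X, W, H, alpha)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break
    return W, H, trace, converged


def _normalize_columns(W, H):
    scale = W.max(axis=0)
    safe = np.where(scale > 0, scale, 1.0)
    return W / safe, H * safe[:, None], scale


def _random_init(X, k, rng):
    lo = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    W = rng.uniform(0, 2 * lo, size=(X.shape[0], k))
    H = rng.uniform(0, 2 * lo, size=(k, X.shape[1]))
    return W, H


def _nndsvd_init(X, k):
    """Deterministic SVD-based init; zeros filled with the matrix mean."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((X.shape[0], k))
    H = np.zeros((k, X.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        u, v = U[:, j], Vt[j, :]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        n_p = np.linalg.norm(up) * np.linalg.norm(vp)
        n_n = np.linalg.norm(un) * np.linalg.norm(vn)
        if n_p >= n_n:
            if n_p > 0:
                W[:, j] = np.sqrt(S[j] * n_p) * up / np.linalg.norm(up)
                H[j, :] = np.sqrt(S[j] * n_p) * vp / np.linalg.norm(vp)
        else:
            W[:, j] = np.sqrt(S[j] * n_n) * un / np.linalg.norm(un)
            H[j, :] = np.sqrt(S[j] * n_n) * vn / np.linalg.norm(vn)
    fill = X.mean() if X.mean() > 0 else 1e-6
    W[W <= 0] = fill
    H[H <= 0] = fill
    return W, H


def _cluster_init(X, k):
    """Deterministic init from average-linkage clustering of feature rows.

    Feature rows are clustered by correlation distance into k groups;
    W starts as (soft) cluster membership and H as the cluster-mean
    profiles.  Steers the updates toward block-partition solutions.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    D = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    labels = fcluster(linkage(D, method="average"), k, criterion="maxclust")
    W = np.where(labels[:, None] == np.arange(1, k + 1)[None, :], 1.0, 0.01)
    H = np.empty((k, X.shape[1]))
    fill = max(X.mean(), 1e-6)
    for f in range(1, k + 1):
        members = labels == f
        H[f - 1] = X[members].mean(axis=0) if members.any() else fill
    H[H <= 0] = fill * 1e-2
    return W, H


def _nnls_scores(W, X):
    """Solve min_{h>=0} ||x - W h|| column by column."""
    k = W.shape[1]
    H = np.empty((k, X.shape[1]))
    for j in range(X.shape[1]):
        H[:, j] = nnls(W, X[:, j])[0]
    return H


# ---------------------------------------------------------------------
# functional conveniences
# ---------------------------------------------------------------------

def fit_nmf(X, k: int, alpha: float = 0.0,
            config: FitConfig | None = None, **kwargs) -> NMFResults:
    """Functional wrapper: ``NMF(X, k, alpha).fit(config)``."""
    return NMF(X, k, alpha).fit(config, **kwargs)


def q2(X, Xhat, mask=None, method: str = "press") -> float:
    """Held-out reconstruction accuracy.

    ``press`` (default): 1 − Σ_mask (X − X̂)² / Σ_mask (X − mean(X over
    mask))², the cross-validated R²; may be negative when the prediction is
    worse than the mask mean.  ``corr``: squared Pearson correlation between
    X and X̂ over the mask.
    """
    X = np.asarray(X, float)
    Xhat = np.asarray(Xhat, float)
    if X.shape != Xhat.shape:
        raise ValueError("shape mismatch")
    if mask is None:
        x, xh = X.ravel(), Xhat.ravel()
    else:
        mask = np.asarray(mask)
        if mask.dtype == bool:
            x, xh = X[mask], Xhat[mask]
        else:
            x, xh = X.ravel()[mask], Xhat.ravel()[mask]
    sst = float(np.sum((x - x.mean()) ** 2))
    if sst == 0:
        raise ValueError("data constant over the evaluation mask; Q2 undefined")
    if method == "press":
        return 1.0 - float(np.sum((x - xh) ** 2)) / sst
    if method == "corr":
        return float(np.corrcoef(x, xh)[0, 1] ** 2)
    raise ValueError("method must be 'press' or 'corr'")
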
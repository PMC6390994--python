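"""Two-layer hierarchical NMF: factors of factors, key joints, patient groups.

The first layer factorizes the joints × patients matrix into tight
"low-level" joint groupings; the second layer factorizes the (rescaled)
low-level patient scores to find "high-level" factors — groupings of
groupings that frequently co-occur.  Multiplying the sparsified loadings of
the two layers yields a *composite* joints × high-level-factors matrix C;
the **key joints** of a high-level factor are the joints with strictly
positive composite loading.  Each patient is assigned to the **patient
group** of their highest-scoring high-level factor.

The layer-2 input is the post-sparsification, re-estimated layer-1 score
matrix with each factor's score row rescaled to unit maximum; the row
scales are stored so external data can be projected with the same scaling
("frozen" projection, used for validation cohorts and follow-up visits).
"""

from __future__ import annotations

from dataclasses import dataclass
from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .coinvolvement import bh_fdr
from .nmf import NMF, FitConfig, NMFResults, q2

__all__ = ["MultilayerNMF", "MultilayerResults", "GroupAssignment",
           "AssociationTable", "fit_multilayer", "group_factor_overlap",
           "group_label_association", "UNSCORED"]

#: reserved group index for patients whose projected scores are all zero
UNSCORED = -1


class MultilayerNMF:
    """Hierarchical two-layer NMF model for a binary involvement matrix.

    Parameters
    ----------
    X : joints × patients binary matrix (DataFrame keeps joint/patient ids).
    k1, k2 : low-level and high-level ranks.  ``k1=19, k2=7`` are the
        defaults for homunculus-shaped (71-joint) data.
    alpha1, alpha2 : L1 penalties on the two layers' loading matrices.
        The defaults are calibrated on planted-structure synthetic cohorts
        of homunculus shape (≈71 joints × several hundred patients); for
        other data scales select them by bi-cross-validation
        (:func:`~jointfactor.model_selection.select_alpha`).
    threshold1, threshold2 : sparsification fractions (of each loading
        column's maximum) applied after each layer's fit; ``threshold2``
        is also applied to the composite loading columns.
    layer2_init : initialisation for the second layer
        (default ``"cluster"`` — deterministic correlation clustering of
        the low-level score rows, which reliably steers the second layer
        toward the block grouping structure).
    """

    def __init__(self, X, k1: int = 19, k2: int = 7,
                 alpha1: float = 3.0, alpha2: float = 2.0,
                 threshold1: float = 0.1, threshold2: float = 0.1,
                 layer2_init: str = "cluster"):
        if k2 > k1:
            raise ValueError("k2 must not exceed k1")
        self.X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        self.k1, self.k2 = int(k1), int(k2)
        self.alpha1, self.alpha2 = float(alpha1), float(alpha2)
        self.threshold1, self.threshold2 = float(threshold1), float(threshold2)
        self.layer2_init = layer2_init

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "MultilayerNMF":
        return cls(cohort.baseline_matrix, **kwargs)

    def fit(self, config: FitConfig | None = None, **kwargs) -> "MultilayerResults":
        cfg = config if config is not None else FitConfig(**kwargs)
        layer1 = (NMF(self.X, self.k1, self.alpha1).fit(cfg)
                  .prune_dead_factors().sparsify(self.threshold1))
        h1_scale = layer1.H.max(axis=1)
        if np.any(h1_scale == 0):
            dead = np.flatnonzero(h1_scale == 0).tolist()
            raise ValueError(f"low-level factor(s) {dead} have all-zero scores; "
                             f"reduce k1 or alpha1")
        H1s = layer1.H / h1_scale[:, None]
        cfg2 = dc_replace(cfg, init=self.layer2_init)
        layer2 = (NMF(H1s, self.k2, self.alpha2).fit(cfg2)
                  .prune_dead_factors().sparsify(self.threshold2))
        if layer2.rank < self.k2:
            raise ValueError(f"only {layer2.rank} of {self.k2} high-level factors "
                             f"survived fitting; reduce k2 or alpha2")
        composite_raw = layer1.W @ (h1_scale[:, None] * layer2.W)
        # the composite is sparsified by the same relative rule as each layer
        comp_scale = composite_raw.max(axis=0)
        if np.any(comp_scale == 0):
            dead = np.flatnonzero(comp_scale == 0).tolist()
            raise ValueError(f"high-level factor(s) {dead} have an empty composite "
                             f"loading; reduce k2 or the sparsify thresholds")
        composite_raw = np.where(
            composite_raw < self.threshold2 * comp_scale, 0.0, composite_raw)
        return MultilayerResults(model=self, layer1=layer1, layer2=layer2,
                                 h1_scale=h1_scale, composite_raw=composite_raw)


@dataclass
class MultilayerResults:
    """Fitted hierarchy: both layers, scaling, composite loadings, groups."""

    model: MultilayerNMF
    layer1: NMFResults   # sparsified, joints × k1
    layer2: NMFResults   # sparsified, k1 × k2
    h1_scale: np.ndarray  # per-low-level-factor row scale (unit-max rescale)
    composite_raw: np.ndarray  # joints × k2, on the scale of X

    # -- views --------------------------------------------------------
    @property
    def joint_ids(self) -> list[str]:
        return list(self.model.X.index)

    @property
    def factor_names(self) -> list[str]:
        return [f"G{i+1}" for i in range(self.model.k2)]

    @property
    def composite(self) -> pd.DataFrame:
        """Composite loadings, column max-normalized to 1 (0–100% reading)."""
        scale = self.composite_raw.max(axis=0)
        return pd.DataFrame(self.composite_raw / scale, index=self.joint_ids,
                            columns=self.factor_names)

    @property
    def key_joints(self) -> list[set[str]]:
        """Per high-level factor: joints with strictly positive composite."""
        C = self.composite_raw
        ids = np.asarray(self.joint_ids)
        return [set(ids[C[:, f] > 0]) for f in range(C.shape[1])]

    @property
    def H2(self) -> np.ndarray:
        return self.layer2.H

    # -- projection through the frozen hierarchy ----------------------
    def project_layer1(self, X_new) -> np.ndarray:
        """Low-level scores of new data, rescaled by the stored row scales."""
        H1n = self.layer1.project(X_new)
        return H1n / self.h1_scale[:, None]

    def project(self, X_new) -> np.ndarray:
        """High-level scores of new data through both frozen layers."""
        return self.layer2.project(self.project_layer1(X_new))

    # -- group assignment ---------------------------------------------
    def assign_groups(self, scores_or_X=None) -> "GroupAssignment":
        """Assign each patient to their highest-scoring high-level factor.

        Accepts a k2 × patients score matrix, a raw joints × patients
        matrix (projected through both frozen layers first), or nothing
        (training scores).  Ties are flagged and broken toward the lowest
        factor index; all-zero score vectors go to the reserved
        ``UNSCORED`` group.
        """
        if scores_or_X is None:
            H2 = self.layer2.H
            names = list(self.model.X.columns)
        else:
            arr = scores_or_X.to_numpy(dtype=float) \
                if isinstance(scores_or_X, pd.DataFrame) else np.asarray(scores_or_X, float)
            if arr.shape[0] == self.model.k2:
                H2 = arr
            elif arr.shape[0] == len(self.joint_ids):
                H2 = self.project(scores_or_X)
            else:
                raise ValueError(f"input has {arr.shape[0]} rows; expected k2="
                                 f"{self.model.k2} scores or {len(self.joint_ids)} joints")
            names = list(scores_or_X.columns) if isinstance(scores_or_X, pd.DataFrame) \
                else [f"s{j}" for j in range(H2.shape[1])]
        return GroupAssignment.from_scores(H2, names, self.factor_names)

    # -- multilevel reconstruction accuracy ----------------------------
    def q2_levels(self, X_new=None) -> dict[str, float]:
        """Q² of reconstruction at the low, high and group level.

        Group-level reconstruction represents each patient by their
        group's composite column scaled by the group's mean score on its
        own factor (one-hot membership times the group centroid score) —
        the coarsest, hard-clustering view of the model.
        """
        X = self.model.X if X_new is None else X_new
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        H1s = self.project_layer1(X) if X_new is not None \
            else self.layer1.H / self.h1_scale[:, None]
        H2 = self.layer2.project(H1s) if X_new is not None else self.layer2.H
        low = q2(Xa, self.layer1.W @ (H1s * self.h1_scale[:, None]))
        high = q2(Xa, self.composite_raw @ H2)
        assign = GroupAssignment.from_scores(H2, list(range(H2.shape[1])),
                                             self.factor_names)
        Hg = np.zeros_like(H2)
        for f in range(self.model.k2):
            members = assign.group_index == f
            if members.any():
                Hg[f, members.to_numpy()] = H2[f, members.to_numpy()].mean()
        group = q2(Xa, self.composite_raw @ Hg)
        return {"low": low, "high": high, "group": group}

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Archive both layers, scalings, thresholds and the training data."""
        import json

        np.savez(
            path,
            X=self.model.X.to_numpy(dtype=float),
            joints=np.asarray(self.joint_ids, dtype=object),
            patients=np.asarray(list(self.model.X.columns), dtype=object),
            W1=self.layer1.W, H1=self.layer1.H, scale1=self.layer1.scale,
            W2=self.layer2.W, H2=self.layer2.H, scale2=self.layer2.scale,
            h1_scale=self.h1_scale, composite_raw=self.composite_raw,
            params=json.dumps({
                "k1": self.model.k1, "k2": self.model.k2,
                "alpha1": self.model.alpha1, "alpha2": self.model.alpha2,
                "threshold1": self.model.threshold1,
                "threshold2": self.model.threshold2,
                "seed": self.layer1.config.seed,
            }),
        )

    @classmethod
    def load(cls, path) -> "MultilayerResults":
        import json

        from dataclasses import replace as _replace

        z = np.load(path, allow_pickle=True)
        params = json.loads(str(z["params"]))
        X = pd.DataFrame(z["X"], index=list(z["joints"]), columns=list(z["patients"]))
        model = MultilayerNMF(X, k1=params["k1"], k2=params["k2"],
                              alpha1=params["alpha1"], alpha2=params["alpha2"],
                              threshold1=params["threshold1"],
                              threshold2=params["threshold2"])

        def rebuild(Xin, W, H, scale, alpha, thr):
            m = NMF(Xin, W.shape[1], alpha)
            return NMFResults(model=m, config=FitConfig(seed=params.get("seed")),
                              W=W, H=H, scale=scale,
                              objective_trace=np.array([np.nan]), converged=True,
                              sparsify_threshold=thr)

        layer1 = rebuild(X, z["W1"], z["H1"], z["scale1"], params["alpha1"],
                         params["threshold1"])
        H1s = pd.DataFrame(z["H1"] / z["h1_scale"][:, None])
        layer2 = rebuild(H1s, z["W2"], z["H2"], z["scale2"], params["alpha2"],
                         params["threshold2"])
        return cls(model=model, layer1=layer1, layer2=layer2,
                   h1_scale=z["h1_scale"], composite_raw=z["composite_raw"])

    def summary(self) -> str:
        sizes = self.assign_groups().sizes()
        lines = [
            "Multilayer NMF",
            "=" * 48,
            f"data:        {self.model.X.shape[0]} joints x {self.model.X.shape[1]} patients",
            f"layer 1:     k1={self.model.k1}, alpha1={self.model.alpha1:g}, "
            f"threshold={self.model.threshold1:g}",
            f"layer 2:     k2={self.model.k2}, alpha2={self.model.alpha2:g}, "
            f"threshold={self.model.threshold2:g}",
            f"key joints:  " + ", ".join(f"{n}:{len(k)}" for n, k in
                                         zip(self.factor_names, self.key_joints)),
            f"group sizes: " + ", ".join(f"{n}:{sizes.get(n, 0)}"
                                         for n in self.factor_names),
        ]
        q = self.q2_levels()
        lines.append(f"training Q2: low={q['low']:.3f}, high={q['high']:.3f}, "
                     f"group={q['group']:.3f}")
        return "\n".join(lines)


@dataclass
class GroupAssignment:
    """Per-patient highest-scoring group with tie and unscored flags."""

    scores: pd.DataFrame       # k2 × patients
    group_index: pd.Series     # patient -> 0-based factor index, UNSCORED if all-zero
    is_tie: pd.Series
    factor_names: list[str]

    @classmethod
    def from_scores(cls, H2: np.ndarray, patient_ids, factor_names) -> "GroupAssignment":
        H2 = np.asarray(H2, dtype=float)
        gi = np.argmax(H2, axis=0)  # argmax takes the lowest index on ties
        best = H2[gi, np.arange(H2.shape[1])]
        tie = (H2 == best).sum(axis=0) > 1
        gi = np.where(best == 0, UNSCORED, gi)
        tie = np.where(best == 0, False, tie)
        scores = pd.DataFrame(H2, index=factor_names, columns=patient_ids)
        return cls(scores=scores,
                   group_index=pd.Series(gi, index=patient_ids, name="group"),
                   is_tie=pd.Series(tie, index=patient_ids, name="is_tie"),
                   factor_names=list(factor_names))

    @property
    def group_name(self) -> pd.Series:
        return self.group_index.map(
            lambda g: "UNSCORED" if g == UNSCORED else self.factor_names[g])

    def sizes(self) -> dict[str, int]:
        return self.group_name.value_counts().to_dict()

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.T.copy()
        out.insert(0, "group", self.group_name)
        out.insert(1, "is_tie", self.is_tie)
        return out


# ---------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------

def group_factor_overlap(assignment: GroupAssignment,
                         fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Which patient groups score higher than expected on which factors.

    Scores are normalized patient-wise to each patient's maximum score,
    then z-transformed factor-wise across patients.  A one-sided z-test per
    (group, factor) asks whether the group's mean normalized score exceeds
    the overall mean; p-values are BH-adjusted and significant below
    ``fdr_threshold``.
    """
    keep = assignment.group_index != UNSCORED
    if keep.sum() == 0:
        raise ValueError("no scored patients")
    H = assignment.scores.loc[:, keep.to_numpy()].to_numpy()
    groups = assignment.group_index[keep]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 patient groups")
    norm = H / H.max(axis=0, keepdims=True)
    sd = norm.std(axis=1, keepdims=True, ddof=0)
    if np.any(sd == 0):
        raise ValueError("factor with zero score variance after normalization")
    Z = (norm - norm.mean(axis=1, keepdims=True)) / sd
    rows = []
    for g in sorted(groups.unique()):
        members = (groups == g).to_numpy()
        n_g = int(members.sum())
        for f, fname in enumerate(assignment.factor_names):
            zstat = Z[f, members].mean() * np.sqrt(n_g)
            p = stats.norm.sf(zstat)
            rows.append((assignment.factor_names[g], fname, n_g, zstat, p))
    out = pd.DataFrame(rows, columns=["group", "factor", "n", "z", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    return out


@dataclass
class AssociationTable:
    """χ² contingency decomposition of patient groups against labels."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    residual: pd.DataFrame   # adjusted standardized (Pearson) residuals
    enriched: pd.DataFrame   # residual >= threshold
    chi2: float
    p: float
    dof: int

    def summary(self) -> str:
        cells = [(g, l) for g in self.enriched.index for l in self.enriched.columns
                 if self.enriched.loc[g, l]]
        return (f"chi2 = {self.chi2:.1f}, dof = {self.dof}, p = {self.p:.3g}\n"
                f"enriched cells (adjusted residual >= 1.96): {cells}")


def group_label_association(assignment: GroupAssignment, labels: pd.Series,
                            residual_threshold: float = 1.96) -> AssociationTable:
    """χ² test of the group × label contingency table with cell residuals.

    Standardized residuals use the adjusted (Pearson) form
    (obs − exp) / sqrt(exp · (1 − row_prop) · (1 − col_prop)), so the 1.96
    enrichment cut reads as a normal 5% quantile.
    """
    keep = assignment.group_index != UNSCORED
    groups = assignment.group_name[keep]
    labels = labels.reindex(groups.index)
    if labels.isna().any():
        raise ValueError("labels missing for some patients")
    if labels.nunique() < 2:
        raise ValueError("labels must cover at least 2 categories")
    empty = [l for l, c in labels.value_counts().items() if c == 0]
    if empty:
        raise ValueError(f"label(s) with zero patients: {empty}")
    obs = pd.crosstab(groups, labels)
    chi2, p, dof, exp = stats.chi2_contingency(obs.to_numpy(), correction=False)
    exp = pd.DataFrame(exp, index=obs.index, columns=obs.columns)
    n = obs.to_numpy().sum()
    rp = obs.sum(axis=1).to_numpy() / n
    cp = obs.sum(axis=0).to_numpy() / n
    denom = np.sqrt(exp.to_numpy() * (1 - rp[:, None]) * (1 - cp[None, :]))
    resid = pd.DataFrame((obs.to_numpy() - exp.to_numpy()) / denom,
                         index=obs.index, columns=obs.columns)
    return AssociationTable(observed=obs, expected=exp, residual=resid,
                            enriched=resid >= residual_threshold,
                            chi2=float(chi2), p=float(p), dof=int(dof))


def fit_multilayer(X, k1: int = 19, alpha1: float = 3.0, k2: int = 7,
                   alpha2: float = 2.0, config: FitConfig | None = None,
                   **kwargs) -> MultilayerResults:
    """Functional wrapper over :class:`MultilayerNMF`."""
    return MultilayerNMF(X, k1=k1, k2=k2, alpha1=alpha1, alpha2=alpha2,
                         **kwargs).fit(config)
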
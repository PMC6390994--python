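"""Synthetic cohorts with planted hierarchical structure and known outcomes.

Because the clinical registries behind this kind of analysis are not
publicly deposited, every downstream module is exercised on synthetic
cohorts with *known* ground truth.  The generator plants:

* **low-level supports** — tight joint groupings, by default one bilateral
  joint type each (both knees, both wrists, ...), ordered along the
  vertical body axis;
* **high-level supports** — groupings of low-level supports covering
  contiguous stretches of the body axis; the union of a high-level
  support's joints is its key-joint set;
* **mixed localization** — each patient draws a group and a localization
  category; localized patients activate only key joints, partially
  localized and extended patients add non-key joints until their exact
  key-joint fraction lands in [0.6, 0.9) or [0, 0.6) respectively;
* **bilateral symmetry** — within an activated joint pair both sides light
  up together with probability ``bilateral_coupling`` (default 0.8),
  mirroring the predominantly symmetric involvement of the disease;
* **longitudinal resolution** — at each follow-up visit every active joint
  resolves independently with a per-(localization) hazard, so time to
  zero joints carries a known monotone ordering (localized fastest);
* symmetric measurement noise at ``noise_rate`` per joint.

Ground-truth localization categories are recomputed from the final
(post-noise) matrices with the localization module, so generated labels
and recomputed labels agree exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import JointCatalog, default_catalog
from .cohort import DEFAULT_SCHEDULE, CohortTable
from .localization import degree_of_localization

__all__ = ["PlantedModel", "make_planted_model", "simulate_baseline",
           "simulate_course", "simulate_cohort"]

#: per-visit, per-joint probability that an active joint resolves
DEFAULT_RESOLUTION_HAZARD = {"localized": 0.5, "partial": 0.35, "extended": 0.25}

#: observed study proportions of (localized, partial, extended) involvement
DEFAULT_LOCALIZATION_MIX = (359 / 640, 124 / 640, 157 / 640)


@dataclass
class PlantedModel:
    """Ground-truth generative structure for a synthetic cohort."""

    catalog: JointCatalog
    low_level_supports: list[list[str]]      # joint ids per low-level factor
    high_level_supports: list[list[int]]     # low-level indices per high-level factor
    group_weights: np.ndarray
    noise_rate: float = 0.02
    localization_mix: tuple = DEFAULT_LOCALIZATION_MIX
    resolution_hazard: dict = field(default_factory=lambda: dict(DEFAULT_RESOLUTION_HAZARD))
    bilateral_coupling: float = 0.8
    support_activation: float = 0.7          # P(a group's low-level support is active)
    flare_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(len(s) == 0 for s in self.low_level_supports):
            raise ValueError("low-level supports must be nonempty")
        if any(len(s) == 0 for s in self.high_level_supports):
            raise ValueError("high-level supports must be nonempty")
        self.group_weights = np.asarray(self.group_weights, dtype=float)
        if not np.isclose(self.group_weights.sum(), 1.0):
            raise ValueError("group_weights must sum to 1")
        for r in (self.noise_rate, self.bilateral_coupling, self.support_activation,
                  self.flare_rate, *self.resolution_hazard.values()):
            if not 0 <= r <= 1:
                raise ValueError("all rates must lie in [0, 1]")

    @property
    def k1(self) -> int:
        return len(self.low_level_supports)

    @property
    def k2(self) -> int:
        return len(self.high_level_supports)

    def key_joints(self, group: int) -> set[str]:
        out: set[str] = set()
        for li in self.high_level_supports[group]:
            out |= set(self.low_level_supports[li])
        return out


def make_planted_model(catalog: JointCatalog | None = None, k1: int = 19,
                       k2: int = 7, seed: int | None = None,
                       **options) -> PlantedModel:
    """Build a planted model over a catalog.

    Low-level supports are disjoint bilateral joint-type pairs ordered
    along the vertical body axis; high-level supports partition them into
    k2 contiguous groups (each the union of at least one support).  With
    ``k1=19, k2=7`` on the default 71-joint catalog this mirrors the
    factor counts reported for homunculus-shaped data.
    """
    if k2 < 1 or k1 < k2:
        raise ValueError("need k1 >= k2 >= 1")
    catalog = catalog if catalog is not None else default_catalog()
    types = sorted(catalog.bilateral_types,
                   key=lambda t: (catalog.pair(t)[0].axis_rank, t))
    if k1 > len(types):
        raise ValueError(f"catalog has only {len(types)} bilateral joint types; "
                         f"cannot plant k1={k1} low-level supports")
    # spread the k1 chosen types evenly over the axis
    pick = np.linspace(0, len(types) - 1, k1).round().astype(int)
    pick = np.unique(pick)
    while len(pick) < k1:  # fill collisions with unused types
        extras = [i for i in range(len(types)) if i not in set(pick)]
        pick = np.sort(np.append(pick, extras[:k1 - len(pick)]))
    low = [[j.joint_id for j in catalog.pair(types[i])] for i in pick]
    high = [list(chunk) for chunk in np.array_split(np.arange(k1), k2)]
    weights = options.pop("group_weights", np.full(k2, 1.0 / k2))
    return PlantedModel(catalog=catalog, low_level_supports=low,
                        high_level_supports=high, group_weights=weights,
                        seed=seed, **options)


def _draw_active_set(planted: PlantedModel, group: int, category: str,
                     rng: np.random.Generator) -> set[str]:
    """Active joints for one patient hitting the requested category exactly."""
    cat = planted.catalog
    key = planted.key_joints(group)
    # activate supports, then pairs within them, with bilateral coupling
    active: set[str] = set()
    while not active:
        for li in planted.high_level_supports[group]:
            if rng.random() >= planted.support_activation:
                continue
            support = planted.low_level_supports[li]
            pairs: dict[str, list[str]] = {}
            for j in support:
                pairs.setdefault(cat.joint(j).joint_type, []).append(j)
            for members in pairs.values():
                if len(members) == 2 and rng.random() < planted.bilateral_coupling:
                    active.update(members)
                else:
                    active.add(members[rng.integers(len(members))])
    if category == "partial" and len(active) < 2:
        # a single active key joint cannot land in [0.6, 0.9); add its partner
        partner = cat.partner(next(iter(active)))
        if partner is not None:
            active.add(partner)
        else:
            active |= set(rng.choice(sorted(key - active), size=1))
    n_key = len(active)
    nonkey = sorted(set(cat.joint_ids) - key)
    if category == "localized":
        n_out = 0
    elif category == "partial":
        lo = n_key // 9 + 1           # fraction < 0.9  ⇒  n_out > n_key/9
        hi = (2 * n_key) // 3         # fraction >= 0.6 ⇒  n_out <= 2 n_key/3
        n_out = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
    else:  # extended: fraction < 0.6  ⇒  n_out > 2 n_key / 3
        lo = (2 * n_key) // 3 + 1
        hi = max(lo, min(len(nonkey), lo + n_key))  # keep extras bounded
        n_out = int(rng.integers(lo, hi + 1))
    n_out = min(n_out, len(nonkey))
    if n_out > 0:
        active |= set(rng.choice(nonkey, size=n_out, replace=False))
    return active


def simulate_baseline(planted: PlantedModel, n_patients: int,
                      seed: int | None = None) -> tuple[CohortTable, pd.DataFrame]:
    """Draw a baseline cohort and its ground truth.

    Returns the one-visit cohort and a ground-truth frame with the planted
    group and the localization category *recomputed* from the final
    (post-noise) active set against the planted key-joint set.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    rng = np.random.default_rng(planted.seed if seed is None else seed)
    jid = planted.catalog.joint_ids
    jindex = {j: i for i, j in enumerate(jid)}
    X = np.zeros((len(jid), n_patients), dtype=np.int8)
    truth_rows = []
    mix = np.asarray(planted.localization_mix, dtype=float)
    mix = mix / mix.sum()
    for p in range(n_patients):
        g = int(rng.choice(planted.k2, p=planted.group_weights))
        category = ("localized", "partial", "extended")[int(rng.choice(3, p=mix))]
        active = _draw_active_set(planted, g, category, rng)
        vec = np.zeros(len(jid), dtype=np.int8)
        vec[[jindex[j] for j in active]] = 1
        if planted.noise_rate > 0:
            flips = rng.random(len(jid)) < planted.noise_rate
            vec[flips] = 1 - vec[flips]
        if vec.sum() == 0:  # enrollment requires arthritis
            vec[jindex[sorted(active)[0]]] = 1
        X[:, p] = vec
        final_active = {jid[i] for i in np.flatnonzero(vec)}
        realized = degree_of_localization(final_active, planted.key_joints(g))
        truth_rows.append((f"p{p:04d}", g, realized.category,
                           realized.n_active, float(realized.fraction)))
    patients = [r[0] for r in truth_rows]
    cohort = CohortTable(planted.catalog,
                         {0: pd.DataFrame(X, index=jid, columns=patients)})
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "group", "category",
                                              "n_active", "fraction"]) \
        .set_index("patient_id")
    return cohort, truth


def simulate_course(baseline: CohortTable, truth: pd.DataFrame,
                    planted: PlantedModel,
                    visit_schedule=DEFAULT_SCHEDULE,
                    seed: int | None = None) -> tuple[CohortTable, pd.DataFrame]:
    """Evolve a baseline cohort over follow-up visits.

    At each visit every active joint resolves independently with the
    per-localization hazard; with ``flare_rate`` > 0 inactive joints can
    (re)activate.  Returns the multi-visit cohort and the truth frame
    augmented with the first-passage ``event_time`` (NaN if never zero).
    """
    visits = [int(v) for v in visit_schedule]
    if visits != sorted(set(visits)):
        raise ValueError("visit schedule must be strictly increasing")
    if visits[0] != baseline.baseline_visit:
        raise ValueError("schedule must start at the baseline visit")
    rng = np.random.default_rng(planted.seed if seed is None else seed)
    jid = planted.catalog.joint_ids
    patients = baseline.patient_ids
    hazards = truth["category"].map(
        lambda c: planted.resolution_hazard.get(c, 0.3)).to_numpy()
    X = {visits[0]: baseline.baseline_matrix.copy()}
    current = baseline.baseline_matrix.to_numpy().copy()
    event_time = np.full(len(patients), np.nan)
    for v in visits[1:]:
        resolve = rng.random(current.shape) < hazards[None, :]
        nxt = np.where(resolve, 0, current).astype(np.int8)
        if planted.flare_rate > 0:
            flare = (current == 0) & (rng.random(current.shape) < planted.flare_rate)
            nxt[flare] = 1
        zero_now = (nxt.sum(axis=0) == 0) & np.isnan(event_time)
        event_time[zero_now] = v
        X[v] = pd.DataFrame(nxt, index=jid, columns=patients)
        current = nxt
    cohort = CohortTable(planted.catalog, X, labels=baseline.labels)
    out = truth.copy()
    out["event_time"] = event_time
    return cohort, out


def simulate_cohort(preset: str = "homunculus", n_patients: int = 600,
                    seed: int | None = None, catalog: JointCatalog | None = None,
                    visit_schedule=DEFAULT_SCHEDULE,
                    **options) -> tuple[CohortTable, pd.DataFrame, PlantedModel]:
    """One-call generator: planted model + baseline + follow-up course.

    Presets: ``homunculus`` (71-joint catalog, k1=19, k2=7) or ``toy``
    (first 6 bilateral types of the catalog, k1=6, k2=3).
    """
    if preset == "homunculus":
        planted = make_planted_model(catalog, k1=19, k2=7, seed=seed, **options)
    elif preset == "toy":
        planted = make_planted_model(catalog, k1=6, k2=3, seed=seed, **options)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    base, truth = simulate_baseline(planted, n_patients, seed=seed)
    cohort, truth = simulate_course(base, truth, planted, visit_schedule,
                                    seed=None if seed is None else seed + 1)
    return cohort, truth, planted
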
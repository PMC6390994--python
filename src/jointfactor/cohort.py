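"""Cohort data model and on-disk formats.

A cohort is a set of patients assessed at scheduled visits; at each visit
every catalog joint is recorded as active (1) or inactive (0).  Visits a
patient did not attend are *absent* from the table — absence is never
zero-filled, and downstream time-to-event analysis treats the last observed
visit as the censoring time.

Two plain-text dialects are supported:

* **wide CSV** — ``patient_id,visit_month,<joint_id_1>,...,<joint_id_K>``
  with 0/1 cells; one row per patient-visit.
* **long TSV** — ``patient_id<TAB>visit_month<TAB>joint_id``; presence of a
  row marks the joint active.  An observed visit with *no* active joints is
  encoded by the reserved joint id ``.`` so that zero-joint visits survive
  a round trip (otherwise they would be indistinguishable from missed
  visits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import JointCatalog

__all__ = ["CohortTable", "read_cohort", "write_cohort", "DEFAULT_SCHEDULE"]

#: default visit schedule, months from baseline: six-month intervals for the
#: first 18 months and yearly thereafter out to five years
DEFAULT_SCHEDULE = (0, 6, 12, 18, 24, 36, 48, 60)

_ZERO_MARKER = "."


class CohortError(ValueError):
    pass


@dataclass
class CohortTable:
    """Patients × joints binary involvement, one matrix per visit.

    ``X[v]`` is a joints × patients DataFrame (rows ordered as the catalog,
    columns = patients observed at visit ``v``); entries are 0/1.  Patients
    missing a visit simply lack a column in that visit's matrix.
    """

    catalog: JointCatalog
    X: dict[int, pd.DataFrame] = field(default_factory=dict)
    labels: pd.Series | None = None  # patient -> categorical label (e.g. ILAR subtype)

    def __post_init__(self) -> None:
        self.X = {int(v): m for v, m in sorted(self.X.items())}
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        jid = self.catalog.joint_ids
        for v, m in self.X.items():
            if v < 0:
                raise CohortError(f"negative visit month {v}")
            if list(m.index) != jid:
                raise CohortError(f"visit {v}: rows must equal the catalog joints in order")
            vals = m.to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise CohortError(f"visit {v}: entries must be 0/1")
            if m.columns.duplicated().any():
                raise CohortError(f"visit {v}: duplicate patient columns")
        if self.X:
            base = self.baseline_matrix
            empty = base.columns[base.sum(axis=0).to_numpy() == 0]
            if len(empty):
                raise CohortError(
                    f"baseline visit has patients with no active joint: {list(empty)[:5]}"
                )

    # -- accessors ----------------------------------------------------
    @property
    def visits(self) -> list[int]:
        return sorted(self.X)

    @property
    def baseline_visit(self) -> int:
        return self.visits[0]

    @property
    def baseline_matrix(self) -> pd.DataFrame:
        return self.X[self.baseline_visit]

    @property
    def patient_ids(self) -> list[str]:
        seen: list[str] = []
        for v in self.visits:
            for p in self.X[v].columns:
                if p not in seen:
                    seen.append(p)
        return seen

    @property
    def followup(self) -> pd.Series:
        """Last observed visit month per patient (censoring time)."""
        last = {}
        for v in self.visits:
            for p in self.X[v].columns:
                last[p] = v
        return pd.Series(last, name="last_visit").loc[self.patient_ids]

    def matrix(self, visit: int) -> pd.DataFrame:
        return self.X[visit]

    def active_set(self, patient: str, visit: int | None = None) -> set[str]:
        v = self.baseline_visit if visit is None else visit
        col = self.X[v][patient]
        return set(col.index[col.to_numpy() == 1])

    def equals(self, other: "CohortTable") -> bool:
        if self.visits != other.visits:
            return False
        for v in self.visits:
            a, b = self.X[v], other.X[v]
            if sorted(a.columns) != sorted(b.columns):
                return False
            if not a[sorted(a.columns)].astype(int).equals(b[sorted(b.columns)].astype(int)):
                return False
        return True

    def subset(self, patients: list[str]) -> "CohortTable":
        X = {}
        for v in self.visits:
            keep = [p for p in self.X[v].columns if p in set(patients)]
            if keep:
                X[v] = self.X[v][keep]
        labels = self.labels.loc[[p for p in patients if p in self.labels.index]] \
            if self.labels is not None else None
        return CohortTable(self.catalog, X, labels)


# ---------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------

def read_cohort(file: str | Path, catalog: JointCatalog,
                dialect: str = "wide_csv") -> CohortTable:
    """Read a cohort table in either dialect, validating against the catalog.

    Unknown joint ids are rejected; duplicate (patient, visit, joint) rows
    in the long dialect collapse to a single active entry.
    """
    if dialect == "wide_csv":
        return _read_wide(file, catalog)
    if dialect == "long_tsv":
        return _read_long(file, catalog)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_wide(file, catalog: JointCatalog) -> CohortTable:
    df = pd.read_csv(file, dtype=str)
    if "patient_id" not in df.columns or "visit_month" not in df.columns:
        raise CohortError("wide CSV needs patient_id and visit_month columns")
    joint_cols = [c for c in df.columns if c not in ("patient_id", "visit_month")]
    unknown = [c for c in joint_cols if c not in catalog]
    if unknown:
        raise CohortError(f"unknown joint_id column(s): {unknown}")
    dup = df.duplicated(subset=["patient_id", "visit_month"])
    if dup.any():
        raise CohortError(f"duplicate patient-visit rows: "
                          f"{df.loc[dup, ['patient_id', 'visit_month']].values.tolist()}")
    X: dict[int, dict[str, np.ndarray]] = {}
    jid = catalog.joint_ids
    for r_i, row in df.iterrows():
        vec = np.zeros(len(jid), dtype=np.int8)
        for c in joint_cols:
            cell = row[c]
            if cell not in ("0", "1"):
                raise CohortError(
                    f"non-binary cell at patient {row['patient_id']}, "
                    f"visit {row['visit_month']}, joint {c}: {cell!r}")
            if cell == "1":
                vec[catalog.index[c]] = 1
        X.setdefault(int(row["visit_month"]), {})[str(row["patient_id"])] = vec
    mats = {v: pd.DataFrame(cols, index=jid) for v, cols in X.items()}
    return CohortTable(catalog, mats)


def _read_long(file, catalog: JointCatalog) -> CohortTable:
    df = pd.read_csv(file, sep="\t", dtype=str,
                     names=["patient_id", "visit_month", "joint_id"], header=0)
    unknown = sorted(set(df["joint_id"]) - set(catalog.joint_ids) - {_ZERO_MARKER})
    if unknown:
        raise CohortError(f"unknown joint_id(s): {unknown}")
    jid = catalog.joint_ids
    X: dict[int, dict[str, np.ndarray]] = {}
    for row in df.itertuples():
        v = int(row.visit_month)
        col = X.setdefault(v, {}).setdefault(str(row.patient_id),
                                             np.zeros(len(jid), dtype=np.int8))
        if row.joint_id != _ZERO_MARKER:
            col[catalog.index[row.joint_id]] = 1  # duplicates collapse
    mats = {v: pd.DataFrame(cols, index=jid) for v, cols in X.items()}
    return CohortTable(catalog, mats)


def write_cohort(cohort: CohortTable, file: str | Path,
                 dialect: str = "wide_csv") -> None:
    """Write a cohort; ``read_cohort(write_cohort(c)) == c`` in both dialects."""
    if dialect == "wide_csv":
        rows = []
        for v in cohort.visits:
            m = cohort.X[v]
            for p in m.columns:
                rows.append([p, v] + m[p].astype(int).tolist())
        out = pd.DataFrame(rows, columns=["patient_id", "visit_month"] + cohort.catalog.joint_ids)
        out.to_csv(file, index=False)
    elif dialect == "long_tsv":
        rows = []
        for v in cohort.visits:
            m = cohort.X[v]
            for p in m.columns:
                active = m.index[m[p].to_numpy() == 1]
                if len(active) == 0:
                    rows.append((p, v, _ZERO_MARKER))
                for j in active:
                    rows.append((p, v, j))
        pd.DataFrame(rows, columns=["patient_id", "visit_month", "joint_id"]) \
            .to_csv(file, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
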
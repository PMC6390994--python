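"""Joint site catalog: the vocabulary of assessable joints.

Joint involvement is recorded on a standardized body map ("homunculus") of
assessable joints.  Each site has an identifier, a human-readable label, a
body side (left / right / midline), a *joint type* (the left/right pair of
corresponding joints, e.g. both knees form the "knee" type) and an integer
rank along the vertical body axis used for ordering displays and for
building vertically proximal joint groupings.

The built-in default catalog enumerates 71 joints: the temporomandibular
joints, cervical spine, sternoclavicular joints, shoulders, elbows, wrists,
thumb MCP and IP joints, finger MCPs/PIPs/DIPs (digits 2-5), sacroiliac
joints, hips, knees, ankles, subtalar joints, midfeet, MTPs (digits 1-5)
and toe IP joints (digits 1-5).  The precise enumeration is a
reconstruction from the standard pediatric 71-joint count; a user-supplied
catalog file overrides it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["Joint", "JointCatalog", "load_catalog", "default_catalog", "DEFAULT"]

#: sentinel accepted by :func:`load_catalog` for the built-in homunculus
DEFAULT = "default"

_SIDES = ("left", "right", "midline")


@dataclass(frozen=True)
class Joint:
    joint_id: str
    label: str
    side: str  # left | right | midline
    joint_type: str
    axis_rank: int


class CatalogError(ValueError):
    """Raised when a catalog violates its structural invariants."""


@dataclass
class JointCatalog:
    """Ordered collection of joint sites with side/type pairing.

    Invariants (checked on construction):

    * joint ids are unique;
    * every left joint's type has exactly one right partner and vice versa;
    * midline joints are the sole member of their type.
    """

    joints: list[Joint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        ids = [j.joint_id for j in self.joints]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise CatalogError(f"duplicate joint_id(s): {sorted(dup)}")
        for j in self.joints:
            if j.side not in _SIDES:
                raise CatalogError(f"{j.joint_id}: side must be one of {_SIDES}, got {j.side!r}")
            if j.axis_rank < 0:
                raise CatalogError(f"{j.joint_id}: axis_rank must be >= 0")
        bad = []
        for jt, members in self._by_type().items():
            sides = sorted(m.side for m in members)
            if sides == ["midline"]:
                continue
            if sides != ["left", "right"]:
                bad.append((jt, sides))
        if bad:
            msg = "; ".join(f"type {jt!r} has sides {s}" for jt, s in bad)
            raise CatalogError(f"unpaired joint types (each non-midline type needs exactly "
                               f"one left and one right member): {msg}")

    def _by_type(self) -> dict[str, list[Joint]]:
        out: dict[str, list[Joint]] = {}
        for j in self.joints:
            out.setdefault(j.joint_type, []).append(j)
        return out

    # -- accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.joints)

    def __iter__(self):
        return iter(self.joints)

    def __contains__(self, joint_id: str) -> bool:
        return joint_id in self.index

    @property
    def joint_ids(self) -> list[str]:
        return [j.joint_id for j in self.joints]

    @property
    def index(self) -> dict[str, int]:
        return {j.joint_id: i for i, j in enumerate(self.joints)}

    def joint(self, joint_id: str) -> Joint:
        return self.joints[self.index[joint_id]]

    @property
    def joint_types(self) -> list[str]:
        seen: list[str] = []
        for j in self.joints:
            if j.joint_type not in seen:
                seen.append(j.joint_type)
        return seen

    @property
    def bilateral_types(self) -> list[str]:
        return [t for t, m in self._by_type().items() if len(m) == 2]

    def pair(self, joint_type: str) -> tuple[Joint, Joint]:
        """(left, right) members of a bilateral joint type."""
        members = self._by_type()[joint_type]
        if len(members) != 2:
            raise KeyError(f"{joint_type!r} is not bilateral")
        left = next(m for m in members if m.side == "left")
        right = next(m for m in members if m.side == "right")
        return left, right

    def partner(self, joint_id: str) -> str | None:
        """Contralateral partner id, or None for midline joints."""
        j = self.joint(joint_id)
        if j.side == "midline":
            return None
        left, right = self.pair(j.joint_type)
        return right.joint_id if j.side == "left" else left.joint_id

    def sides(self) -> pd.Series:
        return pd.Series({j.joint_id: j.side for j in self.joints})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(j.joint_id, j.label, j.side, j.joint_type, j.axis_rank) for j in self.joints],
            columns=["joint_id", "label", "side", "joint_type", "axis_rank"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------
# Default 71-joint homunculus
# ---------------------------------------------------------------------

def _bilateral(entries: Iterable[tuple[str, str, int]]) -> list[Joint]:
    out = []
    for jt, label, rank in entries:
        out.append(Joint(f"{jt}_l", f"Left {label}", "left", jt, rank))
        out.append(Joint(f"{jt}_r", f"Right {label}", "right", jt, rank))
    return out


def default_catalog() -> JointCatalog:
    """The built-in 71-joint homunculus.

    35 bilateral joint types plus the midline cervical spine: 71 sites.
    """
    joints: list[Joint] = []
    joints += _bilateral([("tmj", "temporomandibular joint", 0)])
    joints.append(Joint("cervical_spine", "Cervical spine", "midline", "cervical_spine", 1))
    joints += _bilateral([
        ("sternoclavicular", "sternoclavicular joint", 2),
        ("shoulder", "shoulder", 3),
        ("elbow", "elbow", 4),
        ("wrist", "wrist", 5),
        ("thumb_mcp", "thumb MCP", 6),
        ("thumb_ip", "thumb IP", 7),
    ])
    for d, name in zip(range(2, 6), ["index", "middle", "ring", "little"]):
        joints += _bilateral([(f"mcp{d}", f"{name} finger MCP", 6)])
    for d, name in zip(range(2, 6), ["index", "middle", "ring", "little"]):
        joints += _bilateral([(f"pip{d}", f"{name} finger PIP", 7)])
    for d, name in zip(range(2, 6), ["index", "middle", "ring", "little"]):
        joints += _bilateral([(f"dip{d}", f"{name} finger DIP", 8)])
    joints += _bilateral([
        ("sacroiliac", "sacroiliac joint", 9),
        ("hip", "hip", 10),
        ("knee", "knee", 11),
        ("ankle", "ankle", 12),
        ("subtalar", "subtalar joint", 13),
        ("midfoot", "midfoot", 14),
    ])
    for d in range(1, 6):
        joints += _bilateral([(f"mtp{d}", f"MTP {d}", 15)])
    for d in range(1, 6):
        joints += _bilateral([(f"toe_ip{d}", f"toe {d} IP", 16)])
    cat = JointCatalog(joints)
    assert len(cat) == 71
    return cat


def load_catalog(path_or_default: str | Path = DEFAULT) -> JointCatalog:
    """Load a catalog from a TSV file, or return the built-in homunculus.

    The TSV holds columns ``joint_id  label  side  joint_type  axis_rank``
    (header row required).  Passing the sentinel ``"default"`` (or omitting
    the argument) returns the 71-joint homunculus.
    """
    if path_or_default == DEFAULT:
        return default_catalog()
    df = pd.read_csv(path_or_default, sep="\t", dtype=str)
    required = {"joint_id", "side", "joint_type", "axis_rank"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"catalog file missing columns: {sorted(missing)}")
    if "label" not in df.columns:
        df["label"] = df["joint_id"]
    joints = [
        Joint(r.joint_id, r.label, r.side, r.joint_type, int(r.axis_rank))
        for r in df.itertuples()
    ]
    return JointCatalog(joints)
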
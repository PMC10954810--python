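"""Cylinder-based quantitative structure models (QSMs).

A QSM represents one tree as a rooted hierarchy of fitted cylinders. Each
cylinder carries geometry (start point, unit axis, length, radius) and
topology (parent, extension child, branch id, position within the branch,
branch order). The trunk is branch order 0 and the primary scaffold
branches are order 1, so rules such as "pruned branches must have order
greater than 1" exclude exactly the trunk and the primaries.

This module provides the domain types, structural validation, lossless CSV
serialization, and the topology rebuild used after two yearly QSMs are
fused into one time-integrated model.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChangeLabel",
    "Cylinder",
    "QSM",
    "QSMValidationError",
    "QSMFormatError",
    "ViolationReport",
    "end_point",
    "validate_qsm",
    "recompute_branch_structure",
    "read_qsm_csv",
    "write_qsm_csv",
]

AXIS_UNIT_TOL = 1e-6

QSM_CSV_COLUMNS = [
    "tree_id",
    "cylinder_id",
    "parent_id",
    "extension_id",
    "start_x",
    "start_y",
    "start_z",
    "axis_x",
    "axis_y",
    "axis_z",
    "length",
    "radius",
    "branch_id",
    "position_in_branch",
    "branch_order",
    "is_virtual",
    "change_label",
    "n_pruned_children",
    "n_new_children",
]


class QSMValidationError(ValueError):
    """A cylinder or QSM violates a structural invariant."""


class QSMFormatError(ValueError):
    """A QSM CSV file cannot be parsed into a valid cylinder table."""


class ChangeLabel(enum.IntEnum):
    """Bi-temporal change state of a cylinder (or a point).

    UNCHANGED structure is present in both yearly scans; PRUNED branches
    exist only in the first year; NEW_SHOOT cylinders exist only in the
    second.
    """

    UNCHANGED = 0
    PRUNED = 1
    NEW_SHOOT = 2


@dataclass
class Cylinder:
    """One QSM segment.

    Geometry is in metres; ``axis`` is a unit vector pointing tip-ward so
    the cylinder occupies ``start + t * axis`` for ``t`` in ``[0, length]``.
    ``extension_id`` names the child cylinder that continues the same
    branch, if any.
    """

    cylinder_id: int
    parent_id: int | None
    start: np.ndarray
    axis: np.ndarray
    length: float
    radius: float
    extension_id: int | None = None
    branch_id: int = 0
    position_in_branch: int = 1
    branch_order: int = 0
    is_virtual: bool = False
    change_label: ChangeLabel = ChangeLabel.UNCHANGED
    n_pruned_children: int = 0
    n_new_children: int = 0

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.start.shape != (3,) or self.axis.shape != (3,):
            raise QSMValidationError(
                f"cylinder {self.cylinder_id}: start/axis must be 3-vectors"
            )
        if not (np.all(np.isfinite(self.start)) and np.all(np.isfinite(self.axis))):
            raise QSMValidationError(
                f"cylinder {self.cylinder_id}: non-finite geometry"
            )
        if self.length <= 0:
            raise QSMValidationError(
                f"cylinder {self.cylinder_id}: length must be > 0"
            )
        if self.radius <= 0:
            raise QSMValidationError(
                f"cylinder {self.cylinder_id}: radius must be > 0"
            )
        norm = float(np.linalg.norm(self.axis))
        if abs(norm - 1.0) > AXIS_UNIT_TOL:
            raise QSMValidationError(
                f"cylinder {self.cylinder_id}: axis norm {norm:.6g} is not 1"
            )
        self.change_label = ChangeLabel(self.change_label)


def end_point(cyl: Cylinder) -> np.ndarray:
    """Tip-ward end of a cylinder: ``start + length * axis``."""
    return cyl.start + cyl.length * cyl.axis


@dataclass
class QSM:
    """One tree in one scan year, as an ordered cylinder collection."""

    tree_id: str
    scan_year: str
    cylinders: list[Cylinder] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cylinders)

    def by_id(self) -> dict[int, Cylinder]:
        return {c.cylinder_id: c for c in self.cylinders}

    def children_map(self) -> dict[int, list[Cylinder]]:
        """Map cylinder_id -> children, in cylinder_id order."""
        kids: dict[int, list[Cylinder]] = {c.cylinder_id: [] for c in self.cylinders}
        for c in sorted(self.cylinders, key=lambda c: c.cylinder_id):
            if c.parent_id is not None and c.parent_id in kids:
                kids[c.parent_id].append(c)
        return kids

    def root(self) -> Cylinder:
        roots = [c for c in self.cylinders if c.parent_id is None]
        if len(roots) != 1:
            raise QSMValidationError(
                f"QSM {self.tree_id}/{self.scan_year}: {len(roots)} roots"
            )
        return roots[0]

    def copy(self) -> "QSM":
        return QSM(
            tree_id=self.tree_id,
            scan_year=self.scan_year,
            cylinders=[replace(c, start=c.start.copy(), axis=c.axis.copy())
                       for c in self.cylinders],
        )


@dataclass
class ViolationReport:
    """Result of :func:`validate_qsm`; empty iff the model is structurally valid."""

    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy when violations exist
        return bool(self.violations)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_qsm(qsm: QSM) -> ViolationReport:
    """Check every structural invariant of a QSM, reporting all violations.

    Checks: unique ids, exactly one root, resolvable parent/extension ids,
    acyclic and connected parent graph, extension children belonging to the
    same branch with consecutive positions, and the branch-order recursion
    (a non-trunk branch has the order of its origin branch plus one).
    """
    rep = ViolationReport()
    ids = [c.cylinder_id for c in qsm.cylinders]
    if not ids:
        rep.violations.append("QSM has no cylinders")
        return rep
    seen: set[int] = set()
    for i in ids:
        if i in seen:
            rep.violations.append(f"duplicate cylinder_id {i}")
        seen.add(i)
    by_id = {c.cylinder_id: c for c in qsm.cylinders}

    roots = [c for c in qsm.cylinders if c.parent_id is None]
    if len(roots) != 1:
        rep.violations.append(f"expected exactly one root, found {len(roots)}")

    for c in qsm.cylinders:
        if c.parent_id is not None and c.parent_id not in by_id:
            rep.violations.append(
                f"cylinder {c.cylinder_id}: dangling parent_id {c.parent_id}"
            )
        if c.extension_id is not None and c.extension_id not in by_id:
            rep.violations.append(
                f"cylinder {c.cylinder_id}: dangling extension_id {c.extension_id}"
            )

    # Cycle / connectivity via parent-pointer walk with memoised reachability.
    reaches_root: dict[int, bool] = {}
    for c in qsm.cylinders:
        path: list[int] = []
        cur: Cylinder | None = c
        status: bool | None = None
        while cur is not None:
            cid = cur.cylinder_id
            if cid in reaches_root:
                status = reaches_root[cid]
                break
            if cid in path:
                status = None  # cycle
                break
            path.append(cid)
            if cur.parent_id is None:
                status = True
                break
            cur = by_id.get(cur.parent_id)
            if cur is None:
                status = False  # dangling, already reported
                break
        if status is None:
            rep.violations.append(
                f"cycle in parent pointers involving cylinder {path[-1]}"
            )
            status = False
        for cid in path:
            reaches_root[cid] = status

    for c in qsm.cylinders:
        if c.extension_id is not None:
            ext = by_id.get(c.extension_id)
            if ext is None:
                continue
            if ext.parent_id != c.cylinder_id:
                rep.violations.append(
                    f"cylinder {c.cylinder_id}: extension {ext.cylinder_id} "
                    "is not its child"
                )
            else:
                if ext.branch_id != c.branch_id:
                    rep.violations.append(
                        f"cylinder {c.cylinder_id}: extension changes branch_id"
                    )
                if ext.position_in_branch != c.position_in_branch + 1:
                    rep.violations.append(
                        f"cylinder {c.cylinder_id}: extension position "
                        f"{ext.position_in_branch} != {c.position_in_branch} + 1"
                    )
        if c.parent_id is not None:
            parent = by_id.get(c.parent_id)
            if parent is None:
                continue
            if c.branch_id != parent.branch_id:
                # c starts a new branch: order must step by one
                if c.branch_order != parent.branch_order + 1:
                    rep.violations.append(
                        f"cylinder {c.cylinder_id}: branch order "
                        f"{c.branch_order} != parent order "
                        f"{parent.branch_order} + 1 at branch start"
                    )
                if c.position_in_branch != 1:
                    rep.violations.append(
                        f"cylinder {c.cylinder_id}: branch start position "
                        f"{c.position_in_branch} != 1"
                    )
            else:
                if c.branch_order != parent.branch_order:
                    rep.violations.append(
                        f"cylinder {c.cylinder_id}: order changes within branch"
                    )
    return rep


def _continuation_child(parent: Cylinder, children: Sequence[Cylinder]) -> Cylinder:
    """Pick the child that continues the parent's branch at a junction.

    The child whose axis is most aligned with the parent's axis continues
    the branch; ties break toward larger radius, then smaller cylinder_id,
    so the choice is deterministic.
    """
    return max(
        children,
        key=lambda ch: (float(np.dot(ch.axis, parent.axis)), ch.radius, -ch.cylinder_id),
    )


def recompute_branch_structure(qsm: QSM) -> QSM:
    """Rebuild branch_id, position_in_branch, branch_order and extension_id.

    Performs a root-to-tip traversal of the parent graph: the trunk branch
    has order 0; at each junction exactly one child continues the parent's
    branch (same branch_id, position + 1, recorded as the parent's
    extension) and every other child starts a new branch with order + 1.
    Geometry and labels are untouched. Idempotent.

    Raises :class:`QSMValidationError` for cyclic or disconnected input.
    """
    out = qsm.copy()
    by_id = out.by_id()
    if len(by_id) != len(out.cylinders):
        raise QSMValidationError("duplicate cylinder ids")
    roots = [c for c in out.cylinders if c.parent_id is None]
    if len(roots) != 1:
        raise QSMValidationError(f"expected exactly one root, found {len(roots)}")
    for c in out.cylinders:
        if c.parent_id is not None and c.parent_id not in by_id:
            raise QSMValidationError(
                f"cylinder {c.cylinder_id}: dangling parent_id {c.parent_id}"
            )
    kids = out.children_map()

    next_branch_id = 0
    visited = 0
    # stack of (cylinder, branch_id, position, order)
    stack: list[tuple[Cylinder, int, int, int]] = [(roots[0], 0, 1, 0)]
    next_branch_id = 1
    while stack:
        cyl, bid, pos, order = stack.pop()
        cyl.branch_id = bid
        cyl.position_in_branch = pos
        cyl.branch_order = order
        cyl.extension_id = None
        visited += 1
        children = kids[cyl.cylinder_id]
        if not children:
            continue
        cont = _continuation_child(cyl, children)
        cyl.extension_id = cont.cylinder_id
        for ch in children:
            if ch is cont:
                stack.append((ch, bid, pos + 1, order))
            else:
                stack.append((ch, next_branch_id, 1, order + 1))
                next_branch_id += 1
    if visited != len(out.cylinders):
        raise QSMValidationError(
            f"parent graph disconnected or cyclic: reached {visited} of "
            f"{len(out.cylinders)} cylinders"
        )
    return out


def _fmt_opt_int(v: int | None) -> str:
    return "" if v is None else str(int(v))


def write_qsm_csv(qsm: QSM, path) -> None:
    """Write a QSM as one CSV row per cylinder (schema in QSM_CSV_COLUMNS).

    Empty parent_id / extension_id fields encode None; all lengths are in
    metres. The round-trip through :func:`read_qsm_csv` is lossless.
    """
    rows = []
    for c in qsm.cylinders:
        rows.append(
            {
                "tree_id": qsm.tree_id,
                "cylinder_id": int(c.cylinder_id),
                "parent_id": _fmt_opt_int(c.parent_id),
                "extension_id": _fmt_opt_int(c.extension_id),
                "start_x": repr(float(c.start[0])),
                "start_y": repr(float(c.start[1])),
                "start_z": repr(float(c.start[2])),
                "axis_x": repr(float(c.axis[0])),
                "axis_y": repr(float(c.axis[1])),
                "axis_z": repr(float(c.axis[2])),
                "length": repr(float(c.length)),
                "radius": repr(float(c.radius)),
                "branch_id": int(c.branch_id),
                "position_in_branch": int(c.position_in_branch),
                "branch_order": int(c.branch_order),
                "is_virtual": int(c.is_virtual),
                "change_label": c.change_label.name,
                "n_pruned_children": int(c.n_pruned_children),
                "n_new_children": int(c.n_new_children),
            }
        )
    pd.DataFrame(rows, columns=QSM_CSV_COLUMNS).to_csv(path, index=False)


def _parse_opt_int(v, row: int, col: str) -> int | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    try:
        return int(v)
    except (TypeError, ValueError) as exc:
        raise QSMFormatError(f"row {row}: bad {col} value {v!r}") from exc


def read_qsm_csv(path, scan_year: str | None = None) -> QSM:
    """Read a QSM from the CSV schema written by :func:`write_qsm_csv`.

    Raises :class:`QSMFormatError` on an empty file, missing columns,
    duplicate cylinder ids or unresolvable parents, naming the offending
    row where applicable.
    """
    try:
        # round_trip parser: geometry must survive write/read exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, ValueError) as exc:
        raise QSMFormatError(f"{path}: empty or unreadable QSM CSV") from exc
    missing = [c for c in QSM_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise QSMFormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise QSMFormatError(f"{path}: QSM CSV contains no cylinders")

    cylinders: list[Cylinder] = []
    seen: set[int] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        cid = int(row.cylinder_id)
        if cid in seen:
            raise QSMFormatError(f"row {i}: duplicate cylinder_id {cid}")
        seen.add(cid)
        try:
            label = ChangeLabel[str(row.change_label)]
        except KeyError as exc:
            raise QSMFormatError(
                f"row {i}: unknown change_label {row.change_label!r}"
            ) from exc
        cylinders.append(
            Cylinder(
                cylinder_id=cid,
                parent_id=_parse_opt_int(row.parent_id, i, "parent_id"),
                extension_id=_parse_opt_int(row.extension_id, i, "extension_id"),
                start=np.array([row.start_x, row.start_y, row.start_z], dtype=float),
                axis=np.array([row.axis_x, row.axis_y, row.axis_z], dtype=float),
                length=float(row.length),
                radius=float(row.radius),
                branch_id=int(row.branch_id),
                position_in_branch=int(row.position_in_branch),
                branch_order=int(row.branch_order),
                is_virtual=bool(row.is_virtual),
                change_label=label,
                n_pruned_children=int(row.n_pruned_children),
                n_new_children=int(row.n_new_children),
            )
        )
    for i, c in enumerate(cylinders):
        if c.parent_id is not None and c.parent_id not in seen:
            raise QSMFormatError(
                f"row {i}: parent_id {c.parent_id} does not resolve"
            )
    tree_id = str(df["tree_id"].iloc[0])
    return QSM(tree_id=tree_id, scan_year=scan_year or "", cylinders=cylinders)
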
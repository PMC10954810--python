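"""Transfer point-level change labels onto QSM cylinders.

Each cylinder is judged by its two endpoints: if the sum of the mean
distances from the start and end points to their k nearest changed points
of the year's candidate label (PRUNED for the year-1 model, NEW_SHOOT for
year-2) falls below a threshold, the cylinder takes that label. Three
horticultural plausibility rules then clean the raw labels: changed
cylinders must be thin (one-year shoots stay under 20 mm radius for these
trees), pruned cylinders cannot lie on the trunk or a primary scaffold
branch, and a changed cylinder passes its label to all of its descendants
— a removed branch is removed in its entirety.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .change_detection import ChangedPointSet
from .qsm import QSM, ChangeLabel, Cylinder, end_point

__all__ = [
    "LabellingParams",
    "endpoint_label_score",
    "raw_label_cylinder",
    "apply_label_rules",
    "label_qsm_pair",
]


@dataclass(frozen=True)
class LabellingParams:
    """Tunables of the cylinder-labelling stage (all lengths in metres).

    ``sum_threshold`` is the bound on score(start) + score(end) (default
    0.100 m, i.e. 100 mm); ``max_shoot_radius`` is the one-year-shoot
    thickness cap (default 0.020 m); ``min_pruned_order`` is the smallest
    branch order a pruned cylinder may have (default 2, excluding trunk
    and primaries).
    """

    knn: int = 10
    sum_threshold: float = 0.100
    max_shoot_radius: float = 0.020
    min_pruned_order: int = 2

    def __post_init__(self) -> None:
        if self.knn < 1 or self.sum_threshold <= 0 or self.max_shoot_radius <= 0:
            raise ValueError("labelling parameters must be positive")
        if self.min_pruned_order < 0:
            raise ValueError("min_pruned_order must be >= 0")


def _label_tree(changed: ChangedPointSet, label: ChangeLabel) -> cKDTree | None:
    pts = changed.with_label(label)
    if len(pts) == 0:
        return None
    return cKDTree(pts)


def endpoint_label_score(
    p: np.ndarray,
    labelled_points: ChangedPointSet,
    label: ChangeLabel,
    k: int = 10,
) -> float:
    """Mean distance from ``p`` to its k nearest points carrying ``label``.

    If fewer than k such points exist, all of them are used; if none
    exist, the score is +inf (the cylinder can then never be labelled).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tree = _label_tree(labelled_points, label)
    if tree is None:
        return math.inf
    k_eff = min(k, tree.n)
    d, _ = tree.query(np.asarray(p, dtype=float), k=k_eff)
    return float(np.mean(d))


def _endpoint_scores(
    qsm: QSM, tree: cKDTree | None, k: int
) -> np.ndarray:
    """Score(start) + score(end) for every cylinder, vectorised."""
    n = len(qsm.cylinders)
    if tree is None:
        return np.full(n, math.inf)
    starts = np.array([c.start for c in qsm.cylinders])
    ends = np.array([end_point(c) for c in qsm.cylinders])
    k_eff = min(k, tree.n)
    ds, _ = tree.query(starts, k=k_eff, workers=-1)
    de, _ = tree.query(ends, k=k_eff, workers=-1)
    ds = np.atleast_2d(ds.reshape(n, -1)).mean(axis=1)
    de = np.atleast_2d(de.reshape(n, -1)).mean(axis=1)
    return ds + de


def raw_label_cylinder(
    cyl: Cylinder,
    changed: ChangedPointSet,
    params: LabellingParams = LabellingParams(),
) -> ChangeLabel:
    """Raw endpoint-distance label for one cylinder.

    The candidate label is fixed by the scan year of the changed set
    (PRUNED for t1, NEW_SHOOT for t2); it is assigned when the endpoint
    score sum is strictly below ``params.sum_threshold``.
    """
    candidate = (
        ChangeLabel.PRUNED if changed.source_year == "t1" else ChangeLabel.NEW_SHOOT
    )
    s = endpoint_label_score(cyl.start, changed, candidate, params.knn)
    s += endpoint_label_score(end_point(cyl), changed, candidate, params.knn)
    if s < params.sum_threshold:
        return candidate
    return ChangeLabel.UNCHANGED


def apply_label_rules(qsm: QSM, params: LabellingParams = LabellingParams()) -> QSM:
    """Veto implausible raw labels, then propagate labels to descendants.

    Step 1 (veto): a changed cylinder with radius at or above
    ``max_shoot_radius`` reverts to UNCHANGED; a PRUNED cylinder with
    branch order below ``min_pruned_order`` reverts to UNCHANGED.
    Step 2 (propagate): every descendant of a surviving changed cylinder
    receives that cylinder's label unconditionally — propagation
    overrides the vetoes, because a removed branch's children are gone
    regardless of their fitted radius.
    """
    out = qsm.copy()
    for c in out.cylinders:
        if c.change_label is not ChangeLabel.UNCHANGED:
            if c.radius >= params.max_shoot_radius:
                c.change_label = ChangeLabel.UNCHANGED
            elif (
                c.change_label is ChangeLabel.PRUNED
                and c.branch_order < params.min_pruned_order
            ):
                c.change_label = ChangeLabel.UNCHANGED
    kids = out.children_map()
    by_id = out.by_id()
    # push surviving labels down the topology
    stack = [c for c in out.cylinders if c.change_label is not ChangeLabel.UNCHANGED]
    while stack:
        c = stack.pop()
        for ch in kids[c.cylinder_id]:
            if ch.change_label is not c.change_label:
                ch.change_label = c.change_label
                stack.append(ch)
    return out


def label_qsm_pair(
    qsm_t1: QSM,
    qsm_t2: QSM,
    changes_t1: ChangedPointSet,
    changes_t2: ChangedPointSet,
    params: LabellingParams = LabellingParams(),
) -> tuple[QSM, QSM]:
    """Label both yearly QSMs of one tree from their changed point sets.

    Applies the raw endpoint rule, then the veto and propagation rules,
    to each year. Year-1 cylinders end up UNCHANGED or PRUNED, year-2
    cylinders UNCHANGED or NEW_SHOOT.
    """
    if qsm_t1.tree_id != qsm_t2.tree_id:
        raise ValueError(
            f"tree_id mismatch: {qsm_t1.tree_id!r} vs {qsm_t2.tree_id!r}"
        )
    if changes_t1.source_year != "t1" or changes_t2.source_year != "t2":
        raise ValueError("changed point sets must be (t1, t2)")

    labelled = []
    for qsm, changed, candidate in (
        (qsm_t1, changes_t1, ChangeLabel.PRUNED),
        (qsm_t2, changes_t2, ChangeLabel.NEW_SHOOT),
    ):
        out = qsm.copy()
        tree = _label_tree(changed, candidate)
        scores = _endpoint_scores(out, tree, params.knn)
        for c, s in zip(out.cylinders, scores):
            c.change_label = candidate if s < params.sum_threshold else ChangeLabel.UNCHANGED
        labelled.append(apply_label_rules(out, params))
    return labelled[0], labelled[1]
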
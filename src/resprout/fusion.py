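"""Fuse two yearly QSMs into one time-integrated model and count events.

Pruned branches exist only in the year-1 model, new shoots only in the
year-2 model. Because pruned branches are at least as thick as new shoots
and therefore have the more robust cylinder fits, the pruned subtrees are
extracted from the year-1 QSM and re-hung on the year-2 QSM: each
subtree's base is re-parented to the host cylinder whose end point lies
closest to the base's start point. All topology of the merged model is
then rebuilt, and the pruning/resprouting events are counted per
cylinder, yielding the table the prediction models train on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .qsm import (
    QSM,
    ChangeLabel,
    Cylinder,
    end_point,
    recompute_branch_structure,
)

__all__ = [
    "PrunedSubtree",
    "AttachmentRecord",
    "MergedQSM",
    "extract_pruned",
    "attach_subtree",
    "fuse",
    "count_events",
    "MAX_SHOOT_COUNT_LABEL",
]

logger = logging.getLogger(__name__)

MAX_SHOOT_COUNT_LABEL = 4  # shoot counts above this are capped in the target
PRUNED_TARGET_LABEL = -1

# attachments farther than this are logged as likely mis-attachments
DEFAULT_MAX_ATTACH_DIST = 0.2


@dataclass
class PrunedSubtree:
    """A maximal PRUNED region of the year-1 QSM.

    ``base`` is the PRUNED cylinder whose parent is not PRUNED (or the
    root); ``members`` are base plus all its descendants, all PRUNED.
    """

    base: Cylinder
    members: list[Cylinder]


@dataclass
class AttachmentRecord:
    """Where one pruned subtree base was re-hung in the host QSM."""

    base_id_t1: int
    host_id_t2: int
    distance: float


@dataclass
class MergedQSM:
    """Time-integrated QSM with per-cylinder event counts and targets.

    ``target_label`` per cylinder is -1 for pruned cylinders and
    min(n_new_children, 4) otherwise. ``id_map_t2`` / ``id_map_t1`` map
    original year-2 / pruned year-1 cylinder ids to merged ids.
    """

    qsm: QSM
    attachments: list[AttachmentRecord] = field(default_factory=list)
    id_map_t2: dict[int, int] = field(default_factory=dict)
    id_map_t1: dict[int, int] = field(default_factory=dict)
    target_labels: dict[int, int] = field(default_factory=dict)


def extract_pruned(qsm_t1: QSM) -> list[PrunedSubtree]:
    """Collect the maximal PRUNED subtrees of a labelled year-1 QSM."""
    by_id = qsm_t1.by_id()
    kids = qsm_t1.children_map()
    bases = []
    for c in qsm_t1.cylinders:
        if c.change_label is not ChangeLabel.PRUNED:
            continue
        parent = by_id.get(c.parent_id) if c.parent_id is not None else None
        if parent is None or parent.change_label is not ChangeLabel.PRUNED:
            bases.append(c)
    subtrees = []
    for base in bases:
        members = []
        stack = [base]
        while stack:
            c = stack.pop()
            members.append(c)
            stack.extend(kids[c.cylinder_id])
        non_pruned = [m for m in members if m.change_label is not ChangeLabel.PRUNED]
        if non_pruned:
            raise ValueError(
                f"pruned subtree at {base.cylinder_id} contains non-PRUNED "
                f"descendants {[m.cylinder_id for m in non_pruned]}"
            )
        subtrees.append(PrunedSubtree(base=base, members=members))
    return subtrees


def _eligible_hosts(host: QSM) -> list[Cylinder]:
    # a branch pruned in year 1 cannot hang on a shoot that did not yet exist
    return [c for c in host.cylinders if c.change_label is not ChangeLabel.NEW_SHOOT]


def attach_subtree(
    host: QSM,
    sub: PrunedSubtree,
    max_attach_dist: float = DEFAULT_MAX_ATTACH_DIST,
) -> tuple[QSM, AttachmentRecord]:
    """Re-parent a pruned subtree's base onto the nearest host endpoint.

    The new parent is the eligible host cylinder (NEW_SHOOT cylinders are
    excluded) whose end point is closest to the subtree base's start
    point; exact ties break toward the smaller cylinder_id. Internal
    subtree topology is preserved. Returns the grown host and the
    attachment record; a warning is logged when the attachment distance
    exceeds ``max_attach_dist``.
    """
    if len(host) == 0:
        raise ValueError("host QSM is empty")
    eligible = _eligible_hosts(host)
    if not eligible:
        raise ValueError("no eligible attachment parents in host QSM")
    eligible.sort(key=lambda c: c.cylinder_id)  # ties -> smaller id
    ends = np.array([end_point(c) for c in eligible])
    d = np.linalg.norm(ends - sub.base.start, axis=1)
    idx = int(np.argmin(d))
    parent = eligible[idx]
    dist = float(d[idx])
    if dist > max_attach_dist:
        logger.warning(
            "subtree base %d attached at %.3f m from cylinder %d "
            "(> %.3f m): likely mis-attachment",
            sub.base.cylinder_id,
            dist,
            parent.cylinder_id,
            max_attach_dist,
        )
    out = host.copy()
    existing = {c.cylinder_id for c in out.cylinders}
    # renumber subtree members that collide with host ids
    next_id = max(existing) + 1
    remap: dict[int, int] = {}
    for m in sub.members:
        if m.cylinder_id in existing or m.cylinder_id in remap:
            remap[m.cylinder_id] = next_id
            next_id += 1
        else:
            remap[m.cylinder_id] = m.cylinder_id
            existing.add(m.cylinder_id)
    member_ids = {m.cylinder_id for m in sub.members}
    for m in sub.members:
        new = Cylinder(
            cylinder_id=remap[m.cylinder_id],
            parent_id=(
                parent.cylinder_id
                if m.cylinder_id == sub.base.cylinder_id
                else remap[m.parent_id]
                if m.parent_id in member_ids
                else None
            ),
            start=m.start.copy(),
            axis=m.axis.copy(),
            length=m.length,
            radius=m.radius,
            extension_id=None,
            branch_id=m.branch_id,
            position_in_branch=m.position_in_branch,
            branch_order=m.branch_order,
            is_virtual=m.is_virtual,
            change_label=ChangeLabel.PRUNED,
        )
        out.cylinders.append(new)
    rec = AttachmentRecord(
        base_id_t1=sub.base.cylinder_id,
        host_id_t2=parent.cylinder_id,
        distance=dist,
    )
    return out, rec


def fuse(
    qsm_t1: QSM,
    qsm_t2: QSM,
    max_attach_dist: float = DEFAULT_MAX_ATTACH_DIST,
) -> MergedQSM:
    """Build the time-integrated QSM from two labelled yearly models.

    Moves every pruned subtree of the year-1 model into the year-2 model,
    reassigns contiguous cylinder ids, rebuilds all topology from the
    root, and counts pruned/new-shoot events per cylinder.
    """
    if qsm_t1.tree_id != qsm_t2.tree_id:
        raise ValueError(
            f"tree_id mismatch: {qsm_t1.tree_id!r} vs {qsm_t2.tree_id!r}"
        )
    host = qsm_t2.copy()
    subtrees = extract_pruned(qsm_t1)
    records: list[AttachmentRecord] = []
    base_remaps: list[tuple[int, int]] = []  # (t1 base id, pre-renumber merged id)
    for sub in subtrees:
        host, rec = attach_subtree(host, sub, max_attach_dist=max_attach_dist)
        records.append(rec)
        base_remaps.append((sub.base.cylinder_id, host.cylinders[-len(sub.members)].cylinder_id))

    # contiguous id reassignment in breadth-first order from the root
    host_by_id = host.by_id()
    kids = host.children_map()
    order: list[Cylinder] = []
    queue = [host.root()]
    while queue:
        c = queue.pop(0)
        order.append(c)
        queue.extend(kids[c.cylinder_id])
    if len(order) != len(host.cylinders):
        raise ValueError("merged QSM is disconnected")
    new_id = {c.cylinder_id: i + 1 for i, c in enumerate(order)}
    for c in host.cylinders:
        c.parent_id = None if c.parent_id is None else new_id[c.parent_id]
        c.extension_id = None
        c.cylinder_id = new_id[c.cylinder_id]
    host.cylinders.sort(key=lambda c: c.cylinder_id)
    host.scan_year = f"{qsm_t1.scan_year}+{qsm_t2.scan_year}".strip("+")

    merged = MergedQSM(
        qsm=recompute_branch_structure(host),
        attachments=records,
        id_map_t2={
            c.cylinder_id: new_id[c.cylinder_id] for c in qsm_t2.cylinders
            if c.cylinder_id in new_id
        },
    )
    # host ids in attachment records refer to original t2 ids, which were
    # preserved by attach_subtree; map bases through the renumbering too
    merged.id_map_t1 = {b: new_id[m] for b, m in base_remaps}
    return count_events(merged)


def count_events(merged: MergedQSM) -> MergedQSM:
    """Count pruned and new-shoot branch bases on every cylinder.

    A branch base is a changed cylinder whose parent carries a different
    label; its parent is the cylinder the event is counted on. Also sets
    the prediction target: -1 for pruned cylinders (they no longer exist
    and cannot resprout), otherwise the new-shoot count capped at 4.
    """
    qsm = merged.qsm
    by_id = qsm.by_id()
    for c in qsm.cylinders:
        c.n_pruned_children = 0
        c.n_new_children = 0
    for c in qsm.cylinders:
        if c.change_label is ChangeLabel.UNCHANGED or c.parent_id is None:
            continue
        parent = by_id[c.parent_id]
        if parent.change_label is c.change_label:
            continue
        if c.change_label is ChangeLabel.PRUNED:
            parent.n_pruned_children += 1
        else:
            parent.n_new_children += 1
    merged.target_labels = {
        c.cylinder_id: (
            PRUNED_TARGET_LABEL
            if c.change_label is ChangeLabel.PRUNED
            else min(c.n_new_children, MAX_SHOOT_COUNT_LABEL)
        )
        for c in qsm.cylinders
    }
    return merged
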
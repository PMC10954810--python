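"""Pruned-subtree extraction, re-attachment, fusion and event counting."""

import numpy as np
import pytest

from resprout import (
    ChangeLabel,
    Cylinder,
    QSM,
    attach_subtree,
    count_events,
    extract_pruned,
    fuse,
    validate_qsm,
)
from resprout.fusion import MergedQSM, PrunedSubtree

from conftest import make_chain


def vertical_host(n=3):
    """Host tree: n stacked unit cylinders ending at (0,0,1)...(0,0,n)."""
    return make_chain(n)


def pruned_chain(start_z, cid0=100, n=2, label=ChangeLabel.PRUNED):
    cyls = []
    for i in range(n):
        cyls.append(
            Cylinder(
                cylinder_id=cid0 + i,
                parent_id=None if i == 0 else cid0 + i - 1,
                start=np.array([0.3 * i, 0.0, start_z]),
                axis=np.array([1.0, 0.0, 0.0]),
                length=0.3,
                radius=0.01,
                change_label=label,
                branch_order=2,
            )
        )
    return cyls


class TestExtractPruned:
    def test_unlabelled_tree_gives_empty_list(self, chain3):
        assert extract_pruned(chain3) == []

    def test_fully_pruned_branch_is_one_subtree(self):
        q = make_chain(4)
        for c in q.cylinders[1:]:
            c.change_label = ChangeLabel.PRUNED
        subs = extract_pruned(q)
        assert len(subs) == 1
        assert subs[0].base.cylinder_id == 2
        assert len(subs[0].members) == 3

    def test_disjoint_pruned_branches_are_separate_subtrees(self):
        # trunk of 3 with two pruned side branches off cylinders 1 and 2
        q = make_chain(3)
        side_a = pruned_chain(1.0, cid0=10, n=2)
        side_a[0].parent_id = 1
        side_b = pruned_chain(2.0, cid0=20, n=1)
        side_b[0].parent_id = 2
        q.cylinders.extend(side_a + side_b)
        subs = extract_pruned(q)
        assert {s.base.cylinder_id for s in subs} == {10, 20}
        sizes = {s.base.cylinder_id: len(s.members) for s in subs}
        assert sizes == {10: 2, 20: 1}

    def test_non_closed_labels_rejected(self):
        # an UNCHANGED descendant inside a pruned region violates closure
        q = make_chain(3)
        q.cylinders[1].change_label = ChangeLabel.PRUNED
        with pytest.raises(ValueError, match="non-PRUNED"):
            extract_pruned(q)


class TestAttachSubtree:
    def test_nearest_endpoint_wins(self):
        host = vertical_host(2)  # endpoints at z=1 and z=2
        sub = PrunedSubtree(
            base=pruned_chain(1.9)[0], members=pruned_chain(1.9, n=1)
        )
        out, rec = attach_subtree(host, sub)
        assert rec.host_id_t2 == 2
        assert rec.distance == pytest.approx(0.1)

    def test_exact_tie_broken_by_smaller_id(self):
        # chain along +x with endpoints at x = 1, 2, 3; the base start at
        # (1.5, 1, 0) is equidistant from the first two endpoints
        host = QSM("chain", "t2", [
            Cylinder(cylinder_id=i + 1, parent_id=None if i == 0 else i,
                     start=np.array([float(i), 0.0, 0.0]),
                     axis=np.array([1.0, 0.0, 0.0]), length=1.0, radius=0.05)
            for i in range(3)
        ])
        base = Cylinder(
            cylinder_id=50, parent_id=None, start=np.array([1.5, 1.0, 0.0]),
            axis=np.array([0.0, 1.0, 0.0]), length=0.3, radius=0.01,
            change_label=ChangeLabel.PRUNED,
        )
        out, rec = attach_subtree(host, PrunedSubtree(base=base, members=[base]))
        assert rec.host_id_t2 == 1
        assert rec.distance == pytest.approx(np.sqrt(1.25))

    def test_new_shoot_hosts_ineligible(self):
        # nearest endpoint belongs to a shoot that did not exist in year 1
        host = vertical_host(2)
        host.cylinders[1].change_label = ChangeLabel.NEW_SHOOT
        sub = PrunedSubtree(
            base=pruned_chain(1.9)[0], members=pruned_chain(1.9, n=1)
        )
        out, rec = attach_subtree(host, sub)
        assert rec.host_id_t2 == 1
        assert rec.distance == pytest.approx(0.9)

    def test_empty_host_rejected(self):
        sub = PrunedSubtree(
            base=pruned_chain(1.0)[0], members=pruned_chain(1.0, n=1)
        )
        with pytest.raises(ValueError):
            attach_subtree(QSM("t", "t2", []), sub)


class TestFuse:
    def label_pair(self, scenario):
        """Use generator truth labels directly (bypassing detection)."""
        return scenario.qsm_t1.copy(), scenario.qsm_t2.copy()

    def test_no_changes_is_identity_up_to_renumbering(self, chain3):
        t1 = chain3.copy()
        t2 = chain3.copy()
        merged = fuse(t1, t2)
        assert len(merged.qsm) == 3
        assert merged.attachments == []
        geo = sorted((tuple(c.start), c.length, c.radius)
                     for c in merged.qsm.cylinders)
        ref = sorted((tuple(c.start), c.length, c.radius)
                     for c in chain3.cylinders)
        assert geo == ref

    def test_cylinder_count_conserved(self, default_scenario):
        t1, t2 = self.label_pair(default_scenario)
        merged = fuse(t1, t2)
        n_pruned = sum(c.change_label is ChangeLabel.PRUNED
                       for c in t1.cylinders)
        assert len(merged.qsm) == len(t2) + n_pruned

    def test_fusion_output_valid(self, default_scenario):
        t1, t2 = self.label_pair(default_scenario)
        merged = fuse(t1, t2)
        assert validate_qsm(merged.qsm).ok

    def test_contiguous_ids(self, default_scenario):
        t1, t2 = self.label_pair(default_scenario)
        merged = fuse(t1, t2)
        ids = sorted(c.cylinder_id for c in merged.qsm.cylinders)
        assert ids == list(range(1, len(merged.qsm) + 1))

    def test_truth_labels_attach_to_truth_parents(self, default_scenario):
        # with perfect labels the base starts sit exactly on their true
        # parents' endpoints, so every attachment is exact
        sc = default_scenario
        t1, t2 = self.label_pair(sc)
        merged = fuse(t1, t2)
        tp = sc.truth_parent_of_pruned_base()
        assert len(merged.attachments) == len(tp)
        for rec in merged.attachments:
            assert rec.distance <= 1e-6
            assert tp[rec.base_id_t1] == rec.host_id_t2

    def test_counts_reproduce_generator_truth(self, default_scenario):
        sc = default_scenario
        merged = fuse(sc.qsm_t1.copy(), sc.qsm_t2.copy())
        # map generator counts through the renumbering
        want_new = {
            merged.id_map_t2[c.cylinder_id]: c.n_new_children
            for c in sc.truth_merged.cylinders
            if c.cylinder_id in merged.id_map_t2
        }
        got_new = {c.cylinder_id: c.n_new_children for c in merged.qsm.cylinders}
        for cid, n in want_new.items():
            assert got_new[cid] == n

    def test_new_children_sum_equals_shoot_bases(self, default_scenario):
        sc = default_scenario
        merged = fuse(sc.qsm_t1.copy(), sc.qsm_t2.copy())
        by_id = merged.qsm.by_id()
        bases = sum(
            1 for c in merged.qsm.cylinders
            if c.change_label is ChangeLabel.NEW_SHOOT
            and c.parent_id is not None
            and by_id[c.parent_id].change_label is not ChangeLabel.NEW_SHOOT
        )
        assert sum(c.n_new_children for c in merged.qsm.cylinders) == bases


class TestCountEvents:
    def build_star(self, n_shoots):
        """One trunk cylinder with n new-shoot children branches."""
        cyls = [Cylinder(cylinder_id=1, parent_id=None, start=np.zeros(3),
                         axis=np.array([0.0, 0.0, 1.0]), length=1.0,
                         radius=0.05)]
        for i in range(n_shoots):
            ang = 2 * np.pi * i / max(n_shoots, 1)
            cyls.append(Cylinder(
                cylinder_id=2 + i, parent_id=1,
                start=np.array([0.0, 0.0, 1.0]),
                axis=np.array([np.cos(ang), np.sin(ang), 0.0]),
                length=0.2, radius=0.005,
                change_label=ChangeLabel.NEW_SHOOT, branch_order=1,
            ))
        return MergedQSM(qsm=QSM("t", "m", cyls))

    def test_two_shoot_bases_counted(self):
        m = count_events(self.build_star(2))
        assert m.qsm.by_id()[1].n_new_children == 2
        assert m.target_labels[1] == 2

    def test_target_capped_at_four(self):
        m = count_events(self.build_star(6))
        assert m.qsm.by_id()[1].n_new_children == 6
        assert m.target_labels[1] == 4

    def test_pruned_cylinder_target_minus_one(self):
        m = self.build_star(0)
        m.qsm.cylinders[0].change_label = ChangeLabel.PRUNED
        m = count_events(m)
        assert m.target_labels[1] == -1

    def test_interior_shoot_cylinders_not_counted(self):
        # only branch bases count: a shoot's own child shoot cylinder
        # does not increment anyone's n_new_children
        m = self.build_star(1)
        m.qsm.cylinders.append(Cylinder(
            cylinder_id=10, parent_id=2, start=np.array([0.2, 0.0, 1.0]),
            axis=np.array([1.0, 0.0, 0.0]), length=0.2, radius=0.004,
            change_label=ChangeLabel.NEW_SHOOT, branch_order=1,
        ))
        m = count_events(m)
        assert m.qsm.by_id()[1].n_new_children == 1
        assert m.qsm.by_id()[2].n_new_children == 0
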
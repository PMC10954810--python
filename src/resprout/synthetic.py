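"""Synthetic two-year table-topped tree scenarios with known ground truth.

Emulates the study system: nursery plane trees whose crown is trained
into a flat layer from six primary branches bent horizontal at about 3 m
height, pruned every winter, and resprouting near the cuts the following
season. A scenario holds the year-1 cylinder model (including the
branches about to be pruned), the year-2 model (retained structure with
girth growth plus new shoots), the correct fusion of the two with true
per-cylinder event counts, and surface-sampled point clouds for both
years carrying per-point truth.

New-shoot placement follows a planted, recoverable rule (deterministic
or Poisson in the cylinder's pruning/topology features), so downstream
classifiers have a signal whose strength is known by construction. The
real biological mechanism is of course unknown; the planted rule exists
so that pipeline recovery can be measured exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .change_detection import PointCloud, write_ply
from .qsm import (
    QSM,
    ChangeLabel,
    Cylinder,
    end_point,
    recompute_branch_structure,
    write_qsm_csv,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruthScenario",
    "generate_table_top_tree",
    "generate_scenarios",
    "planted_resprout_count",
    "apply_girth_growth",
    "sample_point_cloud",
    "write_scenario",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic tree generator. Lengths in metres.

    Architectural defaults mimic a 3-4 year old table-topped plane tree:
    a 3 m trunk, six horizontal primary scaffold branches at equal
    azimuth spacing, thin (< 20 mm radius) second- and third-order
    branches of which a fraction is pruned each winter, and girth growth
    on everything retained. ``point_density`` is points per square metre
    of cylinder lateral surface; ``noise_sd`` is the isotropic scanner
    noise; ``outlier_fraction`` the share of spurious points.
    """

    n_primary_branches: int = 6
    trunk_height: float = 3.0
    n_trunk_segments: int = 6
    trunk_radius: float = 0.08
    primary_length: float = 1.5
    primary_segments: int = 7
    primary_radius: float = 0.025
    n_secondary_range: tuple[int, int] = (3, 5)  # per primary branch, inclusive
    secondary_segments: int = 4
    secondary_segment_length: float = 0.25
    secondary_radius_range: tuple[float, float] = (0.009, 0.014)
    n_tertiary_range: tuple[int, int] = (1, 3)  # per secondary branch, inclusive
    tertiary_segments: int = 2
    tertiary_segment_length: float = 0.25
    tertiary_radius_range: tuple[float, float] = (0.005, 0.009)
    shoot_segments: int = 2
    shoot_segment_length: float = 0.22
    shoot_radius_range: tuple[float, float] = (0.005, 0.009)
    # shoots emerge near, not exactly at, the cut: fraction of the parent
    # cylinder's length at which a new shoot is attached
    shoot_attach_range: tuple[float, float] = (0.2, 0.7)
    # side branches and shoots leave their parent axis at a wide crotch
    # angle, as resprouts on trained trees do; shallow angles would let a
    # branch hug its parent's surface and blur the change signal
    min_branch_angle_deg: float = 60.0
    radius_taper: float = 0.90  # per-segment multiplicative taper within a branch
    direction_jitter_deg: float = 8.0
    prune_fraction: float = 0.30
    girth_growth: float = 0.08
    beta: tuple[float, float, float, float] = (-3.0, 1.5, 0.3, 0.0)
    rule_mode: str = "deterministic"  # "deterministic" | "poisson"
    point_density: float = 6000.0
    noise_sd: float = 0.002
    outlier_fraction: float = 0.002
    rigid_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def validate(self) -> None:
        if not (0.0 <= self.prune_fraction <= 1.0):
            raise ValueError("prune_fraction must be in [0, 1]")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.girth_growth < 0:
            raise ValueError("girth_growth must be >= 0")
        for name in (
            "trunk_height",
            "trunk_radius",
            "primary_length",
            "primary_radius",
            "secondary_segment_length",
            "tertiary_segment_length",
            "shoot_segment_length",
            "point_density",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.rule_mode not in ("deterministic", "poisson"):
            raise ValueError("rule_mode must be 'deterministic' or 'poisson'")
        # one-year shoots must satisfy the 20 mm labelling rule
        for rng_name in ("secondary_radius_range", "tertiary_radius_range",
                         "shoot_radius_range"):
            lo, hi = getattr(self, rng_name)
            if not (0 < lo <= hi):
                raise ValueError(f"{rng_name} must be an increasing positive range")
            if hi >= 0.020:
                raise ValueError(f"{rng_name} must stay below 0.020 m")


@dataclass
class GroundTruthScenario:
    """One synthetic tree with full two-year ground truth."""

    tree_id: str
    config: SyntheticConfig
    seed: int
    qsm_t1: QSM
    qsm_t2: QSM
    truth_merged: QSM
    cloud_t1: PointCloud
    cloud_t2: PointCloud

    def truth_target_labels(self) -> dict[int, int]:
        """Per merged-cylinder prediction target: -1 pruned, else capped count."""
        return {
            c.cylinder_id: (-1 if c.change_label is ChangeLabel.PRUNED
                            else min(c.n_new_children, 4))
            for c in self.truth_merged.cylinders
        }

    def truth_parent_of_pruned_base(self) -> dict[int, int]:
        """Map pruned-subtree base cylinder id -> its true parent id."""
        by_id = self.qsm_t1.by_id()
        out = {}
        for c in self.qsm_t1.cylinders:
            if c.change_label is not ChangeLabel.PRUNED or c.parent_id is None:
                continue
            if by_id[c.parent_id].change_label is not ChangeLabel.PRUNED:
                out[c.cylinder_id] = c.parent_id
        return out


def planted_resprout_count(
    n_pruned_children: int,
    branch_order: int,
    radius: float,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> int:
    """Ground-truth number of new shoots a retained cylinder produces.

    Deterministic mode: exactly one shoot iff the cylinder lost at least
    one child branch to pruning and sits on a branch of order >= 2.
    Poisson mode: count ~ Poisson(lambda) truncated at 6, with
    log lambda = b0 + b1 * n_pruned_children + b2 * branch_order
    + b3 * radius.
    """
    if config.rule_mode == "deterministic":
        return 1 if (n_pruned_children >= 1 and branch_order >= 2) else 0
    lam = float(
        np.exp(
            config.beta[0]
            + config.beta[1] * n_pruned_children
            + config.beta[2] * branch_order
            + config.beta[3] * radius
        )
    )
    if rng is None:
        raise ValueError("poisson rule mode requires a random generator")
    return int(min(rng.poisson(lam), 6))


def apply_girth_growth(qsm: QSM, g: float) -> QSM:
    """Scale every cylinder radius by (1 + g); everything else unchanged."""
    if g < 0:
        raise ValueError("girth growth fraction must be >= 0")
    out = qsm.copy()
    for c in out.cylinders:
        c.radius *= 1.0 + g
    return out


# ---------------------------------------------------------------------------
# architecture construction


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _jitter(axis: np.ndarray, max_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Randomly tilt a unit vector by up to ``max_deg`` degrees."""
    if max_deg <= 0:
        return axis
    # random small rotation: perturb with tangential Gaussian, renormalise
    ang = np.deg2rad(max_deg) * rng.uniform(0, 1)
    t = rng.normal(size=3)
    t -= axis * np.dot(t, axis)
    nt = np.linalg.norm(t)
    if nt < 1e-12:
        return axis
    return _unit(np.cos(ang) * axis + np.sin(ang) * t / nt)


def _upward_direction(
    rng: np.random.Generator, elev_lo: float = 40.0, elev_hi: float = 80.0
) -> np.ndarray:
    """Random azimuth, elevation biased toward vertical (resprout geometry)."""
    az = rng.uniform(0, 2 * np.pi)
    elev = np.deg2rad(rng.uniform(elev_lo, elev_hi))
    return np.array(
        [np.cos(elev) * np.cos(az), np.cos(elev) * np.sin(az), np.sin(elev)]
    )


def _branch_direction(
    rng: np.random.Generator,
    parent_axis: np.ndarray,
    elev_lo: float,
    elev_hi: float,
    min_angle_deg: float,
) -> np.ndarray:
    """Upward-biased direction forming a wide crotch with the parent axis.

    Rejection-samples until the angle to ``parent_axis`` reaches
    ``min_angle_deg``; if that fails (parent nearly vertical and the
    elevation band narrow), falls back to a direction perpendicular to
    the parent axis, tilted upward.
    """
    cos_max = np.cos(np.deg2rad(min_angle_deg))
    for _ in range(200):
        d = _upward_direction(rng, elev_lo, elev_hi)
        if abs(float(np.dot(d, parent_axis))) <= cos_max:
            return d
    t = _upward_direction(rng, elev_lo, elev_hi)
    t -= parent_axis * np.dot(t, parent_axis)
    n = np.linalg.norm(t)
    if n < 1e-9:  # pathological parent axis; any horizontal normal works
        t = np.cross(parent_axis, np.array([1.0, 0.0, 0.0]))
        n = np.linalg.norm(t)
    d = t / n
    return d if d[2] >= 0 else -d


class _Builder:
    """Accumulates cylinders with explicit parents; topology is rebuilt later."""

    def __init__(self) -> None:
        self.cylinders: list[Cylinder] = []
        self._next = 1

    def add(self, parent_id, start, axis, length, radius) -> Cylinder:
        c = Cylinder(
            cylinder_id=self._next,
            parent_id=parent_id,
            start=np.asarray(start, float),
            axis=_unit(np.asarray(axis, float)),
            length=float(length),
            radius=float(radius),
        )
        self._next += 1
        self.cylinders.append(c)
        return c

    def add_branch(
        self,
        parent: Cylinder | None,
        origin: np.ndarray,
        direction: np.ndarray,
        n_segments: int,
        seg_length: float,
        radius: float,
        taper: float,
        jitter_deg: float,
        rng: np.random.Generator,
    ) -> list[Cylinder]:
        """A chain of cylinders; each child starts at its parent's end point."""
        cyls = []
        pos = np.asarray(origin, float)
        axis = _unit(np.asarray(direction, float))
        pid = None if parent is None else parent.cylinder_id
        r = radius
        for _ in range(n_segments):
            c = self.add(pid, pos, axis, seg_length, r)
            cyls.append(c)
            pos = end_point(c)
            axis = _jitter(axis, jitter_deg, rng)
            r *= taper
            pid = c.cylinder_id
        return cyls


def _build_year1(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[_Builder, list[list[Cylinder]], dict[int, list[list[Cylinder]]]]:
    """Build the full pre-pruning structure.

    Returns the builder, the secondary branches (list of chains) and, per
    secondary-branch index, its tertiary branch chains.
    """
    b = _Builder()
    # trunk: vertical chain
    trunk = b.add_branch(
        parent=None,
        origin=np.zeros(3),
        direction=np.array([0.0, 0.0, 1.0]),
        n_segments=cfg.n_trunk_segments,
        seg_length=cfg.trunk_height / cfg.n_trunk_segments,
        radius=cfg.trunk_radius,
        taper=0.97,
        jitter_deg=0.0,
        rng=rng,
    )
    top = trunk[-1]
    top_pt = end_point(top)
    # short apical stub above the scaffold whorl: the topped leader remnant.
    # It continues the trunk branch, so all primaries start order-1 branches.
    b.add(
        top.cylinder_id,
        top_pt,
        np.array([0.0, 0.0, 1.0]),
        0.10,
        cfg.trunk_radius * 0.5,
    )
    phase = rng.uniform(0, 2 * np.pi)
    seg_len = cfg.primary_length / cfg.primary_segments
    primaries: list[list[Cylinder]] = []
    for i in range(cfg.n_primary_branches):
        az = phase + 2 * np.pi * i / cfg.n_primary_branches
        direction = np.array([np.cos(az), np.sin(az), 0.0])
        primaries.append(
            b.add_branch(
                parent=top,
                origin=top_pt,
                direction=direction,
                n_segments=cfg.primary_segments,
                seg_length=seg_len,
                radius=cfg.primary_radius,
                taper=cfg.radius_taper,
                jitter_deg=cfg.direction_jitter_deg / 2,
                rng=rng,
            )
        )

    secondaries: list[list[Cylinder]] = []
    tertiaries: dict[int, list[list[Cylinder]]] = {}
    for chain in primaries:
        n_sec = int(rng.integers(cfg.n_secondary_range[0], cfg.n_secondary_range[1] + 1))
        # attach at distinct segment ends, never at the tip: the tip segment
        # keeps no children, so the branch never "continues" into a lateral,
        # and distinct anchors keep junctions apart
        slots = len(chain) - 1
        anchors = rng.choice(slots, size=min(n_sec, slots), replace=False)
        for a in anchors:
            parent = chain[int(a)]
            r = rng.uniform(*cfg.secondary_radius_range)
            sec = b.add_branch(
                parent=parent,
                origin=end_point(parent),
                direction=_branch_direction(
                    rng, parent.axis, 15.0, 55.0, cfg.min_branch_angle_deg
                ),
                n_segments=cfg.secondary_segments,
                seg_length=cfg.secondary_segment_length,
                radius=r,
                taper=cfg.radius_taper,
                jitter_deg=cfg.direction_jitter_deg,
                rng=rng,
            )
            si = len(secondaries)
            secondaries.append(sec)
            tertiaries[si] = []
            n_ter = int(
                rng.integers(cfg.n_tertiary_range[0], cfg.n_tertiary_range[1] + 1)
            )
            t_slots = len(sec) - 1
            t_anchors = rng.choice(t_slots, size=min(n_ter, t_slots), replace=False)
            for ta in t_anchors:
                tparent = sec[int(ta)]
                tr = rng.uniform(*cfg.tertiary_radius_range)
                ter = b.add_branch(
                    parent=tparent,
                    origin=end_point(tparent),
                    direction=_branch_direction(
                        rng, tparent.axis, 25.0, 60.0, cfg.min_branch_angle_deg
                    ),
                    n_segments=cfg.tertiary_segments,
                    seg_length=cfg.tertiary_segment_length,
                    radius=tr,
                    taper=cfg.radius_taper,
                    jitter_deg=cfg.direction_jitter_deg,
                    rng=rng,
                )
                tertiaries[si].append(ter)
    return b, secondaries, tertiaries


def generate_table_top_tree(
    config: SyntheticConfig = SyntheticConfig(),
    seed: int = 0,
    tree_id: str | None = None,
) -> GroundTruthScenario:
    """Generate one two-year scenario with full ground truth.

    Year 1 is the complete structure with pruned branches truth-labelled;
    year 2 is the retained structure with girth growth plus new shoots
    placed by the planted rule; the true merged model carries the exact
    per-cylinder event counts. Clouds are sampled from both yearly
    models, pre-aligned (the study pairs were aligned manually).
    Deterministic for a fixed (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    tree_id = tree_id or f"synthetic-{seed}"

    builder, secondaries, tertiaries = _build_year1(config, rng)

    # --- choose pruned branches (whole higher-order subtrees)
    pruned_ids: set[int] = set()
    for si, sec in enumerate(secondaries):
        if rng.uniform() < config.prune_fraction:
            pruned_ids.update(c.cylinder_id for c in sec)
            for ter in tertiaries[si]:
                pruned_ids.update(c.cylinder_id for c in ter)
        else:
            for ter in tertiaries[si]:
                if rng.uniform() < config.prune_fraction:
                    pruned_ids.update(c.cylinder_id for c in ter)

    qsm_t1 = recompute_branch_structure(
        QSM(tree_id=tree_id, scan_year="t1", cylinders=builder.cylinders)
    )
    by_id = qsm_t1.by_id()
    for c in qsm_t1.cylinders:
        c.change_label = (
            ChangeLabel.PRUNED if c.cylinder_id in pruned_ids else ChangeLabel.UNCHANGED
        )
    # truth pruned-child counts on year-1 retained cylinders
    for c in qsm_t1.cylinders:
        if c.change_label is ChangeLabel.PRUNED and c.parent_id is not None:
            parent = by_id[c.parent_id]
            if parent.change_label is not ChangeLabel.PRUNED:
                parent.n_pruned_children += 1

    # --- year 2: retained structure with girth growth
    retained = [c for c in qsm_t1.cylinders if c.change_label is not ChangeLabel.PRUNED]
    t2_builder_cyls = []
    for c in retained:
        cc = replace(c, start=c.start.copy(), axis=c.axis.copy())
        cc.radius *= 1.0 + config.girth_growth
        cc.change_label = ChangeLabel.UNCHANGED
        cc.n_pruned_children = 0
        cc.n_new_children = 0
        t2_builder_cyls.append(cc)
    qsm_t2 = QSM(tree_id=tree_id, scan_year="t2", cylinders=t2_builder_cyls)

    # --- place new shoots by the planted rule
    next_id = max(c.cylinder_id for c in qsm_t1.cylinders) + 1
    shoot_counts: dict[int, int] = {}
    sb = _Builder()
    sb._next = next_id
    for c in qsm_t1.cylinders:  # iterate year-1 retained, in id order
        if c.change_label is ChangeLabel.PRUNED:
            continue
        k = planted_resprout_count(
            c.n_pruned_children, c.branch_order, c.radius, config, rng
        )
        if k <= 0:
            continue
        shoot_counts[c.cylinder_id] = k
        for _ in range(k):
            u = rng.uniform(*config.shoot_attach_range)
            sb.add_branch(
                parent=c,
                origin=c.start + u * c.length * c.axis,
                direction=_branch_direction(
                    rng, c.axis, 45.0, 85.0, config.min_branch_angle_deg
                ),
                n_segments=config.shoot_segments,
                seg_length=config.shoot_segment_length,
                radius=rng.uniform(*config.shoot_radius_range),
                taper=config.radius_taper,
                jitter_deg=config.direction_jitter_deg,
                rng=rng,
            )
    for c in sb.cylinders:
        c.change_label = ChangeLabel.NEW_SHOOT
        qsm_t2.cylinders.append(c)
    qsm_t2 = recompute_branch_structure(qsm_t2)
    for c in qsm_t2.cylinders:
        c.n_pruned_children = 0
        c.n_new_children = 0

    # --- true merged model: year-2 plus pruned subtrees at their real parents
    merged_cyls = [
        replace(c, start=c.start.copy(), axis=c.axis.copy())
        for c in qsm_t2.cylinders
    ]
    for c in qsm_t1.cylinders:
        if c.change_label is ChangeLabel.PRUNED:
            merged_cyls.append(replace(c, start=c.start.copy(), axis=c.axis.copy()))
    truth_merged = recompute_branch_structure(
        QSM(tree_id=tree_id, scan_year="t1+t2", cylinders=merged_cyls)
    )
    m_by_id = truth_merged.by_id()
    for c in truth_merged.cylinders:
        c.n_pruned_children = 0
        c.n_new_children = int(shoot_counts.get(c.cylinder_id, 0))
    for c in truth_merged.cylinders:
        if c.change_label is ChangeLabel.PRUNED and c.parent_id is not None:
            p = m_by_id[c.parent_id]
            if p.change_label is not ChangeLabel.PRUNED:
                p.n_pruned_children += 1

    # --- point clouds (pre-aligned; optional rigid offset on year 2)
    cloud_t1 = sample_point_cloud(qsm_t1, config, rng)
    cloud_t2 = sample_point_cloud(qsm_t2, config, rng)
    offset = np.asarray(config.rigid_offset, float)
    if np.any(offset != 0):
        cloud_t2 = PointCloud(cloud_t2.points + offset, cloud_t2.attributes)

    return GroundTruthScenario(
        tree_id=tree_id,
        config=config,
        seed=seed,
        qsm_t1=qsm_t1,
        qsm_t2=qsm_t2,
        truth_merged=truth_merged,
        cloud_t1=cloud_t1,
        cloud_t2=cloud_t2,
    )


def generate_scenarios(
    n_trees: int,
    config: SyntheticConfig = SyntheticConfig(),
    seed: int = 0,
) -> list[GroundTruthScenario]:
    """Generate ``n_trees`` independent scenarios from one master seed."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_trees)]
    return [
        generate_table_top_tree(config, seed=s, tree_id=f"synthetic-{seed}-{i}")
        for i, s in enumerate(child_seeds)
    ]


def sample_point_cloud(
    qsm: QSM,
    config: SyntheticConfig = SyntheticConfig(),
    rng: np.random.Generator | int | None = None,
) -> PointCloud:
    """Sample a noisy surface point cloud from a cylinder model.

    Point counts per cylinder are Poisson with mean density x lateral
    area (2 pi r L); points sit on the lateral surface, displaced by
    isotropic Gaussian noise, and a binomial number of uniform bounding
    box outliers is appended. Each surface point carries the truth
    cylinder id and that cylinder's change label; outliers carry id -1.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pts, ids, labels = [], [], []
    for c in qsm.cylinders:
        area = 2 * np.pi * c.radius * c.length
        n = int(rng.poisson(config.point_density * area))
        if n == 0:
            continue
        u = rng.uniform(0, c.length, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        # orthonormal frame around the axis
        a = c.axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, a)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = _unit(np.cross(a, helper))
        e2 = np.cross(a, e1)
        p = (
            c.start
            + u[:, None] * a
            + c.radius * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        )
        if config.noise_sd > 0:
            p = p + rng.normal(0.0, config.noise_sd, p.shape)
        pts.append(p)
        ids.append(np.full(n, c.cylinder_id, dtype=int))
        labels.append(np.full(n, int(c.change_label), dtype=int))
    if not pts:
        raise ValueError("QSM produced no surface points; increase point_density")
    points = np.vstack(pts)
    ids = np.concatenate(ids)
    labels = np.concatenate(labels)
    n_out = int(rng.binomial(len(points), config.outlier_fraction))
    if n_out > 0:
        lo = points.min(axis=0) - 0.1
        hi = points.max(axis=0) + 0.1
        out_pts = rng.uniform(lo, hi, size=(n_out, 3))
        points = np.vstack([points, out_pts])
        ids = np.concatenate([ids, np.full(n_out, -1, dtype=int)])
        labels = np.concatenate(
            [labels, np.full(n_out, int(ChangeLabel.UNCHANGED), dtype=int)]
        )
    return PointCloud(points, {"truth_cyl_id": ids, "truth_label": labels})


def write_scenario(scenario: GroundTruthScenario, out_dir) -> None:
    """Write a scenario bundle: QSM CSVs, truth-labelled PLY clouds, config."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_qsm_csv(scenario.qsm_t1, out / "qsm_t1.csv")
    write_qsm_csv(scenario.qsm_t2, out / "qsm_t2.csv")
    write_qsm_csv(scenario.truth_merged, out / "truth_merged.csv")
    write_ply(scenario.cloud_t1, out / "cloud_t1.ply")
    write_ply(scenario.cloud_t2, out / "cloud_t2.ply")
    meta = asdict(scenario.config)
    meta.update({"tree_id": scenario.tree_id, "seed": scenario.seed})
    with open(out / "config.json", "w") as fh:
        json.dump(meta, fh, indent=2)
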
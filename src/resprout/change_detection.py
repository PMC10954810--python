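"""Point-cloud denoising and bi-temporal change detection.

Two co-registered scans of the same tree, one per winter, are compared by
cloud-to-cloud nearest-neighbour distance: geometry present only in the
first year is a pruned branch, geometry present only in the second is a
new shoot. Before comparison each cloud is denoised with a statistical
outlier removal (SOR) filter.

Also holds the minimal PLY / XYZ point-cloud I/O used across the package
(ASCII PLY with optional integer truth/label properties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .qsm import ChangeLabel

__all__ = [
    "PointCloud",
    "ChangedPointSet",
    "sor_filter",
    "nn_distance",
    "detect_changes",
    "read_ply",
    "write_ply",
    "write_xyz",
]


@dataclass
class PointCloud:
    """N x 3 array of points (metres) with optional per-point attributes.

    Attributes are integer arrays aligned with ``points`` — the synthetic
    generator stores ``truth_cyl_id`` and ``truth_label`` here.
    """

    points: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")
        for k, v in self.attributes.items():
            v = np.asarray(v)
            if v.shape[0] != len(self.points):
                raise ValueError(f"attribute {k!r} length mismatch")
            self.attributes[k] = v

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.points[mask],
            {k: v[mask] for k, v in self.attributes.items()},
        )


@dataclass
class ChangedPointSet:
    """Per-point change labels for one year's scan.

    Year-1 points can only be PRUNED or UNCHANGED (pruned branches exist
    only before pruning); year-2 points only NEW_SHOOT or UNCHANGED.
    """

    points: np.ndarray
    labels: np.ndarray
    source_year: str  # "t1" | "t2"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        if len(self.labels) != len(self.points):
            raise ValueError("labels/points length mismatch")
        if self.source_year not in ("t1", "t2"):
            raise ValueError(f"source_year must be 't1' or 't2', got {self.source_year!r}")
        forbidden = (
            ChangeLabel.NEW_SHOOT if self.source_year == "t1" else ChangeLabel.PRUNED
        )
        if np.any(self.labels == int(forbidden)):
            raise ValueError(
                f"{self.source_year} points may not carry label {forbidden.name}"
            )

    def __len__(self) -> int:
        return len(self.points)

    def with_label(self, label: ChangeLabel) -> np.ndarray:
        """Points carrying ``label`` (possibly empty)."""
        return self.points[self.labels == int(label)]


def sor_filter(cloud: PointCloud, k: int = 6, sigma_mult: float = 1.0) -> PointCloud:
    """Statistical outlier removal.

    For each point, the mean distance to its ``k`` nearest neighbours
    (excluding itself) is computed; points whose mean distance exceeds the
    global mean by more than ``sigma_mult`` standard deviations are
    dropped. Defaults follow the standard CloudCompare-style setting of
    k=6 neighbours and a multiplier of 1.

    ``k`` is clipped to n-1 for tiny clouds; a single-point cloud is
    returned unchanged with a warning.
    """
    if len(cloud) == 0:
        raise ValueError("cannot SOR-filter an empty cloud")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(cloud)
    if n < 2:
        warnings.warn("SOR filter: single-point cloud returned unchanged")
        return cloud
    k_eff = min(k, n - 1)
    tree = cKDTree(cloud.points)
    # first neighbour is the point itself
    dists, _ = tree.query(cloud.points, k=k_eff + 1, workers=-1)
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + sigma_mult * mean_d.std()
    return cloud.select(mean_d <= thresh)


def nn_distance(query: PointCloud, reference: PointCloud) -> np.ndarray:
    """Per-point distance from each query point to its nearest reference point.

    This is the cloud-to-cloud distance operator: the Euclidean distance
    from every point of ``query`` to its nearest neighbour in
    ``reference``, in query order.
    """
    if len(reference) == 0:
        raise ValueError("reference cloud is empty")
    tree = cKDTree(reference.points)
    d, _ = tree.query(query.points, k=1, workers=-1)
    return np.asarray(d, dtype=float)


def detect_changes(
    cloud_t1: PointCloud,
    cloud_t2: PointCloud,
    tau_t1: float = 0.030,
    tau_t2: float = 0.030,
) -> tuple[ChangedPointSet, ChangedPointSet]:
    """Segment both clouds into unchanged vs changed points.

    A year-1 point strictly farther than ``tau_t1`` from every year-2
    point belongs to geometry removed between the scans and is labelled
    PRUNED; a year-2 point strictly farther than ``tau_t2`` from the
    year-1 cloud is labelled NEW_SHOOT. Points at exactly the threshold
    count as unchanged. The default threshold of 0.030 m is the midpoint
    of the 0.020-0.045 m range that accommodates alignment quality.
    """
    if len(cloud_t1) == 0 or len(cloud_t2) == 0:
        raise ValueError("both input clouds must be non-empty")
    if tau_t1 <= 0 or tau_t2 <= 0:
        raise ValueError("distance thresholds must be positive")
    d1 = nn_distance(cloud_t1, cloud_t2)
    d2 = nn_distance(cloud_t2, cloud_t1)
    lab1 = np.where(d1 > tau_t1, int(ChangeLabel.PRUNED), int(ChangeLabel.UNCHANGED))
    lab2 = np.where(d2 > tau_t2, int(ChangeLabel.NEW_SHOOT), int(ChangeLabel.UNCHANGED))
    return (
        ChangedPointSet(cloud_t1.points, lab1, "t1"),
        ChangedPointSet(cloud_t2.points, lab2, "t2"),
    )


# ---------------------------------------------------------------------------
# PLY / XYZ I/O (ASCII). Extra integer vertex properties carry truth ids and
# change labels; coordinates are double precision so round-trips are exact.

def write_ply(cloud: PointCloud, path, int_attrs: tuple[str, ...] | None = None) -> None:
    """Write an ASCII PLY point cloud with optional integer properties."""
    if int_attrs is None:
        int_attrs = tuple(cloud.attributes.keys())
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        for name in int_attrs:
            fh.write(f"property int {name}\n")
        fh.write("end_header\n")
        cols = [cloud.points]
        for name in int_attrs:
            cols.append(cloud.attributes[name].reshape(-1, 1))
        for row in range(len(cloud)):
            parts = [repr(float(v)) for v in cloud.points[row]]
            parts += [str(int(cloud.attributes[name][row])) for name in int_attrs]
            fh.write(" ".join(parts) + "\n")


def read_ply(path) -> PointCloud:
    """Read an ASCII PLY point cloud; non-xyz properties become attributes."""
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = fh.readline().strip()
        if not fmt.startswith("format ascii"):
            raise ValueError(f"{path}: only ASCII PLY is supported")
        n = None
        props: list[tuple[str, str]] = []
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            line = line.strip()
            if line.startswith("element vertex"):
                n = int(line.split()[-1])
            elif line.startswith("property"):
                _, dtype, name = line.split()
                props.append((name, dtype))
            elif line == "end_header":
                break
        if n is None:
            raise ValueError(f"{path}: no vertex element")
        names = [p[0] for p in props]
        if names[:3] != ["x", "y", "z"]:
            raise ValueError(f"{path}: vertex properties must start with x y z")
        data = np.loadtxt(fh, max_rows=n, ndmin=2)
        if data.shape != (n, len(props)):
            raise ValueError(f"{path}: vertex data shape mismatch")
    attrs = {
        name: data[:, 3 + i].astype(int)
        for i, (name, dtype) in enumerate(props[3:])
    }
    return PointCloud(data[:, :3], attrs)


def write_xyz(cloud: PointCloud, path) -> None:
    """Write plain whitespace-separated XYZ (no attributes)."""
    np.savetxt(path, cloud.points, fmt="%.9f")
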
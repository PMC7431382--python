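"""3D morphometry: dendritic spine classification and density, microglia-
spine interaction scoring on anisotropic confocal voxel grids, and microglial
arbor analysis (centrifugal branch order, Sholl profiles, convex hull volume)
from SWC traces.

Spine subtypes follow the standard four-class geometric taxonomy:

* stubby     - no neck,
* mushroom   - necked spine with head diameter >= 0.6 um,
* filopodia  - neck longer than 3 um,
* thin       - everything else (combined head + neck extent < 3 um).

Microglia-spine contacts are scored in three nested classes from the
minimum 3D distance d, the z-plane separation of the minimizing point, and
the fraction of the spine-head perimeter covered by microglial processes:

* encapsulation - d <= 0.3 um, within one z-plane, coverage >= 1/2,
* apposition    - d <= 0.9 um, within three z-planes,
* proximity     - d <= 1.5 um, within five z-planes.

With the 0.3 um z-step of the default voxel grid the three radii equal the
plane counts times the z-step (1, 3, 5 planes), a consistency asserted by
config validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "SpineRecord",
    "DendriteSegment",
    "ProcessPointCloud",
    "InteractionRecord",
    "MicrogliaTrace",
    "ShollProfile",
    "SPINE_SUBTYPES",
    "INTERACTION_CLASSES",
    "classify_spine",
    "spine_density",
    "min_distance_3d",
    "coverage_fraction",
    "classify_interaction",
    "interaction_density",
    "branch_order_counts",
    "sholl",
    "convex_hull_volume",
    "puncta_interaction_density",
    "read_swc",
]

SPINE_SUBTYPES = ("thin", "stubby", "mushroom", "filopodia")
INTERACTION_CLASSES = ("encapsulation", "apposition", "proximity", "none")

#: (max distance um, max z-plane separation) per nested contact class
INTERACTION_THRESHOLDS = {
    "encapsulation": (0.3, 1),
    "apposition": (0.9, 3),
    "proximity": (1.5, 5),
}

MUSHROOM_HEAD_UM = 0.6
FILOPODIA_NECK_UM = 3.0
THIN_EXTENT_UM = 3.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SpineRecord:
    """One dendritic spine: geometry in um plus its voxel-grid head center."""

    spine_id: str
    position_um: float
    neck_um: float
    head_um: float
    head_voxel: tuple[int, int, int] = (0, 0, 0)
    subtype: str = ""

    def __post_init__(self) -> None:
        if self.neck_um < 0 or self.head_um < 0:
            raise ValueError("spine geometry must be non-negative")
        if not self.subtype:
            self.subtype = classify_spine(self.neck_um, self.head_um)


@dataclass
class DendriteSegment:
    """A dendritic branch with its spines."""

    length_um: float
    distance_from_soma_um: float = 0.0
    spines: list[SpineRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("segment length must be positive")
        for sp in self.spines:
            if not 0.0 <= sp.position_um <= self.length_um:
                raise ValueError(f"spine {sp.spine_id} outside segment")


@dataclass
class ProcessPointCloud:
    """Microglial process points as voxel indices on an anisotropic grid."""

    voxels: np.ndarray  # (n, 3) integer (i, j, k)
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be strictly positive")

    def __len__(self) -> int:
        return len(self.voxels)

    def points_um(self) -> np.ndarray:
        return self.voxels * np.asarray(self.voxel_size_um)


@dataclass
class InteractionRecord:
    """Scored microglia-spine interaction."""

    spine_id: str
    distance_um: float
    z_planes: int
    coverage: float
    interaction: str


@dataclass
class ShollProfile:
    """Arbor intersections with concentric spheres around the soma."""

    radii_um: np.ndarray
    crossings: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_um": self.radii_um, "crossings": self.crossings})


# ---------------------------------------------------------------------------
# spines
# ---------------------------------------------------------------------------

def classify_spine(neck_um: float, head_um: float) -> str:
    """Assign exactly one spine subtype from neck length and head diameter.

    Precedence stubby -> mushroom -> filopodia -> thin resolves overlapping
    rules (a long neck with a large head is a mushroom).  The fall-through
    thin class nominally requires a combined head + neck extent below 3 um;
    geometries outside that bound that match no other rule (the boundary
    dead zone) are assigned thin with a warning.
    """
    if neck_um < 0 or head_um < 0:
        raise ValueError("neck length and head diameter must be non-negative")
    if neck_um == 0:
        return "stubby"
    if head_um >= MUSHROOM_HEAD_UM:
        return "mushroom"
    if neck_um > FILOPODIA_NECK_UM:
        return "filopodia"
    if neck_um + head_um >= THIN_EXTENT_UM:
        warnings.warn(
            f"spine geometry (neck {neck_um}, head {head_um}) in the classification "
            "dead zone; assigned thin",
            stacklevel=2,
        )
    return "thin"


def spine_density(segment: DendriteSegment, per_subtype: bool = True) -> dict[str, float]:
    """Spine counts per 10 um of dendrite, total and per subtype."""
    scale = 10.0 / segment.length_um
    out = {"total": len(segment.spines) * scale}
    if per_subtype:
        for subtype in SPINE_SUBTYPES:
            out[subtype] = sum(sp.subtype == subtype for sp in segment.spines) * scale
    return out


# ---------------------------------------------------------------------------
# microglia-spine interactions
# ---------------------------------------------------------------------------

def min_distance_3d(
    head_voxel, cloud: ProcessPointCloud
) -> tuple[float, int]:
    """Minimum Euclidean distance (um) from a voxel to a point cloud, and the
    z-plane separation |delta k| of the minimizing point.

    Distances are computed on physical coordinates: each voxel-index offset
    is scaled by the anisotropic voxel size before the Pythagorean sum.
    """
    if len(cloud) == 0:
        raise ValueError("empty point cloud")
    head = np.asarray(head_voxel, dtype=int)
    delta = (cloud.voxels - head) * np.asarray(cloud.voxel_size_um)
    d2 = (delta**2).sum(axis=1)
    best = int(np.argmin(d2))
    return float(np.sqrt(d2[best])), int(abs(cloud.voxels[best, 2] - head[2]))


def coverage_fraction(
    head_voxel,
    head_um: float,
    cloud: ProcessPointCloud,
    contact_radius_um: float = 0.3,
    n_bins: int = 36,
) -> float:
    """Fraction of the spine-head perimeter adjacent to microglial processes.

    The head perimeter is discretized into ``n_bins`` angular bins on the
    in-plane circle of diameter ``head_um`` around the head center; a bin
    counts as covered when some cloud point lies within
    ``contact_radius_um`` (3D) of its perimeter sample point.
    """
    if head_um <= 0:
        raise ValueError("head diameter must be positive")
    if len(cloud) == 0:
        return 0.0
    sx, sy, sz = cloud.voxel_size_um
    center = np.asarray(head_voxel) * np.array([sx, sy, sz])
    angles = 2.0 * np.pi * np.arange(n_bins) / n_bins
    ring = center + (head_um / 2.0) * np.stack(
        [np.cos(angles), np.sin(angles), np.zeros(n_bins)], axis=1
    )
    pts = cloud.points_um()
    d2 = ((ring[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    covered = (d2.min(axis=1) <= contact_radius_um**2).sum()
    return covered / n_bins


def classify_interaction(
    distance_um: float, z_planes: int, coverage: float
) -> str:
    """Nested contact classes from distance, z-plane separation and coverage.

    Boundaries are inclusive.  Encapsulation additionally requires the
    microglia to surround at least half the spine head perimeter.
    """
    if distance_um < 0 or z_planes < 0 or not 0.0 <= coverage <= 1.0:
        raise ValueError("invalid interaction inputs")
    enc_d, enc_z = INTERACTION_THRESHOLDS["encapsulation"]
    app_d, app_z = INTERACTION_THRESHOLDS["apposition"]
    prox_d, prox_z = INTERACTION_THRESHOLDS["proximity"]
    if distance_um <= enc_d and z_planes <= enc_z and coverage >= 0.5:
        return "encapsulation"
    if distance_um <= app_d and z_planes <= app_z:
        return "apposition"
    if distance_um <= prox_d and z_planes <= prox_z:
        return "proximity"
    return "none"


def score_interactions(
    spines: list[SpineRecord],
    clouds,
    contact_radius_um: float = 0.3,
    n_bins: int = 36,
) -> list[InteractionRecord]:
    """Score each spine against its microglia cloud.

    ``clouds`` is either a single shared :class:`ProcessPointCloud` (the
    nearest processes of one microglia) or a mapping spine_id -> cloud.
    """
    records = []
    for sp in spines:
        cloud = clouds[sp.spine_id] if isinstance(clouds, dict) else clouds
        d, zp = min_distance_3d(sp.head_voxel, cloud)
        cov = (
            coverage_fraction(sp.head_voxel, sp.head_um, cloud, contact_radius_um, n_bins)
            if sp.head_um > 0
            else 0.0
        )
        records.append(InteractionRecord(sp.spine_id, d, zp, cov, classify_interaction(d, zp, cov)))
    return records


def interaction_density(
    segment: DendriteSegment,
    clouds,
    contact_radius_um: float = 0.3,
    n_bins: int = 36,
) -> dict[str, float]:
    """Microglia-contacted spines per 10 um of dendrite.

    Returns the total plus breakdowns per interaction class and per spine
    subtype (keys ``class:<name>`` and ``subtype:<name>``); per-class counts
    partition the total.
    """
    records = score_interactions(segment.spines, clouds, contact_radius_um, n_bins)
    scale = 10.0 / segment.length_um
    contacted = [r for r in records if r.interaction != "none"]
    subtype_of = {sp.spine_id: sp.subtype for sp in segment.spines}
    out = {"total": len(contacted) * scale}
    for cls in INTERACTION_CLASSES[:-1]:
        out[f"class:{cls}"] = sum(r.interaction == cls for r in contacted) * scale
    for subtype in SPINE_SUBTYPES:
        out[f"subtype:{subtype}"] = (
            sum(subtype_of[r.spine_id] == subtype for r in contacted) * scale
        )
    return out


# ---------------------------------------------------------------------------
# microglia arbor morphology
# ---------------------------------------------------------------------------

class MicrogliaTrace:
    """A traced microglial arbor: nodes with parent links, soma at the root.

    SWC convention: 1-based node ids, parent -1 for the root, coordinates in
    um, type 1 = soma.
    """

    def __init__(self, nodes: pd.DataFrame):
        required = {"node_id", "type", "x", "y", "z", "parent"}
        if not required.issubset(nodes.columns):
            raise ValueError(f"trace table needs columns {sorted(required)}")
        self.nodes = nodes.set_index("node_id", drop=False)
        roots = self.nodes.index[self.nodes["parent"] == -1]
        if len(roots) != 1:
            raise ValueError("trace must have exactly one root")
        self.root = int(roots[0])
        self.children: dict[int, list[int]] = {int(i): [] for i in self.nodes.index}
        for nid, parent in zip(self.nodes["node_id"], self.nodes["parent"]):
            if parent != -1:
                if parent not in self.children:
                    raise ValueError(f"node {nid} references missing parent {parent}")
                self.children[int(parent)].append(int(nid))
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n in seen:
                raise ValueError("cyclic structure in trace")
            seen.add(n)
            stack.extend(self.children[n])
        if len(seen) != len(self.nodes):
            raise ValueError("cyclic structure in trace (unreachable nodes)")

    def coords(self, node_id: int) -> np.ndarray:
        row = self.nodes.loc[node_id]
        return np.array([row["x"], row["y"], row["z"]], dtype=float)

    def soma_nodes(self) -> list[int]:
        soma = self.nodes.index[self.nodes["type"] == 1].to_list()
        return [int(s) for s in soma] or [self.root]

    def all_coords(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)


def read_swc(path) -> MicrogliaTrace:
    """Minimal SWC reader: id type x y z radius parent, '#' comments."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            rows.append(
                {
                    "node_id": int(f[0]),
                    "type": int(f[1]),
                    "x": float(f[2]),
                    "y": float(f[3]),
                    "z": float(f[4]),
                    "radius": float(f[5]),
                    "parent": int(f[6]),
                }
            )
    return MicrogliaTrace(pd.DataFrame(rows))


def branch_order_counts(trace: MicrogliaTrace, max_order: int = 25) -> dict[int, int]:
    """Centrifugal branch-order census of an arbor.

    Order 1 branches adjoin the soma; the order increments at each branch
    point as processes traverse outward.  A branch is a maximal unbranched
    run of nodes; counts are reported per order up to ``max_order``.
    """
    soma = set(trace.soma_nodes())
    counts: dict[int, int] = {}
    # each non-soma child of a soma node starts an order-1 branch
    stack: list[tuple[int, int]] = []
    for s in soma:
        for c in trace.children[s]:
            if c not in soma:
                stack.append((c, 1))
    while stack:
        node, order = stack.pop()
        if order <= max_order:
            counts[order] = counts.get(order, 0) + 1
        # walk to the end of this unbranched run
        while True:
            kids = trace.children[node]
            if len(kids) == 1:
                node = kids[0]
                continue
            if len(kids) >= 2:  # branch point: children start order+1 branches
                stack.extend((k, order + 1) for k in kids)
            break
    return dict(sorted(counts.items()))


def sholl(trace: MicrogliaTrace, radii_um) -> ShollProfile:
    """Sholl profile: arbor crossings of concentric spheres about the soma.

    Each parent-child segment of the trace is treated as a straight chord;
    crossings with the sphere of radius r are the roots of the quadratic
    |p1 + t (p2 - p1)|^2 = r^2 on t in [0, 1) (half-open so shared nodes are
    not double counted).
    """
    radii = np.asarray(radii_um, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radius grid must be strictly increasing")
    origin = trace.coords(trace.root)
    segments = []
    for parent, kids in trace.children.items():
        p1 = trace.coords(parent) - origin
        for k in kids:
            segments.append((p1, trace.coords(k) - origin))
    crossings = np.zeros(len(radii), dtype=int)
    for p1, p2 in segments:
        d = p2 - p1
        a = d @ d
        if a == 0:
            continue
        b = 2.0 * (p1 @ d)
        for i, r in enumerate(radii):
            c = p1 @ p1 - r * r
            disc = b * b - 4.0 * a * c
            if disc < 0:
                continue
            sq = np.sqrt(disc)
            for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
                if 0.0 <= t < 1.0:
                    crossings[i] += 1
            if disc == 0:  # tangent: single root counted once
                if 0.0 <= -b / (2 * a) < 1.0:
                    crossings[i] -= 1
    return ShollProfile(radii, crossings)


def convex_hull_volume(trace: MicrogliaTrace) -> float:
    """Volume (um^3) of the 3D convex hull of all trace node coordinates.

    Degenerate (coplanar or fewer than 4 distinct) point sets return 0 with
    a warning.
    """
    pts = np.unique(trace.all_coords(), axis=0)
    if len(pts) < 4:
        warnings.warn("fewer than 4 distinct points: hull volume 0", stacklevel=2)
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        warnings.warn("degenerate (coplanar) trace: hull volume 0", stacklevel=2)
        return 0.0


# ---------------------------------------------------------------------------
# synaptic puncta
# ---------------------------------------------------------------------------

def puncta_interaction_density(
    puncta_um: np.ndarray,
    footprint_um: np.ndarray,
    footprint_area_um2: float,
    overlap_radius_um: float = 0.3,
) -> float:
    """Synaptic puncta overlapping a microglial footprint, per um^2.

    A punctum overlaps when it lies within ``overlap_radius_um`` of any
    footprint point; the count is normalized by the footprint surface area.
    """
    if footprint_area_um2 <= 0:
        raise ValueError("footprint area must be positive")
    puncta = np.asarray(puncta_um, dtype=float)
    if puncta.size == 0:
        return 0.0
    footprint = np.asarray(footprint_um, dtype=float).reshape(len(footprint_um), -1)
    puncta = puncta.reshape(len(puncta), -1)
    d2 = ((puncta[:, None, :] - footprint[None, :, :]) ** 2).sum(axis=2)
    overlapping = int((d2.min(axis=1) <= overlap_radius_um**2).sum())
    return overlapping / footprint_area_um2
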
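"""Idealized left-atrial geometry, fibrosis fields, and ablation lesion sets.

Patient anatomies are not available, so the substrate is a flat triangulated
sheet carrying the topological essentials of the left atrium: four disc-shaped
pulmonary-vein (PV) sleeve regions arranged in two encirclable pairs, a mitral
"boundary" rim, per-node fiber orientations with circumferential deflection
around each ostium, and a seeded clustered fibrosis label field.

Lesion sets model virtual catheter ablation:

* ring lesions — stadium-shaped circumferential lines around a PV pair
  (two rings = a complete PVI);
* gaps — unablated corridors of fixed arc width (2 mm clinically) left in a
  ring, identified by stable string ids;
* focal discs — e.g. ablation of the highest-DF site.

Coordinates are mm, edge lengths are reported in μm, node indices 0-based.
Mesh I/O is legacy ASCII VTK polydata with named per-node attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "REGION_CODES", "TISSUE_CODES",
    "AtrialMesh", "RingLesion", "GapSpec", "FocalLesion", "LesionSet",
    "build_idealized_la", "generate_fibrosis",
    "make_pvi_lesions", "fill_gaps", "make_focal_lesion", "apply_lesions",
    "idw_interpolate", "read_mesh", "write_mesh",
    "MeshParseError",
]

REGION_CODES = {"la_body": 0, "pv1": 1, "pv2": 2, "pv3": 3, "pv4": 4,
                "boundary": 5}
TISSUE_CODES = {"normal": 0, "fibrotic": 1, "ablated": 2}

PV_REGION_IDS = (1, 2, 3, 4)


class MeshParseError(ValueError):
    """Malformed mesh file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------
@dataclass
class AtrialMesh:
    """Triangulated atrial surface with region/tissue labels and fibers.

    Attributes
    ----------
    points : (n, 3) float array, mm
    triangles : (m, 3) int array
    region : (n,) int array, codes per :data:`REGION_CODES`
    tissue : (n,) int array, codes per :data:`TISSUE_CODES`
    fibers : (n, 3) float array of unit vectors
    point_data : optional named per-node scalar fields (exports, maps)
    """

    points: np.ndarray
    triangles: np.ndarray
    region: np.ndarray
    tissue: np.ndarray
    fibers: np.ndarray
    point_data: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.region = np.asarray(self.region, dtype=np.int32)
        self.tissue = np.asarray(self.tissue, dtype=np.int32)
        self.fibers = np.asarray(self.fibers, dtype=np.float64)
        n = self.points.shape[0]
        if self.triangles.size and (self.triangles.min() < 0
                                    or self.triangles.max() >= n):
            raise ValueError("triangle references a nonexistent node")

    # -- basic queries ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    def copy(self) -> "AtrialMesh":
        return AtrialMesh(self.points.copy(), self.triangles.copy(),
                          self.region.copy(), self.tissue.copy(),
                          self.fibers.copy(), dict(self.point_data),
                          dict(self.meta))

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) index array."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths_um(self) -> np.ndarray:
        e = self.edges()
        d = np.linalg.norm(self.points[e[:, 0]] - self.points[e[:, 1]], axis=1)
        return d * 1000.0

    def mean_edge_um(self) -> float:
        return float(np.mean(self.edge_lengths_um()))

    def summary(self) -> dict:
        el = self.edge_lengths_um()
        return {
            "n_nodes": self.n_nodes,
            "n_triangles": int(self.triangles.shape[0]),
            "mean_edge_um": float(el.mean()),
            "sd_edge_um": float(el.std()),
            "n_fibrotic": int(np.sum(self.tissue == TISSUE_CODES["fibrotic"])),
            "n_ablated": int(np.sum(self.tissue == TISSUE_CODES["ablated"])),
        }

    def region_nodes(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.region == REGION_CODES[name])

    def pv_nodes(self) -> np.ndarray:
        return np.flatnonzero(np.isin(self.region, PV_REGION_IDS))

    def active(self) -> np.ndarray:
        """Boolean mask of non-ablated nodes."""
        return self.tissue != TISSUE_CODES["ablated"]

    def adjacency(self, respect_ablation: bool = True):
        """Sparse symmetric node adjacency; ablated nodes isolated if asked."""
        from scipy.sparse import coo_matrix

        e = self.edges()
        if respect_ablation:
            act = self.active()
            keep = act[e[:, 0]] & act[e[:, 1]]
            e = e[keep]
        n = self.n_nodes
        ones = np.ones(len(e))
        a = coo_matrix((ones, (e[:, 0], e[:, 1])), shape=(n, n))
        return (a + a.T).tocsr()


# ---------------------------------------------------------------------------
# Lesion geometry
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class RingLesion:
    """Stadium-shaped circumferential line around a PV pair.

    The centerline is the locus of points at distance ``ring_radius_mm`` from
    the segment joining the two PV centers; nodes within half the line width
    of the centerline are ablated.
    """

    name: str
    c1: tuple          # first PV center (x, y), mm
    c2: tuple          # second PV center (x, y), mm
    ring_radius_mm: float
    width_mm: float

    def _frame(self):
        c1 = np.asarray(self.c1, dtype=float)
        c2 = np.asarray(self.c2, dtype=float)
        axis = c2 - c1
        d = float(np.linalg.norm(axis))
        u = axis / d
        nvec = np.array([-u[1], u[0]])
        return c1, c2, d, u, nvec

    @property
    def arc_length(self) -> float:
        _, _, d, _, _ = self._frame()
        return 2.0 * d + 2.0 * np.pi * self.ring_radius_mm

    def curve_distance_and_arcpos(self, pts: np.ndarray):
        """For (k, 2) points: distance to the ring centerline and the arc
        position (mm along the curve) of the nearest centerline point.

        Arc parameterization: s=0 at the +n side of c1, side A straight
        segment for s in [0, d], semicircle around c2, side B straight
        segment, semicircle around c1.
        """
        c1, c2, d, u, nvec = self._frame()
        r = self.ring_radius_mm
        p = np.asarray(pts, dtype=float)[:, :2]
        rel = p - c1
        t = np.clip(rel @ u, 0.0, d)
        foot = c1 + t[:, None] * u
        radial = p - foot
        rad_norm = np.linalg.norm(radial, axis=1)
        # points on the segment axis: push off along +n deterministically
        degenerate = rad_norm < 1e-12
        w = np.where(degenerate[:, None],
                     nvec, radial / np.where(degenerate, 1.0, rad_norm)[:, None])
        dist = np.abs(rad_norm - r)

        wn = w @ nvec
        wu = w @ u
        s = np.empty(len(p))
        interior = (t > 1e-12) & (t < d - 1e-12)
        side_a = interior & (wn >= 0)
        side_b = interior & (wn < 0)
        s[side_a] = t[side_a]
        s[side_b] = d + np.pi * r + (d - t[side_b])
        at_c2 = ~interior & (t >= d - 1e-12)
        alpha2 = np.arctan2(wu[at_c2], wn[at_c2]) % (2 * np.pi)
        s[at_c2] = d + alpha2 * r
        at_c1 = ~interior & (t <= 1e-12)
        alpha1 = np.arctan2(-wu[at_c1], -wn[at_c1]) % (2 * np.pi)
        s[at_c1] = 2 * d + np.pi * r + alpha1 * r
        return dist, s

    def point_at(self, s: float, offset: float = 0.0) -> np.ndarray:
        """Point at arc position ``s``, displaced ``offset`` mm outward
        (negative = toward the PV pair)."""
        c1, c2, d, u, nvec = self._frame()
        r = self.ring_radius_mm + offset
        L = self.arc_length
        s = s % L
        if s <= d:
            return c1 + s * u + r * nvec
        s -= d
        if s <= np.pi * self.ring_radius_mm:
            a = s / self.ring_radius_mm
            w = np.cos(a) * nvec + np.sin(a) * u
            return c2 + r * w
        s -= np.pi * self.ring_radius_mm
        if s <= d:
            return c2 - s * u - r * nvec
        s -= d
        a = s / self.ring_radius_mm
        w = -np.cos(a) * nvec - np.sin(a) * u
        return c1 + r * w


@dataclass(frozen=True)
class GapSpec:
    """Unablated corridor on a parent ring, centered at arc position
    ``arc_pos_mm`` with arc width ``arc_width_mm``."""

    gap_id: str
    ring_name: str
    arc_pos_mm: float
    arc_width_mm: float

    def __post_init__(self):
        if self.arc_width_mm <= 0:
            raise ValueError("gap arc width must be > 0")


@dataclass(frozen=True)
class FocalLesion:
    """Disc lesion centered on a mesh node."""

    center_node: int
    radius_mm: float


@dataclass(frozen=True)
class LesionSet:
    rings: tuple = ()
    gaps: tuple = ()
    focal: tuple = ()

    def __post_init__(self):
        ring_names = {r.name for r in self.rings}
        for g in self.gaps:
            if g.ring_name not in ring_names:
                raise ValueError(f"gap {g.gap_id} references unknown ring "
                                 f"{g.ring_name!r}")

    def gap_ids(self):
        return [g.gap_id for g in self.gaps]

    def ring(self, name: str) -> RingLesion:
        for r in self.rings:
            if r.name == name:
                return r
        raise KeyError(name)

    def merged(self, other: "LesionSet") -> "LesionSet":
        return LesionSet(self.rings + other.rings, self.gaps + other.gaps,
                         self.focal + other.focal)


# ---------------------------------------------------------------------------
# Synthetic geometry generation
# ---------------------------------------------------------------------------
def _pv_layout(width_mm: float, height_mm: float):
    """PV centers: two left (pv1 superior, pv2 inferior) and two right."""
    return {
        "pv1": (0.27 * width_mm, 0.68 * height_mm),
        "pv2": (0.27 * width_mm, 0.32 * height_mm),
        "pv3": (0.73 * width_mm, 0.68 * height_mm),
        "pv4": (0.73 * width_mm, 0.32 * height_mm),
    }


def build_idealized_la(width_mm: float = 50.0, height_mm: float = 50.0,
                       target_edge_um: float = 400.0,
                       pv_radius_mm: float = 4.0,
                       seed: int = 0,
                       jitter_fraction: float = 0.12) -> AtrialMesh:
    """Flat rectangular LA-like sheet with four PV sleeve discs.

    A structured right-triangle grid is jittered (seeded) in the interior to
    break lattice symmetry while preserving edge-length uniformity
    (SD/mean stays well below 0.5). The grid spacing is chosen so that the
    mean edge length (including diagonals) matches ``target_edge_um``.

    PV sleeves sit in two vertical pairs so that one stadium-shaped ring can
    encircle each pair. Sheet-border nodes are tagged ``boundary`` (mitral
    rim surrogate). Fibers default to the x direction with circumferential
    deflection around each ostium.
    """
    if target_edge_um < 100.0:
        raise ValueError("target_edge_um must be >= 100")
    # mean edge of the structured pattern is (2 + sqrt(2))/3 * h
    h = (target_edge_um / 1000.0) / ((2.0 + np.sqrt(2.0)) / 3.0)
    nx = max(2, int(round(width_mm / h)) + 1)
    ny = max(2, int(round(height_mm / h)) + 1)
    xs = np.linspace(0.0, width_mm, nx)
    ys = np.linspace(0.0, height_mm, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(),
                              np.zeros(nx * ny)])

    rng = np.random.default_rng(seed)
    interior = ((points[:, 0] > 1e-9) & (points[:, 0] < width_mm - 1e-9)
                & (points[:, 1] > 1e-9) & (points[:, 1] < height_mm - 1e-9))
    jit = rng.uniform(-jitter_fraction * h, jitter_fraction * h,
                      size=(interior.sum(), 2))
    points[interior, :2] += jit

    def nid(i, j):
        return i * ny + j

    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris.append((a, b, c)); tris.append((a, c, d))
            else:
                tris.append((a, b, d)); tris.append((b, c, d))
    triangles = np.array(tris, dtype=np.int64)

    with_pv = pv_radius_mm > 0
    centers = _pv_layout(width_mm, height_mm) if with_pv else {}
    ring_clearance = 2.0
    ring_r = pv_radius_mm + ring_clearance
    if with_pv:
        pair_half = abs(centers["pv1"][1] - centers["pv2"][1]) / 2.0
        margin = ring_r + 1.0
        cx_left = centers["pv1"][0]
        cx_right = centers["pv3"][0]
        if (cx_left - margin < 0 or cx_right + margin > width_mm
                or centers["pv2"][1] - margin < 0
                or centers["pv1"][1] + margin > height_mm):
            raise ValueError("geometric infeasibility: PV ostia/ring do not "
                             "fit inside the sheet")
        if (cx_right - cx_left) < 2 * ring_r + 2.0:
            raise ValueError("geometric infeasibility: left and right PV "
                             "rings overlap")
        if 2 * pv_radius_mm > 2 * pair_half:
            raise ValueError("geometric infeasibility: PV discs within a "
                             "pair overlap")

    region = np.zeros(len(points), dtype=np.int32)
    on_border = ~interior
    region[on_border] = REGION_CODES["boundary"]
    # The sleeve region is the whole encirclable antrum (everything inside
    # the PVI ring locus), split between the pair's two veins by proximity,
    # so that applying a gap-free ring disconnects exactly region-vs-body.
    for pair in ((("pv1", "pv2"), ("pv3", "pv4")) if with_pv else ()):
        c1 = np.asarray(centers[pair[0]])
        c2 = np.asarray(centers[pair[1]])
        axis = c2 - c1
        t = np.clip((points[:, :2] - c1) @ axis / (axis @ axis), 0.0, 1.0)
        foot = c1 + t[:, None] * axis
        dseg = np.linalg.norm(points[:, :2] - foot, axis=1)
        inside = dseg <= ring_r
        d1 = np.linalg.norm(points[:, :2] - c1, axis=1)
        d2 = np.linalg.norm(points[:, :2] - c2, axis=1)
        region[inside & (d1 <= d2)] = REGION_CODES[pair[0]]
        region[inside & (d1 > d2)] = REGION_CODES[pair[1]]

    tissue = np.zeros(len(points), dtype=np.int32)

    # fibers: x-aligned with circumferential swirl near each ostium
    fibers = np.zeros((len(points), 3))
    fibers[:, 0] = 1.0
    for name in (("pv1", "pv2", "pv3", "pv4") if with_pv else ()):
        c = np.asarray(centers[name])
        rel = points[:, :2] - c
        r = np.linalg.norm(rel, axis=1)
        near = r < 2.0 * pv_radius_mm
        tang = np.column_stack([-rel[near, 1], rel[near, 0]])
        nrm = np.linalg.norm(tang, axis=1)
        nrm[nrm < 1e-12] = 1.0
        fibers[near, 0] = tang[:, 0] / nrm
        fibers[near, 1] = tang[:, 1] / nrm
    fibers /= np.linalg.norm(fibers, axis=1, keepdims=True)

    mesh = AtrialMesh(points, triangles, region, tissue, fibers,
                      meta={"width_mm": width_mm, "height_mm": height_mm,
                            "pv_radius_mm": pv_radius_mm,
                            "ring_radius_mm": ring_r,
                            **({"pv_centers": {k: tuple(v) for k, v in centers.items()}}
                               if with_pv else {}),
                            "target_edge_um": target_edge_um, "seed": seed})
    el = mesh.edge_lengths_um()
    if el.std() / el.mean() >= 0.5:
        raise RuntimeError("generated mesh violates edge-uniformity invariant")
    return mesh


def generate_fibrosis(mesh: AtrialMesh, density_fraction: float,
                      cluster_radius_mm: float = 3.0,
                      seed: int = 0) -> AtrialMesh:
    """Label a clustered random fraction of non-ablated LA-body nodes fibrotic.

    Cluster seed nodes are drawn uniformly and grown to ``cluster_radius_mm``
    discs until the target count is reached; the realized fraction is then
    trimmed to the target exactly, so it always lies within the ±10% contract.
    Same seed → identical labels.
    """
    if not 0.0 <= density_fraction < 1.0:
        raise ValueError("density_fraction must be in [0, 1)")
    out = mesh.copy()
    body = np.flatnonzero((out.region == REGION_CODES["la_body"])
                          & (out.tissue != TISSUE_CODES["ablated"]))
    target = int(round(density_fraction * len(body)))
    if target == 0:
        return out
    rng = np.random.default_rng(seed)
    tree = cKDTree(out.points[body, :2])
    fibrotic = np.zeros(len(body), dtype=bool)
    order = []   # growth order, for exact trimming
    guard = 0
    while fibrotic.sum() < target and guard < 10000:
        guard += 1
        center = out.points[rng.choice(body), :2]
        hit = tree.query_ball_point(center, cluster_radius_mm)
        hit = [i for i in hit if not fibrotic[i]]
        if not hit:
            continue
        # grow outward from the cluster center
        hit = sorted(hit, key=lambda i: np.linalg.norm(
            out.points[body[i], :2] - center))
        fibrotic[hit] = True
        order.extend(hit)
    if fibrotic.sum() > target:
        for i in order[target:]:
            fibrotic[i] = False
    out.tissue[body[fibrotic]] = TISSUE_CODES["fibrotic"]
    return out


# ---------------------------------------------------------------------------
# Lesion construction and application
# ---------------------------------------------------------------------------
def make_pvi_lesions(mesh: AtrialMesh, with_gaps: bool,
                     gap_width_mm: float = 2.0,
                     gaps_per_model: int = 4,
                     line_width_mm: float | None = None) -> LesionSet:
    """PVI lesion set: one ring per PV pair, optionally with gaps.

    With gaps, ``gaps_per_model`` corridors (default 4, i.e. anterior and
    posterior on each ring) of arc width ``gap_width_mm`` are left unablated.
    Gap ids are ``"<ring>:g<k>"`` with k=0 the anterior (straight-segment
    midpoint) position.
    """
    meta = mesh.meta
    if "pv_centers" not in meta:
        raise ValueError("mesh has no PV layout metadata; build it with "
                         "build_idealized_la or supply region metadata")
    centers = meta["pv_centers"]
    ring_r = meta.get("ring_radius_mm", meta["pv_radius_mm"] + 2.0)
    mean_edge_mm = mesh.mean_edge_um() / 1000.0
    if line_width_mm is None:
        line_width_mm = max(2.0, 2.5 * mean_edge_mm)
    if line_width_mm < mean_edge_mm:
        raise ValueError("lesion line width below local mean edge length; "
                         "the line would be non-contiguous")

    rings = (
        RingLesion("left", centers["pv1"], centers["pv2"], ring_r,
                   line_width_mm),
        RingLesion("right", centers["pv3"], centers["pv4"], ring_r,
                   line_width_mm),
    )
    # feasibility: ring band must not touch the sheet border
    w, hgt = meta["width_mm"], meta["height_mm"]
    for r in rings:
        for s in np.linspace(0, r.arc_length, 64, endpoint=False):
            p = r.point_at(s, offset=line_width_mm / 2)
            if not (0 < p[0] < w and 0 < p[1] < hgt):
                raise ValueError(f"ring {r.name} cannot be routed: it reaches "
                                 "the sheet boundary")
    gaps = ()
    if with_gaps:
        if gaps_per_model < 2 or gaps_per_model % 2:
            raise ValueError("gaps_per_model must be even and >= 2")
        per_ring = gaps_per_model // 2
        gg = []
        for r in rings:
            c1, c2, d, _, _ = r._frame()
            L = r.arc_length
            for k in range(per_ring):
                s = (d / 2.0 + k * L / per_ring) % L
                gg.append(GapSpec(f"{r.name}:g{k}", r.name, s, gap_width_mm))
        gaps = tuple(gg)
    return LesionSet(rings=rings, gaps=gaps)


def fill_gaps(lesions: LesionSet, gap_ids) -> LesionSet:
    """Convert the named gaps to ablation (remove the corridors).

    Filling every gap makes the applied lesion set node-equivalent to the
    gap-free PVI.
    """
    known = set(lesions.gap_ids())
    gap_ids = list(gap_ids)
    unknown = [g for g in gap_ids if g not in known]
    if unknown:
        raise KeyError(f"unknown gap id(s): {unknown}")
    keep = tuple(g for g in lesions.gaps if g.gap_id not in set(gap_ids))
    return replace(lesions, gaps=keep)


def make_focal_lesion(mesh: AtrialMesh, center_node: int,
                      radius_mm: float) -> LesionSet:
    """Disc lesion of ``radius_mm`` centered on a node."""
    mean_edge_mm = mesh.mean_edge_um() / 1000.0
    if radius_mm < mean_edge_mm - 1e-9:
        raise ValueError("focal radius below mean edge length")
    return LesionSet(focal=(FocalLesion(int(center_node), float(radius_mm)),))


def lesion_mask(mesh: AtrialMesh, lesions: LesionSet) -> np.ndarray:
    """Boolean mask of nodes inside the lesion geometry (gap corridors
    excluded)."""
    pts = mesh.points[:, :2]
    mask = np.zeros(mesh.n_nodes, dtype=bool)
    for ring in lesions.rings:
        dist, s = ring.curve_distance_and_arcpos(pts)
        in_band = dist <= ring.width_mm / 2.0
        L = ring.arc_length
        for g in lesions.gaps:
            if g.ring_name != ring.name:
                continue
            ds = np.abs((s - g.arc_pos_mm + L / 2.0) % L - L / 2.0)
            in_band &= ~(ds <= g.arc_width_mm / 2.0)
        mask |= in_band
    for f in lesions.focal:
        c = pts[f.center_node]
        mask |= np.linalg.norm(pts - c, axis=1) <= f.radius_mm
    return mask


def apply_lesions(mesh: AtrialMesh, lesions: LesionSet) -> AtrialMesh:
    """Label lesion nodes ablated; other labels untouched; idempotent."""
    out = mesh.copy()
    out.tissue[lesion_mask(mesh, lesions)] = TISSUE_CODES["ablated"]
    return out


# ---------------------------------------------------------------------------
# Inverse-distance-weighted interpolation (electroanatomical map stand-in)
# ---------------------------------------------------------------------------
def idw_interpolate(sample_points: np.ndarray, sample_values: np.ndarray,
                    mesh: AtrialMesh, power: float = 2.0,
                    eps_mm: float = 1e-9) -> np.ndarray:
    """Shepard inverse-distance-weighted interpolation onto mesh nodes.

    ``value(x) = Σ w_i v_i / Σ w_i`` with ``w_i = d_i^-power``; a node closer
    than ``eps_mm`` to a sample takes that sample's value exactly.
    """
    sp = np.atleast_2d(np.asarray(sample_points, dtype=float))
    sv = np.asarray(sample_values, dtype=float)
    if sp.shape[0] == 0:
        raise ValueError("at least one sample point required")
    if sp.shape[1] == 2:
        sp = np.column_stack([sp, np.zeros(len(sp))])
    diff = mesh.points[:, None, :] - sp[None, :, :]
    d = np.linalg.norm(diff, axis=2)
    exact = d < eps_mm
    d_safe = np.where(exact, 1.0, d)
    w = d_safe ** (-power)
    vals = (w @ sv) / w.sum(axis=1)
    hit_rows = exact.any(axis=1)
    if hit_rows.any():
        first = np.argmax(exact[hit_rows], axis=1)
        vals[hit_rows] = sv[first]
    return vals


# ---------------------------------------------------------------------------
# VTK legacy ASCII polydata I/O
# ---------------------------------------------------------------------------
_TISSUE_ATTR = "tissue_label"


def write_mesh(mesh: AtrialMesh, path) -> None:
    """Write the mesh as legacy ASCII VTK polydata with named POINT_DATA
    attributes ``region`` (int), ``tissue_label`` (int) and ``fiber``
    (vectors), plus any extra scalar fields in ``mesh.point_data``."""
    n = mesh.n_nodes
    m = mesh.triangles.shape[0]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("atrialab atrial mesh\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        for p in mesh.points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {m} {4 * m}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"POINT_DATA {n}\n")
        for name, arr in (("region", mesh.region),
                          (_TISSUE_ATTR, mesh.tissue)):
            fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(int(v)) for v in arr) + "\n")
        fh.write("VECTORS fiber double\n")
        for v in mesh.fibers:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for name, arr in mesh.point_data.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{float(v):.9g}" for v in arr) + "\n")


def read_mesh(path) -> AtrialMesh:
    """Read a legacy ASCII VTK polydata mesh written by :func:`write_mesh`.

    A file missing the ``tissue_label`` attribute loads with all-normal
    labels and a warning; an out-of-range triangle index raises
    :class:`MeshParseError` with the line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    idx = 0

    def fail(msg):
        raise MeshParseError(f"{path}: line {idx + 1}: {msg}")

    def next_tokens():
        nonlocal idx
        while idx < len(lines):
            toks = lines[idx].split()
            idx += 1
            if toks:
                return toks
        return None

    points = triangles = None
    region = tissue = fibers = None
    extras = {}
    npoints = 0
    toks = next_tokens()
    while toks is not None:
        key = toks[0].upper()
        if key == "POINTS":
            try:
                npoints = int(toks[1])
            except (IndexError, ValueError):
                fail("malformed POINTS header")
            vals = []
            while len(vals) < 3 * npoints:
                t = next_tokens()
                if t is None:
                    fail("unexpected EOF in POINTS")
                vals.extend(float(x) for x in t)
            points = np.array(vals).reshape(npoints, 3)
        elif key == "POLYGONS":
            try:
                m = int(toks[1])
            except (IndexError, ValueError):
                fail("malformed POLYGONS header")
            tris = []
            for _ in range(m):
                t = next_tokens()
                if t is None:
                    fail("unexpected EOF in POLYGONS")
                if int(t[0]) != 3:
                    fail("only triangles are supported")
                tri = [int(x) for x in t[1:4]]
                if min(tri) < 0 or max(tri) >= npoints:
                    fail(f"triangle references nonexistent node {max(tri)}")
                tris.append(tri)
            triangles = np.array(tris, dtype=np.int64)
        elif key == "SCALARS":
            name = toks[1]
            nt = next_tokens()   # LOOKUP_TABLE line
            if nt is None or nt[0].upper() != "LOOKUP_TABLE":
                fail(f"SCALARS {name} missing LOOKUP_TABLE")
            vals = []
            while len(vals) < npoints:
                t = next_tokens()
                if t is None:
                    fail(f"unexpected EOF in SCALARS {name}")
                vals.extend(float(x) for x in t)
            arr = np.array(vals)
            if name == "region":
                region = arr.astype(np.int32)
            elif name == _TISSUE_ATTR:
                tissue = arr.astype(np.int32)
            else:
                extras[name] = arr
        elif key == "VECTORS":
            vals = []
            while len(vals) < 3 * npoints:
                t = next_tokens()
                if t is None:
                    fail("unexpected EOF in VECTORS")
                vals.extend(float(x) for x in t)
            fibers = np.array(vals).reshape(npoints, 3)
        toks = next_tokens()

    if points is None or triangles is None:
        raise MeshParseError(f"{path}: no POINTS/POLYGONS sections found")
    if region is None:
        region = np.zeros(npoints, dtype=np.int32)
    if tissue is None:
        warnings.warn(f"{path}: no '{_TISSUE_ATTR}' attribute; "
                      "defaulting all tissue labels to normal")
        tissue = np.zeros(npoints, dtype=np.int32)
    if fibers is None:
        fibers = np.zeros((npoints, 3))
        fibers[:, 0] = 1.0
    return AtrialMesh(points, triangles, region, tissue, fibers,
                      point_data=extras)
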
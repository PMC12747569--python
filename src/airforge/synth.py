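"""Synthetic fixtures: CT-like phantoms, watertight tube trees, mesh defects.

Everything downstream of the scanner is testable from this module alone:

* :func:`make_ct_phantom` builds Hounsfield-unit volumes with analytic air
  cavities (tubes, ellipsoidal pockets, branching trees) embedded in soft
  tissue, with optional Gaussian noise and metal inserts.
* :func:`make_tube_tree` builds a watertight bifurcating tube-tree surface
  with a known centerline; open variants expose exactly ``2**n + 1`` boundary
  loops (terminals plus root).
* :func:`inject_defects` damages a clean mesh in controlled, manifest-tracked
  ways (holes, non-manifold fins, flipped faces, duplicate vertices).
* :func:`make_probability_patches` tiles a mask into overlapping probability
  sub-volumes the way patch-wise network inference would produce them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure

from ._clip import clip_mesh_plane, compact
from .network import CenterlineNetwork
from .volume import ScalarVolume

import networkx as nx

AIR_HU = -1000.0


# --------------------------------------------------------------------------
# phantom specification
# --------------------------------------------------------------------------

@dataclass
class TubeCavity:
    """Straight cylindrical air cavity; radius derived from target volume."""

    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    volume_cm3: float
    air_hu: float = AIR_HU

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end_mm, self.start_mm)))

    @property
    def radius_mm(self) -> float:
        # V = pi r^2 L, V in mm^3
        return float(np.sqrt(self.volume_cm3 * 1000.0 / (np.pi * self.length_mm)))


@dataclass
class PocketCavity:
    """Isolated spherical air pocket of controlled volume."""

    center_mm: tuple[float, float, float]
    volume_cm3: float
    air_hu: float = AIR_HU

    @property
    def radius_mm(self) -> float:
        return float((3.0 * self.volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass
class MetalInsert:
    center_mm: tuple[float, float, float]
    radius_mm: float
    hu: float = 3000.0


@dataclass
class PhantomSpec:
    """CT phantom description: cavities in soft tissue plus optional metal."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cavities: list = field(default_factory=list)
    background_hu: float = 40.0
    noise_sd_hu: float = 0.0
    metal: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.shape):
            raise ValueError("phantom grid must be at least 8 voxels per axis")
        for m in self.metal:
            if m.hu <= 2000:
                raise ValueError("metal inserts must exceed 2000 HU")
        for c in self.cavities:
            if c.air_hu >= -900.0:
                raise ValueError("cavity air intensity must be below -900 HU")


def _voxel_centers(shape, spacing):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij")


def _raster_majority(inside_fn, shape, spacing):
    """Rasterize an analytic solid by 3x3x3 subsampling per voxel.

    A voxel is inside when a strict majority of its 27 subsample points are
    inside. The odd subsample count avoids coverage ties, so the voxel count
    tracks the true volume to within a few percent even for lattice-aligned
    primitives (plain center sampling can be off by close to 10%).
    """
    count = np.zeros(shape, dtype=np.int8)
    offsets = (-1.0 / 3.0, 0.0, 1.0 / 3.0)
    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                ax = [
                    (np.arange(n) + off) * s
                    for n, s, off in zip(shape, spacing, (ox, oy, oz))
                ]
                X, Y, Z = np.meshgrid(*ax, indexing="ij")
                count += inside_fn(X, Y, Z)
    return count >= 14


def _check_inside(lo, hi, extent, what):
    if np.any(np.asarray(lo) < 0) or np.any(np.asarray(hi) > np.asarray(extent)):
        raise ValueError(f"{what} does not fit inside the phantom grid")


def make_ct_phantom(spec: PhantomSpec, seed: int = 0):
    """Build an HU volume and per-cavity ground-truth masks.

    Returns
    -------
    vol : ScalarVolume
    masks : list of bool arrays, one per cavity, exact analytic rasterization.
    """
    shape = tuple(spec.shape)
    spacing = tuple(spec.spacing)
    extent = np.array(shape) * np.array(spacing)

    rng = np.random.default_rng(seed)
    values = np.full(shape, spec.background_hu, dtype=np.float64)
    masks: list[np.ndarray] = []

    for cav in spec.cavities:
        if isinstance(cav, TubeCavity):
            a = np.asarray(cav.start_mm, float)
            b = np.asarray(cav.end_mm, float)
            r = cav.radius_mm
            # tight cylinder bounding box: radial pad shrinks along the axis,
            # so a through-tube may legitimately reach the grid faces
            d_unit = (b - a) / np.linalg.norm(b - a)
            pad = r * np.sqrt(np.clip(1.0 - d_unit**2, 0.0, 1.0))
            _check_inside(np.minimum(a, b) - pad, np.maximum(a, b) + pad, extent, "tube cavity")
            d = b - a
            L2 = d @ d

            def _in_tube(X, Y, Z, a=a, d=d, L2=L2, r=r):
                px, py, pz = X - a[0], Y - a[1], Z - a[2]
                t = (px * d[0] + py * d[1] + pz * d[2]) / L2
                dx = px - t * d[0]
                dy = py - t * d[1]
                dz = pz - t * d[2]
                # flat-ended analytic cylinder: target volume is pi r^2 L
                return (dx * dx + dy * dy + dz * dz <= r * r) & (t >= 0.0) & (t < 1.0)

            mask = _raster_majority(_in_tube, shape, spacing)
        elif isinstance(cav, PocketCavity):
            c = np.asarray(cav.center_mm, float)
            r = cav.radius_mm
            _check_inside(c - r, c + r, extent, "pocket cavity")

            def _in_pocket(X, Y, Z, c=c, r=r):
                return (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r * r

            mask = _raster_majority(_in_pocket, shape, spacing)
        else:
            raise TypeError(f"unknown cavity primitive {type(cav)!r}")
        values[mask] = cav.air_hu
        masks.append(mask)

    for m in spec.metal:
        c = np.asarray(m.center_mm, float)
        _check_inside(c - m.radius_mm, c + m.radius_mm, extent, "metal insert")

        def _in_metal(X, Y, Z, c=c, r=m.radius_mm):
            return (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r * r

        values[_raster_majority(_in_metal, shape, spacing)] = m.hu

    if spec.noise_sd_hu > 0:
        values = values + rng.normal(0.0, spec.noise_sd_hu, size=shape)

    return ScalarVolume(values, spacing), masks


# --------------------------------------------------------------------------
# tube trees
# --------------------------------------------------------------------------

@dataclass
class TreeSpec:
    """Self-similar bifurcating tube tree.

    ``generations=0`` is a single (root) tube. Each generation halves into two
    children whose radii and lengths shrink by ``decay`` and whose directions
    tilt by ``half_angle_deg`` from the parent, in branch planes that rotate
    90 degrees per generation to keep the tree three-dimensional.
    """

    generations: int = 2
    root_radius_mm: float = 4.0
    decay: float = 0.8
    root_length_mm: float = 24.0
    half_angle_deg: float = 35.0
    resolution: int = 12
    open_ends: bool = False

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.root_radius_mm <= 0 or self.decay <= 0:
            raise ValueError("radii must stay strictly positive")
        if self.resolution < 6:
            raise ValueError("circumferential resolution must be >= 6")


@dataclass
class _Segment:
    p0: np.ndarray
    p1: np.ndarray
    radius: float
    gen: int
    parent: int  # segment index, -1 for root


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * (axis @ v) * (1.0 - np.cos(angle))
    )


def _build_segments(spec: TreeSpec) -> list[_Segment]:
    segs: list[_Segment] = []
    root_dir = np.array([0.0, 0.0, 1.0])
    segs.append(
        _Segment(np.zeros(3), root_dir * spec.root_length_mm, spec.root_radius_mm, 0, -1)
    )
    frontier = [0]
    theta = np.deg2rad(spec.half_angle_deg)
    for gen in range(1, spec.generations + 1):
        nxt = []
        r = spec.root_radius_mm * spec.decay**gen
        length = spec.root_length_mm * spec.decay**gen
        ref = np.array([1.0, 0.0, 0.0]) if gen % 2 == 1 else np.array([0.0, 1.0, 0.0])
        for si in frontier:
            parent = segs[si]
            d = parent.p1 - parent.p0
            d = d / np.linalg.norm(d)
            axis = np.cross(d, ref)
            if np.linalg.norm(axis) < 1e-9:
                axis = np.cross(d, np.array([0.0, 0.0, 1.0]))
            for sign in (+1.0, -1.0):
                cd = _rotate(d, axis, sign * theta)
                seg = _Segment(parent.p1.copy(), parent.p1 + cd * length, r, gen, si)
                segs.append(seg)
                nxt.append(len(segs) - 1)
        frontier = nxt
    return segs


def _segment_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 3D segments."""
    d1 = a1 - a0
    d2 = b1 - b0
    r = a0 - b0
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    c = d1 @ r
    b = d1 @ d2
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0, 1) if denom > 1e-12 else 0.0
    t = (b * s + f) / e if e > 1e-12 else 0.0
    if t < 0:
        t = 0.0
        s = np.clip(-c / a, 0, 1) if a > 1e-12 else 0.0
    elif t > 1:
        t = 1.0
        s = np.clip((b - c) / a, 0, 1) if a > 1e-12 else 0.0
    pa = a0 + s * d1
    pb = b0 + t * d2
    return float(np.linalg.norm(pa - pb))


def _check_collisions(segs: list[_Segment]) -> None:
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            si, sj = segs[i], segs[j]
            # adjacent segments legitimately touch at shared junctions
            if sj.parent == i or si.parent == j or si.parent == sj.parent:
                continue
            if _segment_distance(si.p0, si.p1, sj.p0, sj.p1) < si.radius + sj.radius:
                raise ValueError(
                    "tree parameterization self-intersects: "
                    f"segments {i} and {j} collide; widen half-angle or lengths"
                )


def _capsule_union_distance(segs, X, Y, Z):
    dist = np.full(X.shape, np.inf)
    for s in segs:
        a, b = s.p0, s.p1
        d = b - a
        L2 = d @ d
        px, py, pz = X - a[0], Y - a[1], Z - a[2]
        t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / L2, 0.0, 1.0)
        dx = px - t * d[0]
        dy = py - t * d[1]
        dz = pz - t * d[2]
        dist = np.minimum(dist, np.sqrt(dx * dx + dy * dy + dz * dz) - s.radius)
    return dist


def _ground_truth_network(spec: TreeSpec, segs: list[_Segment]) -> CenterlineNetwork:
    points: list[np.ndarray] = []
    radii: list[float] = []
    branch: list[int] = []
    g = nx.Graph()
    junction_index: dict[int, int] = {}  # segment index -> node index at its p1

    def add_point(p, r, bid):
        points.append(np.asarray(p, float))
        radii.append(r)
        branch.append(bid)
        g.add_node(len(points) - 1)
        return len(points) - 1

    for si, s in enumerate(segs):
        length = np.linalg.norm(s.p1 - s.p0)
        n_samp = max(2, int(np.ceil(length / 1.0)) + 1)
        ts = np.linspace(0.0, 1.0, n_samp)
        if s.parent < 0:
            prev = add_point(s.p0, s.radius, si)
        else:
            prev = junction_index[s.parent]
        for t in ts[1:]:
            idx = add_point(s.p0 + t * (s.p1 - s.p0), s.radius, si)
            g.add_edge(prev, idx)
            prev = idx
        junction_index[si] = prev

    net = CenterlineNetwork(np.vstack(points), np.array(radii), g, np.array(branch))
    # inlet: largest-radius endpoint = the root opening
    eps = net.endpoints
    net.inlet = int(eps[np.argmax(net.radii[eps])])
    return net


def make_tube_tree(spec: TreeSpec, pitch: float | None = None):
    """Build a tube-tree surface mesh and its ground-truth centerline.

    The solid is the union of capsules around the construction skeleton,
    surfaced with marching cubes — a single watertight genus-0 manifold. With
    ``open_ends`` the root and every terminal are clipped by a plane at the
    skeleton endpoint, leaving ``2**generations + 1`` boundary loops.
    """
    segs = _build_segments(spec)
    _check_collisions(segs)

    min_r = min(s.radius for s in segs)
    if pitch is None:
        pitch = min_r / 2.5
    pts = np.array([s.p0 for s in segs] + [s.p1 for s in segs])
    max_r = max(s.radius for s in segs)
    lo = pts.min(axis=0) - (max_r + 3 * pitch)
    hi = pts.max(axis=0) + (max_r + 3 * pitch)
    shape = np.ceil((hi - lo) / pitch).astype(int) + 1
    if np.prod(shape) > 320**3:
        raise ValueError("tree too large for the default pitch; pass a coarser pitch")
    ax = [lo[i] + np.arange(shape[i]) * pitch for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    dist = _capsule_union_distance(segs, X, Y, Z)

    verts, faces, _, _ = measure.marching_cubes(dist, level=0.0, spacing=(pitch,) * 3)
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()

    if spec.open_ends:
        root = segs[0]
        rd = (root.p1 - root.p0) / np.linalg.norm(root.p1 - root.p0)
        cuts = [(root.p0, -rd, root.radius)]
        children = {s.parent for s in segs}
        for si, s in enumerate(segs):
            if si not in children:  # terminal
                d = (s.p1 - s.p0) / np.linalg.norm(s.p1 - s.p0)
                cuts.append((s.p1, d, s.radius))
        for origin, normal, r in cuts:
            centroids = mesh.triangles_center
            local = np.linalg.norm(centroids - origin, axis=1) < 2.2 * r
            mesh = clip_mesh_plane(mesh, origin, normal, face_mask=local)
        mesh = compact(mesh)

    net = _ground_truth_network(spec, segs)
    return mesh, net


# --------------------------------------------------------------------------
# defect injection
# --------------------------------------------------------------------------

def inject_defects(
    mesh: trimesh.Trimesh,
    holes: int = 0,
    fins: int = 0,
    flips: int = 0,
    duplicates: int = 0,
    seed: int = 0,
):
    """Damage a clean watertight mesh in controlled ways.

    Returns the damaged mesh (``process=False``) and a manifest listing each
    injected defect with its kind, location, and size. Hole injection removes
    pairwise non-adjacent faces; fin injection adds a face hanging off an
    interior edge (incidence 3); flip injection reverses face winding;
    duplicate injection splits a shared vertex into two copies a sub-merge-
    tolerance distance apart.
    """
    rng = np.random.default_rng(seed)
    V = np.asarray(mesh.vertices, float).copy()
    F = np.asarray(mesh.faces, np.int64).copy()
    manifest: list[dict] = []

    n_faces = len(F)
    if holes + fins + flips > n_faces:
        raise ValueError("requested defect count exceeds available faces")

    # --- flipped faces (chosen first, from faces that will survive) ---------
    removed: set[int] = set()

    # --- holes: remove pairwise non-adjacent faces --------------------------
    hole_faces: list[int] = []
    used_verts: set[int] = set()
    order = rng.permutation(n_faces)
    for fi in order:
        if len(hole_faces) == holes:
            break
        vs = set(F[fi])
        if vs & used_verts:
            continue
        hole_faces.append(int(fi))
        used_verts |= vs
    if len(hole_faces) < holes:
        raise ValueError("not enough non-adjacent faces for the requested holes")
    removed |= set(hole_faces)
    for fi in hole_faces:
        manifest.append(
            {"kind": "hole", "location": V[F[fi]].mean(axis=0).tolist(), "size": 3}
        )

    survivors = [i for i in range(n_faces) if i not in removed]

    # --- flips ---------------------------------------------------------------
    flip_faces = [int(i) for i in rng.choice(survivors, size=flips, replace=False)] if flips else []
    for fi in flip_faces:
        F[fi] = F[fi][::-1]
        manifest.append(
            {"kind": "flipped_face", "location": V[F[fi]].mean(axis=0).tolist(), "size": 1}
        )

    # --- fins: new face hanging off an existing interior edge ---------------
    fin_faces: list[np.ndarray] = []
    if fins:
        # interior edges of surviving faces, not touching hole rims
        edges = {}
        for fi in survivors:
            a, b, c = F[fi]
            for u, v in ((a, b), (b, c), (c, a)):
                key = (u, v) if u < v else (v, u)
                edges.setdefault(key, 0)
                edges[key] += 1
        interior = [e for e, cnt in edges.items() if cnt == 2 and not (set(e) & used_verts)]
        if len(interior) < fins:
            raise ValueError("not enough interior edges for the requested fins")
        picks = rng.choice(len(interior), size=fins, replace=False)
        for k in picks:
            u, v = interior[int(k)]
            mid = 0.5 * (V[u] + V[v])
            edge_len = np.linalg.norm(V[u] - V[v])
            # offset roughly along the local surface normal
            normal = V[u] - V.mean(axis=0)
            normal = normal / (np.linalg.norm(normal) + 1e-12)
            new_v = mid + normal * 0.5 * edge_len
            V = np.vstack([V, new_v])
            fin_faces.append(np.array([u, v, len(V) - 1], dtype=np.int64))
            manifest.append({"kind": "nonmanifold_fin", "location": mid.tolist(), "size": float(edge_len)})

    # --- duplicates: split shared vertices by a tiny offset ------------------
    if duplicates:
        vert_faces: dict[int, list[int]] = {}
        for fi in survivors:
            for vv in F[fi]:
                vert_faces.setdefault(int(vv), []).append(fi)
        candidates = [v for v, fl in vert_faces.items() if len(fl) >= 4 and v not in used_verts]
        if len(candidates) < duplicates:
            raise ValueError("not enough shared vertices for the requested duplicates")
        picks = rng.choice(len(candidates), size=duplicates, replace=False)
        for k in picks:
            v = candidates[int(k)]
            offset = rng.normal(size=3)
            offset = offset / np.linalg.norm(offset) * 1e-6  # mm, below merge eps
            V = np.vstack([V, V[v] + offset])
            new_idx = len(V) - 1
            fl = vert_faces[v]
            for fi in fl[: len(fl) // 2]:
                F[fi][F[fi] == v] = new_idx
            manifest.append({"kind": "duplicate_vertices", "location": V[v].tolist(), "size": 1e-6})

    keep = np.array([i for i in range(n_faces) if i not in removed], dtype=np.int64)
    out_faces = F[keep]
    if fin_faces:
        out_faces = np.vstack([out_faces, np.array(fin_faces)])
    out = trimesh.Trimesh(vertices=V, faces=out_faces, process=False)
    return out, manifest


# --------------------------------------------------------------------------
# probability patches
# --------------------------------------------------------------------------

def make_probability_patches(
    mask: np.ndarray,
    patch_shape: tuple[int, int, int] = (128, 128, 64),
    overlap: tuple[int, int, int] = (0, 0, 0),
):
    """Tile a binary mask into probability patches plus a reassembly layout.

    Patches are placed on a regular grid with the given voxel overlap; the
    final patch along each axis is shifted back so the tiling always covers
    the full volume. Patch values are the mask cast to float (probability
    1 inside, 0 outside), matching what a converged patch-wise classifier
    would emit.
    """
    mask = np.asarray(mask)
    shape = mask.shape
    patch_shape = tuple(int(p) for p in patch_shape)
    overlap = tuple(int(o) for o in overlap)
    if any(p > s for p, s in zip(patch_shape, shape)):
        raise ValueError("patch shape exceeds volume shape")
    if any(o >= p for o, p in zip(overlap, patch_shape)):
        raise ValueError("overlap must be smaller than the patch size")

    starts_per_axis = []
    for s, p, o in zip(shape, patch_shape, overlap):
        step = p - o
        starts = list(range(0, max(s - p, 0) + 1, step))
        if starts[-1] + p < s:
            starts.append(s - p)
        starts_per_axis.append(starts)

    patches: list[np.ndarray] = []
    offsets: list[tuple[int, int, int]] = []
    for i in starts_per_axis[0]:
        for j in starts_per_axis[1]:
            for k in starts_per_axis[2]:
                sl = (slice(i, i + patch_shape[0]), slice(j, j + patch_shape[1]), slice(k, k + patch_shape[2]))
                patches.append(mask[sl].astype(np.float64))
                offsets.append((i, j, k))

    layout = {"shape": list(shape), "patch_shape": list(patch_shape), "offsets": [list(o) for o in offsets]}
    return patches, layout
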
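"""Automated inlet/outlet capping of open airway endpoints.

Every centerline endpoint is capped by subtracting a thin oriented prism from
the geometry: the prism's face normal follows the local centerline tangent,
its footprint covers the airway cross-section completely, and the subtraction
separates the geometry into bodies of which the largest (by enclosed volume)
is retained. The planar cut loop is triangulated and labeled as a cap patch;
after all endpoints are processed the cap with the largest area becomes the
inlet, the rest are outlets.

Because the prism fully transects the lumen, the subtraction is computed as a
local plane clip at the prism's inner face restricted to the endpoint's
above-plane connected face region, which is exact for this configuration and
keeps the rest of the geometry untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from ._clip import clip_mesh_plane
from .meshrepair import fix_winding, is_strictly_watertight
from .network import CenterlineNetwork


@dataclass
class CapSpec:
    """One endpoint cap: position, outward normal, footprint radius, thickness."""

    endpoint: np.ndarray  # p_b, mm
    normal: np.ndarray  # unit outward tangent n_b
    radius: float  # r_b: hexagon circumradius, must cover the cross-section
    thickness: float = 0.3  # t, mm

    def __post_init__(self) -> None:
        self.endpoint = np.asarray(self.endpoint, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-8:
            raise ValueError("cap normal must be a unit vector")
        if self.radius <= 0:
            raise ValueError("cap radius must be positive")
        if not (0.05 <= self.thickness <= 1.0):
            raise ValueError("cap thickness outside the sensible range (mm)")


@dataclass
class CappedGeometry:
    """Watertight surface with per-face patch labels.

    Label 0 is the wall; labels 1..n are caps. ``patches`` tabulates label,
    kind (inlet/outlet/wall), area (mm^2), and centroid.
    """

    mesh: trimesh.Trimesh
    face_labels: np.ndarray
    patches: list[dict] = field(default_factory=list)

    @property
    def inlet_label(self) -> int:
        for p in self.patches:
            if p["kind"] == "inlet":
                return p["label"]
        raise ValueError("no inlet patch")

    def patch_mesh(self, label: int) -> trimesh.Trimesh:
        keep = self.face_labels == label
        return trimesh.Trimesh(
            vertices=self.mesh.vertices, faces=self.mesh.faces[keep], process=False
        )


def endpoint_tangent(net: CenterlineNetwork, endpoint: int, lookback_mm: float | None = None) -> np.ndarray:
    """Outward unit tangent n_b = (p_b - p_next) / |p_b - p_next|.

    ``p_next`` is the neighboring centerline point at least ``lookback_mm``
    away along the branch (default: the local inscribed radius), which keeps
    the tangent stable against point-level jitter in traced centerlines;
    coincident points are skipped.
    """
    p_b = net.points[endpoint]
    if lookback_mm is None:
        lookback_mm = max(1.0, float(net.radii[endpoint]))
    nxt = endpoint
    prev = None
    best = None
    while True:
        nbrs = [n for n in net.graph.neighbors(nxt) if n != prev]
        if not nbrs:
            break
        prev, nxt = nxt, nbrs[0]
        d = p_b - net.points[nxt]
        norm = np.linalg.norm(d)
        if norm > 1e-12:
            best = d / norm
        if norm >= lookback_mm or net.graph.degree(nxt) > 2:
            break
    if best is None:
        raise ValueError("endpoint has no distinct neighbor")
    return best


def _local_lumen_radius(net: CenterlineNetwork, endpoint: int) -> float:
    """Largest inscribed radius within a few radii of the endpoint.

    The inscribed radius exactly at an endpoint is attenuated by the nearby
    end wall (the sphere is limited axially, not radially), so the cap
    footprint is sized from the local branch maximum instead.
    """
    r0 = float(net.radii[endpoint])
    budget = 3.0 * r0
    best = r0
    prev, cur = None, endpoint
    walked = 0.0
    while walked < budget:
        nbrs = [n for n in net.graph.neighbors(cur) if n != prev]
        if not nbrs:
            break
        prev, cur = cur, nbrs[0]
        walked += float(np.linalg.norm(net.points[cur] - net.points[prev]))
        best = max(best, float(net.radii[cur]))
        if net.graph.degree(cur) > 2:
            break
    return best


def rodrigues_rotation(n_b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking the +z axis onto ``n_b``.

    R = I + sin(theta) K + (1 - cos(theta)) K^2 with rotation axis
    a = z x n_b and theta = arccos(n_b . z). The antiparallel case rotates by
    pi about x; the parallel case is the identity (the formula is singular at
    both poles).
    """
    n_b = np.asarray(n_b, dtype=float)
    if abs(np.linalg.norm(n_b) - 1.0) > 1e-8:
        raise ValueError("n_b must be a unit vector")
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(n_b @ z, -1.0, 1.0))
    a = np.cross(z, n_b)
    s = np.linalg.norm(a)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate by pi about x
        return np.diag([1.0, -1.0, -1.0])
    a = a / s
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    theta = np.arccos(c)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def make_cap(spec: CapSpec) -> trimesh.Trimesh:
    """Closed hexagonal prism solid: 12 vertices, oriented along ``normal``.

    The prism is centered at the endpoint with its axis along the cap normal;
    its volume is ``(3*sqrt(3)/2) * r^2 * t`` (hexagon area with circumradius
    r times thickness t).
    """
    r, t = spec.radius, spec.thickness
    ang = np.arange(6) * np.pi / 3.0
    hexagon = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    bottom = np.column_stack([hexagon, np.full(6, -t / 2.0)])
    top = np.column_stack([hexagon, np.full(6, +t / 2.0)])
    verts = np.vstack([bottom, top])

    faces = []
    # bottom fan (normal -z) and top fan (normal +z)
    for i in range(1, 5):
        faces.append([0, i + 1, i])
        faces.append([6, 6 + i, 6 + i + 1])
    # sides
    for i in range(6):
        j = (i + 1) % 6
        faces.append([i, j, 6 + i])
        faces.append([j, 6 + j, 6 + i])

    R = rodrigues_rotation(spec.normal)
    verts = verts @ R.T + spec.endpoint
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _flood_above_plane(mesh: trimesh.Trimesh, h: np.ndarray, seed_face: int) -> np.ndarray:
    """Faces connected to ``seed_face`` while having any vertex above the plane."""
    F = np.asarray(mesh.faces)
    touch = (h[F] > 0).any(axis=1)
    adjacency: dict[tuple[int, int], list[int]] = {}
    for fi in np.nonzero(touch)[0]:
        a, b, c = F[fi]
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            adjacency.setdefault(key, []).append(fi)
    region = np.zeros(len(F), dtype=bool)
    stack = [seed_face]
    region[seed_face] = True
    while stack:
        fi = stack.pop()
        a, b, c = F[fi]
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            for fj in adjacency.get(key, []):
                if not region[fj]:
                    region[fj] = True
                    stack.append(fj)
    return region


def _planar_loops(mesh: trimesh.Trimesh, origin, normal, tol: float):
    """Boundary loops of the mesh whose vertices all lie on the given plane."""
    from .meshrepair import boundary_loops

    V = np.asarray(mesh.vertices)
    loops = boundary_loops(mesh)
    out = []
    for loop in loops:
        d = np.abs((V[loop] - origin) @ normal)
        if np.all(d < tol):
            out.append(loop)
    return out


def _fan_cap(loop: list[int], V: np.ndarray, outward: np.ndarray):
    """Triangulate a planar loop with a centroid fan, oriented along outward."""
    centroid = V[loop].mean(axis=0)
    new_vi = len(V)
    V = np.vstack([V, centroid])
    faces = []
    n = len(loop)
    # loop orientation: make the fan normal point along `outward`
    area_vec = np.zeros(3)
    for i in range(n):
        a, b = V[loop[i]], V[loop[(i + 1) % n]]
        area_vec += np.cross(a - centroid, b - centroid)
    order = loop if area_vec @ outward > 0 else loop[::-1]
    for i in range(n):
        faces.append([order[i], order[(i + 1) % n], new_vi])
    return V, np.asarray(faces, dtype=np.int64)


def cap_endpoint(
    mesh: trimesh.Trimesh,
    spec: CapSpec,
    face_labels: np.ndarray | None = None,
    cap_label: int = 1,
):
    """Subtract one cap prism and retain the largest resulting body.

    Returns ``(mesh, face_labels)`` where the new planar cap faces carry
    ``cap_label`` and surviving faces keep their previous labels. Raises if
    the prism does not transect the lumen or does not cover the full
    cross-section.
    """
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces, dtype=np.int64)
    if face_labels is None:
        face_labels = np.zeros(len(F), dtype=np.int64)

    n_b = spec.normal
    p_cut = spec.endpoint - spec.thickness * n_b  # inner prism face
    h = (V - p_cut) @ n_b

    # seed: nearest face to the endpoint with a vertex above the cut plane
    tol = 1e-9 * (1.0 + float(np.abs(V).max()))
    touch = (h[F] > tol).any(axis=1)
    if not touch.any():
        if h.max() >= -spec.thickness - tol:
            # already planar at (or within a thickness of) the cut plane:
            # repeating the cap is a no-op
            return (
                trimesh.Trimesh(vertices=V, faces=F, process=False),
                face_labels.copy(),
            )
        raise ValueError("cap prism does not transect the geometry at this endpoint")
    centroids = V[F].mean(axis=1)
    cand = np.nonzero(touch)[0]
    seed = int(cand[np.argmin(np.linalg.norm(centroids[cand] - spec.endpoint, axis=1))])
    region = _flood_above_plane(mesh, h, seed)

    # local subtraction: clip the above-plane region at the inner prism face
    clipped, face_src = clip_mesh_plane(mesh, p_cut, n_b, face_mask=region, return_face_map=True)
    labels = face_labels[face_src]

    tol = 1e-6 + 1e-9 * float(np.abs(V).max())
    loops = _planar_loops(clipped, p_cut, n_b, tol)
    if not loops:
        raise ValueError("cap produced no planar cut loop (no transection)")

    # footprint check: the prism must cover the whole cross-section
    CV = np.asarray(clipped.vertices)
    for loop in loops:
        rel = CV[loop] - p_cut
        radial = np.linalg.norm(rel - np.outer(rel @ n_b, n_b), axis=1)
        if radial.max() > spec.radius + 1e-9:
            raise ValueError(
                f"cap radius {spec.radius:.3f} mm does not cover the cross-section "
                f"(loop radius {radial.max():.3f} mm); increase the radius scale"
            )

    newV = CV
    newF = np.asarray(clipped.faces, dtype=np.int64)
    for loop in loops:
        newV, cap_faces = _fan_cap(list(loop), newV, n_b)
        newF = np.vstack([newF, cap_faces])
        labels = np.concatenate([labels, np.full(len(cap_faces), cap_label, dtype=np.int64)])

    capped = trimesh.Trimesh(vertices=newV, faces=newF, process=False)

    # split into bodies and keep the largest by |enclosed volume|
    comps = trimesh.graph.connected_components(capped.face_adjacency, min_len=1, nodes=np.arange(len(newF)))
    if len(comps) > 1:
        best, best_vol, best_len, best_cz = None, -np.inf, -1, np.inf
        for comp in comps:
            sub = trimesh.Trimesh(vertices=newV, faces=newF[comp], process=False)
            vol = abs(sub.volume)
            cz = sub.triangles_center[:, 2].mean()
            key = (vol, len(comp), -cz)
            if key > (best_vol, best_len, -best_cz):
                best, best_vol, best_len, best_cz = comp, vol, len(comp), cz
        keep = np.zeros(len(newF), dtype=bool)
        keep[best] = True
        capped = trimesh.Trimesh(vertices=newV, faces=newF[keep], process=False)
        labels = labels[keep]
    return capped, labels


def cap_all(
    mesh: trimesh.Trimesh,
    net: CenterlineNetwork,
    radius_scale: float = 1.5,
    thickness: float = 0.3,
) -> CappedGeometry:
    """Cap every centerline endpoint and label patches; inlet by largest area.

    The cap footprint radius is ``radius_scale`` times the local maximal
    inscribed radius at the endpoint. All caps applied, winding made globally
    consistent, and the result must be watertight.
    """
    current = trimesh.Trimesh(
        vertices=np.asarray(mesh.vertices, float),
        faces=np.asarray(mesh.faces, np.int64),
        process=False,
    )
    labels = np.zeros(len(current.faces), dtype=np.int64)
    endpoints = net.endpoints
    for k, ep in enumerate(endpoints, start=1):
        n_b = endpoint_tangent(net, int(ep))
        # footprint: scaled local lumen radius plus a discretization allowance
        # for networks traced on a voxel grid (radii are pitch-accurate only)
        spec = CapSpec(
            endpoint=net.points[ep],
            normal=n_b,
            radius=radius_scale * _local_lumen_radius(net, int(ep)) + 2.0 * net.pitch,
            thickness=thickness,
        )
        try:
            current, labels = cap_endpoint(current, spec, labels, cap_label=k)
        except ValueError as err:
            raise ValueError(f"capping failed at endpoint {ep}: {err}") from err

    current, _ = fix_winding(current)
    if not is_strictly_watertight(current):
        warnings.warn("capped geometry is not strictly watertight")

    # patch table
    V = np.asarray(current.vertices)
    F = np.asarray(current.faces)
    tri_area = 0.5 * np.linalg.norm(
        np.cross(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]]), axis=1
    )
    patches = []
    cap_areas = {}
    for lab in range(1, len(endpoints) + 1):
        sel = labels == lab
        if not sel.any():
            continue
        area = float(tri_area[sel].sum())
        centroid = (V[F[sel]].mean(axis=1) * tri_area[sel, None]).sum(axis=0) / area
        cap_areas[lab] = area
        patches.append({"label": int(lab), "kind": "outlet", "area_mm2": area, "centroid": centroid.tolist()})
    if not cap_areas:
        raise ValueError("no cap patches were created")
    inlet_lab = max(cap_areas, key=cap_areas.get)
    for p in patches:
        if p["label"] == inlet_lab:
            p["kind"] = "inlet"
    wall_sel = labels == 0
    patches.insert(
        0,
        {
            "label": 0,
            "kind": "wall",
            "area_mm2": float(tri_area[wall_sel].sum()),
            "centroid": (V[F[wall_sel]].mean(axis=1) * tri_area[wall_sel, None]).sum(axis=0)
            .__truediv__(max(tri_area[wall_sel].sum(), 1e-12))
            .tolist(),
        },
    )
    return CappedGeometry(mesh=current, face_labels=labels, patches=patches)
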
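"""Exact triangle/plane clipping used by the fixture generator and capping.

Keeps the half-space ``(x - origin) . normal < 0``, splitting straddling
triangles along the plane so the resulting boundary is a clean polyline lying
exactly on the plane. An optional face mask restricts the clip to a local
region, leaving all other faces untouched (needed when the plane would also
graze distant parts of the geometry).
"""

from __future__ import annotations

import numpy as np
import trimesh


def clip_mesh_plane(
    mesh: trimesh.Trimesh,
    origin: np.ndarray,
    normal: np.ndarray,
    face_mask: np.ndarray | None = None,
    return_face_map: bool = False,
):
    """Clip ``mesh`` against a plane, keeping the negative side.

    Parameters
    ----------
    mesh : trimesh.Trimesh
    origin, normal : (3,) arrays
        Plane point and (not necessarily unit) normal. Material with
        ``(x - origin) . normal > 0`` is removed.
    face_mask : (n_faces,) bool, optional
        If given, only faces with ``face_mask[i]`` are candidates for removal
        or splitting; all other faces are kept verbatim.

    Returns
    -------
    trimesh.Trimesh (process=False) with unreferenced vertices retained;
    callers typically run a vertex-compaction afterwards.
    """
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces, dtype=np.int64)
    if face_mask is None:
        face_mask = np.ones(len(F), dtype=bool)

    h = (V - origin) @ normal
    pos = h > 0.0

    new_vertices: list[np.ndarray] = [V]
    extra: list[np.ndarray] = []
    cut_cache: dict[tuple[int, int], int] = {}
    next_idx = len(V)

    def cut_point(a: int, b: int) -> int:
        nonlocal next_idx
        key = (a, b) if a < b else (b, a)
        if key in cut_cache:
            return cut_cache[key]
        t = h[a] / (h[a] - h[b])
        p = V[a] + t * (V[b] - V[a])
        extra.append(p)
        cut_cache[key] = next_idx
        next_idx += 1
        return cut_cache[key]

    kept_faces: list[tuple[int, int, int]] = []
    face_src: list[int] = []

    def emit(face, fi):
        kept_faces.append(face)
        face_src.append(fi)

    for fi, (a, b, c) in enumerate(F):
        if not face_mask[fi]:
            emit((a, b, c), fi)
            continue
        pa, pb, pc = pos[a], pos[b], pos[c]
        n_pos = int(pa) + int(pb) + int(pc)
        if n_pos == 0:
            emit((a, b, c), fi)
        elif n_pos == 3:
            continue
        elif n_pos == 1:
            # rotate so the positive vertex is last: (u, v, w) with w positive
            if pa:
                u, v, w = b, c, a
            elif pb:
                u, v, w = c, a, b
            else:
                u, v, w = a, b, c
            p1 = cut_point(v, w)
            p2 = cut_point(w, u)
            emit((u, v, p1), fi)
            emit((u, p1, p2), fi)
        else:  # two positive: rotate so the negative vertex is first
            if not pa:
                u, v, w = a, b, c
            elif not pb:
                u, v, w = b, c, a
            else:
                u, v, w = c, a, b
            p1 = cut_point(u, v)
            p2 = cut_point(w, u)
            emit((u, p1, p2), fi)

    if extra:
        new_vertices.append(np.vstack(extra))
    verts = np.vstack(new_vertices)
    faces = np.asarray(kept_faces, dtype=np.int64).reshape(-1, 3)
    out = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if return_face_map:
        return out, np.asarray(face_src, dtype=np.int64)
    return out


def compact(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Drop unreferenced vertices and reindex faces (no vertex merging)."""
    V = np.asarray(mesh.vertices)
    F = np.asarray(mesh.faces)
    used = np.unique(F)
    remap = -np.ones(len(V), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return trimesh.Trimesh(vertices=V[used], faces=remap[F], process=False)
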
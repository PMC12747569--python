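"""Medial-axis centerline extraction from watertight airway surfaces.

The medial axis is realized volumetrically: the watertight mesh is voxelized
and flood-filled, the Euclidean distance transform of the interior gives the
maximal-inscribed-sphere radius at every interior voxel, and centerlines are
least-cost paths under the metric ``ds / r(s)`` — wide lumens are cheap, so
paths hug the medial axis. Arrival times solve the Eikonal equation
``|grad T| = 1/r`` by a first-order upwind fast-marching sweep, and each
centerline is recovered by steepest descent on T from an endpoint back to the
source. Endpoints are degree-1 nodes of the skeletonized interior; the inlet
is the endpoint with the largest inscribed radius.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import networkx as nx
import numpy as np
import trimesh
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from scipy.spatial import cKDTree

from .network import CenterlineNetwork

_NEIGH26 = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


@dataclass
class RadiusField:
    """Interior voxelization with per-voxel inscribed-sphere radii (mm)."""

    radius: np.ndarray  # (nx, ny, nz) float, 0 outside
    mask: np.ndarray  # interior voxels
    origin: np.ndarray  # world position of voxel (0,0,0) center, mm
    pitch: float

    def world_to_index(self, p) -> tuple[int, int, int]:
        idx = np.round((np.asarray(p, float) - self.origin) / self.pitch).astype(int)
        return tuple(np.clip(idx, 0, np.array(self.mask.shape) - 1))

    def index_to_world(self, idx) -> np.ndarray:
        return np.asarray(idx, float) * self.pitch + self.origin


@dataclass
class ArrivalField:
    """Fast-marching arrival times over an interior voxelization."""

    T: np.ndarray  # inf outside the reachable interior
    field: RadiusField
    source_index: tuple[int, int, int]


def interior_radius_field(mesh: trimesh.Trimesh, pitch: float) -> RadiusField:
    """Voxelize the mesh interior and compute inscribed-sphere radii.

    The radius at an interior voxel is its Euclidean distance to the nearest
    exterior voxel (the distance-transform realization of the maximal
    inscribed sphere). Raises when the lumen is unresolved (under two voxels
    of clearance anywhere the skeleton would run).
    """
    vg = mesh.voxelized(pitch)
    surface = np.asarray(vg.matrix, dtype=bool).copy()
    filled = np.asarray(vg.fill().matrix, dtype=bool)
    origin = np.asarray(vg.transform[:3, 3], dtype=float)
    # strictly interior voxels only: surface-touching voxels would dilate the
    # lumen by a voxel and flatten the medial radius ridge at coarse pitch
    mask = filled & ~surface
    if not mask.any():
        raise ValueError(
            f"voxel pitch {pitch} too coarse for this lumen; use a finer pitch"
        )
    # EDT measures distance to the nearest non-interior voxel center, which
    # sits about half a voxel inside the true surface
    radius = ndimage.distance_transform_edt(mask, sampling=pitch)
    radius = np.where(mask, radius + 0.5 * pitch, 0.0)
    if radius.max() < 2.0 * pitch:
        raise ValueError(
            f"voxel pitch {pitch} too coarse for this lumen; use a finer pitch"
        )
    return RadiusField(radius=radius, mask=mask, origin=origin, pitch=float(pitch))


def solve_eikonal(field: RadiusField, source) -> ArrivalField:
    """First-order upwind fast marching for ``|grad T| = 1/r`` on the interior.

    ``source`` is a world-coordinate point (or voxel index triple) inside the
    interior mask. Disconnected interior regions keep ``T = inf``.
    """
    mask = field.mask
    r = field.radius
    h = field.pitch
    if isinstance(source, tuple) and len(source) == 3 and all(isinstance(v, (int, np.integer)) for v in source):
        src = source
    else:
        src = field.world_to_index(source)
    if not mask[src]:
        raise ValueError("source point is not inside the interior mask")

    T = np.full(mask.shape, np.inf)
    done = np.zeros(mask.shape, dtype=bool)
    shape = mask.shape

    # analytic near-source initialization: the first-order upwind stencil is
    # worst right behind the source, so seed a 5x5x5 ball with exact values
    heap = []
    si, sj, sk = src
    for di in range(-2, 3):
        for dj in range(-2, 3):
            for dk in range(-2, 3):
                i, j, k = si + di, sj + dj, sk + dk
                if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
                    continue
                if not mask[i, j, k]:
                    continue
                dist = h * np.sqrt(di * di + dj * dj + dk * dk)
                t0 = dist * 2.0 / (r[i, j, k] + r[src])
                T[i, j, k] = t0
                heap.append((t0, (i, j, k)))
    heapq.heapify(heap)
    offsets = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))

    def update(i, j, k):
        """Solve the upwind quadratic for T[i,j,k] given accepted neighbors.

        Uses a second-order one-sided difference per axis whenever two
        upwind accepted neighbors are available (falling back to first
        order), which keeps the diagonal-direction error well below the
        grid-graph metrication scale.
        """
        terms = []  # (alpha, a): contribution alpha^2 (T - a)^2
        p = (i, j, k)
        for axis in range(3):
            best = None
            for d in (-1, 1):
                q = list(p)
                q[axis] += d
                q = tuple(q)
                if not (0 <= q[axis] < shape[axis]) or not done[q]:
                    continue
                t1 = T[q]
                q2 = list(p)
                q2[axis] += 2 * d
                q2 = tuple(q2)
                if 0 <= q2[axis] < shape[axis] and done[q2] and T[q2] <= t1:
                    cand = (1.5 / h, (4.0 * t1 - T[q2]) / 3.0, t1)
                else:
                    cand = (1.0 / h, t1, t1)
                if best is None or cand[2] < best[2]:
                    best = cand
            if best is not None:
                terms.append(best)
        if not terms:
            return np.inf
        inv_r2 = 1.0 / (r[i, j, k] * r[i, j, k])
        # include axes in causal order, dropping any whose upwind value
        # exceeds the solution
        terms.sort(key=lambda x: x[2])
        for n_use in range(len(terms), 0, -1):
            use = terms[:n_use]
            A = sum(al * al for al, _, _ in use)
            B = sum(al * al * a for al, a, _ in use)
            C = sum(al * al * a * a for al, a, _ in use) - inv_r2
            disc = B * B - A * C
            if disc < 0:
                continue
            t = (B + np.sqrt(disc)) / A
            if t + 1e-12 >= use[-1][2]:
                return t
        return terms[0][2] + h / r[i, j, k]

    while heap:
        t, (i, j, k) = heapq.heappop(heap)
        if done[i, j, k]:
            continue
        done[i, j, k] = True
        for di, dj, dk in offsets:
            ii, jj, kk = i + di, j + dj, k + dk
            if not (0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]):
                continue
            if not mask[ii, jj, kk] or done[ii, jj, kk]:
                continue
            t_new = update(ii, jj, kk)
            if t_new < T[ii, jj, kk]:
                T[ii, jj, kk] = t_new
                heapq.heappush(heap, (t_new, (ii, jj, kk)))

    return ArrivalField(T=T, field=field, source_index=src)


def _interp(T_filled: np.ndarray, pos: np.ndarray) -> float:
    """Trilinear interpolation at a fractional voxel index."""
    p0 = np.floor(pos).astype(int)
    p0 = np.clip(p0, 0, np.array(T_filled.shape) - 2)
    f = pos - p0
    val = 0.0
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = (
                    (f[0] if di else 1 - f[0])
                    * (f[1] if dj else 1 - f[1])
                    * (f[2] if dk else 1 - f[2])
                )
                val += w * T_filled[p0[0] + di, p0[1] + dj, p0[2] + dk]
    return float(val)


def backtrack_path(arrival: ArrivalField, target, step_factor: float = 0.5):
    """Steepest-descent path on T from target to source (world mm polyline).

    Follows ``dx/ds = -grad T`` with central-difference gradients and
    trilinear interpolation at half-pitch steps; on a plateau (no descent
    direction) it falls back to the lowest-T neighboring voxel. Returns
    ``(points, radii)`` ordered target -> source.
    """
    field = arrival.field
    T = arrival.T
    if isinstance(target, tuple) and len(target) == 3 and all(isinstance(v, (int, np.integer)) for v in target):
        tgt = target
    else:
        tgt = field.world_to_index(target)
    if not np.isfinite(T[tgt]):
        raise ValueError("target unreachable: infinite arrival time")

    finite = np.isfinite(T)
    big = T[finite].max() * 4.0 + 1.0
    Tf = np.where(finite, T, big)
    src = np.array(arrival.source_index, dtype=float)
    shape = np.array(T.shape)

    pos = np.array(tgt, dtype=float)
    path = [pos.copy()]
    step = step_factor  # in voxel units
    max_steps = int(20 * np.sum(shape))
    for _ in range(max_steps):
        if np.linalg.norm(pos - src) <= 1.0:
            break
        p = np.clip(pos, 1, shape - 2)
        grad = np.zeros(3)
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = 1.0
            grad[ax] = (_interp(Tf, p + e) - _interp(Tf, p - e)) / 2.0
        norm = np.linalg.norm(grad)
        moved = False
        if norm > 1e-12:
            cand = pos - step * grad / norm
            cand = np.clip(cand, 0, shape - 1)
            if _interp(Tf, cand) < _interp(Tf, np.clip(pos, 0, shape - 1)) - 1e-12:
                pos = cand
                moved = True
        if not moved:
            # plateau: hop to the lowest-T neighboring voxel
            vi = np.round(pos).astype(int)
            best_t = Tf[tuple(np.clip(vi, 0, shape - 1))]
            best = None
            for d in _NEIGH26:
                nb = vi + d
                if np.any(nb < 0) or np.any(nb >= shape):
                    continue
                if Tf[tuple(nb)] < best_t:
                    best_t = Tf[tuple(nb)]
                    best = nb
            if best is None:
                raise RuntimeError("descent stalled: no lower-T neighbor")
            pos = best.astype(float)
        path.append(pos.copy())
    path.append(src.copy())

    pts_idx = np.array(path)
    points = pts_idx * field.pitch + field.origin
    radii = np.array([max(_interp(field.radius, np.clip(p, 0, shape - 1)), 1e-9) for p in pts_idx])
    return points, radii


# --------------------------------------------------------------------------
# network construction
# --------------------------------------------------------------------------

def _interior_graph(field: RadiusField):
    """26-neighbor sparse graph over interior voxels; weights = step length."""
    mask = field.mask
    flat_ids = -np.ones(mask.size, dtype=np.int64)
    interior = np.flatnonzero(mask.ravel())
    flat_ids[interior] = np.arange(len(interior))
    shape = mask.shape
    rows, cols, ws = [], [], []
    idx3 = np.array(np.unravel_index(interior, shape)).T
    for d in _NEIGH26:
        nb = idx3 + d
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, shape)
        src = interior[ok]
        valid = flat_ids[nb_flat] >= 0
        rows.append(flat_ids[src[valid]])
        cols.append(flat_ids[nb_flat[valid]])
        ws.append(np.full(valid.sum(), np.linalg.norm(d) * field.pitch))
    g = sparse.csr_matrix(
        (np.concatenate(ws), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(interior), len(interior)),
    )
    return g, interior, idx3


def _hill_climb_radius(field: RadiusField, start: tuple[int, int, int]) -> tuple[int, int, int]:
    """Walk 26-neighbor steps up the radius field to a local maximum."""
    cur = np.asarray(start)
    shape = np.asarray(field.mask.shape)
    for _ in range(10000):
        best, best_r = None, field.radius[tuple(cur)]
        for d in _NEIGH26:
            nb = cur + d
            if np.any(nb < 0) or np.any(nb >= shape):
                continue
            if field.radius[tuple(nb)] > best_r:
                best_r = field.radius[tuple(nb)]
                best = nb
        if best is None:
            break
        cur = best
    return tuple(int(v) for v in cur)


def detect_endpoints(field: RadiusField, coverage_factor: float = 2.5) -> list[tuple[int, int, int]]:
    """Find one endpoint per lumen opening by farthest-point path growing.

    A path network is grown greedily over the interior voxel graph: each
    iteration takes the voxel geodesically farthest from the current network,
    hill-climbs it onto the local inscribed-radius maximum (so candidates sit
    on the medial axis, not at wall corners or surface bumps), and accepts it
    as an endpoint only while its snapped position is farther from the
    network than ``coverage_factor`` times its own inscribed radius. Wall
    artifacts snap onto already-covered axis points and are rejected, which
    terminates the search.
    """
    g, interior, idx3 = _interior_graph(field)
    shape = field.mask.shape
    r_flat = field.radius.ravel()[interior]
    flat_of = -np.ones(field.mask.size, dtype=np.int64)
    flat_of[np.flatnonzero(field.mask.ravel())] = np.arange(len(interior))
    pitch = field.pitch

    def snap(node: int) -> int:
        climbed = _hill_climb_radius(field, tuple(idx3[node]))
        return int(flat_of[np.ravel_multi_index(climbed, shape)])

    # farthest pair, both snapped to the medial axis
    c = int(np.argmax(r_flat))
    d0 = _csgraph_dijkstra(g, indices=c, min_only=True)
    e1 = snap(int(np.argmax(np.where(np.isfinite(d0), d0, -1.0))))
    d1, p1, _ = _csgraph_dijkstra(g, indices=e1, min_only=True, return_predecessors=True)
    far = int(np.argmax(np.where(np.isfinite(d1), d1, -1.0)))
    e2 = snap(far)

    endpoints = [e1, e2]
    # seed the network with the path joining the first endpoint pair
    sources = [e1, e2]
    node = far
    while node >= 0:
        sources.append(node)
        nxt = p1[node]
        if nxt < 0:
            break
        node = int(nxt)
    for _ in range(10000):
        dist, preds, _ = _csgraph_dijkstra(
            g, indices=sorted(set(sources)), min_only=True, return_predecessors=True
        )
        order = np.argsort(-np.where(np.isfinite(dist), dist, -1.0))
        accepted = None
        for u in order[: max(32, len(order) // 64)]:
            u = int(u)
            if not np.isfinite(dist[u]) or dist[u] <= 2.0 * pitch:
                break
            s = snap(u)
            if dist[s] > coverage_factor * r_flat[s] + 2.0 * pitch and s not in endpoints:
                accepted = (u, s)
                break
        if accepted is None:
            break
        u, s = accepted
        endpoints.append(s)
        # add the shortest path from the candidate back into the network
        node = u
        path = [s]
        while node >= 0:
            path.append(node)
            nxt = preds[node]
            if nxt < 0:
                break
            node = int(nxt)
        sources.extend(path)

    out = []
    seen = set()
    for e in endpoints:
        key = tuple(idx3[e])
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


def build_network(
    mesh: trimesh.Trimesh,
    pitch: float | None = None,
    resample_mm: float = 0.5,
) -> CenterlineNetwork:
    """Extract the full centerline network of a watertight airway mesh.

    Endpoints come from the skeletonized interior; the inlet is the endpoint
    with the largest inscribed radius; every other endpoint is connected to
    the inlet by fast-marching + gradient backtracking; shared path prefixes
    are merged so divergence points become bifurcation nodes; branches are
    resampled at a uniform arc-length interval.
    """
    if pitch is None:
        # probe coarsely, then refine to a third of the smallest opening radius
        probe_pitch = float(np.ptp(mesh.bounds, axis=0).max()) / 48.0
        probe = interior_radius_field(mesh, probe_pitch)
        probe_eps = detect_endpoints(probe)
        rmin = min(probe.radius[e] for e in probe_eps) if probe_eps else probe.radius.max()
        pitch = max(float(rmin) / 3.0, float(np.ptp(mesh.bounds, axis=0).max()) / 256.0)

    field = interior_radius_field(mesh, pitch)
    endpoints_idx = detect_endpoints(field)
    if len(endpoints_idx) < 2:
        raise ValueError("fewer than 2 endpoints found")
    radii_at = np.array([field.radius[e] for e in endpoints_idx])
    order = np.argsort([-r for r in radii_at])
    # inlet tie-break: largest radius, then deterministic by index order
    inlet_idx = endpoints_idx[int(order[0])]

    arrival = solve_eikonal(field, inlet_idx)

    # trace source->target paths and merge shared prefixes
    merge_tol = 2.0 * field.pitch
    points: list[np.ndarray] = []
    radii: list[float] = []
    g = nx.Graph()

    def add_point(p, r):
        points.append(np.asarray(p, float))
        radii.append(float(r))
        g.add_node(len(points) - 1)
        return len(points) - 1

    inlet_node = add_point(field.index_to_world(inlet_idx), field.radius[inlet_idx])
    endpoint_nodes = [inlet_node]

    for rank in order[1:]:
        ep = endpoints_idx[int(rank)]
        if not np.isfinite(arrival.T[ep]):
            continue  # disconnected pocket
        pts, rs = backtrack_path(arrival, ep)
        pts, rs = pts[::-1], rs[::-1]  # source -> target
        tree = cKDTree(np.vstack(points))
        dists, nearest = tree.query(pts)
        # longest prefix still on the existing network
        on_net = dists <= merge_tol
        k = 0
        while k + 1 < len(pts) and on_net[k + 1]:
            k += 1
        graft = int(nearest[k])
        prev = graft
        for p, r in zip(pts[k + 1 :], rs[k + 1 :]):
            idx = add_point(p, r)
            g.add_edge(prev, idx)
            prev = idx
        if prev == graft:
            continue
        endpoint_nodes.append(prev)

    net = CenterlineNetwork(np.vstack(points), np.array(radii), g, pitch=field.pitch)
    net = _split_and_resample(net, resample_mm)
    eps = net.endpoints
    net.inlet = int(eps[np.argmax(net.radii[eps])])
    return net


def _split_and_resample(net: CenterlineNetwork, interval: float) -> CenterlineNetwork:
    """Split into branches at junctions and resample each at ``interval`` mm."""
    g = net.graph
    junctions = {n for n in g.nodes if g.degree(n) != 2}

    # walk maximal chains between junction nodes
    branches: list[list[int]] = []
    seen_edges = set()
    for j in junctions:
        for nb in g.neighbors(j):
            ek = (min(j, nb), max(j, nb))
            if ek in seen_edges:
                continue
            chain = [j, nb]
            seen_edges.add(ek)
            prev, cur = j, nb
            while cur not in junctions:
                nxts = [x for x in g.neighbors(cur) if x != prev]
                if not nxts:
                    break
                prev, cur = cur, nxts[0]
                seen_edges.add((min(prev, cur), max(prev, cur)))
                chain.append(cur)
            branches.append(chain)

    new_points: list[np.ndarray] = []
    new_radii: list[float] = []
    new_branch: list[int] = []
    ng = nx.Graph()
    junction_map: dict[int, int] = {}

    def add(p, r, bid):
        new_points.append(p)
        new_radii.append(r)
        new_branch.append(bid)
        ng.add_node(len(new_points) - 1)
        return len(new_points) - 1

    for bid, chain in enumerate(branches):
        pts = net.points[chain]
        rs = net.radii[chain]
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        total = arc[-1]
        n_samp = max(2, int(np.round(total / interval)) + 1)
        s = np.linspace(0.0, total, n_samp)
        interp_pts = np.column_stack([np.interp(s, arc, pts[:, d]) for d in range(3)])
        interp_rs = np.interp(s, arc, rs)

        start, end = chain[0], chain[-1]
        if start in junction_map:
            prev = junction_map[start]
        else:
            prev = add(interp_pts[0], interp_rs[0], bid)
            junction_map[start] = prev
        for p, r in zip(interp_pts[1:-1], interp_rs[1:-1]):
            idx = add(p, max(r, 1e-9), bid)
            ng.add_edge(prev, idx)
            prev = idx
        if end in junction_map:
            last = junction_map[end]
        else:
            last = add(interp_pts[-1], interp_rs[-1], bid)
            junction_map[end] = last
        ng.add_edge(prev, last)

    out = CenterlineNetwork(
        np.vstack(new_points), np.array(new_radii), ng, np.array(new_branch), pitch=net.pitch
    )
    out.inlet = net.inlet if net.inlet >= 0 else -1
    return out
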
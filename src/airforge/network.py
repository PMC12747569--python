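"""Centerline network container: 3D points, inscribed radii, branch graph."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass
class CenterlineNetwork:
    """Graph of centerline points with maximal-inscribed-sphere radii.

    Attributes
    ----------
    points : (N, 3) float array, mm
    radii : (N,) float array, mm — local maximal inscribed sphere radius.
    graph : networkx.Graph on point indices.
    branch_ids : (N,) int — id of the branch each point belongs to.
    inlet : int — index of the inlet endpoint (largest-radius criterion).
    """

    points: np.ndarray
    radii: np.ndarray
    graph: nx.Graph
    branch_ids: np.ndarray = field(default=None)
    inlet: int = -1
    pitch: float = 0.0  # voxel pitch the network was traced at (0 = exact)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.branch_ids is None:
            self.branch_ids = np.zeros(len(self.points), dtype=int)
        self.branch_ids = np.asarray(self.branch_ids, dtype=int)
        if np.any(self.radii <= 0):
            raise ValueError("all centerline radii must be positive")

    @property
    def endpoints(self) -> np.ndarray:
        """Indices of degree-1 nodes."""
        return np.array(sorted(n for n in self.graph.nodes if self.graph.degree(n) == 1), dtype=int)

    @property
    def n_branches(self) -> int:
        return int(len(np.unique(self.branch_ids)))

    def neighbor(self, idx: int) -> int:
        """First graph neighbor of a point (nearest along the polyline)."""
        nbrs = list(self.graph.neighbors(idx))
        if not nbrs:
            raise ValueError(f"point {idx} has no neighbors")
        return nbrs[0]

    def branch_points(self, branch_id: int) -> np.ndarray:
        return np.nonzero(self.branch_ids == branch_id)[0]

    def to_dict(self) -> dict:
        return {
            "points": self.points.tolist(),
            "radii": self.radii.tolist(),
            "edges": [[int(a), int(b)] for a, b in self.graph.edges],
            "branch_ids": self.branch_ids.tolist(),
            "endpoints": [int(i) for i in self.endpoints],
            "inlet": int(self.inlet),
            "pitch": float(self.pitch),
        }

    def save_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "CenterlineNetwork":
        g = nx.Graph()
        g.add_nodes_from(range(len(d["points"])))
        g.add_edges_from((a, b) for a, b in d["edges"])
        return cls(
            points=np.asarray(d["points"], dtype=float),
            radii=np.asarray(d["radii"], dtype=float),
            graph=g,
            branch_ids=np.asarray(d["branch_ids"], dtype=int),
            inlet=int(d["inlet"]),
            pitch=float(d.get("pitch", 0.0)),
        )

    @classmethod
    def load_json(cls, path: str | os.PathLike) -> "CenterlineNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save_vtp(self, path: str | os.PathLike) -> None:
        """Write an XML VTP polyline (one line cell per graph edge)."""
        pts = self.points
        lines = []
        lines.append('<?xml version="1.0"?>')
        lines.append('<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">')
        lines.append("<PolyData>")
        edges = list(self.graph.edges)
        lines.append(
            f'<Piece NumberOfPoints="{len(pts)}" NumberOfLines="{len(edges)}">'
        )
        lines.append("<Points>")
        coords = " ".join(f"{x:.6f}" for x in pts.ravel())
        lines.append(f'<DataArray type="Float32" NumberOfComponents="3" format="ascii">{coords}</DataArray>')
        lines.append("</Points>")
        lines.append("<PointData>")
        rad = " ".join(f"{r:.6f}" for r in self.radii)
        lines.append(f'<DataArray type="Float32" Name="radius" format="ascii">{rad}</DataArray>')
        lines.append("</PointData>")
        lines.append("<Lines>")
        conn = " ".join(f"{a} {b}" for a, b in edges)
        lines.append(f'<DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>')
        offs = " ".join(str(2 * (i + 1)) for i in range(len(edges)))
        lines.append(f'<DataArray type="Int64" Name="offsets" format="ascii">{offs}</DataArray>')
        lines.append("</Lines>")
        lines.append("</Piece></PolyData></VTKFile>")
        with open(path, "w") as fh:
            fh.write("\n".join(lines))
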
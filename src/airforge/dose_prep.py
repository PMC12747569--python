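"""Dose-assessment preparation from particle deposition records.

Converts the output of a particle-deposition simulation into Monte Carlo
transport inputs: the overall deposition fraction with a correction for the
unresolved distal airways, per-particle activities proportional to particle
volume, point-source batches under a per-simulation source limit, and rigid
alignment of the deposition cloud onto a reference phantom using the tracheal
carina as the landmark.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .capping import rodrigues_rotation

MAX_SOURCES_PER_BATCH = 500


@dataclass
class DepositionRecord:
    """One simulated particle: position (mm), diameter (m), and fate."""

    particle_id: int
    position_mm: tuple[float, float, float]
    diameter_m: float
    fate: str  # "stuck" | "escaped"
    volume_m3: float | None = None

    def __post_init__(self) -> None:
        if self.fate not in ("stuck", "escaped"):
            raise ValueError(f"fate must be 'stuck' or 'escaped', got {self.fate!r}")
        v_sphere = math.pi * self.diameter_m**3 / 6.0
        if self.volume_m3 is None:
            self.volume_m3 = v_sphere
        elif abs(self.volume_m3 - v_sphere) > 1e-9 * max(v_sphere, 1e-300):
            raise ValueError("volume inconsistent with diameter (V = pi d^3 / 6)")


@dataclass
class SourceBatch:
    """Point sources for one transport run (at most 500 per batch)."""

    index: int
    sources: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sources) > MAX_SOURCES_PER_BATCH:
            raise ValueError("batch exceeds the 500-source limit")

    @property
    def total_activity_bq(self) -> float:
        return sum(s["activity_bq"] for s in self.sources)


@dataclass
class RigidTransform:
    rotation: np.ndarray
    translation_mm: np.ndarray
    reference: str = "carina"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10) or not np.isclose(np.linalg.det(R), 1.0, atol=1e-10):
            raise ValueError("rotation must be orthonormal with determinant +1")
        self.rotation = R
        self.translation_mm = np.asarray(self.translation_mm, dtype=float)

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        return np.asarray(points_mm, float) @ self.rotation.T + self.translation_mm


def deposition_fraction(
    n_stick: int, n_escape: int, n_total: int, icrp_correction: float
) -> float:
    """Corrected deposition fraction (n_stick + n_escape * c) / n_total.

    ``icrp_correction`` is the fraction of escaped particles expected to
    deposit in the unresolved distal region (0 disables the correction).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_stick + n_escape > n_total:
        raise ValueError("stick + escape exceeds the particle total")
    if not (0.0 <= icrp_correction <= 1.0):
        raise ValueError("correction factor must lie in [0, 1]")
    return (n_stick + n_escape * icrp_correction) / n_total


def load_correction_table(path) -> "IcrpCorrectionTable":
    """Correction factors vs aerodynamic diameter (CSV: diameter_um,fraction)."""
    diam, frac = [], []
    with open(path) as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().startswith("#") or not row[0][0].isdigit():
                continue
            diam.append(float(row[0]))
            frac.append(float(row[1]))
    return IcrpCorrectionTable(np.asarray(diam), np.asarray(frac))


@dataclass
class IcrpCorrectionTable:
    diameter_um: np.ndarray
    fraction: np.ndarray

    def __call__(self, diameter_um: float) -> float:
        return float(np.interp(diameter_um, self.diameter_um, self.fraction))


def assign_activity(
    records: list[DepositionRecord], specific_activity_bq_kg: float, density_kg_m3: float
) -> np.ndarray:
    """Per-particle activity A_i = V_i * a * rho (Bq)."""
    if specific_activity_bq_kg <= 0 or density_kg_m3 <= 0:
        raise ValueError("specific activity and density must be positive")
    return np.array([r.volume_m3 * specific_activity_bq_kg * density_kg_m3 for r in records])


def batch_sources(
    records: list[DepositionRecord],
    activities_bq: np.ndarray,
    max_sources: int = MAX_SOURCES_PER_BATCH,
    dual_decay: bool = False,
) -> list[SourceBatch]:
    """Group stuck particles into point-source batches.

    Dual-decay nuclides emit both gamma and beta, so each particle becomes
    two co-located point sources and only ``max_sources // 2`` particles fit
    per batch; both sources of a particle always share a batch.
    """
    spp = 2 if dual_decay else 1
    if max_sources < spp:
        raise ValueError("max_sources smaller than sources per particle")
    per_batch = max_sources // spp
    stuck = [(r, a) for r, a in zip(records, activities_bq) if r.fate == "stuck"]
    batches: list[SourceBatch] = []
    for bi in range(0, len(stuck), per_batch):
        chunk = stuck[bi : bi + per_batch]
        sources = []
        for r, a in chunk:
            modes = ("gamma", "beta") if dual_decay else ("gamma",)
            for mode in modes:
                sources.append(
                    {
                        "particle_id": r.particle_id,
                        "position_mm": list(r.position_mm),
                        "activity_bq": float(a),
                        "mode": mode,
                    }
                )
        batches.append(SourceBatch(index=len(batches), sources=sources))
    return batches


def align_to_reference(
    points_mm: np.ndarray,
    source_carina_mm,
    target_carina_mm,
    source_axis,
    target_axis,
) -> tuple[np.ndarray, RigidTransform]:
    """Rigidly map a deposition cloud onto a reference frame.

    Translates the source carina onto the target carina and rotates the
    source tracheal axis onto the target axis (rotation about their common
    perpendicular). Distances between points are preserved exactly up to
    floating point.
    """
    sa = np.asarray(source_axis, dtype=float)
    ta = np.asarray(target_axis, dtype=float)
    if np.linalg.norm(sa) < 1e-12 or np.linalg.norm(ta) < 1e-12:
        raise ValueError("axis vectors must be nonzero")
    sa = sa / np.linalg.norm(sa)
    ta = ta / np.linalg.norm(ta)
    # rotate sa onto ta: compose R(z->ta) with R(z->sa)^T
    R = rodrigues_rotation(ta) @ rodrigues_rotation(sa).T
    sc = np.asarray(source_carina_mm, dtype=float)
    tc = np.asarray(target_carina_mm, dtype=float)
    translation = tc - R @ sc
    tf = RigidTransform(rotation=R, translation_mm=translation)
    return tf.apply(points_mm), tf


def save_batches(batches: list[SourceBatch], directory, manifest_name: str = "sources.json") -> None:
    """Write batches as plain text (x y z activity mode batch) plus a manifest."""
    os.makedirs(directory, exist_ok=True)
    rows_path = os.path.join(directory, "sources.txt")
    with open(rows_path, "w") as fh:
        fh.write("# x_mm y_mm z_mm activity_bq mode batch\n")
        for b in batches:
            for s in b.sources:
                x, y, z = s["position_mm"]
                fh.write(f"{x:.6f} {y:.6f} {z:.6f} {s['activity_bq']:.6e} {s['mode']} {b.index}\n")
    manifest = {
        "n_batches": len(batches),
        "max_sources_per_batch": MAX_SOURCES_PER_BATCH,
        "total_activity_bq": sum(b.total_activity_bq for b in batches),
        "batches": [{"index": b.index, "n_sources": len(b.sources)} for b in batches],
    }
    with open(os.path.join(directory, manifest_name), "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_records_csv(path) -> list[DepositionRecord]:
    """Read deposition records (CSV: id,x,y,z,diameter_m,fate)."""
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            records.append(
                DepositionRecord(
                    particle_id=int(row["id"]),
                    position_mm=(float(row["x"]), float(row["y"]), float(row["z"])),
                    diameter_m=float(row["diameter_m"]),
                    fate=row["fate"].strip(),
                )
            )
    return records
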
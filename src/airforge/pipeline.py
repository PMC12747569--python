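"""End-to-end pipeline: volume -> mask -> surface -> repaired -> centerline
-> capped geometry -> CFD case and dose-prep inputs, with a JSON manifest."""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import capping, centerline, cfd_setup, meshrepair, voxelseg
from .volume import ScalarVolume, load_nifti


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults."""

    i0_hu: float = -900.0
    i1_hu: float = -115.0
    oral_window_cm3: tuple[float, float] = (3.0, 9.66)
    metal_threshold_hu: float = 2500.0
    merge_eps_mm: float = meshrepair.MERGE_EPS_MM
    taubin_lambda: float = 0.60
    taubin_nu: float = 0.635
    taubin_iterations: int = 20
    smooth: bool = True
    centerline_pitch_mm: float | None = None
    cap_thickness_mm: float = 0.3
    cap_radius_scale: float = 1.5
    q_max_lpm: float = 100.0
    period_s: float = 2.0
    turbulence_intensity: float = 0.04
    seed: int = 0
    out_dir: str = "airforge_out"


def _sha(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(input_path: str, config: PipelineConfig = PipelineConfig()) -> dict:
    """Run all remaining stages for the given input (volume or STL).

    Entry stage is inferred from the extension: NIfTI volumes enter at
    segmentation, STL surfaces skip the voxel stages. Returns the manifest;
    artifacts and the manifest itself are written to ``config.out_dir``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {"input": input_path, "config": _jsonable(asdict(config)), "stages": []}

    def record(stage: str, t0: float, outputs: dict, **extra):
        entry = {
            "stage": stage,
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": {k: {"path": v, "sha": _sha(v)} for k, v in outputs.items()},
        }
        entry.update(_jsonable(extra))
        manifest["stages"].append(entry)

    lower = input_path.lower()
    mesh = None
    if lower.endswith((".nii", ".nii.gz", ".nrrd")):
        vol = load_nifti(input_path)
        t0 = time.time()
        mask, mesh, report = voxelseg.segment_extrathoracic(
            vol,
            window=voxelseg.WindowParams(config.i0_hu, config.i1_hu),
            filt=voxelseg.BodyFilterParams(*config.oral_window_cm3),
            metal_threshold=config.metal_threshold_hu,
        )
        from .volume import save_nifti

        mask_path = os.path.join(config.out_dir, "mask.nii.gz")
        save_nifti(ScalarVolume(mask.astype(np.float32), vol.spacing, vol.origin), mask_path)
        raw_path = os.path.join(config.out_dir, "surface_raw.stl")
        meshrepair.save_stl(mesh, raw_path)
        record("segment", t0, {"mask": mask_path, "surface": raw_path}, report=report)
    elif lower.endswith(".stl"):
        mesh = meshrepair.load_stl(input_path)
    else:
        raise ValueError(f"cannot infer entry stage for {input_path!r}")

    t0 = time.time()
    mesh, rep = meshrepair.repair_to_watertight(mesh, merge_eps=config.merge_eps_mm)
    if config.smooth:
        mesh = meshrepair.taubin_smooth(
            mesh,
            meshrepair.TaubinParams(config.taubin_lambda, config.taubin_nu, config.taubin_iterations),
        )
    repaired_path = os.path.join(config.out_dir, "surface_repaired.stl")
    meshrepair.save_stl(mesh, repaired_path)
    quality = meshrepair.quality_report(mesh).summary
    record("repair", t0, {"surface": repaired_path}, repair=asdict(rep), quality=quality)

    t0 = time.time()
    net = centerline.build_network(mesh, pitch=config.centerline_pitch_mm)
    net_path = os.path.join(config.out_dir, "centerline.json")
    net.save_json(net_path)
    record("centerline", t0, {"network": net_path}, n_endpoints=len(net.endpoints), n_branches=net.n_branches)

    t0 = time.time()
    cg = capping.cap_all(mesh, net, radius_scale=config.cap_radius_scale, thickness=config.cap_thickness_mm)
    capped_path = os.path.join(config.out_dir, "surface_capped.stl")
    meshrepair.save_stl(cg.mesh, capped_path)
    patches_path = os.path.join(config.out_dir, "patches.json")
    with open(patches_path, "w") as fh:
        json.dump({"patches": cg.patches, "face_labels": cg.face_labels.tolist()}, fh)
    record("cap", t0, {"surface": capped_path, "patches": patches_path}, n_caps=len(cg.patches) - 1)

    t0 = time.time()
    case = cfd_setup.emit_case(
        cg.patches,
        breathing=cfd_setup.BreathingPattern(config.q_max_lpm, config.period_s),
    )
    case_path = os.path.join(config.out_dir, "case.json")
    cfd_setup.save_case(case, case_path)
    record("case", t0, {"case": case_path})

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
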
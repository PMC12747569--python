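"""Boundary-condition and particle-physics calculators for airway CFPD cases.

Covers the sinusoidal breathing waveform, inlet velocity from flow rate and
area, k-omega SST transition-model inlet quantities (k, omega, intermittency,
transition momentum-thickness Reynolds number), the Stokes-Cunningham slip
correction, Stokes drag, and the Brownian force model for submicron aerosol
transport — plus a solver-agnostic case emitter.

Units are SI internally; flow rates are L/min and areas mm^2 at the interface
because that is how respiratory cases are specified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

K_BOLTZMANN = 1.380649e-23  # J/K
C_MU = 0.09

# Cunningham slip coefficients (classical set)
CUNNINGHAM_A1 = 1.257
CUNNINGHAM_A2 = 0.4
CUNNINGHAM_A3 = 1.1

# turbulence-intensity floor for the Re_theta correlation (percent)
TU_FLOOR = 0.027


@dataclass
class BreathingPattern:
    """Sinusoidal respiratory waveform Q(t) = Q_max sin(2 pi t / T)."""

    q_max_lpm: float = 100.0
    period_s: float = 2.0

    def __post_init__(self) -> None:
        if self.q_max_lpm <= 0 or self.period_s <= 0:
            raise ValueError("Q_max and T must be positive")


@dataclass
class TurbulenceBC:
    u_ref: float  # m/s
    intensity: float  # fraction
    k: float  # m^2/s^2
    omega: float  # 1/s
    gamma: float  # intermittency (1 at inlet)
    re_theta: float
    tu_percent: float
    length_scale: float  # m (hydraulic diameter)
    c_mu: float = C_MU


@dataclass
class ParticleForceParams:
    """Physical inputs for the particle force models (SI units)."""

    diameter_m: float = 0.42e-6
    particle_density: float = 1000.0  # kg/m^3
    fluid_density: float = 1.204  # kg/m^3, air at 20 C
    fluid_temperature_k: float = 310.0  # body temperature
    dynamic_viscosity: float = 1.81e-5  # Pa s
    time_step_s: float = 1e-5
    mean_free_path_m: float = 6.8e-8
    volume_fraction: float = 1e-6

    def __post_init__(self) -> None:
        for name in (
            "diameter_m",
            "particle_density",
            "fluid_density",
            "fluid_temperature_k",
            "dynamic_viscosity",
            "time_step_s",
            "mean_free_path_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.volume_fraction < 0.01):
            raise ValueError("particle volume fraction must be near zero")


def flow_waveform(t, bp: BreathingPattern = BreathingPattern()):
    """Instantaneous flow Q(t) (L/min) and the cycle mean of |Q|.

    The mean of |Q_max sin(2 pi t / T)| over one period is 2 Q_max / pi
    (about 63 L/min for the default 100 L/min peak).
    """
    q = bp.q_max_lpm * np.sin(2.0 * np.pi * np.asarray(t, dtype=float) / bp.period_s)
    mean_abs = 2.0 * bp.q_max_lpm / np.pi
    return q, mean_abs


def inlet_velocity(q_lpm: float, area_mm2: float) -> float:
    """Mean inlet speed ||u|| = Q / A in m/s (Q in L/min, A in mm^2)."""
    if area_mm2 <= 0:
        raise ValueError("inlet area must be positive")
    q_m3s = q_lpm / 1000.0 / 60.0
    a_m2 = area_mm2 * 1e-6
    return q_m3s / a_m2


def re_theta_correlation(tu_percent: float) -> float:
    """Transition momentum-thickness Reynolds number vs Tu (percent).

    Piecewise correlation: ``1173.51 - 589.428 Tu + 0.2196 / Tu^2`` for
    Tu <= 1.3 and ``331.5 (Tu - 0.5658)^-0.671`` above; the branches agree at
    the switch point to about 0.1%.
    """
    tu = max(float(tu_percent), TU_FLOOR)
    if tu <= 1.3:
        return 1173.51 - 589.428 * tu + 0.2196 / (tu * tu)
    return 331.5 * (tu - 0.5658) ** (-0.671)


def turbulence_bcs(u_ref: float, intensity: float = 0.04, length_scale: float = 0.01) -> TurbulenceBC:
    """Inlet turbulence quantities for the k-omega SST transition model.

    k = (3/2) I^2 u_ref^2, omega = sqrt(k) / (C_mu^0.25 L), intermittency 1,
    Tu = 100 sqrt((2/3) k) / u_ref (identically 100 I), Re_theta from the
    piecewise correlation. ``length_scale`` is the inlet hydraulic diameter
    in meters.
    """
    if u_ref <= 0 or length_scale <= 0:
        raise ValueError("u_ref and length scale must be positive")
    k = 1.5 * intensity**2 * u_ref**2
    omega = np.sqrt(k) / (C_MU**0.25 * length_scale)
    tu = 100.0 * np.sqrt(2.0 * k / 3.0) / u_ref
    return TurbulenceBC(
        u_ref=u_ref,
        intensity=intensity,
        k=k,
        omega=float(omega),
        gamma=1.0,
        re_theta=re_theta_correlation(tu),
        tu_percent=float(tu),
        length_scale=length_scale,
    )


def cunningham_slip(diameter_m: float, mean_free_path_m: float = 6.8e-8) -> float:
    """Cunningham slip correction C_c = 1 + Kn (1.257 + 0.4 exp(-1.1/Kn))."""
    if diameter_m <= 0 or mean_free_path_m <= 0:
        raise ValueError("diameter and mean free path must be positive")
    kn = 2.0 * mean_free_path_m / diameter_m
    return 1.0 + kn * (CUNNINGHAM_A1 + CUNNINGHAM_A2 * np.exp(-CUNNINGHAM_A3 / kn))


def brownian_force(p: ParticleForceParams, rng=None, xi: np.ndarray | None = None) -> np.ndarray:
    """One Brownian force sample F = xi sqrt(2 k_b T / (alpha dt)) in newtons.

    ``alpha = 1/(3 pi eta d)`` is the particle mobility (Einstein relation
    divided by k_b T); ``xi`` is a standard-normal 3-vector, drawn from
    ``rng`` unless supplied explicitly.
    """
    if xi is None:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        xi = rng.standard_normal(3)
    alpha = 1.0 / (3.0 * np.pi * p.dynamic_viscosity * p.diameter_m)
    magnitude = np.sqrt(2.0 * K_BOLTZMANN * p.fluid_temperature_k / (alpha * p.time_step_s))
    return np.asarray(xi, dtype=float) * magnitude


def drag_force(p: ParticleForceParams, slip_velocity) -> np.ndarray:
    """Slip-corrected Stokes drag F = 0.5 C_d rho A_p |v_s| v_s (newtons).

    C_d = 24 / (Re_p C_c) in the Stokes regime with the Cunningham-corrected
    particle Reynolds number; algebraically this reduces to
    ``3 pi eta d |v_s| / C_c``.
    """
    v_s = np.asarray(slip_velocity, dtype=float)
    speed = float(np.linalg.norm(v_s))
    if speed == 0.0:
        return np.zeros(3)
    c_c = cunningham_slip(p.diameter_m, p.mean_free_path_m)
    re_p = p.fluid_density * speed * p.diameter_m / p.dynamic_viscosity
    c_d = 24.0 / (re_p * c_c)
    a_p = np.pi * p.diameter_m**2 / 4.0
    return 0.5 * c_d * p.fluid_density * a_p * speed * v_s


# --------------------------------------------------------------------------
# case emission
# --------------------------------------------------------------------------

# pass-through hex-meshing defaults for the OpenFOAM rendering
SNAPPY_DEFAULTS = {
    "castellatedMesh": True,
    "snap": True,
    "addLayers": True,
    "maxLocalCells": 2_000_000,
    "maxGlobalCells": 30_000_000,
    "nCellsBetweenLevels": 3,
    "surfaceRefinementLevel": [1, 2],
    "resolveFeatureAngle": 30,
    "nSurfaceLayers": 5,
    "expansionRatio": 1.2,
    "finalLayerThickness": 0.3,
    "minThickness": 0.1,
    "backgroundCellSizeMaxMM": 1.5,
}

DEFAULT_PARTICLE_COUNT = 100_000


def emit_case(
    patches: list[dict],
    breathing: BreathingPattern = BreathingPattern(),
    turbulence: TurbulenceBC | None = None,
    particles: ParticleForceParams = ParticleForceParams(),
    n_particles: int = DEFAULT_PARTICLE_COUNT,
    dialect: str = "json",
) -> dict | str:
    """Emit a solver-agnostic case description.

    Every outlet gets a fixed-pressure condition (0 gauge), walls no-slip
    with stick-on-contact particle capture, and the single inlet carries the
    breathing waveform plus the turbulence inlet values. ``dialect='json'``
    returns the case dict; ``'openfoam'`` returns a text rendering of the
    field dictionaries.
    """
    inlets = [p for p in patches if p.get("kind") == "inlet"]
    if len(inlets) != 1:
        raise ValueError(f"case requires exactly one inlet patch, found {len(inlets)}")
    inlet = inlets[0]
    if turbulence is None:
        u_ref = inlet_velocity(breathing.q_max_lpm, inlet["area_mm2"])
        d_h = 2.0 * np.sqrt(inlet["area_mm2"] * 1e-6 / np.pi)  # m
        turbulence = turbulence_bcs(u_ref, length_scale=d_h)

    bc = {}
    for p in patches:
        kind = p.get("kind")
        if kind == "inlet":
            bc[f"patch_{p['label']}"] = {
                "type": "inlet",
                "velocity": "waveform",
                "q_max_lpm": breathing.q_max_lpm,
                "period_s": breathing.period_s,
                "k": turbulence.k,
                "omega": turbulence.omega,
                "gamma": turbulence.gamma,
                "re_theta": turbulence.re_theta,
            }
        elif kind == "outlet":
            bc[f"patch_{p['label']}"] = {"type": "outlet", "pressure_gauge_pa": 0.0, "k": "zeroGradient", "omega": "zeroGradient"}
        else:
            bc[f"patch_{p['label']}"] = {"type": "wall", "velocity": "noSlip", "particles": "stick"}

    case = {
        "boundary_conditions": bc,
        "waveform": {"form": "Qmax*sin(2*pi*t/T)", "q_max_lpm": breathing.q_max_lpm, "period_s": breathing.period_s},
        "turbulence": {
            "model": "kOmegaSST-LM",
            "u_ref": turbulence.u_ref,
            "intensity": turbulence.intensity,
            "k": turbulence.k,
            "omega": turbulence.omega,
            "gamma": turbulence.gamma,
            "re_theta": turbulence.re_theta,
            "tu_percent": turbulence.tu_percent,
            "c_mu": turbulence.c_mu,
        },
        "particles": {
            "count": int(max(n_particles, DEFAULT_PARTICLE_COUNT)),
            "diameter_m": particles.diameter_m,
            "density_kg_m3": particles.particle_density,
            "wall_mode": "stick",
        },
        "meshing": SNAPPY_DEFAULTS,
    }
    if dialect == "json":
        return case
    if dialect == "openfoam":
        return _render_openfoam(case)
    raise ValueError(f"unknown dialect {dialect!r}")


def _render_openfoam(case: dict) -> str:
    """Minimal text rendering of the boundary field dictionaries."""
    out = []
    for fieldname, key in (("U", "velocity"), ("p", "pressure"), ("k", "k"), ("omega", "omega"), ("gammaInt", "gamma"), ("ReThetat", "re_theta")):
        out.append(f"// field {fieldname}")
        out.append("boundaryField\n{")
        for patch, spec in case["boundary_conditions"].items():
            out.append(f"    {patch}")
            out.append("    {")
            if spec["type"] == "inlet":
                if fieldname == "U":
                    out.append("        type            codedFixedValue; // Qmax*sin(2*pi*t/T)/A")
                else:
                    val = spec.get(key, case["turbulence"].get(key, 0))
                    out.append(f"        type            fixedValue; value uniform {val};")
            elif spec["type"] == "outlet":
                if fieldname == "p":
                    out.append("        type            fixedValue; value uniform 0;")
                else:
                    out.append("        type            zeroGradient;")
            else:
                if fieldname == "U":
                    out.append("        type            noSlip;")
                elif fieldname == "k":
                    out.append("        type            kLowReWallFunction; value uniform 1e-10;")
                elif fieldname == "omega":
                    out.append("        type            omegaWallFunction; value uniform 1;")
                else:
                    out.append("        type            zeroGradient;")
            out.append("    }")
        out.append("}\n")
    return "\n".join(out)


def save_case(case: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(case, fh, indent=2)
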
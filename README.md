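# airforge

Automated subject-specific airway modeling for computational fluid and
particle dynamics (CFPD) and inhalation dosimetry.

Going from a CT scan of the respiratory tract to a simulation-ready geometry
normally takes hours of manual work: segmenting the air passages, repairing
the extracted surface until it is watertight, finding the centerline of every
branch, cutting and capping each of the `2^n + 1` openings of an n-generation
airway tree, and writing out consistent boundary conditions. `airforge`
implements that chain as a tested, deterministic pipeline:

1. **Segmentation** (`airforge.voxelseg`) — classical extrathoracic airway
   segmentation from Hounsfield-unit volumes: sinogram-space metal-artifact
   reduction, 3×3×3 median filtering, linear windowing
   `I* = clip((I − I0)/(I1 − I0), 0, 1)` with I0 = −900 HU (air) and
   I1 = −115 HU (fat), Canny-based edge amplification (cubing inside the
   refined edge mask), Laplacian enhancement `I − ∇²I`, watershed labeling
   with background-air removal, and a body filter that keeps the largest air
   body plus any isolated body in the oral-cavity volume window
   (3–9.66 cm³). Plus the probability-map post-processing used for
   tracheobronchial masks: patch reassembly by product weighting, lung-mask
   constraining to [−1000, −600] HU, thresholding at 0.5, largest
   26-connected component.
2. **Surface repair** (`airforge.meshrepair`) — non-manifold edge removal
   (edges shared by more than two faces and every face touching them), hole
   filling via cycle-basis boundary loops (triangle / quad split / projected
   Delaunay), sub-tolerance vertex merging (ε = 10⁻⁶ cm), global winding
   repair, iterated to a strictly watertight 2-manifold; Taubin smoothing
   (λ = 0.60, ν = 0.635, 20 iterations, stability bound
   `0 < 1/λ − 1/ν < 0.1`) and triangle quality metrics
   (shape factor `SQ = 4√3·A / Σ lᵢ²`, minimum internal angle).
3. **Centerlines** (`airforge.centerline`) — maximal-inscribed-sphere radii
   from a Euclidean distance transform of the voxelized interior, arrival
   times from a second-order fast-marching solution of the Eikonal equation
   `|∇T| = 1/r(x)` (wide lumens propagate fast, so least-cost paths hug the
   medial axis), gradient backtracking `dx/ds = −∇T`, endpoint detection by
   farthest-point path growing, and branch splitting/merging into a
   `CenterlineNetwork`.
4. **Capping** (`airforge.capping`) — every endpoint is capped by
   subtracting a thin hexagonal prism oriented along the local centerline
   tangent (Rodrigues rotation of the prism axis onto the tangent), keeping
   the largest resulting body and triangulating the planar cut; the largest
   cap by area becomes the inlet.
5. **CFD setup** (`airforge.cfd_setup`) — sinusoidal breathing waveform
   `Q(t) = Q_max·sin(2πt/T)` (default Q_max = 100 L/min, T = 2 s; cycle mean
   of |Q| is 2·Q_max/π ≈ 63.7 L/min), inlet speed `‖u‖ = Q/A`, k–ω SST
   transition-model inlet values (`k = (3/2)I²u²` with I = 4 %,
   `ω = √k/(C_μ^0.25·L)`, γ = 1, Re_θ from the piecewise Tu correlation),
   Stokes–Cunningham slip correction, Brownian force
   `F = ξ·√(2 k_B T/(α Δt))` with Einstein mobility `α = 1/(3πηd)`, and a
   solver-agnostic case emitter (JSON, optional OpenFOAM-style text).
6. **Dose preparation** (`airforge.dose_prep`) — deposition fraction with a
   distal-airway correction `(n_stick + n_escape·c)/n_total`, per-particle
   activities `A = V·a·ρ`, point-source batching under a 500-source-per-run
   limit (two co-located sources per particle for dual beta/gamma decay), and
   carina-referenced rigid alignment onto a reference phantom.

Everything is exercisable without patient data: `airforge.synth` generates
CT-like phantoms (air cavities near −1000 HU in soft tissue, optional noise
and metal inserts) with exact ground-truth masks, watertight bifurcating
tube-tree meshes with known centerlines, controlled mesh defects (holes,
non-manifold fins, flipped faces, duplicate vertices), and probability patch
sets.

## Worked example

```python
from airforge.synth import PhantomSpec, TubeCavity, make_ct_phantom
from airforge.volume import save_nifti
from airforge.pipeline import run_pipeline, PipelineConfig
import json

spec = PhantomSpec(
    shape=(48, 48, 80),
    cavities=[TubeCavity(start_mm=(24.3, 23.7, 2.0),
                         end_mm=(24.3, 23.7, 78.0), volume_cm3=8.0)],
    noise_sd_hu=15.0,
)
vol, truth_masks = make_ct_phantom(spec, seed=5)
save_nifti(vol, "phantom.nii.gz")

manifest = run_pipeline("phantom.nii.gz", PipelineConfig(out_dir="out"))
for stage in manifest["stages"]:
    print(stage["stage"], "->", ", ".join(stage["outputs"]))

report = manifest["stages"][0]["report"]
print("segmented volume:", report["air_volume_cm3"], "cm^3 (requested 8.0)")
case = json.load(open("out/case.json"))
print("inlet k =", round(case["turbulence"]["k"], 4), "m^2/s^2,",
      "omega =", round(case["turbulence"]["omega"], 1), "1/s,",
      "Re_theta =", round(case["turbulence"]["re_theta"], 1))
```

prints

```
segment -> mask, surface
repair -> surface
centerline -> network
cap -> surface, patches
case -> case
segmented volume: 8.144 cm^3 (requested 8.0)
inlet k = 0.5623 m^2/s^2, omega = 116.3 1/s, Re_theta = 144.9
```

The segmented cavity volume recovers the requested 8 cm³ tube to under 2 %
despite 15 HU of added noise; the capped surface in `out/surface_capped.stl`
is strictly watertight (every edge shared by exactly two faces, Euler
characteristic 2) with one inlet and one outlet patch, and `out/case.json`
carries the waveform, turbulence, and particle settings for a transient
inhalation simulation at heavy-exercise breathing.

The same stages are available from the shell:

```sh
airforge synth-tree --generations 3 --open --out tree.stl
airforge centerline tree.stl --out net.json
airforge cap tree.stl net.json --scale 1.5 --thickness 0.3 --out capped.stl
airforge run phantom.nii.gz --out-dir out
```

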
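# Methods

This note documents the models and numerical choices behind each pipeline
stage, what the synthetic fixtures do and do not emulate, and the known
limitations.

## Scalar volumes and coordinate conventions

A `ScalarVolume` is a 3D grid with axes ordered (x, y, z), z the
through-plane direction, 0-based indices, and `world = index·spacing +
origin` in millimetres. NIfTI I/O supports axis-aligned affines only; DICOM
series are read slice-wise with the rescale slope/intercept applied so values
are Hounsfield units.

## Extrathoracic segmentation

The segmentation chain assumes air near −1000 HU embedded in soft tissue and
proceeds: metal-artifact reduction → median filter → windowing → edge
refinement → Laplacian enhancement → watershed body selection → marching
cubes.

* **Metal-artifact reduction** operates per axial slice: voxels at or above
  the metal threshold (default 2500 HU) are masked, the slice is
  forward-projected (Radon transform), detector bins whose rays cross metal
  are replaced by 1D linear interpolation along the detector axis, the slice
  is reconstructed by filtered back-projection, and the original metal voxels
  are restored. This is a deliberately simple sinogram-inpainting scheme: it
  damps streaks in synthetic tests but is not a clinical-grade MAR method.
* **Windowing** maps I0 = −900 HU → 0 and I1 = −115 HU → 1 with linear
  interpolation and clamping. Both thresholds are configurable; the defaults
  are the air and fat thresholds appropriate for airway CT.
* **Edge refinement** runs the Canny detector slice-wise on axial planes
  (classical Canny is 2D), refines the stacked mask by binary dilation, hole
  filling, and erosion, and cubes the voxel values inside the refined mask —
  darkening the air side of boundaries without touching anything else.
* **Laplacian enhancement** subtracts the 6-neighbor second-difference
  Laplacian (scaled by the squared spacing, one-sided boundaries zeroed),
  which deepens large dark cavities relative to thin bright membranes.
* **Body selection**: watershed over the enhanced image with strong-air
  seeds and a clear-tissue marker labels candidate air; air connected to the
  in-plane border in *both* the axial and coronal 2D views is classified as
  exterior background and removed (the two-view intersection keeps a
  through-going airway that touches the grid ends). Remaining 26-connected
  bodies are measured in cm³; the largest is kept, together with any isolated
  body inside the oral-cavity window (3, 9.66) cm³. Everything else (mastoid
  cells, detached sinuses, noise blobs) is dropped.
* **Marching cubes** runs at level 0.5 on the one-voxel-padded mask after a
  0.7-voxel Gaussian pre-filter. The pre-filter anti-aliases the binary
  field: a staircase isosurface overestimates surface area by ~10 %, the
  filtered one is within ~1 % on analytic spheres while changing enclosed
  volume by under 0.5 %. Bodies thin enough that filtering would sink the
  peak below the iso level fall back to the raw staircase.

The tracheobronchial helpers post-process externally produced probability
patches: reassembly multiplies overlapping probabilities (a conservative
AND-like combination), the lung mask is a plain [−1000, −600] HU threshold,
binarization is inclusive at 0.5, and the final mask is the largest
26-connected component.

## Surface repair

Repair targets the strict watertight contract: every edge shared by exactly
two faces, consistent winding, positive enclosed volume.

* Non-manifold edges are those with face incidence > 2; every face containing
  one is removed, then unreferenced vertices. Incidence-1 edges are
  boundaries and are routed to hole filling instead (the two treatments
  compose to the same watertight result).
* Boundary loops are the cycle basis of the incidence-1 edge graph; loops
  sharing a vertex are thereby split into simple cycles, and open chains are
  reported but not filled. A 3-loop becomes one face, a 4-loop two faces
  (split v1–v3), larger loops are Delaunay-triangulated on their
  principal-component best-fit plane with triangles filtered to the polygon
  interior; if the projection self-intersects or coverage fails, a fan
  triangulation is used with a warning. New faces are flipped so shared edges
  are traversed oppositely to their neighbors.
* Vertex merging (union-find over KD-tree pairs) uses ε = 10⁻⁵ mm
  (= 10⁻⁶ cm) and runs every iteration after filling; degenerate faces
  produced by a merge are dropped.
* The remove/fill/merge loop iterates until manifold and watertight
  (default cap 10 iterations; the randomized defect suite converges in 1,
  and the acceptance bound is ≤ 3). Winding is then repaired globally:
  orientation is propagated breadth-first over the face-adjacency graph and
  each connected shell is flipped outward (positive signed volume).
* Taubin smoothing uses the uniform (combinatorial) neighborhood Laplacian —
  the weighting is a choice; cotangent weights would track geometry more
  closely but are less robust on the near-degenerate triangles marching
  cubes emits. Parameters must satisfy the pass-band condition
  `0 < 1/λ − 1/ν < 0.1`; the defaults λ = 0.60, ν = 0.635 give margin
  0.0919. On a subdivision-4 icosphere, 20 iterations change volume by
  ~0.6 % versus ~10 % shrinkage for the λ-only filter with the same λ.
* Quality: shape factor `SQ = 4√3·A/Σlᵢ²` (1 for equilateral, 0 for
  degenerate) and minimum internal angle per face.

STL round trips weld exactly coincident vertices on load, since STL stores a
disconnected triangle soup.

## Centerlines

The medial axis is realized volumetrically rather than from an exact
polygonal Voronoi diagram (exact medial axes of noisy triangulations are
notoriously unstable): the watertight mesh is voxelized at pitch `h`, the
strict interior (filled minus surface-touching voxels) is kept, and the
inscribed-sphere radius at each interior voxel is its Euclidean distance
transform value plus `h/2` (the EDT measures to the nearest non-interior
voxel center, about half a voxel inside the true surface). Radii are
therefore accurate to roughly ± one pitch; the default pitch is a third of
the smallest opening radius found on a coarse probe pass.

**Arrival times** solve `|∇T| = 1/r(x)` — speed equal to the inscribed
radius, so travel cost is `∫ ds/r(s)` and wide lumens are cheap — by a
heap-ordered upwind fast-marching sweep. Two accuracy measures matter:
second-order one-sided differences are used per axis whenever two accepted
upwind neighbors exist, and a 5×5×5 ball around the source is initialized
analytically (the first-order stencil is worst diagonally behind the source).
With both, arrival times match an independent dense-stencil (5×5×5 primitive
directions) Dijkstra oracle to under 5 % on 36³ random smooth speed fields,
and exact straight-tube values to ~3 %.

**Backtracking** follows `dx/ds = −∇T` with central differences and
trilinear interpolation at half-pitch steps, hopping to the lowest-T
neighbor voxel on plateaus. Traced path costs reproduce the arrival time at
the endpoint to a few percent (cylinder: 2.8 %).

**Endpoint detection** grows a path network by farthest-point sampling on
the interior voxel graph: start from the voxel farthest (geodesic) from the
widest point, add its farthest counterpart and the joining path, then
repeatedly take the voxel farthest from the network, hill-climb it onto the
local inscribed-radius maximum, and accept it while its snapped position is
farther from the network than 2.5× its own radius (plus two voxels). Wall
corners and surface bumps snap onto already-covered medial points and are
rejected, which terminates the search. This replaces topological thinning,
whose 3D implementations can annihilate symmetric solid masks entirely. The
inlet is the endpoint with the largest inscribed radius (deterministic index
order breaks ties).

**Network assembly** traces a fast-marching path from the inlet to every
other endpoint, grafts each new path onto the existing network at the last
point within two pitches of it, splits the result into branches at nodes of
degree ≠ 2, and resamples each branch at 0.5 mm arc length (configurable).
On symmetric n-generation trees this yields exactly `2^n + 1` endpoints and
`2^(n+1) − 1` branches.

## Capping

Each endpoint is capped by subtracting a thin hexagonal prism (12 vertices;
volume `(3√3/2)·r_b²·t`) whose axis is aligned with the outward centerline
tangent via the Rodrigues rotation of +z onto the tangent (identity at the
parallel pole, rotation by π about x at the antiparallel pole, where the
formula is singular). The tangent uses the neighboring centerline point at
least one local radius away, which is robust to point-level jitter in traced
networks. The footprint radius is 1.5× the local lumen radius — the maximum
inscribed radius within three radii of the endpoint along its branch, since
the radius exactly at an endpoint is attenuated by the nearby end wall —
plus a two-pitch allowance when the network was traced on a voxel grid.

Because the prism must fully transect the lumen (a stated precondition), the
boolean difference reduces to an exact local operation: faces above the
prism's inner plane that are edge-connected to the endpoint region are
clipped against that plane (splitting straddling triangles exactly on it),
each resulting planar boundary loop is fan-triangulated around its centroid
and labeled as a cap patch, bodies are separated, and the largest by
enclosed volume is retained (ties broken by face count, then lowest
centroid, deterministically). A cut loop extending beyond the footprint
radius means the prism did not cover the cross-section and raises an error;
re-capping an endpoint whose geometry already ends at the cut plane is a
no-op. After all endpoints are processed, winding is re-fixed globally, the
largest cap by area becomes the inlet, and per-patch areas/centroids are
tabulated. Patch labels live in a JSON sidecar (STL has no patch concept),
with optional per-patch STL export.

## CFD boundary conditions and particle forces

All formulas are evaluated in SI with L/min and mm² at the interface.
Defaults: Q_max = 100 L/min, T = 2 s (heavy-exercise breathing; the cycle
mean of |Q| is 2Q_max/π ≈ 63.7 L/min), turbulence intensity I = 4 %,
C_μ = 0.09, length scale the inlet hydraulic diameter. The transition-model
correlation is `Re_θ = 1173.51 − 589.428·Tu + 0.2196/Tu²` for Tu ≤ 1.3 and
`331.5(Tu − 0.5658)^−0.671` above; the `0.2196/Tu²` reading makes the
branches continuous at Tu = 1.3 (≈ 0.1 % gap), whereas `0.2196·Tu²` would
leave a large jump. Tu is floored at 0.027 % to guard the division. The
Cunningham slip correction uses the classical coefficient set
(1.257, 0.4, 1.1), configurable. The Brownian force is
`F = ξ·√(2 k_B T₀/(α Δt))` with mobility `α = 1/(3πηd)` (the Einstein
relation divided by k_B T) and ξ a standard-normal 3-vector; drag is Stokes
with the slip-corrected drag coefficient, which reduces algebraically to
`3πηd‖v_s‖/C_c`. Lift and virtual-mass forces are solver-side models and are
not computed here. The case emitter assigns fixed pressure (0 gauge — the
ambient static pressure) at outlets, no-slip stick walls, and the waveform
plus turbulence values at the single inlet; the OpenFOAM-style text rendering
and the hex-meshing parameter block are pass-through configuration, not a
solver interface.

## Dose preparation

The deposition fraction `(n_stick + n_escape·c)/n_total` takes the
distal-deposition correction `c ∈ [0, 1]` as an input scalar or as a
diameter-interpolated table — computing `c` requires respiratory-tract
deposition models outside this package's scope. Activities are proportional
to particle volume, `A = V·a·ρ`. Batching packs stuck particles into runs of
at most 500 point sources; dual-decay nuclides contribute two co-located
sources per particle (so 250 particles per batch), each carrying the full
particle activity — the transport code's emission probabilities decide the
split, an assumption documented here because the physical convention is not
universal. Alignment onto a reference phantom translates the tracheal carina
and rotates the tracheal axis via the same Rodrigues operation used for
capping; it is rigid, hence exact on pairwise distances but blind to
anatomical deformation.

## Synthetic fixtures

* **Phantoms** embed analytic air cavities (flat-ended cylinders, spheres,
  at −1000 HU) in uniform soft tissue (default 40 HU) with optional additive
  Gaussian noise and spherical metal inserts (> 2000 HU). Rasterization uses
  3×3×3 subsampling with strict majority per voxel: the odd subsample count
  avoids coverage ties, keeping ground-truth voxel counts within a few
  percent of the requested cm³ even for lattice-aligned primitives. Phantoms
  emulate intensity statistics and topology, not anatomy: no turbinates, no
  partial-volume gradients, no beam-hardening physics — so passing tests
  demonstrate the pipeline's correctness on its stated contract, not
  clinical segmentation accuracy.
* **Tube trees** are self-similar binary trees (radius and length scaled by
  `decay` per generation, branch planes rotated 90° per generation, collision
  checked and rejected). The solid is the union of capsules around the
  construction skeleton, surfaced by marching cubes — a single genus-0
  watertight manifold by construction; open variants clip the root and every
  terminal with an exact local plane cut, leaving `2^n + 1` boundary loops.
  The generator's skeleton and radii are the ground-truth centerline.
* **Defects** are injected with full bookkeeping: holes remove pairwise
  non-adjacent faces, fins add a face hanging off an interior edge
  (incidence 3), flips reverse winding, duplicates split a shared vertex by
  10⁻⁶ mm (below the merge tolerance).

## Determinism

Every stochastic step takes an explicit seed (`numpy.random.default_rng`);
pipeline reruns produce byte-identical artifacts, verified by manifest
hashes.

## Problem sizes

Tests and the acceptance script run on deliberately small instances chosen to
exercise every code path at interactive speed: phantoms of 48³–64·96 voxels,
tube trees of 0–4 generations at marching-cubes pitches of ~0.5–1.6 mm,
Eikonal oracles on ≤ 36³ grids, and a 50-mesh randomized repair suite.
Finer pitches and larger volumes change runtimes, not code paths; the
discretization-sensitive quantities (radius accuracy ± pitch, endpoint
stability under pitch halving) are tested explicitly.

## Known limitations

* The sinogram inpainting is a minimal stand-in for clinical MAR; strong
  streaks between multiple metal objects are only partially removed.
* Self-intersecting faces are not auto-resolved (detection and the
  watertight contract are enforced; geometric self-intersection repair is
  out of scope).
* The centerline is voxel-accurate (± pitch), not sub-voxel; extremely thin
  lumens (< 2 voxels at the chosen pitch) are rejected rather than traced.
* Capping assumes the cap prism fully transects exactly one lumen at each
  endpoint; geometries where two branches pass within one footprint radius
  of an endpoint need a smaller radius scale.
* Neural-network tracheobronchial segmentation, volumetric meshing, flow
  solving, and Monte Carlo transport are intentionally outside the package:
  the pipeline prepares their inputs and consumes their outputs.
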
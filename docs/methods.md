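# Methods

## Scope and models

`wristsim` estimates wrist muscle forces, joint reaction forces and
articular contact forces quasi-statically: every sample of a motion cycle
is an independent static equilibrium, with gravity and inertia off (a
gravity-style external load can be applied explicitly). Three tiers share
one package so that each can serve as an oracle for the next.

### Planar statics

A single hinge in the sagittal plane with one lumped flexor (or extensor).
The lever arm of the lumped muscle shortens with deviation angle α as
A′ = A cos α; moment balance F·D = F_M·A′ yields the summarized force, and
the external load decomposes into F_X = F_E sin α, F_Y = F_E cos α with
resultant F_E at every angle. The model is deliberately crude — its role
is the closed-form bound and the sanity oracle for the multi-body tier.

Parameters (config-overridable): neutral lever arm A = 10 mm for both the
flexor and the extensor group (symmetric by construction: the flexion and
extension sweeps produce the same curves), load lever arm D = 80 mm
(distance from the wrist hinge to the third-metacarpal load point),
external load F_E = 100 N. Angles are degrees at all interfaces, radians
internally; α is restricted to [0°, 90°) and an effective lever arm below
1 µm raises a degenerate-geometry error instead of returning huge forces.

### Cardan-joint multi-body model

Frames: right-handed, z along the forearm axis (proximal→distal), x the FE
axis (radial), y palmar→dorsal. The hand attitude is composed FE first,
RUD second, R = R_rud·R_fe, about a common wrist center; the instantaneous
FE axis is therefore the FE axis rotated by the RUD rotation while the RUD
axis stays fixed. Signs: flexion and ulnar deviation positive, so the FE
protocol spans −60° (extension) to +80° (flexion) and RUD −20° (radial) to
+40° (ulnar). Motion cycles are piecewise linear in normalized time
(0 → first extreme → 0 → second extreme → 0) with the waypoints merged
into the sample grid so the extrema are attained exactly.

Muscles are polylines: origin on the forearm, one retinaculum-style via
point fixed to the forearm just proximal to the joint, insertion on the
hand. The via points matter: they make the flexor lever arms collapse
toward full extension (and vice versa), which reproduces the planar-model
force growth and is why flexor forces peak at the extension end of the FE
cycle under a dorsally directed load. Moment arms are tendon excursion,
r = −dL/dθ, central differences with a 1e-4 rad step; because the same
forward kinematics produces both the lengths and the external generalized
load (τ_j = ((p − c) × F)·axis_j with posed axes), equilibrium is
virtual-work consistent to finite-difference error.

The default geometry and the strengths (ECU 1500, ECRB 1600, ECRL 2400,
FCR 1700, FCU 2000 N) are synthetic. The strengths are set well above
physiological isometric values on purpose: at the extreme postures the
effective lever arms drop to ~3 mm and the 8 N·m demanded by the 100 N
metacarpal load then requires flexor forces above 1 kN. The recruitment
criterion normalizes by strength, so the force *distribution* behaves like
a standard model even with inflated bounds; absolute magnitudes on this
geometry are not comparable to cadaver data (see Limitations).

Recruitment minimizes Σ (f_i/N_i)^p subject to torque equilibrium about
the FE and RUD axes and 0 ≤ f_i ≤ N_i. Default p = 3, configurable; a
min/max (LP) criterion is available. Implementation: an LP feasibility
check first (elastic HiGHS linear program; an infeasible demand raises an
error naming the violated axis), then a root find on the KKT stationarity
map in the torque multipliers, with an SLSQP fallback; axes that no muscle
can influence are dropped when their demand is negligible and rejected as
infeasible otherwise. The accepted solution must satisfy equilibrium to
1e-8 N·m. With a p-norm objective and nonnegativity there is no source of
co-contraction: for a single-axis demand, antagonists are exactly silent.

Joint reactions: the tendon force on the hand acts along the posed distal
path segment (insertion toward its via point); the reaction is the
negative sum of the external force and the muscle force vectors, reported
in the (global = forearm) frame.

### Contact and force-dependent kinematics

The contact law is volumetric elastic foundation: a pair's force magnitude
is PM·V_overlap, with the pressure module PM in N/m³ and V the penetration
volume of the two rigid surfaces, directed along the mean contact normal
so the surfaces are pushed apart. The N/m³ unit of PM makes volume the
natural conjugate quantity; the law is isolated behind `contact_force` so
an area×depth variant could be swapped in without touching the solver.
Default PM 0.6 × 10¹⁰ N/m³, with 1.2 × 10¹⁰ as the standard sensitivity
variant; force is exactly linear in both PM and volume, and pairs with
zero overlap contribute exactly zero force.

Penetration volumes: closed forms for sphere–sphere (lens) and
sphere–half-space (spherical cap); any pair involving a triangle mesh is
voxel-sampled (default pitch 0.2 mm) with point-in-solid membership by the
generalized winding number (Van Oosterom–Strackee solid angles, single
precision, bounding-sphere prefilter). Meshes must be watertight. At
0.2 mm pitch on a subdivision-4 icosphere the voxel estimate is within
~0.6% of the closed-form cap; subdivision-3 meshes carry a ~2–3%
polyhedral volume deficit of their own, which the mesh-path tests
tolerate explicitly.

FDK: the carpal block receives three translational free coordinates α_s
(the driver form Φ_s − α_s = 0 with zero time derivatives). The FDK
residual along each direction is the net force — axial external load plus
contact — projected on that direction; muscle forces do not enter these
translational balances in the fixture, where they are carried by the
intact kinematic constraints. The solver is a damped Newton iteration:
forward-difference Jacobian (step 1 µm), step clamp 0.5 mm, displacement
box ±2 mm, backtracking line search, convergence at max |residual| ≤
1e-6 N, at most 200 iterations. Outside contact the residual is locally
flat (zero Jacobian); the solver then relaxes along the unbalanced force
direction until a pair engages, after which Newton convergence is fast
(~7 iterations on the fixture). The reported resultant F_R is the scalar
sum of the pair force magnitudes — the aggregation under which the
canonical per-pair contact-force tables sum exactly to their printed
resultant.

## Synthetic fixture

Three pairs named Scaphoid-Radius, Lunate-Radius and Lunate-Ulna: carpal
spheres (radii 9, 5, 3.5 mm) seated over planar facets on the distal
radius/ulna with initial clearances 0, 0.1 and 0.3 mm. Sphere-on-plane
keeps every volume closed-form (exact oracles) while the same geometry is
exported as watertight icosphere STLs to exercise the mesh path. The facet
normals are tilted up to ~12° off the forearm axis so the three
translational FDK coordinates are statically determinate; a consequence is
that the equilibrium resultant slightly exceeds the axial load (141.9 vs
140 N at defaults) because the pair forces are not collinear. The size
ordering of the pair forces follows the anatomical pattern (scaphoid fossa
carries most), but per-pair magnitudes are geometry-specific and are not
meant to reproduce patient-derived values. `scale` applies geometric
similarity to every length, so overlap volumes scale cubically at
similarity-scaled displacements; `perturb_mm` (default 0) adds seeded
Gaussian jitter to the muscle points — with it at 0 the fixture is
identical for every seed, and for any fixed parameter set the generator is
a pure function (byte-identical STL output).

What the fixture does *not* emulate: real articular surface topography and
congruence, ligament restraint (no springs in v1), pronation–supination,
finger articulation, muscle wrapping over bone, activation dynamics.
Passing tests therefore demonstrate correctness of the mechanics and the
solvers, not anatomical fidelity of any specific wrist.

## Validation report

Packaged reference values: average peak and average mean muscle forces [N]
with SD for FE and RUD cycles from a cadaveric wrist-motion study with
servo-actuated tendons. The report lists simulated peak (max |f|) and mean
per muscle, the simulated/reference ratio and a flag outside the ±2 SD
band. The trend reported for comparable inverse-dynamics wrist simulations
(ECRB/ECRL/FCR/FCU above the cadaver values, ECU below) is carried as a
context column, never enforced. On the default synthetic geometry the
flexors overshoot by an order of magnitude under the 100 N load — expected
and documented, not a defect the report hides.

## Numerical choices and problem sizes

- Moment-arm finite difference 1e-4 rad (central); halving the step moves
  no arm by more than 1e-4 m on the default model.
- Recruitment tolerance 1e-8 N·m on the equilibrium residual; typical
  achieved residuals are 1e-15–1e-10 N·m.
- FDK: tolerance 1e-6 N, achieved ~1e-8 N on the fixture in 7 iterations.
- Motion sweeps in the tests use 9–21 samples per cycle and the examples
  13–21; the protocol waypoints are always included, so coarse grids still
  hit the extrema exactly. Voxel oracles run at 0.2 mm pitch on
  subdivision-4 icospheres (~11 s); coarser checks use subdivision 3.
- Degenerate inputs raise typed errors (`GeometryError`, `RangeError`,
  `InfeasibleLoadError`, `ConvergenceError`, `ValidationError`) rather
  than returning poisoned numbers.

## Known limitations

Quasi-static only; no ligaments, friction or viscoelasticity; no muscle
activation dynamics or nonlinear material laws; the five-finger hand is a
single segment; the external load keeps a fixed global direction rather
than riding with the hand (the alternative is one flag away in
`generalized_load` by posing the force, but the fixed-direction reading
matches the planar tier's decomposition); contact normals are averaged
per pair, so torque transfer through a contact patch is not resolved.
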
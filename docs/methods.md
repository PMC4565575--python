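# Methods

This note documents the models, numerical choices and limitations behind
`ectplan`. It is written for a reader who wants to judge what the package's
results do and do not show.

## Physical model

Pulse durations (100 µs) are long compared with tissue charge-relaxation
times, so each pulse is treated as electro-quasi-static: the potential φ
satisfies ∇·(σ∇φ) = 0 with Dirichlet values on the two active electrode
tips of the pair being pulsed (applied voltage / 0 V) and homogeneous
Neumann conditions on the outer boundary (the body far from the array is
approximated as insulated). Displacement currents, transient membrane
charging, Joule heating and electrode–tissue contact impedance are not
modelled.

Electroporation is represented through a field-dependent conductivity.
Each tissue has a baseline conductivity σ₀, a saturation factor k, and two
thresholds (V/cm): reversible (E_rev) and irreversible (E_irrev).
Conductivity is

σ(E) = σ₀ · [1 + (k − 1) · f((E − E_rev)/(E_irrev − E_rev))],

with f a raised-cosine ramp clipped to [0, 1] (a `linear` ramp is available
through `SolverConfig.ramp`; the exact transition shape is not strongly
constrained, so it is configurable and the smooth default is chosen for
fixed-point stability). σ(E) is monotone, equals σ₀ at or below E_rev and
σ₀·k at or above E_irrev.

### Default tissue properties

The defaults are literature-typical assumptions, not measured values, and
every one is configurable:

| tissue | σ₀ (S/m) | k | E_rev (V/cm) | E_irrev (V/cm) |
|--------|---------:|----:|----:|----:|
| normal soft tissue | 0.2 | 3.5 | 350 | 800 |
| tumor | 0.3 | 3.5 | 400 | 800 |
| blood / vessel | 0.7 | 3.5 | 350 | 800 |
| bone | 0.02 | 1.0 | 350 | 800 |

The 400/350 V/cm reversible thresholds follow the display convention used
for tumor vs normal tissue in ECT field maps; 800 V/cm is a conventional
irreversible threshold for 8 × 100 µs pulses. Bone is treated as
non-electroporating (k = 1).

## Discretization

The grid is the phantom's voxel grid (axis-aligned, no orientation
matrices; world position of a voxel center is origin + (index + ½)·spacing).
The operator is a 7-point finite-volume scheme with **harmonic-mean face
conductivities**, which keeps fluxes consistent across the strong σ jumps
at tissue interfaces (bone is 10× less conductive than soft tissue). The
resulting system is symmetric positive definite and solved by conjugate
gradients with a Jacobi preconditioner to a relative residual of 1e-8 —
deterministic, no randomized components. Fields are reported in V/cm
(internal solve in SI units).

### Sub-grid needle model

A 0.6 mm-radius needle is below the voxel size at practical spacings
(0.5–2 mm), and a naive rasterized Dirichlet electrode behaves like a rod
of a *grid-dependent* radius (≈0.2 h for a single-voxel column — the
classic well-model result), which makes predicted currents change by tens
of percent under refinement. Three corrections make the discrete electrode
behave like the physical needle:

1. **Radius calibration.** The equivalent radius r_num of the rasterized
   cross-section stencil is measured by a small 2-D Laplace solve (flux
   from the stencil at unit potential against a distant ring, inverted
   through Q = 2π/ln(R/r_num), cached per stencil shape). The lateral
   boundary faces of the electrode are then scaled by
   β = 2π / (2π + n_perim·ln(r_num/r_w)), the series-resistance match
   between the numerical and physical radius.
2. **Insulated proximal shaft.** The needle between skin entry and the
   start of the active tip is an insulated rod: its voxels are excluded
   from the domain (all adjacent faces removed) and inherit the nearest
   tissue potential for field evaluation.
3. **Distal cap.** Voxel-center rasterization extends the discrete rod
   half a voxel past the physical tip; the flat end-cap face is removed so
   the end length is not counted twice (a trocar tip tapers to a point and
   contributes little flux).

With these corrections the two-needle benchmark current changes by <1%
between 1.0 mm and 0.5 mm grids and sits ~10% above the infinite-medium
two-cylinder closed form πσL/arccosh(d/2a) — the excess being genuine 3-D
end spreading that the closed form excludes, partly offset by the insulated
outer boundary. The corrections apply to needles parallel to a grid axis
(within 1°) on in-plane-isotropic grids; oblique needles fall back to the
plain rasterized electrode.

### Nonlinear iteration

σ(E) feedback is resolved by damped fixed-point iteration: solve, evaluate
|E| (central differences), update σ toward σ(|E|) with damping 0.5, repeat
until the predicted current changes by <1e-3 (relative) or 50 iterations
(typically ~11 at clinical voltages). Intermediate iterations use a looser
inner CG tolerance (1e-5); after convergence one tight solve (1e-8) is done
so the reported potential and the anode/cathode charge balance are at full
accuracy (mismatch ~1e-8 on the benchmarks). σ never falls below its
baseline. By default pairs are solved independently (no pulse-history
memory); a `persistent_sigma` mode carries conductivity increases forward
as a floor, but whether real plans should model such memory is unresolved,
so it is off.

### Grid padding

Fixture grids are padded so the outer boundary is ≥1.5 array diameters from
any electrode; closer insulating boundaries visibly depress predicted
currents.

## Rasterization and collision checking

An electrode's active-tip mask is the set of voxels whose centers lie
within the needle radius of the active segment. On coarse grids a
sub-voxel needle can rasterize to nothing; callers that coarsen for speed
pass a floor of 0.75·spacing (≥ √2/2·h guarantees the axis cannot thread
between voxel centers), and the radius calibration above absorbs the
resulting stencil change. Collision checking (shaft vs vessel/bone over the
full entry→tip segment) inflates the radius to at least half the voxel
diagonal — deliberately conservative: a safety check must not miss a graze
because of voxel granularity.

## Coverage and robustness

Coverage uses the voxelwise **maximum** field over delivered pairs: a voxel
is treated as electroporated if any pulse exposed it above threshold.
Thresholds are inclusive (≥). The CVH reports the covered fraction of a
target mask as a function of threshold; it is nonincreasing and equals 1 at
threshold 0. The safety margin is the belt of *normal* tissue (vessel and
bone excluded) within a given Euclidean distance (spacing-aware distance
transform) of the tumor; the clinical convention is up to 5 mm.

Robustness re-solves the plan over a seeded ensemble: rigid array shifts
drawn uniformly in a sphere (default radius 1 mm — the navigation system's
placement accuracy scale) and a global conductivity scaling uniform in
±20%, 20 members by default, reporting min/mean/max tumor coverage at
E_rev. Members whose shifted electrodes leave the grid are flagged
infeasible and excluded with a warning. The ensemble perturbs geometry and
σ₀ only; threshold uncertainty (which dominates clinical robustness) can be
explored by editing the tissue table.

## Optimization

The objective of an admissible plan is
w₁·tumor_coverage(E_rev) + w₂·margin_coverage(E_rev) − w₃·overreach,
with weights (1, 0.5, 0.5) and overreach the fraction of non-margin normal
tissue above its irreversible threshold — cover the target, spare the rest.
Constraints: no vessel/bone collision, voltage bounds (500–1500 V), and a
device current cap (50 A — a placeholder for an unquantified generator
limit; configurable). The search is deliberately transparent rather than
clever: seeded random candidates for the array center (tumor centroid
±5 mm), then coordinate descent on insertion depth and the distinct voltage
levels in 50 V steps (or exhaustive enumeration over a user-supplied
voltage grid, which is also how the search is tested against brute force).
Candidate evaluation runs on a 2× coarsened grid; the winner is re-scored
at full resolution and both scores are reported. Ties break
lexicographically: higher tumor coverage, lower overreach, lower total
voltage. With fixed seed and configuration the search is bit-reproducible
and the best-so-far trace is nondecreasing by construction.

## Navigation export

Entry and tip of each needle are marked on a copy of the image volume by
setting the single containing voxel (floor((world − origin)/spacing)) to
intensity 3000 — no marker spheres. Planned insertion length is reported
per electrode because depth is not tracked by the guidance system and is
measured with a ruler. Placement error is the 3-D point-to-line distance
from an achieved entry to the planned trajectory, also expressed in pixels
of the (isotropic in-plane) image resolution; whether a 2-D in-plane
definition was intended is ambiguous, and the 3-D distance is the
conservative choice.

## Synthetic phantoms: what they do and do not show

The phantom generator reproduces the *geometric scale* of the treated case:
near-spherical lesions of 20.3/20.6 mm, 0.57 mm CT-like pixels (1–2 mm for
fast grids), a 4 mm-radius vessel 8 mm from the tumor surface, a bone slab
at the grid edge, the star array and the 1000/1200 V, 64-pulse protocol.
Vessel and bone placement is invented (chosen so at least one naive
approach direction collides, exercising the admissibility check); tissues
are homogeneous; lesions are perfect spheres; anatomy does not deform.
Passing tests on these phantoms validates the *machinery* — geometry,
solver, coverage arithmetic, search — not patient-specific accuracy:
real currents depend on irradiated-tissue properties and intra-operative
vessel displacement that no phantom captures, and the packaged
measured-vs-computed current table (errors −17% to +58%, RMSE 2.1/3.7 A)
is the honest reminder of that gap.

## Problem sizes

Default analyses run at 1 mm spacing (the case fixture is then 80×80×90
voxels; the full 8-pair nonlinear schedule solves in ~2–3 min on one core);
the two-needle benchmark runs at 0.5 mm (~6·10⁵ unknowns, seconds);
optimizer and robustness studies default to 2 mm grids. The native 0.57 mm
resolution is supported and simply scales the same machinery up.

## Known limitations

- No transient electric or thermal modelling; no pulse-train dynamics
  beyond the optional persistent-σ floor.
- Conductivities and thresholds are assumptions; predicted currents are
  validated against an analytic oracle and conservation, not against
  patient measurements.
- The optimizer explores parallel-array placements only (no per-needle
  angulation); multi-array plans are out of scope.
- DICOM and vendor navigation protocols are not implemented; volumes go
  through NIfTI/NRRD.
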
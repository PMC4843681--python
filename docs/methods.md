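# Methods

## The model

A perfused vessel is modelled as a line of spherical oxygen point sources
along its axis. Each point source obeys steady-state diffusion with uniform
volumetric consumption; with the boundary conditions that the partial
pressure and its radial gradient both vanish at the diffusion distance
`r_n`, the point solution is

    p_pt(r) = κ (r² + 2 r_n³ / r − 3 r_n²),   r ≤ r_n;   p_pt = 0 beyond,

which diverges like 1/r towards the source and is C¹ at `r_n`. All
physiological constants — diffusion coefficient D (~2×10⁻⁹ m²/s in tissue),
consumption rate a, per-length source strength s_L and the Henry's-law
conversion Ω — are mutually degenerate here and enter only through the
composite strength κ (mmHg/µm³). Integrating along the axis with
r = √(d² + z²) gives the closed-form line-source pressure at perpendicular
distance d, with axial limits clipped to ±z_m, z_m = √(r_n² − d²):

    G(z) = κ (d² z + z³/3 + 2 r_n³ asinh(z/d) − 3 r_n² z),
    p(d; z_a, z_b) = G(ẑ_b) − G(ẑ_a).

`asinh` is used rather than the equivalent logarithmic form; they are
identical to rounding.

### Calibration

A perfusion scenario fixes the wall pressure `p_o` of a reference capillary
(radius `r_o` = 5 µm) and its diffusion distance `r_n`; κ follows from
demanding `p(r_o) = p_o` for the effectively infinite reference vessel.
Defaults:

| scenario | p_o (mmHg) | r_n (µm) | interpretation |
|---|---|---|---|
| high | 40 | 150 | well-perfused, normal venous pressure |
| low  | 20 | 100 | poorly perfused chaotic tumour vasculature, high consumption |

### Radius scaling

A vessel of radius `r_v` under the same boundary condition pushes oxygen to
an effective diffusion distance `r_f` solving `p(r_v; r_f, κ) = p_o`, found
by Brent's method on the bracket [1.0001·r_v, 10·r_n] (the function is
strictly increasing in `r_f`, so the root is unique; xtol 1e-9 µm).
`r_f` is strictly increasing in `r_v` with `r_f(r_o) = r_n` by construction.

## The kernel engine

For each segment of length L: the unscaled kernel is the unit-strength
point profile with support `r_f(r_v)`; copies are placed at equidistant
points from one endpoint to the other inclusive (step L/round(L/spacing),
default spacing 1 µm) and summed at every voxel centre with the exact
radial formula (no precomputed stamp). The summed field is normalized by
`S_f = P_w / U_w`, where `U_w` is the unscaled sum at the continuous wall
evaluation point W — the segment midpoint offset perpendicular by `r_v`
(configurable) — and `P_w` is the finite-length wall pressure: `p_o` when
L/2 ≥ √(r_f² − r_v²) (W then receives its full contributing length),
otherwise the truncated line integral, which is lower. Network maps are the
voxel-wise sum of the per-segment scaled maps in input order; overlapping
supports add, and the resulting local overestimation where vessels crowd is
accepted, not corrected (an optional pressure cap is deliberately absent
from the default path).

Numerical choices:

* evaluation radii are floored at half a voxel, regularizing the 1/r
  divergence for voxels crossed by an axis;
* voxels whose perpendicular distance to the axis is < r_v within the
  axial extent (the lumen) are clamped to the segment's `P_w`:
  intravascular oxygen is outside the model, and the clamp keeps maps
  finite while matching the wall boundary condition. Lumen voxels are
  included in all statistics;
* the perpendicular direction for W is the axis crossed with the least
  aligned canonical basis vector — deterministic and well-conditioned for
  every orientation;
* default voxel size 2 µm (1 µm for validation work); refinement tests
  bound the spacing discretization at well under 0.5 % r.m.s.;
* contributions outside the grid are silently cropped; to be free of edge
  bias a target volume of size (X, Y, Z) needs vessel data out to
  (X + 2 r_f,max, Y + 2 r_f,max, Z + 2 r_f,max)
  (`required_context_volume`).

The wall evaluation offset deserves a note: normalizing at perpendicular
distance `r_f` from the midpoint is not meaningful — every point kernel's
support ends at `r_f`, so the unscaled field there is identically zero —
hence the default offset is the wall itself (`r_v`), which reproduces the
expected behaviour that a long well-perfused vessel reads 40 mmHg at its
wall. The offset is configurable for sensitivity studies.

A 200 µm vessel of radius 5 µm under the high calibration is *just short*
of the full-contribution length 2·√(r_f² − r_v²) = 299.83 µm: its wall
pressure is 39.67 mmHg, 0.8 % below p_o. A 400 µm vessel reads exactly
40 mmHg.

### Float precision

The closed form evaluates an antiderivative difference whose terms are
~10⁶ κ; for degenerate integration ranges that barely clip the support
edge the result loses relative precision to cancellation (float64), though
absolute accuracy stays at ~10⁻⁸ of the field scale. Tests compare against
adaptive quadrature at 1e-8 relative with an absolute floor at 1e-8 of the
full-length field.

## Statistics

Hypoxia: voxels with 0 ≤ p ≤ 2.5 mmHg. Anoxia: p = 0 within 1e-12 mmHg —
the kernel support is compact, so true zeros are exact. EF5 range: 0.8–10
mmHg, the binding window of the EF5 hypoxia stain. Histograms default to
1 mmHg bins from zero to the map maximum. The image-side statistic
`ef5_positive_fraction` thresholds masked pixels at mean + k·σ (k
configurable, default 1 — the threshold multiplier is a free parameter of
the staining protocol, not of the model).

## Simulated 2D histology

`flatten_slab` keeps every segment whose axis intersects the slab
z_center ± ΔW/2, *clips* it to the slab (a stain only reveals in-slab
endothelium; keeping whole vessels would overweight long croppable
segments), and projects the clipped geometry onto the central plane.
Segments crossing perpendicular to the plane flatten to near-points and
are retained with a 10⁻³ µm minimal length so they remain valid point-like
sources. The planar map then runs the identical 3D kernels and
normalization (using the clipped, flattened lengths) on a one-voxel-thick
grid whose voxel centres lie in the plane — a 2D analogue of the 3D
method, not re-derived 2D physics. `compare_slice` tabulates mean ± sd and
hypoxic/anoxic percentages for the true 3D slice and each ΔW.

On dense synthetic networks the thin-slab analogue shows the expected
sampling bias: as ΔW decreases, fewer vessels survive into the plane and
the hypoxic fraction estimate is non-decreasing (verified over 20 seeds).

## Finite-difference oracle

An independent check of the kernel maps: steady state ∇²p = M with uniform
consumption M (mmHg/µm², diffusion coefficient absorbed), Dirichlet
pressure at vessel voxels, zero-flux outer boundaries, and p ≥ 0 enforced
by projection — a free-boundary (linear-complementarity) problem mirroring
the analytic model's finite diffusion distance. The solver is projected
red–black SOR over the 7-point Laplacian; an active-set sparse-LU
acceleration jumps to the exact discrete solution first (alternating
restricted linear solves with active-set updates), after which the SOR
sweeps certify the max-update < tol criterion (default 1e-6 mmHg).
Domains are capped at 200³ voxels; this is a validation oracle, not a
production solver.

M is not measurable from histology and is the numerical method's free
parameter. Two calibrations:

* `fit_consumption`: bisection on the monotone map M → zero-pressure
  distance until the reference vessel's reach equals `r_n`. The reach is
  measured sub-voxel by extrapolating √p (locally linear at a quadratic
  free boundary) through the last two positive voxels, which keeps the fit
  stable (±2 %) under 2 → 1 µm refinement.
* `fit_consumption_to_map`: golden-section search for the M minimizing the
  r.m.s. discrepancy against a reference kernel map — the calibration used
  for the kernel-vs-FD comparison, since agreement is exactly what the
  free parameter is fitted for. Matching the reach to `r_n` instead leaves
  an r.m.s. of ~0.6 mmHg for the isolated reference vessel: a uniform-M
  cylindrical solution that reaches exactly `r_n` necessarily sits above
  the line-source profile in the mid-range (the line-source's implied
  consumption 12 κ √(r_n² − d²) falls off with distance where uniform M
  cannot).

The isolated-vessel comparison (r.m.s. ≤ 0.2 mmHg at 1 µm) uses a vessel
passing entirely through the FD domain with zero-flux z boundaries, making
the solution z-invariant — the infinite-vessel limit on a one-voxel-thick
311×311 µm plane (≈10⁵ voxels, well under the cap). The mid-plane of a
kernel-mapped segment longer than ~300 µm receives full contributions at
every in-plane distance, so the two fields are directly comparable; the
r.m.s. is taken over all shared voxels (lumen voxels agree by
construction: Dirichlet p_o versus clamp P_w = p_o).

## Synthetic networks

`random_network` (NumPy PCG64, seeded, platform-stable; coordinates
rounded to 1e-6 µm) draws straight segments inside a box: radii log-uniform
(vessel calibres are roughly log-distributed) in 1–50 µm by default,
lengths uniform in 10–200 µm, and with probability `tortuosity` (default
0.5) a segment continues the previous one with a perturbed direction,
forming tortuous polyline paths. Presets emulate the *scale* of real
tumour stacks — `rat`: 104 segments in 555×525×215 µm; `mouse`: 357
segments in 425×425×272 µm — plus `single`, the canonical 200 µm, 5 µm
radius vessel centred in a 400 µm box. The generator reproduces segment
counts, size ranges and volumes, not real vascular topology (no branching
statistics, Strahler orders, or spatial correlation); conclusions drawn
from it concern the mapping machinery and sampling geometry, not the
biology of any particular tumour. The bias-trend checks run at 4 µm voxels
and 4 µm kernel spacing — the trend is a coarse ordering property that
refinement tests show is insensitive to these resolutions.

## Known limitations

* No intravascular haemodynamics: wall pressure is uniform along a
  segment. The longitudinal gradient utility (`longitudinal_drop`,
  default 0.07 ± 0.04 mmHg/µm) only *reports* the estimated drop — e.g.
  8.82 ± 5.04 mmHg over a 126 µm vessel — and is never applied inside
  maps, since flow direction is not an input.
* Uniform consumption; no oxygen–haemoglobin dissociation; no time
  dependence.
* Overlapping vessels superpose, locally overestimating pressure.
* Straight-segment geometry only; curved vessels must be supplied as
  polylines.
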
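# Methods

This note records the model, the measurement definitions, the numerical
choices, and what the synthetic data do and do not emulate.

## Mechanical model

**Lattice.** The epithelium is a double layer of Hookean springs. The outer
layer is an icosahedron subdivided `f` times per edge and projected to a
sphere of radius `R` (vertex count `10f²+2`), cropped to a cap by the vertex
polar-angle filter (faces kept only when all three vertices survive). The
inner layer is the same mesh rescaled to radius `R−h`; cross-layer springs
join each vertex to its own copy and to the copies of its in-layer
neighbours (1 vertical + 6 diagonals). Regular vertices therefore carry 13
springs, the icosahedral point defects 11. All rest lengths equal the
as-built lengths, so the initial state is exactly stress-free. The reference
geometry is `f = 30`, `R = 77.66 μm` (mean edge 3.11 μm), cap half-angle
`θ_M = ½(w_DV + 2 w_ODV)/R = 49.63°` from the tissue dimensions
`w_DV = 15 μm`, `w_ODV = 59.77 μm`, and `h = 0.1 R`. `build_from_surface`
applies the identical layering rule to an arbitrary open mesh by offsetting
along the inward vertex normals (it warns when the offset exceeds the local
radius of curvature, estimated per edge as `|Δv|/|Δn̂|`).

**Regional frames.** Two origin points `O_D`, `O_V` sit at polar angle
`θ_DV/2` on either side of the apex (default `θ_DV = w_DV/R`, configurable).
The boundary band (DVB) is the strip of in-surface half-width `w_DV/2`
around the great circle separating them; the rest of the cap splits into the
two flanking halves. In each half, `ē₁` is the tangent-projected direction
from the origin point and the scalar coordinate `r` is geodesic distance
normalised by the regional maximum; in the band, the transversal segment
`O_D–O_V` is the origin line for `ρ` and `ē₁` points away from it (i.e.
along the band). `ē₃` is the surface normal and `ē₂ = ē₃×ē₁`. At the origin
vertices `ē₁` is undefined; those vertices copy the nearest regular frame and
their anisotropic factor is forced to 1. With `w_DV = 0` everything collapses
to a single radial chart with `r = θ/θ_M`.

**Programming and relaxation.** The spontaneous strain tensor is assembled
as `T = I + (λλ̃−1) ē₁⊗ē₁ + (λ/λ̃−1) ē₂⊗ē₂` — algebraically the spectral form
with `λ₃₃ = 1` (no thickness strain), written so that the identity program is
bitwise exact. Per spring, `T` is averaged over the two endpoints in lab
coordinates and the target rest length is `δ_F = ‖T·ΔX̄‖` on the stress-free
reference vectors, for both layers alike. Rest lengths ramp linearly over
`T_F = 5` quasi-static steps (runs with `T_F = 1` are indistinguishable in
our tests, matching the reference behaviour); within each step, positions
follow synchronous overdamped gradient descent
`x̄ ← x̄ − dτ(k/γ) Σ_a (δ−δ_T) δ̂` with `dτ·k/γ = 0.01`, stopping when the mean
per-step displacement drops below `10⁻⁹ R`. `k = γ = 1` (only the product
matters). The iteration has no randomness and a fixed order, so outputs are
bitwise reproducible. Rigid-body drift is not constrained; analyses either
use curvature (drift-invariant) or fit spheres/align curves post hoc.

**Deformation measurement.** The per-vertex deformation gradient `F̄̄`
minimises `Σ_a ‖F̄̄ X̄ᵃ − x̄ᵃ‖²` over the vertex's springs (reference = initial
stress-free configuration), an ordinary least-squares problem solved per
spatial component; rank-deficient neighbourhoods are flagged and given the
pseudo-inverse solution. In the local frame, the in-plane 2×2 block is
polar-decomposed and the rotation factor discarded before reading the
stretch diagonal — this coincides with reading `F_rr`, `F_φφ` directly
whenever the block is symmetric, and makes rigid rotations decompose to
unity. The isotropic and anisotropic components default to the square-root
convention `F = √(F_rr F_φφ)`, `F̃ = √(F_rr/F_φφ)`, which composes
multiplicatively with the `(λ, λ̃)` decomposition; the plain-product
convention is available as `convention="printed"`. Residual strain is
`λ̄̄_res = F̄̄ λ̄̄⁻¹`.

## Curvature of cross sections

Sections of the top layer record the intersections of in-layer springs with
a plane (vertices lying exactly on the plane count once), ordered by the
horizontal coordinate. Arc length is the cumulative polyline length offset
to zero at the curve's mid-length; alignment translates the midpoint to the
origin, rotates the centre of mass onto the y-axis and enforces a
counterclockwise traversal (positive net turning), under which a dome has
`κ = +1/R`. Curvature `κ = (x′y″−y′x″)/(x′²+y′²)^{3/2}` is evaluated on
least-squares cubic splines of `x(s)` and `y(s)` with five fixed interior
knots — the midpoint and the points at one half and three quarters of the
half-length on either side. Fixing the knots makes the fit parameter-free
(no smoothing weight to choose); its fidelity degrades for curves whose
tangent angle swings far between knots, so oracle tolerances (1% on a
circle, 2% at a parabola vertex) hold for arcs up to roughly 60° of turning.
Averages across curves are taken every 5 μm on the common arc-length
support; curvature change is compared on 40 positions of the normalised
[0, 1] coordinate, with the mean arc length re-attached per position.

## Cell-network quantification

Cell centroid, area and normal follow the fan construction
`n̄ᵢ = (v̄ᵢ₊₁−v̄ᵢ)×(R̄−v̄ᵢ)`: `A = ½Σ‖n̄ᵢ‖`, normal = normalised `Σ n̄ᵢ`. Each
cell is triangulated against its centroid; every triangle is the image of a
unit-area equilateral reference triangle under a shape tensor whose planar
part decomposes into area, elongation and in-plane rotation. The elongation
magnitude is `‖Q‖ = arcsinh(‖S_ts‖/√(‖S_ta‖²−‖S_ts‖²))` with the coefficient
norm `‖M‖ = √(½ tr MᵀM)` — the unique norm under which `‖Q‖` equals the SVD
log-aspect `½ ln(σ₁/σ₂)` exactly. The axis angle is read from the
traceless-symmetric part *after* removing the in-plane rotation `θ_z`
carried by the trace-antisymmetric part (the ts part carries `2φ−θ_z`);
without this correction the lab-frame tensor would not be rotation
covariant. Cell tensors are area-weighted means over the triangles;
directional components contract twice with the tangent-projected direction
from the regional origin (for origin lines, from the averaged position of
the nearest origin cells).

**Topological coordinates.** Cell adjacency (shared bonds) defines the
graph; `k` is multi-source BFS distance from the origin set. The outDVB
origin is the band-adjacent cell metrically closest to the mean position of
the cells maximally distant from the tissue margin (ties resolve to the
lowest cell index); the band origin line is, at larval-type stages, the
cells within `1.2·√(A_cell/π)` of the segment joining the two centre cells,
and at pupal-type stages the first row on the distal margin. The metric
coordinate `r` (or `ρ`) is the ring-averaged shortest path length along cell
centres, normalised by the outermost ring's mean. Networks are treated as
division-free between stages; unreachable cells are flagged and excluded.

**Observed strains.** Bins are the earlier stage's rings, matched at the
later stage through the cumulative cell count `N`; later-stage per-ring
quantities are integrated piecewise-constantly over the matched count range.
`λ_A* = √(A₂/A₁)` on mean areas; `λ̃_Q* = L₂/L₁` on area-weighted ring means
of `L = exp(sign(Q_rr)·‖Q‖)`; `λ̃_R* = k₂[N(k)] − k₂[N(k−1)]` with the
continuous ring index interpolated through `(N(j), j)` and anchored at
`k(0) = −1` (so the identity transition gives exactly 1 per bin);
`λ̃* = λ̃_Q* λ̃_R*`. Terminal bins beyond the later stage's total are dropped
with a warning, never extrapolated. Bootstrap CIs resample cells within
(stage, region, bin) — 10,000 repeats, percentile 95% intervals, cell-area
weights for elongation; per-specimen resampling is available through the
same interface by passing specimen-level values. A ring-averaged
`|Q_{rφ}| > 0.05` triggers a warning that the elongation axes do not align
with the coordinate axes.

## Synthetic epithelia

The ring-structured generator tiles a cap with one apex cell plus annular
rings of programmable cell counts and boundary radii. Cells are true
junction polygons (no extra collinear vertices), as segmentation pipelines
emit. Stage transitions operate on the layout: an area schedule rescales the
cumulative area attached to each matched count range (so the matched-bin
area ratio is the prescribed factor exactly); a rearrangement schedule
re-partitions the cumulative counts into new rings (total conserved,
division-free), with the ground-truth `λ̃_R*` given by the same
ring-index-interpolation arithmetic applied to the input count tables. The
ground-truth `λ̃_Q*` is the rectangle-equivalent aspect scale
`L = √(radial/azimuthal extent)` integrated over the matched span — an
analytic approximation that agrees with the triangle method to ~3% for the
trapezoidal cells of moderate schedules; harsher schedules that leave inner
rings with very few, strongly curved cells degrade this agreement, which is
why the standard ~2000-cell stage pairs keep rings of at least six cells and
stretch ring indices by 1.3 outside ring 6 (within the range of
rearrangement strains observed in everting tissue). A Lloyd-relaxed
spherical-Voronoi generator provides organic-looking tessellations (seeded,
deterministic; density-graded sampling with damped relaxation when an area
gradient is requested) for fixtures where polygonal disorder matters and
exact ground truth does not.

What passing these tests shows: the measurement stack recovers programmed
area, rearrangement and elongation strains from ideal polygonal geometry
with exact adjacency. What it does not show: robustness to segmentation
errors, curved bonds, cell divisions/extrusions, imaging noise, or
out-of-plane junction scatter — real tissues have all of these.

## Numerical choices and degenerate inputs

* Relaxation guard: 5×10⁶ inner iterations; non-convergence returns the
  partial state with `converged=False`.
* Collinear cell loops yield zero area and a zero normal (flagged by the
  caller); zero-area triangles and orientation-reversing triangle maps raise.
* Duplicate consecutive curve points are dropped with a warning; curves with
  fewer than 8 points fall back to finite-difference curvature (warned).
* The spherical-cap crop rejects empty, face-free or disconnected results.
* Origin-cell ties and equidistant origin candidates resolve to the lowest
  cell index, deterministically.
* The cap-placement replicate option rotates a seeded random axis onto the
  crop pole; the default is a single placement (tests use ≤ 3), since
  replicate variability was found to be small relative to the effects under
  study.

## Known limitations

* A uniform in-plane growth program is not perfectly compatible with an
  unchanged thickness: the free rim develops a boundary layer in which the
  residual anisotropy deviates at the 10⁻³ level and the rim curvature
  departs from the compatible sphere. Interior (apex-region) quantities are
  the meaningful observables for such programs.
* The five-knot section spline limits curvature fidelity for strongly curved
  or strongly asymmetric sections; the curvature-change subtraction cancels
  most of the systematic bias between stages of similar extent.
* Frames on arbitrary (non-cap) surfaces use Euclidean stand-ins where the
  cap uses exact geodesics; for gently curved tissues the difference is
  below the measurement noise, but strongly folded surfaces would need true
  geodesic distances.
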
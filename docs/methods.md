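# Methods

This note records the model equations, the numerical choices behind them,
and what the synthetic benchmarks do and do not demonstrate.

## Lattice Boltzmann core

The solver evolves D3Q19 particle distributions `f_i(x, t)` with the
two-step collide/stream update. Collision is multiple-relaxation-time
(MRT): `f' = f − M⁻¹S(m − m_eq)` with the standard orthogonal
(d'Humières-type) moment basis built programmatically from the velocity
set, `m_eq = M f_eq`, and the second-order athermal equilibrium

    f_i^eq = w_i ρ (1 + 3 c_i·u + 9/2 (c_i·u)² − 3/2 u²).

Computing `m_eq` as `M f_eq` (rather than a separate closed form) makes
the operator collapse *exactly* onto the BGK update when every
non-conserved rate equals `1/τ`, which is how the BGK oracle equivalence
is tested. In production the operator is applied as `f + B(f_eq − f)` with
the constant matrix `B = M⁻¹SM` (half the flops of the two-matrix form).

**Relaxation rates.** The shear moments relax at `s_ν = 1/τ` with
`τ = 3ν_lbm + ½`. The non-hydrodynamic even rates keep commonly published
values (`s_e = 1.19`, `s_ε = s_π = 1.4`). For the *odd* energy-flux
moments we use a two-relaxation-time-style pairing
`(1/s_ν − ½)(1/s_q − ½) = Λ` with `Λ = 0.005` by default. Near the
viscosity floor (`τ ≈ 0.503`) the no-slip wall position of bounce-back
schemes otherwise drifts with viscosity; the pairing removes most of that
drift. Λ was calibrated once on the resolved Poiseuille/Womersley pipe
benchmarks (profile L2, pressure gradient and wall shear simultaneously);
it is exposed in `make_mrt(magic=...)`. The third-order odd moments are
*not* paired: relaxing them as slowly as the pairing suggests destabilizes
curved walls near the viscosity floor, so they keep `s_m = 1.98`. All
rates are configurable.

**Units.** Physical↔lattice conversion uses the scale factors δx, δt and
δm = ρδx³ (lattice density 1); `c_s² = 1/3`; pressure is reported as the
gauge `c_s²(ρ_lbm − 1)` converted by `δm/(δx δt²)`. Everything runs in
double precision.

## Boundaries

**Walls and inlets** use the interpolated (Bouzidi-type) bounce-back on
each cut link with wall fraction `q = φ(x)/(φ(x) − φ(x+c_i))`:

    q < ½ :  f_ī(x,t+1) = 2q f̂_i(x) + (1−2q) f̂_i(x−c_i) + α_i c_ī·u_w
    q ≥ ½ :  f_ī(x,t+1) = f̂_i(x)/(2q) + (2q−1)/(2q) f̂_ī(x) + α_i c_ī·u_w/(2q)

with `α_i = 2w_iρ₀/c_s²`. Both branches reduce to plain bounce-back at
`q = ½`, `u_w = 0`; the moving-wall source is the classic correction
there. One-node-thick regions (no upstream neighbour for the q < ½ form)
fall back to the q = ½ form; the preprocessing counts such links.

**Inlet flow delivery.** A flat (plug) profile `u_w = Q(t)/A · n̂` is
imposed on every inlet-crossing link. Two corrections make the *delivered*
flow match the prescribed waveform: (i) the plug speed is normalized by
the ratio of the ideal to the actual link-sum of the bounce-back mass
source (rim nodes lose part of their stencil to wall links — a first-order
staircase deficit of 2–8 % at 8–15 nodes/diameter, converging away with
resolution); (ii) a slow multiplicative servo compares the mass flux the
streaming step actually transports across a control plane three cells
inside the inlet with the target during the first cycles and trims the
residual (≲2 %, mostly rim leakage the link-sum cannot see), then freezes
before the collected cycle so the analyzed physics sees a fixed inflow.
Both are deterministic; the delivered steady flow is then accurate to
~0.3 %.

**Outlets** impose a zero gauge pressure by non-equilibrium extrapolation:
all 19 populations are replaced by
`f_eq(ρ_target, u_nb) + (I − Ω)(f − f_eq)(x_nb)` with the neighbour chosen
along the discrete direction best aligned with the inward patch normal
(rim outlet nodes chain through an already-resolved outlet neighbour).
Outflow nodes do not stream; their values are wholly replaced each step.

**Update schedule.** collide (all nodes) → stream with bounce-back (all
non-outlet fluid nodes) → outlet replacement. Initial state is
`f = f_eq(1, 0)` everywhere; an optional half-cosine inflow ramp
suppresses the start-up water hammer (default off; the synthetic
benchmarks use 10–70 ms).

## Voxelization

Node `x_ijk = origin + (i,j,k)δx`, origin at the mesh bounding box minus
3.5 cells — the extra half cell keeps axis-aligned planar patches (inlet
caps) from coinciding with node planes, where cut links would degenerate
to `q = 0`; a node numerically *on* the surface (|φ| < 10⁻⁹δx) is snapped
to the solid side for the same reason (the adjacent fluid link then
carries q → 1, which the q ≥ ½ branch handles as a stable average).

Exact signed point-to-triangle distances (angle-weighted pseudo-normal
sign) are computed only within ±2δx of the surface; outside the band only
the sign is propagated (connected components adjacent to the negative/
positive band, grid-edge components positive) with a sentinel magnitude.
Labels follow the strict sequential priority (inlet/outlet → wall → bulk →
solid) from segment-triangle intersection tests of every sign-crossing
link; numerically tied (grazing) hits resolve to the opening tag so that
triangle ordering cannot change labels. Links whose segment intersects no
triangle (floating-point grazing) fall back to the nearest-triangle tag
within 1.5δx, else the geometry is declared inconsistent.

## Wall shear stress

The deviatoric stress is reconstructed from non-equilibrium moments,
`σ = −(1 − s_ν/2)(Π^neq − tr/3 I)`, `Π^neq = Σ c_i c_i (f_i − f_i^eq)` —
no velocity differencing. The traction `σ·n̂` (normal from the nearest
surface triangle) is projected tangentially. Because the wall-adjacent
node's own non-equilibrium moments carry the bounce-back closure error
(~1.5δx deep), the production estimate fits the tangential traction
linearly over interior nodes 1.6–4.6δx along the inward normal (within a
1.5δx-radius cylinder) and evaluates the fit at the surface; thin regions
fall back to two-point extrapolation, then to the node value. On the
resolved Poiseuille pipe this recovers `4μQ/πR³` to ~1 %.

## 1D reduced-order model

MacCormack (predictor/corrector) on `[A, q]` per centerline segment with
`α = 4/3`, `K_R = −8πν` (parabolic profile), tube law
`p = p₀ + (4Eh/3r₀)(1 − √(A₀/A))`, and stiffness set so the wave speed is
~120 m/s — numerically rigid, area excursions ~10⁻⁵. Inlet: prescribed
`q = Q(t)` with pressure from the backward characteristic; leaves:
`p = 0` with flow from the forward characteristic; bifurcations: flow and
total-pressure (`p + ρ(q/A)²/2`) continuity solved by Newton on
*linearized* characteristics — exact in the rigid limit the model is run
in. CFL is handled internally (the user never sees a time step); the
inflow ramps over the first 10 % of a period because the rigid network
would otherwise carry the start-up water-hammer wave for many transit
times. The ROM's only product is the peak-velocity estimate
`u_max = max 2q/A`, accurate to a few percent on the tube benchmark.

Centerlines: minimum-cost paths (inlet→outlets) over the interior voxel
graph of a provisional coarse grid, with weight `δx/(d_wall + δx/2)²`
plus a small length penalty; paths sharing a prefix merge into a segment
tree. Polylines are resampled, smoothed (full-window moving average), and
re-centered by maximizing the *exact* wall distance in the normal plane
(pattern search), giving sub-voxel radii (min-diameter error ~1 % on the
stenosis benchmark). Cross-sectional areas come from plane-mesh
intersection loops (shoelace), falling back to `πr₀²` for oblique cuts.

## Resolution selection and refinement

`δx* = u_lim ν/(ν_min u_max)` at the wedge intersection; the initial
(ROM-based) plan is coarsened by 20 % (`δx ← 1.2 δx*`) for speed —
deliberately risking a refinement or two — then clamped to
`δx ≤ D_min/15` with `D_min` from the centerline radii; `δt` sits 1 % above
the viscosity floor. Thresholds `u_lim = 0.15`, `ν_min = 10⁻³` are strict
subsets of the published stability limits (0.19, 2.54×10⁻³). The running
peak lattice velocity (actively evolved nodes only — outflow rows are BC
copies) is checked every `monitor_every` steps; on a crossing the plan is
recomputed from the observed velocity inflated by 1.05 *and projected to
the waveform peak* by the flow-rate ratio `Q_peak/Q(t_obs)` (clamped to
[1, 2]). Without the projection a crossing during the systolic rise sizes
the grid to the instantaneous rather than the peak velocity and the loop
restarts once per crossing; with it, one to three restarts suffice even
when the initial estimate is forced ten times too low. Restart is always
from t = 0 on a freshly built grid, so an interrupted-and-refined run is
bit-identical to a fresh run at the final plan.

## Synthetic benchmarks — what they show and what they do not

The fixtures mirror the cerebral regime: radii 0.75–3 mm, ν = 4 mm²/s,
ρ = 1000 kg/m³, so the autotuned δx lands at 40–270 µm depending on the
flow. Problem sizes were chosen so the full suite solves 10⁴–10⁵ fluid
nodes for 10⁴–10⁵ steps per case:

* steady pipe, Re = 20, 15 nodes/diameter — profile, pressure drop, wall
  shear, flux balance against closed forms;
* pulsatile pipe, two-harmonic waveform, period 0.2 s (Womersley number
  α ≈ 5.6, physiological) — velocity series against the analytic
  solution over one period;
* long-throat stenosis (severity 0.4) driven just past the velocity
  ceiling with the estimate forced 10× low — the refinement loop. Note
  that the ceiling-crossing regime *implies* a throat Reynolds number
  ≥ u_lim·15/ν_min ≈ 2250 whatever the geometry, so this scenario is
  intrinsically a fast-jet case; a gentle (quasi-Poiseuille) throat keeps
  the peak velocity deterministic.

They do not exercise: irregular patient anatomy (staircase statistics on
smooth analytic shapes are friendlier), outflow division among competing
branches, non-Newtonian rheology, wall compliance, or cycle periods at
the physiological 1 s scale for the refinement case (its compressed cycle
makes unsteady-inertia effects relatively larger than in vivo).

## Degenerate inputs and tie-breaks

Non-watertight meshes are rejected naming open edges; a δx too coarse to
resolve the lumen raises a geometry error ("no interior nodes"); equal
point-to-triangle distances resolve to the lower triangle index (after
the tolerance-tie on distance), grazing segment hits to the opening tag;
`ρ ≤ 0` or non-finite moments abort with a stability diagnostic naming
the step, min density and max velocity; more than `max_refinements`
(default 5) restarts abort likewise.

## Known limitations

* The inlet delivers the prescribed flow to ~1 %; sub-percent flow
  accuracy would need an outlet-side flux controller as well.
* WSS at sharp corners (cap rims) uses the fallback estimators and is
  noisier than on smooth wall; dome averages are robust, pointwise maps
  less so.
* The acoustic (compressible) propagation delay of the explicit scheme is
  not compensated; at the benchmark scales it is ≤ 2 % of a period.
* Junctions with more than two daughters are not supported by the 1D
  solver (split the mesh or supply centerlines).
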
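# Methods

## Physical model and assumptions

The simulator advances N independent point particles in a 2D plane assumed to
lie on the centerlines of all vessels (a top–down view; gravity and buoyancy
act out of plane and are excluded). Two forces act: the magnetic gradient
force on the chain's volume-equivalent sphere and Stokes drag on the
individual particle. The semi-static assumption removes inertia: at these
scales the viscous relaxation time (ρ_p d²/18η ~ 10⁻⁹ s) is far below the
0.002 s timestep, so within every minor step the drag balances the applied
force exactly and the particle moves at

    v_p = v_f + F_mag / (3πηd_drag).

Particles do not interact: the swarm is a population of identical
non-coupled trajectories differing only in their seeded starting points, with
the chain model (n, D_eq, V_eq) entering as a shared effective parameter.
Chain formation/breakup dynamics, magnetic torque and dipole–dipole coupling
are out of scope.

### Force model

* `F = V_eq · M_m · ρ · ∇B`. The commanded "magnetic gradient" in mT/m is
  treated as a flux-density gradient, converted to T/m; because the emu/g
  magnetization (≡ A·m²/kg) is converted to volumetric magnetization by
  multiplying with the mass density, µ₀ cancels and never appears
  numerically. With stock parameters the force at 1000 mT/m is 1.29×10⁻¹² N.
* `M_m(B) = 1 + 19(10B)^0.16`, B in mT. This form reproduces the published
  operating point (33.74 emu/g at 3 mT) to all printed digits; it is the
  model's definition here, valid only in the low-field (unsaturated) regime.
* `D_eq = d(3n)^(1/3)`. Note this equals the volume-equivalent diameter of a
  cylinder of diameter d and height n·d times 2^(1/3); the form is chosen to
  reproduce the platform's published D_eq/V_eq values (2.48 µm,
  7.95×10⁻¹⁸ m³ at d = 75 nm, n = 12000), which take precedence over the
  idealized cylinder algebra.
* Chain length n(B): only one anchor is characterized (12000 at 3 mT). The
  default rule is linear through it, n = round(4000·B), clamped to
  [1, 50000]; the clamp ceiling is an arbitrary guard. The rule is a
  pluggable hook (`chain_length_for_field(rule=...)`) so a measured
  chain-length curve can be substituted.
* Drag diameter: Stokes law is applied with the individual particle diameter
  d (75 nm) by default, which puts the magnetic drift at 1.82 mm/s at
  1000 mT/m against channel flows of 5–60 mm/s — the regime in which the
  steering results are physically coherent. A `drag_diameter_mode` switch
  applies D_eq instead for sensitivity studies (drift ×33, qualitatively
  different regime).

## Geometry

Networks are unions of constant-width straight segments; the navigable lumen
is the union of their rectangles with junction interiors filled (shapely
union backs area/boundary queries; containment uses the exact per-segment
rectangle test, which is identical on the union and vectorizes over the
swarm). Boundary points count as inside, so a particle resting on a wall is
valid. The default comb network reconstructs the study layout from its
printed dimensions (1 mm width, 5 mm segment length, one inlet, five
outlets); exact junction spacing and branch angles were not printed, so the
comb uses uniform spacing and 90° downward branches, both configurable, and
arbitrary networks load from a JSON schema. Outlet gates are the open end
edges of terminal vessels; a crossing is a directed segment–segment
intersection test, robust at any timestep.

## Flow field

The CFD stage is replaced by an analytic stand-in that preserves the lookup
table architecture: a slit-Poiseuille resistor-network solve (conductance
w³/12ηL per unit depth — the 2D slit law, consistent with a planar model,
rather than the w⁴ circular-pipe law), parabolic transverse profiles
v(s) = v_c(1 − (2s/w)²), inlet inflow Q = (2/3)v_c·w, all outlets at one
reference pressure. The lookup table samples a rectangular grid over the
lumen (default spacing 75 µm → 7976 in-lumen points for the default
network); grid points covered by several segments (junctions) take the
nearest centerline's profile — no recirculation detail is attempted, since
the table mechanism rather than CFD fidelity is the modelling target.
Runtime sampling is nearest-neighbor (bilinear interpolation was considered
and rejected as unstated in the reference architecture); queries outside the
lumen return zero velocity. A regular-grid index answers most queries in
O(1) — the axis-wise rounded grid node is provably the Euclidean-nearest
node, so when it carries a sample it is the exact nearest neighbor — with a
KD-tree fallback near walls; the result is bit-identical to a brute-force
scan, which the tests assert. Externally computed fields (e.g. a CFD export)
can be substituted through the CSV interchange path.

## Integration, collisions, timing

One major step = read policy input once → cap it with the gradient limit
(pure scaling of the unit-disc input, so ‖∇B‖ ≤ limit always) → 25 minor
steps with all forces frozen → one log record. dt_minor is defined as
major_period / minors_per_major (0.05/25 = 0.002 s, exact in floating
point); after each major step the clock is snapped to the exact multiple of
the major period to keep long runs free of accumulation drift.

A proposed step leaving the lumen is resolved by bisecting the crossing
parameter until the bracket is below 1 nm (robust at junction corners, where
an exact edge-intersection test is ambiguous), then reflecting the residual
displacement and velocity about the wall tangent at the contact's nearest
boundary edge. With wall friction µ = 0 (default — no friction coefficient
was characterized) the reflection is elastic and preserves speed exactly;
otherwise the tangential components are attenuated by (1 − µ), a minimal
contact model that avoids inventing a normal-force scale. A particle still
outside after 4 reflection attempts (a corner trap) is marked stuck at its
last wall contact. Exit checks precede collision checks, so gate crossings
are never misclassified as wall hits. Exited and stuck particles are removed
from further computation.

The batch loop is free-running (no wall-clock pacing); trajectories are
timer-independent by construction, and a fixed seed plus a fixed policy
reproduces a run bit-identically — the replay policy closes this loop by
re-driving a run from its own log.

## Steering policies

The human operator cannot be reproduced; the quantitative stand-in is a
deterministic waypoint autopilot. It plans waypoints along the inlet→goal
path, offsetting each leg toward the goal-side wall — the side away from
competing branch mouths — by 0.7·(w/2) = 0.35 mm by default. Because the
magnetic drift is an order of magnitude below the flow, the emitted input is
not a pursuit vector toward the waypoint (which would spend authority along
the flow axis); it blends a saturated cross-track correction toward the
offset waypoint line (weight 1, saturating at 0.1 mm error) with a small
along-track cruise term (weight 0.35), normalized to the unit disc. This is
the strategy an experienced operator converges on: push across the channel,
let the flow carry downstream. Control acts on the active-swarm centroid,
matching the single global gradient actuation. The capture radius (0.5 mm)
advances the plan leg; leg selection is a pure function of the centroid
position, so the policy is stateless. Gain, offsets, radius and weights are
exposed.

Seeding: the reference platform shows its start regions only as small squares
near the inlet. The defaults place a 0.6 mm square (comparable to the 1 mm
channel width) centered on the inlet-segment centerline 1 mm downstream of
the inlet; split mode puts half the swarm in a matching square 1 mm past the
first junction. The clump position follows from a lift-off feasibility
argument made before any acceptance run: a particle seeded at the bottom of
the square (y = −0.3 mm) and lifted at the 1000 mT/m drift (1.8 mm/s) while
advected at up to 20 mm/s clears the centerline about 3.6 mm downstream, so
the square must sit within ~1.5 mm of the inlet for the whole swarm to be in
the safe upper half-channel before the first branch-capture cone at 5 mm.

## Experiments and validation utilities

Sweeps repeat seeded runs (default 10, sample SD with ddof = 1; SD is
reported as-is even when mean ± SD exceeds 100%) over flow velocity,
gradient limit or seed mode, reusing one seed list across values so
comparisons are paired. Runs are capped at 30 s simulated time; particles
still in transit count as failures. The digital-shadow utilities compute the
open-workspace time to travel 1 mm (closed form distance/‖v_p‖, with a
simulated cross-check that agrees to <0.1%), the mean percentage difference
against user-supplied measured times (the bench measurements themselves are
not redistributable, so no measured dataset ships with the package), and the
binarize-and-centroid reduction of grayscale frames (dark foreground below
an Otsu-selected or explicit threshold; center of mass in px or mm).

## What the synthetic conditions do and do not show

The generator-side defaults are the study conditions: 500 particles, the
five-outlet comb, flows 0.005–0.06 m/s, gradient limits 100–1000 mT/m,
clump/split seeding. Passing regressions show that under these conditions
the implemented physics reproduces the platform's operating behaviour:
complete delivery at steep gradients (100% at 1000 mT/m, 0.02 m/s and at
500 mT/m, 0.005 m/s over 10×500 particles) and the monotone degradation of
success with rising flow and falling gradient cap. They do not show fidelity
to real vasculature (rigid straight walls, steady Newtonian flow, no
recirculation at junctions, no particle coupling, no Brownian motion, no
static-friction threshold — experimentally, swarms can remain stationary at
low gradients, which this model does not reproduce), and autopilot success
levels at intermediate parameters are a property of the scripted policy, not
a prediction of human operator performance.

## Numerical choices, in brief

Containment tolerance 1e-12 m (boundary inclusive); collision bisection
tolerance 1e-9 m; hydraulic solve by dense grounded nodal analysis (networks
here have tens of nodes); junction flow balance holds to 1e-12 of the inlet
flow; nearest-neighbor ties broken by table order (corner ties in
nearest-boundary queries by edge order — any tied answer is valid); seeded
randomness confined to initial positions from one `numpy` generator per run,
so policy logic cannot perturb reproducibility.
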
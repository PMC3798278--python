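# Methods

`mdcell` simulates a deformable cell — concretely, a red blood cell (RBC) —
as a closed triangulated surface whose contact with smooth rigid bodies is
resolved by Maugis–Dugdale (MD) adhesive contact mechanics applied per
triangle, coupled to a viscoelastic spectrin-cortex model and an overdamped
(first-order) equation of motion.  This note records the model, its
assumptions, the numerical choices, and what the shipped tests do and do not
demonstrate.

## Adhesive contact model

Two elastic bodies with reduced radius `R` and combined modulus
`1/E* = (1−ν₁²)/E₁ + (1−ν₂²)/E₂` interact, in the Dugdale idealisation,
through a constant adhesive tension `σ₀ = W/h₀` acting wherever the surface
gap is below the effective range `h₀`; `W` (J/m²) is the work of adhesion.
Inside the intimate-contact circle of radius `a` the normal traction is the
Hertz pressure `p(r) = (2aE*/πR)·√(1−r²/a²)` plus the corrective Dugdale
tension `−(2σ₀/π)·arctan√((c²−a²)/(a²−r²))`; on the annulus `a < r ≤ c` it
is exactly `−σ₀`; beyond the adhesive radius `c` it vanishes.  With `m = c/a`,
`c` solves the cohesive-zone closure condition (gap at the annulus edge
equal to `h₀`)

    (σ₀a²/πWR)[√(m²−1) + (m²−2)·arccos(1/m)]
      + (4σ₀²a/πWE*)[√(m²−1)·arccos(1/m) − m + 1] = 1,

and the net force of the pair is

    F = 4E*a³/3R − 2σ₀a²[√(m²−1) + m²·arccos(1/m)].

The transition parameter `λ = σ₀(9R/2πWE*²)^{1/3}` (1.16 × the Tabor
coefficient) locates the contact between the DMT (`λ≪1`, pull-off `2πWR`)
and JKR (`λ≫1`, pull-off `1.5πWR`) limits.  With the default RBC parameters
(`W = 1 mJ/m²`, `h₀ = 20 nm`, `E = 800 kPa`, `ν = 0.4`, `R = 3.25 µm`)
λ ≈ 0.86: a genuinely transitional contact, which is why the general MD
framework is used rather than either limit.  Pull-off under force control is
computed as the first local minimum of `F(a)` on retraction when one exists
(JKR-like) and as the `a → 0` Dugdale-disc limit `σ₀πc₀²` otherwise
(DMT-like); both limits are verified to 5 % in the tests.

For a sphere approaching a surface *without* intimate contact (positive gap
`g ≤ h₀`), the traction is `−σ₀` on the disc where the spherical gap profile
is below `h₀` — this supplies the initial attraction that starts spreading.

## Contact of a triangulated surface

Each triangle is assigned an *encompassing sphere* matching the local
surface curvature.  Discrete mean curvature comes from the cotangent
Laplace–Beltrami operator on mixed Voronoi areas (circumcentric regions,
with the half/quarter-area rule for obtuse triangles so corner areas always
partition each triangle exactly); the triangle curvature is the mean of its
corner curvatures weighted by their Voronoi share of that triangle, clamped
below by `κ_min` (default `0.2 / r_cell`, i.e. sphere radii capped at five
cell radii) to keep flat patches finite.  The sphere center sits on the
inward side so the three corners lie on the sphere (radius floored at the
triangle circumradius).

Per contacting triangle the sphere–plane (or sphere–sphere) frame yields
`a` directly as the radius of the intersection circle, `c` from the closure
equation, and the contact point `P` at the center of that circle.  The
traction is integrated over the flat triangle with a symmetric 16-point
degree-8 quadrature rule (a 7-point degree-5 rule is available for speed
comparisons), evaluating each quadrature point at its in-plane distance
from `P`; points outside the adhesive disc contribute nothing.  Numerical
choices around this integral:

- **Edge refinement.**  Where the triangle straddles `r = a` or `r = c` the
  integrand is non-smooth; such triangles are integrated with the same rule
  composited on a uniform `4^k` split (default `k = 3` for static
  validation, `k = 2` inside the time loop).  When the disc is smaller than
  the triangle the level is raised so that sub-triangles stay comparable to
  the disc (capped at `k = 6`).
- **Small-contact fallback.**  When the disc area falls below the triangle
  area per quadrature point, quadrature cannot resolve the contact at all;
  the closed-form net sphere force, scaled by the fraction of the disc
  covered by the triangle, is applied at `P` (or the nearest point of the
  covered region).  The force–displacement curve is continuous across this
  switch to better than 2 %.
- **Physical-patch test.**  A triangle's sphere may intersect the substrate
  far from the triangle itself (e.g. triangles on top of the cell); contact
  requires the triangle to be within `h₀` plus a chord-sag margin of the
  other body *and* its projected footprint to overlap the contact disc.

Forces and moments (about `P`) are distributed to the three triangle nodes
along the contact normal by solving the 3×3 system that conserves both
exactly; the friction weights reuse the same distribution (clamped
barycentric coordinates of `P`) with a floor of 0.2 per node so that every
node of a contacting triangle retains a share of its drag — without the
floor, grazing contacts concentrate all drag on one vertex and leave the
others nearly undamped.

Summed over a whole icosphere pressed on a rigid plane, the per-triangle
forces reproduce analytic Hertz (`W = 0`) to better than 1 % and the MD net
force to ~1 % of its components across mesh refinements of 642–10242
triangles, which is the mesh-independence property the scheme is built for.
(Near the depth where repulsion and adhesion cancel, the *relative* error
of the small net force is correspondingly magnified; validation depths are
chosen away from that zero crossing.)

## Cortex model

Cortex nodes interact along the edges of the triangulation:

- **FENE + power-law edges.**  Attraction `k_s L/(1−(L/L_max)²)` with
  `L_max = x₀ L₀`, plus repulsion `k_c/L^m` (`m = 2`) with `k_c` fixed so the
  net force vanishes at the rest length `L₀`.  Defaults: `k_s = 3.2 µN/m`,
  `x₀ = 2.05`.  (`k_s` is occasionally quoted in energy units in the RBC
  literature; the spectrin network scale is ~1 µN/m, so N/m is used here.)
- **Kelvin–Voigt dashpots.**  Axial damping `c·v_rel` per edge
  (`c = 1.5 µN·s/m` default).  The dashpots enter the friction operator, so
  their damping is treated implicitly by the velocity solve — this is what
  stabilises the stiff FENE/area terms at the default time step.
- **Bending.**  Moment `k_b(θ−θ₀)` per interior edge (`k_b = 2.4×10⁻¹⁹ N·m`),
  realised as forces on the two opposite nodes normal to their triangles
  with magnitude moment/(distance to the shared edge), plus compensating
  forces on the shared edge computed from the exact gradient of the
  dihedral angle — each 4-node stencil conserves force and torque to
  machine precision, and the forces are the exact gradient of
  `Σ k_b(θ−θ₀)²/2`.
- **Area penalties.**  Local and global terms with constants in N/m²
  (`6×10³` each).  The displayed prefactor conventions of the sources
  differ; here the forces are gradients of
  `E = k_a (A−A₀)²/(2√A₀)` per triangle (local) and for the total area
  (global) — dimensionally consistent with N/m², in-plane, conservative,
  and summing to zero per triangle.
- **Volume penalty.**  The cytosol volume is constant on the time scales
  modelled, so a pressure-like penalty
  `f_i = k_v·((V₀−V)/V₀)·∂V/∂x_i` (the gradient of
  `k_v V₀((V−V₀)/V₀)²/2`) restores the enclosed volume along each node's
  discrete outward direction.  `k_v` is the restoring pressure per unit
  relative deficit (Pa); the default of 5 kPa was chosen once so that
  spreading runs conserve the volume to about a percent — the stretched
  cap of a spreading cell squeezes the cytosol with a Laplace pressure of
  tens of Pa, which sets the needed stiffness scale.  This is the same
  criterion the constant is calibrated by in this model family.  Weaker,
  force-per-node readings of this constant let the spreading cell flatten
  by losing a quarter of its volume instead of stretching its cortex,
  which contradicts the constant-volume assumption.  Because the adhesive
  rim of a spreading cell squeezes the cytosol with an effective pressure
  of hundreds of Pa — more than any penalty stiffness the explicit
  integrator tolerates — the integrator additionally enforces `V = V₀`
  exactly after each step by a scalar projection of the nodes along their
  outward directions (the Lagrange-multiplier form of the same
  constraint; `volume_projection` in the dynamics parameters, default on).
- **Cortex tension.**  The node observable `T_i = (1/N_i) Σ_j f_ij/l_ij`
  (tensile positive) used for the spreading snapshots.

Gravity and a random membrane-fluctuation force exist only as optional
hooks and default to off; they are negligible for the phenomena modelled.

## Equation of motion

Inertia is dropped: conservative forces balance a symmetric
positive-definite friction operator, `Γv = F`.  `Γ` collects (i) substrate
friction per contacting triangle, `A_contact(γ_n n nᵀ + γ_t(I−n nᵀ))` with
`γ_n = 8×10⁹`, `γ_t = 6×10⁹ N·s/m³`, split over the triangle nodes by the
contact-point weights (symmetry by construction); (ii) the edge dashpots as
`±c ê êᵀ` coupling blocks; (iii) a diagonal Stokes drag `6πηr/N` per node
(`η = 0.8 mPa·s`), which recovers the exact Stokes velocity for a rigid
spherical cell; and (iv) a pinning drag (`10³ × γ_n ×` mean triangle area)
on nodes all of whose triangles are in full contact — it damps numerical
flutter in the stiff contact potential without measurably changing the
spreading curves, which is asserted by a test.

The system is solved each step by Jacobi-preconditioned conjugate
gradients, warm-started from the previous velocities, iterated until the
residual ∞-norm is below `e_max = 10⁻¹⁴ N`; positions advance by forward
Euler with `Δt = 6 µs` by default.  Two guards protect the explicit scheme:
a step is rejected if any node would move more than 0.1 × the smallest rest
edge or if any edge would reach 99.5 % of its FENE limit; the protocol
drivers then retry the step in quarters (up to 6 levels).  Without
substrate contact, node motion transverse to the edges is damped only by
the small Stokes term, so protocol forces are ramped over a few
milliseconds rather than applied as steps.

## Mesh generation

Icospheres are built by subdividing an icosahedron and projecting onto the
sphere (node count `10·4ⁿ + 2`; exactly 12 five-fold nodes at every level).
The biconcave RBC rest shape derives from a sphere of radius 3.25 µm by
quasi-static deflation to 60 % of its volume: the enclosed volume is an
exact constraint (scalar Newton projection along node normals each step)
ramped down linearly, while linear edge springs and a local-area restoring
term conserve the surface area and a zero-spontaneous-angle dihedral
bending term selects the smooth buckling mode — at reduced volume ≈ 0.6 the
minimiser is the classic discocyte.  A weak oblate guide force along the
symmetry axis, active only during the ramp, makes the buckling orientation
deterministic; it is released for the final relaxation.  The pseudo-dynamic
rates (springs 1, bending 0.1, area 2, guide 0.1, in units of the mean edge
length per pseudo-time) were chosen once for stable, monotone deflation;
the result has volume 60.0 %, area within ~1 % of the sphere, and two
axisymmetric dimples (centre half-thickness ≈ 0.16 r, rim ≈ 0.5 r).  The
relaxed shape's edge lengths and dihedral angles become the stress-free
reference of the cortex, so the discocyte — not the sphere — is the
mechanical rest state, as in the stretching experiments.

## Protocols and problem sizes

- **Stretching.**  Opposite forces on the outermost 5 % of nodes per side
  (total per side split equally), ramped over 5 ms, run to an equilibrium
  criterion (max node speed below threshold, sustained).  Axial and
  transversal diameters are reported.
- **Relaxation.**  Stretch to a target axial diameter, release, record
  `D_A(t)` and fit `D_rest + (D_A(0)−D_rest)e^{−t/τ}` log-linearly.
- **Spreading.**  The cell starts with its lowest node `h₀/2` above the
  plane; `r_c(t) = √(ΣA_contact/π)` is recorded and the early power-law
  exponent fitted by OLS in log–log over the window `r_c ∈ [15 %, 50 %]` of
  the final radius (window config-exposed; at least 10 samples required).
  The effective contact angle of a spread cell is estimated by a
  least-squares sphere through the top 50 % of nodes (fraction
  config-exposed), as `arccos(−z_center/R_fit)`.

The shipped test suite and acceptance script run these protocols scaled
down so the whole suite completes on a single CPU in minutes: meshes of
162–642 nodes, horizons of 10–100 ms instead of the full 1.2 s, and a time
step of up to 2.4×10⁻⁵ s (halving the step changes short-run spreading
curves by < 2 %, which is tested).  Because a truncated run's "final"
radius underestimates the full-spread value (≈ 3.3 µm for the 642-node
mesh), the exponent window of a truncated run is mapped accordingly:
20–60 % of the truncated final radius corresponds to the canonical
15–50 % of the full-spread radius.  These sizes resolve the early,
adhesion-driven regime — the `t^{1/2}` growth, the ordering of final radii
with adhesion strength, reversibility after retraction, and the
stretch/relax diameters — but not the fully spread 2562-node end state with
its extreme rim curvatures; the contact-angle comparison against the
spread-cell geometry is therefore a long-run (not suite) computation.

## What the tests show — and what they do not

All inputs are generated internally (icospheres, the deflated discocyte);
no experimental data enters any test.  Passing tests therefore demonstrate
internal consistency against closed-form contact mechanics, conservation
laws, discretisation-independence, and the qualitative experimental trends
the model family is known for (diameter trends under stretching, relaxation
times of order 0.1 s with cortex damping of order 50 µPa·s·m, early
`t^{1/2}` spreading robust to parameter changes).  They do not calibrate
the model against digitized experimental curves, which can be overlaid for
plotting only.

## Known limitations

- No remeshing: the fixed triangulation must resolve the smallest features
  of interest, and coarse meshes underestimate the final spreading radius.
- The linear dissipative operator is a first-order model of contact
  dissipation; friction constants are not transferable across substrate
  chemistries or time scales.
- Contact is supported against rigid planes and spheres; two deformable
  triangulated bodies share the same per-triangle machinery but are not
  exercised by the shipped protocols.  Tangential contact tractions and
  cell self-contact are out of scope.
- Near the fully spread state the cortex approaches its extensibility
  limit and the explicit integrator requires small steps; the step-rejection
  guards make this a clean failure rather than a corrupted state.
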
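# Methods

This note documents the models, numerical choices and limitations of
`plaquemech`, in the order of the processing chain.

## Constitutive model

Vessel layers are hyperelastic, fiber-reinforced, nearly incompressible and
homogeneous; lipid and calcification are isotropic.  The strain energy is
the modified Mooney–Rivlin form

    W = c1 (Ī1 − 3) + c2 (Ī2 − 3) + D1 [exp(D2 (Ī1 − 3)) − 1]
        + (K1/K2) {exp[K2 (Ī4 − 1)²] − 1}  +  κ/2 (J − 1)²

with the deviatoric part expressed in the isochoric invariants
Ī = J^(−2/3)-scaled, so the printed layer parameters act purely
deviatorically next to the volumetric penalty.  Parameters (kPa where
dimensional): intima c1 = −169.23, c2 = 177.40, D1 = 2.4, D2 = 13, K1 = 32,
K2 = 36; media c1 = −67.25, c2 = 35.01, D1 = 17, D2 = 2, K1 = 7, K2 = 4,
φ = 24.9°; adventitia c1 = −94.44, c2 = 102.42, D1 = 0.8, D2 = 10, K1 = 10,
K2 = 40, φ = 75.3°; lipid c1 = 0.5, D1 = 0.5, D2 = 1.5; calcification
c1 = 920, D1 = 360, D2 = 2.0.  Single-layer models bind the intima record to
the whole wall.  Decisions taken where the source literature is silent:

- **Intima fiber angle.**  K1, K2 are given for the intima but no angle; the
  default is φ = 0° (circumferential), config-overridable.
- **Fiber recruitment.**  The fiber term is active only in tension
  (Ī4 > 1), the standard collagen-recruitment convention.  One fiber family
  at +φ is used; in the shear-free thin-slice kinematics Ī4 equals
  λθ²cos²φ + λz²sin²φ exactly, so a symmetric ±φ pair would be identical.
- **Volumetric penalty.**  κ = 1e5 kPa by default.  This keeps the element
  dilatation within ±0.5% at coronary loads including the residually
  stressed states; stress results were verified insensitive to κ over
  1e4–1e5.  Pressures are converted once at the loading boundary with
  1 mmHg = 0.133322 kPa.
- **Derivatives.**  Stress is σ = (1/J) (∂W/∂F) Fᵀ with ∂W/∂F evaluated by
  the complex-step method (exact to machine precision); finite-difference
  consistency is enforced in the test-suite, not assumed.
- **Convexity caveat.**  The fitted c1 < 0 makes the deviatoric energy
  weakly non-convex in a neighbourhood of the reference state (the tangent
  there has small negative eigenvalues on fine meshes).  This is a property
  of the published parameter set, not of the discretization; the solver
  handles it (see below) and all working-load states are stable.

## Zero-stress reconstruction

The imaged (in vivo) slice is pressurized and axially stretched, so model
construction walks backwards:

1. **Pre-shrink.**  Radii about the lumen centroid are scaled by
   (1 − s_circ); the 5% axial pre-shrink is carried as the target in vivo
   stretch λz = 1/0.95 for the mechanics stage.  s_circ starts at 5% and is
   calibrated per model variant by a secant iteration until the slice,
   re-pressurized to diastolic pressure, matches the imaged lumen
   circumference to < 0.1% (it converges in 2–3 iterations because the
   response is nearly affine in 1 − s_circ).
2. **Opening.**  The closed no-load ring is cut open into a sector of
   central angle Θs = 2(π − OA) — Fung's tip-angle convention, with
   OA = 120° the literature average for human coronaries; for OA = 120° the
   sector spans 120°.  This convention choice matters: any other reading of
   "opening angle" changes all residual-stress magnitudes, so Θs can also be
   supplied directly.  The map is Θ = (Θs/2π)θ, R(r)² = R_m² + (2π/Θs)(r² −
   r_m²) with R_m = (2π/Θs) r_m, which conserves wall area exactly
   (point-wise, R dR dΘ = r dr dθ) for arbitrary star-shaped contours.
3. **Middle line.**  The "middle line of the wall" is the curve midway in
   radius between lumen and ADV; its conserved circumference is defined as
   2π times the angular mean of the midwall radius (identical to the true
   arc length for circular rings, where the map conserves genuine arc length
   exactly).  For irregular contours the point-wise image of the midwall
   polyline is not an invariant of any global polar map; the mean-radius
   circumference is the quantity this construction conserves, to machine
   precision.
4. Plaque-component polygons are carried through the same polar map.
   Layer-specific opening angles are deliberately not modelled: one
   whole-wall angle per case.

## Thin-slice finite elements

The 0.5 mm-thick slice is modelled as 2-D generalized plane strain with a
uniform prescribed axial stretch — identical in-plane response to a
shear-free 3-D slab at a fraction of the cost; the physical thickness is
carried as metadata.  Discretization and solver:

- Structured "volume-fitting" quadrilateral meshes: each layer band is
  subdivided radially (defaults: calibration 2/layer × 32 columns, reporting
  3/layer × 48), elements labelled by layer or by the component polygon
  containing their centroid.  Problem sizes were chosen so a full four-model
  case solves in ~15–25 s.
- Bilinear displacement elements with selective reduced integration: the
  deviatoric energy at 2×2 Gauss points, the volumetric penalty at the
  centroid (avoids locking).  Flanagan–Belytschko hourglass control with
  stiffness 3e-3·κ constrains the spurious modes the centroid rule leaves
  free — essential once soft lipid pockets (shear modulus ~1 kPa inside a
  ~100 kPa wall) enter the wrap step, and a <2% effect on the smooth
  benchmark solutions.
- Incompressibility is reported as the element dilatation (J at the
  volumetric point, the quantity the penalty constrains), which stays within
  ±1% in all shipped runs; point-wise J at the 2×2 points is exposed
  separately as a diagnostic and can deviate a few % inside coarse lipid
  elements.
- Newton iteration with complex-step-exact residuals, forward-difference
  element tangents (branch-frozen at the fiber-recruitment switch so the
  tangent stays consistent on the I4 = 1 kink), backtracking line search,
  modified-Newton reuse of the factorized tangent, and Levenberg diagonal
  damping as a fallback for the weakly indefinite near-reference states.
  Relative residual tolerance 1e-8 with an absolute floor of 1e-9 kPa·mm
  (covers identically force-free states such as pure axial stretch of a
  homogeneous ring).
- **Three-step procedure.** (a) *Wrap*: the opened sector's cut faces are
  brought to coincidence and tied node-to-node, then the ring is released
  with zero traction.  Because the material is hyperelastic the released
  equilibrium is path-independent (verified: doubling wrap increments
  changes stresses by <1e-9 relative), so the wrap is applied kinematically
  in one shot along the analytic partial-closing map and relaxed; an
  incremental prescribed-displacement wrap and a decaying-spring
  continuation serve as fallbacks.  Rigid modes are pinned at one node plus
  one transverse component (pure gauge; reactions vanish in the
  self-equilibrated state).  (b) *Stretch*: λz is ramped adaptively,
  warm-started with the incompressible homogeneous contraction.  (c)
  *Pressurize*: the lumen pressure is a follower load on the deformed
  boundary (scaled by λz, the deformed wetted area per unit reference
  thickness), ramped with adaptive halving.
- The semi-analytic oracle solves the same layered cylinder under
  incompressible kinematics by shooting on the deformed inner radius;
  FE-vs-oracle hoop-stress profiles agree to 1–3% at the shipped meshes.

## Segmentation

Detection is Canny-style, specialized to the anatomy of polar OCT slices: a
Gaussian-derivative gradient along depth only (σ_depth = 1.5 px, σ_θ = 2
rows), candidate edges as local gradient extrema above a low threshold
(12% of the robust maximum), a step-contrast validation against the image's
noise scale (rejects pure speckle, e.g. inside guide-wire shadows), ordered
outward assignment of the four interfaces by a sign-constrained
maximum-score chain (+, −, +, − for bright intima / darker media / brighter
adventitia) with a minimum radial gap, and two-threshold hysteresis linking
along θ (35% high threshold; weaker detections join when radially within 5
px of a visible neighbour).  Repair interpolates across slices where a
neighbour sees the same angle, then bridges residual gaps with a periodic
interpolating cubic spline per slice; an optional truncated-Fourier
least-squares smoother is available for noisy detections, but the default is
interpolating so that fully visible input is reproduced exactly.  Interface
ordering is enforced by iterated pair-averaging with a one-pixel minimum
gap (deterministic, mean-preserving).

Known limitation: strong interior edges of plaque components (a lipid pool's
borders) can capture the IEM/EEM chain in the A-lines they cross; accuracy
criteria apply to wall phantoms, and the modelling pipeline consumes
ground-truth contours for component-bearing cases.

## Synthetic data

The generator emulates what the downstream stages need, not OCT physics:
star-shaped interfaces (base radii ~1.3–1.7 mm lumen, wall layers 0.2–0.4
mm) with low-order Fourier perturbations bounded to preserve ordering;
lipid/calcification bands inside the capped intima; a polar phantom with
bright-intima/dark-media/bright-adventitia contrast, guide-wire shadow
sectors, and unit-mean multiplicative Gamma speckle; cohorts with blood
pressures drawn in the clinically observed ranges (systolic 115–175,
diastolic 64–92 mmHg) and opening angle 120°.  Not emulated: ray physics,
catheter eccentricity, rotation distortion, pull-back geometry beyond a
simple slice stack.  Passing tests on phantoms therefore demonstrate the
correctness of the algorithms, not clinical-grade segmentation performance.

## Extraction and statistics

Each wall contour is split into four quarters at the rays 0/90/180/270°
from the deformed lumen centroid; 25 points per quarter are placed at equal
arc-length steps on each wall and paired by index ("piecewise equal-step"),
which avoids the connector distortion that purely radial pairing suffers at
thick eccentric plaques.  Per-point fields are the per-element maximum
principal Cauchy stress and Green–Lagrange strain of the boundary element.
Cohort tables report Mean ± sample (n−1) STD of the absolute quantities and
of the per-case percent ratios (100 × with/without residual stress); the
headline percentages follow the mean-of-ratios convention, reduction% =
100 − mean(ratio%) and increase% = mean(ratio%) − 100.  Ratios with
near-zero denominators (<1e-9 kPa) are excluded and counted.

## Behaviour worth knowing

- **Directionality.**  On every synthetic cohort case, residual stress
  strictly lowers inner-wall maximum and mean stress and raises the
  outer-wall values, in both layer modes — the qualitative effect the
  four-model comparison is designed to expose.  For *strain* the per-case
  inequality can genuinely reverse (wrap closure thickens the inner wall
  radially, raising the largest principal Green strain even as the stress
  falls), so the strain effect is asserted at the cohort-mean level; this
  mirrors the published per-patient tables, which also contain strain ratios
  above 100%.
- **Uniformization.**  Residual stress flattens the transmural hoop-stress
  profile at systolic load in almost every case, but the effect is
  pressure-dependent: below a crossover pressure (~120 mmHg for the default
  geometry and a 120° opening angle) the pre-compression of the intima can
  overshoot, widening the spread although the mean is unchanged.  Cohorts
  drawn from the clinical pressure range may therefore contain an occasional
  case whose coefficient of variation does not decrease; the cohort-level
  effect is robust.
- **Reporting pressure** defaults to systolic (diastolic is consumed by the
  shrink calibration); "mean" and "diastolic" are config options.

## Limitations

Single slices only (no 3-D multi-slice models), no fluid–structure
interaction or pulsatile dynamics, tied (not frictional-contact) closure,
one whole-wall opening angle, and material parameters adopted from published
fits rather than refitted.  Reported magnitudes depend strongly on the
opening-angle convention and the intima fiber-angle default documented
above.
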
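# Methods

## Problem and approach

Non-contact tonometry (NCT) indents the cornea with an air pulse while a
camera records the deformation.  The mechanical information in that
recording is mostly unused clinically because classical inverse
identification (iterative finite-element model updating) needs thousands
of expensive forward solves.  This package implements an *update-free*
alternative built on the equilibrium gap method (EGM): given a
displacement snapshot `u` of the whole eye and the matching external
loads `f_ext`, the discrete residual

    R(alpha) = f_int(u; alpha) - f_ext

is minimised over the material parameters directly — no forward solve is
involved.  For the corneal constitutive model used here the internal
force is *exactly linear* in three of the four parameters, so the
minimiser of `||R||^2` is a single 3x3 normal-equation solve.

## Constitutive model

Fiber-reinforced hyperelasticity with dispersion (mm–N–MPa units):

    psi = K/4 (J^2 - 1 - 2 ln J)                      volumetric penalty
        + mu/2 (I1t - 3)                              isotropic matrix
        + sum_{i=1,2} k1/(2 k2) (exp[k2 (I4t*_i - 1)^2] - 1)

with isochoric invariants `I1t = J^{-2/3} tr C` and, per fiber family,
`I4t*_i = kappa I1t + (1 - 3 kappa) I4t_i`, where `kappa in [0, 1/3]` is
the orientation dispersion (0 = perfectly aligned, 1/3 = isotropic) and
the two families run nasal–temporal and superior–inferior.  The isotropic
part is the one-parameter neo-Hookean collapse `mu = mu1 + mu2` of the
Mooney–Rivlin form: the two invariants are nearly indistinguishable in
the corneal stretch range, and the collapse also guarantees polyconvexity
of the isotropic part.

Parameters and defaults (the healthy reference set):

| symbol | meaning                       | default | unit |
|--------|-------------------------------|---------|------|
| K      | volumetric penalty modulus    | 10      | MPa  |
| mu     | matrix shear modulus          | 0.275   | MPa  |
| k1     | collagen fiber stiffness      | 0.04    | MPa  |
| k2     | fiber nonlinearity            | 200     | —    |
| kappa  | dispersion (constant profile) | 0.1     | —    |

Keratoconus-like degradation is modelled purely as reduced `k1`
(0.02 / 0.01 / 0.00 MPa for the sets KK-I/II/III).  Choices fixed here:

* **Variance-correction factor** `a = 1 + K* sigma^2` of the fiber term:
  disabled by default (`a = 1`); both coefficients are exposed as
  optional configuration because no reference values accompany the
  parameter sets.  When enabled it simply rescales the `k1` column, so
  the linear structure is unaffected.
* **Fiber tension switch**: fibers contribute only for `I4t* > 1`
  (collagen carries no compression), switchable.  The recovery results
  are insensitive to the switch because generator and identifier share
  it.
* **Small-k2 branch**: for `k2 < 1e-6` the fiber energy uses its
  quadratic Taylor limit `k1/2 (I4t*-1)^2 (1 + k2/2 (I4t*-1)^2)`,
  continuous at the branch point, so the outer search can probe
  `k2 -> 0` without 0/0.
* `k2` is implemented as dimensionless (its role is an exponent scale).

`K, mu, k1` multiply separate additive energy terms, so the Cauchy
stress and hence every internal-force vector splits exactly as
`f_int = K c_K + mu c_mu + k1 c_k1` at fixed kinematics and fixed `k2`.
Each column `c_i` is obtained by assembling with that parameter set to
one and the others zero — an operation any FE code provides unmodified.

## Discretisation

8-node hexahedra, 2x2x2 Gauss quadrature, mean-dilatation F-bar
(constitutive evaluation at `Fbar = (Jbar/J)^{1/3} F` with the
element-averaged dilatation) against volumetric locking, internal forces
integrated in the current configuration (`B^T sigma` with the spatial
gradient matrix), follower pressures on deformed facets.  The *same*
assembly is used to generate synthetic data and to identify parameters;
exact recovery relies on that, not on mesh convergence.  Quadrature
order is switchable (a fixture test verifies <0.1% sensitivity of the
apex displacement between orders 2 and 3).

## Eye model

Quarter model (half/full by reflection).  The cornea is an ellipsoidal
cap (semi-axes 7.2/7.2/6.65 mm) with cosine-blended thickness from
CCT = 0.545 mm at the apex to 0.71 mm at the limbus; the limbus is a
2 mm annular transition starting at r = 4.6 mm; a spherical scleral
shell (radius 11.5 mm) continues to a fixation ring at a 30 degree cone
about the posterior pole.  The in-plane grid uses the elliptical
square-to-disc mapping, so there is no polar singularity and all
Jacobians are positive.  Default fixture resolution: 8x8 in-plane cells,
2 layers through the thickness, 6 meridian rows of sclera — 320 elements
and 549 nodes.  This size was chosen so the complete study suite
(stress-free recovery, four forward tonometry runs, grid searches,
morphing) runs on a single CPU core in minutes while keeping PD and
contour extraction meaningful.

The interior is a single fluid cavity (aqueous and vitreous combined;
the lens is omitted, so the two-chamber pressure split reported by the
full production models is out of scope here).  The cavity has one
uniform pressure with the linear law `p = p0 + K_W (V0 - V)/V0`,
`K_W = 2 GPa` (water).  Including the compliant sclera is what makes
this realistic: the ocular volume compliance comes from scleral stretch,
and the IOP then rises by a few mmHg over a ~1 mm indentation, as it
should.  A cornea-only variant (clamped limbal rim) exists behind a
flag, but with a rigid closure the water-stiff cavity would forbid
realistic indentation, so the shell model is the default.  The enclosed
volume is computed exactly by a divergence-theorem surface integral
`V = -sum (z - z_ref) n_z da` over the wetted facets; symmetry planes
and the flat posterior closure contribute nothing by construction.

Auxiliary components (limbus `E = 1.4 MPa`, sclera `E = 2.3 MPa`,
`nu = 0.49`) are implemented as compressible neo-Hookean solids with
`(K, mu)` matched to `(E, nu)` — equivalent at small strain, objective
at finite strain, and identical in generator and identifier, which is
all the recovery contracts require.

**Stress-free geometry.**  In vivo imaging sees the pressurised eye; the
unloaded reference is recovered by the classical fixed point
`X0 <- X0 - (x(X0) - X_target)` under a fixed IOP of 17.5 mmHg, with a
2 um termination criterion on the maximum nodal distance and an optional
relaxation factor (default 1).  On the fixture it converges in 3
iterations, and reloading the converged mesh reproduces the target to
~0.3 um.

## Forward solver

Quasi-static Newton with consistent tangents obtained by batched
forward finite differences of the element/facet force vectors.  The
fluid cavity is coupled monolithically: unknowns `(u, p)` with the
volume constraint `R_p = (V - V0) + (p - p0) V0/K_W`, solved through a
bordered (Schur) elimination.  Eliminating `p` exactly instead makes the
residual catastrophically stiff (the fluid is three orders of magnitude
stiffer than the tissue), which is why the pressure is kept as an
explicit unknown.  Globalisation matters for thin-shell bending: the
residual norm is *not* monotone along good Newton paths, so the line
search accepts full steps non-monotonically (bounded growth with a
watchdog budget), reuses factorised tangents while full steps make fast
progress, and the load ramp substeps adaptively on failure.  The morph
solves additionally use a trust clamp on the increment and
pseudo-transient continuation (tangent augmented by `kappa(|R|) I`,
vanishing at convergence, hence unbiased).  Convergence contract in all
modes: free-DOF residual below `rtol ||f_ext|| + atol`
(defaults 1e-8 / 1e-10 N).

## Virtual tonometry (synthetic data)

The air pulse is a surrogate: a Gaussian spatial pressure profile
`p(r) = P exp(-r^2 / 2 s^2)` with `s = 1.5 mm`, ramped in 12 steps, and
`P = 0.014 MPa` calibrated once so the healthy fixture reaches an apex
deflection (DefA) of ~1.1 mm at full load.  (The published analytic
air-jet load of the original device model is not reproduced here, which
is also why absolute DefA/PD/IOP tables are not reproduction targets;
the degradation ordering DefA(H) < KK-I < KK-II < KK-III does hold.)

Three deformation states are stored with *matched* external-force
vectors (pulse plus cavity pressure at the converged configuration):
state 1 is the applanation state (first step at which the central
anterior disc of radius 1 mm deviates from its best-fit plane by less
than 5 um, with the symmetry quadrant mirrored before fitting), state 3
the maximum deformation, and state 2 the step nearest to the load factor
halfway between them (a DefA-halfway variant is a one-line change).
Displacements are stored from the stress-free reference.  2D anterior/
posterior contours in the y = 0 symmetry plane emulate the device
output; PD is the distance between the bending crests (local maxima of
the deformed anterior contour flanking the dimple), reported with the
radial node spacing as its resolution.

Noise emulation adds independent uniform offsets in `[-a, a]` to every
displacement component (seeded generator, no smoothing), leaving the
paired force vectors untouched.

What the generator does *not* emulate: device pressure-sensing channel,
image noise statistics of a real camera (uniform, not Gaussian),
patient-specific topography, the lens/two-chamber hydraulics, and the
production-scale load profile.  Passing recovery tests therefore
demonstrate the correctness and conditioning of the identification
machinery under its own equilibrium assumption — not clinical accuracy.

## Identification

Per state, the sensitivity columns are restricted to the free DOFs
(Dirichlet and symmetry rows carry unknown reactions and are excluded;
an option restricts further to corneal-node DOFs).  Internal forces of
the known-modulus components (limbus, sclera) are folded into the
effective load, keeping the unknown vector strictly three-dimensional.
Columns are norm-scaled before the 3x3 normal-equation solve (`c_K` and
`c_k1` differ by orders of magnitude); non-negativity is enforced by an
NNLS fallback with active-set flags; a numerically zero column raises an
identifiability warning naming the deficient direction.

The fiber nonlinearity `k2` enters through the exponential only and is
found by a nested grid search (default 10..400 step 10) minimising

    f_rel(k2) = sum_i std(alpha_i over states) / mean(alpha_i over states)

with the *population* standard deviation over m >= 3 states (the
convention is fixed so the toy examples are deterministic) and a
zero-mean guard (`|mean| < 1e-12` replaces the denominator by 1e-12,
flagging instead of dividing by zero).  With `k1 ~ 0` the fiber term —
and with it all information about `k2` — leaves the residual; the search
flags `k1` below 1e-3 MPa as unidentifiable.  On the fixture the curve
has its exact zero at the generating `k2 = 200` and rises on both sides;
a secondary interior minimum toward `k2 -> 0` (reported for
production-scale models) does not occur at this scale — the curve
decreases monotonically from its low-`k2` plateau into the optimum.

Measured sensitivity: with 0.01 um noise all three parameters stay
within +/-10% of truth in >= 8 of 10 repetitions; 0.1 um breaks the
identification in nearly every repetition, with `K` collapsing first
(random noise violates incompressibility at element level).  The
fixture has ~1400 identification rows; larger meshes average noise down
by roughly the square root of the row count.

## Mechanical morphing (contour-only input)

Devices measure contours, not point displacements.  The morphing module
reconstructs a representative 3D field: the two contours are
rotationally extruded into axisymmetric stamps (monotone PCHIP in r),
and a neutral surrogate eye (isotropic cornea, E = 1 MPa, penalty bulk
modulus giving nu ~ 0.4995 — no constitutive knowledge may enter) is
driven so that its corneal surfaces adopt the stamp heights.  Only the
vertical coordinate is prescribed, at each node's *current* radius, so
material points slide horizontally — contours constrain shape, not
correspondence.  The surrogate has its own stress-free reference
(recovered for the acquisition IOP from the measured geometry); morphed
fields are converted to the identification model's reference through the
common deformed configuration.  The imprint is restricted to
r <= 4.2 mm, the half-width of the device's imaged strip; the periphery
follows elastically.  Each sliding iteration runs an adaptive
continuation over interpolated stamps, starting from a geometrically
compatible through-thickness guess (whole node columns pre-displaced) —
an instantaneous surface jump would volumetrically crush the nearly
incompressible surrogate.  The cavity pressure follows the enclosed
volume and is returned as the updated IOP.

At fixture scale the morphed configuration tracks the generating forward
solve to ~5–15 um and `max|J-1|` stays below 3e-4 (contract: 0.02).
Those ~10 um of smooth reconstruction error are nevertheless far above
the 0.1 um noise threshold of the EGM, so the contour-only route loses
the absolute parameter values (the least-squares optimum degenerates to
the non-negativity boundary for K and mu and the k2 argmin slides to the
grid edge) while *retaining the fiber-stiffness ordering*: identified k1
decreases strictly across H -> KK-I -> KK-II -> KK-III.  That ordering —
detectability of degraded-stiffness ranges from data a device actually
measures — is the feasibility property this module is meant to
demonstrate.  Consequences at this scale, both verified by tests:
the identity morph leaves a residual equal to the azimuthal anisotropy
of the quarter-grid prestress (~2.4 um on the default mesh, shrinking
roughly with the square of the in-plane resolution), and doubling the
surrogate modulus shifts the morphed field by ~17 um (the cavity
stiffness is absolute, so the fluid/solid ratio depends on E) — the
*kinematics* is insensitive, the degenerate absolute parameter values
are not.

## Numerical choices and degenerate inputs

* FD step 1e-6 mm for all tangents and gradients; identification uses
  no derivatives at all.
* Tie-break in the grid search: `argmin` takes the first minimum;
  competing local minima within a 10% band set an ambiguity flag.
* Degenerate inputs: zero-deformation contours abort the enriched
  pipeline with a rank warning; a never-applanating load raises a
  detection error (an infinite sagitta tolerance degenerates to state
  0); zero noise amplitude and single-repetition studies are legal and
  flagged.
* Record bundles are plain text (JSON + CSV at 17 significant digits),
  which round-trips IEEE doubles exactly; meshes and fields also export
  to legacy-ASCII VTK.

## Known limitations

* Reduced geometry: no lens, single cavity, constant-thickness sclera,
  constant dispersion profile; absolute DefA/PD/IOP values are not
  comparable to production-scale models.
* The surrogate pulse is axisymmetric and shear-free.
* Contour-only identification at fixture scale yields ordering, not
  absolute values (see above).
* The applanation criterion (best-fit-plane sagitta) is a documented
  choice; devices use proprietary image criteria.
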
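"""Mechanical morphing: 3D full-field kinematics from 2D contours.

Tonometers observe only the anterior/posterior corneal contours in a
single cross-section, not the displacement of material points.  The
morphing step closes this gap: the measured contours are rotationally
extruded into axisymmetric stamps, and a nearly incompressible,
isotropic surrogate model of the eye (the mechanical properties are
unknown at this point, so a neutral linear-elastic-type material is
deliberately used) is driven so that its corneal surfaces adopt the
stamp shapes.  Only the vertical coordinate is imposed -- each surface
node is pulled to the stamp height evaluated at the node's *current*
horizontal position and may slide horizontally -- mirroring the fact
that the contour constrains shape, not point correspondence.  The
fixed-point iteration over the sliding positions converges when the
vertical imprint residual and the horizontal motion stagnate.

Outputs are the approximated full-field displacement, the updated
cavity pressure (the indentation raises the IOP through the enclosed
volume) and an incompressibility diagnostic max|J-1|, after which the
standard equilibrium-gap identification runs unchanged on the morphed
kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .constitutive import MaterialParameters
from .fem import SolverError, newton_solve
from .geometry import EyeModel
from .k2search import K2SearchResult, grid_search_k2
from .nct import ContourPair, PulseLoad

__all__ = [
    "Stamp",
    "MorphResult",
    "extrude_stamps",
    "morph_full_field",
    "make_morph_model",
    "enriched_identification",
]


@dataclass
class Stamp:
    """Axisymmetric surface of revolution z(r) from a contour polyline."""

    r: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if np.any(np.diff(self.r) <= 0.0):
            raise ValueError("stamp polyline must be strictly increasing in r")
        self._interp = PchipInterpolator(self.r, self.z, extrapolate=False)

    def height(self, r) -> np.ndarray:
        """Stamp height at radius r (clamped to the sampled range)."""
        rc = np.clip(np.asarray(r, dtype=float), self.r[0], self.r[-1])
        return self._interp(rc)


@dataclass
class MorphResult:
    """Morphed kinematics and diagnostics."""

    u_morph: np.ndarray            # total displacement from stress-free ref
    u_imprint: np.ndarray          # relative to the prestressed state
    iop: float                     # updated cavity pressure, MPa
    vertical_residual: float       # max |z - stamp(r)| on imprinted nodes, mm
    max_abs_J_minus_1: float       # incompressibility diagnostic
    outer_iterations: int
    residual_history: List[float]


def extrude_stamps(contours: ContourPair) -> Tuple[Stamp, Stamp]:
    """Rotationally extrude the anterior/posterior contours into stamps.

    The polylines must be strictly ordered in r and non-intersecting
    (anterior above posterior); contours produced by
    :func:`eyegap.nct.extract_contours` satisfy this by construction.
    """
    ant = np.asarray(contours.anterior, dtype=float)
    post = np.asarray(contours.posterior, dtype=float)
    a = Stamp(r=ant[:, 0], z=ant[:, 1])
    p = Stamp(r=post[:, 0], z=post[:, 1])
    rr = np.linspace(max(a.r[0], p.r[0]), min(a.r[-1], p.r[-1]), 64)
    if np.any(a.height(rr) <= p.height(rr)):
        raise ValueError("anterior contour must lie strictly above the "
                         "posterior contour (positive thickness)")
    return a, p


def make_morph_model(model: EyeModel, modulus: float = 1.0,
                     nu_eff: float = 0.4995) -> EyeModel:
    """Surrogate model for morphing, prestressed at the acquisition IOP.

    The cornea is replaced by an isotropic, nearly incompressible
    material (default E = 1 MPa; the penalty bulk modulus corresponds to
    nu ~ 0.4995), since no constitutive knowledge may enter this step;
    auxiliary components and the fluid cavity are kept.  The measured
    (in vivo) geometry is taken from the input model's pressurised
    configuration, and the surrogate's own stress-free reference is then
    recovered for the same IOP -- the surrogate is a different material,
    so it has its own unloaded shape.

    The imprint is displacement-driven, so the morphed corneal
    kinematics is insensitive to ``modulus``; only the unimprinted
    periphery responds mildly to it through the (absolute) fluid-cavity
    stiffness.
    """
    from .geometry import stress_free_geometry

    if model.u_pre is None or model.iop is None:
        raise ValueError("input model must be prestressed (the measured "
                         "geometry is its pressurised configuration)")
    out = model.copy()
    out.mesh.nodes = model.mesh.nodes + model.u_pre.reshape(-1, 3)
    K = modulus / (3.0 * (1.0 - 2.0 * nu_eff))
    mu = modulus / (2.0 * (1.0 + nu_eff))
    out.materials["cornea"] = MaterialParameters(K=K, mu=mu, k1=0.0, k2=1.0)
    out.u_pre = None
    out, _ = stress_free_geometry(out, model.iop)
    return out


def _imprint_nodes(model: EyeModel,
                   imprint_radius: float) -> Tuple[np.ndarray, np.ndarray]:
    """Surface nodes inside the imprint radius (reference geometry).

    The tonometer images only the central ~8.5 mm of the cornea, so the
    stamps constrain the surfaces out to that radius; the periphery
    follows elastically.
    """
    mesh = model.mesh
    out = []
    for name in ("anterior_surface", "posterior_surface"):
        ids = mesh.node_sets[name]
        r = np.hypot(mesh.nodes[ids, 0], mesh.nodes[ids, 1])
        out.append(ids[r <= imprint_radius])
    return tuple(out)


def _initial_imprint_guess(morph_model: EyeModel, u: np.ndarray,
                           ant_stamp: Stamp, post_stamp: Stamp,
                           imprint_radius: float,
                           taper_width: float = 1.5) -> np.ndarray:
    """Geometrically compatible starting field for the imprint solve.

    The target surface shapes are known from the stamps, so every node
    of the corneal block is pre-displaced vertically by blending the
    anterior/posterior stamp offsets through the thickness (tapered to
    zero beyond the imprint radius).  Moving whole columns together
    avoids the spurious volumetric compression an instantaneous surface
    jump would impose on the nearly incompressible surrogate.
    """
    from .nct import extract_contours

    mesh = morph_model.mesh
    cp_cur = extract_contours(morph_model, u)
    cur_ant, cur_post = extrude_stamps(cp_cur)
    block = np.unique(np.concatenate(
        [mesh.elems[mesh.elem_sets[t]].ravel()
         for t in ("cornea", "limbus") if t in mesh.elem_sets]))
    x = mesh.nodes + u.reshape(-1, 3)
    r = np.hypot(x[block, 0], x[block, 1])
    za_c, zp_c = cur_ant.height(r), cur_post.height(r)
    za_t, zp_t = ant_stamp.height(r), post_stamp.height(r)
    f = np.clip((x[block, 2] - zp_c) / np.maximum(za_c - zp_c, 1e-6), 0, 1)
    dz = (1 - f) * (zp_t - zp_c) + f * (za_t - za_c)
    w = np.clip((imprint_radius + taper_width - r) / taper_width, 0.0, 1.0)
    w = 0.5 * (1.0 - np.cos(np.pi * w))
    out = u.copy()
    zdofs = 3 * block + 2
    fixed = np.isin(zdofs, morph_model.bcs.fixed_dofs)
    out[zdofs[~fixed]] += (w * dz)[~fixed]
    return out


def morph_full_field(morph_model: EyeModel, contours: ContourPair,
                     imprint_tol: float = 1e-3, slide_tol: float = 1e-4,
                     imprint_radius: float = 4.2,
                     max_outer: int = 30, order: int = 2, fbar: bool = True,
                     rtol: float = 1e-9, atol: float = 1e-12,
                     dt0: float = 0.125) -> MorphResult:
    """Imprint the contour stamps onto the surrogate model.

    The model must be prestressed at the acquisition IOP.  The imprint
    proceeds in two phases.  First an adaptive continuation drives the
    surfaces from their current shape to the stamp shape through
    interpolated intermediate stamps (step ``dt0``, bisected whenever
    the Newton solve diverges -- the combination of near-incompressible
    response, free horizontal sliding and the fluid cavity makes the
    path strongly nonlinear); each substep starts from a geometrically
    compatible through-thickness guess.  Then sliding iterations
    re-prescribe, on every surface node within ``imprint_radius``, the
    stamp height at the node's *current* radius (vertical DOF only)
    until the vertical residual is below ``imprint_tol`` (mm) and
    horizontal positions move less than ``slide_tol`` (mm).
    """
    from .nct import extract_contours

    if morph_model.u_pre is None:
        raise ValueError("morph model must be prestressed")
    mesh = morph_model.mesh
    asm = morph_model.assembler(order=order, fbar=fbar)
    ant_stamp, post_stamp = extrude_stamps(contours)
    ant_ids, post_ids = _imprint_nodes(morph_model, imprint_radius)
    fixed = set(morph_model.bcs.fixed_dofs.tolist())
    X = mesh.nodes
    cav = morph_model.cavities[0]

    def dirichlet(ant_s, post_s, uref):
        x = X + uref.reshape(-1, 3)
        dofs, values = [], []
        for ids, stamp in ((ant_ids, ant_s), (post_ids, post_s)):
            r = np.hypot(x[ids, 0], x[ids, 1])
            zt = stamp.height(r)
            for n, z in zip(ids, zt):
                d = 3 * int(n) + 2
                if d not in fixed:
                    dofs.append(d)
                    values.append(z - X[n, 2])
        return np.array(dofs, int), np.array(values)

    def drive_to_stamps(u, p_prev):
        """Adaptive continuation from the current surfaces to the stamps."""
        cp_cur = extract_contours(morph_model, u)
        ant_c, post_c = extrude_stamps(cp_cur)

        def stamps_at(ts):
            return (Stamp(r=ant_stamp.r,
                          z=(1 - ts) * np.asarray(ant_c.height(ant_stamp.r))
                          + ts * ant_stamp.z),
                    Stamp(r=post_stamp.r,
                          z=(1 - ts) * np.asarray(post_c.height(post_stamp.r))
                          + ts * post_stamp.z))

        t_done, dt = 0.0, dt0
        while t_done < 1.0 - 1e-9:
            ts = min(t_done + dt, 1.0)
            ant_s, post_s = stamps_at(ts)
            ug = _initial_imprint_guess(morph_model, u, ant_s, post_s,
                                        imprint_radius)
            dofs, values = dirichlet(ant_s, post_s, ug)
            bcs = morph_model.bcs.with_prescribed(dofs, values)
            try:
                u_new, info = newton_solve(
                    asm, bcs, ug, loads=(), cavities=morph_model.cavities,
                    initial_pressures={cav.facet_set: p_prev},
                    rtol=rtol, atol=atol, max_iter=60, max_step=0.2,
                    ptc_kappa0=1.0)
            except SolverError as err:
                dt *= 0.5
                if dt < dt0 / 256:
                    raise SolverError(
                        f"morph continuation stalled at t={t_done:.3f}: {err}"
                    ) from err
                continue
            u, t_done = u_new, ts
            p_prev = info["cavity_pressures"][cav.facet_set]
            dt = min(dt * 1.5, 2 * dt0)
        return u, p_prev

    u = morph_model.u_pre.copy()
    p_prev = cav.p0
    history = []
    prev_xy = None
    it_count = 0
    for it in range(max_outer):
        it_count = it + 1
        u, p_prev = drive_to_stamps(u, p_prev)
        x = X + u.reshape(-1, 3)
        vr = 0.0
        for ids, stamp in ((ant_ids, ant_stamp), (post_ids, post_stamp)):
            r = np.hypot(x[ids, 0], x[ids, 1])
            vr = max(vr, float(np.max(np.abs(x[ids, 2] - stamp.height(r)))))
        history.append(vr)
        xy = np.concatenate([x[ant_ids, :2].ravel(), x[post_ids, :2].ravel()])
        dh = np.inf if prev_xy is None else float(np.max(np.abs(xy - prev_xy)))
        prev_xy = xy
        if vr <= imprint_tol and dh <= slide_tol:
            break
    else:
        raise SolverError(
            f"morphing did not converge in {max_outer} sliding iterations; "
            f"vertical residual history: {history}")

    J = asm.deformation_jacobians(u, only_tags=("cornea",))
    return MorphResult(
        u_morph=u, u_imprint=u - morph_model.u_pre, iop=float(p_prev),
        vertical_residual=history[-1],
        max_abs_J_minus_1=float(np.max(np.abs(J - 1.0))),
        outer_iterations=it_count, residual_history=history)


def enriched_identification(model: EyeModel,
                            contour_states: Sequence[ContourPair],
                            pulse: PulseLoad,
                            state_load_factors: Sequence[float],
                            k2_min: float = 10.0, k2_max: float = 400.0,
                            step: float = 10.0,
                            morph_modulus: float = 1.0,
                            order: int = 2, fbar: bool = True,
                            **morph_kw) -> Tuple[K2SearchResult, List[MorphResult]]:
    """Contour-only identification pipeline.

    For each deformation state the contours are morphed into a full
    displacement field on the (prestressed) eye model; the external
    forces are reconstructed from the known pulse pressure at the
    state's load factor plus the morph-updated cavity pressure; then the
    standard nested EGM identification (grid search over k2) runs on the
    morphed states.
    """
    if len(contour_states) < 3:
        raise ValueError("enriched identification needs >= 3 contour states")
    if len(state_load_factors) != len(contour_states):
        raise ValueError("one load factor per contour state is required")
    if model.u_pre is None:
        raise ValueError("model must be prestressed")

    morph_model = make_morph_model(model, modulus=morph_modulus)
    asm = model.assembler(order=order, fbar=fbar)
    cav = model.cavities[0]

    # rank check: zero-deformation contours carry no information
    ref = extrude_stamps(contour_states[0])
    defas = [c.defa for c in contour_states]
    if max(abs(d) for d in defas) < 1e-6:
        raise ValueError("zero-deformation contours: identification is rank "
                         "deficient (nothing to identify)")

    # the surrogate has its own stress-free reference; the identification
    # model consumes displacements from *its* reference, so fields are
    # converted through the common deformed configuration
    shift = (morph_model.mesh.nodes - model.mesh.nodes).ravel()
    states = []
    morphs = []
    for cp, lam in zip(contour_states, state_load_factors):
        res = morph_full_field(morph_model, cp, order=order, fbar=fbar,
                               **morph_kw)
        morphs.append(res)
        u_ident = res.u_morph + shift
        f_ext = asm.external_force(u_ident,
                                   [pulse.pressure_load(float(lam))],
                                   {cav.facet_set: res.iop})
        states.append((u_ident, f_ext))

    result = grid_search_k2(model, states, k2_min=k2_min, k2_max=k2_max,
                            step=step, order=order, fbar=fbar)
    return result, morphs
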
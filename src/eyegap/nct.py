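"""Virtual non-contact tonometry: synthetic full-field reference data.

An air-pulse surrogate (Gaussian spatial pressure profile, stepwise
temporal ramp) indents the prestressed eye model.  The solver history is
reduced to three deformation states -- (1) applanation, (2) midway
between applanation and peak on the load schedule, (3) maximum
deformation -- each stored with its matched external force vector so
that the equilibrium-gap identification sees exactly the equilibrium the
forward solve achieved.  2D deformation contours (anterior/posterior
surface in the symmetry plane) emulate what the tonometer camera can
actually observe, and a seeded uniform noise injector supports the noise
sensitivity study (no smoothing or regularisation is applied to the
perturbed fields).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .fem import PressureLoad, SolverError, newton_solve
from .geometry import EyeModel

__all__ = [
    "PulseLoad",
    "NoiseSpec",
    "ContourPair",
    "NCTRecord",
    "run_virtual_nct",
    "detect_applanation",
    "extract_contours",
    "add_noise",
    "compute_defa_pd",
]


class ApplanationError(RuntimeError):
    pass


@dataclass
class PulseLoad:
    """Surrogate air-pulse pressure: p(r) = peak * exp(-r^2 / (2 width^2)).

    ``peak`` (MPa) is calibrated once so the default fixture reaches an
    apex deflection of roughly 1 mm at full load; ``ramp`` is the list of
    monotone load factors in [0, 1] defining the stepwise simulation.
    Shear tractions are neglected by default.
    """

    peak: float = 0.014
    width: float = 1.5
    ramp: Sequence[float] = field(
        default_factory=lambda: tuple(np.linspace(0.0, 1.0, 13)[1:]))
    include_shear: bool = False

    def __post_init__(self):
        r = np.asarray(self.ramp, dtype=float)
        if np.any(r < 0) or np.any(r > 1) or np.any(np.diff(r) <= 0):
            raise ValueError("ramp factors must be monotone within [0, 1]")
        if self.include_shear:
            raise NotImplementedError("surface shear is not part of the "
                                      "surrogate pulse")

    def pressure_load(self, factor: float,
                      facet_set: str = "anterior") -> PressureLoad:
        peak, width = self.peak, self.width

        def p(x):
            r2 = x[..., 0] ** 2 + x[..., 1] ** 2
            return factor * peak * np.exp(-r2 / (2.0 * width ** 2))

        return PressureLoad(facet_set=facet_set, pressure=p)


@dataclass
class NoiseSpec:
    """Uniform absolute noise on displacement components, in mm."""

    amplitude: float
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class ContourPair:
    """Anterior/posterior (r, z) polylines in the symmetry plane (mm)."""

    anterior: np.ndarray           # (Na, 2)
    posterior: np.ndarray          # (Np, 2)
    defa: float = 0.0
    cct: float = 0.0
    iop: float = 0.0

    def __post_init__(self):
        self.anterior = np.asarray(self.anterior, dtype=float)
        self.posterior = np.asarray(self.posterior, dtype=float)
        for arr, name in ((self.anterior, "anterior"),
                          (self.posterior, "posterior")):
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"{name} contour must be an (n, 2) polyline")


@dataclass
class NCTRecord:
    """Synthetic tonometry record: history, three states, contours."""

    model: EyeModel
    pulse: PulseLoad
    load_factors: np.ndarray
    displacements: np.ndarray         # (n_steps, n_dofs), from stress-free ref
    cavity_pressures: np.ndarray      # (n_steps,), MPa
    defa_trace: np.ndarray            # (n_steps,), mm
    state_indices: Tuple[int, int, int]
    u_states: np.ndarray              # (3, n_dofs)
    f_ext_states: np.ndarray          # (3, n_dofs)
    state_cavity_pressures: np.ndarray
    state_load_factors: np.ndarray
    contours: List[ContourPair]
    contour_reference: ContourPair
    material_tag: str = ""
    seed: int = 0

    @property
    def states(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        """(displacement, external force) pairs of the three states."""
        return [(self.u_states[i], self.f_ext_states[i]) for i in range(3)]

    @property
    def defa_states(self) -> np.ndarray:
        return self.defa_trace[list(self.state_indices)]


def _apex_deflection(model: EyeModel, u: np.ndarray) -> float:
    """Downward apex displacement relative to the prestressed state (mm)."""
    apex = int(model.mesh.node_sets["apex_anterior"][0])
    dz = (u.reshape(-1, 3)[apex, 2]
          - model.u_pre.reshape(-1, 3)[apex, 2])
    return float(-dz)


def detect_applanation(positions_history: Sequence[np.ndarray],
                       ref_nodes: np.ndarray,
                       surface_ids: np.ndarray,
                       disc_radius: float = 1.0,
                       sagitta_tol: float = 5e-3,
                       symmetry: str = "quarter") -> int:
    """First history index at which the central anterior surface is flat.

    Flatness is measured as the maximum deviation (sagitta) of the
    surface nodes inside a disc of ``disc_radius`` (selected on the
    reference geometry) from their best-fit plane.  For symmetry-reduced
    models the disc nodes are mirrored into the full disc first --
    otherwise a tilted plane can fit a single quadrant of the curved cap
    and applanation would trigger spuriously.  Linear interpolation
    between steps is implicit in taking the first satisfying step of a
    fine ramp.
    """
    r_ref = np.hypot(ref_nodes[surface_ids, 0], ref_nodes[surface_ids, 1])
    disc = surface_ids[r_ref <= disc_radius]
    if disc.size < 3:
        raise ApplanationError("fewer than 3 surface nodes in the central "
                               "disc; increase disc_radius")
    mirrors = {"quarter": ((1, 1), (-1, 1), (1, -1), (-1, -1)),
               "half": ((1, 1), (1, -1)),
               "full": ((1, 1),)}[symmetry]
    for step, x in enumerate(positions_history):
        pts = np.vstack([x[disc] * np.array([sx, sy, 1.0])
                         for sx, sy in mirrors])
        A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
        coef, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
        sag = np.max(np.abs(pts[:, 2] - A @ coef))
        if sag < sagitta_tol:
            return step
    raise ApplanationError(
        f"surface never applanates within sagitta tolerance {sagitta_tol} mm")


def extract_contours(model: EyeModel, u: np.ndarray,
                     defa: float = 0.0, iop: float = 0.0,
                     plane_tol: float = 1e-9) -> ContourPair:
    """(r, z) polylines of the anterior/posterior corneal surfaces in the
    y = 0 symmetry plane at displacement ``u``."""
    mesh = model.mesh
    x = mesh.nodes + u.reshape(-1, 3)

    def polyline(set_name):
        ids = mesh.node_sets[set_name]
        in_plane = ids[(np.abs(mesh.nodes[ids, 1]) < plane_tol)
                       & (mesh.nodes[ids, 0] >= -plane_tol)]
        if in_plane.size == 0:
            raise ValueError(f"no '{set_name}' nodes in the symmetry plane")
        order = np.argsort(mesh.nodes[in_plane, 0])
        sel = in_plane[order]
        return np.column_stack([x[sel, 0], x[sel, 2]])

    ant = polyline("anterior_surface")
    post = polyline("posterior_surface")
    cct = float(ant[0, 1] - post[0, 1])
    return ContourPair(anterior=ant, posterior=post, defa=defa, cct=cct,
                       iop=iop)


def add_noise(u: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Seeded uniform perturbation in [-a, a] per displacement component."""
    rng = np.random.default_rng(spec.seed)
    return u + rng.uniform(-spec.amplitude, spec.amplitude, size=u.shape)


def run_virtual_nct(model: EyeModel, pulse: Optional[PulseLoad] = None,
                    order: int = 2, fbar: bool = True,
                    rtol: float = 1e-8, atol: float = 1e-10,
                    disc_radius: float = 1.0, sagitta_tol: float = 5e-3,
                    material_tag: str = "", seed: int = 0) -> NCTRecord:
    """Stepwise forward simulation of the tonometer pulse.

    The model must be prestressed (``stress_free_geometry`` output) so
    displacements are measured from the stress-free reference and the
    cavity pressure-volume law is anchored at the clinical IOP.
    """
    if model.u_pre is None:
        raise ValueError("model must be prestressed (run stress_free_geometry)")
    pulse = pulse or PulseLoad()
    asm = model.assembler(order=order, fbar=fbar)
    u = model.u_pre.copy()
    factors = np.asarray(pulse.ramp, dtype=float)

    n_steps = len(factors) + 1
    ndof = model.mesh.n_dofs
    U = np.zeros((n_steps, ndof))
    P = np.zeros(n_steps)
    U[0] = u
    P[0] = model.cavities[0].pressure(asm.cavity_volume(u, model.cavities[0]))

    def solve_at(lam, u_start):
        return newton_solve(asm, model.bcs, u_start,
                            loads=[pulse.pressure_load(lam)],
                            cavities=model.cavities, rtol=rtol, atol=atol)

    lam_prev = 0.0
    for s, lam in enumerate(factors, start=1):
        # adaptive substepping between the stored ramp factors
        lam_done, dlam = lam_prev, lam - lam_prev
        while lam_done < lam - 1e-12:
            lam_try = min(lam_done + dlam, lam)
            try:
                u_new, info = solve_at(lam_try, u)
            except SolverError as err:
                dlam *= 0.5
                if dlam < 1e-3 * (lam - lam_prev):
                    raise SolverError(
                        f"forward NCT failed at load factor {lam_try:.4f}: "
                        f"{err}") from err
                continue
            u, lam_done = u_new, lam_try
        lam_prev = lam
        U[s] = u
        P[s] = info["cavity_pressures"][model.cavities[0].facet_set]

    defa = np.array([_apex_deflection(model, U[s]) for s in range(n_steps)])

    positions = [model.mesh.nodes + U[s].reshape(-1, 3)
                 for s in range(n_steps)]
    i1 = detect_applanation(positions, model.mesh.nodes,
                            model.mesh.node_sets["anterior_surface"],
                            disc_radius=disc_radius, sagitta_tol=sagitta_tol,
                            symmetry=model.geometry.symmetry)
    if i1 == 0:
        # degenerate tolerance: the undeformed cap already counts as flat
        state_ids = (0, (n_steps - 1) // 2, n_steps - 1)
    else:
        i3 = n_steps - 1
        all_factors = np.concatenate([[0.0], factors])
        lam_mid = 0.5 * (all_factors[i1] + all_factors[i3])
        i2 = int(np.argmin(np.abs(all_factors - lam_mid)))
        i2 = min(max(i2, i1 + 1), i3 - 1)
        if not (0 < i1 < i2 < i3):
            raise ApplanationError(
                "cannot place three distinct states (applanation too close "
                "to peak load); refine the pulse ramp")
        state_ids = (i1, i2, i3)

    all_factors = np.concatenate([[0.0], factors])
    u_states = U[list(state_ids)]
    p_states = P[list(state_ids)]
    lam_states = all_factors[list(state_ids)]
    f_ext = np.empty_like(u_states)
    cav = model.cavities[0]
    for j, (us, ps, lam) in enumerate(zip(u_states, p_states, lam_states)):
        f_ext[j] = asm.external_force(us, [pulse.pressure_load(lam)],
                                      {cav.facet_set: ps})

    iop = model.iop or 0.0
    contour_ref = extract_contours(model, model.u_pre, defa=0.0, iop=iop)
    contours = [extract_contours(model, u_states[j], defa=float(defa[i]),
                                 iop=float(p_states[j]))
                for j, i in enumerate(state_ids)]

    return NCTRecord(
        model=model, pulse=pulse, load_factors=all_factors,
        displacements=U, cavity_pressures=P, defa_trace=defa,
        state_indices=state_ids, u_states=u_states, f_ext_states=f_ext,
        state_cavity_pressures=p_states, state_load_factors=lam_states,
        contours=contours, contour_reference=contour_ref,
        material_tag=material_tag, seed=seed)


def compute_defa_pd(record: NCTRecord, state: int):
    """(DefA, PD) of a stored state; PD is None when no bending maxima
    flank the apex (flagged by the caller via the None).

    PD is the in-plane distance between the two deflection maxima of the
    anterior contour; by symmetry of the reduced model it equals twice
    the radius of the maximum on the half-profile.  The radial node
    spacing limits its resolution and is returned alongside.
    """
    idx = record.state_indices[state]
    defa = float(record.defa_trace[idx])
    ant = record.contours[state].anterior
    r0 = record.contour_reference.anterior[:, 0]
    z = ant[:, 1]                    # deformed anterior contour height
    pd = None
    spacing = float(np.max(np.diff(r0)))
    # bending crest: interior local maximum of the deformed contour
    # flanking the central dimple (mirror-symmetric on the half profile)
    for i in range(1, len(z) - 1):
        if z[i] > z[i - 1] and z[i] >= z[i + 1]:
            pd = 2.0 * float(ant[i, 0])
            break
    return defa, pd, spacing
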
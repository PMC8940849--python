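"""Hexahedral finite-element core: kinematics, force assembly, Newton solver.

Discretisation choices (shared verbatim between the synthetic-data
generator and the inverse identification, which is what makes exact
parameter recovery possible):

* 8-node hexahedra, Gauss quadrature (2x2x2 by default, order switchable
  for convergence checks);
* mean-dilatation F-bar treatment of the volumetric response to avoid
  locking at near-incompressibility: the constitutive law is evaluated at
  ``Fbar = (Jbar/J)^(1/3) F`` with ``Jbar`` the element volume average;
* internal forces evaluated in the current configuration,
  ``f_e = int B^T sigma dv`` with the spatial gradient matrix and the
  Cauchy stress;
* follower pressure loads integrated on the deformed facets;
* fluid cavities with a single uniform pressure per cavity and a linear
  pressure-volume law ``p = p0 + K_W (V0 - V)/V0``, solved monolithically
  as an augmented (u, p) Newton system through a bordered elimination.

The Newton tangent is assembled by batched forward finite differences of
the element/facet force vectors (the solver contract is only the
converged residual tolerance), which keeps it consistent with whatever
residual the constitutive law defines.  Globalisation is tailored to
thin-shell bending and the stiff fluid coupling: non-monotone full-step
acceptance with a watchdog budget, chord reuse of factorised tangents,
an optional trust clamp on the increment, and optional pseudo-transient
continuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import (KinematicState, MaterialParameters, cauchy_stress,
                           det3, inv3)

__all__ = [
    "Mesh",
    "FluidCavity",
    "BoundaryConditions",
    "PressureLoad",
    "FiberField",
    "Assembler",
    "newton_solve",
    "cavity_state",
    "SolverError",
    "KinematicsError",
    "GeometryError",
]

# mmHg -> MPa, single authoritative definition
MMHG_TO_MPA = 133.322e-6


class SolverError(RuntimeError):
    pass


class KinematicsError(RuntimeError):
    pass


class GeometryError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# shape functions and quadrature

_HEX_CORNERS = np.array(
    [[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
     [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)

_QUAD_CORNERS = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)


def _gauss_1d(n: int):
    return np.polynomial.legendre.leggauss(n)


def hex_quadrature(order: int = 2):
    """Gauss points/weights and shape-function derivatives for hex8."""
    g, w = _gauss_1d(order)
    pts = np.array([[a, b, c] for a in g for b in g for c in g])
    wts = np.array([wa * wb * wc for wa in w for wb in w for wc in w])
    G = len(pts)
    N = np.empty((G, 8))
    dN = np.empty((G, 8, 3))
    for q, (xi, eta, zeta) in enumerate(pts):
        for a, (xa, ya, za) in enumerate(_HEX_CORNERS):
            N[q, a] = 0.125 * (1 + xi * xa) * (1 + eta * ya) * (1 + zeta * za)
            dN[q, a] = 0.125 * np.array([
                xa * (1 + eta * ya) * (1 + zeta * za),
                (1 + xi * xa) * ya * (1 + zeta * za),
                (1 + xi * xa) * (1 + eta * ya) * za,
            ])
    return pts, wts, N, dN


def quad_quadrature(order: int = 2):
    g, w = _gauss_1d(order)
    pts = np.array([[a, b] for a in g for b in g])
    wts = np.array([wa * wb for wa in w for wb in w])
    G = len(pts)
    N = np.empty((G, 4))
    dN = np.empty((G, 4, 2))
    for q, (xi, eta) in enumerate(pts):
        for a, (xa, ya) in enumerate(_QUAD_CORNERS):
            N[q, a] = 0.25 * (1 + xi * xa) * (1 + eta * ya)
            dN[q, a] = 0.25 * np.array([xa * (1 + eta * ya),
                                        (1 + xi * xa) * ya])
    return pts, wts, N, dN


# ---------------------------------------------------------------------------
# containers


@dataclass
class Mesh:
    """Hex8 mesh with named node, element and facet sets.

    ``facet_sets`` hold quad facets as (F, 4) node-id arrays ordered
    counter-clockwise seen from outside the solid (outward normal).
    ``elem_sets`` partition the elements by material tag.
    """

    nodes: np.ndarray
    elems: np.ndarray
    elem_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    node_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    facet_sets: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_dofs(self) -> int:
        return 3 * self.n_nodes

    def element_tag(self) -> np.ndarray:
        """Per-element tag array (object dtype) built from elem_sets."""
        tags = np.empty(self.elems.shape[0], dtype=object)
        for name, ids in self.elem_sets.items():
            tags[ids] = name
        return tags

    def check_jacobians(self, order: int = 2) -> float:
        """Min reference Jacobian over all elements/quadrature points."""
        _, _, _, dN = hex_quadrature(order)
        Xe = self.nodes[self.elems]                       # (E,8,3)
        J0 = np.einsum("eai,gaj->egij", Xe, dN)
        det = np.linalg.det(J0)
        return float(det.min())


@dataclass
class FluidCavity:
    """Closed fluid volume with one uniform pressure degree of freedom.

    The wetted facet set uses the solid-outward orientation (normals
    pointing into the fluid).  The enclosed volume is computed with the
    divergence theorem as ``V = -sum (z - z_ref) n_z da`` over the wetted
    facets; symmetry planes (n_z = 0) and the flat closure plane at
    ``z = z_ref`` contribute nothing, so the open fixture surface still
    yields the exact enclosed volume.
    """

    facet_set: str
    bulk_modulus: float          # K_W, MPa
    p0: float = 0.0              # baseline pressure, MPa
    V0: float = 0.0              # reference volume, mm^3
    z_ref: float = 0.0           # closure plane height, mm

    def pressure(self, volume: float) -> float:
        if self.V0 <= 0.0:
            raise GeometryError("cavity reference volume V0 must be > 0")
        return self.p0 + self.bulk_modulus * (self.V0 - volume) / self.V0


@dataclass
class BoundaryConditions:
    """Dirichlet data: fixed, symmetry and prescribed displacement DOFs."""

    fixed_dofs: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    symmetry_dofs: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    prescribed_dofs: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    prescribed_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def constrained_dofs(self) -> np.ndarray:
        return np.unique(np.concatenate(
            [self.fixed_dofs, self.symmetry_dofs, self.prescribed_dofs]))

    def free_mask(self, n_dofs: int) -> np.ndarray:
        mask = np.ones(n_dofs, dtype=bool)
        mask[self.constrained_dofs().astype(int)] = False
        return mask

    def with_prescribed(self, dofs, values) -> "BoundaryConditions":
        return BoundaryConditions(
            fixed_dofs=self.fixed_dofs, symmetry_dofs=self.symmetry_dofs,
            prescribed_dofs=np.asarray(dofs, int),
            prescribed_values=np.asarray(values, float))


@dataclass
class PressureLoad:
    """Follower pressure on a facet set; ``pressure(x)`` in MPa."""

    facet_set: str
    pressure: Callable[[np.ndarray], np.ndarray] | float

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        if callable(self.pressure):
            return np.asarray(self.pressure(points), dtype=float)
        return np.full(points.shape[:-1], float(self.pressure))


@dataclass
class FiberField:
    """Per-quadrature-point fiber data for the corneal element group.

    Arrays are ordered like the element ids of the group they belong to:
    ``a1``/``a2`` have shape (Ec, G, 3) and ``kappa`` (Ec, G).
    """

    elem_ids: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    kappa: np.ndarray


# ---------------------------------------------------------------------------
# assembly


class Assembler:
    """Internal/external force and tangent assembly over a mesh.

    Parameters
    ----------
    mesh : Mesh
    materials : dict
        Material per element-set tag.
    fiber_field : FiberField or None
        Fiber data for the ``fiber_tag`` group (default "cornea").
    order : int
        Gauss order per direction (2 or 3).
    fbar : bool
        Mean-dilatation F-bar treatment (default on).
    """

    def __init__(self, mesh: Mesh, materials: Dict[str, MaterialParameters],
                 fiber_field: Optional[FiberField] = None,
                 fiber_tag: str = "cornea", order: int = 2,
                 fbar: bool = True):
        self.mesh = mesh
        self.materials = dict(materials)
        self.fiber_field = fiber_field
        self.fiber_tag = fiber_tag
        self.fbar = fbar
        _, self._w, self._N, self._dN = hex_quadrature(order)
        _, self._wq, self._Nq, self._dNq = quad_quadrature(order)
        self.groups = []
        for name, ids in mesh.elem_sets.items():
            if name not in self.materials:
                raise KeyError(f"no material for element set '{name}'")
            conn = mesh.elems[ids]
            fibers = None
            if name == fiber_tag and fiber_field is not None:
                if not np.array_equal(np.asarray(fiber_field.elem_ids), ids):
                    raise ValueError("fiber field element ids do not match "
                                     f"element set '{name}'")
                fibers = (fiber_field.a1, fiber_field.a2, fiber_field.kappa)
            self.groups.append((name, ids, conn, fibers))
        # global dof indices per group for scatter, and cached reference
        # geometry data (the mesh nodes are fixed for an assembler's life)
        self._dofmaps = {}
        self._refdata = {}
        for name, ids, conn, _ in self.groups:
            dof = (3 * conn[:, :, None] + np.arange(3)).reshape(len(ids), 24)
            self._dofmaps[name] = dof
            Xe = mesh.nodes[conn]
            J0 = np.einsum("eai,gaj->egij", Xe, self._dN)
            detJ0 = np.linalg.det(J0)
            if np.any(detJ0 <= 0.0):
                bad = np.unique(np.where(detJ0 <= 0.0)[0])
                raise KinematicsError(
                    f"non-positive reference Jacobian in group '{name}', "
                    f"elements {bad.tolist()[:10]}")
            dNdX = np.einsum("gaj,egji->egai", self._dN, np.linalg.inv(J0))
            vol0 = np.einsum("eg,g->e", detJ0, self._w)
            self._refdata[name] = (detJ0, dNdX, vol0)

    # -- element level ------------------------------------------------------

    def _group_stress(self, F, name, fibers, params):
        """Cauchy stress for one element group, batched over (E, G)."""
        fib = None
        if fibers is not None:
            fib = fibers
        state = KinematicState.from_deformation_gradient(F, None)
        return cauchy_stress(state, params, fib)

    def _element_forces(self, ue, name, fibers, params):
        """Internal nodal forces of one element group, (..., E, 8, 3).

        ``ue`` may carry leading batch axes (used for the vectorised
        finite-difference tangent).
        """
        w = self._w
        detJ0, dNdX, vol0 = self._refdata[name]
        F = np.einsum("...eai,egaj->...egij", ue, dNdX) + np.eye(3)
        J = det3(F)
        if np.any(J <= 0.0):
            bad = np.unique(np.where(J <= 0.0)[J.ndim - 2])
            raise KinematicsError(
                f"inverted element(s) in group '{name}': {bad.tolist()[:10]}")
        if self.fbar:
            Jbar = np.einsum("...eg,eg,g->...e", J, detJ0, w,
                             optimize=True) / vol0
            Fc = (Jbar[..., None] / J) ** (1.0 / 3.0)
            Fbar = Fc[..., None, None] * F
        else:
            Fbar = F
        sigma = self._group_stress(Fbar, name, fibers, params)
        Finv = inv3(F, J)
        dNdx = np.einsum("egai,...egij->...egaj", dNdX, Finv)
        jx = detJ0 * J
        f = np.einsum("...egij,...egaj,...eg,g->...eai", sigma, dNdx, jx, w,
                      optimize=True)
        return f

    # -- global internal force ---------------------------------------------

    def internal_force(self, u: np.ndarray,
                       params_override: Optional[Dict[str, MaterialParameters]] = None,
                       only_tags: Optional[Sequence[str]] = None) -> np.ndarray:
        """Assembled global internal force vector (length n_dofs, N).

        ``params_override`` substitutes materials per tag (used to build
        the unit-parameter sensitivity columns); ``only_tags`` restricts
        assembly to a subset of element groups (used to fold the
        known-material internal forces into the effective load).
        """
        u = u.reshape(-1, 3)
        f = np.zeros(self.mesh.n_dofs)
        for name, ids, conn, fibers in self.groups:
            if only_tags is not None and name not in only_tags:
                continue
            params = (params_override or {}).get(name, self.materials[name])
            ue = u[conn]
            fe = self._element_forces(ue, name, fibers, params)
            np.add.at(f, self._dofmaps[name].ravel(), fe.reshape(len(ids), 24).ravel())
        return f

    def tangent_internal(self, u: np.ndarray, h: float = 1e-6) -> sp.csr_matrix:
        """Element-wise central-difference tangent of the internal force."""
        u = u.reshape(-1, 3)
        rows, cols, vals = [], [], []
        for name, ids, conn, fibers in self.groups:
            params = self.materials[name]
            ue = u[conn]
            E = len(ids)
            # batched forward differences: one vectorised call for the
            # unperturbed state plus all 24 element-DOF perturbations
            pert = np.zeros((25, 1, 8, 3))
            for j in range(24):
                a, i = divmod(j, 3)
                pert[j + 1, 0, a, i] = h
            fb = self._element_forces(ue[None] + pert, name, fibers, params)
            Ke = ((fb[1:] - fb[0]).reshape(24, E, 24) / h).transpose(1, 2, 0)
            dof = self._dofmaps[name]
            rows.append(np.repeat(dof, 24, axis=1).ravel())
            cols.append(np.tile(dof, (1, 24)).ravel())
            vals.append(Ke.transpose(0, 2, 1).ravel())
        n = self.mesh.n_dofs
        K = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n))
        return K.tocsr()

    def deformation_jacobians(self, u: np.ndarray,
                              only_tags: Optional[Sequence[str]] = None,
                              bar: Optional[bool] = None) -> np.ndarray:
        """Per-quadrature-point det(F) (flattened over the selected groups).

        With ``bar`` (default: the assembler's F-bar setting) the
        element-averaged dilatation actually seen by the material is
        reported.
        """
        if bar is None:
            bar = self.fbar
        u = u.reshape(-1, 3)
        w = self._w
        out = []
        for name, ids, conn, _ in self.groups:
            if only_tags is not None and name not in only_tags:
                continue
            detJ0, dNdX, vol0 = self._refdata[name]
            F = np.einsum("eai,egaj->egij", u[conn], dNdX) + np.eye(3)
            J = np.linalg.det(F)
            if bar:
                Jbar = np.einsum("eg,eg,g->e", J, detJ0, w) / vol0
                J = np.broadcast_to(Jbar[:, None], J.shape)
            out.append(np.asarray(J).ravel())
        return np.concatenate(out) if out else np.empty(0)

    # -- facet integrals ----------------------------------------------------

    def _facet_force(self, xf: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Nodal forces from pressure p (per facet gp) on facets xf (F,4,3).

        Traction is ``-p n`` with n the outward facet normal, i.e. the
        pressure pushes against the solid.
        """
        dNq, Nq, wq = self._dNq, self._Nq, self._wq
        t1 = np.einsum("fai,ga->fgi", xf, dNq[:, :, 0])
        t2 = np.einsum("fai,ga->fgi", xf, dNq[:, :, 1])
        nda = np.cross(t1, t2)
        return -np.einsum("fg,ga,fgi,g->fai", p, Nq, nda, wq)

    def facet_points(self, xf: np.ndarray) -> np.ndarray:
        return np.einsum("ga,fai->fgi", self._Nq, xf)

    def external_force(self, u: np.ndarray, loads: Sequence[PressureLoad],
                       cavity_pressures: Optional[Dict[str, float]] = None
                       ) -> np.ndarray:
        """Global follower-load vector at configuration x = X + u.

        ``cavity_pressures`` maps wetted facet-set names to their current
        uniform pressure.
        """
        x = self.mesh.nodes + u.reshape(-1, 3)
        f = np.zeros(self.mesh.n_dofs)
        items: List[Tuple[str, object]] = [(ld.facet_set, ld) for ld in loads]
        for name, pval in (cavity_pressures or {}).items():
            items.append((name, float(pval)))
        for fs_name, spec in items:
            facets = self.mesh.facet_sets[fs_name]
            xf = x[facets]
            pts = self.facet_points(xf)
            if isinstance(spec, PressureLoad):
                p = spec.evaluate(pts)
            else:
                p = np.full(pts.shape[:-1], spec)
            fe = self._facet_force(xf, p)
            dof = (3 * facets[:, :, None] + np.arange(3)).reshape(len(facets), 12)
            np.add.at(f, dof.ravel(), fe.reshape(len(facets), 12).ravel())
        return f

    def tangent_external(self, u: np.ndarray, loads: Sequence[PressureLoad],
                         cavity_pressures: Optional[Dict[str, float]] = None,
                         h: float = 1e-6) -> sp.csr_matrix:
        """Facet-wise FD tangent of the follower loads (pressures frozen)."""
        x = self.mesh.nodes + u.reshape(-1, 3)
        rows, cols, vals = [], [], []
        items: List[Tuple[str, object]] = [(ld.facet_set, ld) for ld in loads]
        for name, pval in (cavity_pressures or {}).items():
            items.append((name, float(pval)))
        for fs_name, spec in items:
            facets = self.mesh.facet_sets[fs_name]
            xf = x[facets]
            Fn = len(facets)
            Ke = np.empty((Fn, 12, 12))
            for j in range(12):
                a, i = divmod(j, 3)
                xp = xf.copy(); xp[:, a, i] += h
                xm = xf.copy(); xm[:, a, i] -= h
                for sgn, xx in ((1, xp), (-1, xm)):
                    pts = self.facet_points(xx)
                    if isinstance(spec, PressureLoad):
                        p = spec.evaluate(pts)
                    else:
                        p = np.full(pts.shape[:-1], spec)
                    fe = self._facet_force(xx, p).reshape(Fn, 12)
                    if sgn == 1:
                        acc = fe
                    else:
                        acc = acc - fe
                Ke[:, :, j] = acc / (2 * h)
            dof = (3 * facets[:, :, None] + np.arange(3)).reshape(Fn, 12)
            rows.append(np.repeat(dof, 12, axis=1).ravel())
            cols.append(np.tile(dof, (1, 12)).ravel())
            vals.append(Ke.transpose(0, 2, 1).ravel())
        n = self.mesh.n_dofs
        if not rows:
            return sp.csr_matrix((n, n))
        K = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n))
        return K.tocsr()

    # -- cavity geometry ----------------------------------------------------

    def cavity_volume(self, u: np.ndarray, cavity: FluidCavity) -> float:
        """Enclosed cavity volume at configuration x = X + u (mm^3)."""
        x = self.mesh.nodes + u.reshape(-1, 3)
        facets = self.mesh.facet_sets[cavity.facet_set]
        return self._cavity_volume_coords(x[facets], cavity.z_ref)

    def _cavity_volume_coords(self, xf: np.ndarray, z_ref: float) -> float:
        dNq, Nq, wq = self._dNq, self._Nq, self._wq
        t1 = np.einsum("fai,ga->fgi", xf, dNq[:, :, 0])
        t2 = np.einsum("fai,ga->fgi", xf, dNq[:, :, 1])
        nda = np.cross(t1, t2)
        z = np.einsum("ga,fa->fg", Nq, xf[:, :, 2]) - z_ref
        # cavity outward normal is -n (solid-outward points into the fluid)
        return float(-np.einsum("fg,fg,g->", z, nda[:, :, 2], wq))

    def cavity_volume_gradient(self, u: np.ndarray, cavity: FluidCavity,
                               h: float = 1e-6) -> np.ndarray:
        """dV/du by facet-wise central differences (global vector)."""
        x = self.mesh.nodes + u.reshape(-1, 3)
        facets = self.mesh.facet_sets[cavity.facet_set]
        xf = x[facets]
        Fn = len(facets)
        g = np.zeros(self.mesh.n_dofs)
        dof = (3 * facets[:, :, None] + np.arange(3)).reshape(Fn, 12)
        for j in range(12):
            a, i = divmod(j, 3)
            xp = xf.copy(); xp[:, a, i] += h
            xm = xf.copy(); xm[:, a, i] -= h
            dvp = self._facet_volume_contrib(xp, cavity.z_ref)
            dvm = self._facet_volume_contrib(xm, cavity.z_ref)
            contrib = (dvp - dvm) / (2 * h)
            np.add.at(g, dof[:, j], contrib)
        return g

    def _facet_volume_contrib(self, xf: np.ndarray, z_ref: float) -> np.ndarray:
        dNq, Nq, wq = self._dNq, self._Nq, self._wq
        t1 = np.einsum("fai,ga->fgi", xf, dNq[:, :, 0])
        t2 = np.einsum("fai,ga->fgi", xf, dNq[:, :, 1])
        nda = np.cross(t1, t2)
        z = np.einsum("ga,fa->fg", Nq, xf[:, :, 2]) - z_ref
        return -np.einsum("fg,fg,g->f", z, nda[:, :, 2], wq)


def cavity_state(assembler: Assembler, u: np.ndarray,
                 cavity: FluidCavity) -> Tuple[float, float]:
    """(volume mm^3, pressure MPa) of a cavity at displacement u."""
    V = assembler.cavity_volume(u, cavity)
    return V, cavity.pressure(V)


# ---------------------------------------------------------------------------
# Newton solver


def _line_search(trial, rn, tol, fresh_tangent, grow_left):
    """Backtracking line search with non-monotone full-step acceptance.

    Thin-shell bending makes the residual norm non-monotone along
    perfectly good Newton paths, so a full step from a fresh tangent may
    be accepted even if the residual transiently grows (bounded by a
    large factor and a watchdog budget managed by the caller; the stiff
    cavity constraint can inflate the merit by orders of magnitude for
    one iteration before quadratic convergence sets in).
    ``trial(step)`` returns a tuple whose first entry is the residual
    norm; it may raise KinematicsError for inadmissible steps.
    """
    best = None
    step = 1.0
    for _ in range(9):
        try:
            cand = trial(step)
        except KinematicsError:
            step *= 0.5
            continue
        if best is None or cand[0] < best[0]:
            best = cand
        if cand[0] < (1.0 - 1e-4) * rn or cand[0] <= tol:
            return cand
        if (step == 1.0 and fresh_tangent and grow_left > 0
                and cand[0] <= 1e3 * rn):
            return cand
        step *= 0.5
    return best


def _newton_fixed_pressures(assembler: Assembler, bcs: BoundaryConditions,
                            u0: np.ndarray, loads, pressures: Dict[str, float],
                            rtol: float, atol: float, max_iter: int,
                            h_fd: float, free: np.ndarray,
                            max_step: Optional[float] = None,
                            ptc_kappa0: Optional[float] = None):
    """Inner Newton loop with all cavity pressures held fixed.

    Returns (u, info, lu) where ``lu`` is the LU factorisation of the
    last free-DOF tangent (reused by the outer cavity-pressure Newton).
    """
    u = u0.copy()

    def residual(uv):
        fint = assembler.internal_force(uv)
        fext = assembler.external_force(uv, loads, pressures)
        return fint - fext, fext

    R, fext = residual(u)
    ref = np.linalg.norm(fext[free])
    rn = np.linalg.norm(R[free])
    history = [rn]
    it = 0
    stall = 0
    lu = None
    fresh = False
    grow_budget = [3]
    while rn > rtol * ref + atol:
        if it >= max_iter:
            raise SolverError(
                f"Newton did not converge after {max_iter} iterations "
                f"(|R|={rn:.3e}, ref={ref:.3e}, history={history[-5:]})")
        if lu is None or not fresh or ptc_kappa0 is not None:
            K = assembler.tangent_internal(u, h=h_fd)
            K = K - assembler.tangent_external(u, loads, pressures, h=h_fd)
            Kf = K[free][:, free]
            if ptc_kappa0 is not None:
                # pseudo-transient continuation: the damping vanishes
                # with the residual, so the converged state is unbiased
                kap = ptc_kappa0 * rn / max(ref, 1e-12)
                Kf = Kf + kap * sp.identity(Kf.shape[0], format="csr")
            lu = spla.splu(Kf.tocsc())
            fresh = True
        du = -lu.solve(R[free])
        if max_step is not None:
            mx = np.abs(du).max()
            if mx > max_step:
                du *= max_step / mx

        def trial(step):
            u_try = u.copy()
            u_try[free] += step * du
            R_try, fext_try = residual(u_try)
            return np.linalg.norm(R_try[free]), step, u_try, R_try, fext_try

        best = _line_search(trial, rn, rtol * ref + atol, fresh,
                            grow_budget[0])
        if best is None:
            raise SolverError("line search failed: element inversion at all "
                              "step lengths")
        grew = best[0] >= rn
        grow_budget[0] = grow_budget[0] - 1 if grew else 3
        stall = stall + 1 if best[0] >= (1.0 - 1e-4) * rn else 0
        # chord strategy: reuse the factorised tangent while full steps
        # make good progress, reassemble otherwise
        reuse = (best[1] == 1.0 and best[0] < 0.5 * rn)
        rn, _, u, R, fext = best
        fresh = fresh and reuse
        ref = max(ref, np.linalg.norm(fext[free]))
        history.append(rn)
        it += 1
        if stall >= 6:
            raise SolverError(
                f"Newton stagnated after {it} iterations "
                f"(|R|={rn:.3e}, ref={ref:.3e}, history={history[-5:]})")
    info = {"iterations": it, "residual_norm": rn, "reference_norm": ref,
            "history": history}
    return u, info, lu


def newton_solve(assembler: Assembler, bcs: BoundaryConditions,
                 u0: np.ndarray, loads: Sequence[PressureLoad] = (),
                 cavities: Sequence[FluidCavity] = (),
                 fixed_cavity_pressures: Optional[Dict[str, float]] = None,
                 initial_pressures: Optional[Dict[str, float]] = None,
                 rtol: float = 1e-8, atol: float = 1e-10,
                 max_iter: int = 60, max_pressure_iter: int = 25,
                 h_fd: float = 1e-6, max_step: Optional[float] = None,
                 ptc_kappa0: Optional[float] = None):
    """Solve quasi-static equilibrium for the free DOFs.

    ``fixed_cavity_pressures`` (facet-set name -> MPa) holds cavity
    pressures constant (used while the stress-free geometry and the
    prestress are computed).  Otherwise each cavity pressure follows its
    linear pressure-volume law; because the fluid is orders of magnitude
    stiffer than the tissue, the pressure unknowns are solved by an
    exact nested (Schur-complement) Newton: the inner loop equilibrates
    the displacements at fixed pressures, the outer scalar Newton
    updates the pressures using the condensed compliance
    ``dV_i/dp_j = a_i^T K^-1 g_j``.  Both loops converge to the same
    monolithic residual tolerance.

    Returns ``(u, info)``; ``info`` carries residual norms, iteration
    counts and the final cavity pressures.
    """
    n = assembler.mesh.n_dofs
    u = np.array(u0, dtype=float).reshape(-1).copy()
    if u.size != n:
        raise ValueError("u0 has wrong size")
    u[bcs.fixed_dofs.astype(int)] = 0.0
    u[bcs.symmetry_dofs.astype(int)] = 0.0
    if bcs.prescribed_dofs.size:
        u[bcs.prescribed_dofs.astype(int)] = bcs.prescribed_values
    free = bcs.free_mask(n)

    fixed_p = dict(fixed_cavity_pressures or {})
    live = [c for c in cavities if c.facet_set not in fixed_p]

    if not live:
        u, info, _ = _newton_fixed_pressures(
            assembler, bcs, u, loads, fixed_p, rtol, atol, max_iter, h_fd,
            free, max_step=max_step, ptc_kappa0=ptc_kappa0)
        info["cavity_pressures"] = dict(fixed_p)
        info["pressure_iterations"] = 0
        return u, info

    # augmented monolithic Newton: unknowns (u, p); the pressure enters
    # the displacement residual linearly, and the volume constraint
    # R_p = (V - V0) + (p - p0) V0/K_W is only mildly nonlinear, so the
    # bordered Newton is robust despite the fluid/tissue stiffness
    # contrast (exact elimination of p would make the residual stiff)
    nc = len(live)
    # the default initial pressure follows the volume law at u0 (good
    # when u0 is a nearby converged state); callers supplying a
    # constructed initial guess should pass initial_pressures instead
    p = np.array([
        (initial_pressures or {}).get(
            c.facet_set, c.pressure(assembler.cavity_volume(u, c)))
        for c in live])
    D = np.array([c.V0 / c.bulk_modulus for c in live])
    scale_p = np.array([c.bulk_modulus / c.V0 for c in live])

    def pressures_of(pvec):
        out = dict(fixed_p)
        out.update({c.facet_set: float(pi) for c, pi in zip(live, pvec)})
        return out

    def residuals(uv, pvec):
        cp = pressures_of(pvec)
        Ru = assembler.internal_force(uv) - assembler.external_force(
            uv, loads, cp)
        V = np.array([assembler.cavity_volume(uv, c) for c in live])
        Rp = (V - np.array([c.V0 for c in live])
              + (pvec - np.array([c.p0 for c in live])) * D)
        fext = assembler.external_force(uv, loads, cp)
        return Ru, Rp, fext

    def merit(Ru, Rp):
        # volume mismatch converted to an equivalent force scale
        return np.sqrt(np.linalg.norm(Ru[free]) ** 2
                       + np.sum((scale_p * Rp) ** 2) * gnorm2)

    gnorm2 = 1.0
    Ru, Rp, fext = residuals(u, p)
    gvecs = [assembler.external_force(u, (), {c.facet_set: 1.0})
             for c in live]
    gnorm2 = float(np.mean([np.linalg.norm(g[free]) ** 2 for g in gvecs]))
    ref = np.linalg.norm(fext[free])
    rn = merit(Ru, Rp)
    history = [rn]
    it = 0
    stall = 0
    lu = None
    fresh = False
    grow_budget = [3]
    while rn > rtol * ref + atol:
        if it >= max_iter:
            raise SolverError(
                f"augmented Newton did not converge after {max_iter} "
                f"iterations (|R|={rn:.3e}, ref={ref:.3e}, "
                f"history={history[-5:]})")
        cp = pressures_of(p)
        if lu is None or not fresh or ptc_kappa0 is not None:
            K = assembler.tangent_internal(u, h=h_fd)
            K = K - assembler.tangent_external(u, loads, cp, h=h_fd)
            Kf0 = K[free][:, free]
            if ptc_kappa0 is not None:
                kap = ptc_kappa0 * rn / max(ref, 1e-12)
                Kf0 = Kf0 + kap * sp.identity(Kf0.shape[0], format="csr")
            lu = spla.splu(Kf0.tocsc())
            fresh = True
        G = np.column_stack([g[free] for g in gvecs])
        A = np.column_stack([assembler.cavity_volume_gradient(u, c, h=h_fd)[free]
                             for c in live])
        x0 = lu.solve(Ru[free])
        X = np.column_stack([lu.solve(G[:, j]) for j in range(nc)])
        M = A.T @ X + np.diag(D)
        dp = np.linalg.solve(M, -Rp + A.T @ x0)
        du = -x0 + X @ dp
        if max_step is not None:
            mx = np.abs(du).max()
            if mx > max_step:
                du *= max_step / mx
                dp = dp * (max_step / mx)

        def trial(step):
            u_try = u.copy()
            u_try[free] += step * du
            p_try = p + step * dp
            Ru_t, Rp_t, fext_t = residuals(u_try, p_try)
            return (merit(Ru_t, Rp_t), step, u_try, p_try, Ru_t, Rp_t,
                    fext_t)

        best = _line_search(trial, rn, rtol * ref + atol, fresh,
                            grow_budget[0])
        if best is None:
            raise SolverError("line search failed: element inversion at all "
                              "step lengths")
        grew = best[0] >= rn
        grow_budget[0] = grow_budget[0] - 1 if grew else 3
        stall = stall + 1 if best[0] >= (1.0 - 1e-4) * rn else 0
        reuse = (best[1] == 1.0 and best[0] < 0.5 * rn)
        rn, _, u, p, Ru, Rp, fext = best
        fresh = fresh and reuse
        gvecs = [assembler.external_force(u, (), {c.facet_set: 1.0})
                 for c in live]
        ref = max(ref, np.linalg.norm(fext[free]))
        history.append(rn)
        it += 1
        if stall >= 6:
            raise SolverError(
                f"augmented Newton stagnated after {it} iterations "
                f"(|R|={rn:.3e}, ref={ref:.3e}, history={history[-5:]})")
    info = {
        "iterations": it,
        "pressure_iterations": it,
        "residual_norm": rn,
        "reference_norm": ref,
        "history": history,
        "cavity_pressures": pressures_of(p),
    }
    return u, info
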
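"""Equilibrium-gap identification of the linear material parameters.

The discrete residual of the eye model is linear in the corneal
parameters (K, mu, k1) at fixed displacements and fixed k2::

    R(u) = K c_K + mu c_mu + k1 c_k1 - f_eff ,

where each sensitivity column ``c_i`` is simply the assembled internal
force with that parameter set to one and the others to zero, and
``f_eff`` collects the known external loads plus the cavity pressure
minus the internal forces of the components with known moduli (limbus,
sclera).  Minimising ``||R||^2`` over the free DOFs is a convex 3x3
normal-equation solve; non-negativity of the moduli is enforced by an
NNLS fallback when the unconstrained optimum leaves the admissible set.
No forward solve is involved anywhere -- the method is update-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import scipy.optimize

from .geometry import EyeModel

__all__ = [
    "SensitivityMatrices",
    "LinearIdentification",
    "StateSensitivity",
    "compute_sensitivity_vectors",
    "solve_linear_parameters",
    "identify_states",
]


@dataclass
class SensitivityMatrices:
    """Unit-parameter force columns and effective load on the ID DOFs."""

    c_K: np.ndarray
    c_mu: np.ndarray
    c_k1: np.ndarray
    f_eff: np.ndarray
    mask: np.ndarray            # boolean over global DOFs
    k2: float


@dataclass
class LinearIdentification:
    """Result of one linear-parameter identification."""

    K: float
    mu: float
    k1: float
    residual_norm: float
    rel_residual: float
    constraint_active: Tuple[bool, bool, bool] = (False, False, False)
    warnings: List[str] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.K, self.mu, self.k1])


def identification_mask(model: EyeModel,
                        cornea_only: bool = False) -> np.ndarray:
    """Boolean DOF mask for the identification residual.

    Dirichlet and symmetry DOFs carry unknown reactions and are always
    excluded; optionally the mask is restricted to DOFs of nodes touched
    by corneal elements.
    """
    mask = model.bcs.free_mask(model.mesh.n_dofs)
    if cornea_only:
        ids = model.mesh.elem_sets["cornea"]
        nodes = np.unique(model.mesh.elems[ids])
        sub = np.zeros(model.mesh.n_dofs, dtype=bool)
        sub[(3 * nodes[:, None] + np.arange(3)).ravel()] = True
        mask = mask & sub
    return mask


class StateSensitivity:
    """Per-state assembly cache for the nested k2 search.

    ``c_K`` and ``c_mu`` do not depend on k2; only the fiber column has
    to be re-assembled per grid point.
    """

    def __init__(self, model: EyeModel, u: np.ndarray, f_ext: np.ndarray,
                 order: int = 2, fbar: bool = True,
                 cornea_only: bool = False):
        self.model = model
        self.u = np.asarray(u, dtype=float)
        self.asm = model.assembler(order=order, fbar=fbar)
        self.mask = identification_mask(model, cornea_only=cornea_only)
        base = model.cornea_params
        pK = base.replace(K=1.0, mu=0.0, k1=0.0)
        pmu = base.replace(K=0.0, mu=1.0, k1=0.0)
        self._base = base
        self.c_K = self.asm.internal_force(
            self.u, {"cornea": pK}, only_tags=("cornea",))
        self.c_mu = self.asm.internal_force(
            self.u, {"cornea": pmu}, only_tags=("cornea",))
        known_tags = tuple(t for t in model.mesh.elem_sets if t != "cornea")
        f_known = (self.asm.internal_force(self.u, only_tags=known_tags)
                   if known_tags else 0.0)
        self.f_eff = np.asarray(f_ext, dtype=float) - f_known

    def fiber_column(self, k2: float) -> np.ndarray:
        pk1 = self._base.replace(K=0.0, mu=0.0, k1=1.0, k2=float(k2))
        return self.asm.internal_force(self.u, {"cornea": pk1},
                                       only_tags=("cornea",))

    def at_k2(self, k2: float) -> SensitivityMatrices:
        m = self.mask
        return SensitivityMatrices(
            c_K=self.c_K[m], c_mu=self.c_mu[m],
            c_k1=self.fiber_column(k2)[m], f_eff=self.f_eff[m],
            mask=m, k2=float(k2))


def compute_sensitivity_vectors(model: EyeModel, u: np.ndarray, k2: float,
                                f_ext: np.ndarray, order: int = 2,
                                fbar: bool = True,
                                cornea_only: bool = False
                                ) -> SensitivityMatrices:
    """Assemble (c_K, c_mu, c_k1, f_eff) for one displacement state.

    Each column is the internal-force vector returned by the assembler
    with the corresponding parameter set to one, the others to zero and
    external forces zero -- the "unit parameter" evaluation that any FE
    code can provide without modification.
    """
    cache = StateSensitivity(model, u, f_ext, order=order, fbar=fbar,
                             cornea_only=cornea_only)
    return cache.at_k2(k2)


def solve_linear_parameters(S: SensitivityMatrices) -> LinearIdentification:
    """Least-squares optimum of ||K c_K + mu c_mu + k1 c_k1 - f_eff||.

    Solved through column-scaled 3x3 normal equations; if any parameter
    leaves the admissible set (K, mu, k1 >= 0) the problem is re-solved
    with non-negativity constraints (NNLS) and the active set flagged.
    """
    A = np.column_stack([S.c_K, S.c_mu, S.c_k1])
    b = S.f_eff
    norm_b = np.linalg.norm(b)
    col_norms = np.linalg.norm(A, axis=0)
    warnings = []
    names = ("K", "mu", "k1")
    scale = np.where(col_norms > 0, col_norms, 1.0)
    ref = max(col_norms.max(), 1e-300)
    for i, cn in enumerate(col_norms):
        if cn <= 1e-12 * ref:
            warnings.append(
                f"identifiability: column c_{names[i]} is numerically zero "
                "(deficient direction)")
    As = A / scale
    G = As.T @ As
    rhs = As.T @ b
    try:
        alpha_s = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError:
        alpha_s, *_ = np.linalg.lstsq(As, b, rcond=None)
        warnings.append("identifiability: singular normal equations, "
                        "minimum-norm solution returned")
    alpha = alpha_s / scale
    active = (False, False, False)
    if np.any(alpha < 0.0):
        sol_s, _ = scipy.optimize.nnls(As, b)
        alpha = sol_s / scale
        active = tuple(bool(a <= 0.0) for a in alpha)
    r = A @ alpha - b
    rn = float(np.linalg.norm(r))
    return LinearIdentification(
        K=float(alpha[0]), mu=float(alpha[1]), k1=float(alpha[2]),
        residual_norm=rn,
        rel_residual=float(rn / norm_b) if norm_b > 0 else np.inf,
        constraint_active=active, warnings=warnings)


def identify_states(model: EyeModel,
                    states: Sequence[Tuple[np.ndarray, np.ndarray]],
                    k2: float, order: int = 2, fbar: bool = True,
                    cornea_only: bool = False) -> List[LinearIdentification]:
    """Independent linear-parameter identification per deformation state.

    ``states`` are (displacement, external force) pairs as stored in an
    NCT record.  Deterministic; states do not interact.
    """
    if len(states) < 1:
        raise ValueError("at least one deformation state is required")
    out = []
    for u, f_ext in states:
        S = compute_sensitivity_vectors(model, u, k2, f_ext, order=order,
                                        fbar=fbar, cornea_only=cornea_only)
        out.append(solve_linear_parameters(S))
    return out
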
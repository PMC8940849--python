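"""Anisotropic hyperelastic constitutive model of the corneal stroma.

The strain energy density is additively split into a volumetric penalty,
an isotropic (neo-Hookean) matrix part and two transversely isotropic
collagen-fiber parts with orientation dispersion::

    psi = psi_vol(J) + psi_iso(I1t) + sum_i psi_ti(I4t*_i),      i = 1, 2

with

    psi_vol = K/4 * (J^2 - 1 - 2 ln J)
    psi_iso = mu/2 * (I1t - 3)
    psi_ti  = k1/(2 k2) * (exp[k2 (I4t* - 1)^2] - 1) * a

where ``I1t`` is the isochoric first invariant, ``I4t`` the isochoric
fourth (fiber) invariant and the modified invariant blends both through
the dispersion parameter ``kappa``::

    I4t* = kappa * I1t + (1 - 3 kappa) * I4t .

``K`` (volumetric penalty), ``mu`` (matrix shear modulus) and ``k1``
(fiber stiffness) enter the Cauchy stress *linearly*; ``k2`` (fiber
nonlinearity, dimensionless) enters through the exponential only.  This
exact linearity is the property exploited by the equilibrium gap
identification and is exposed here as :func:`stress_decomposition`.

Units: mm-N-MPa system throughout (stresses and moduli in MPa), except
:func:`plate_rigidity` which is a stand-alone SI utility (Pa, m -> N*m).

All stress/energy routines are vectorised: deformation gradients of shape
``(..., 3, 3)`` with matching per-point fiber data are evaluated in one
call, which the FEM assembly relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "MaterialParameters",
    "FiberPoint",
    "KinematicState",
    "PlateLayer",
    "modified_invariant",
    "strain_energy",
    "cauchy_stress",
    "stress_decomposition",
    "plate_rigidity",
]

#: below this value of k2 the fiber energy switches to its quadratic
#: series limit  k1/2 * (I4*-1)^2 * (1 + k2/2 (I4*-1)^2)  to avoid 0/0
K2_SERIES_THRESHOLD = 1e-6

_I3 = np.eye(3)


@dataclass
class MaterialParameters:
    """Constitutive parameters of the cornea model.

    Parameters
    ----------
    K : float
        Volumetric penalty (quasi-incompressibility) modulus, MPa.
    mu : float
        Shear modulus of the isotropic matrix (collapsed Mooney-Rivlin
        ``mu1 + mu2``), MPa.
    k1 : float
        Collagen fiber stiffness, MPa.
    k2 : float
        Dimensionless fiber nonlinearity parameter.  ``k2 = 0`` is
        admitted through the quadratic series branch.
    variance_correction_enabled : bool
        Switch for the dispersion-variance correction factor
        ``a = 1 + Kstar * sigma2_I4`` multiplying the fiber energy.
        Disabled by default (``a = 1``).
    fiber_tension_only : bool
        If true (default), fibers contribute only when ``I4t* > 1``
        (collagen does not support compression).
    """

    K: float
    mu: float
    k1: float
    k2: float
    variance_correction_enabled: bool = False
    Kstar: Optional[float] = None
    sigma2_I4: Optional[float] = None
    fiber_tension_only: bool = True

    def __post_init__(self) -> None:
        if self.K < 0.0:
            raise ValueError(f"penalty modulus K must be >= 0, got {self.K}")
        if self.mu < 0.0:
            raise ValueError(f"shear modulus mu must be >= 0, got {self.mu}")
        if self.k1 < 0.0:
            raise ValueError(f"fiber stiffness k1 must be >= 0, got {self.k1}")
        if self.k2 < 0.0:
            raise ValueError(f"fiber nonlinearity k2 must be >= 0, got {self.k2}")
        if self.variance_correction_enabled and (
            self.Kstar is None or self.sigma2_I4 is None
        ):
            raise ValueError(
                "variance correction requires both Kstar and sigma2_I4"
            )

    @property
    def a_factor(self) -> float:
        """Fiber-energy correction factor ``a`` (1 when correction is off)."""
        if self.variance_correction_enabled:
            return 1.0 + self.Kstar * self.sigma2_I4
        return 1.0

    def replace(self, **kw) -> "MaterialParameters":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass
class FiberPoint:
    """Two unit fiber directions and a dispersion parameter at one point."""

    a1: np.ndarray
    a2: np.ndarray
    kappa: float

    def __post_init__(self) -> None:
        self.a1 = np.asarray(self.a1, dtype=float)
        self.a2 = np.asarray(self.a2, dtype=float)
        for v, name in ((self.a1, "a1"), (self.a2, "a2")):
            n = np.linalg.norm(v, axis=-1)
            if not np.allclose(n, 1.0, atol=1e-8):
                raise ValueError(f"fiber direction {name} must be a unit vector")
        k = np.asarray(self.kappa, dtype=float)
        if np.any(k < 0.0) or np.any(k > 1.0 / 3.0):
            raise ValueError("dispersion kappa must lie in [0, 1/3]")


def modified_invariant(I1tilde, I4tilde, kappa):
    """Dispersion-blended fourth invariant ``I4* = k*I1t + (1-3k)*I4t``."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0.0) or np.any(kappa > 1.0 / 3.0):
        raise ValueError("dispersion kappa must lie in [0, 1/3]")
    return kappa * np.asarray(I1tilde) + (1.0 - 3.0 * kappa) * np.asarray(I4tilde)


def det3(A: np.ndarray) -> np.ndarray:
    """Determinant of batched 3x3 matrices (fast explicit cofactors)."""
    return (A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2]
                            - A[..., 1, 2] * A[..., 2, 1])
            - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2]
                              - A[..., 1, 2] * A[..., 2, 0])
            + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1]
                              - A[..., 1, 1] * A[..., 2, 0]))


def inv3(A: np.ndarray, det: Optional[np.ndarray] = None) -> np.ndarray:
    """Inverse of batched 3x3 matrices via the adjugate."""
    if det is None:
        det = det3(A)
    adj = np.empty_like(A)
    adj[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    adj[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    adj[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    adj[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    adj[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    adj[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    adj[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    adj[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    adj[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return adj / det[..., None, None]


class KinematicState:
    """Batched kinematic quantities derived from a deformation gradient.

    ``F`` has shape ``(..., 3, 3)``; invariants broadcast accordingly.
    Fiber invariants have a trailing axis of length 2 (the two families).
    ``Ctilde`` is computed lazily (the stress routines work in the
    spatial configuration and only need ``btilde``).
    """

    def __init__(self, F, J, I1tilde, btilde, Ctilde=None, I4tilde=None,
                 I4star=None):
        self.F = F
        self.J = J
        self.I1tilde = I1tilde
        self.btilde = btilde
        self._Ctilde = Ctilde
        self.I4tilde = I4tilde
        self.I4star = I4star

    @property
    def Ctilde(self) -> np.ndarray:
        if self._Ctilde is None:
            F, J = self.F, self.J
            C = np.einsum("...ki,...kj->...ij", F, F)
            self._Ctilde = (J ** (-2.0 / 3.0))[..., None, None] * C
        return self._Ctilde

    @classmethod
    def from_deformation_gradient(cls, F, fiber=None) -> "KinematicState":
        F = np.asarray(F, dtype=float)
        J = det3(F)
        if np.any(J <= 0.0):
            raise ValueError("non-positive det(F): invalid kinematic state")
        Jm23 = J ** (-2.0 / 3.0)
        b = np.einsum("...ik,...jk->...ij", F, F)
        btilde = Jm23[..., None, None] * b
        I1t = np.trace(btilde, axis1=-2, axis2=-1)
        I4t = I4s = Ct = None
        if fiber is not None:
            a1, a2, kappa = _fiber_arrays(fiber)
            C = np.einsum("...ki,...kj->...ij", F, F)
            Ct = Jm23[..., None, None] * C
            I4t = np.stack(
                [
                    np.einsum("...i,...ij,...j->...", a, Ct, a)
                    for a in (a1, a2)
                ],
                axis=-1,
            )
            I4s = modified_invariant(I1t[..., None], I4t, kappa[..., None])
        return cls(F=F, J=J, I1tilde=I1t, btilde=btilde, Ctilde=Ct,
                   I4tilde=I4t, I4star=I4s)


def _fiber_arrays(fiber):
    """Normalise fiber input to broadcastable (a1, a2, kappa) arrays."""
    if isinstance(fiber, FiberPoint):
        return fiber.a1, fiber.a2, np.asarray(fiber.kappa, dtype=float)
    a1, a2, kappa = fiber
    return (np.asarray(a1, dtype=float), np.asarray(a2, dtype=float),
            np.asarray(kappa, dtype=float))


def _psi_ti_unit(x, k2):
    """Fiber energy per unit k1 as a function of x = I4* - 1 (a = 1)."""
    x = np.asarray(x, dtype=float)
    if k2 < K2_SERIES_THRESHOLD:
        # quadratic Taylor limit, continuous at the branch switch
        return 0.5 * x * x * (1.0 + 0.5 * k2 * x * x)
    return np.expm1(k2 * x * x) / (2.0 * k2)


def _dpsi_ti_unit(x, k2):
    """d(psi_ti)/d(I4*) per unit k1 as a function of x = I4* - 1."""
    x = np.asarray(x, dtype=float)
    if k2 < K2_SERIES_THRESHOLD:
        return x * (1.0 + k2 * x * x)
    return x * np.exp(k2 * x * x)


def strain_energy(state: KinematicState, params: MaterialParameters, fiber):
    """Strain energy density (MPa) at the given kinematic state."""
    psi = params.K * _energy_vol_unit(state)
    psi = psi + params.mu * _energy_iso_unit(state)
    if params.k1 != 0.0 and fiber is not None:
        psi = psi + params.k1 * _energy_fiber_unit(
            state, fiber, params.k2,
            tension_only=params.fiber_tension_only) * params.a_factor
    return psi


def _energy_vol_unit(state):
    J = state.J
    return 0.25 * (J * J - 1.0 - 2.0 * np.log(J))


def _energy_iso_unit(state):
    return 0.5 * (state.I1tilde - 3.0)


def _energy_fiber_unit(state, fiber, k2, tension_only=True):
    if state.I4star is None:
        state2 = KinematicState.from_deformation_gradient(state.F, fiber)
        I4s = state2.I4star
    else:
        I4s = state.I4star
    x = I4s - 1.0
    psi = _psi_ti_unit(x, k2)
    if tension_only:
        psi = np.where(x > 0.0, psi, 0.0)
    return np.sum(psi, axis=-1)


def _sigma_vol_unit(state):
    """Volumetric Cauchy stress per unit K: (1/2)(J - 1/J) * I."""
    J = state.J
    p = 0.5 * (J - 1.0 / J)
    return p[..., None, None] * _I3


def _sigma_iso_unit(state):
    """Isochoric neo-Hookean Cauchy stress per unit mu: dev(btilde)/J."""
    dev = state.btilde - (state.I1tilde / 3.0)[..., None, None] * _I3
    return dev / state.J[..., None, None]


def _sigma_fiber_unit(state, fiber, k2, tension_only=True, a_factor=1.0):
    """Fiber Cauchy stress per unit k1, summed over both families."""
    a1, a2, kappa = _fiber_arrays(fiber)
    F, J = state.F, state.J
    Jm23 = J ** (-2.0 / 3.0)
    dev_b = state.btilde - (state.I1tilde / 3.0)[..., None, None] * _I3
    sig = np.zeros_like(F)
    for fam, a in enumerate((a1, a2)):
        fa = np.einsum("...ij,...j->...i", F, a)
        mt = Jm23[..., None, None] * (fa[..., :, None] * fa[..., None, :])
        I4t = np.trace(mt, axis1=-2, axis2=-1)
        I4s = modified_invariant(state.I1tilde, I4t, kappa)
        x = I4s - 1.0
        dpsi = _dpsi_ti_unit(x, k2)
        if tension_only:
            dpsi = np.where(x > 0.0, dpsi, 0.0)
        dev_m = mt - (I4t / 3.0)[..., None, None] * _I3
        term = kappa[..., None, None] * dev_b + (1.0 - 3.0 * kappa)[..., None, None] * dev_m
        sig = sig + (2.0 * dpsi / J)[..., None, None] * term
    return a_factor * sig


def cauchy_stress(state: KinematicState, params: MaterialParameters, fiber):
    """Cauchy stress tensor sigma = (2/J) F dpsi/dC F^T, shape (..., 3, 3)."""
    sig = params.K * _sigma_vol_unit(state)
    sig = sig + params.mu * _sigma_iso_unit(state)
    if params.k1 != 0.0 and fiber is not None:
        sig = sig + params.k1 * _sigma_fiber_unit(
            state, fiber, params.k2,
            tension_only=params.fiber_tension_only,
            a_factor=params.a_factor)
    return sig


def stress_decomposition(state: KinematicState, fiber, k2,
                         tension_only: bool = True, a_factor: float = 1.0):
    """Exact split of the Cauchy stress into terms linear in (K, mu, k1).

    Returns ``(sigma_hat_K, sigma_hat_mu, sigma_hat_k1)`` such that for any
    parameter triple ``cauchy_stress = K*s_K + mu*s_mu + k1*s_k1`` to
    round-off; each piece equals the stress with that parameter set to one
    and the others to zero.
    """
    if k2 < 0.0:
        raise ValueError("k2 must be >= 0")
    return (
        _sigma_vol_unit(state),
        _sigma_iso_unit(state),
        _sigma_fiber_unit(state, fiber, k2, tension_only=tension_only,
                          a_factor=a_factor),
    )


@dataclass
class PlateLayer:
    """Elastic layer for the plate-rigidity utility (SI units: Pa, m)."""

    E: float
    t: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0.0:
            raise ValueError("elastic modulus E must be > 0")
        if self.t <= 0.0:
            raise ValueError("thickness t must be > 0")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


def plate_rigidity(layer: PlateLayer) -> float:
    """Bending rigidity of a thin plate, ``E t^3 / (12 (1 - nu^2))`` in N*m.

    Used to rank the mechanical relevance of the individual corneal layers
    (epithelium ... endothelium) and justify lumping them into the stroma.
    """
    return layer.E * layer.t ** 3 / (12.0 * (1.0 - layer.nu ** 2))


def elastic_to_hyperelastic(E: float, nu: float,
                            **kw) -> MaterialParameters:
    """Neo-Hookean (K, mu) equivalent of a small-strain (E, nu) material.

    Used for the auxiliary, nearly incompressible ocular components
    (limbus, sclera) whose moduli are known and fixed during
    identification.  ``K`` here is the bulk modulus at the reference
    state, matching the volumetric penalty of the cornea model.
    """
    if not (0.0 <= nu < 0.5):
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    K = E / (3.0 * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return MaterialParameters(K=K, mu=mu, k1=0.0, k2=1.0, **kw)
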
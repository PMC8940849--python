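"""Nested identification of the nonlinear fiber parameter k2.

k2 enters the residual through the exponential fiber term and cannot be
identified from a single state.  Following the nested-loop idea, the
linear parameters are identified independently for m >= 3 deformation
states at each candidate k2, and the scatter of the resulting parameter
sets serves as the outer objective::

    f_rel(k2) = sum_i  std(alpha_i over states) / mean(alpha_i over states)

(population standard deviation; the convention is fixed so toy examples
are deterministic).  At the generating k2 all states agree and f_rel
vanishes; the curve typically also shows a secondary local minimum
toward k2 -> 0, so a plain grid search from near zero upwards is used
(default grid 10..400, step 10).  With k1 ~ 0 the fiber term -- and with
it k2 -- drops out of the residual, which is detected and flagged as
unidentifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .geometry import EyeModel
from .inverse import LinearIdentification, StateSensitivity, solve_linear_parameters

__all__ = ["K2SearchResult", "relative_scatter", "f_rel", "grid_search_k2"]

#: guard against division by a zero mean: the term is replaced by
#: std/EPS_MEAN, which effectively flags the parameter instead of
#: producing inf/nan
EPS_MEAN = 1e-12


def relative_scatter(param_sets: np.ndarray) -> float:
    """Sum over parameters of population std divided by mean.

    ``param_sets`` has shape (m_states, 3).
    """
    P = np.asarray(param_sets, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need at least two parameter sets")
    std = P.std(axis=0)                      # population (divide by m)
    mean = P.mean(axis=0)
    denom = np.where(np.abs(mean) < EPS_MEAN, EPS_MEAN, np.abs(mean))
    return float(np.sum(std / denom))


@dataclass
class K2SearchResult:
    k2_grid: np.ndarray
    f_rel_values: np.ndarray
    k2_opt: float
    params_per_state: np.ndarray            # (m, 3) at the argmin
    params_mean: np.ndarray                 # (3,)
    identifications: List[LinearIdentification]
    k1_identifiable: bool                   # False when mean k1 < threshold
    local_minima: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    ambiguous: bool = False                 # competing minima within band


def _identify_grid(caches: Sequence[StateSensitivity],
                   k2_values: np.ndarray):
    """Identify all states on all grid points (order-independent)."""
    results = []
    for k2 in k2_values:
        idents = [solve_linear_parameters(c.at_k2(k2)) for c in caches]
        results.append(idents)
    return results


def f_rel(model: EyeModel,
          states: Sequence[Tuple[np.ndarray, np.ndarray]],
          k2: float, order: int = 2, fbar: bool = True,
          cornea_only: bool = False) -> float:
    """Relative-scatter objective at one k2 (runs the per-state EGM)."""
    if len(states) < 2:
        raise ValueError("f_rel needs at least two deformation states")
    caches = [StateSensitivity(model, u, f, order=order, fbar=fbar,
                               cornea_only=cornea_only)
              for u, f in states]
    idents = [solve_linear_parameters(c.at_k2(k2)) for c in caches]
    return relative_scatter(np.array([i.params for i in idents]))


def _local_minima(values: np.ndarray) -> np.ndarray:
    """Indices of strict-or-boundary local minima of a 1D curve."""
    v = np.asarray(values)
    idx = []
    for i in range(len(v)):
        left = v[i - 1] if i > 0 else np.inf
        right = v[i + 1] if i < len(v) - 1 else np.inf
        if v[i] <= left and v[i] <= right:
            idx.append(i)
    return np.array(idx, dtype=int)


def grid_search_k2(model: EyeModel,
                   states: Sequence[Tuple[np.ndarray, np.ndarray]],
                   k2_min: float = 10.0, k2_max: float = 400.0,
                   step: float = 10.0, order: int = 2, fbar: bool = True,
                   cornea_only: bool = False,
                   k1_threshold: float = 1e-3,
                   ambiguity_band: float = 0.1) -> K2SearchResult:
    """Grid search of f_rel over k2 (default 10..400, step 10).

    Returns the argmin, the full curve, the per-state linear parameters
    at the argmin, and diagnostic flags: ``k1_identifiable`` is cleared
    when the averaged identified k1 falls below ``k1_threshold`` MPa (the
    fiber term then carries no information about k2), and ``ambiguous``
    is set when a competing local minimum lies within a relative
    ``ambiguity_band`` of the global one.
    """
    if len(states) < 3:
        raise ValueError("k2 identification requires m >= 3 deformation "
                         "states")
    grid = np.arange(k2_min, k2_max + 0.5 * step, step, dtype=float)
    if grid.size == 0:
        raise ValueError("empty k2 grid")
    caches = [StateSensitivity(model, u, f, order=order, fbar=fbar,
                               cornea_only=cornea_only)
              for u, f in states]
    per_point = _identify_grid(caches, grid)
    curve = np.array([
        relative_scatter(np.array([i.params for i in idents]))
        for idents in per_point])
    i_opt = int(np.argmin(curve))
    idents = per_point[i_opt]
    P = np.array([i.params for i in idents])
    mean = P.mean(axis=0)
    minima = _local_minima(curve)
    competing = [i for i in minima if i != i_opt]
    ambiguous = any(curve[i] <= curve[i_opt] * (1.0 + ambiguity_band)
                    for i in competing)
    flat = np.ptp(curve) <= 1e-12 * max(1.0, np.max(np.abs(curve)))
    identifiable = (mean[2] >= k1_threshold) and not flat
    return K2SearchResult(
        k2_grid=grid, f_rel_values=curve, k2_opt=float(grid[i_opt]),
        params_per_state=P, params_mean=mean, identifications=idents,
        k1_identifiable=bool(identifiable), local_minima=minima,
        ambiguous=bool(ambiguous))
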
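"""Establishment probabilities when the B-allele frequency changes.

Away from equalizing selection the frequency ``p`` of allele B moves
deterministically from its value ``p0`` at the birth of allele A toward the
stable equilibrium ``p*``.  Rewriting the time-dependent two-type branching
process along that deterministic trajectory gives a pair of coupled ODEs in
``p``:

``M_p dphi_B/dp = phi_B^2/2 - [alpha - (1-p) r - u] phi_B - [(1-p) r + u] phi_b``
``M_p dphi_b/dp = phi_b^2/2 - [p r + v] phi_B - [beta - p r - v] phi_b``

The boundary condition sits at ``p*``, where ``p`` no longer moves and the
constant-``p`` cubic applies; since ``M_p(p*) = 0`` the integration starts
from ``p* +- eps``.  Solutions are cached on a grid on each side of ``p*``
and interpolated monotonically, because the unconditional-probability
quadrature issues many queries.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .branching import EstablishmentProbabilities, _coefficients, phi_constant_p
from .model import ModelConfig, equilibrium_p, mean_change

__all__ = ["OdeSolution", "solve_phi_ode", "phi_variable_p", "decompose_at_pstar"]

_GRID_POINTS = 512
_BOUNDARY_MARGIN = 1e-4


@dataclass(frozen=True)
class OdeSolution:
    """Cached establishment probabilities ``phi_B(p)``, ``phi_b(p)``.

    ``p_grid`` spans (almost) the open unit interval; values exactly at
    ``p*`` reproduce the constant-``p`` solution.  ``epsilon`` is the
    offset used to move the initial condition off the ``M_p = 0`` point.
    """

    p_star: float
    epsilon: float
    p_grid: np.ndarray
    phi_B_of_p: np.ndarray
    phi_b_of_p: np.ndarray
    _interp_B: PchipInterpolator
    _interp_b: PchipInterpolator

    def phi_B(self, p):
        p = np.clip(p, self.p_grid[0], self.p_grid[-1])
        return np.clip(self._interp_B(p), 0.0, 1.0)

    def phi_b(self, p):
        p = np.clip(p, self.p_grid[0], self.p_grid[-1])
        return np.clip(self._interp_b(p), 0.0, 1.0)


def _rhs_factory(cfg: ModelConfig):
    sel, mut = cfg.selection, cfg.mutation

    def rhs(p, y):
        phi_B = min(max(y[0], 0.0), 1.0)
        phi_b = min(max(y[1], 0.0), 1.0)
        a, b, c, d = _coefficients(p, cfg)
        mp = mean_change(p, sel, mut)
        dB = (0.5 * phi_B * phi_B - a * phi_B - b * phi_b) / mp
        db = (0.5 * phi_b * phi_b - c * phi_B - d * phi_b) / mp
        return (dB, db)

    return rhs


def _integrate_side(cfg: ModelConfig, p_start: float, p_end: float, y0) -> tuple[np.ndarray, np.ndarray]:
    """Integrate from p_start to p_end, returning (p_grid ascending, y[2, n])."""
    if abs(p_end - p_start) < 1e-12:
        grid = np.array([p_start])
        return grid, np.array([[y0[0]], [y0[1]]])
    # geometric spacing toward the far boundary resolves the stiff approach
    # to p in {0, 1} where M_p is dominated by the mutation terms
    lin = np.linspace(p_start, p_end, _GRID_POINTS // 2)
    geo = p_end + (p_start - p_end) * np.geomspace(1e-6, 1.0, _GRID_POINTS // 2)
    grid = np.unique(
        np.clip(
            np.concatenate([lin, geo]),
            min(p_start, p_end),
            max(p_start, p_end),
        )
    )
    if p_end < p_start:
        grid = grid[::-1]
    sol = solve_ivp(
        _rhs_factory(cfg),
        (p_start, p_end),
        y0,
        method="LSODA",
        t_eval=grid,
        rtol=1e-8,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(
            f"stiff integration of the establishment ODE failed: {sol.message}; "
            "consider reducing epsilon or refining tolerances"
        )
    order = np.argsort(sol.t)
    return sol.t[order], np.clip(sol.y[:, order], 0.0, 1.0)


@lru_cache(maxsize=32)
def _solve_cached(cfg: ModelConfig, epsilon: float | None) -> OdeSolution:
    eq = equilibrium_p(cfg.selection, cfg.mutation)
    p_star = eq.p_star
    eps = 1e-4 if epsilon is None else float(epsilon)
    # keep the offset inside (0, 1) even for near-boundary equilibria
    eps = min(eps, 0.5 * p_star, 0.5 * (1.0 - p_star))
    const = phi_constant_p(p_star, cfg)
    y0 = (const.phi_B, const.phi_b)

    # integrate only within the basin of p*: crossing another root of M_p
    # would divide by zero (p0 outside the basin is rejected by the caller)
    lo = min(_BOUNDARY_MARGIN, 0.5 * p_star)
    hi = 1.0 - min(_BOUNDARY_MARGIN, 0.5 * (1.0 - p_star))
    for root in eq.roots:
        if root < p_star - eps:
            lo = max(lo, root + 0.05 * (p_star - root))
        elif root > p_star + eps:
            hi = min(hi, root - 0.05 * (root - p_star))
    lo = min(lo, p_star - eps)
    hi = max(hi, p_star + eps)
    left_t, left_y = _integrate_side(cfg, p_star - eps, lo, y0)
    right_t, right_y = _integrate_side(cfg, p_star + eps, hi, y0)

    p_grid = np.concatenate([left_t, [p_star], right_t])
    phi_B = np.concatenate([left_y[0], [const.phi_B], right_y[0]])
    phi_b = np.concatenate([left_y[1], [const.phi_b], right_y[1]])
    order = np.argsort(p_grid)
    p_grid, phi_B, phi_b = p_grid[order], phi_B[order], phi_b[order]
    p_grid, keep = np.unique(p_grid, return_index=True)
    phi_B, phi_b = phi_B[keep], phi_b[keep]
    return OdeSolution(
        p_star=p_star,
        epsilon=eps,
        p_grid=p_grid,
        phi_B_of_p=phi_B,
        phi_b_of_p=phi_b,
        _interp_B=PchipInterpolator(p_grid, phi_B, extrapolate=False),
        _interp_b=PchipInterpolator(p_grid, phi_b, extrapolate=False),
    )


def solve_phi_ode(cfg: ModelConfig, epsilon: float | None = None) -> OdeSolution:
    """Solve the variable-``p`` establishment ODE on both sides of ``p*``.

    Results are cached per configuration.  ``epsilon`` overrides the
    default boundary offset of 1e-4 (shrunk automatically when ``p*`` sits
    near a boundary).
    """
    return _solve_cached(cfg, epsilon)


def phi_variable_p(
    p0: float, cfg: ModelConfig, epsilon: float | None = None
) -> EstablishmentProbabilities:
    """Establishment probabilities ``phi_B(p0)``, ``phi_b(p0)`` when ``p``
    relaxes from ``p0`` to ``p*`` during the escape phase.

    At ``p0 = p*`` this reduces to :func:`sdturnover.branching.phi_constant_p`.
    Establishment through near-neutral drift (of order ``2/N``) is outside
    the branching description; when the branching component collapses the
    result simply reports a probability near zero with
    ``drift_dominated=True``, and the Wright-Fisher simulator is the tool
    that resolves the drift floor.

    Raises
    ------
    ValueError
        If ``p0`` lies beyond an interior unstable equilibrium, i.e. in a
        basin from which the deterministic trajectory does not reach
        ``p*``.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0={p0} outside [0, 1]")
    eq = equilibrium_p(cfg.selection, cfg.mutation)
    for root, stable in zip(eq.roots, eq.stable):
        if not stable and min(eq.p_star, p0) < root < max(eq.p_star, p0):
            raise ValueError(
                f"p0={p0} lies beyond the unstable equilibrium at {root:.6g}; "
                f"the deterministic trajectory from p0 does not reach p*={eq.p_star:.6g}"
            )
    sol = solve_phi_ode(cfg, epsilon)
    if abs(p0 - sol.p_star) <= sol.epsilon:
        const = phi_constant_p(sol.p_star, cfg)
        phi_B, phi_b = const.phi_B, const.phi_b
    else:
        phi_B = float(sol.phi_B(p0))
        phi_b = float(sol.phi_b(p0))
    drift = max(phi_B, phi_b) < 2.0 / cfg.N
    return EstablishmentProbabilities(
        phi_B, phi_b, p0, method="ode", p_star=sol.p_star, drift_dominated=drift
    )


def decompose_at_pstar(
    X_B: int, X_b: int, cfg: ModelConfig
) -> tuple[float, float]:
    """Establishment probability given haplotype copy numbers at ``p*``.

    If the descendants of the original A copy number ``X_B`` on the B
    background and ``X_b`` on the b background once ``p`` has reached
    ``p*``, establishment occurs unless every copy's lineage dies out:

    exact  : ``1 - (1 - phi_B(p*))**X_B (1 - phi_b(p*))**X_b``
    linear : ``phi_B(p*) X_B + phi_b(p*) X_b``

    Both forms are returned ``(exact, linearized)``; they agree unless the
    population (hence the probabilities) is small.
    """
    if X_B < 0 or X_b < 0 or X_B != int(X_B) or X_b != int(X_b):
        raise ValueError("X_B and X_b must be non-negative integers")
    p_star = equilibrium_p(cfg.selection, cfg.mutation).p_star
    const = phi_constant_p(p_star, cfg)
    exact = 1.0 - (1.0 - const.phi_B) ** X_B * (1.0 - const.phi_b) ** X_b
    linear = const.phi_B * X_B + const.phi_b * X_b
    return exact, linear
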
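"""Constant-frequency branching-process establishment probabilities.

While the new sex-determining allele A is rare, its A-B and A-b haplotype
copies reproduce almost independently, so their joint fate is a two-type
branching process.  When the B-allele frequency ``p`` can be treated as
constant on the escape timescale, the two establishment probabilities
``phi_B(p)`` (A arose linked to B) and ``phi_b(p)`` (linked to b) solve a
pair of coupled quadratics whose elimination yields a cubic in ``phi_B``
with a closed-form solution.  This module implements that closed form, a
small-``r`` approximation, and the negative-selection threshold
approximation at ``p*`` near zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .model import ModelConfig, alpha, beta, classify_mode, SelectionMode

__all__ = [
    "EstablishmentProbabilities",
    "dynamics_matrix",
    "leading_eigenvalue",
    "phi_constant_p",
    "phi_small_r",
    "phi_negative_approx",
    "threshold_r",
    "residuals",
]

logger = logging.getLogger(__name__)

_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class EstablishmentProbabilities:
    """Establishment probabilities of allele A conditional on its linkage.

    ``phi_B`` (``phi_b``) is the probability that a single new A copy
    escapes stochastic loss and its sex-determination system takes over,
    given that it arose on a B-bearing (b-bearing) haplotype with the
    B-allele frequency at ``p0``.  ``method`` records how the numbers were
    obtained (``cubic``, ``small_r``, ``approx_eq_negative``, ``ode`` or
    ``simulation``).
    """

    phi_B: float
    phi_b: float
    p0: float
    method: str
    p_star: float | None = None
    drift_dominated: bool = False

    def __post_init__(self) -> None:
        for name in ("phi_B", "phi_b"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")

    @property
    def weighted(self) -> float:
        """Linkage-weighted probability ``p0 phi_B + (1 - p0) phi_b`` — the
        establishment probability of an A arising on a random haplotype."""
        return self.p0 * self.phi_B + (1.0 - self.p0) * self.phi_b


def _coefficients(p: float, cfg: ModelConfig) -> tuple[float, float, float, float]:
    """Return (a, b, c, d): entries of the rare-A haplotype dynamics matrix
    ``[[a, c], [b, d]]`` acting on ``(x_B, x_b)``."""
    sel, mut, r = cfg.selection, cfg.mutation, cfg.r
    al = alpha(p, sel, cfg.case)
    be = beta(p, sel, cfg.case)
    a = al - (1.0 - p) * r - mut.u
    b = (1.0 - p) * r + mut.u
    c = p * r + mut.v
    d = be - p * r - mut.v
    return a, b, c, d


def dynamics_matrix(p: float, cfg: ModelConfig) -> np.ndarray:
    """Linearized one-generation dynamics of the rare haplotype frequencies.

    Returns the 2x2 matrix ``M`` with
    ``(E[dx_B], E[dx_b])^T = M (x_B, x_b)^T``:

    ``[[alpha(p) - (1-p) r - u,  p r + v],
      [(1-p) r + u,             beta(p) - p r - v]]``

    Selection enters through the heterogametic-side sex only; recombination
    and mutation exchange the two backgrounds.
    """
    a, b, c, d = _coefficients(p, cfg)
    return np.array([[a, c], [b, d]])


def leading_eigenvalue(p: float, cfg: ModelConfig) -> float:
    """Leading eigenvalue of :func:`dynamics_matrix`; the branching process
    is supercritical (escape possible) iff it is positive."""
    a, b, c, d = _coefficients(p, cfg)
    return 0.5 * (a + d) + np.sqrt(0.25 * (a - d) ** 2 + b * c)


def residuals(
    phi_B: float, phi_b: float, p: float, cfg: ModelConfig
) -> tuple[float, float]:
    """Left-hand sides of the two coupled branching equations.

    Both vanish at a genuine solution:

    ``a phi_B + b phi_b - phi_B^2 / 2 = 0``
    ``c phi_B + d phi_b - phi_b^2 / 2 = 0``
    """
    a, b, c, d = _coefficients(p, cfg)
    return (
        a * phi_B + b * phi_b - 0.5 * phi_B**2,
        c * phi_B + d * phi_b - 0.5 * phi_b**2,
    )


def _cubic_coefficients(p: float, cfg: ModelConfig) -> tuple[float, float, float]:
    """Coefficients (A2, A1, A0) of ``phi^3 + A2 phi^2 + A1 phi + A0`` solved
    by the nontrivial phi_B."""
    a, b, c, d = _coefficients(p, cfg)
    al = alpha(p, cfg.selection, cfg.case)
    be = beta(p, cfg.selection, cfg.case)
    A0 = 8.0 * b * (al * be - c * al - b * be)
    A1 = 4.0 * a * a - 4.0 * b * d
    A2 = -4.0 * a
    return A2, A1, A0


def _closed_form_root(A2: float, A1: float, A0: float) -> float:
    """Printed closed-form root of the cubic (Cardano / trigonometric
    branch by the sign of the discriminant-like quantity R)."""
    P = A1 - A2 * A2 / 3.0
    Q = A0 - A1 * A2 / 3.0 + 2.0 * A2**3 / 27.0
    R = (P / 3.0) ** 3 + (Q / 2.0) ** 2
    if R > 0.0:
        sqrtR = np.sqrt(R)
        return float(np.cbrt(-Q / 2.0 + sqrtR) + np.cbrt(-Q / 2.0 - sqrtR) - A2 / 3.0)
    # three real roots; the arccos argument can graze +-1 at R ~ 0
    arg = np.clip(3.0 * Q / (2.0 * P) * np.sqrt(-3.0 / P), -1.0, 1.0)
    return float(2.0 * np.sqrt(-P / 3.0) * np.cos(np.arccos(arg) / 3.0) - A2 / 3.0)


def _phi_b_from_phi_B(phi_B: float, p: float, cfg: ModelConfig) -> float:
    a, b, _, _ = _coefficients(p, cfg)
    if b > 0.0:
        return (phi_B**2 - 2.0 * a * phi_B) / (2.0 * b)
    return 0.0


def _clamp(x: float, name: str) -> float:
    if x < -1e-6 or x > 1.0 + 1e-6:
        logger.warning("%s=%g outside [0, 1] by more than 1e-6; clamping", name, x)
    return min(max(x, 0.0), 1.0)


def phi_constant_p(p: float, cfg: ModelConfig) -> EstablishmentProbabilities:
    """Establishment probabilities at constant B-allele frequency ``p``.

    Valid when the mean change of ``p`` is negligible on the escape
    timescale (``|M_p|`` of order ``1/N`` — e.g. equalizing selection, or
    any mode evaluated exactly at ``p*``).  If the leading eigenvalue of
    the haplotype dynamics matrix is non-positive the process is
    (sub)critical and both probabilities are zero.  Otherwise the printed
    closed-form cubic root is used, guarded by a residual check and, if the
    closed form fails it (possible only through numerical fragility near
    branch boundaries), a fallback to a full numeric polynomial solve.

    Raises
    ------
    RuntimeError
        If no root of the cubic satisfies the residual tolerance.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if leading_eigenvalue(p, cfg) <= 1e-14:
        return EstablishmentProbabilities(0.0, 0.0, p, method="cubic")
    a, b, c, d = _coefficients(p, cfg)
    if b == 0.0:
        # decoupled A-B lineage: phi_B = 2a exactly; the A-b equation is a
        # scalar quadratic fed by mutation/recombination onto B
        phi_B = max(0.0, 2.0 * a)
        phi_b = max(0.0, d + np.sqrt(d * d + 2.0 * c * phi_B))
        return EstablishmentProbabilities(
            _clamp(phi_B, "phi_B"), _clamp(phi_b, "phi_b"), p, method="cubic"
        )
    A2, A1, A0 = _cubic_coefficients(p, cfg)
    phi_B = _closed_form_root(A2, A1, A0)
    phi_b = _phi_b_from_phi_B(phi_B, p, cfg)
    res = residuals(phi_B, phi_b, p, cfg)
    # the trivial solution (0, 0) always has zero residual, so a genuinely
    # supercritical process must additionally yield a strictly positive root
    ok = (
        max(abs(res[0]), abs(res[1])) <= _RESIDUAL_TOL
        and phi_B > 1e-13
        and -1e-6 <= phi_B <= 1.0 + 1e-6
        and -1e-6 <= phi_b <= 1.0 + 1e-6
    )
    if not ok:
        # guard: pick the largest admissible root of the cubic numerically.
        # The closed-form branch is fragile exactly at double-root
        # boundaries (R ~ 0), e.g. the decoupled r = u = 0 limit.
        roots = np.roots([1.0, A2, A1, A0])
        best = None
        for root in roots:
            if abs(root.imag) > 1e-12:
                continue
            cand_B = float(root.real)
            if cand_B <= 1e-13:
                continue
            cand_b = _phi_b_from_phi_B(cand_B, p, cfg)
            r1, r2 = residuals(cand_B, cand_b, p, cfg)
            if max(abs(r1), abs(r2)) > _RESIDUAL_TOL:
                continue
            if cand_B <= 1.0 + 1e-6 and -1e-6 <= cand_b <= 1.0 + 1e-6:
                if best is None or cand_B > best[0]:
                    best = (cand_B, cand_b)
        if best is None:
            # marginally supercritical with no resolvable positive root
            return EstablishmentProbabilities(0.0, 0.0, p, method="cubic")
        phi_B, phi_b = best
    return EstablishmentProbabilities(
        _clamp(phi_B, "phi_B"), _clamp(phi_b, "phi_b"), p, method="cubic"
    )


def phi_small_r(p: float, cfg: ModelConfig) -> EstablishmentProbabilities:
    """Small-recombination approximation.

    ``phi_B ~ 2 [alpha(p) - (1-p) r]`` and ``phi_b ~ 0``; intended for
    ``r`` small compared with ``alpha(p)``.
    """
    val = 2.0 * (alpha(p, cfg.selection, cfg.case) - (1.0 - p) * cfg.r)
    return EstablishmentProbabilities(
        max(0.0, min(val, 1.0)), 0.0, p, method="small_r"
    )


def threshold_r(cfg: ModelConfig) -> float:
    """Critical recombination rate for establishment under negative selection.

    For ``r`` above ``h_m s_m`` (case 1; ``h_f s_f`` for case 2) an A copy
    that loses its B background by recombination can essentially never
    re-acquire it, so linked selection stops working and establishment
    becomes drift-driven.
    """
    s, h = cfg.effective.s_m, cfg.effective.h_m
    return h * s


def phi_negative_approx(cfg: ModelConfig) -> EstablishmentProbabilities:
    """Negative-selection approximation of the probabilities at ``p* ~ 0``.

    ``phi_B(p*) ~ 2 (h_m s_m - r)`` below the threshold ``r = h_m s_m`` and
    0 above it; ``phi_b(p*) ~ 0``.  A warning is emitted (result still
    returned) when the fitness scheme is not in the negative mode.
    """
    mode = classify_mode(cfg.selection)
    if mode is not SelectionMode.NEGATIVE:
        warnings.warn(
            f"negative-selection approximation requested for {mode.value} "
            "selection; result may be meaningless",
            stacklevel=2,
        )
    thr = threshold_r(cfg)
    phi_B = 2.0 * (thr - cfg.r) if cfg.r < thr else 0.0
    return EstablishmentProbabilities(
        max(0.0, min(phi_B, 1.0)),
        0.0,
        0.0,
        method="approx_eq_negative",
        drift_dominated=cfg.r >= thr,
    )
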
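"""Stationary distribution of the B-allele frequency and unconditional
establishment probability.

Under drift, sexually antagonistic selection, and recurrent mutation the
frequency ``p`` of allele B wanders over (0, 1) with Wright's stationary
density

``g(p) = C (1-p)^(4Nu-1) p^(4Nv-1) exp(2N(h_f s_f + h_m s_m) p
        + N((1-2h_f) s_f + (1-2h_m) s_m) p^2)``

valid to first order in the selection intensities.  For equalizing
selection (``h_f ~ h_m`` and ``s_f ~ -s_m``) the first-order terms cancel
and the leading selective sculpting of the density is second order:

``g(p) = C (1-p)^(4Nu-1) p^(4Nv-1)
        exp(-N s_f^2 p^2 [(1-2h_f) p + 2 h_f]^2)``

The unconditional establishment probability of a new sex-determining
mutation averages the linkage-weighted branching probability over this
density:  ``phi = int g(p) [p phi_B(p) + (1-p) phi_b(p)] dp``.

Endpoint exponents ``4Nu - 1`` and ``4Nv - 1`` are typically negative at
realistic mutation rates, so all quadrature is performed with an algebraic
endpoint weight rather than naively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .branching import phi_constant_p
from .model import (
    ModelConfig,
    SelectionMode,
    alpha,
    classify_mode,
    equilibrium_p,
)
from .ode import solve_phi_ode

__all__ = [
    "StationaryDensity",
    "stationary_density",
    "unconditional_phi",
    "UnconditionalPhi",
    "approx_balancing_r0",
    "approx_negative_r0",
]


@dataclass(frozen=True)
class StationaryDensity:
    """Normalized stationary density of the B-allele frequency.

    ``grid``/``density`` tabulate g on an interior grid for plotting and
    export; ``pdf`` evaluates the density exactly anywhere in (0, 1).
    ``normalizer`` is the constant C of the unnormalized kernel.
    """

    grid: np.ndarray
    density: np.ndarray
    normalizer: float
    variant: str
    a_left: float  # exponent of p at the left endpoint: 4Nv - 1
    a_right: float  # exponent of (1-p) at the right endpoint: 4Nu - 1
    _log_smooth_coeffs: tuple[float, ...]
    _log_scale: float

    def _log_smooth(self, p):
        """Log of the non-singular exponential factor, shifted by a constant
        so that quadrature stays in range."""
        c1, c2, c3, c4 = self._log_smooth_coeffs
        p = np.asarray(p, dtype=float)
        return c1 * p + c2 * p**2 + c3 * p**3 + c4 * p**4 - self._log_scale

    def pdf(self, p):
        p = np.asarray(p, dtype=float)
        return (
            self.normalizer
            * p**self.a_left
            * (1.0 - p) ** self.a_right
            * np.exp(self._log_smooth(p))
        )

    def integrate_weighted(self, weight) -> tuple[float, float]:
        """Return ``(integral of g(p) weight(p) dp, quadrature error)`` with
        the endpoint singularities handled by an algebraic weight."""
        val, err = integrate.quad(
            lambda p: np.exp(self._log_smooth(p)) * weight(p),
            0.0,
            1.0,
            weight="alg",
            wvar=(self.a_left, self.a_right),
            limit=200,
        )
        return self.normalizer * val, self.normalizer * err

    def cdf_mass(self, lo: float, hi: float) -> float:
        """Probability mass on [lo, hi] (interior interval or endpoint)."""
        val, err = integrate.quad(
            lambda p: np.exp(self._log_smooth(p)),
            lo,
            hi,
            weight="alg",
            wvar=(self.a_left, self.a_right),
            limit=200,
        )
        return self.normalizer * val

    def quantile(self, q: float, tol: float = 1e-10) -> float:
        """Inverse CDF by bisection on the endpoint-weighted mass."""
        if not 0.0 < q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if self.cdf_mass(0.0, mid) < q:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw frequencies by rejection against the Beta(4Nv, 4Nu) kernel.

        The exponential factor is bounded on [0, 1], so acceptance uses the
        ratio exp(log_smooth(p) - max log_smooth).
        """
        a, b = self.a_left + 1.0, self.a_right + 1.0
        pgrid = np.linspace(0.0, 1.0, 4097)
        log_max = float(np.max(self._log_smooth(pgrid)))
        out = np.empty(0)
        while out.size < n:
            m = max(4 * (n - out.size), 1024)
            props = rng.beta(a, b, size=m)
            accept = np.log(rng.random(m)) < self._log_smooth(props) - log_max
            out = np.concatenate([out, props[accept]])
        return out[:n]


def _variant_for(cfg: ModelConfig, variant: str) -> str:
    if variant == "auto":
        mode = classify_mode(cfg.selection)
        return "equalizing" if mode is SelectionMode.EQUALIZING else "wright"
    if variant not in ("wright", "equalizing"):
        raise ValueError("variant must be 'wright', 'equalizing' or 'auto'")
    return variant


def stationary_density(
    cfg: ModelConfig, variant: str = "auto", grid_size: int = 512
) -> StationaryDensity:
    """Normalized stationary density of the B-allele frequency.

    ``variant='wright'`` uses the first-order exponent (the generic
    formula); ``'equalizing'`` uses the second-order form appropriate when
    the two sexes' selection pressures cancel; ``'auto'`` picks by
    :func:`sdturnover.model.classify_mode`.

    Raises
    ------
    ValueError
        If ``u == 0`` or ``v == 0`` — without recurrent mutation both
        boundaries absorb and no proper stationary density exists.
    """
    sel, mut, N = cfg.selection, cfg.mutation, cfg.N
    if mut.u <= 0.0 or mut.v <= 0.0:
        raise ValueError(
            "stationary density requires u > 0 and v > 0; with one-way or no "
            "mutation the frequency is eventually absorbed at a boundary"
        )
    variant = _variant_for(cfg, variant)
    if variant == "wright":
        c1 = 2.0 * N * (sel.h_f * sel.s_f + sel.h_m * sel.s_m)
        c2 = N * ((1.0 - 2.0 * sel.h_f) * sel.s_f + (1.0 - 2.0 * sel.h_m) * sel.s_m)
        coeffs = (c1, c2, 0.0, 0.0)
    else:
        hf, sf = sel.h_f, sel.s_f
        k = N * sf * sf
        # -N s_f^2 p^2 [(1-2h_f) p + 2 h_f]^2, expanded in powers of p
        coeffs = (
            0.0,
            -k * 4.0 * hf * hf,
            -k * 4.0 * hf * (1.0 - 2.0 * hf),
            -k * (1.0 - 2.0 * hf) ** 2,
        )
    a_left = 4.0 * N * mut.v - 1.0
    a_right = 4.0 * N * mut.u - 1.0

    pgrid = np.linspace(0.0, 1.0, 4097)[1:-1]
    raw_log = (
        coeffs[0] * pgrid + coeffs[1] * pgrid**2 + coeffs[2] * pgrid**3 + coeffs[3] * pgrid**4
    )
    log_scale = float(np.max(raw_log))

    dens = StationaryDensity(
        grid=np.empty(0),
        density=np.empty(0),
        normalizer=1.0,
        variant=variant,
        a_left=a_left,
        a_right=a_right,
        _log_smooth_coeffs=coeffs,
        _log_scale=log_scale,
    )
    mass, _ = dens.integrate_weighted(lambda p: 1.0)
    normalizer = 1.0 / mass
    grid = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]
    out = StationaryDensity(
        grid=grid,
        density=np.empty(0),
        normalizer=normalizer,
        variant=variant,
        a_left=a_left,
        a_right=a_right,
        _log_smooth_coeffs=coeffs,
        _log_scale=log_scale,
    )
    object.__setattr__(out, "density", out.pdf(grid))
    return out


@dataclass(frozen=True)
class UnconditionalPhi:
    """Unconditional establishment probability with provenance."""

    phi: float
    quadrature_error: float
    mode: SelectionMode
    variant: str
    phi_source: str


def unconditional_phi(
    cfg: ModelConfig,
    phi_source: str = "auto",
    variant: str = "auto",
) -> UnconditionalPhi:
    """Average the establishment probability over the stationary density.

    ``phi = int_0^1 g(p) [p phi_B(p) + (1-p) phi_b(p)] dp``

    ``phi_source='constant'`` evaluates the constant-``p`` cubic at every
    ``p`` — valid only in the equalizing regime, where ``p`` has no
    systematic pressure; ``'ode'`` uses the variable-``p`` solution anchored
    at ``p*``; ``'auto'`` picks by mode.  Using ``'constant'`` outside the
    equalizing regime triggers a warning naming the regime rule.
    """
    mode = classify_mode(cfg.selection)
    if phi_source == "auto":
        phi_source = "constant" if mode is SelectionMode.EQUALIZING else "ode"
    if phi_source not in ("constant", "ode"):
        raise ValueError("phi_source must be 'constant', 'ode' or 'auto'")
    if phi_source == "constant" and mode is not SelectionMode.EQUALIZING:
        warnings.warn(
            "constant-p establishment probabilities are only valid when p has "
            "no systematic pressure (equalizing selection); under "
            f"{mode.value} selection use phi_source='ode'",
            stacklevel=2,
        )
    dens = stationary_density(cfg, variant=variant)

    if phi_source == "ode":
        sol = solve_phi_ode(cfg)

        def weighted(p):
            return p * float(sol.phi_B(p)) + (1.0 - p) * float(sol.phi_b(p))

    else:

        def weighted(p):
            est = phi_constant_p(float(p), cfg)
            return p * est.phi_B + (1.0 - p) * est.phi_b

    phi, err = dens.integrate_weighted(weighted)
    return UnconditionalPhi(
        phi=max(phi, 0.0),
        quadrature_error=err,
        mode=mode,
        variant=dens.variant,
        phi_source=phi_source,
    )


def approx_balancing_r0(cfg: ModelConfig) -> float:
    """Closed-form unconditional probability for balancing selection, r = 0.

    ``phi ~ 2 p* alpha(p*)`` — the chance that the mutation lands on a B
    background times twice the selective advantage it enjoys there; of the
    same order of magnitude as ``s_m``.
    """
    p_star = equilibrium_p(cfg.selection, cfg.mutation).p_star
    return 2.0 * p_star * alpha(p_star, cfg.selection, cfg.case)


def approx_negative_r0(cfg: ModelConfig) -> dict:
    """Closed-form unconditional probability for negative selection, r = 0.

    With ``p* ~ 0`` and selection much stronger than mutation, the
    branching system at ``p = 0`` collapses to

    ``alpha(0) phi_B(0) = phi_B(0)^2 / 2``  ->  ``phi_B(0) = 2 h_m s_m``
    ``v phi_B(0) = phi_b(0)^2 / 2``         ->  ``phi_b(0) = sqrt(2 v phi_B(0))``

    and ``phi ~ phi_b(0) = 2 sqrt(v h_m s_m)``: almost every new A arises on
    the (ubiquitous) b background and must wait for a b -> B mutation in its
    own lineage.  The returned dict also reports ``selection_dominant``,
    true when ``N phi_b(0) >> 1`` so that linked selection, not drift,
    governs establishment.
    """
    s, h = cfg.effective.s_m, cfg.effective.h_m
    v = cfg.mutation.v
    phi_B0 = 2.0 * h * s
    phi_b0 = float(np.sqrt(max(2.0 * v * phi_B0, 0.0)))
    return {
        "phi": phi_b0,
        "phi_B0": phi_B0,
        "phi_b0": phi_b0,
        "selection_dominant": cfg.N * phi_b0 > 10.0,
    }
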
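"""Core three-locus model of sex-determination turnover.

The model follows the fate of a new sex-determining allele A that arises at
an autosomal locus A/a while sex is still determined by an ancestral X/Y
locus.  A second autosomal locus B/b, at recombination fraction ``r`` from
A/a, is under sexually antagonistic selection: genotypes BB, Bb and bb have
fitness ``1 + s_m``, ``1 + h_m s_m``, ``1`` in males and ``1 + s_f``,
``1 + h_f s_f``, ``1`` in females.  Two turnover scenarios are handled:

* **case 1** — allele A is masculinizing; male heterogamety is retained and
  allele B is male-beneficial (``s_m > 0 > s_f``).
* **case 2** — allele A is strongly feminizing; heterogamety flips to the
  female side and allele B is female-beneficial (``s_f > 0 > s_m``).

All analytic machinery is written for case 1; case 2 is served by swapping
the male and female selection coefficients (:func:`case2_swap`), which makes
the two systems formally identical.  The module also provides the mean
per-generation change of the B-allele frequency, its stable equilibria, and
a classifier for the mode of selection implied by the sex-averaged fitness
scheme (equalizing / positive / negative / balancing).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SelectionParams",
    "MutationRates",
    "ModelConfig",
    "SelectionMode",
    "EquilibriumResult",
    "alpha",
    "beta",
    "mean_change",
    "equilibrium_p",
    "classify_mode",
    "case2_swap",
    "effective_selection",
]


@dataclass(frozen=True)
class SelectionParams:
    """Sexually antagonistic fitness scheme at the B/b locus.

    Parameters
    ----------
    s_m, s_f
        Selection coefficients in males and females.  Either may be
        negative; the four genotype fitnesses ``1 + s`` and ``1 + h s``
        must stay positive.
    h_m, h_f
        Dominance of allele B in males and females, in ``[0, 1]``.
    """

    s_m: float
    s_f: float
    h_m: float
    h_f: float

    def __post_init__(self) -> None:
        for name in ("h_m", "h_f"):
            h = getattr(self, name)
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"{name}={h} must lie in [0, 1]")
        for w in self.fitness_male + self.fitness_female:
            if w <= 0.0:
                raise ValueError("all genotype fitnesses must be positive")

    @property
    def fitness_male(self) -> tuple[float, float, float]:
        """Male fitness of (BB, Bb, bb)."""
        return (1.0 + self.s_m, 1.0 + self.h_m * self.s_m, 1.0)

    @property
    def fitness_female(self) -> tuple[float, float, float]:
        """Female fitness of (BB, Bb, bb)."""
        return (1.0 + self.s_f, 1.0 + self.h_f * self.s_f, 1.0)

    def sex_averaged_fitness(self) -> tuple[float, float, float]:
        """Sex-averaged fitness of (bb, Bb, BB) — the ordering that defines
        the mode of selection."""
        wm, wf = self.fitness_male, self.fitness_female
        return (
            0.5 * (wm[2] + wf[2]),
            0.5 * (wm[1] + wf[1]),
            0.5 * (wm[0] + wf[0]),
        )


@dataclass(frozen=True)
class MutationRates:
    """Recurrent mutation at the B/b locus.

    ``u`` is the per-generation rate B -> b, ``v`` the reverse rate b -> B.
    The analytic theory drops second-order terms in ``u`` and ``v``; a
    warning is emitted for rates above 1e-3 where that assumption frays.
    """

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.u < 1.0 and 0.0 <= self.v < 1.0):
            raise ValueError("mutation rates must lie in [0, 1)")
        if self.u > 1e-3 or self.v > 1e-3:
            warnings.warn(
                "mutation rates above 1e-3: second-order terms in u, v are "
                "not negligible and the analytic approximations degrade",
                stacklevel=2,
            )


class SelectionMode(enum.Enum):
    """Mode of selection at B/b implied by sex-averaged genotype fitnesses."""

    EQUALIZING = "equalizing"
    POSITIVE = "positive"
    NEGATIVE = "negative"
    BALANCING = "balancing"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ModelConfig:
    """Full scenario specification consumed by every downstream module.

    Parameters
    ----------
    N
        Diploid population size.
    r
        Recombination fraction between A/a and B/b per meiosis.
    case
        1 for a masculinizing A (heterogamety retained), 2 for a strongly
        feminizing A (heterogamety flips).
    selection, mutation
        Fitness scheme and recurrent-mutation rates at B/b.
    """

    N: int
    r: float
    case: int
    selection: SelectionParams
    mutation: MutationRates = field(default_factory=lambda: MutationRates(1e-6, 1e-6))

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if not 0.0 <= self.r <= 0.5:
            raise ValueError("r must lie in [0, 0.5]")
        if self.case not in (1, 2):
            raise ValueError("case must be 1 or 2")
        s = self.selection
        if self.case == 1 and not (s.s_m >= 0.0 >= s.s_f):
            raise ValueError(
                "case 1 (masculinizing A) requires s_m >= 0 >= s_f: allele B "
                "must be male-beneficial for A to profit from linkage"
            )
        if self.case == 2 and not (s.s_f >= 0.0 >= s.s_m):
            raise ValueError(
                "case 2 (feminizing A) requires s_f >= 0 >= s_m: allele B "
                "must be female-beneficial for A to profit from linkage"
            )

    # -- conveniences -----------------------------------------------------

    @property
    def effective(self) -> SelectionParams:
        """Selection parameters seen by the case-1 analytic layer.

        For case 2 the male and female roles are exchanged so that every
        case-1 formula applies verbatim.
        """
        return case2_swap(self.selection) if self.case == 2 else self.selection

    def to_dict(self) -> dict:
        s, m = self.selection, self.mutation
        return {
            "N": self.N,
            "r": self.r,
            "case": self.case,
            "s_m": s.s_m,
            "s_f": s.s_f,
            "h_m": s.h_m,
            "h_f": s.h_f,
            "u": m.u,
            "v": m.v,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            N=int(d["N"]),
            r=float(d["r"]),
            case=int(d.get("case", 1)),
            selection=SelectionParams(
                s_m=float(d["s_m"]),
                s_f=float(d["s_f"]),
                h_m=float(d["h_m"]),
                h_f=float(d["h_f"]),
            ),
            mutation=MutationRates(
                u=float(d.get("u", 1e-6)), v=float(d.get("v", 1e-6))
            ),
        )


def case2_swap(sel: SelectionParams) -> SelectionParams:
    """Exchange male and female roles of the selection parameters.

    The haplotype dynamics of a feminizing turnover (case 2) are identical
    to those of the masculinizing case after replacing ``(h_m, s_m)`` by
    ``(h_f, s_f)``; applying the swap twice is the identity.
    """
    return replace(sel, s_m=sel.s_f, s_f=sel.s_m, h_m=sel.h_f, h_f=sel.h_m)


def effective_selection(sel: SelectionParams, case: int) -> tuple[float, float]:
    """Return ``(s, h)`` driving the haplotype dynamics for the given case.

    The expected change of the A-bearing haplotype frequencies involves only
    the selection parameters of the heterogametic-side sex: males for case 1,
    females for case 2.
    """
    if case == 1:
        return sel.s_m, sel.h_m
    if case == 2:
        return sel.s_f, sel.h_f
    raise ValueError("case must be 1 or 2")


def _check_p(p: float) -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency p={p} outside [0, 1]")
    return p


def alpha(p: float, sel: SelectionParams, case: int = 1) -> float:
    """Per-generation growth rate of the A-B haplotype while rare.

    ``alpha(p) = h s + (s - 3 h s) p + (2 h s - s) p**2`` with ``(s, h)``
    the selection/dominance pair of the heterogametic-side sex
    (:func:`effective_selection`).
    """
    p = _check_p(p)
    s, h = effective_selection(sel, case)
    return h * s + (s - 3.0 * h * s) * p + (2.0 * h * s - s) * p * p


def beta(p: float, sel: SelectionParams, case: int = 1) -> float:
    """Per-generation growth rate of the A-b haplotype while rare.

    ``beta(p) = -h s p + (2 h s - s) p**2``; ``beta(0) = 0`` always, since an
    A-b haplotype in a population devoid of B experiences no selection.
    """
    p = _check_p(p)
    s, h = effective_selection(sel, case)
    return -h * s * p + (2.0 * h * s - s) * p * p


def mean_change(p: float, sel: SelectionParams, mut: MutationRates) -> float:
    """Expected one-generation change ``M_p`` of the B-allele frequency.

    Sex-averaged selection response plus recurrent mutation, to first order
    in the selection and mutation parameters:

    ``M_p = (1/2) sum_i s_i p (1-p) [h_i + (1 - 2 h_i) p] - u p + v (1-p)``

    The formula is symmetric in the two sexes, so it applies unchanged to
    both turnover cases.
    """
    p = _check_p(p)
    sel_term = 0.0
    for s, h in ((sel.s_m, sel.h_m), (sel.s_f, sel.h_f)):
        sel_term += 0.5 * s * p * (1.0 - p) * (h + (1.0 - 2.0 * h) * p)
    return sel_term - mut.u * p + mut.v * (1.0 - p)


@dataclass(frozen=True)
class EquilibriumResult:
    """Roots of ``M_p`` in (0, 1) with their stability.

    ``p_star`` is the stable equilibrium (the smallest stable root when more
    than one exists, in which case ``multistable`` is set).
    """

    p_star: float
    roots: tuple[float, ...]
    stable: tuple[bool, ...]
    multistable: bool


def equilibrium_p(
    sel: SelectionParams,
    mut: MutationRates,
    grid_points: int = 10_001,
    deriv_step: float = 1e-6,
) -> EquilibriumResult:
    """Locate the stable equilibrium frequency ``p*`` of allele B.

    ``M_p`` is scanned on a uniform grid over (0, 1); each sign change is
    polished with bracketed root finding, and stability is decided by the
    sign of a central-difference derivative.  With ``u, v > 0`` the
    boundaries repel (``M_p(0+) = v > 0``, ``M_p(1-) = -u < 0``), so at
    least one stable interior root always exists.

    Raises
    ------
    ValueError
        If no root lies in (0, 1); the message names the absorbing
        direction implied by the sign of ``M_p``.
    """
    f = lambda p: mean_change(p, sel, mut)  # noqa: E731
    eps = 1.0 / (10.0 * grid_points)
    grid = np.linspace(eps, 1.0 - eps, grid_points)
    vals = np.array([f(p) for p in grid])
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    roots: list[float] = []
    for i in idx:
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
            continue
        roots.append(float(brentq(f, grid[i], grid[i + 1], xtol=1e-15)))
    # dedupe near-identical roots from grid artefacts
    roots = sorted(roots)
    deduped: list[float] = []
    for root in roots:
        if not deduped or abs(root - deduped[-1]) > 1e-9:
            deduped.append(root)
    if not deduped:
        direction = "p -> 1 (B fixes)" if vals[0] > 0 else "p -> 0 (B is lost)"
        raise ValueError(
            f"M_p has no root in (0, 1); the frequency is absorbed toward {direction}"
        )
    stable = tuple(
        (f(min(root + deriv_step, 1.0)) - f(max(root - deriv_step, 0.0))) < 0.0
        for root in deduped
    )
    stable_roots = [root for root, st in zip(deduped, stable) if st]
    if not stable_roots:
        raise ValueError("no stable root of M_p found in (0, 1)")
    return EquilibriumResult(
        p_star=stable_roots[0],
        roots=tuple(deduped),
        stable=stable,
        multistable=len(stable_roots) > 1,
    )


def classify_mode(sel: SelectionParams, tol: float = 1e-12) -> SelectionMode:
    """Classify the mode of selection from sex-averaged genotype fitnesses.

    Let ``w(bb) <= / >= w(Bb) <= / >= w(BB)`` denote the sex-averaged
    fitnesses.  The modes are: *equalizing* if all three agree within
    ``tol``; *balancing* if the heterozygote is fittest
    (``bb < Bb > BB``); *positive* if fitness increases with the number of
    B copies; *negative* if it decreases.  Any other ordering (e.g. average
    underdominance) is reported as :attr:`SelectionMode.UNCLASSIFIED`
    rather than silently forced into a class.
    """
    w_bb, w_Bb, w_BB = sel.sex_averaged_fitness()
    if abs(w_bb - w_Bb) <= tol and abs(w_Bb - w_BB) <= tol:
        return SelectionMode.EQUALIZING
    if w_Bb > w_bb + tol and w_Bb > w_BB + tol:
        return SelectionMode.BALANCING
    if w_BB > w_Bb + tol and w_Bb > w_bb + tol:
        return SelectionMode.POSITIVE
    if w_bb > w_Bb + tol and w_Bb > w_BB + tol:
        return SelectionMode.NEGATIVE
    # Remaining orderings: ties with one strict inequality, or average
    # underdominance.  Resolve near-ties conservatively.
    if w_Bb < w_bb - tol and w_Bb < w_BB - tol:
        return SelectionMode.UNCLASSIFIED
    # one tie + one strict difference: directional mode implied by the
    # strict difference
    if abs(w_bb - w_Bb) <= tol:
        return SelectionMode.POSITIVE if w_BB > w_Bb else SelectionMode.NEGATIVE
    if abs(w_Bb - w_BB) <= tol:
        return SelectionMode.NEGATIVE if w_bb > w_Bb else SelectionMode.POSITIVE
    return SelectionMode.UNCLASSIFIED  # pragma: no cover - defensive
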
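"""Forward Wright-Fisher simulation of sex-determination turnover.

The stochastic oracle for the branching/ODE theory: an exact discrete-
generation model of N diploids with the ancestral X/Y locus, the new
sex-determining locus A/a, and the linked antagonistic locus B/b.  The
population is represented by genotype-category counts updated by
multinomial sampling (see :mod:`sdturnover._wf_kernels`), which makes
hundreds of thousands of replicates tractable.

Life cycle per generation: viability selection by the B/b fitness scheme
within each sex, random mating (mother drawn from females, father from
males) with recombination ``r`` between A/a and B/b, per-gamete mutation at
B/b, multinomial sampling of N offspring, sex assigned by genotype.  The
sex ratio is emergent, never forced.  Unlike the analytic layer, case 2 is
simulated as the true six-genotype feminizing system — no symbol swap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _wf_kernels as k
from .model import ModelConfig
from .stationary import stationary_density

__all__ = [
    "EstablishmentEstimate",
    "offspring_distribution",
    "step_generation",
    "simulate_establishment",
    "simulate_unconditional",
    "track_B_frequency",
    "LOST",
    "ESTABLISHED",
    "UNRESOLVED",
]

LOST, ESTABLISHED, UNRESOLVED = k.LOST, k.ESTABLISHED, k.UNRESOLVED


@dataclass(frozen=True)
class EstablishmentEstimate:
    """Monte-Carlo estimate of an establishment probability.

    ``n_unresolved`` counts replicates that hit the generation cap or lost
    one sex entirely (population collapse); they are reported separately,
    never silently binned.  The 95% confidence interval is Wilson's score
    interval for ``n_established`` successes out of resolved + unresolved
    replicates.
    """

    n_reps: int
    n_established: int
    n_lost: int
    n_unresolved: int
    estimate: float
    ci_low: float
    ci_high: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_established + self.n_lost + self.n_unresolved != self.n_reps:
            raise ValueError("outcome counts must sum to n_reps")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("confidence interval must contain the estimate")


def _wilson_ci(successes: int, n: int, z: float = 1.959963984540054):
    if n == 0:
        return 0.0, 1.0
    phat = successes / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    # rounding can push the bounds a ulp past the point estimate at 0 or n
    return min(max(0.0, center - half), phat), max(min(1.0, center + half), phat)


def _fitness_arrays(cfg: ModelConfig):
    sel = cfg.selection
    return (
        np.array(sel.fitness_male, dtype=np.float64),
        np.array(sel.fitness_female, dtype=np.float64),
    )


def offspring_distribution(counts: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """Exact offspring-category distribution for one generation.

    Accepts fractional counts, which makes the infinite-``N`` deterministic
    recursion available for validation against the analytic mean-change
    ``M_p``.  Raises if either sex has no reproducing individuals.
    """
    ncat = 14 if cfg.case == 1 else 21
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != (ncat,):
        raise ValueError(f"case {cfg.case} expects a count vector of length {ncat}")
    q = np.empty(ncat)
    wm, wf = _fitness_arrays(cfg)
    dist = k._case1_dist if cfg.case == 1 else k._case2_dist
    if not dist(counts, wm, wf, cfg.r, cfg.mutation.u, cfg.mutation.v, q):
        raise ValueError("one sex has no reproducing individuals (collapse)")
    return q


def step_generation(
    counts: np.ndarray, cfg: ModelConfig, rng: np.random.Generator
) -> np.ndarray:
    """Advance the population by one generation (selection, mating,
    recombination, mutation, multinomial resampling of N offspring)."""
    q = offspring_distribution(counts, cfg)
    return rng.multinomial(cfg.N, q)


def initial_state(
    cfg: ModelConfig, p0: float, linked_to: str, seed: int
) -> np.ndarray:
    """Old-system equilibrium population with one A copy on a ``linked_to``
    (``"B"`` or ``"b"``) haplotype."""
    np.random.seed(seed % 2147483647)
    return k._initial_state(cfg.case, cfg.N, p0, linked_to == "B")


def _summarize(outcomes: np.ndarray, seed: int) -> EstablishmentEstimate:
    n = outcomes.size
    est = int(np.sum(outcomes == ESTABLISHED))
    lost = int(np.sum(outcomes == LOST))
    unres = n - est - lost
    lo, hi = _wilson_ci(est, n)
    return EstablishmentEstimate(
        n_reps=n,
        n_established=est,
        n_lost=lost,
        n_unresolved=unres,
        estimate=est / n,
        ci_low=lo,
        ci_high=hi,
        seed=seed,
    )


def simulate_establishment(
    cfg: ModelConfig,
    p0: float,
    linked_to: str,
    n_reps: int,
    seed: int,
    max_generations: int | None = None,
    return_details: bool = False,
):
    """Monte-Carlo establishment probability of a single new A copy.

    Each replicate starts from the old-system equilibrium with the B allele
    at Hardy-Weinberg frequency ``p0``, introduces one A copy on a
    ``linked_to`` haplotype, and runs until A is lost, the old sex locus
    becomes monomorphic with A segregating (establishment), or
    ``max_generations`` (default ``100 N``) is reached.  Replicate ``j``
    uses an independent counter-derived seed, so any single replicate can
    be reproduced in isolation.
    """
    if linked_to not in ("B", "b"):
        raise ValueError("linked_to must be 'B' or 'b'")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    max_gens = 100 * cfg.N if max_generations is None else int(max_generations)
    wm, wf = _fitness_arrays(cfg)
    p0s = np.full(n_reps, float(p0))
    linked = np.full(n_reps, linked_to == "B")
    outcomes, gens, pB = k.run_establishment_batch(
        cfg.case,
        cfg.N,
        p0s,
        linked,
        wm,
        wf,
        cfg.r,
        cfg.mutation.u,
        cfg.mutation.v,
        max_gens,
        seed % 2147483647,
    )
    summary = _summarize(outcomes, seed)
    if return_details:
        return summary, outcomes, gens, pB
    return summary


def simulate_unconditional(
    cfg: ModelConfig,
    n_reps: int,
    seed: int,
    max_generations: int | None = None,
    p0_draws: np.ndarray | None = None,
) -> EstablishmentEstimate:
    """Unconditional establishment probability.

    For each replicate, the B frequency ``p0`` is drawn from the stationary
    density and the A copy arises on a random haplotype (linked to B with
    probability ``p0``); the pooled outcome estimates the stationary-
    averaged probability that the analytic layer computes by quadrature.
    ``p0_draws`` overrides the density sampling (e.g. to feed frequencies
    from a neutral burn-in instead).
    """
    rng = np.random.default_rng(seed)
    if p0_draws is None:
        dens = stationary_density(cfg)
        p0s = dens.sample(n_reps, rng)
    else:
        p0s = np.asarray(p0_draws, dtype=float)
        if p0s.shape != (n_reps,):
            raise ValueError("p0_draws must have length n_reps")
    linked = rng.random(n_reps) < p0s
    max_gens = 100 * cfg.N if max_generations is None else int(max_generations)
    wm, wf = _fitness_arrays(cfg)
    outcomes, _, _ = k.run_establishment_batch(
        cfg.case,
        cfg.N,
        p0s,
        linked,
        wm,
        wf,
        cfg.r,
        cfg.mutation.u,
        cfg.mutation.v,
        max_gens,
        seed % 2147483647,
    )
    return _summarize(outcomes, seed)


def track_B_frequency(
    cfg: ModelConfig,
    p_init: float,
    n_generations: int,
    seed: int,
    thin: int = 1,
) -> np.ndarray:
    """Trajectory of the B-allele frequency in the resident population (no
    A allele) — used to compare the realized frequency distribution with
    the analytic stationary density."""
    wm, wf = _fitness_arrays(cfg)
    return k.track_B_frequency(
        cfg.case,
        cfg.N,
        p_init,
        wm,
        wf,
        cfg.r,
        cfg.mutation.u,
        cfg.mutation.v,
        int(n_generations),
        int(thin),
        seed % 2147483647,
    )
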
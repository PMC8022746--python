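"""Infinite-sites diversity profiles around a sex-determination turnover.

An individual-based forward simulation of a chromosome segment carrying
the new sex-determining locus A/a at relative position 0.25 and the
antagonistic locus B/b at position 0.75.  Neutral mutations arise at
Poisson-distributed new positions; crossovers per gamete are Poisson with
mean ``segment_r`` and placed uniformly, so the A/a-B/b recombination
fraction is ``segment_r / 2``.  After a burn-in that lets the B/b locus
reach its selection-mutation(-drift) regime, a single A copy is
introduced; replicates are conditioned on establishment (old sex locus
monomorphic, A segregating — the same criterion as the Wright-Fisher
count simulator), and windowed nucleotide diversity is measured within
the A-bearing haplotype class (pi_A-A), within the a class (pi_a-a) and
between the classes (pi_A-a), each normalized by the per-window neutral
expectation ``theta = 4 N mu / n_windows``.

Implementation notes: haplotypes store neutral alleles as packed 64-bit
words over a fine lattice of ``n_sites`` candidate positions; a mutation
flips one uniformly chosen site, which approximates infinite sites to
within the (monitored) chance of hitting a segregating site.  Fixed
mutations are pruned every 100 generations and never count toward pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import ModelConfig, equilibrium_p

__all__ = [
    "HaplotypeSegment",
    "DiversityProfile",
    "DiversityRun",
    "pairwise_pi",
    "resident_diversity",
    "simulate_diversity",
    "A_POSITION",
    "B_POSITION",
]

A_POSITION = 0.25
B_POSITION = 0.75


# ---------------------------------------------------------------------------
# small pure-Python surface for tests and tiny examples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HaplotypeSegment:
    """One haplotype: neutral mutation positions plus the selected alleles.

    ``positions`` are unique floats in (0, 1); the selected loci live at
    fixed coordinates (0.25 and 0.75) and are held in ``allele_A``/
    ``allele_B``, never in ``positions``.
    """

    positions: frozenset[float]
    allele_A: int = 0
    allele_B: int = 0

    def __post_init__(self) -> None:
        for pos in self.positions:
            if not 0.0 < pos < 1.0:
                raise ValueError("neutral positions must lie in (0, 1)")
            if pos in (A_POSITION, B_POSITION):
                raise ValueError("selected loci cannot appear as neutral positions")


def pairwise_pi(
    class_a: list[HaplotypeSegment],
    class_b: list[HaplotypeSegment],
    n_windows: int = 50,
    theta_per_window: float | None = None,
) -> np.ndarray:
    """Mean per-window pairwise difference count between two haplotype
    classes (use the same list twice for within-class diversity).

    Returns raw per-window pi, or pi normalized by ``theta_per_window``
    when given.  Within-class calls exclude self-pairs.
    """
    if not class_a or not class_b:
        empty = "first" if not class_a else "second"
        raise ValueError(f"the {empty} haplotype class is empty")
    within = class_a is class_b
    if within and len(class_a) < 2:
        raise ValueError("within-class pi needs at least two haplotypes")
    edges = np.linspace(0.0, 1.0, n_windows + 1)
    acc = np.zeros(n_windows)
    n_pairs = 0
    for i, hap_i in enumerate(class_a):
        js = range(i + 1, len(class_b)) if within else range(len(class_b))
        for j in js:
            diff = hap_i.positions.symmetric_difference(class_b[j].positions)
            if diff:
                idx = np.clip(
                    np.searchsorted(edges, sorted(diff), side="right") - 1,
                    0,
                    n_windows - 1,
                )
                np.add.at(acc, idx, 1.0)
            n_pairs += 1
    acc /= n_pairs
    if theta_per_window is not None:
        acc /= theta_per_window
    return acc


# ---------------------------------------------------------------------------
# numba kernels: packed-bit population
# ---------------------------------------------------------------------------


@njit(cache=True)
def _make_gamete(neut, hapA, hapB, parent, out_neut, out_row, n_words, n_sites, segment_r):
    """Meiosis: recombine the parent's two haplotypes (read from the parent
    arrays) into row ``out_row`` of the offspring buffer; returns the A and
    B alleles carried by the gamete."""
    h0 = 2 * parent
    ncx = np.random.poisson(segment_r)
    start = 0 if np.random.random() < 0.5 else 1
    if ncx == 0:
        src = h0 + start
        for w in range(n_words):
            out_neut[out_row, w] = neut[src, w]
        return hapA[src], hapB[src]
    cuts = np.sort(np.random.random(ncx))
    # mosaic copy: segment [prev, cut) from current haplotype
    cur = start
    prev_site = 0
    a_allele = np.uint8(0)
    b_allele = np.uint8(0)
    iA = int(A_POSITION * n_sites)
    iB = int(B_POSITION * n_sites)
    a_done = False
    b_done = False
    for ci in range(ncx + 1):
        end_site = n_sites if ci == ncx else int(cuts[ci] * n_sites)
        if end_site > prev_site:
            src = h0 + cur
            # copy sites [prev_site, end_site)
            w0 = prev_site >> 6
            w1 = (end_site - 1) >> 6
            for w in range(w0, w1 + 1):
                lo = w << 6
                mask = np.uint64(0xFFFFFFFFFFFFFFFF)
                if lo < prev_site:
                    mask &= np.uint64(0xFFFFFFFFFFFFFFFF) << np.uint64(prev_site - lo)
                hi = lo + 64
                if hi > end_site:
                    mask &= np.uint64(0xFFFFFFFFFFFFFFFF) >> np.uint64(hi - end_site)
                out_neut[out_row, w] = (out_neut[out_row, w] & ~mask) | (
                    neut[src, w] & mask
                )
            if (not a_done) and prev_site <= iA < end_site:
                a_allele = hapA[src]
                a_done = True
            if (not b_done) and prev_site <= iB < end_site:
                b_allele = hapB[src]
                b_done = True
            prev_site = end_site
        cur = 1 - cur
    return a_allele, b_allele


@njit(cache=True)
def _evolve(
    neut,
    hapA,
    hapB,
    ycnt,
    buf_neut,
    buf_hapA,
    buf_hapB,
    buf_ycnt,
    case,
    wm,
    wf,
    segment_r,
    mu,
    u,
    v,
    n_gens,
    watch_A,
    seed,
):
    """Advance the population n_gens generations in place.

    Returns (code, generations_done): code 0 = ran to completion,
    1 = A lost, 2 = established (old locus monomorphic, A present),
    3 = population collapse (one sex empty).  With watch_A false the
    establishment/loss checks are skipped (burn-in / post-turnover mode).
    """
    np.random.seed(seed)
    N = ycnt.shape[0]
    n_words = neut.shape[1]
    n_sites = n_words * 64
    w_male = np.empty(N)
    w_female = np.empty(N)
    male_idx = np.empty(N, dtype=np.int64)
    female_idx = np.empty(N, dtype=np.int64)
    for gen in range(n_gens):
        # --- sexes and fitnesses ---------------------------------------
        n_m = 0
        n_f = 0
        for i in range(N):
            has_A = hapA[2 * i] | hapA[2 * i + 1]
            if case == 1:
                is_male = has_A == 1 or ycnt[i] > 0
            else:
                is_male = has_A == 0 and ycnt[i] > 0
            g = 2 - (hapB[2 * i] + hapB[2 * i + 1])  # 0 BB, 1 Bb, 2 bb
            if is_male:
                male_idx[n_m] = i
                w_male[n_m] = wm[g] + (w_male[n_m - 1] if n_m > 0 else 0.0)
                n_m += 1
            else:
                female_idx[n_f] = i
                w_female[n_f] = wf[g] + (w_female[n_f - 1] if n_f > 0 else 0.0)
                n_f += 1
        if n_m == 0 or n_f == 0:
            return 3, gen
        tot_m = w_male[n_m - 1]
        tot_f = w_female[n_f - 1]

        # --- offspring ---------------------------------------------------
        for j in range(N):
            father = male_idx[
                np.searchsorted(w_male[:n_m], np.random.random() * tot_m, side="right")
            ]
            mother = female_idx[
                np.searchsorted(
                    w_female[:n_f], np.random.random() * tot_f, side="right"
                )
            ]
            yc = 0
            for parent, row in ((mother, 2 * j), (father, 2 * j + 1)):
                aA, aB = _make_gamete(
                    neut, hapA, hapB, parent, buf_neut, row, n_words, n_sites, segment_r
                )
                # sex chromosome transmits independently of the segment
                if ycnt[parent] == 2:
                    yc += 1
                elif ycnt[parent] == 1 and np.random.random() < 0.5:
                    yc += 1
                # mutation at B/b
                if aB == 1:
                    if u > 0.0 and np.random.random() < u:
                        aB = np.uint8(0)
                elif v > 0.0 and np.random.random() < v:
                    aB = np.uint8(1)
                # neutral mutations at uniformly chosen lattice sites
                nm = np.random.poisson(mu)
                for _ in range(nm):
                    site = np.random.randint(n_sites)
                    buf_neut[row, site >> 6] ^= np.uint64(1) << np.uint64(site & 63)
                buf_hapA[row] = aA
                buf_hapB[row] = aB
            buf_ycnt[j] = yc

        # commit generation
        neut[:, :] = buf_neut
        hapA[:] = buf_hapA
        hapB[:] = buf_hapB
        ycnt[:] = buf_ycnt

        # --- prune fixed neutral mutations every 100 generations --------
        if gen % 100 == 99:
            for w in range(n_words):
                m = np.uint64(0xFFFFFFFFFFFFFFFF)
                for row in range(2 * N):
                    m &= neut[row, w]
                    if m == 0:
                        break
                if m != 0:
                    for row in range(2 * N):
                        neut[row, w] ^= m

        if watch_A:
            a_tot = 0
            y_tot = 0
            for i in range(N):
                a_tot += hapA[2 * i] + hapA[2 * i + 1]
                y_tot += ycnt[i]
            if a_tot == 0:
                return 1, gen + 1
            if case == 1:
                if y_tot == 0:
                    return 2, gen + 1
            else:
                if y_tot == 2 * N:
                    return 2, gen + 1
    return 0, n_gens


@njit(cache=True)
def _class_site_counts(neut, hapA):
    """Per-site derived-allele counts within the A and a haplotype classes."""
    n_hap, n_words = neut.shape
    n_sites = n_words * 64
    cA = np.zeros(n_sites, dtype=np.int64)
    ca = np.zeros(n_sites, dtype=np.int64)
    nA = 0
    na = 0
    for row in range(n_hap):
        in_A = hapA[row] == 1
        if in_A:
            nA += 1
        else:
            na += 1
        for w in range(n_words):
            word = neut[row, w]
            while word != 0:
                b = int(np.log2(float(word & (~word + np.uint64(1)))) + 0.5)
                site = (w << 6) + b
                if in_A:
                    cA[site] += 1
                else:
                    ca[site] += 1
                word &= word - np.uint64(1)
    return cA, ca, nA, na


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiversityProfile:
    """Windowed nucleotide diversity at one sampling time.

    ``pi_AA``/``pi_aa``/``pi_Aa`` are normalized by the per-window neutral
    expectation ``theta_per_window = 4 N mu / n_windows``; the ``raw_``
    fields carry the unnormalized mean pairwise difference counts.  ``t``
    is generations since the old sex locus became monomorphic.
    """

    t: int
    window_mid: np.ndarray
    pi_AA: np.ndarray
    pi_aa: np.ndarray
    pi_Aa: np.ndarray
    raw_AA: np.ndarray
    raw_aa: np.ndarray
    raw_Aa: np.ndarray
    theta_per_window: float
    n_A_haplotypes: int
    n_a_haplotypes: int


@dataclass(frozen=True)
class DiversityRun:
    """Profiles from one establishment-conditioned replicate."""

    profiles: list[DiversityProfile]
    attempts: int
    establishment_generation: int
    established: bool
    segment_r: float
    mu: float
    seed: int
    final_pB: float = field(default=np.nan)


class _Population:
    def __init__(self, cfg: ModelConfig, n_sites: int, p_init: float, rng):
        N = cfg.N
        n_words = n_sites // 64
        self.neut = np.zeros((2 * N, n_words), dtype=np.uint64)
        self.hapA = np.zeros(2 * N, dtype=np.uint8)
        self.hapB = (rng.random(2 * N) < p_init).astype(np.uint8)
        self.ycnt = np.zeros(N, dtype=np.uint8)
        self.ycnt[N // 2 :] = 1  # males XY, females XX (both cases ancestrally)
        self._buffers = (
            np.zeros_like(self.neut),
            np.zeros_like(self.hapA),
            np.zeros_like(self.hapB),
            np.zeros_like(self.ycnt),
        )

    def snapshot(self):
        return (
            self.neut.copy(),
            self.hapA.copy(),
            self.hapB.copy(),
            self.ycnt.copy(),
        )

    def restore(self, snap) -> None:
        self.neut[:, :] = snap[0]
        self.hapA[:] = snap[1]
        self.hapB[:] = snap[2]
        self.ycnt[:] = snap[3]

    def evolve(self, cfg, segment_r, mu, n_gens, watch_A, seed):
        wm = np.array(cfg.selection.fitness_male)
        wf = np.array(cfg.selection.fitness_female)
        return _evolve(
            self.neut,
            self.hapA,
            self.hapB,
            self.ycnt,
            *self._buffers,
            cfg.case,
            wm,
            wf,
            segment_r,
            mu,
            cfg.mutation.u,
            cfg.mutation.v,
            int(n_gens),
            watch_A,
            int(seed) % 2147483647,
        )


def _profile(pop: _Population, cfg, mu, n_windows, t) -> DiversityProfile:
    cA, ca, nA, na = _class_site_counts(pop.neut, pop.hapA)
    n_sites = pop.neut.shape[1] * 64
    sites = np.arange(n_sites)
    win = (sites * n_windows) // n_sites
    raw_AA = np.zeros(n_windows)
    raw_aa = np.zeros(n_windows)
    raw_Aa = np.zeros(n_windows)
    cA = cA.astype(float)
    ca = ca.astype(float)
    if nA >= 2:
        term = 2.0 * cA * (nA - cA) / (nA * (nA - 1.0))
        np.add.at(raw_AA, win, term)
    if na >= 2:
        term = 2.0 * ca * (na - ca) / (na * (na - 1.0))
        np.add.at(raw_aa, win, term)
    if nA >= 1 and na >= 1:
        term = (cA * (na - ca) + ca * (nA - cA)) / (nA * na)
        np.add.at(raw_Aa, win, term)
    theta_w = 4.0 * cfg.N * mu / n_windows
    mid = (np.arange(n_windows) + 0.5) / n_windows
    return DiversityProfile(
        t=t,
        window_mid=mid,
        pi_AA=raw_AA / theta_w,
        pi_aa=raw_aa / theta_w,
        pi_Aa=raw_Aa / theta_w,
        raw_AA=raw_AA,
        raw_aa=raw_aa,
        raw_Aa=raw_Aa,
        theta_per_window=theta_w,
        n_A_haplotypes=nA,
        n_a_haplotypes=na,
    )


def resident_diversity(
    cfg: ModelConfig,
    segment_r: float,
    mu: float,
    n_windows: int = 50,
    n_sites: int = 8192,
    seed: int = 0,
    burn_in: int | None = None,
    initial_pB: float | None = None,
) -> DiversityProfile:
    """Windowed diversity of the resident population after burn-in, with no
    A allele introduced (all haplotypes fall in the a class, so ``pi_aa``
    is population diversity).  The neutral-equilibrium calibration of the
    simulator: with selection off, normalized pi should scatter around 1.
    """
    rng = np.random.default_rng(seed)
    if initial_pB is None:
        try:
            initial_pB = equilibrium_p(cfg.selection, cfg.mutation).p_star
        except ValueError:
            initial_pB = 0.5
    burn = 10 * cfg.N if burn_in is None else int(burn_in)
    pop = _Population(cfg, n_sites, initial_pB, rng)
    code, _ = pop.evolve(cfg, segment_r, mu, burn, False, rng.integers(1, 2**31 - 1))
    if code == 3:
        raise RuntimeError("population collapsed during burn-in")
    return _profile(pop, cfg, mu, n_windows, 0)


def simulate_diversity(
    cfg: ModelConfig,
    segment_r: float,
    mu: float,
    sample_times: list[int],
    n_windows: int = 50,
    n_sites: int = 8192,
    seed: int = 0,
    max_attempts: int = 100_000,
    burn_in: int | None = None,
    initial_pB: float | None = None,
    condition: bool = True,
    max_generations: int | None = None,
    burn_in_Bb_mutation: bool = False,
) -> DiversityRun:
    """One establishment-conditioned replicate with diversity profiles.

    The population burns in for ``burn_in`` generations (default ``20 N``)
    with the B/b locus evolving under its selection mode and the old X/Y
    system determining sex.  A single A copy is then introduced on a random
    haplotype (so it falls on a B background with probability equal to the
    current B frequency); the attempt is repeated from the same burned-in
    state with fresh randomness until one lineage establishes.  Profiles
    are recorded at every requested time ``t`` (generations after the old
    locus became monomorphic; ``t=0`` is the establishment moment).

    By default recurrent B/b mutation is switched off *during the burn-in
    only* (``burn_in_Bb_mutation=False``): under balancing selection an
    occasional new allelic lineage can replace its class and reset the
    age of the polymorphism, whereas the scenario being emulated is a
    polymorphism that predates the turnover by the whole burn-in.  The
    neutral mutation process and all post-introduction dynamics always use
    the configured rates.

    With ``condition=False`` the first attempt is returned regardless of
    outcome (useful for neutral calibration, where no A is introduced if
    ``sample_times`` only require the resident population).

    Raises
    ------
    RuntimeError
        If no attempt establishes within ``max_attempts``.
    """
    if n_sites % 64:
        raise ValueError("n_sites must be a multiple of 64")
    rng = np.random.default_rng(seed)
    if initial_pB is None:
        try:
            initial_pB = equilibrium_p(cfg.selection, cfg.mutation).p_star
        except ValueError:
            initial_pB = 0.5
    burn = 20 * cfg.N if burn_in is None else int(burn_in)
    max_gens = 100 * cfg.N if max_generations is None else int(max_generations)

    burn_cfg = cfg
    if not burn_in_Bb_mutation:
        from dataclasses import replace as _replace
        from .model import MutationRates as _MR

        burn_cfg = _replace(cfg, mutation=_MR(0.0, 0.0))
    pop = _Population(cfg, n_sites, initial_pB, rng)
    code, _ = pop.evolve(
        burn_cfg, segment_r, mu, burn, False, rng.integers(1, 2**31 - 1)
    )
    if code == 3:
        raise RuntimeError("population collapsed during burn-in")

    snap = pop.snapshot()
    attempts = 0
    while True:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"no establishment in {max_attempts} attempts; consider the "
                "analytic establishment probability for this configuration "
                "before rerunning with a larger budget"
            )
        pop.restore(snap)
        # introduce one A copy on a random haplotype of the offspring pool
        row = int(rng.integers(0, 2 * cfg.N))
        pop.hapA[row] = 1
        code, gens = pop.evolve(
            cfg, segment_r, mu, max_gens, True, rng.integers(1, 2**31 - 1)
        )
        established = code == 2
        if established or not condition:
            break

    profiles = []
    if established:
        t_prev = 0
        for t in sorted(sample_times):
            if t > t_prev:
                code, _ = pop.evolve(
                    cfg, segment_r, mu, t - t_prev, False, rng.integers(1, 2**31 - 1)
                )
                if code == 3:
                    break
                t_prev = t
            profiles.append(_profile(pop, cfg, mu, n_windows, t))
    pB = float(pop.hapB.mean())
    return DiversityRun(
        profiles=profiles,
        attempts=attempts,
        establishment_generation=gens if established else -1,
        established=established,
        segment_r=segment_r,
        mu=mu,
        seed=seed,
        final_pB=pB,
    )
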
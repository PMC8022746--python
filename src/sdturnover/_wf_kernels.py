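"""Numba kernels for the exact multinomial Wright-Fisher simulator.

State is a vector of genotype-category counts; one generation is
viability selection within each sex, random mating with recombination
between A/a and B/b, mutation at B/b applied per gamete, and multinomial
resampling of N offspring whose sexes follow their genotypes.

Case 1 (masculinizing A, 14 categories)::

    0..2   females aa XX, B-genotype in {BB, Bb, bb}
    3..5   males   aa XY, B-genotype
    6..13  males   Aa:  6 + 4*sc + hp,  sc in {0: XY, 1: XX},
           hp = 2*x + y with x = allele on the A haplotype, y = allele on
           the a haplotype (0 = B, 1 = b)

Case 2 (strongly feminizing A, 21 categories)::

    0..2   females aa XX        3..5  males aa XY       6..8  males aa YY
    9..20  females Aa:  9 + 4*sc + hp,  sc in {0: XX, 1: XY, 2: YY}

Outcome codes: 0 = allele A lost, 1 = established (old sex locus
monomorphic with A segregating), 2 = unresolved / population collapse.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOST = 0
ESTABLISHED = 1
UNRESOLVED = 2

_B_TRANSMIT = np.array([1.0, 0.5, 0.0])  # P(gamete carries B | genotype BB,Bb,bb)


@njit(cache=True)
def _sample_multinomial(n, q, out):
    """Sequential-binomial multinomial sampler robust to rounding in the
    conditional probabilities (which can graze 1 after normalization)."""
    remaining = 1.0
    left = n
    for i in range(q.shape[0] - 1):
        if left <= 0 or remaining <= 0.0:
            out[i] = 0
            continue
        p = q[i] / remaining
        if p >= 1.0:
            out[i] = left
            left = 0
        elif p <= 0.0:
            out[i] = 0
        else:
            c = np.random.binomial(left, p)
            out[i] = c
            left -= c
        remaining -= q[i]
    out[q.shape[0] - 1] = left


@njit(cache=True)
def _mutate_pair(gB, gb, u, v):
    """Apply B<->b mutation to a (B-bearing, b-bearing) gamete-mass pair."""
    return gB * (1.0 - u) + gb * v, gb * (1.0 - v) + gB * u


@njit(cache=True)
def _case1_dist(n, wm, wf, r, u, v, q):
    """Offspring-category distribution for case 1.

    ``n`` is the (possibly fractional) count vector, ``wm``/``wf`` the male
    and female fitnesses of (BB, Bb, bb).  Fills ``q`` (length 14) and
    returns False if either sex has no reproducing individuals.
    """
    # --- female gametes: always (X, a-hap); only P(B) matters -----------
    wtot_f = 0.0
    wB_f = 0.0
    for g in range(3):
        w = n[g] * wf[g]
        wtot_f += w
        wB_f += w * _B_TRANSMIT[g]
    if wtot_f <= 0.0:
        return False
    pBf = wB_f / wtot_f
    pBf = pBf * (1.0 - u) + (1.0 - pBf) * v

    # --- male gametes: 8 types, idx = 4*S + H, S in {X=0, Y=1},
    #     H in {A-B=0, A-b=1, a-B=2, a-b=3} ------------------------------
    gm = np.zeros(8)
    wtot_m = 0.0
    for g in range(3):
        w = n[3 + g] * wm[g]
        wtot_m += w
        cB = _B_TRANSMIT[g]
        gm[0 * 4 + 2] += 0.5 * w * cB
        gm[0 * 4 + 3] += 0.5 * w * (1.0 - cB)
        gm[1 * 4 + 2] += 0.5 * w * cB
        gm[1 * 4 + 3] += 0.5 * w * (1.0 - cB)
    for sc in range(2):
        for hp in range(4):
            cnt = n[6 + 4 * sc + hp]
            if cnt == 0.0:
                continue
            x = hp >> 1
            y = hp & 1
            w = cnt * wm[x + y]
            wtot_m += w
            # parental haplotypes A-x, a-y; recombinants A-y, a-x
            hap_mass = np.zeros(4)
            hap_mass[x] += 0.5 * (1.0 - r)
            hap_mass[2 + y] += 0.5 * (1.0 - r)
            hap_mass[y] += 0.5 * r
            hap_mass[2 + x] += 0.5 * r
            if sc == 0:  # XY male: X and Y gametes in halves
                for H in range(4):
                    gm[H] += 0.5 * w * hap_mass[H]
                    gm[4 + H] += 0.5 * w * hap_mass[H]
            else:  # XX male transmits X only
                for H in range(4):
                    gm[H] += w * hap_mass[H]
    if wtot_m <= 0.0:
        return False
    for i in range(8):
        gm[i] /= wtot_m
    for S in range(2):
        gm[4 * S], gm[4 * S + 1] = _mutate_pair(gm[4 * S], gm[4 * S + 1], u, v)
        gm[4 * S + 2], gm[4 * S + 3] = _mutate_pair(gm[4 * S + 2], gm[4 * S + 3], u, v)

    # --- offspring categories -------------------------------------------
    for i in range(14):
        q[i] = 0.0
    for S in range(2):
        for H in range(4):
            pg = gm[4 * S + H]
            if pg == 0.0:
                continue
            for ym in range(2):
                pm = pBf if ym == 0 else 1.0 - pBf
                w = pg * pm
                if H < 2:  # child Aa male; sc = XY iff father passed Y
                    sc = 0 if S == 1 else 1
                    q[6 + 4 * sc + 2 * H + ym] += w
                else:  # child aa; male iff Y
                    g = (H - 2) + ym
                    if S == 1:
                        q[3 + g] += w
                    else:
                        q[g] += w
    tot = 0.0
    for i in range(14):
        tot += q[i]
    for i in range(14):
        q[i] /= tot
    return True


@njit(cache=True)
def _case2_dist(n, wm, wf, r, u, v, q):
    """Offspring-category distribution for case 2 (21 categories)."""
    # --- male gametes: 4 types, idx = 2*S + z, z in {a-B=0, a-b=1} ------
    gmm = np.zeros(4)
    wtot_m = 0.0
    for g in range(3):  # XY males
        w = n[3 + g] * wm[g]
        wtot_m += w
        cB = _B_TRANSMIT[g]
        gmm[0] += 0.5 * w * cB
        gmm[1] += 0.5 * w * (1.0 - cB)
        gmm[2] += 0.5 * w * cB
        gmm[3] += 0.5 * w * (1.0 - cB)
    for g in range(3):  # YY males
        w = n[6 + g] * wm[g]
        wtot_m += w
        cB = _B_TRANSMIT[g]
        gmm[2] += w * cB
        gmm[3] += w * (1.0 - cB)
    if wtot_m <= 0.0:
        return False
    for i in range(4):
        gmm[i] /= wtot_m
    gmm[0], gmm[1] = _mutate_pair(gmm[0], gmm[1], u, v)
    gmm[2], gmm[3] = _mutate_pair(gmm[2], gmm[3], u, v)

    # --- female gametes: 8 types, idx = 4*S + H -------------------------
    gf = np.zeros(8)
    wtot_f = 0.0
    for g in range(3):  # aa XX females
        w = n[g] * wf[g]
        wtot_f += w
        cB = _B_TRANSMIT[g]
        gf[2] += w * cB
        gf[3] += w * (1.0 - cB)
    for sc in range(3):
        for hp in range(4):
            cnt = n[9 + 4 * sc + hp]
            if cnt == 0.0:
                continue
            x = hp >> 1
            y = hp & 1
            w = cnt * wf[x + y]
            wtot_f += w
            hap_mass = np.zeros(4)
            hap_mass[x] += 0.5 * (1.0 - r)
            hap_mass[2 + y] += 0.5 * (1.0 - r)
            hap_mass[y] += 0.5 * r
            hap_mass[2 + x] += 0.5 * r
            if sc == 0:  # XX
                for H in range(4):
                    gf[H] += w * hap_mass[H]
            elif sc == 1:  # XY
                for H in range(4):
                    gf[H] += 0.5 * w * hap_mass[H]
                    gf[4 + H] += 0.5 * w * hap_mass[H]
            else:  # YY
                for H in range(4):
                    gf[4 + H] += w * hap_mass[H]
    if wtot_f <= 0.0:
        return False
    for i in range(8):
        gf[i] /= wtot_f
    for S in range(2):
        gf[4 * S], gf[4 * S + 1] = _mutate_pair(gf[4 * S], gf[4 * S + 1], u, v)
        gf[4 * S + 2], gf[4 * S + 3] = _mutate_pair(gf[4 * S + 2], gf[4 * S + 3], u, v)

    # --- offspring -------------------------------------------------------
    for i in range(21):
        q[i] = 0.0
    for Sm in range(2):
        for H in range(4):
            pgf = gf[4 * Sm + H]
            if pgf == 0.0:
                continue
            for Sf in range(2):
                for z in range(2):
                    w = pgf * gmm[2 * Sf + z]
                    if w == 0.0:
                        continue
                    yc = Sm + Sf  # number of Y alleles: 0 XX, 1 XY, 2 YY
                    if H < 2:  # maternal A haplotype: child Aa female
                        q[9 + 4 * yc + 2 * H + z] += w
                    else:
                        g = (H - 2) + z
                        if yc == 0:
                            q[g] += w
                        elif yc == 1:
                            q[3 + g] += w
                        else:
                            q[6 + g] += w
    tot = 0.0
    for i in range(21):
        tot += q[i]
    for i in range(21):
        q[i] /= tot
    return True


@njit(cache=True)
def _hw_counts(n_total, p):
    """Deterministic Hardy-Weinberg rounding of n_total individuals to
    (BB, Bb, bb) counts by largest remainder."""
    probs = np.array([p * p, 2.0 * p * (1.0 - p), (1.0 - p) * (1.0 - p)])
    out = np.empty(3, dtype=np.int64)
    rem = np.empty(3)
    tot = 0
    for g in range(3):
        x = probs[g] * n_total
        out[g] = np.int64(x)
        rem[g] = x - out[g]
        tot += out[g]
    while tot < n_total:
        best = 0
        for g in range(1, 3):
            if rem[g] > rem[best]:
                best = g
        out[best] += 1
        rem[best] = -1.0
        tot += 1
    return out


@njit(cache=True)
def _initial_state(case, N, p0, linked_B):
    """Old-system equilibrium with a single A copy inserted.

    Half the population is female; B/b genotypes are at Hardy-Weinberg
    proportions of p0 within each sex.  One random individual is replaced
    by the A carrier, whose sex follows the new determination rules and
    whose old-locus genotype is XY or XX (case 1; XY or XX for the case-2
    female as well) with probability 1/2 each, as implied by the mutant
    gamete arising in the maternal or paternal pool.
    """
    ncat = 14 if case == 1 else 21
    n = np.zeros(ncat, dtype=np.int64)
    nf = N // 2
    nm = N - nf
    cf = _hw_counts(nf, p0)
    cm = _hw_counts(nm, p0)
    for g in range(3):
        n[g] = cf[g]
        n[3 + g] = cm[g]
    # remove a random resident
    k = np.random.randint(N)
    acc = 0
    for i in range(6):
        acc += n[i]
        if k < acc:
            n[i] -= 1
            break
    sc = 0 if np.random.random() < 0.5 else 1
    x = 0 if linked_B else 1
    y = 0 if np.random.random() < p0 else 1
    if case == 1:
        n[6 + 4 * sc + 2 * x + y] += 1
    else:
        n[9 + 4 * sc + 2 * x + y] += 1
    return n


@njit(cache=True)
def _a_count(case, n):
    tot = 0
    if case == 1:
        for i in range(6, 14):
            tot += n[i]
    else:
        for i in range(9, 21):
            tot += n[i]
    return tot


@njit(cache=True)
def _old_locus_poly(case, n):
    """True while the ancestral sex locus still segregates.

    Case 1: any Y left (categories 3..5 and Aa-XY 6..9).
    Case 2: any X left (all categories except aa-YY 6..8 and Aa-YY 17..20).
    """
    if case == 1:
        tot = 0
        for i in range(3, 10):
            tot += n[i]
        return tot > 0
    tot = 0
    for i in range(0, 6):
        tot += n[i]
    for i in range(9, 17):
        tot += n[i]
    return tot > 0


@njit(cache=True)
def _freq_B(case, n, N):
    tot = 0.0
    for g in range(3):
        w = 2.0 - g  # B copies in genotype g
        tot += w * (n[g] + n[3 + g])
        if case == 2:
            tot += w * n[6 + g]
    base = 6 if case == 1 else 9
    nsc = 2 if case == 1 else 3
    for sc in range(nsc):
        for hp in range(4):
            x = hp >> 1
            y = hp & 1
            tot += (2.0 - x - y) * n[base + 4 * sc + hp]
    return tot / (2.0 * N)


@njit(cache=True)
def _run_replicate(case, N, n, wm, wf, r, u, v, max_gens):
    """Run one initialized replicate to resolution.

    Returns (outcome, generations, final B frequency)."""
    ncat = 14 if case == 1 else 21
    q = np.empty(ncat)
    nf = n.astype(np.float64)
    for gen in range(max_gens):
        ok = (
            _case1_dist(nf, wm, wf, r, u, v, q)
            if case == 1
            else _case2_dist(nf, wm, wf, r, u, v, q)
        )
        if not ok:
            return UNRESOLVED, gen, _freq_B(case, n, N)
        _sample_multinomial(N, q, n)
        nf = n.astype(np.float64)
        if _a_count(case, n) == 0:
            return LOST, gen + 1, _freq_B(case, n, N)
        if not _old_locus_poly(case, n):
            return ESTABLISHED, gen + 1, _freq_B(case, n, N)
    return UNRESOLVED, max_gens, _freq_B(case, n, N)


@njit(cache=True)
def _rep_seed(seed0, rep):
    return (seed0 + 2654435761 * (rep + 1)) % 2147483647


@njit(cache=True)
def run_establishment_batch(case, N, p0s, linked_B, wm, wf, r, u, v, max_gens, seed0):
    """Replicate batch; p0s/linked_B give per-replicate initial conditions.

    Per-replicate counter-based seeding makes every replicate individually
    reproducible.  Returns (outcome, generations, final_pB) arrays.
    """
    nrep = p0s.shape[0]
    outcomes = np.empty(nrep, dtype=np.int64)
    gens = np.empty(nrep, dtype=np.int64)
    pB = np.empty(nrep)
    for rep in range(nrep):
        np.random.seed(_rep_seed(seed0, rep))
        n = _initial_state(case, N, p0s[rep], linked_B[rep])
        o, g, p = _run_replicate(case, N, n, wm, wf, r, u, v, max_gens)
        outcomes[rep] = o
        gens[rep] = g
        pB[rep] = p
    return outcomes, gens, pB


@njit(cache=True)
def track_B_frequency(case, N, p_init, wm, wf, r, u, v, n_gens, thin, seed):
    """Evolve the resident population (no A allele) and record the B-allele
    frequency every ``thin`` generations — the stochastic counterpart of the
    stationary density."""
    np.random.seed(seed)
    ncat = 14 if case == 1 else 21
    n = np.zeros(ncat, dtype=np.int64)
    nf_ = N // 2
    cf = _hw_counts(nf_, p_init)
    cm = _hw_counts(N - nf_, p_init)
    for g in range(3):
        n[g] = cf[g]
        n[3 + g] = cm[g]
    q = np.empty(ncat)
    out = np.empty(n_gens // thin)
    nf = n.astype(np.float64)
    for gen in range(n_gens):
        ok = (
            _case1_dist(nf, wm, wf, r, u, v, q)
            if case == 1
            else _case2_dist(nf, wm, wf, r, u, v, q)
        )
        if not ok:
            out[gen // thin :] = np.nan
            return out
        _sample_multinomial(N, q, n)
        nf = n.astype(np.float64)
        if gen % thin == 0:
            out[gen // thin] = _freq_B(case, n, N)
    return out
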
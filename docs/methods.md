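# Methods

## Model and assumptions

Three loci in a discrete-generation diploid population of size N: the
ancestral X/Y sex locus (males XY), a new sex-determining locus A/a on an
autosome, and a sexually antagonistic locus B/b at recombination fraction
r from A/a.  Fitness acts on viability through the B/b genotype only —
the new and old sex-determination systems are assumed fitness-equivalent,
so the fate of allele A is decided entirely by linkage to B/b.  All
analytic results are first-order in s, r, u, v; the simulators carry the
exact dynamics.

Case 1 (masculinizing A) keeps male heterogamety and requires a
male-beneficial B (s_m ≥ 0 ≥ s_f); case 2 (strongly feminizing A, XYAa
female) flips heterogamety and requires s_f ≥ 0 ≥ s_m.  The rare-A
haplotype dynamics of case 2 are identical to case 1 after exchanging the
male and female selection parameters, so every analytic routine internally
applies that swap; the Wright–Fisher simulator instead simulates the true
six-genotype case-2 system, which is what makes the swap testable.

The mode of selection at B/b is classified by the ordering of sex-averaged
genotype fitnesses (equalizing / positive / negative / balancing), with an
absolute tolerance of 1e-12 on ties and an explicit `unclassified` outcome
for average underdominance.  One-sided ties are resolved to the
directional mode implied by the strict inequality.

## Establishment probabilities

**Constant p (equalizing regime).**  The two coupled quadratics for
(phi_B, phi_b) reduce to a cubic in phi_B.  We evaluate the printed
closed-form branch (Cardano for R > 0, trigonometric otherwise, with the
arccos argument clipped to [-1, 1]); a guard accepts the root only if the
residuals of both quadratics are < 1e-10, the values lie in [0, 1], and —
because the trivial solution (0, 0) also has zero residual — the root is
strictly positive whenever the leading eigenvalue of the dynamics matrix
is positive.  If the closed form fails the guard (it is fragile exactly at
double-root boundaries), all cubic roots are scanned and the largest
admissible one is used.  The fully decoupled case b = (1-p) r + u = 0 is
special-cased analytically (phi_B = 2a exactly, phi_b from a scalar
quadratic), avoiding the ill-conditioning of numerical root-finding at a
double root.  Criticality is decided by the leading eigenvalue with
tolerance 1e-14; (sub)critical processes return (0, 0).

**Variable p.**  When selection moves p, the probabilities satisfy ODEs in
p along the deterministic M_p trajectory.  The boundary condition sits at
the stable equilibrium p* where the constant-p solution applies; since
M_p(p*) = 0 the integration starts at p* ± eps with eps = 1e-4 (shrunk
near boundaries).  Halving eps changes phi_B by well under 1e-4 relative.
Integration uses LSODA with rtol 1e-8 / atol 1e-12 on a grid of ~512
points per side (linear plus geometric refinement toward the boundaries),
restricted to the basin of p* — crossing another root of M_p would divide
by zero, and initial frequencies outside the basin raise an error naming
the unstable equilibrium.  Cached solutions are interpolated with a
monotone (PCHIP) interpolant and clamped to [0, 1]; queries outside the
cached range are clamped to the nearest endpoint (boundary margin 1e-4),
an error far below the quadrature tolerance because phi is flat there.

When the recombination rate exceeds the negative-selection threshold
r = h_m s_m, the branching component of phi collapses; establishment then
proceeds by drift at the ~2/N scale, which the branching description
deliberately excludes.  Results carry a `drift_dominated` flag instead of
guessing a drift correction; the Wright–Fisher simulator is the instrument
that resolves that floor.  Just above the threshold the exact
branching system retains a small mutation/recombination-mediated tail
(phi_B of order a few 1e-4 at 1.1x threshold for the reference negative
scheme), reaching the <1e-4 level around 1.5–2x threshold; the collapse is
therefore verified at the flanking recombination rates 0.005 and 0.02
that the theory's own worked example uses.

## Stationary density and unconditional probability

Wright's formula gives g(p) ∝ p^(4Nv-1) (1-p)^(4Nu-1) exp(c1 p + c2 p²)
with first-order selection coefficients; under equalizing selection the
first-order terms cancel and the printed second-order variant applies,
whose exponent factors as -N s_f² p² [(1-2h_f) p + 2h_f]².  At realistic
mutation rates the endpoint exponents are negative (4Nu - 1 ≈ -0.96 at
N = 10^4, u = 10^-6), so all integrals use QUADPACK's algebraic endpoint
weight rather than naive quadrature; the smooth factor is computed in log
space and rescaled by its maximum to avoid overflow at N s ~ 10².
Sampling from g uses rejection against the Beta(4Nv, 4Nu) kernel — the
exponential factor is bounded, so acceptance is exact.

The negative-selection closed form solves the printed two-equation system
at p = 0: phi_B(0) = 2 h_m s_m and v phi_B(0) = phi_b(0)²/2, giving
phi = phi_b(0) = 2 sqrt(v h_m s_m) (2.0e-4 at h_m = 0.5, s_m = 0.02,
v = 1e-6).  The independent quadrature of the full formula reproduces this
to 0.5%, which fixes the reading of the collapsed constant whose radical
is typographically ambiguous.

## Wright–Fisher simulator

Genotype-count representation: 14 categories for case 1 (3 female, 3
resident male, 8 phased Aa male) and 21 for case 2, updated by
(i) viability selection within each sex, (ii) random mating with
recombination r in the A-carrying parent's gamete pool, (iii) per-gamete
mutation at B/b, (iv) multinomial resampling of N offspring with sex
assigned by genotype.  Sex ratio is emergent; a generation in which either
sex is empty terminates the replicate as a collapse, reported separately.
The multinomial sampler is a sequential-binomial routine with explicit
clipping of the conditional probabilities, which rounding can push past 1.

Establishment means the old sex locus is monomorphic while A segregates —
in case 1 the Y is extinct (all males then are Aa by construction); in
case 2 the X is extinct (Y fixes; females are Aa, males aa YY).  The new
mutation enters as a single gamete: the carrier's sex follows the new
determination rules and its old-locus genotype is XY or XX with equal
probability (the mutant gamete is maternal or paternal with equal odds,
and either way carries Y with probability 1/2).  Initial populations are
at Hardy–Weinberg proportions of the chosen p0 (largest-remainder
rounding), replacing one random resident with the carrier.  Replicates are
seeded counter-style (seed + 2654435761·k mod 2^31-1), so any single
replicate reproduces in isolation.  The cap is 100 N generations;
capped replicates are reported as unresolved, never binned.

**One-step validation.**  The exact offspring-distribution recursion,
evaluated on fractional counts (the infinite-N limit), reproduces the
analytic M_p to O(s²): at s ~ 0.004 the one-generation discrepancy is
below 5e-6 across the frequency range.

**Theory-vs-simulation cells and desk-scale accuracy.**  The agreement
test uses N = 2,000 and 2×10^5 replicates per cell — CI half-widths of
~4–10% of the estimate — with eight cells spanning equalizing (h = 0.5
and 1.0, with and without recombination), balancing (below and at p*,
plus a b-linked cell), and negative selection on both sides of the
threshold.  This replication level resolves relative differences
comparable to the theory's own accuracy at N = 2,000: the branching
treatment holds p (or its deterministic trajectory) fixed, whereas p
actually diffuses with per-generation standard deviation sqrt(p(1-p)/2N)
during the ~1/phi-generation escape phase.  The resulting bias tracks the
curvature of phi(p) — downward for h = 0 equalizing (phi concave, ~-10%),
upward for h = 1 equalizing with recombination and for balancing around
p* (convexity/Jensen, +6–9%), downward for the negative-mode descent
(~-8%) — and shrinks like 1/N, reaching the ~1% level at N = 10^4 where
the full-scale scenarios live.  An independent Monte Carlo of the
two-type branching process itself (Poisson offspring, no finite-N
feedback on p) reproduces the closed-form cubic to sampling precision,
confirming that these gaps are finite-N physics rather than solver error.
The above-threshold negative cell is the drift-dominated regime — the
branching prediction is ~0 while the simulator resolves the ~2/N floor
(measured ≈ 2.1e-3 at N = 2,000).

**Neutral stationary check.**  The resident-population trajectory of the
B frequency over 4×10^6 generations at N = 1,000 with 4Nu = 4Nv = 1 (the
uniform-density case, which still exercises the singular endpoint
exponents) matches the analytic stationary CDF to a Kolmogorov–Smirnov
distance < 0.02 after thinning to ~autocorrelation-length spacing.

## Infinite-sites diversity simulator

Individual-based, with neutral alleles packed as 64-bit words over a fine
lattice of candidate positions (default 8,192; 4,096 in the scaled
acceptance runs).  A mutation flips one uniformly chosen site — an
approximation to infinite sites whose error is the probability of hitting
a segregating site (a few percent at the occupancies used, and neutral
with respect to the peak-to-background ratio statistic).  Crossovers per
gamete are Poisson(segment_r) at uniform positions, so the A/a–B/b
recombination fraction is segment_r/2 with the loci at positions 0.25 and
0.75.  Fixed mutations are pruned every 100 generations and never count
toward diversity.  Windowed pi (within-A, within-a, between) is computed
from per-site allele counts in each class — algebraically identical to
averaging pairwise differences — and normalized by theta = 4 N mu per
window; the set-based reference implementation `pairwise_pi` validates the
bit-level computation exactly on small cases.

**Burn-in and the old-polymorphism premise.**  Profiles at the moment of
turnover are meaningful only relative to the age of the B/b polymorphism.
The scenario being emulated is a balanced polymorphism that long predates
the turnover, so the default burn-in is 20 N generations with B/b
mutation switched off during the burn-in only: recurrent mutation would
occasionally let a new allelic lineage replace its class (rate ≈ 2Nuv-
driven, ~2e-5 per generation at the scaled parameters), resetting the
polymorphism's age mid-burn-in and silently violating the premise in a
fifth of replicates.  Neutral mutation, recombination and drift run
throughout; B/b mutation is restored the moment the sex-determining
mutation is introduced.  Establishment conditioning repeats attempts from
the same burned-in state with fresh randomness, introducing one A copy on
a random haplotype (B-linked with probability equal to the current B
frequency).

**Scaling.**  The full-scale scenario (N = 10,000, segment recombination
2e-4, u = v = 1e-6, |s| = 0.02) is run at N = 1,000 with all rates
ten-fold (N s, N r, N u invariant) for the acceptance checks, and at
N = 250 / rates forty-fold in the quick unit test.  Two caveats of such
scaling are documented rather than hidden: second-order selection terms
(N s²) are inflated, which under ×10-scaled "equalizing" selection
produces a real weak directional pressure on p (visible as B frequencies
relaxing below 1/2 during long burn-ins); and the drift of p during the
escape phase is stronger, as discussed above.  Both effects vanish at full
scale.  The neutral calibration (selection off, segment recombination
0.2, N = 500) yields window-averaged normalized pi within a few percent
of 1.

**What passing these tests does and does not show.**  The simulators
emulate exactly the model's assumptions — unstructured population,
discrete generations, viability selection, two alleles per locus, no
mutation at A/a.  Agreement of theory and simulation validates the
derivations and their numerical implementation at desk scale; it does not
test robustness to demography, selfing, sex-specific recombination, or
recurrent sex-determining mutations, all of which are outside the model.

## Defaults

| parameter | default | meaning |
|---|---|---|
| u, v | 1e-6 /generation | B↔b mutation rates (full scale) |
| eps (ODE boundary offset) | 1e-4 | distance from p* of the initial condition |
| ODE tolerances | rtol 1e-8, atol 1e-12 | LSODA |
| cubic residual tolerance | 1e-10 | acceptance of a root |
| equalizing tie tolerance | 1e-12 | mode classification |
| equilibrium grid | 10,001 points | sign-change scan for M_p roots |
| max_generations | 100 N | replicate cap, unresolved reported |
| n_windows | 50 | diversity windows on (0,1) |
| n_sites | 8,192 | neutral-site lattice |
| burn-in (diversity) | 20 N | pre-turnover generations |
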
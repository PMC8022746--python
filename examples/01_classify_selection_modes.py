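"""Classify the mode of selection at a sexually antagonistic locus.

The fate of a new sex-determining allele A hinges on how selection acts on
the linked locus B/b, summarized by the ordering of the sex-averaged
genotype fitnesses.  This script classifies four reference schemes and
prints the corresponding equilibrium frequency of allele B.
"""

from sdturnover import (
    MutationRates,
    SelectionParams,
    classify_mode,
    equilibrium_p,
)

schemes = {
    "dominant male-benefit, recessive female-cost": SelectionParams(0.02, -0.02, 1.0, 0.0),
    "additive, stronger female cost": SelectionParams(0.02, -0.025, 0.5, 0.5),
    "additive, weaker female cost": SelectionParams(0.02, -0.01, 0.5, 0.5),
    "additive, exactly opposed": SelectionParams(0.02, -0.02, 0.5, 0.5),
}
mut = MutationRates(1e-6, 1e-6)

for label, sel in schemes.items():
    mode = classify_mode(sel)
    try:
        p_star = f"{equilibrium_p(sel, mut).p_star:.4g}"
    except ValueError:
        p_star = "boundary"
    print(f"{label:46s} -> {mode.value:10s} (p* = {p_star})")

# The first scheme keeps B at an intermediate frequency (balancing), the
# second drives it out (negative), the third fixes it (positive), and the
# fourth leaves it to drift (equalizing): four very different landscapes
# for a new sex-determining mutation to arise into.
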
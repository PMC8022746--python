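"""Establishment probability of a new sex-determining allele.

Computes phi_B(p0) and phi_b(p0) — the probability that a single new
masculinizing allele A escapes stochastic loss given it arose linked to
allele B or b — by the constant-p closed form (valid under equalizing
selection) and by the variable-p ODE (balancing selection, where the B
frequency relaxes to p* = 1/2 during the escape).
"""

import numpy as np

from sdturnover import (
    ModelConfig,
    MutationRates,
    SelectionParams,
    phi_constant_p,
    phi_variable_p,
)

mut = MutationRates(1e-6, 1e-6)

print("equalizing selection (s = +-0.02, h = 1), constant-p closed form, r = 0")
cfg = ModelConfig(N=10_000, r=0.0, case=1,
                  selection=SelectionParams(0.02, -0.02, 1.0, 1.0), mutation=mut)
print("  p0    phi_B      phi_b      weighted")
for p0 in (0.1, 0.3, 0.5, 0.7, 0.9):
    est = phi_constant_p(p0, cfg)
    print(f"  {p0:.1f}  {est.phi_B:.6f}  {est.phi_b:.6f}  {est.weighted:.6f}")

print("\nbalancing selection (h_m=1, h_f=0), variable-p ODE vs constant-p, r = 0")
cfg = ModelConfig(N=10_000, r=0.0, case=1,
                  selection=SelectionParams(0.02, -0.02, 1.0, 0.0), mutation=mut)
print("  p0    ODE        constant-p")
for p0 in (0.2, 0.35, 0.5, 0.65, 0.8):
    ode = phi_variable_p(p0, cfg)
    const = phi_constant_p(p0, cfg)
    print(f"  {p0:.2f}  {ode.phi_B:.6f}  {const.phi_B:.6f}")

# Below p* = 0.5 the ODE value is smaller than the constant-p value (the
# rising B frequency dilutes the A-B advantage); above p* it is larger.
# All values dwarf the neutral expectation 2/N = 2e-4.
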
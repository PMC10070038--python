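"""How many covariate draws does the semi-simulation method need?

The SS power estimate is Monte Carlo in B, the number of covariate rows
used to estimate the unit information.  This script prints the seed-to-seed
standard error of the power at several B on the binary-covariate scenario;
the SE falls roughly as 1/sqrt(B) and is below 0.01 at the default
B = 10000.
"""

import binpower as bp

design_cov, trait, design = bp.scenario("S2")
curve = bp.power_se_curve(
    design_cov,
    trait,
    design,
    n=2000,
    b_grid=(1000, 2000, 5000, 10_000, 20_000),
    replicates=100,
    seed=1,
)
print(curve.to_string(index=False, float_format="%.4f"))
print(
    "\nEach row: sample SD of the SS power over 100 independent seeds. "
    "The log10(SE) vs log10(B) relationship is close to linear with "
    "slope -1/2 (the central-limit rate)."
)
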
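"""Accuracy of the analytic estimators against full simulation.

Runs the case-control benchmark scenario (no covariate, 1:1 sampling,
prevalence 0.2, MAF 0.1 dominant, OR 1.5) on a short n-grid with a
300-replicate empirical oracle, and prints the absolute errors of the
semi-simulation (SS) and representative-dataset (RD) powers.
"""

import binpower as bp

result = bp.benchmark_table1(
    "S1", n_grid=(600, 1000, 2000, 4000), replicates=300, seed=1
)
print(result.per_n.to_string(index=False, float_format="%.4f"))
print()
print(result.summary.to_string(index=False, float_format="%.4f"))
print(
    "\nae_* columns are |computed - empirical| power; with only 300 "
    "replicates the oracle itself carries a Monte-Carlo SE of ~0.03 at "
    "mid-range powers, which dominates these errors."
)
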
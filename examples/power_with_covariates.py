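"""Power for a SNP on a binary trait, with and without a covariate.

A prospective study of a disease with 20% prevalence tests a SNP (MAF 0.1,
dominant coding, OR 1.5) while adjusting for a binary exposure (rate 0.3,
OR 2.5 on the trait) that is negatively associated with the genotype
(second-stage gamma_G = log 0.2).  Ignoring the covariate at the planning
stage overstates the power of the adjusted analysis.
"""

import numpy as np

import binpower as bp

design_cov = bp.CovariateDesign(
    genotype=bp.GenotypeModel(maf=0.1, coding="dominant"),
    covariates=(
        bp.CovariateSpec(
            kind="binary",
            gamma_G=np.log(0.2),
            exposure_rate=0.3,
            beta_E=np.log(2.5),
        ),
    ),
)
trait = bp.TraitModel(beta_G=np.log(1.5), beta_E=(np.log(2.5),), prevalence=0.2)
design = bp.StudyDesign(mode="prospective")

n = 3000
res_ss = bp.power_ss(design_cov, trait, design, n, seed=1)
res_rd = bp.power_rd(design_cov, trait, design, n)

no_cov = bp.CovariateDesign(genotype=design_cov.genotype)
naive = bp.power_ss(
    no_cov, bp.TraitModel(beta_G=np.log(1.5), prevalence=0.2), design, n, seed=1
)

print(f"gleaned beta0  = {res_ss.resolved_params['beta0']:.4f}")
print(f"gleaned gamma0 = {res_ss.resolved_params['covariates'][0]['gamma0']:.4f}")
print(f"power at n={n}, alpha=0.05:")
print(f"  semi-simulation (B=10000)  : {res_ss.power:.4f}")
print(f"  representative dataset     : {res_rd.power:.4f}")
print(f"  ignoring the covariate     : {naive.power:.4f}")
print(
    "The two estimators agree closely; dropping the covariate from the plan "
    "overstates the power of the covariate-adjusted test."
)
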
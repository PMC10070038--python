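"""Canonical simulation scenarios used throughout the test-bench.

Three study settings with a common MAF of 0.1, a dominant genetic effect and
a disease prevalence of 20%:

* ``S1`` — no covariate, retrospective case-control sampling at a 1:1
  case-to-control ratio, ``beta_G = log(1.5)``.
* ``S2`` — one binary covariate (population exposure rate 0.3,
  ``beta_E = log(2.5)``, second-stage ``gamma_G = log(0.2)``), prospective
  sampling, ``beta_G = log(1.5)``.
* ``S3`` — one continuous covariate (standard normal given G,
  ``beta_E = log(2.5)``, ``gamma_G = log(0.5)``), prospective sampling,
  ``beta_G = log(1.3)``.
"""

from __future__ import annotations

import numpy as np

from .covariate_space import CovariateDesign, CovariateSpec, GenotypeModel
from .exceptions import InvalidParameterError
from .trait_model import StudyDesign, TraitModel

SCENARIO_IDS = ("S1", "S2", "S3")

_MAF = 0.1
_CODING = "dominant"
_PREVALENCE = 0.2


def scenario(
    name: str, beta_G: float | None = None
) -> tuple[CovariateDesign, TraitModel, StudyDesign]:
    """Return the (covariate design, trait model, study design) of a scenario.

    ``beta_G`` overrides the scenario's default genetic effect, e.g. for
    sample-size curves over a grid of odds ratios.
    """
    name = name.upper()
    geno = GenotypeModel(maf=_MAF, coding=_CODING)
    if name == "S1":
        design_cov = CovariateDesign(genotype=geno)
        trait = TraitModel(
            beta_G=np.log(1.5) if beta_G is None else beta_G,
            prevalence=_PREVALENCE,
        )
        design = StudyDesign(mode="retrospective", case_fraction=0.5)
    elif name == "S2":
        design_cov = CovariateDesign(
            genotype=geno,
            covariates=(
                CovariateSpec(
                    kind="binary",
                    gamma_G=np.log(0.2),
                    exposure_rate=0.3,
                    beta_E=np.log(2.5),
                ),
            ),
        )
        trait = TraitModel(
            beta_G=np.log(1.5) if beta_G is None else beta_G,
            beta_E=(np.log(2.5),),
            prevalence=_PREVALENCE,
        )
        design = StudyDesign(mode="prospective")
    elif name == "S3":
        design_cov = CovariateDesign(
            genotype=geno,
            covariates=(
                CovariateSpec(
                    kind="continuous",
                    gamma_G=np.log(0.5),
                    mean=0.0,
                    conditional_sd=1.0,
                    beta_E=np.log(2.5),
                ),
            ),
        )
        trait = TraitModel(
            beta_G=np.log(1.3) if beta_G is None else beta_G,
            beta_E=(np.log(2.5),),
            prevalence=_PREVALENCE,
        )
        design = StudyDesign(mode="prospective")
    else:
        raise InvalidParameterError(
            f"unknown scenario {name!r}; expected one of {SCENARIO_IDS}"
        )
    return design_cov, trait, design
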
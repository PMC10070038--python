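"""Joint covariate distribution of genotype and non-genetic covariates.

The covariate space is specified hierarchically: a SNP genotype ``G`` under
Hardy-Weinberg equilibrium with a chosen effect coding, and zero or more
non-genetic covariates ``E`` whose dependence on ``G`` is expressed through a
second-stage regression of ``E`` on ``G``,

    g2( E[E | G] ) = gamma0 + gamma_G * G,

with a logit link ``g2`` for binary ``E`` and the identity link for continuous
``E``.  Users provide only interpretable quantities (slopes and marginal
summaries such as the exposure rate or the marginal mean/SD); the intercepts
``gamma0`` and the conditional SD ``sigma_{E|G}`` are gleaned automatically by
:func:`resolve_stage2`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .exceptions import (
    ConvergenceError,
    InfeasibleModelError,
    InvalidParameterError,
    UnresolvedModelError,
)

CODINGS = ("additive", "dominant", "recessive")

_GAMMA0_BRACKET = 50.0
_GAMMA0_XTOL = 1e-12


@dataclass(frozen=True)
class GenotypeModel:
    """A bi-allelic SNP under Hardy-Weinberg equilibrium.

    Parameters
    ----------
    maf : float
        Minor allele frequency ``p``, in ``(0, 0.5]``.
    coding : {"additive", "dominant", "recessive"}
        Genetic effect coding.  Additive maps genotypes (aa, Aa, AA) to
        (0, 1, 2); dominant maps them to (0, 1, 1); recessive to (0, 0, 1).
    """

    maf: float
    coding: str = "additive"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise InvalidParameterError(
                f"maf must lie in (0, 0.5], got {self.maf!r}"
            )
        if self.coding not in CODINGS:
            raise InvalidParameterError(
                f"coding must be one of {CODINGS}, got {self.coding!r}"
            )

    def support(self) -> np.ndarray:
        """Distinct genotype values implied by the coding."""
        if self.coding == "additive":
            return np.array([0.0, 1.0, 2.0])
        return np.array([0.0, 1.0])

    def probabilities(self) -> np.ndarray:
        """HWE probabilities aligned with :meth:`support`."""
        p = self.maf
        q0, q1, q2 = (1 - p) ** 2, 2 * p * (1 - p), p**2
        if self.coding == "additive":
            return np.array([q0, q1, q2])
        if self.coding == "dominant":
            return np.array([q0, q1 + q2])
        return np.array([q0 + q1, q2])


def hwe_probs(model: GenotypeModel) -> dict[float, float]:
    """Map each genotype value to its Hardy-Weinberg probability."""
    return dict(zip(model.support().tolist(), model.probabilities().tolist()))


def genotype_moments(model: GenotypeModel) -> tuple[float, float]:
    """Closed-form mean and variance of the coded genotype value."""
    g = model.support()
    p = model.probabilities()
    mean = float(g @ p)
    var = float((g**2) @ p - mean**2)
    return mean, var


@dataclass(frozen=True)
class CovariateSpec:
    """One non-genetic covariate and its second-stage dependence on G.

    Exactly one marginal specification must be given: ``exposure_rate`` for a
    binary covariate, and either (``mean``, ``sd``) or ``conditional_sd``
    (optionally with ``mean``, default 0) for a continuous one.  ``gamma0``
    and ``sigma_cond`` are filled in by :func:`resolve_stage2`.
    """

    kind: str
    gamma_G: float
    beta_E: float | None = None
    exposure_rate: float | None = None
    mean: float | None = None
    sd: float | None = None
    conditional_sd: float | None = None
    gamma0: float | None = None
    sigma_cond: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise InvalidParameterError(
                f"covariate kind must be 'binary' or 'continuous', got {self.kind!r}"
            )
        if self.kind == "binary":
            if self.exposure_rate is None:
                raise InvalidParameterError(
                    "binary covariate requires an exposure_rate"
                )
            if not (0.0 < self.exposure_rate < 1.0):
                raise InvalidParameterError(
                    f"exposure_rate must lie in (0, 1), got {self.exposure_rate!r}"
                )
            if any(v is not None for v in (self.mean, self.sd, self.conditional_sd)):
                raise InvalidParameterError(
                    "binary covariate accepts only exposure_rate as its marginal"
                )
        else:
            if self.exposure_rate is not None:
                raise InvalidParameterError(
                    "continuous covariate does not accept exposure_rate"
                )
            if self.sd is not None and self.conditional_sd is not None:
                raise InvalidParameterError(
                    "over-specified continuous covariate: give either the "
                    "marginal sd or the conditional_sd, not both"
                )
            if self.sd is None and self.conditional_sd is None:
                raise InvalidParameterError(
                    "continuous covariate requires a marginal sd (with mean) "
                    "or a conditional_sd"
                )
            if self.sd is not None:
                if self.sd <= 0:
                    raise InvalidParameterError(f"sd must be > 0, got {self.sd!r}")
                if self.mean is None:
                    raise InvalidParameterError(
                        "continuous covariate specified by marginal sd also "
                        "requires its marginal mean"
                    )
            if self.conditional_sd is not None and self.conditional_sd <= 0:
                raise InvalidParameterError(
                    f"conditional_sd must be > 0, got {self.conditional_sd!r}"
                )

    @property
    def is_resolved(self) -> bool:
        if self.gamma0 is None:
            return False
        return self.kind == "binary" or self.sigma_cond is not None


def _binary_marginal_rate(
    gamma0: float, gamma_G: float, model: GenotypeModel
) -> float:
    g = model.support()
    p = model.probabilities()
    return float(p @ expit(gamma0 + gamma_G * g))


def resolve_stage2(spec: CovariateSpec, model: GenotypeModel) -> CovariateSpec:
    """Glean the second-stage intercept (and conditional SD) of a covariate.

    Binary ``E``: solves ``sum_g P(g) expit(gamma0 + gamma_G g) = exposure_rate``
    for ``gamma0`` by bracketed root finding (the map is strictly increasing in
    ``gamma0``).  Continuous ``E``: ``gamma0 = mean - gamma_G E[G]`` and, when
    the marginal SD was given, ``sigma_cond = sqrt(sd^2 - gamma_G^2 Var(G))``.
    """
    g_mean, g_var = genotype_moments(model)
    if spec.kind == "binary":
        target = spec.exposure_rate
        if spec.gamma_G == 0.0:
            gamma0 = float(logit(target))
        else:
            lo, hi = -_GAMMA0_BRACKET, _GAMMA0_BRACKET
            try:
                gamma0 = brentq(
                    lambda c: _binary_marginal_rate(c, spec.gamma_G, model) - target,
                    lo,
                    hi,
                    xtol=_GAMMA0_XTOL,
                )
            except ValueError as exc:  # pragma: no cover - bracket is safe
                raise ConvergenceError(
                    f"could not glean gamma0 for exposure_rate={target}"
                ) from exc
        return replace(spec, gamma0=float(gamma0))

    mean = spec.mean if spec.mean is not None else 0.0
    if spec.conditional_sd is not None:
        sigma_cond = spec.conditional_sd
    else:
        resid_var = spec.sd**2 - spec.gamma_G**2 * g_var
        if resid_var <= 0:
            raise InfeasibleModelError(
                "infeasible continuous covariate: marginal variance "
                f"sd^2={spec.sd**2:.6g} does not exceed the genotype-explained "
                f"variance gamma_G^2*Var(G)={spec.gamma_G**2 * g_var:.6g}"
            )
        sigma_cond = float(np.sqrt(resid_var))
    gamma0 = float(mean - spec.gamma_G * g_mean)
    return replace(spec, mean=mean, gamma0=gamma0, sigma_cond=sigma_cond)


@dataclass(frozen=True)
class CovariateDesign:
    """The full covariate space F_x = law of (G, E_1, ..., E_K).

    Covariates are mutually conditionally independent given G; this is the
    only multi-covariate structure supported.
    """

    genotype: GenotypeModel
    covariates: tuple[CovariateSpec, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    @property
    def all_discrete(self) -> bool:
        return all(c.kind == "binary" for c in self.covariates)

    @property
    def is_resolved(self) -> bool:
        return all(c.is_resolved for c in self.covariates)

    def resolve(self) -> "CovariateDesign":
        """Return a copy with all second-stage intercepts/SDs gleaned."""
        if self.is_resolved:
            return self
        resolved = tuple(
            c if c.is_resolved else resolve_stage2(c, self.genotype)
            for c in self.covariates
        )
        return replace(self, covariates=resolved)

    def column_names(self) -> list[str]:
        return ["G"] + [f"E{k + 1}" for k in range(self.n_covariates)]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_matrix(
    design: CovariateDesign, count: int, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. draws from F_x as a (count, 1+K) array with columns (G, E...)."""
    geno = design.genotype
    support = geno.support()
    g = support[rng.choice(len(support), size=count, p=geno.probabilities())]
    cols = [g]
    for spec in design.covariates:
        loc = spec.gamma0 + spec.gamma_G * g
        if spec.kind == "binary":
            cols.append((rng.random(count) < expit(loc)).astype(float))
        else:
            cols.append(rng.normal(loc, spec.sigma_cond))
    return np.column_stack(cols)


def sample_covariates(design: CovariateDesign, count: int, seed=None) -> pd.DataFrame:
    """Draw ``count`` i.i.d. rows (G, E1, ..., EK) from the population F_x.

    The design must be resolved (all gleaned parameters filled in).
    Reproducible for a fixed integer ``seed``.
    """
    if count < 1:
        raise InvalidParameterError(f"count must be >= 1, got {count}")
    if not design.is_resolved:
        raise UnresolvedModelError(
            "covariate design is unresolved; call design.resolve() first"
        )
    rng = _as_rng(seed)
    mat = _sample_matrix(design, count, rng)
    return pd.DataFrame(mat, columns=design.column_names())
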
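"""Outcome model, study design and the design-induced covariate law.

The trait follows a logistic regression on the covariate space,

    logit P(Y=1 | G, E) = beta0 + beta_G * G + sum_k beta_Ek * Ek,

with the intercept ``beta0`` gleaned from the disease prevalence ``K`` when
not supplied.  A retrospective (case-control) design changes two things
relative to a prospective one: the covariates are sampled from the mixture
``phi * P(x | Y=1) + (1 - phi) * P(x | Y=0)``, and the logistic intercept
shifts by the classical sampling-odds offset ``log(phi/(1-phi)) -
log(K/(1-K))`` (the slope parameters are unaffected, as in the
Prentice-Pyke result for case-control logistic regression).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import _core
from .covariate_space import CovariateDesign, _as_rng, _sample_matrix
from .exceptions import (
    ConvergenceError,
    InvalidParameterError,
    UnresolvedModelError,
)

_BETA0_BRACKET = 50.0
_BETA0_XTOL = 1e-12
_REJECTION_MIN_EFFICIENCY = 1e-4


@dataclass(frozen=True)
class TraitModel:
    """Logistic outcome model for the binary trait.

    ``beta_E`` may be left empty, in which case the per-covariate effects are
    taken from the ``beta_E`` fields of the covariate specs.  ``prevalence``
    is required whenever ``beta0`` must be gleaned and for any retrospective
    design.
    """

    beta_G: float
    beta_E: tuple[float, ...] = ()
    prevalence: float | None = None
    beta0: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_E", tuple(self.beta_E))
        if self.prevalence is not None and not (0.0 < self.prevalence < 1.0):
            raise InvalidParameterError(
                f"prevalence must lie in (0, 1), got {self.prevalence!r}"
            )
        if self.beta0 is None and self.prevalence is None:
            raise InvalidParameterError(
                "either beta0 or the prevalence must be supplied"
            )


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: prospective cohort or retrospective case-control."""

    mode: str = "prospective"
    case_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("prospective", "retrospective"):
            raise InvalidParameterError(
                f"mode must be 'prospective' or 'retrospective', got {self.mode!r}"
            )
        if not (0.0 < self.case_fraction < 1.0):
            raise InvalidParameterError(
                f"case_fraction must lie in (0, 1), got {self.case_fraction!r}"
            )


def _beta_E_vector(trait: TraitModel, design_cov: CovariateDesign) -> np.ndarray:
    k = design_cov.n_covariates
    if trait.beta_E:
        if len(trait.beta_E) != k:
            raise InvalidParameterError(
                f"trait supplies {len(trait.beta_E)} covariate effects but the "
                f"design has {k} covariates"
            )
        return np.asarray(trait.beta_E, dtype=float)
    effects = [spec.beta_E for spec in design_cov.covariates]
    if any(e is None for e in effects):
        raise InvalidParameterError(
            "covariate effect beta_E missing: set it on the trait model or on "
            "each covariate spec"
        )
    return np.asarray(effects, dtype=float)


def solve_beta0(trait: TraitModel, design_cov: CovariateDesign) -> float:
    """Glean the intercept from the prevalence: E_{F_x}[expit(eta)] = K.

    The expectation is exact over discrete covariates and uses 64-node
    Gauss-Hermite quadrature over each continuous covariate.
    """
    if trait.prevalence is None:
        raise InvalidParameterError("prevalence is required to glean beta0")
    design_cov = design_cov.resolve()
    beta_E = _beta_E_vector(trait, design_cov)
    target = trait.prevalence

    def gap(b0: float) -> float:
        return (
            _core.population_case_rate(design_cov, b0, trait.beta_G, beta_E)
            - target
        )

    try:
        return float(
            brentq(gap, -_BETA0_BRACKET, _BETA0_BRACKET, xtol=_BETA0_XTOL)
        )
    except ValueError as exc:  # pragma: no cover - bracket is safe for K in (0,1)
        raise ConvergenceError(
            f"could not glean beta0 for prevalence {target}"
        ) from exc


def effective_intercept(trait: TraitModel, design: StudyDesign) -> float:
    """Intercept entering the analysis model under the sampling design.

    Prospective: ``beta0`` unchanged.  Retrospective: ``beta0 +
    log(phi/(1-phi)) - log(K/(1-K))``, the intercept of the prospective
    logistic model fitted to case-control data.
    """
    if trait.beta0 is None:
        raise UnresolvedModelError("trait model has no resolved beta0")
    if design.mode == "prospective":
        return float(trait.beta0)
    if trait.prevalence is None:
        raise UnresolvedModelError(
            "retrospective design requires the disease prevalence"
        )
    return float(
        trait.beta0
        + logit(design.case_fraction)
        - logit(trait.prevalence)
    )


@dataclass(frozen=True, eq=False)
class ResolvedModel:
    """Fully gleaned bundle of covariate design, trait model and study design."""

    design_cov: CovariateDesign
    trait: TraitModel
    design: StudyDesign
    beta0_eff: float
    beta_E: tuple[float, ...]

    @property
    def beta0(self) -> float:
        return self.trait.beta0

    @property
    def beta_G(self) -> float:
        return self.trait.beta_G

    @property
    def prevalence(self) -> float | None:
        return self.trait.prevalence

    def slopes(self) -> np.ndarray:
        return np.concatenate([[self.trait.beta_G], self.beta_E])

    def eta(self, cov_rows: np.ndarray, effective: bool = True) -> np.ndarray:
        """Linear predictor for covariate rows with columns (G, E...)."""
        cov_rows = np.asarray(cov_rows, dtype=float)
        b0 = self.beta0_eff if effective else self.trait.beta0
        return b0 + cov_rows @ self.slopes()

    def params_dict(self) -> dict:
        """Echo of all resolved (gleaned) parameters, for reports."""
        return {
            "genotype": {
                "maf": self.design_cov.genotype.maf,
                "coding": self.design_cov.genotype.coding,
            },
            "covariates": [
                {
                    "kind": s.kind,
                    "gamma_G": s.gamma_G,
                    "gamma0": s.gamma0,
                    "sigma_cond": s.sigma_cond,
                    "exposure_rate": s.exposure_rate,
                    "mean": s.mean,
                    "sd": s.sd,
                    "beta_E": b,
                }
                for s, b in zip(self.design_cov.covariates, self.beta_E)
            ],
            "beta0": self.trait.beta0,
            "beta0_effective": self.beta0_eff,
            "beta_G": self.trait.beta_G,
            "beta_E": list(self.beta_E),
            "prevalence": self.trait.prevalence,
            "design": {
                "mode": self.design.mode,
                "case_fraction": self.design.case_fraction,
            },
        }


def resolve(
    design_cov: CovariateDesign, trait: TraitModel, design: StudyDesign
) -> ResolvedModel:
    """Glean every free intercept/SD and apply the design's intercept shift.

    For a retrospective design the intercept is always re-gleaned from the
    prevalence (a user-supplied ``beta0`` does not alter case-control power,
    so the prevalence governs the sampling law).
    """
    design_cov = design_cov.resolve()
    beta_E = _beta_E_vector(trait, design_cov)
    trait = replace(trait, beta_E=tuple(beta_E.tolist()))
    if design.mode == "retrospective":
        if trait.prevalence is None:
            raise InvalidParameterError(
                "retrospective design requires the disease prevalence"
            )
        beta0 = solve_beta0(trait, design_cov)
    elif trait.beta0 is not None:
        beta0 = float(trait.beta0)
    else:
        beta0 = solve_beta0(trait, design_cov)
    trait = replace(trait, beta0=beta0)
    return ResolvedModel(
        design_cov=design_cov,
        trait=trait,
        design=design,
        beta0_eff=effective_intercept(trait, design),
        beta_E=tuple(beta_E.tolist()),
    )


def retrospective_cell_probs(
    rm: ResolvedModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cell law of an all-discrete design under case-control sampling.

    Returns ``(C, p_design, p_case, p_control)`` where ``C`` enumerates the
    (G, E...) cells, ``p_case = P(cell | Y=1)``, ``p_control = P(cell | Y=0)``
    and ``p_design`` is their ``phi``-mixture.
    """
    cells, p_pop = _core.discrete_cells(rm.design_cov)
    pc = expit(rm.eta(cells, effective=False))
    k = float(p_pop @ pc)
    p_case = p_pop * pc / k
    p_control = p_pop * (1.0 - pc) / (1.0 - k)
    phi = rm.design.case_fraction
    return cells, phi * p_case + (1.0 - phi) * p_control, p_case, p_control


class CovariateSampler:
    """Sampler for the design-induced covariate law.

    Prospective designs sample the population F_x directly.  Retrospective
    designs sample the case-control mixture: by exact cell reweighting when
    all covariates are discrete, by rejection from F_x otherwise.
    """

    def __init__(self, rm: ResolvedModel):
        self._rm = rm
        self._cells = None
        if rm.design.mode == "retrospective" and rm.design_cov.all_discrete:
            cells, _, p_case, p_control = retrospective_cell_probs(rm)
            self._cells = (cells, p_case, p_control)

    def sample_outcome_matrix(
        self, y: int, count: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw covariate rows from P(x | Y=y)."""
        rm = self._rm
        if self._cells is not None:
            cells, p_case, p_control = self._cells
            probs = p_case if y == 1 else p_control
            idx = rng.choice(len(cells), size=count, p=probs)
            return cells[idx]
        # rejection from F_x with acceptance probability P(Y=y | x)
        out = []
        got, proposed = 0, 0
        base_rate = rm.prevalence if y == 1 else 1.0 - rm.prevalence
        while got < count:
            m = int((count - got) / max(base_rate, 0.01) * 1.2) + 64
            cand = _sample_matrix(rm.design_cov, m, rng)
            pc = expit(rm.eta(cand, effective=False))
            accept_p = pc if y == 1 else 1.0 - pc
            keep = cand[rng.random(m) < accept_p]
            out.append(keep)
            got += len(keep)
            proposed += m
            if proposed > 1000 and got / proposed < _REJECTION_MIN_EFFICIENCY:
                raise ConvergenceError(
                    "rejection sampler efficiency below 1e-4; the outcome "
                    f"Y={y} is nearly impossible under this model"
                )
        return np.vstack(out)[:count]

    def matrix(self, count: int, rng: np.random.Generator) -> np.ndarray:
        rm = self._rm
        if rm.design.mode == "prospective":
            return _sample_matrix(rm.design_cov, count, rng)
        if self._cells is not None:
            cells, p_case, p_control = self._cells
            phi = rm.design.case_fraction
            probs = phi * p_case + (1.0 - phi) * p_control
            idx = rng.choice(len(cells), size=count, p=probs)
            return cells[idx]
        n_case = rng.binomial(count, rm.design.case_fraction)
        rows = np.vstack(
            [
                self.sample_outcome_matrix(1, n_case, rng),
                self.sample_outcome_matrix(0, count - n_case, rng),
            ]
        )
        return rows[rng.permutation(count)]

    def sample(self, count: int, seed=None) -> pd.DataFrame:
        if count < 1:
            raise InvalidParameterError(f"count must be >= 1, got {count}")
        rng = _as_rng(seed)
        return pd.DataFrame(
            self.matrix(count, rng), columns=self._rm.design_cov.column_names()
        )


def sampling_law(
    design_cov: CovariateDesign, trait: TraitModel, design: StudyDesign
) -> CovariateSampler:
    """Covariate sampler under the study design (see :class:`CovariateSampler`)."""
    return CovariateSampler(resolve(design_cov, trait, design))


def enumerated_unit_information(
    design_cov: CovariateDesign, trait: TraitModel, design: StudyDesign
) -> np.ndarray:
    """Exact unit Fisher information for an all-discrete covariate design.

    Enumerates every (G, E...) cell under the design-induced covariate law and
    sums ``P(cell) * w(eta) * x x^T`` with the effective intercept inside eta.
    """
    rm = resolve(design_cov, trait, design)
    if not rm.design_cov.all_discrete:
        raise ValueError(
            "enumerated_unit_information requires an all-discrete design"
        )
    if rm.design.mode == "retrospective":
        cells, p_design, _, _ = retrospective_cell_probs(rm)
    else:
        cells, p_design = _core.discrete_cells(rm.design_cov)
    x = np.column_stack([np.ones(len(cells)), cells])
    w = _core.logistic_weight(rm.eta(cells))
    return (x * (p_design * w)[:, None]).T @ x


def enumerated_power(
    design_cov: CovariateDesign,
    trait: TraitModel,
    design: StudyDesign,
    n: int,
    alpha: float = 0.05,
) -> float:
    """Closed-form power from the exactly enumerated unit information."""
    info = enumerated_unit_information(design_cov, trait, design)
    v = _core.solve_variance(n * info)
    return _core.power_from_variance(trait.beta_G, v, alpha)
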
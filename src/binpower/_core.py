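"""Shared numerics: logistic weights, quadrature expectations, cell tools.

Column order of every design matrix in the package is (1, G, E1, ..., EK),
so the genotype coefficient always sits at index ``GENO_IDX``.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit
from scipy.stats import norm

from .covariate_space import CovariateDesign
from .exceptions import SingularInformationError

GENO_IDX = 1  # position of the G column in (1, G, E...)

_GH_ORDER = 64
_GH_NODES, _GH_WEIGHTS = hermgauss(_GH_ORDER)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(np.pi)

_COND_LIMIT = 1e12


def logistic_weight(eta: np.ndarray) -> np.ndarray:
    """IRLS weight mu(1-mu) of a logistic model at linear predictor eta."""
    mu = expit(eta)
    return mu * (1.0 - mu)


def power_from_variance(beta_G: float, v_G: float, alpha: float) -> float:
    """Two-sided Wald power given Var(beta_G_hat) = v_G."""
    z = norm.ppf(1.0 - alpha / 2.0)
    shift = beta_G / np.sqrt(v_G)
    return float(norm.cdf(-z + shift) + norm.cdf(-z - shift))


def eta_support_given_g(
    design: CovariateDesign,
    beta0: float,
    beta_G: float,
    beta_E: np.ndarray,
    g: float,
    fixed_binary: dict[int, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Support/quadrature representation of eta | G=g.

    Returns (etas, weights) such that ``sum(weights * f(etas))`` approximates
    ``E[f(eta) | G=g]`` exactly for binary covariates (enumeration) and by
    64-node Gauss-Hermite quadrature for continuous ones.  ``fixed_binary``
    pins specific binary covariates (by index) to a value instead of
    enumerating them.
    """
    etas = np.array([beta0 + beta_G * g])
    wts = np.array([1.0])
    for k, spec in enumerate(design.covariates):
        if fixed_binary is not None and k in fixed_binary:
            vals = np.array([beta_E[k] * fixed_binary[k]])
            probs = np.array([1.0])
        elif spec.kind == "binary":
            pk = expit(spec.gamma0 + spec.gamma_G * g)
            vals = np.array([0.0, beta_E[k]])
            probs = np.array([1.0 - pk, pk])
        else:
            m = spec.gamma0 + spec.gamma_G * g
            vals = beta_E[k] * (m + np.sqrt(2.0) * spec.sigma_cond * _GH_NODES)
            probs = _GH_WEIGHTS
        etas = (etas[:, None] + vals[None, :]).ravel()
        wts = (wts[:, None] * probs[None, :]).ravel()
    return etas, wts


def case_rate_given_g(
    design: CovariateDesign,
    beta0: float,
    beta_G: float,
    beta_E: np.ndarray,
    g: float,
    fixed_binary: dict[int, float] | None = None,
) -> float:
    """P(Y=1 | G=g) under the population covariate law."""
    etas, wts = eta_support_given_g(design, beta0, beta_G, beta_E, g, fixed_binary)
    return float(wts @ expit(etas))


def population_case_rate(
    design: CovariateDesign, beta0: float, beta_G: float, beta_E: np.ndarray
) -> float:
    """Population prevalence E_{F_x}[expit(eta)] implied by the model."""
    support = design.genotype.support()
    probs = design.genotype.probabilities()
    return float(
        sum(
            p * case_rate_given_g(design, beta0, beta_G, beta_E, g)
            for g, p in zip(support, probs)
        )
    )


def discrete_cells(design: CovariateDesign) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate an all-discrete covariate space.

    Returns ``(C, p)`` where ``C`` is (M, 1+K) with columns (G, E...), and
    ``p`` the population cell probabilities.  Requires every covariate to be
    binary.
    """
    if not design.all_discrete:
        raise ValueError("discrete_cells requires an all-binary covariate design")
    support = design.genotype.support()
    cells = support[:, None]
    probs = design.genotype.probabilities().copy()
    for spec in design.covariates:
        pk = expit(spec.gamma0 + spec.gamma_G * cells[:, 0])
        c0 = np.column_stack([cells, np.zeros(len(cells))])
        c1 = np.column_stack([cells, np.ones(len(cells))])
        cells = np.vstack([c0, c1])
        probs = np.concatenate([probs * (1.0 - pk), probs * pk])
    return cells, probs


def largest_remainder(weights: np.ndarray, n: int) -> np.ndarray:
    """Apportion n units proportionally to ``weights`` (Hamilton method).

    Floors ``n * w`` and hands the remaining units to the largest fractional
    parts; ties broken by index order.  The result always sums to ``n``.
    """
    weights = np.asarray(weights, dtype=float)
    target = n * weights / weights.sum()
    counts = np.floor(target).astype(int)
    short = n - counts.sum()
    if short > 0:
        frac = target - counts
        order = np.lexsort((np.arange(len(frac)), -frac))
        counts[order[:short]] += 1
    return counts


def solve_variance(information: np.ndarray, index: int = GENO_IDX) -> float:
    """Diagonal element ``[inv(I)]_{index,index}`` via a linear solve.

    Avoids a full inversion; raises :class:`SingularInformationError` when the
    matrix is singular and warns when it is badly conditioned.
    """
    information = np.asarray(information, dtype=float)
    cond = np.linalg.cond(information)
    if not np.isfinite(cond):
        raise SingularInformationError(
            "Fisher information matrix is singular; the covariate draw or "
            "representative dataset is degenerate (try a larger b or n)"
        )
    if cond > _COND_LIMIT:
        import warnings

        warnings.warn(
            f"Fisher information is ill-conditioned (cond={cond:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    basis = np.zeros(information.shape[0])
    basis[index] = 1.0
    try:
        col = np.linalg.solve(information, basis)
    except np.linalg.LinAlgError as exc:
        raise SingularInformationError(
            "Fisher information matrix could not be inverted"
        ) from exc
    v = float(col[index])
    if v <= 0:
        raise SingularInformationError(
            f"non-positive variance estimate ({v:.3g}) from the information matrix"
        )
    return v
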
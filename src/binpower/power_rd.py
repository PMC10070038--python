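"""Representative-dataset estimator of unconditional power (method RD).

Instead of sampling the covariate space, this method constructs a
deterministic size-n covariate set that mirrors the design-induced law:
discrete strata receive integer counts ``n * P(cell)`` (largest-remainder
rounding), and each continuous covariate is filled, within its genotype
stratum of size ``n_i``, with the Blom-type normal quantile scores

    E_j = gamma0 + gamma_G * g + sigma_{E|G} * PhiInv[(j - 0.375) / (n_i + 0.25)].

Each covariate row is then expanded into both outcomes with weights
``delta_l = P(Y=l | x)``, yielding 2n weighted observations whose weighted
Fisher information at the true coefficients gives ``V_Gn`` directly.  The
whole construction is deterministic, but its cost grows linearly with n.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from . import _core
from .covariate_space import CovariateDesign
from .exceptions import InvalidParameterError, UnresolvedModelError
from .results import PowerResult
from .trait_model import (
    ResolvedModel,
    StudyDesign,
    TraitModel,
    effective_intercept,
    resolve,
)


@dataclass(frozen=True, eq=False)
class RepresentativeDataset:
    """Expanded representative dataset of 2n weighted observations.

    ``x`` has rows (1, G, E...); rows ``i`` and ``i + n`` share the same
    covariates and carry outcomes 0 and 1 with weights summing to one.
    """

    x: np.ndarray
    y: np.ndarray
    weight: np.ndarray
    n: int


def _discrete_cell_design_probs(
    rm: ResolvedModel,
) -> tuple[list[tuple[float, ...]], np.ndarray]:
    """Design-law probabilities of the discrete cells (G x binary Es).

    Continuous covariates are integrated out by quadrature when the
    retrospective tilt is applied.
    """
    geno = rm.design_cov.genotype
    support = geno.support()
    g_probs = geno.probabilities()
    binary_idx = [
        k for k, s in enumerate(rm.design_cov.covariates) if s.kind == "binary"
    ]
    cells: list[tuple[float, ...]] = []
    probs: list[float] = []
    for g, pg in zip(support, g_probs):
        for combo in itertools.product((0.0, 1.0), repeat=len(binary_idx)):
            p_cell = pg
            for k, val in zip(binary_idx, combo):
                spec = rm.design_cov.covariates[k]
                pk = expit(spec.gamma0 + spec.gamma_G * g)
                p_cell *= pk if val == 1.0 else 1.0 - pk
            cells.append((float(g),) + combo)
            probs.append(p_cell)
    probs = np.asarray(probs)
    if rm.design.mode == "retrospective":
        case_rates = np.array(
            [
                _core.case_rate_given_g(
                    rm.design_cov,
                    rm.beta0,
                    rm.beta_G,
                    np.asarray(rm.beta_E),
                    cell[0],
                    fixed_binary=dict(zip(binary_idx, cell[1:])),
                )
                for cell in cells
            ]
        )
        k = float(probs @ case_rates)
        phi = rm.design.case_fraction
        probs = phi * probs * case_rates / k + (1.0 - phi) * probs * (
            1.0 - case_rates
        ) / (1.0 - k)
    return cells, probs


def representative_counts(
    design_cov: CovariateDesign,
    trait: TraitModel,
    design: StudyDesign,
    n: int,
) -> dict[tuple[float, ...], int]:
    """Integer counts per discrete covariate cell, summing exactly to n.

    Cells are keyed by (G, binary E values...).  Counts follow
    largest-remainder apportionment of ``n * P(cell)`` under the
    design-induced law; a cell rounding to zero is kept (at zero) with a
    warning since its stratum drops out of the information.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    rm = resolve(design_cov, trait, design)
    cells, probs = _discrete_cell_design_probs(rm)
    counts = _core.largest_remainder(probs, n)
    zeroed = [c for c, m, p in zip(cells, counts, probs) if m == 0 and p > 0]
    if zeroed:
        warnings.warn(
            f"{len(zeroed)} covariate cell(s) received a zero count at n={n}; "
            "their strata do not contribute to the information",
            UserWarning,
            stacklevel=2,
        )
    return dict(zip(cells, counts.tolist()))


def representative_continuous_values(
    gamma0: float, gamma_G: float, sigma_cond: float, g: float, n_i: int
) -> np.ndarray:
    """Quantile-spaced conditional-normal scores for a stratum of size n_i.

    Values are ``gamma0 + gamma_G g + sigma_cond * PhiInv[(j - 0.375) /
    (n_i + 0.25)]`` for j = 1..n_i, symmetric about the conditional mean.
    """
    if n_i < 1:
        raise InvalidParameterError(f"n_i must be >= 1, got {n_i}")
    j = np.arange(1, n_i + 1)
    scores = norm.ppf((j - 0.375) / (n_i + 0.25))
    return gamma0 + gamma_G * g + sigma_cond * scores


def build_representative_covariates(
    design_cov: CovariateDesign,
    trait: TraitModel,
    design: StudyDesign,
    n: int,
) -> np.ndarray:
    """The size-n representative covariate table with columns (G, E...).

    Discrete strata get largest-remainder counts; within each stratum every
    continuous covariate is filled with its quantile scores.  With several
    continuous covariates the later columns are deterministically permuted
    within the stratum so that the quantile sequences do not induce spurious
    rank correlation (the covariates are conditionally independent given G).
    """
    rm = resolve(design_cov, trait, design)
    counts = representative_counts(design_cov, trait, design, n)
    binary_idx = [
        k for k, s in enumerate(rm.design_cov.covariates) if s.kind == "binary"
    ]
    cont_idx = [
        k for k, s in enumerate(rm.design_cov.covariates) if s.kind == "continuous"
    ]
    n_cols = 1 + rm.design_cov.n_covariates
    blocks = []
    for cell, m in counts.items():
        if m == 0:
            continue
        block = np.empty((m, n_cols))
        g = cell[0]
        block[:, 0] = g
        for k, val in zip(binary_idx, cell[1:]):
            block[:, 1 + k] = val
        for order, k in enumerate(cont_idx):
            spec = rm.design_cov.covariates[k]
            vals = representative_continuous_values(
                spec.gamma0, spec.gamma_G, spec.sigma_cond, g, m
            )
            if order > 0:  # decorrelate from the first quantile sequence
                vals = vals[np.random.default_rng(order).permutation(m)]
            block[:, 1 + k] = vals
        blocks.append(block)
    return np.vstack(blocks)


def expand_rd(
    covariate_rows,
    trait: TraitModel,
    design: StudyDesign,
    design_cov: CovariateDesign | None = None,
) -> RepresentativeDataset:
    """Expand covariate rows into 2n outcome-weighted observations.

    ``covariate_rows`` may come from :func:`build_representative_covariates`
    or be a user-observed covariate table (the conditional-power path); a
    DataFrame or an (n, 1+K) array with columns (G, E...) is accepted.
    ``design_cov`` is needed whenever the trait intercept must be gleaned.
    """
    if isinstance(covariate_rows, pd.DataFrame):
        covariate_rows = covariate_rows.to_numpy(dtype=float)
    covariate_rows = np.asarray(covariate_rows, dtype=float)
    if covariate_rows.ndim != 2:
        raise InvalidParameterError("covariate_rows must be a 2-D table")
    n = covariate_rows.shape[0]
    if design_cov is not None:
        rm = resolve(design_cov, trait, design)
        eta = rm.eta(covariate_rows)
    else:
        if trait.beta0 is None:
            raise UnresolvedModelError(
                "expand_rd without a covariate design requires a resolved beta0"
            )
        slopes = np.concatenate([[trait.beta_G], np.asarray(trait.beta_E)])
        eta = effective_intercept(trait, design) + covariate_rows @ slopes
    delta1 = expit(eta)
    x = np.column_stack([np.ones(n), covariate_rows])
    return RepresentativeDataset(
        x=np.vstack([x, x]),
        y=np.concatenate([np.zeros(n), np.ones(n)]),
        weight=np.concatenate([1.0 - delta1, delta1]),
        n=n,
    )


def power_rd(
    design_cov: CovariateDesign,
    trait: TraitModel,
    design: StudyDesign,
    n: int,
    alpha: float = 0.05,
) -> PowerResult:
    """Unconditional power at sample size n from the representative dataset.

    The weighted information of the expanded dataset at the true coefficients
    is ``sum_i w(eta_i) x_i x_i^T`` (the outcome weights sum to one within a
    pair), whose inverse (G, G) element is ``V_Gn``.  Fully deterministic.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidParameterError(f"alpha must lie in (0, 1), got {alpha}")
    rm = resolve(design_cov, trait, design)
    n_params = 2 + rm.design_cov.n_covariates
    if n < n_params:
        raise InvalidParameterError(
            f"n must be at least the number of model parameters ({n_params})"
        )
    rows = build_representative_covariates(design_cov, trait, design, n)
    x = np.column_stack([np.ones(len(rows)), rows])
    w = _core.logistic_weight(rm.eta(rows))
    info = (x * w[:, None]).T @ x
    v_g = _core.solve_variance(info)
    return PowerResult(
        power=_core.power_from_variance(rm.beta_G, v_g, alpha),
        v_G=v_g,
        n=int(n),
        alpha=alpha,
        method="RD",
        resolved_params=rm.params_dict(),
    )


def sample_size_rd(
    design_cov: CovariateDesign,
    trait: TraitModel,
    design: StudyDesign,
    target_power: float = 0.8,
    alpha: float = 0.05,
    n_max: int = 10_000_000,
) -> int:
    """Smallest n whose representative-dataset power reaches ``target_power``.

    Each candidate n rebuilds its representative dataset (the construction
    depends on n), so the search uses doubling plus integer bisection and a
    final local sweep to absorb the O(1/n) rounding jitter of the counts.
    """
    if not (alpha < target_power < 1.0):
        raise InvalidParameterError(
            f"target_power must lie in (alpha, 1), got {target_power}"
        )
    rm = resolve(design_cov, trait, design)
    if rm.beta_G == 0.0:
        raise InvalidParameterError(
            "beta_G is 0: no finite sample size attains the target power"
        )
    n_lo = 2 + rm.design_cov.n_covariates

    def power_at(n: int) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return power_rd(design_cov, trait, design, n, alpha=alpha).power

    lo, hi = n_lo, max(2 * n_lo, 64)
    while power_at(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise InvalidParameterError(
                f"target power {target_power} not reached below n_max={n_max}"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    while hi > n_lo and power_at(hi - 1) >= target_power:
        hi -= 1
    while power_at(hi) < target_power:
        hi += 1
    return hi
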
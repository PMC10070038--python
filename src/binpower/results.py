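"""Result containers shared across the power-computation methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True, eq=False)
class UnitInformation:
    """Estimated unit (per-observation) Fisher information I_1(beta).

    ``matrix`` is symmetric (K+2)x(K+2) with column order (1, G, E...); the
    information of a sample of size n is ``n * matrix``.
    """

    matrix: np.ndarray
    b_used: int
    seed: object = None


@dataclass(frozen=True)
class PowerResult:
    """Computed power together with the quantities behind it.

    ``v_G`` is the variance of the genotype coefficient estimate at the
    stated sample size ``n``; ``method`` tags how the information was
    obtained ("SS", "RD" or "empirical"); ``resolved_params`` echoes every
    gleaned parameter so the computation is reproducible from the result.
    """

    power: float
    v_G: float
    n: int
    alpha: float
    method: str
    resolved_params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EmpiricalPowerResult:
    """Empirical rejection rate from full simulation, with its binomial SE."""

    power: float
    se: float
    n: int
    alpha: float
    replicates: int
    n_failed: int = 0
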
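"""Configuration parsing and validation for the command-line interface.

A run configuration is a plain mapping (YAML, TOML or JSON on disk) with the
keys::

    genotype:   {maf, coding}
    covariates: [{kind, gamma_G, exposure_rate | mean+sd | conditional_sd,
                  beta_E | odds_ratio_E}]
    trait:      {beta_G | odds_ratio_G, prevalence, beta0 (optional)}
    design:     {mode, case_control_ratio | case_fraction}

plus run-level keys ``method`` (ss/rd/empirical), ``alpha``, exactly one of
``n``/``target_power``, ``b``, ``replicates`` and ``seed``.  Odds ratios are
converted to log-odds; every violated invariant raises a named
:class:`ConfigError`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .covariate_space import CovariateDesign, CovariateSpec, GenotypeModel
from .exceptions import BinpowerError
from .trait_model import StudyDesign, TraitModel

DEFAULT_ALPHA = 0.05
DEFAULT_TARGET_POWER = 0.8
DEFAULT_B = 10_000
DEFAULT_REPLICATES = 1000
METHODS = ("ss", "rd", "empirical")


class ConfigError(BinpowerError, ValueError):
    """A configuration document violates the schema."""


@dataclass(frozen=True)
class RunConfig:
    """Validated, normalized run configuration."""

    design_cov: CovariateDesign
    trait: TraitModel
    design: StudyDesign
    method: str = "ss"
    alpha: float = DEFAULT_ALPHA
    n: int | None = None
    target_power: float | None = None
    b: int = DEFAULT_B
    replicates: int = DEFAULT_REPLICATES
    seed: int | None = None


def load_config(path: str | Path) -> dict:
    """Read a YAML/TOML/JSON config file into a mapping."""
    path = Path(path)
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    if suffix == ".toml":
        import tomllib

        return tomllib.loads(text)
    if suffix == ".json":
        return json.loads(text)
    raise ConfigError(f"unsupported config format {suffix!r} for {path}")


def _log_of(section: dict, beta_key: str, or_key: str, context: str):
    has_beta = beta_key in section
    has_or = or_key in section
    if has_beta and has_or:
        raise ConfigError(f"{context}: give either {beta_key} or {or_key}, not both")
    if has_beta:
        return float(section[beta_key])
    if has_or:
        value = float(section[or_key])
        if value <= 0:
            raise ConfigError(f"{context}: {or_key} must be positive")
        return float(np.log(value))
    return None


def _parse_case_fraction(section: dict) -> float:
    if "case_fraction" in section and "case_control_ratio" in section:
        raise ConfigError(
            "design: give either case_fraction or case_control_ratio, not both"
        )
    if "case_fraction" in section:
        return float(section["case_fraction"])
    ratio = section.get("case_control_ratio", "1:1")
    if isinstance(ratio, str):
        try:
            cases, controls = (float(part) for part in ratio.split(":"))
        except ValueError as exc:
            raise ConfigError(
                f"design: case_control_ratio must look like '1:1', got {ratio!r}"
            ) from exc
        return cases / (cases + controls)
    return float(ratio)


def validate_config(raw: dict) -> RunConfig:
    """Normalize and validate a raw configuration mapping.

    Fills defaults (alpha 0.05, b 10 000, replicates 1000), converts odds
    ratios to the log scale, and runs the model feasibility checks by
    constructing the domain objects.
    """
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    try:
        geno_raw = raw.get("genotype")
        if not geno_raw or "maf" not in geno_raw:
            raise ConfigError("genotype: section with a maf key is required")
        genotype = GenotypeModel(
            maf=float(geno_raw["maf"]),
            coding=geno_raw.get("coding", "additive"),
        )
        covariates = []
        for i, cov in enumerate(raw.get("covariates", []) or []):
            label = f"covariates[{i}]"
            if "kind" not in cov:
                raise ConfigError(f"{label}: kind is required")
            covariates.append(
                CovariateSpec(
                    kind=cov["kind"],
                    gamma_G=float(cov.get("gamma_G", 0.0)),
                    beta_E=_log_of(cov, "beta_E", "odds_ratio_E", label),
                    exposure_rate=(
                        float(cov["exposure_rate"])
                        if "exposure_rate" in cov
                        else None
                    ),
                    mean=float(cov["mean"]) if "mean" in cov else None,
                    sd=float(cov["sd"]) if "sd" in cov else None,
                    conditional_sd=(
                        float(cov["conditional_sd"])
                        if "conditional_sd" in cov
                        else None
                    ),
                )
            )
        design_cov = CovariateDesign(
            genotype=genotype, covariates=tuple(covariates)
        ).resolve()

        trait_raw = raw.get("trait")
        if not trait_raw:
            raise ConfigError("trait: section is required")
        beta_G = _log_of(trait_raw, "beta_G", "odds_ratio_G", "trait")
        if beta_G is None:
            raise ConfigError("trait: beta_G or odds_ratio_G is required")
        trait = TraitModel(
            beta_G=beta_G,
            prevalence=(
                float(trait_raw["prevalence"])
                if "prevalence" in trait_raw
                else None
            ),
            beta0=float(trait_raw["beta0"]) if "beta0" in trait_raw else None,
        )

        design_raw = raw.get("design", {}) or {}
        design = StudyDesign(
            mode=design_raw.get("mode", "prospective"),
            case_fraction=_parse_case_fraction(design_raw),
        )
    except ConfigError:
        raise
    except BinpowerError as exc:
        raise ConfigError(str(exc)) from exc

    method = raw.get("method", "ss")
    if method not in METHODS:
        raise ConfigError(f"method must be one of {METHODS}, got {method!r}")
    n = raw.get("n")
    target_power = raw.get("target_power")
    if n is not None and target_power is not None:
        raise ConfigError("give exactly one of the keys n and target_power, not both")
    alpha = float(raw.get("alpha", DEFAULT_ALPHA))
    if not (0.0 < alpha < 1.0):
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    return RunConfig(
        design_cov=design_cov,
        trait=trait,
        design=design,
        method=method,
        alpha=alpha,
        n=int(n) if n is not None else None,
        target_power=float(target_power) if target_power is not None else None,
        b=int(raw.get("b", DEFAULT_B)),
        replicates=int(raw.get("replicates", DEFAULT_REPLICATES)),
        seed=raw.get("seed"),
    )


def run(config: RunConfig) -> dict:
    """Execute a validated configuration and return a self-contained report.

    Dispatches on ``method`` and on whether ``n`` or ``target_power`` was
    supplied; the report echoes every gleaned parameter and the seed, so a
    run can be reproduced exactly from its own output.
    """
    from .power_rd import power_rd, sample_size_rd
    from .power_ss import power_ss, sample_size_ss
    from .oracle import empirical_power
    from .trait_model import resolve

    rm = resolve(config.design_cov, config.trait, config.design)
    report: dict = {
        "method": config.method,
        "alpha": config.alpha,
        "seed": config.seed,
        "resolved_params": rm.params_dict(),
    }
    if config.n is None and config.target_power is None:
        raise ConfigError("one of n or target_power is required to run")
    if config.target_power is not None:
        if config.method == "ss":
            n_star = sample_size_ss(
                config.design_cov,
                config.trait,
                config.design,
                target_power=config.target_power,
                alpha=config.alpha,
                b=config.b,
                seed=config.seed,
            )
        elif config.method == "rd":
            n_star = sample_size_rd(
                config.design_cov,
                config.trait,
                config.design,
                target_power=config.target_power,
                alpha=config.alpha,
            )
        else:
            raise ConfigError(
                "sample-size search is available for methods 'ss' and 'rd' only"
            )
        report.update({"target_power": config.target_power, "sample_size": n_star})
        return report
    if config.method == "ss":
        res = power_ss(
            config.design_cov,
            config.trait,
            config.design,
            config.n,
            alpha=config.alpha,
            b=config.b,
            seed=config.seed,
        )
        report.update({"n": res.n, "power": res.power, "v_G": res.v_G, "b": config.b})
    elif config.method == "rd":
        res = power_rd(
            config.design_cov,
            config.trait,
            config.design,
            config.n,
            alpha=config.alpha,
        )
        report.update({"n": res.n, "power": res.power, "v_G": res.v_G})
    else:
        emp = empirical_power(
            config.design_cov,
            config.trait,
            config.design,
            config.n,
            alpha=config.alpha,
            replicates=config.replicates,
            seed=config.seed,
        )
        report.update(
            {
                "n": emp.n,
                "power": emp.power,
                "se": emp.se,
                "replicates": emp.replicates,
                "failed_replicates": emp.n_failed,
            }
        )
    return report
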
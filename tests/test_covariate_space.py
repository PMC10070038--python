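"""Covariate-space construction: HWE models, second-stage gleaning, sampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

import binpower as bp
from binpower.exceptions import (
    InfeasibleModelError,
    InvalidParameterError,
    UnresolvedModelError,
)


@pytest.mark.parametrize(
    "maf, coding, expected",
    [
        (0.1, "additive", {0.0: 0.81, 1.0: 0.18, 2.0: 0.01}),
        (0.5, "additive", {0.0: 0.25, 1.0: 0.50, 2.0: 0.25}),
        (0.1, "dominant", {0.0: 0.81, 1.0: 0.19}),
        (0.1, "recessive", {0.0: 0.99, 1.0: 0.01}),
    ],
)
def test_hwe_probs_match_hardy_weinberg_arithmetic(maf, coding, expected):
    probs = bp.hwe_probs(bp.GenotypeModel(maf=maf, coding=coding))
    assert set(probs) == set(expected)
    for g, p in expected.items():
        assert probs[g] == pytest.approx(p, abs=1e-12)


@pytest.mark.parametrize("bad_maf", [0.0, -0.1, 0.6, 1.0])
def test_maf_outside_range_rejected(bad_maf):
    with pytest.raises(InvalidParameterError):
        bp.GenotypeModel(maf=bad_maf)


def test_unknown_coding_rejected():
    with pytest.raises(InvalidParameterError):
        bp.GenotypeModel(maf=0.1, coding="codominant")


@pytest.mark.parametrize(
    "maf, coding, mean, var",
    [
        (0.1, "dominant", 0.19, 0.19 * 0.81),
        (0.1, "additive", 0.2, 2 * 0.1 * 0.9),
        (0.5, "additive", 1.0, 0.5),
    ],
)
def test_genotype_moments_closed_forms(maf, coding, mean, var):
    m, v = bp.genotype_moments(bp.GenotypeModel(maf=maf, coding=coding))
    assert m == pytest.approx(mean, abs=1e-12)
    assert v == pytest.approx(var, abs=1e-12)


@given(maf=st.floats(1e-4, 0.5), coding=st.sampled_from(["additive", "dominant", "recessive"]))
def test_hwe_probabilities_sum_to_one(maf, coding):
    probs = bp.GenotypeModel(maf=maf, coding=coding).probabilities()
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    assert (probs >= 0).all()


class TestResolveStage2:
    def test_binary_without_g_dependence_is_logit_of_rate(self):
        spec = bp.CovariateSpec(kind="binary", gamma_G=0.0, exposure_rate=0.3)
        res = bp.resolve_stage2(spec, bp.GenotypeModel(0.1, "dominant"))
        assert res.gamma0 == pytest.approx(np.log(0.3 / 0.7), abs=1e-10)

    def test_binary_gleaning_matches_bisection_oracle(self):
        model = bp.GenotypeModel(0.1, "dominant")
        spec = bp.CovariateSpec(
            kind="binary", gamma_G=np.log(0.2), exposure_rate=0.3
        )

        def marginal(c):  # independent of the implementation's root finder
            return 0.81 * expit(c) + 0.19 * expit(c + np.log(0.2))

        lo, hi = -50.0, 50.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if marginal(mid) < 0.3:
                lo = mid
            else:
                hi = mid
        res = bp.resolve_stage2(spec, model)
        assert res.gamma0 == pytest.approx((lo + hi) / 2, abs=1e-9)
        assert marginal(res.gamma0) == pytest.approx(0.3, abs=1e-10)

    def test_continuous_with_conditional_sd_closed_form(self):
        model = bp.GenotypeModel(0.1, "dominant")
        spec = bp.CovariateSpec(
            kind="continuous", gamma_G=np.log(0.5), mean=0.0, conditional_sd=1.0
        )
        res = bp.resolve_stage2(spec, model)
        assert res.gamma0 == pytest.approx(-np.log(0.5) * 0.19, abs=1e-12)
        assert res.sigma_cond == 1.0

    def test_continuous_marginal_sd_decomposed_by_total_variance(self):
        model = bp.GenotypeModel(0.3, "additive")
        spec = bp.CovariateSpec(
            kind="continuous", gamma_G=0.8, mean=1.5, sd=2.0
        )
        res = bp.resolve_stage2(spec, model)
        _, g_var = bp.genotype_moments(model)
        assert res.sigma_cond**2 + 0.8**2 * g_var == pytest.approx(4.0, abs=1e-12)
        g_mean, _ = bp.genotype_moments(model)
        assert res.gamma0 + 0.8 * g_mean == pytest.approx(1.5, abs=1e-12)

    def test_infeasible_continuous_marginal_raises(self):
        model = bp.GenotypeModel(0.5, "additive")  # Var(G) = 0.5
        spec = bp.CovariateSpec(
            kind="continuous", gamma_G=3.0, mean=0.0, sd=1.0
        )
        with pytest.raises(InfeasibleModelError, match="gamma_G"):
            bp.resolve_stage2(spec, model)

    def test_over_specified_continuous_marginal_rejected(self):
        with pytest.raises(InvalidParameterError, match="over-specified"):
            bp.CovariateSpec(
                kind="continuous", gamma_G=0.5, mean=0.0, sd=1.0, conditional_sd=1.0
            )


@given(
    maf=st.floats(0.02, 0.5),
    coding=st.sampled_from(["additive", "dominant", "recessive"]),
    gamma_G=st.floats(-3.0, 3.0),
    rate=st.floats(0.05, 0.95),
)
def test_resolved_binary_marginal_reproduced(maf, coding, gamma_G, rate):
    model = bp.GenotypeModel(maf, coding)
    res = bp.resolve_stage2(
        bp.CovariateSpec(kind="binary", gamma_G=gamma_G, exposure_rate=rate), model
    )
    g = model.support()
    p = model.probabilities()
    implied = float(p @ expit(res.gamma0 + gamma_G * g))
    assert implied == pytest.approx(rate, abs=1e-10)


@given(
    maf=st.floats(0.02, 0.5),
    gamma_G=st.floats(-1.0, 1.0),
    sd=st.floats(1.5, 4.0),
    mean=st.floats(-2.0, 2.0),
)
def test_resolved_continuous_total_variance_reconstruction(maf, gamma_G, sd, mean):
    model = bp.GenotypeModel(maf, "additive")
    res = bp.resolve_stage2(
        bp.CovariateSpec(kind="continuous", gamma_G=gamma_G, mean=mean, sd=sd), model
    )
    g_mean, g_var = bp.genotype_moments(model)
    assert res.sigma_cond**2 + gamma_G**2 * g_var == pytest.approx(sd**2, abs=1e-12)
    assert res.gamma0 + gamma_G * g_mean == pytest.approx(mean, abs=1e-12)


class TestSampleCovariates:
    def test_genotype_frequencies_match_hwe(self):
        design = bp.CovariateDesign(genotype=bp.GenotypeModel(0.1, "additive"))
        table = bp.sample_covariates(design, 100_000, seed=11)
        freqs = table["G"].value_counts(normalize=True)
        assert freqs[0.0] == pytest.approx(0.81, abs=0.01)
        assert freqs[1.0] == pytest.approx(0.18, abs=0.01)
        assert freqs[2.0] == pytest.approx(0.01, abs=0.01)

    def test_binary_covariate_marginal_rate_recovered(self, s2):
        design_cov, _, _ = s2
        table = bp.sample_covariates(design_cov.resolve(), 100_000, seed=12)
        assert table["E1"].mean() == pytest.approx(0.3, abs=0.01)

    def test_same_seed_identical_tables(self, s3):
        design_cov, _, _ = s3
        design_cov = design_cov.resolve()
        a = bp.sample_covariates(design_cov, 1000, seed=7)
        b = bp.sample_covariates(design_cov, 1000, seed=7)
        assert a.equals(b)

    def test_unresolved_design_raises(self):
        design = bp.CovariateDesign(
            genotype=bp.GenotypeModel(0.1, "dominant"),
            covariates=(
                bp.CovariateSpec(kind="binary", gamma_G=1.0, exposure_rate=0.4),
            ),
        )
        with pytest.raises(UnresolvedModelError):
            bp.sample_covariates(design, 10, seed=0)

    def test_zero_gamma_means_independence_of_g(self):
        design = bp.CovariateDesign(
            genotype=bp.GenotypeModel(0.3, "additive"),
            covariates=(
                bp.CovariateSpec(
                    kind="continuous", gamma_G=0.0, mean=0.0, sd=1.0
                ),
            ),
        ).resolve()
        table = bp.sample_covariates(design, 200_000, seed=13)
        corr = np.corrcoef(table["G"], table["E1"])[0, 1]
        assert abs(corr) < 0.01
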
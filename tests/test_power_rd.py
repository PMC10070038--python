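"""Representative-dataset power: counts, quantile scores, expansion, inversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import norm

import binpower as bp


class TestRepresentativeCounts:
    def test_exact_multiples_without_rounding(self):
        design_cov = bp.CovariateDesign(genotype=bp.GenotypeModel(0.5, "additive"))
        trait = bp.TraitModel(beta_G=0.2, prevalence=0.2)
        counts = bp.representative_counts(
            design_cov, trait, bp.StudyDesign("prospective"), 100
        )
        assert counts == {(0.0,): 25, (1.0,): 50, (2.0,): 25}

    def test_s2_counts_match_largest_remainder_oracle(self, s2):
        design_cov, trait, design = s2
        dc = design_cov.resolve()
        g0, gG = dc.covariates[0].gamma0, dc.covariates[0].gamma_G
        probs = {}
        for g, pg in ((0.0, 0.81), (1.0, 0.19)):
            pe = expit(g0 + gG * g)
            probs[(g, 0.0)] = pg * (1 - pe)
            probs[(g, 1.0)] = pg * pe
        n = 100
        cells = list(probs)
        target = np.array([n * probs[c] for c in cells])
        base = np.floor(target).astype(int)
        frac = target - base
        for idx in np.argsort(-frac)[: n - base.sum()]:
            base[idx] += 1
        oracle = dict(zip(cells, base.tolist()))
        counts = bp.representative_counts(design_cov, trait, design, n)
        assert counts == oracle
        assert sum(counts.values()) == n

    @pytest.mark.filterwarnings("ignore::UserWarning")  # tiny cells may round to 0
    @given(
        maf=st.floats(0.05, 0.5),
        rate=st.floats(0.1, 0.9),
        gamma_G=st.floats(-2.0, 2.0),
        n=st.integers(10, 5000),
    )
    def test_counts_always_sum_to_n(self, maf, rate, gamma_G, n):
        design_cov = bp.CovariateDesign(
            genotype=bp.GenotypeModel(maf, "additive"),
            covariates=(
                bp.CovariateSpec(
                    kind="binary", gamma_G=gamma_G, exposure_rate=rate, beta_E=0.5
                ),
            ),
        )
        trait = bp.TraitModel(beta_G=0.3, prevalence=0.2)
        counts = bp.representative_counts(
            design_cov, trait, bp.StudyDesign("prospective"), n
        )
        assert sum(counts.values()) == n


class TestContinuousScores:
    def test_single_observation_sits_at_the_conditional_mean(self):
        vals = bp.representative_continuous_values(0.3, 0.7, 2.0, 1.0, 1)
        assert vals == pytest.approx([0.3 + 0.7], abs=1e-12)

    def test_first_of_five_standard_scores(self):
        vals = bp.representative_continuous_values(0.0, 0.0, 1.0, 0.0, 5)
        assert vals[0] == pytest.approx(norm.ppf(0.625 / 5.25), abs=1e-9)
        assert vals[0] == pytest.approx(-1.1798, abs=1e-4)

    @pytest.mark.parametrize("n_i", [2, 5, 40, 101])
    def test_scores_symmetric_about_conditional_mean(self, n_i):
        center = 0.4 + 1.2 * 2.0
        vals = bp.representative_continuous_values(0.4, 1.2, 1.5, 2.0, n_i)
        assert np.allclose(vals + vals[::-1], 2 * center, atol=1e-10)


class TestExpandRD:
    def test_weights_pair_to_one_and_rows_double(self, s2):
        design_cov, trait, design = s2
        rows = bp.build_representative_covariates(design_cov, trait, design, 500)
        rd = bp.expand_rd(rows, trait, design, design_cov=design_cov)
        assert rd.x.shape[0] == 1000
        assert rd.weight.sum() == pytest.approx(500, abs=1e-9)
        assert np.allclose(rd.weight[:500] + rd.weight[500:], 1.0, atol=1e-12)
        assert ((rd.weight >= 0) & (rd.weight <= 1)).all()

    def test_zero_linear_predictor_splits_evenly(self):
        trait = bp.TraitModel(beta_G=0.0, beta0=0.0)
        rd = bp.expand_rd(
            np.array([[1.0], [0.0]]), trait, bp.StudyDesign("prospective")
        )
        assert np.allclose(rd.weight, 0.5)

    def test_weighted_mle_at_true_beta_matches_irls_fit(self, s2):
        # the RD weights make the weighted score vanish at the true beta, so a
        # weighted GLM fit must recover it; statsmodels is the reference
        import statsmodels.api as sm

        design_cov, trait, design = s2
        rm = bp.resolve(design_cov, trait, design)
        rows = bp.build_representative_covariates(design_cov, trait, design, 2000)
        rd = bp.expand_rd(rows, trait, design, design_cov=design_cov)
        fit = sm.GLM(
            rd.y, rd.x, family=sm.families.Binomial(), freq_weights=rd.weight
        ).fit()
        truth = np.concatenate([[rm.beta0_eff], rm.slopes()])
        assert np.allclose(fit.params, truth, atol=1e-6)


class TestPowerRD:
    def test_power_equals_alpha_under_the_null(self, s3):
        design_cov, _, design = s3
        trait = bp.TraitModel(beta_G=0.0, beta_E=(np.log(2.5),), prevalence=0.2)
        res = bp.power_rd(design_cov, trait, design, 4000)
        assert res.power == pytest.approx(0.05, abs=1e-12)

    def test_repeated_calls_bit_identical(self, s3):
        a = bp.power_rd(*bp.scenario("S3"), n=3000)
        b = bp.power_rd(*bp.scenario("S3"), n=3000)
        assert a.power == b.power and a.v_G == b.v_G

    def test_converges_to_enumerated_power_for_discrete_designs(self, s2):
        design_cov, trait, design = s2
        exact = bp.enumerated_power(design_cov, trait, design, 20_000)
        approx = bp.power_rd(design_cov, trait, design, 20_000).power
        assert approx == pytest.approx(exact, abs=0.003)

    def test_agrees_with_semi_simulation_across_scenarios(self):
        for sid in bp.SCENARIO_IDS:
            design_cov, trait, design = bp.scenario(sid)
            for n in (1000, 5000):
                p_rd = bp.power_rd(design_cov, trait, design, n).power
                p_ss = bp.power_ss(
                    design_cov, trait, design, n, b=1_000_000, seed=21
                ).power
                assert p_rd == pytest.approx(p_ss, abs=0.005), (sid, n)

    def test_runtime_grows_with_n(self, s3):
        import time

        design_cov, trait, design = s3

        def timed(n):
            times = []
            for _ in range(3):
                t0 = time.perf_counter()
                bp.power_rd(design_cov, trait, design, n)
                times.append(time.perf_counter() - t0)
            return np.median(times)

        assert timed(500_000) > timed(2000)


class TestSampleSizeRD:
    def test_round_trip_brackets_target_power(self, s2):
        design_cov, trait, design = s2
        n_star = bp.sample_size_rd(design_cov, trait, design, target_power=0.8)
        assert bp.power_rd(design_cov, trait, design, n_star).power >= 0.8
        assert bp.power_rd(design_cov, trait, design, n_star - 1).power < 0.8

    def test_agrees_with_semi_simulation_size(self, s2):
        design_cov, trait, design = s2
        n_rd = bp.sample_size_rd(design_cov, trait, design, target_power=0.8)
        ui = bp.unit_information_ss(design_cov, trait, design, b=1_000_000, seed=22)
        n_ss = bp.sample_size_ss(
            design_cov, trait, design, target_power=0.8, unit_info=ui
        )
        assert abs(n_rd - n_ss) / n_ss < 0.02

    def test_monotone_in_effect_size(self, s1):
        design_cov, _, design = s1
        sizes = []
        for or_g in (1.2, 1.5, 2.0):
            trait = bp.TraitModel(beta_G=np.log(or_g), prevalence=0.2)
            sizes.append(
                bp.sample_size_rd(design_cov, trait, design, target_power=0.8)
            )
        assert sizes[0] > sizes[1] > sizes[2]
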
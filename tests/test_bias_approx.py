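import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gxebias.bias_approx import (
    approx_gamma_model1,
    approx_gamma_model2,
    invert_bias,
    make_bias_report,
    remarks_predicates,
)
from gxebias.pseudo_true import PseudoTrueProblem, pseudo_true_gamma
from gxebias.risk_models import (
    ContaminationSpec,
    GammaVector,
    RiskCoefficients,
)

from .conftest import draw_trinomial

beta = st.floats(-2.0, 2.0)
rate = st.floats(0.0, 0.49)


class TestModel1Examples:
    def test_no_contamination_identity_exact(self):
        B = RiskCoefficients(-1.3, 0.8, -0.6, 0.25)
        theo, lin = approx_gamma_model1(B, ContaminationSpec(0.0, 0.0), Z_effects=(0.3,))
        expected = np.array([-1.3, 0.8, -0.6, 0.25, 0.3])
        np.testing.assert_allclose(theo.as_array(), expected, rtol=0, atol=1e-12)
        np.testing.assert_allclose(lin.as_array(), expected, rtol=0, atol=1e-12)

    def test_linearized_gammaG_hand_value(self):
        # independent evaluation of the attenuation-weight formula
        expected = math.exp(-1.0) / (math.exp(-1.0) + 0.36) * (-0.41)
        _, lin = approx_gamma_model1(
            RiskCoefficients(-1.0, -0.41, 0.0, 0.0), ContaminationSpec(0.36, 0.06)
        )
        assert lin.gammaG == pytest.approx(expected, abs=1e-12)
        assert lin.gammaG == pytest.approx(-0.2072, abs=1e-4)

    def test_linearized_gamma0_hand_value(self):
        expected = math.log(1.36 / 0.64) + (1 / 1.36) * (-1.0)
        _, lin = approx_gamma_model1(
            RiskCoefficients(-1.0, 0.0, 0.0, 0.0), ContaminationSpec(0.36, 0.0)
        )
        assert lin.gamma0 == pytest.approx(expected, abs=1e-12)
        assert lin.gamma0 == pytest.approx(0.0185, abs=1e-4)

    def test_theoretical_is_log_odds_contrast(self):
        """Theoretical gammas are contrasts of log{(e^eta + S(x)) / (1 - S(x))}."""
        B = RiskCoefficients(-0.8, 0.5, 0.7, -0.3)
        S = ContaminationSpec(0.25, 0.1)
        theo, _ = approx_gamma_model1(B, S)

        def lo(g, x):
            eta = B.beta0 + B.betaG * g + B.betaX * x + B.betaGxX * g * x
            s = S.S1 if x else S.S0
            return math.log((math.exp(eta) + s) / (1 - s))

        assert theo.gamma0 == pytest.approx(lo(0, 0), abs=1e-12)
        assert theo.gammaG == pytest.approx(lo(1, 0) - lo(0, 0), abs=1e-12)
        assert theo.gammaX == pytest.approx(lo(0, 1) - lo(0, 0), abs=1e-12)
        assert theo.gammaGxX == pytest.approx(
            lo(1, 1) - lo(1, 0) - lo(0, 1) + lo(0, 0), abs=1e-12
        )

    def test_unphysical_rejected(self):
        with pytest.raises(ValueError):
            approx_gamma_model1(
                RiskCoefficients(-1, 0, 0, 0),
                ContaminationSpec(0.1, 0.1),
                Z_effects=(21.0,),
            )


class TestModel2Examples:
    def test_null_genotype_both_forms(self):
        theo, lin = approx_gamma_model2(
            RiskCoefficients(-1.0, 0.0, 1.3, 0.4), RiskCoefficients(-1.7, 0.0, 0.5, 0.2)
        )
        assert theo.gammaG == pytest.approx(0.0, abs=1e-14)
        assert lin.gammaG == 0.0

    def test_setting_b_theoretical_gammaX(self):
        # independent log-sum contrast evaluation
        expected = math.log(math.exp(0.3) + math.exp(-1.2)) - math.log(
            math.exp(-1.0) + math.exp(-1.7)
        )
        theo, _ = approx_gamma_model2(
            RiskCoefficients(-1.0, -0.69, 1.3, 1.099),
            RiskCoefficients(-1.7, 0.0, 0.5, 0.0),
        )
        assert theo.gammaX == pytest.approx(expected, abs=1e-12)
        assert theo.gammaX == pytest.approx(1.098, abs=1e-3)

    def test_setting_b_linearized_gammaG(self):
        expected = math.exp(-1.0) / (math.exp(-1.0) + math.exp(-1.7)) * (-0.69)
        _, lin = approx_gamma_model2(
            RiskCoefficients(-1.0, -0.69, 1.3, 1.099),
            RiskCoefficients(-1.7, 0.0, 0.5, 0.0),
        )
        assert lin.gammaG == pytest.approx(expected, abs=1e-12)
        assert lin.gammaG == pytest.approx(-0.461, abs=1e-3)

    def test_shared_z_effects_pass_through(self):
        """With identical Z effects in both states, gammaZ equals betaZ exactly."""
        theo, _ = approx_gamma_model2(
            RiskCoefficients(-1.0, 0.3, 0.5, 0.1),
            RiskCoefficients(-1.7, -0.2, 0.4, 0.0),
            Z_effects=(0.10, -0.083),
        )
        assert theo.gammaZ[0] == pytest.approx(0.10, abs=1e-12)
        assert theo.gammaZ[1] == pytest.approx(-0.083, abs=1e-12)


class TestRemarkProperties:
    @given(b0=beta, bx=beta, bgx=beta, s0=rate, s1=rate)
    def test_m1_null_G_preserved(self, b0, bx, bgx, s0, s1):
        _, lin = approx_gamma_model1(
            RiskCoefficients(b0, 0.0, bx, bgx), ContaminationSpec(s0, s1)
        )
        assert lin.gammaG == 0.0

    @given(b0=beta, bx=beta, s0=rate, s1=rate)
    def test_m1_null_G_and_GxX_preserved(self, b0, bx, s0, s1):
        _, lin = approx_gamma_model1(
            RiskCoefficients(b0, 0.0, bx, 0.0), ContaminationSpec(s0, s1)
        )
        assert lin.gammaG == 0.0
        assert abs(lin.gammaGxX) <= 1e-12

    @given(b0=beta, bg=beta, bgx=beta, s=rate)
    def test_m1_nondifferential_null_X(self, b0, bg, bgx, s):
        _, lin = approx_gamma_model1(
            RiskCoefficients(b0, bg, 0.0, bgx), ContaminationSpec(s, s)
        )
        assert abs(lin.gammaX) <= 1e-12

    @given(s=rate)
    def test_m1_nondifferential_all_null_GxX(self, s):
        _, lin = approx_gamma_model1(
            RiskCoefficients(0.0, 0.0, 0.0, 0.0), ContaminationSpec(s, s)
        )
        assert abs(lin.gammaGxX) <= 1e-12

    @given(b0=beta, b0s=beta, bx=beta, bxs=beta, bgx=beta, bgxs=beta)
    def test_m2_null_G(self, b0, b0s, bx, bxs, bgx, bgxs):
        theo, lin = approx_gamma_model2(
            RiskCoefficients(b0, 0.0, bx, bgx), RiskCoefficients(b0s, 0.0, bxs, bgxs)
        )
        assert lin.gammaG == 0.0
        assert abs(theo.gammaG) <= 1e-12

    @given(b0=beta, b0s=beta, bg=beta, bgs=beta)
    def test_m2_null_X(self, b0, b0s, bg, bgs):
        theo, lin = approx_gamma_model2(
            RiskCoefficients(b0, bg, 0.0, 0.0), RiskCoefficients(b0s, bgs, 0.0, 0.0)
        )
        assert lin.gammaX == 0.0
        assert abs(theo.gammaX) <= 1e-12

    @given(b0=beta, b0s=beta)
    def test_m2_all_null_GxX(self, b0, b0s):
        _, lin = approx_gamma_model2(
            RiskCoefficients(b0, 0.0, 0.0, 0.0), RiskCoefficients(b0s, 0.0, 0.0, 0.0)
        )
        assert abs(lin.gammaGxX) <= 1e-12


class TestRemarksPredicates:
    def test_m1_null_G_example(self):
        results = remarks_predicates(
            "model1",
            RiskCoefficients(-1.0, 0.0, 0.7, 0.3),
            ContaminationSpec(0.3, 0.1),
        )
        by_id = {r.remark_id: r for r in results}
        r = by_id["m1_null_G_preserved"]
        assert r.applicable and r.holds

    def test_m1_nondifferential_null_X_example(self):
        results = remarks_predicates(
            "model1",
            RiskCoefficients(-1.0, 0.5, 0.0, 0.3),
            ContaminationSpec(0.2, 0.2),
        )
        by_id = {r.remark_id: r for r in results}
        assert by_id["m1_nondifferential_null_X_preserved"].holds

    def test_m1_differential_null_X_flagged(self):
        """betaX = 0 with differential contamination leaves gammaX nonzero."""
        results = remarks_predicates(
            "model1",
            RiskCoefficients(-1.0, 0.5, 0.0, 0.7),
            ContaminationSpec(0.36, 0.06),
        )
        by_id = {r.remark_id: r for r in results}
        caution = by_id["m1_null_X_not_preserved"]
        assert caution.kind == "caution"
        assert caution.applicable and caution.holds

    def test_m2_log_form_intercept_discrepancy_recorded(self):
        """At beta0 = beta0* = 0 the linearized intercept is 0 but the log form is log 2."""
        results = remarks_predicates(
            "model2",
            RiskCoefficients(0.0, 0.3, 0.2, 0.1),
            RiskCoefficients(0.0, 0.1, 0.4, 0.0),
        )
        by_id = {r.remark_id: r for r in results}
        r = by_id["m2_null_intercepts_preserved"]
        assert r.applicable and r.holds
        assert f"{math.log(2):.6g}"[:6] in r.detail

    def test_wrong_assumption_type(self):
        with pytest.raises(TypeError):
            remarks_predicates(
                "model1", RiskCoefficients(0, 0, 0, 0), RiskCoefficients(0, 0, 0, 0)
            )


class TestLinearizedTheoreticalConvergence:
    def test_model1_gammaG_difference_vanishes(self):
        S = ContaminationSpec(0.36, 0.06)
        diffs = []
        for k in range(1, 9):
            bg = 0.5**k
            theo, lin = approx_gamma_model1(RiskCoefficients(-1.0, bg, 0.8, 0.0), S)
            diffs.append(abs(lin.gammaG - theo.gammaG))
        assert all(a >= b for a, b in zip(diffs, diffs[1:]))
        assert diffs[-1] < 1e-5

    def test_model2_gammaGxX_difference_vanishes(self):
        B_star = RiskCoefficients(-1.7, 0.2, 0.5, -0.1)
        diffs = []
        for k in range(1, 9):
            bgx = 0.5**k
            theo, lin = approx_gamma_model2(
                RiskCoefficients(-1.0, 0.4, 1.3, bgx), B_star
            )
            diffs.append(abs(lin.gammaGxX - theo.gammaGxX))
        assert all(a >= b for a, b in zip(diffs, diffs[1:]))
        assert diffs[-1] < 1e-5


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(10))
    def test_model2_theoretical_matches_oracle_slopes(self, seed, no_z_cov):
        rng = np.random.default_rng(seed)
        model = draw_trinomial(rng)
        theo, _ = approx_gamma_model2(model.B, model.B_star)
        cf = rng.choice([0.25, 0.5, 0.75])
        oracle = pseudo_true_gamma(
            PseudoTrueProblem(model=model, cov=no_z_cov, case_fraction=cf)
        )
        np.testing.assert_allclose(
            oracle.main_slopes(), theo.main_slopes(), atol=1e-8
        )


class TestInvertBias:
    def test_identity_without_contamination(self):
        gamma_hat = GammaVector(-0.9, 0.4, 1.1, -0.3, provenance="mle")
        result = invert_bias(gamma_hat, ContaminationSpec(0.0, 0.0))
        assert np.allclose(result.corrected.as_array(), gamma_hat.as_array(), atol=1e-12)
        assert result.converged

    @pytest.mark.parametrize("seed", range(5))
    def test_model1_round_trip(self, seed):
        rng = np.random.default_rng(300 + seed)
        B = RiskCoefficients(*rng.uniform(-1.0, 1.0, size=4))
        S = ContaminationSpec(0.36, 0.06)
        _, lin = approx_gamma_model1(B, S)
        result = invert_bias(lin, S)
        np.testing.assert_allclose(
            result.corrected.as_array(), B.as_array(), atol=1e-6
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_model2_round_trip(self, seed):
        rng = np.random.default_rng(400 + seed)
        B = RiskCoefficients(*rng.uniform(-1.0, 1.0, size=4))
        B_star = RiskCoefficients(-1.7, 0.0, 0.5, 0.0)
        _, lin = approx_gamma_model2(B, B_star)
        result = invert_bias(lin, B_star)
        np.testing.assert_allclose(
            result.corrected.as_array(), B.as_array(), atol=1e-6
        )

    def test_round_trip_with_z(self):
        B = RiskCoefficients(-1.0, 0.5, 0.8, -0.4)
        S = ContaminationSpec(0.3, 0.1)
        _, lin = approx_gamma_model1(B, S, Z_effects=(0.2, -0.1))
        result = invert_bias(lin, S)
        np.testing.assert_allclose(
            result.corrected.as_array(),
            np.array([-1.0, 0.5, 0.8, -0.4, 0.2, -0.1]),
            atol=1e-6,
        )

    def test_non_convergence_raises(self):
        gamma_hat = GammaVector(1.5, -1.0, 2.0, 0.5)
        with pytest.raises(RuntimeError, match="did not converge"):
            invert_bias(gamma_hat, ContaminationSpec(0.45, 0.45), max_iter=1)

    def test_plugin_bias_reported(self):
        gamma_hat = GammaVector(-1.0, -0.41, 2.0, 0.0)
        result = invert_bias(gamma_hat, ContaminationSpec(0.36, 0.06))
        assert set(result.plugin_bias) == {"gamma0", "gammaG", "gammaX", "gammaGxX"}
        # plug-in bias for the genotype slope: (weight - 1) * gammaG_hat
        w = math.exp(-1.0) / (math.exp(-1.0) + 0.36)
        assert result.plugin_bias["gammaG"] == pytest.approx((w - 1) * -0.41, abs=1e-12)


class TestBiasReport:
    def test_bias_columns_are_exact_differences(self, setting_b_model):
        report = make_bias_report(setting_b_model)
        t = report.table
        np.testing.assert_array_equal(
            t["bias_theoretical"], t["gamma_theoretical"] - t["true_beta"]
        )
        np.testing.assert_array_equal(
            t["bias_linearized"], t["gamma_linearized"] - t["true_beta"]
        )
        assert list(t["coefficient"]) == [
            "gamma0",
            "gammaG",
            "gammaX",
            "gammaGxX",
            "gammaZ1",
            "gammaZ2",
        ]
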
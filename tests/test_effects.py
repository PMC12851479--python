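"""Back-transformation of effects, predictions, and log-ratio differences."""

import numpy as np
import pandas as pd
import pytest

from codalmm.data import OCCASION_COL, compute_olr, stack
from codalmm.effects import (
    CompositionalCoefficient,
    coefficient_table,
    compositional_coefficients,
    fitted_compositions,
    logratio_difference,
    perturbation_vs_neutral,
    predict_composition,
)
from codalmm.fit import fit_cmrlmm, fit_univariate_suite
from codalmm.simplex import close, neutral, olr_inv, perturb
from codalmm.simulate import PART_LABELS, alt_basis, loh_basis


class TestCompositionalCoefficients:
    def test_roles_and_closure_conventions(self, loh_fit):
        coefs = compositional_coefficients(loh_fit)
        by_term = {c.term: c for c in coefs}
        assert by_term["Intercept"].role == "baseline"
        assert by_term["Intercept"].composition.kappa == 1440.0
        for term, c in by_term.items():
            if term != "Intercept":
                assert c.role == "perturbation"
                assert c.composition.values.sum() == pytest.approx(1.0)

    def test_matches_direct_inverse_olr_of_blocks(self, loh_fit):
        B = loh_fit.beta_matrix()
        coefs = {c.term: c for c in compositional_coefficients(loh_fit)}
        z_t3 = B.loc["time[T.T3]", ["z1", "z2", "z3"]].to_numpy(dtype=float)
        expected = olr_inv(z_t3, loh_fit.spec.basis, 1.0)
        np.testing.assert_allclose(
            coefs["time[T.T3]"].composition.parts, expected.parts, rtol=1e-12
        )

    def test_table_layout(self, loh_fit):
        tab = coefficient_table(loh_fit)
        assert list(tab.columns[:3]) == ["term", "role", "closure"]
        assert set(PART_LABELS) <= set(tab.columns)
        parts = tab[list(PART_LABELS)].to_numpy()
        np.testing.assert_allclose(parts.sum(axis=1), tab["closure"], rtol=1e-9)


class TestPredictions:
    def test_reference_setting_equals_intercept_composition(self, loh_fit):
        pred = predict_composition(
            loh_fit, {"zBMI": 0.0, "income": "middle", OCCASION_COL: "T1"},
            average_covariates=False,
        )
        intercept = compositional_coefficients(loh_fit)[0].composition
        np.testing.assert_allclose(pred.values, intercept.values, rtol=1e-9)

    def test_predictions_sum_to_kappa_everywhere(self, loh_fit):
        for occ in ("T1", "T2", "T3", "T4", "T5"):
            for z in (-2.0, 0.0, 1.5):
                pred = predict_composition(loh_fit, {OCCASION_COL: occ, "zBMI": z})
                assert pred.values.sum() == pytest.approx(1440.0, abs=1e-9)

    def test_perturbation_consistency(self, loh_fit):
        # baseline ⊕ T3 coefficient = prediction at T3 (reference covariates)
        coefs = {c.term: c for c in compositional_coefficients(loh_fit)}
        base = coefs["Intercept"].composition.with_kappa(1.0)
        pred = predict_composition(
            loh_fit, {"zBMI": 0.0, "income": "middle", OCCASION_COL: "T3"},
            average_covariates=False,
        )
        combo = perturb(base, coefs["time[T.T3]"].composition)
        np.testing.assert_allclose(combo.parts, pred.parts, rtol=1e-9)

    def test_blup_prediction_needs_known_subject(self, loh_fit):
        with pytest.raises(ValueError, match="subject"):
            predict_composition(loh_fit, include_blups=True)
        with pytest.raises(KeyError):
            predict_composition(loh_fit, include_blups=True, subject="ghost")

    def test_unknown_occasion_rejected(self, loh_fit):
        with pytest.raises(ValueError, match="setting"):
            predict_composition(loh_fit, {OCCASION_COL: "T9"})


class TestBasisInvariance:
    def test_full_model_agrees_across_bases(self, loh_table, loh_spec):
        b1, b2 = loh_basis(), alt_basis()
        f1 = fit_cmrlmm(stack(compute_olr(loh_table, b1)), loh_spec)
        f2 = fit_cmrlmm(stack(compute_olr(loh_table, b2)), loh_spec.with_(basis=b2))
        t1 = coefficient_table(f1).set_index("term")[list(PART_LABELS)]
        t2 = coefficient_table(f2).set_index("term")[list(PART_LABELS)]
        np.testing.assert_allclose(t1.to_numpy(), t2.loc[t1.index].to_numpy(), atol=1e-6)
        F1 = fitted_compositions(f1, loh_table)[list(PART_LABELS)].to_numpy()
        F2 = fitted_compositions(f2, loh_table)[list(PART_LABELS)].to_numpy()
        assert np.abs(F1 - F2).max() < 1e-6

    def test_univariate_suite_depends_on_basis(self, loh_table, loh_spec):
        b1, b2 = loh_basis(), alt_basis()
        s1 = fit_univariate_suite(stack(compute_olr(loh_table, b1)), loh_spec)
        s2 = fit_univariate_suite(
            stack(compute_olr(loh_table, b2)), loh_spec.with_(basis=b2)
        )

        def suite_fitted(suite, basis):
            from codalmm.effects import predict_linear

            Z = np.column_stack(
                [predict_linear(f, loh_table, include_blups=True)[:, 0] for f in suite]
            )
            W = np.exp(Z @ basis.contrast.T)
            return 1440.0 * W / W.sum(axis=1, keepdims=True)

        diff = np.abs(suite_fitted(s1, b1) - suite_fitted(s2, b2)).max()
        assert diff > 1e-3  # minutes: clearly basis dependent


class TestLogratioDifference:
    def test_zero_for_identical_and_antisymmetric(self, rng):
        a = close(rng.lognormal(size=4), 1440.0, labels=PART_LABELS)
        b = close(rng.lognormal(size=4), 1.0, labels=PART_LABELS)
        np.testing.assert_allclose(logratio_difference(a, a), 0, atol=1e-12)
        np.testing.assert_allclose(
            logratio_difference(a, b), -logratio_difference(b, a), atol=1e-12
        )

    def test_components_sum_to_zero(self, rng):
        for _ in range(20):
            a = close(rng.lognormal(size=4), 1.0, labels=PART_LABELS)
            b = close(rng.lognormal(size=4), 1.0, labels=PART_LABELS)
            assert logratio_difference(a, b).sum() == pytest.approx(0, abs=1e-10)

    def test_closure_invariance(self, rng):
        raw = rng.lognormal(size=4)
        a1 = close(raw, 1.0, labels=PART_LABELS)
        a2 = close(raw, 1440.0, labels=PART_LABELS)
        b = close(rng.lognormal(size=4), 1.0, labels=PART_LABELS)
        np.testing.assert_allclose(
            logratio_difference(a1, b), logratio_difference(a2, b), atol=1e-12
        )


class TestPerturbationVsNeutral:
    def test_published_t3_directions(self):
        comp = olr_inv([0.09, 0.22, 0.21], loh_basis(), 1.0)
        coef = CompositionalCoefficient("T3", comp, "perturbation")
        tab = perturbation_vs_neutral(coef).set_index("part")
        assert tab.loc["MVPA", "deviation"] < 0       # time away from MVPA
        assert tab.loc["SB", "deviation"] > 0         # toward SB
        assert tab.loc["MVPA", "direction"] == "away"
        assert tab["deviation"].sum() == pytest.approx(0, abs=1e-12)

    def test_neutral_input_all_zero(self):
        coef = CompositionalCoefficient(
            "null", neutral(4, 1.0, labels=PART_LABELS), "perturbation"
        )
        tab = perturbation_vs_neutral(coef)
        np.testing.assert_allclose(tab["deviation"], 0, atol=1e-12)

    def test_baseline_role_rejected(self, loh_fit):
        intercept = compositional_coefficients(loh_fit)[0]
        with pytest.raises(ValueError, match="baseline"):
            perturbation_vs_neutral(intercept)
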
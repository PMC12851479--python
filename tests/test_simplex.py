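"""Aitchison-geometry primitives: closure, perturbation, powering, olr."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codalmm.simplex import (
    Composition,
    SbpSignMatrix,
    ZeroPartError,
    basis_from_sbp,
    change_of_basis,
    close,
    clr,
    inverse,
    neutral,
    olr,
    olr_inv,
    perturb,
    pivot_basis,
    power,
)
from codalmm.simulate import PART_LABELS, loh_basis, alt_basis

positive_parts = st.lists(
    st.floats(min_value=1e-3, max_value=1e3), min_size=4, max_size=4
)


def comp(parts, kappa=1.0):
    return close(parts, kappa, labels=PART_LABELS)


class TestClosure:
    @pytest.mark.parametrize(
        "raw, kappa, expected",
        [
            ([1, 1, 1, 1], 1.0, [0.25, 0.25, 0.25, 0.25]),
            ([8, 8, 4, 4], 1440.0, [480, 480, 240, 240]),  # hours -> minutes
        ],
    )
    def test_examples(self, raw, kappa, expected):
        c = close(raw, kappa)
        np.testing.assert_allclose(c.values, expected, rtol=1e-12)

    def test_round_trip_between_closure_constants(self):
        minutes = close([584, 483, 294, 79], 1.0).with_kappa(1440.0)
        np.testing.assert_allclose(minutes.values, [584, 483, 294, 79], rtol=1e-12)

    @pytest.mark.parametrize("bad", [[1, 0, 1, 1], [1, -2, 1, 1]])
    def test_zero_or_negative_parts_rejected(self, bad):
        with pytest.raises(ZeroPartError, match="x2"):
            close(bad, 1.0)

    def test_nonpositive_kappa_rejected(self):
        with pytest.raises(ValueError):
            close([1, 2, 3], 0.0)


class TestGroupOperations:
    @given(positive_parts)
    @settings(max_examples=50, deadline=None)
    def test_neutral_and_inverse_axioms(self, parts):
        x = comp(parts)
        e = neutral(4, 1.0, labels=PART_LABELS)
        assert perturb(x, e).isclose(x)
        assert perturb(x, inverse(x)).isclose(e)
        assert inverse(e).isclose(e)

    @given(positive_parts)
    @settings(max_examples=50, deadline=None)
    def test_power_special_cases(self, parts):
        x = comp(parts)
        assert power(1.0, x).isclose(x)
        assert power(0.0, x).isclose(neutral(4, 1.0, labels=PART_LABELS))

    @given(positive_parts, positive_parts)
    @settings(max_examples=50, deadline=None)
    def test_olr_linearity(self, pa, pb):
        basis = loh_basis()
        x, y = comp(pa), comp(pb)
        np.testing.assert_allclose(
            olr(perturb(x, y), basis), olr(x, basis) + olr(y, basis), atol=1e-10
        )
        np.testing.assert_allclose(
            olr(power(2.0, x), basis), 2.0 * olr(x, basis), atol=1e-10
        )

    def test_label_mismatch_rejected(self):
        x = close([1, 2, 3, 4], 1.0, labels=PART_LABELS)
        y = close([1, 2, 3, 4], 1.0, labels=["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="labels"):
            perturb(x, y)


class TestSbpBasis:
    def test_contrast_columns_from_sign_matrix(self):
        V = loh_basis().contrast
        np.testing.assert_allclose(
            V[:, 0],
            [np.sqrt(3 / 4), -np.sqrt(1 / 12), -np.sqrt(1 / 12), -np.sqrt(1 / 12)],
            atol=1e-12,
        )
        np.testing.assert_allclose(
            V[:, 2], [0, 0, np.sqrt(1 / 2), -np.sqrt(1 / 2)], atol=1e-12
        )

    @pytest.mark.parametrize("basis_fn", [loh_basis, alt_basis])
    def test_orthonormal_zero_sum(self, basis_fn):
        V = basis_fn().contrast
        np.testing.assert_allclose(V.T @ V, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(V.sum(axis=0), 0, atol=1e-10)

    @pytest.mark.parametrize(
        "rows, err",
        [
            ([[1, 1, 1, 1], [0, 1, -1, -1], [0, 0, 1, -1]], "row 1"),
            ([[1, -1, -1, -1], [1, 1, -1, -1], [0, 0, 1, -1]], "row 2"),
            ([[1, -1, -1, -1], [0, 1, -1, 0], [0, 0, 1, -1]], "row"),
        ],
    )
    def test_invalid_partitions_rejected(self, rows, err):
        with pytest.raises(ValueError, match=err):
            SbpSignMatrix(np.array(rows), PART_LABELS)

    def test_entries_outside_signs_rejected(self):
        with pytest.raises(ValueError, match="entries"):
            SbpSignMatrix(
                np.array([[2, -1, -1, -1], [0, 1, -1, -1], [0, 0, 1, -1]]), PART_LABELS
            )


class TestPivotBasis:
    def test_first_column_equals_sbp_pivot_row(self):
        b = pivot_basis(PART_LABELS)
        np.testing.assert_allclose(
            b.contrast[:, 0],
            [np.sqrt(3 / 4), -np.sqrt(1 / 12), -np.sqrt(1 / 12), -np.sqrt(1 / 12)],
            atol=1e-12,
        )

    @given(positive_parts)
    @settings(max_examples=50, deadline=None)
    def test_first_coordinate_proportional_to_clr(self, parts):
        x = comp(parts)
        z1 = olr(x, pivot_basis(PART_LABELS))[0]
        assert z1 == pytest.approx(np.sqrt(4 / 3) * clr(x)[0], abs=1e-10)

    @given(positive_parts)
    @settings(max_examples=25, deadline=None)
    def test_round_trip_identical_across_pivot_orders(self, parts):
        x = comp(parts)
        for order in (PART_LABELS, tuple(reversed(PART_LABELS))):
            b = pivot_basis(PART_LABELS, order=order)
            assert olr_inv(olr(x, b), b).isclose(x)


class TestOlrTransform:
    def test_neutral_maps_to_origin(self):
        e = neutral(4, 1440.0, labels=PART_LABELS)
        np.testing.assert_allclose(olr(e, loh_basis()), 0, atol=1e-12)
        np.testing.assert_allclose(clr(e), 0, atol=1e-12)

    @given(positive_parts, st.floats(min_value=0.01, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, parts, kappa):
        basis = loh_basis()
        np.testing.assert_allclose(
            olr(comp(parts, 1.0), basis), olr(comp(parts, kappa), basis), atol=1e-10
        )

    def test_round_trip_many_random_compositions(self, rng):
        basis = loh_basis()
        X = rng.lognormal(size=(1000, 4))
        for row in X:
            x = comp(row)
            assert olr_inv(olr(x, basis), basis).isclose(x, rtol=1e-9)

    @given(positive_parts)
    @settings(max_examples=50, deadline=None)
    def test_clr_relation_and_zero_sum(self, parts):
        x = comp(parts)
        basis = loh_basis()
        assert clr(x).sum() == pytest.approx(0, abs=1e-10)
        np.testing.assert_allclose(basis.contrast @ olr(x, basis), clr(x), atol=1e-10)

    @given(positive_parts)
    @settings(max_examples=50, deadline=None)
    def test_basis_invariance_of_inverse(self, parts):
        x = comp(parts)
        b1, b2 = loh_basis(), alt_basis()
        assert olr_inv(olr(x, b1), b1).isclose(olr_inv(olr(x, b2), b2))

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            olr_inv([np.inf, 0, 0], loh_basis())


class TestChangeOfBasis:
    @given(positive_parts)
    @settings(max_examples=50, deadline=None)
    def test_rotation_round_trip(self, parts):
        x = comp(parts)
        b1, b2 = loh_basis(), alt_basis()
        z1 = olr(x, b1)
        z2 = change_of_basis(z1, b1, b2)
        np.testing.assert_allclose(z2, olr(x, b2), atol=1e-10)
        np.testing.assert_allclose(change_of_basis(z2, b2, b1), z1, atol=1e-10)
        assert olr_inv(z2, b2).isclose(olr_inv(z1, b1))

    def test_rotation_matrix_is_orthogonal(self):
        b1, b2 = loh_basis(), alt_basis()
        Q = b2.contrast.T @ b1.contrast
        np.testing.assert_allclose(Q @ Q.T, np.eye(3), atol=1e-12)


class TestWorkedExample:
    """Back-transformations of the published coefficient vectors."""

    def test_intercepts_to_baseline_minutes(self):
        c = olr_inv([0.83, 0.94, 0.93], loh_basis(), kappa=1440.0)
        assert round(c.values[0]) == 584  # sleep
        assert round(c.values[3]) == 79   # MVPA
        np.testing.assert_allclose(
            np.round(c.values), [584, 483, 294, 79], atol=1.0
        )

    def test_t3_perturbation_vector(self):
        c = olr_inv([0.09, 0.22, 0.21], loh_basis(), kappa=1.0)
        np.testing.assert_allclose(
            c.values, [0.266, 0.289, 0.256, 0.190], atol=2e-3
        )

    def test_olr_of_baseline_recovers_intercepts(self):
        x = close([584, 483, 294, 79], 1440.0, labels=PART_LABELS)
        np.testing.assert_allclose(
            olr(x, loh_basis()), [0.83, 0.94, 0.93], atol=5e-3
        )

    def test_perturbation_additivity_on_olr_scale(self):
        # baseline ⊕ T3-effect = olr_inv of coordinate-wise sums; the printed
        # perturbation parts are rounded to 3 dp, so parts agree to ~2e-3
        basis = loh_basis()
        base = olr_inv([0.83, 0.94, 0.93], basis, kappa=1.0)
        eff = close([0.266, 0.289, 0.256, 0.190], 1.0, labels=PART_LABELS)
        lhs = perturb(base, eff)
        rhs = olr_inv(np.add([0.83, 0.94, 0.93], [0.09, 0.22, 0.21]), basis, 1.0)
        np.testing.assert_allclose(lhs.parts, rhs.parts, atol=2e-3)
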
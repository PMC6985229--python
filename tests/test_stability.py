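"""Jacobian linearization, eigenvalue spectrum and stability classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hhpair import (
    ASYMPTOTICALLY_STABLE,
    INCONCLUSIVE,
    UNSTABLE,
    NeuronParams,
    analytic_jacobian,
    classify,
    eigen_spectrum,
    find_equilibrium,
    nominal_equilibrium,
    numeric_jacobian,
    stability_report,
)

# reference linearization at the resting point, printed to 4 decimals
REFERENCE_JACOBIAN = np.array(
    [
        [-0.6773, 69.1743, 2.0474, -55.1966],
        [0.0264, -4.2236, 0.0, 0.0],
        [-0.0041, 0.0, -0.1174, 0.0],
        [0.0028, 0.0, 0.0, -0.1832],
    ]
)
# reported spectrum of that linearization (4-decimal print precision)
REFERENCE_SPECTRUM = np.array(
    [-4.6755, -0.2026 - 0.3824j, -0.2026 + 0.3824j, -0.1207]
)


def _jac_tol(a: np.ndarray) -> np.ndarray:
    return np.maximum(1e-4 * np.abs(a), 1e-8)


class TestAnalyticJacobian:
    def test_voltage_row_leading_entry_and_gate_rows(self, params):
        """Spot-check against the reference matrix: A11 and the m-gate row.

        The reference linearization evaluates the rate laws exactly at the
        nominal resting potential, so that is the evaluation point here.
        """
        J = analytic_jacobian(params, nominal_equilibrium(params))
        assert round(J[0, 0], 4) == -0.6773
        assert round(J[1, 0], 4) == 0.0264
        assert round(J[1, 1], 4) == -4.2236

    def test_gate_gate_cross_entries_exactly_zero(self, params):
        """Each gate ODE depends only on V and itself."""
        J = analytic_jacobian(params, find_equilibrium(params))
        for i, j in [(1, 2), (1, 3), (2, 1), (2, 3), (3, 1), (3, 2)]:
            assert J[i, j] == 0.0

    def test_diagonal_negative(self, params):
        J = analytic_jacobian(params, find_equilibrium(params))
        assert np.all(np.diag(J) < 0.0)

    def test_matches_finite_differences_at_reference(self, params):
        eq = find_equilibrium(params)
        Ja = analytic_jacobian(params, eq)
        Jn = numeric_jacobian(params, eq, step=1e-6)
        assert np.all(np.abs(Ja - Jn) <= _jac_tol(Ja))

    @given(
        fna=st.floats(min_value=0.8, max_value=1.2),
        fk=st.floats(min_value=0.8, max_value=1.2),
        fl=st.floats(min_value=0.8, max_value=1.2),
        fena=st.floats(min_value=0.8, max_value=1.2),
        fek=st.floats(min_value=0.8, max_value=1.2),
    )
    def test_matches_finite_differences_under_perturbed_params(
        self, fna, fk, fl, fena, fek
    ):
        """Analytic vs central-difference Jacobian across +-20% parameter scalings."""
        p = NeuronParams(
            G_Na=120.0 * fna,
            G_K=36.0 * fk,
            G_L=0.3 * fl,
            E_Na=50.0 * fena,
            E_K=-77.0 * fek,
        )
        eq = find_equilibrium(p)
        Ja = analytic_jacobian(p, eq)
        Jn = numeric_jacobian(p, eq, step=1e-6)
        assert np.all(np.abs(Ja - Jn) <= _jac_tol(Ja))


class TestNumericJacobian:
    def test_second_order_in_step(self, params):
        """Halving the step shrinks the error vs the analytic value ~4x."""
        eq = find_equilibrium(params)
        Ja = analytic_jacobian(params, eq)
        e1 = np.max(np.abs(numeric_jacobian(params, eq, step=2e-3) - Ja))
        e2 = np.max(np.abs(numeric_jacobian(params, eq, step=1e-3) - Ja))
        assert 3.0 < e1 / e2 < 5.0

    def test_invalid_step_rejected(self, params):
        with pytest.raises(ValueError):
            numeric_jacobian(params, find_equilibrium(params), step=0.0)


class TestEigenSpectrum:
    def test_diagonal_matrix(self):
        ev = eigen_spectrum(np.diag([-3.0, -1.0, 2.0, 5.0]))
        assert ev == pytest.approx([-3.0, -1.0, 2.0, 5.0])

    def test_symmetric_matrix_matches_characteristic_polynomial_roots(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(4, 4))
        A = A + A.T
        ev = eigen_spectrum(A)
        roots = np.sort(np.roots(np.poly(A)).real)
        assert np.all(np.abs(ev.imag) < 1e-9)
        assert ev.real == pytest.approx(roots, rel=1e-8, abs=1e-8)

    def test_conjugate_closure_and_trace_det_identities(self, params):
        J = analytic_jacobian(params, find_equilibrium(params))
        ev = eigen_spectrum(J)
        assert sorted(ev) == pytest.approx(sorted(np.conj(ev)), abs=1e-12)
        assert np.sum(ev).real == pytest.approx(np.trace(J), rel=1e-6)
        assert np.prod(ev).real == pytest.approx(np.linalg.det(J), rel=1e-6)

    def test_spectrum_invariant_under_permutation(self, params):
        J = analytic_jacobian(params, find_equilibrium(params))
        perm = [2, 0, 3, 1]
        Jp = J[np.ix_(perm, perm)]
        assert eigen_spectrum(Jp) == pytest.approx(eigen_spectrum(J), abs=1e-10)

    def test_reference_matrix_spectrum_frozen(self):
        """Eigenvalues of the 4-decimal reference matrix (numpy oracle, frozen).

        Note these differ from the *reported* spectrum by up to ~7e-4: the
        reference matrix and reference spectrum were printed from slightly
        different internal precision, so they are mutually consistent only
        at the ~1e-3 level.
        """
        ev = eigen_spectrum(REFERENCE_JACOBIAN)
        expected = np.array(
            [
                -4.676177124353764,
                -0.2023361451484901 - 0.3818888865505704j,
                -0.2023361451484901 + 0.3818888865505704j,
                -0.12065058534925462,
            ]
        )
        assert ev == pytest.approx(expected, rel=1e-10)
        assert np.max(np.abs(ev - REFERENCE_SPECTRUM)) < 1e-3

    def test_full_precision_spectrum_near_reported_values(self, params):
        """Our linearization's spectrum agrees with the reported one to ~1e-3."""
        ev = eigen_spectrum(analytic_jacobian(params, find_equilibrium(params)))
        assert np.max(np.abs(ev - REFERENCE_SPECTRUM)) < 1e-3

    def test_non_finite_matrix_rejected(self):
        J = np.zeros((4, 4))
        J[0, 0] = np.nan
        with pytest.raises(ValueError):
            eigen_spectrum(J)


class TestClassify:
    def test_all_negative_real_parts_stable(self):
        verdict, margin = classify(REFERENCE_SPECTRUM, tol=1e-9)
        assert verdict == ASYMPTOTICALLY_STABLE
        assert margin == pytest.approx(-0.1207)

    def test_zero_real_part_inconclusive(self):
        verdict, _ = classify(np.array([0.0, -1.0, -2.0, -3.0]), tol=1e-9)
        assert verdict == INCONCLUSIVE

    def test_positive_real_part_unstable(self):
        verdict, margin = classify(np.array([0.1, -1.0, -1.0, -1.0]))
        assert verdict == UNSTABLE
        assert margin == pytest.approx(0.1)

    def test_negative_tol_rejected(self):
        with pytest.raises(ValueError):
            classify(np.array([-1.0]), tol=-1.0)


class TestReport:
    def test_resting_point_classified_asymptotically_stable(self, params):
        rep = stability_report(params)
        assert rep.classification == ASYMPTOTICALLY_STABLE
        assert rep.margin == pytest.approx(-0.1207, abs=1e-4)

    def test_report_serializes_to_json_friendly_dict(self, params):
        import json

        d = stability_report(params).to_dict()
        json.dumps(d)  # must not raise
        assert len(d["jacobian"]) == 4
        assert len(d["eigenvalues"]) == 4
        assert all(len(pair) == 2 for pair in d["eigenvalues"])
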
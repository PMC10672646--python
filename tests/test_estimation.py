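"""Tests of midpoint interpolation, collocation rows, system assembly and
the least-squares solvers, with independent oracles (sympy symbolic
expansion, brute-force numerical minimization, known-truth construction)."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from organofit import (
    ESTIMATED_ORDER,
    EstimatedParameters,
    KnownParameters,
    LinearSystem,
    MeasurementSeries,
    assemble,
    fit,
    interval_rows,
    midpoint,
    midpoint_state,
    scheme_residual,
    solve,
)
from organofit.exceptions import InsufficientDataError, RankDeficiencyError
from organofit.model import _rhs
from organofit.synthetic import CohortSpec, generate_cohort, sample_truth

positive = st.floats(1e-6, 1e6)


class TestMidpoint:
    def test_harmonic_of_equal_inputs_is_identity(self):
        assert midpoint(2.0, 2.0, "harmonic") == 2.0

    def test_harmonic_hand_value(self):
        assert midpoint(1.0, 3.0, "harmonic") == pytest.approx(1.5)

    def test_auto_falls_back_to_arithmetic_at_zero(self):
        assert midpoint(0.0, 4.0, "auto") == 2.0

    def test_harmonic_rejects_zero(self):
        with pytest.raises(ValueError, match="strictly positive"):
            midpoint(0.0, 4.0, "harmonic")

    @given(a=positive, b=positive)
    def test_harmonic_never_exceeds_arithmetic(self, a, b):
        h = midpoint(a, b, "harmonic")
        m = midpoint(a, b, "arithmetic")
        assert h <= m + 1e-12 * m
        if abs(a - b) > 1e-9 * max(a, b):
            assert h < m

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            midpoint(-1.0, 1.0)


class TestIntervalRows:
    def test_zero_states_give_zero_rows(self, known):
        A4, b4, _ = interval_rows([0] * 4, [0] * 4, 7, 14, known)
        assert np.all(A4 == 0) and np.all(b4 == 0)

    def test_zero_interval_rejected(self, known):
        with pytest.raises(ValueError, match="interval length"):
            interval_rows([1] * 4, [2] * 4, 7, 7, known)

    def test_against_symbolic_expansion(self, known):
        """Independent oracle: expand the difference scheme symbolically in
        sympy and compare every coefficient and right-hand side."""
        import sympy as sp

        z_i = np.array([1e4, 1e3, 1e3, 1e2])
        z_n = np.array([2e4, 1.2e3, 1.1e3, 1.5e2])
        t_i, t_n = 7.0, 14.0
        A4, b4, _ = interval_rows(z_i, z_n, t_i, t_n, known)

        q = sp.symbols("q2 q4 q5 q6 dCAF q7 q8 q9", positive=True)
        zs = [2 * a * b / (a + b) for a, b in zip(z_i, z_n)]  # all positive -> harmonic
        N, M2, CAF, Tc = zs
        dt = t_n - t_i
        F = [
            known.gamma * (1 - N / known.K) * N + known.q1 * N * M2 + q[0] * N * CAF
            - known.k * Tc * N,
            known.q3 * M2 * N + q[1] * M2 * CAF - known.delta_M2 * M2,
            q[2] * CAF * N + q[3] * CAF * M2 - q[4] * CAF,
            q[5] * Tc * N - q[6] * Tc * M2 - q[7] * Tc * CAF - known.delta_Tc * Tc,
        ]
        for row in range(4):
            expr = sp.expand((z_n[row] - z_i[row]) / dt - F[row])
            # expr == B - A q  =>  coefficient of q_j is -A[row, j]
            poly = sp.Poly(expr, *q)
            const = float(poly.coeff_monomial(1))
            assert const == pytest.approx(b4[row], rel=1e-12)
            for j, sym in enumerate(q):
                coeff = -float(poly.coeff_monomial(sym))
                assert coeff == pytest.approx(A4[row, j], rel=1e-12, abs=1e-15)

    def test_exact_for_data_generated_by_the_scheme(self, known, est_example):
        """If z_next solves the implicit midpoint difference equation with
        rates Q*, the produced rows satisfy A Q* = B exactly."""
        q_star = est_example.to_array()
        z_i = np.array([40.0, 8.0, 8.0, 4.0])
        dt = 3.0
        z_n = z_i.copy()
        for _ in range(200):  # fixed-point iteration of the implicit step
            z_mid = midpoint_state(z_i, z_n, "auto")
            z_new = z_i + dt * _rhs(z_mid, known, est_example)
            if np.max(np.abs(z_new - z_n)) < 1e-14 * np.max(z_i):
                z_n = z_new
                break
            z_n = z_new
        A4, b4, _ = interval_rows(z_i, z_n, 0.0, dt, known)
        assert A4 @ q_star == pytest.approx(b4, rel=1e-9, abs=1e-12)


class TestAssemble:
    def test_one_patient_three_days_gives_8x8(self, known):
        s = MeasurementSeries(
            "p1", np.array([7.0, 14.0, 21.0]), np.abs(np.random.default_rng(0).normal(10, 2, (3, 4)))
        )
        system = assemble([s], known)
        assert system.A.shape == (8, 8)
        assert system.B.shape == (8,)
        assert len(system.row_provenance) == 8

    def test_rows_add_across_patients(self, known, sparse_cohort):
        system = assemble(sparse_cohort.series[:2], known)
        assert system.A.shape[0] == 16

    def test_empty_series_list_is_insufficient(self, known):
        with pytest.raises(InsufficientDataError, match="2 measurement intervals"):
            assemble([], known)

    def test_single_interval_is_insufficient(self, known):
        s = MeasurementSeries("p1", np.array([7.0, 14.0]), np.ones((2, 4)))
        with pytest.raises(InsufficientDataError):
            assemble([s], known)

    def test_provenance_tracks_patient_interval_equation(self, known, sparse_cohort):
        system = assemble(sparse_cohort.series, known)
        pids = {p for p, _, _ in system.row_provenance}
        assert pids == {s.patient_id for s in sparse_cohort.series}
        assert [eq for _, _, eq in system.row_provenance[:4]] == ["N", "M2", "CAF", "Tc"]


def _random_system(rng, n=12):
    A = rng.normal(size=(n, 8))
    B = rng.normal(size=n)
    return LinearSystem(A, B, tuple(("p", i // 4, "N") for i in range(n)))


class TestSolve:
    def test_identity_system_returns_rhs(self):
        system = LinearSystem(
            np.eye(8), np.ones(8), tuple(("p", 0, "N") for _ in range(8))
        )
        for method in ("normal_equations", "pseudoinverse", "nonnegative"):
            assert solve(system, method).q == pytest.approx(np.ones(8))

    def test_normal_equations_match_pseudoinverse_and_brute_force(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(42)
        for _ in range(5):
            system = _random_system(rng)
            q_ne = solve(system, "normal_equations").q
            q_pi = solve(system, "pseudoinverse").q
            assert np.linalg.norm(q_ne - q_pi) / np.linalg.norm(q_pi) < 1e-8
            obj = lambda q: np.sum((system.A @ q - system.B) ** 2)
            jac = lambda q: 2 * system.A.T @ (system.A @ q - system.B)
            q_bf = minimize(obj, np.zeros(8), jac=jac, method="BFGS",
                            options={"gtol": 1e-14}).x
            assert np.linalg.norm(q_bf - q_ne) / np.linalg.norm(q_ne) < 1e-6

    def test_nnls_clamps_negative_component_and_costs_residual(self):
        rng = np.random.default_rng(3)
        # Build a system whose unconstrained optimum has a negative entry.
        A = rng.normal(size=(12, 8))
        q_true = np.array([1.0, -0.5, 0.8, 0.3, 0.2, 0.6, 0.1, 0.4])
        B = A @ q_true
        system = LinearSystem(A, B, tuple(("p", i // 4, "N") for i in range(12)))
        unc = solve(system, "pseudoinverse")
        nn = solve(system, "nonnegative")
        assert unc.q[1] < 0
        assert nn.q[1] == 0.0
        assert np.all(nn.q >= 0)
        assert nn.residual_norm >= unc.residual_norm

    def test_singular_normal_equations_raise_with_advice(self):
        A = np.zeros((8, 8))
        A[:, 0] = 1.0
        system = LinearSystem(A, np.ones(8), tuple(("p", 0, "N") for _ in range(8)))
        with pytest.raises(RankDeficiencyError, match="pseudoinverse"):
            solve(system, "normal_equations")

    def test_block_rank_diagnostics(self, known, sparse_cohort):
        res = solve(assemble(sparse_cohort.series, known))
        assert res.block_ranks["N"] == 1
        assert res.block_ranks["M2"] == 1
        assert res.block_ranks["CAF"] == 3
        assert res.block_ranks["Tc"] == 3


class TestFit:
    def test_single_patient_per_patient_warns_underdetermined(self, known, sparse_cohort):
        s = sparse_cohort.series[0]
        with pytest.warns(UserWarning, match="rank-deficient"):
            results = fit([s], known, pooling="per_patient", method="pseudoinverse")
        res = results[s.patient_id]
        assert any("CAF" in w or "Tc" in w for w in res.warnings)
        assert res.block_ranks["CAF"] < 3 and res.block_ranks["Tc"] < 3

    def test_duplicated_patient_matches_single_patient_minimum_norm(self, known, sparse_cohort):
        s = sparse_cohort.series[0]
        twin = MeasurementSeries("copy", s.times, s.states)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            single = fit([s], known, pooling="per_patient", method="pseudoinverse")[s.patient_id]
            pooled = fit([s, twin], known, pooling="pooled", method="pseudoinverse")
        assert pooled.q == pytest.approx(single.q, rel=1e-8, abs=1e-12)

    def test_scale_covariance(self, known, sparse_cohort):
        """Rescaling all abundances by c (with the per-cell knowns K, q1,
        q3, k transformed accordingly) divides the fitted per-cell rates
        (q2..q9) by c and leaves the pure rate delta_CAF unchanged."""
        c = 500.0
        scaled = [
            MeasurementSeries(s.patient_id, s.times, s.states * c)
            for s in sparse_cohort.series
        ]
        known_scaled = known.replace(
            K=known.K * c, q1=known.q1 / c, q3=known.q3 / c, k=known.k / c
        )
        base = fit(sparse_cohort.series, known, method="nonnegative")
        resc = fit(scaled, known_scaled, method="nonnegative")
        expected = base.q.copy()
        for j, name in enumerate(ESTIMATED_ORDER):
            if name != "delta_CAF":
                expected[j] /= c
        assert resc.q == pytest.approx(expected, rel=1e-6, abs=1e-15)

    def test_scheme_residual_shrinks_with_spacing(self):
        """Collocating an exact trajectory: the relative residual of the true
        rates decreases monotonically as the sampling interval shrinks."""
        spec0 = CohortSpec(n_patients=1, measurement_days=(7.0, 14.0, 21.0),
                           noise_cv=0.0, seed=3)
        truth, inits = sample_truth(spec0)
        residuals = []
        for dt in (7.0, 1.0, 0.1):
            days = tuple(np.arange(7.0, 21.0001, dt))
            spec = CohortSpec(n_patients=1, measurement_days=days, noise_cv=0.0, seed=3)
            cohort = generate_cohort(spec, truth=truth, initial_states=inits)
            residuals.append(scheme_residual(cohort.series[0], spec.known, truth))
        assert residuals[0] > residuals[1] > residuals[2]

    def test_dense_noiseless_recovery_within_one_percent(self, noiseless_cohort):
        """With dense (eighth-of-a-day) sampling the collocation bias is
        negligible and a pooled nonnegative fit recovers every rate to
        better than 1%."""
        cohort = noiseless_cohort
        res = fit(cohort.series, cohort.spec.known, pooling="pooled", method="nonnegative")
        truth = cohort.truth.to_array()
        rel = np.abs(res.q - truth) / truth
        assert np.max(rel) < 0.01
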
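"""Change of variables, numerical Jacobians and the explicit-dynamics oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from stagecomm import (
    AggregatedState,
    ConfigurationError,
    StageODESystem,
    aggregate,
    disaggregate,
    find_equilibrium,
    numerical_jacobian,
    structured_matrix_from_system,
    transformed_rhs,
    two_species_fixture,
)
from stagecomm.dynamics import (
    stage_space_jacobian,
    trajectory_equivalence_error,
    transformed_rhs_flat,
)
from stagecomm.errors import NumericalError


class TestChangeOfVariables:
    def test_aggregate_simple_values(self):
        state = aggregate(np.array([[1.0, 1.0]]))
        assert state.totals[0] == 2.0
        assert state.fractions[0, 0] == 0.5
        state = aggregate(np.array([[3.0, 1.0]]))
        assert state.totals[0] == 4.0
        assert state.fractions[0, 0] == 0.75

    @given(arrays(np.float64, (3, 4),
                  elements=st.floats(0.5, 2.0)))
    def test_round_trip_is_identity(self, stage_state):
        back = disaggregate(aggregate(stage_state))
        np.testing.assert_allclose(back, stage_state, rtol=1e-14, atol=1e-14)

    @given(arrays(np.float64, (3, 4),
                  elements=st.floats(0.01, 100.0)))
    def test_round_trip_error_bounded_by_total_density(self, stage_state):
        # the implicit last fraction cancels against the total, so the
        # achievable bound scales with N_i, not with the smallest stage
        back = disaggregate(aggregate(stage_state))
        totals = stage_state.sum(axis=1, keepdims=True)
        assert np.all(np.abs(back - stage_state) <= 1e-13 * totals)

    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_round_trip_across_stage_counts(self, K, rng):
        stage_state = rng.uniform(0.5, 2.0, size=(5, K))
        back = disaggregate(aggregate(stage_state))
        np.testing.assert_allclose(back, stage_state, rtol=1e-14, atol=1e-14)

    def test_zero_total_is_a_domain_error(self):
        with pytest.raises(ConfigurationError):
            aggregate(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_negative_density_rejected(self):
        with pytest.raises(ConfigurationError):
            aggregate(np.array([[1.0, -0.1]]))

    def test_invalid_fraction_complement_rejected(self):
        state = AggregatedState(totals=np.array([1.0]),
                                fractions=np.array([[0.7, 0.6]]))
        with pytest.raises(ConfigurationError):
            disaggregate(state)

    def test_vector_layout_round_trip(self):
        state = AggregatedState(totals=np.array([2.0, 3.0]),
                                fractions=np.array([[0.25], [0.5]]))
        y = state.to_vector()
        np.testing.assert_array_equal(y, [2.0, 3.0, 0.25, 0.5])
        back = AggregatedState.from_vector(y, 2, 2)
        np.testing.assert_array_equal(back.totals, state.totals)
        np.testing.assert_array_equal(back.fractions, state.fractions)


class TestTransformedSystem:
    def test_equilibrium_maps_to_equilibrium(self):
        system, eq = two_species_fixture("adult_juvenile")
        dN, dZ = transformed_rhs(system, aggregate(eq.stage_densities))
        np.testing.assert_allclose(dN, 0.0, atol=1e-12)
        np.testing.assert_allclose(dZ, 0.0, atol=1e-12)

    def test_stage_fractions_conserve_to_one(self, rng):
        # sum_k dZ_ik = 0 over all K stages, at any state
        system, _ = two_species_fixture("adult_adult")
        stage = rng.uniform(0.2, 2.0, size=(2, 2))
        agg = aggregate(stage)
        g = system.rhs_matrix(stage)
        dN, dZ = transformed_rhs(system, agg)
        z_last = 1.0 - agg.fractions.sum(axis=1)
        dZ_last = (g[:, -1] - z_last * dN) / agg.totals
        np.testing.assert_allclose(dZ.sum(axis=1) + dZ_last, 0.0, atol=1e-12)

    def test_trajectory_equivalence_raw_vs_transformed(self):
        system, eq = two_species_fixture("adult_juvenile")
        x0 = eq.stage_densities * np.array([[1.08, 0.95], [0.92, 1.05]])
        err = trajectory_equivalence_error(system, x0, t_final=100.0)
        assert err < 1e-6


class TestNumericalJacobian:
    def test_linear_system_is_recovered_exactly(self, rng):
        a = rng.normal(size=(5, 5))
        jac = numerical_jacobian(lambda x: a @ x, rng.normal(size=5))
        np.testing.assert_allclose(jac, a, atol=1e-8)

    def test_logistic_jacobian_at_carrying_capacity(self):
        r, kcap = 0.7, 2.5
        jac = numerical_jacobian(lambda x: r * x * (1 - x / kcap),
                                 np.array([kcap]))
        assert jac[0, 0] == pytest.approx(-r, abs=1e-8)

    def test_non_finite_rhs_is_diagnosed(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            with pytest.raises(NumericalError):
                numerical_jacobian(lambda x: np.array([1.0 / (x[0] - 1.0)]),
                                   np.array([1.0]))
            with pytest.raises(NumericalError):
                numerical_jacobian(lambda x: np.sqrt(x), np.array([0.0]))


def _symbolic_structured_jacobian(system, equilibrium):
    """Independent oracle: build the fixture's transformed system in sympy,
    differentiate symbolically, evaluate at the aggregated equilibrium."""
    import sympy as sp

    p = system.params
    S = system.S
    N = [sp.Symbol(f"n{i}", positive=True) for i in range(S)]
    Z = [sp.Symbol(f"z{i}", positive=True) for i in range(S)]
    # stage densities in terms of totals and juvenile fractions
    juv = [N[i] * Z[i] for i in range(S)]
    adu = [N[i] * (1 - Z[i]) for i in range(S)]
    stages = [juv, adu]

    g = {}
    for i in range(S):
        tot = juv[i] + adu[i]
        for k in range(2):
            inter = sum(p["alpha"][i, k, j, l] * stages[l][j]
                        for j in range(S) for l in range(2))
            percap = p["r"][i, k] - p["s"][i] * tot + inter
            expr = stages[k][i] * percap
            if k == 0:
                expr += p["b"][i] * adu[i] - p["m"][i] * juv[i]
            else:
                expr += p["m"][i] * juv[i]
            g[(i, k)] = expr

    dN = [g[(i, 0)] + g[(i, 1)] for i in range(S)]
    dZ = [(g[(i, 0)] - Z[i] * dN[i]) / N[i] for i in range(S)]
    variables = N + Z
    funcs = dN + dZ
    jac = sp.Matrix(funcs).jacobian(variables)

    agg = aggregate(equilibrium.stage_densities)
    subs = {N[i]: agg.totals[i] for i in range(S)}
    subs.update({Z[i]: agg.fractions[i, 0] for i in range(S)})
    return np.array(jac.subs(subs).evalf(), dtype=float)


class TestStructuredMatrixOracle:
    @pytest.mark.parametrize("mode", ["adult_adult", "adult_juvenile"])
    def test_finite_difference_matches_symbolic_jacobian(self, mode):
        system, eq = two_species_fixture(mode)
        ms = structured_matrix_from_system(system, eq)
        expected = _symbolic_structured_jacobian(system, eq)
        np.testing.assert_allclose(ms.entries, expected, atol=1e-6)

    def test_uncoupled_species_have_zero_cross_entries(self):
        system, eq = two_species_fixture("none")
        ms = structured_matrix_from_system(system, eq)
        for r in (1, 2):
            for c in (1, 2):
                block = ms.block(r, c)
                assert abs(block[0, 1]) < 1e-8
                assert abs(block[1, 0]) < 1e-8

    def test_stage_symmetric_interactions_cancel_in_fraction_rows(self):
        # when species j acts identically on every stage of species i, the
        # interaction depends on totals only and drops out of the fraction
        # dynamics by the chain rule
        system, eq = two_species_fixture("stage_symmetric")
        ms = structured_matrix_from_system(system, eq)
        for c in (1, 2):
            block = ms.block(2, c)
            assert abs(block[0, 1]) < 1e-8
            assert abs(block[1, 0]) < 1e-8

    @pytest.mark.parametrize("mode", ["adult_adult", "adult_juvenile",
                                      "stage_symmetric"])
    def test_stability_verdict_survives_change_of_variables(self, mode):
        system, eq = two_species_fixture(mode)
        ms = structured_matrix_from_system(system, eq)
        raw = stage_space_jacobian(system, eq)
        lam_ms = np.linalg.eigvals(ms.entries).real.max()
        lam_raw = np.linalg.eigvals(raw).real.max()
        assert (lam_ms < 0) == (lam_raw < 0)

    def test_top_left_block_is_aggregated_community_matrix(self):
        # columns of block (1,1) are d(dN_i)/d(N_j) at fixed fractions
        system, eq = two_species_fixture("adult_adult")
        ms = structured_matrix_from_system(system, eq)
        agg = aggregate(eq.stage_densities)
        f = transformed_rhs_flat(system)

        def total_derivs(n_vec):
            y = np.concatenate([n_vec, agg.fractions.ravel(order="F")])
            return f(y)[:2]

        expected = numerical_jacobian(total_derivs, agg.totals)
        np.testing.assert_allclose(ms.block(1, 1), expected, atol=1e-6)


class TestEquilibriumSearch:
    def test_constructed_equilibrium_is_recovered(self):
        system, eq = two_species_fixture("adult_juvenile")
        found = find_equilibrium(system, eq.stage_densities * 1.3)
        np.testing.assert_allclose(found.stage_densities, eq.stage_densities,
                                   atol=1e-10)
        assert found.residual_norm < 1e-9

    def test_boundary_root_is_rejected_as_infeasible(self):
        # pure decay: the only equilibrium is extinction
        system = StageODESystem(S=1, K=2, rhs=lambda x: -np.asarray(x))
        with pytest.raises(NumericalError):
            find_equilibrium(system, np.array([[0.5, 0.5]]))

    def test_non_positive_guess_rejected(self):
        system, eq = two_species_fixture()
        with pytest.raises(ConfigurationError):
            find_equilibrium(system, np.zeros((2, 2)))
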
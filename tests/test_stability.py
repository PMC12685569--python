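"""Stability classification, analytic criteria and Monte-Carlo ensembles."""

from dataclasses import replace

import numpy as np
import pytest

from stagecomm import (
    CommunityConfig,
    ConfigurationError,
    InteractionType,
    MagnitudeDistribution,
    classify_stability,
    classify_structure_effect,
    elliptic_criterion,
    ensemble_stability,
    estimate_critical_gamma,
    may_criterion,
    stability_grid,
    two_stage_config,
)
from stagecomm.errors import NumericalError
from stagecomm.stability import derive_seeds


class TestClassification:
    def test_negative_identity_is_stable(self):
        res = classify_stability(-np.eye(7))
        assert res.stable and res.lambda_max_real == pytest.approx(-1.0)

    def test_purely_imaginary_pair_is_marginal_not_stable(self):
        res = classify_stability(np.array([[0.0, 1.0], [-1.0, 0.0]]))
        assert res.lambda_max_real == pytest.approx(0.0, abs=1e-12)
        assert not res.stable

    def test_non_square_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_stability(np.zeros((3, 4)))

    def test_spectrum_closed_under_conjugation(self, rng):
        m = rng.normal(size=(40, 40))
        spectrum = classify_stability(m).spectrum
        paired = np.sort_complex(np.conj(spectrum))
        np.testing.assert_allclose(np.sort_complex(spectrum), paired,
                                   atol=1e-8)


class TestCriteria:
    def test_zero_strength_predicts_stable(self):
        assert may_criterion(0.0, 100, 1.0).predicted_stable
        assert elliptic_criterion("predation", 0.0, 100, 1.0).predicted_stable

    def test_may_criterion_hand_values(self):
        res = may_criterion(0.05, 100, 0.5, d=1.0)
        assert res.gamma == pytest.approx(0.05 * np.sqrt(50))
        assert res.predicted_stable
        res = may_criterion(0.1, 200, 1.0, d=1.0)
        assert res.gamma == pytest.approx(np.sqrt(2), rel=1e-12)
        assert not res.predicted_stable

    def test_predator_prey_hand_value(self):
        res = elliptic_criterion("predation", 0.1, 200, 1.0)
        assert res.gamma == pytest.approx((np.pi - 2) / np.pi * np.sqrt(2),
                                          rel=1e-12)
        assert res.predicted_stable
        assert res.label == "predator_prey"

    def test_predation_always_below_random_gamma(self):
        for sigma, S, C in [(0.05, 100, 1.0), (0.2, 300, 0.3)]:
            gp = elliptic_criterion("predation", sigma, S, C).gamma
            gr = may_criterion(sigma, S, C).gamma
            assert gp < gr

    def test_unsupported_type_rejected(self):
        with pytest.raises(ConfigurationError):
            elliptic_criterion("random", 0.1, 100, 1.0)
        with pytest.raises(ConfigurationError):
            elliptic_criterion("commensalism", 0.1, 100, 1.0)


def _may_config(S, sigma, seed=0):
    return CommunityConfig(
        S=S, C=1.0, d=1.0, interaction_type=InteractionType.RANDOM,
        distribution=MagnitudeDistribution("normal_signed", sigma), seed=seed)


class TestEnsembles:
    def test_zero_strength_ensemble_fully_stable(self):
        cfg = two_stage_config(10, 1.0, 1.0, seed=0)
        res = ensemble_stability(cfg, n_reps=20, seed=1)
        assert res.proportion_stable == 1.0

    def test_proportion_is_exact_count(self):
        cfg = _may_config(40, 0.5)
        res = ensemble_stability(cfg, n_reps=16, seed=5)
        n_stable = int(np.sum(res.lambda_max_real < -1e-10))
        assert res.proportion_stable == n_stable / 16

    def test_seed_determinism_bitwise(self):
        cfg = two_stage_config(15, 1.0, 1.0, gamma1=0.8, gamma2=0.3,
                               gamma3=0.3, seed=0)
        a = ensemble_stability(cfg, n_reps=10, seed=3)
        b = ensemble_stability(cfg, n_reps=10, seed=3)
        np.testing.assert_array_equal(a.lambda_max_real, b.lambda_max_real)

    def test_strong_interactions_destabilise(self):
        # gamma = 1.5 > d: essentially no stable communities
        sigma = 1.5 / np.sqrt(150)
        res = ensemble_stability(_may_config(150, sigma), n_reps=20, seed=2)
        assert res.proportion_stable <= 0.1

    def test_derived_seeds_are_31_bit_and_distinct(self):
        seeds = derive_seeds(123, 50)
        assert all(0 <= s < 2 ** 31 for s in seeds)
        assert len(set(seeds)) == 50


class TestGrid:
    def test_grid_shape_range_and_determinism(self):
        cfg = two_stage_config(12, 1.0, 1.0, gamma1=0.8, seed=0)
        g2, g3 = [0.0, 0.4], [0.0, 0.3, 0.6]
        a = stability_grid(cfg, g2, g3, n_reps=8, seed=9)
        b = stability_grid(cfg, g2, g3, n_reps=8, seed=9)
        assert a.proportions.shape == (2, 3)
        assert np.all((a.proportions >= 0) & (a.proportions <= 1))
        np.testing.assert_array_equal(a.proportions, b.proportions)
        frame = a.to_frame()
        assert set(frame.columns) == {"gamma2", "gamma3", "proportion_stable"}
        assert len(frame) == 6

    def test_zero_cross_cell_matches_block_diagonal_prediction(self):
        # at gamma2 = gamma3 = 0 stability is that of the diagonal blocks:
        # unstable whenever gamma1 > d
        cfg = two_stage_config(60, 1.0, 1.0, gamma1=1.3, seed=0)
        grid = stability_grid(cfg, [0.0], [0.0], n_reps=10, seed=4)
        assert grid.proportions[0, 0] == 0.0

    def test_monotone_proportion_along_gamma1(self):
        # stability can only degrade as the within-stage strength grows
        props = []
        for gamma1 in (0.7, 1.0, 1.3):
            cfg = two_stage_config(80, 1.0, 1.0, gamma1=gamma1, seed=0)
            props.append(ensemble_stability(cfg, n_reps=30, seed=8)
                         .proportion_stable)
        tol = 2 / np.sqrt(30)
        assert props[0] >= props[1] - tol >= props[2] - 2 * tol


class TestCriticalGamma:
    def test_interpolated_crossing_on_deterministic_proxy(self):
        # 1x1 matrices with lambda = gamma - 1: proportion drops 1 -> 0
        # across gamma = 1, interpolation lands exactly on 1.0
        def factory(gamma):
            return lambda seed: np.array([[gamma - 1.0]])

        est = estimate_critical_gamma(factory, [0.8, 0.9, 1.1, 1.2],
                                      n_reps=4, seed=0)
        assert est == pytest.approx(1.0)

    def test_no_crossing_is_diagnosed(self):
        def factory(gamma):
            return lambda seed: -np.eye(2)

        with pytest.raises(NumericalError):
            estimate_critical_gamma(factory, [0.1, 0.2], n_reps=2, seed=0)

    def test_unsorted_scan_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_critical_gamma(lambda g: None, [1.0, 0.5], n_reps=2,
                                    seed=0)

    def test_critical_gamma_scales_with_self_regulation(self):
        # doubling d doubles the transition location
        def factory_for(d):
            def factory(gamma):
                sigma = gamma / np.sqrt(120)
                return CommunityConfig(
                    S=120, C=1.0, d=d,
                    distribution=MagnitudeDistribution("normal_signed", sigma),
                    seed=0)
            return factory

        est1 = estimate_critical_gamma(
            factory_for(1.0), np.linspace(0.7, 1.3, 7), n_reps=40, seed=6)
        est2 = estimate_critical_gamma(
            factory_for(2.0), np.linspace(1.4, 2.6, 7), n_reps=40, seed=6)
        assert est2 / est1 == pytest.approx(2.0, rel=0.1)


class TestStructureEffect:
    def test_stabilising_destabilising_neutral(self):
        structured = np.array([[0.9, 0.9], [0.9, 0.1]])
        unstructured = np.array([[0.1, 0.1], [0.1, 0.1]])
        assert classify_structure_effect(structured, unstructured,
                                         n_reps=400) == "stabilising"
        assert classify_structure_effect(unstructured, structured,
                                         n_reps=400) == "destabilising"
        assert classify_structure_effect(structured, structured,
                                         n_reps=400) == "neutral"

    def test_scalar_unstructured_broadcasts(self):
        structured = np.array([[0.95, 0.9]])
        assert classify_structure_effect(structured, 0.0,
                                         n_reps=400) == "stabilising"

    def test_mixed_effect_is_diagnosed(self):
        structured = np.array([[0.9, 0.1]])
        unstructured = np.array([[0.1, 0.9]])
        with pytest.raises(NumericalError):
            classify_structure_effect(structured, unstructured, n_reps=400)

    def test_mismatched_lattices_rejected(self):
        with pytest.raises(ValueError):
            classify_structure_effect(np.zeros((2, 2)), np.zeros((3, 3)),
                                      n_reps=100)

    def test_cross_stage_predation_is_stabilising_for_strong_m1(self):
        # gamma1 > d: unstructured always unstable, structured stable at
        # intermediate cross-stage strength
        cfg = two_stage_config(100, 1.0, 1.0, gamma1=1.2, seed=0)
        grid = stability_grid(cfg, [0.0, 0.5], [0.0, 0.5], n_reps=20, seed=3)
        # keep only the matched-strength diagonal of the lattice
        structured = np.diag(grid.proportions)[None, :]
        assert classify_structure_effect(structured, 0.0,
                                         n_reps=20) == "stabilising"

    def test_cross_stage_competition_is_destabilising_for_weak_m1(self):
        # gamma1 < d: unstructured stable, but cross-stage competition builds
        # positive feedback loops and a destabilising mean outlier
        cfg = two_stage_config(100, 1.0, 1.0, gamma1=0.5,
                               cross_type="competition", seed=0)
        grid = stability_grid(cfg, [0.0, 0.5], [0.0, 0.5], n_reps=20, seed=3)
        structured = np.diag(grid.proportions)[None, :]
        unstructured = np.array([[1.0, 1.0]])
        assert classify_structure_effect(structured, unstructured,
                                         n_reps=20) == "destabilising"
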
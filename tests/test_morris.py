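"""Tests for the Morris elementary-effects screening machinery."""

import numpy as np
import pytest

from atosense.model import TCSParameters
from atosense.morris import (
    FEATURES,
    MorrisDesign,
    ParameterSpace,
    aggregate_and_normalise,
    default_space,
    elementary_effects,
    evaluate_feature_map,
    generate_candidate_trajectories,
    rank_parameters,
    select_optimal_trajectories,
    trajectory_distance_matrix,
)


def small_space(k=2):
    names = ("S", "C", "pato", "k_bnd")[:k]
    return ParameterSpace(names, [0.1] * k, [10.0] * k, ("log10",) * k)


class TestDesignAndSpace:
    def test_design_validation(self):
        with pytest.raises(ValueError):
            MorrisDesign(p=3)
        with pytest.raises(ValueError):
            MorrisDesign(R=10, r=20)
        assert MorrisDesign(p=4).delta == pytest.approx(2.0 / 3.0)

    def test_space_validation(self):
        with pytest.raises(ValueError, match="lower < upper"):
            ParameterSpace(("S",), [1.0], [1.0], ("linear",))
        with pytest.raises(ValueError, match="log10"):
            ParameterSpace(("S",), [0.0], [1.0], ("log10",))
        with pytest.raises(ValueError, match="unknown parameter"):
            ParameterSpace(("bogus",), [0.1], [1.0], ("linear",))

    def test_log_scale_midpoint_maps_to_geometric_mean(self):
        space = ParameterSpace(("S",), [1e-3], [1e1], ("log10",))
        assert space.map_unit(np.array([0.5]))[0] == pytest.approx(0.1)

    def test_default_space_covers_the_16_screened_parameters(self):
        space = default_space()
        assert len(space.names) == 16
        assert "k_ap" not in space.names  # swept dose proxy, not screened
        base = TCSParameters()
        from atosense.model import PARAM_FILE_KEYS
        for nm, lo, hi in zip(space.names, space.lower, space.upper):
            nominal = getattr(base, PARAM_FILE_KEYS[nm])
            assert lo == pytest.approx(nominal / 10)
            assert hi == pytest.approx(nominal * 10)


class TestTrajectoryGeneration:
    def test_structure_for_two_parameters(self):
        space = small_space(2)
        design = MorrisDesign(p=4, R=50, r=10, seed=7)
        trajs = generate_candidate_trajectories(space, design)
        assert trajs.shape == (50, 3, 2)
        diffs = np.diff(trajs, axis=1)
        changed = (np.abs(diffs) > 1e-12).sum(axis=2)
        assert np.all(changed == 1)  # one coordinate per step
        steps = np.abs(diffs[np.abs(diffs) > 1e-12])
        np.testing.assert_allclose(steps, design.delta)
        assert trajs.min() >= 0.0 and trajs.max() <= 1.0
        # every coordinate perturbed exactly once per trajectory
        which = np.argmax(np.abs(diffs), axis=2)
        assert np.all(np.sort(which, axis=1) == np.arange(2))

    def test_reproducible_from_seed(self):
        space = small_space(3)
        design = MorrisDesign(p=4, R=20, r=5, seed=11)
        a = generate_candidate_trajectories(space, design)
        b = generate_candidate_trajectories(space, design)
        assert a.tobytes() == b.tobytes()

    def test_first_perturbed_coordinate_is_uniform(self):
        space = small_space(3)
        design = MorrisDesign(p=4, R=1000, r=10, seed=5)
        trajs = generate_candidate_trajectories(space, design)
        first = np.argmax(np.abs(trajs[:, 1] - trajs[:, 0]), axis=1)
        freqs = np.bincount(first, minlength=3) / len(first)
        np.testing.assert_allclose(freqs, 1 / 3, atol=0.03)


class TestSelection:
    def test_selecting_all_returns_candidates_unchanged(self):
        space = small_space(2)
        trajs = generate_candidate_trajectories(space, MorrisDesign(p=4, R=6, r=6, seed=0))
        out = select_optimal_trajectories(trajs, 6)
        assert out.tobytes() == trajs.tobytes()

    def test_requesting_too_many_raises(self):
        space = small_space(2)
        trajs = generate_candidate_trajectories(space, MorrisDesign(p=4, R=4, r=4, seed=0))
        with pytest.raises(ValueError, match="cannot select"):
            select_optimal_trajectories(trajs, 5)

    def test_duplicate_trajectories_not_both_kept(self):
        space = small_space(2)
        trajs = generate_candidate_trajectories(space, MorrisDesign(p=4, R=6, r=6, seed=3))
        cands = np.concatenate([trajs, trajs[:1]])  # candidate 6 duplicates 0
        _, idx = select_optimal_trajectories(cands, 3, return_indices=True)
        assert not {0, 6} <= set(idx)

    def test_greedy_beats_random_subsets_on_larger_instance(self, rng):
        # beyond the enumeration cutoff the search is heuristic; it should
        # at least dominate random subsets of the same size
        from atosense.morris import _spread

        cands = rng.uniform(size=(60, 4, 3))
        D = trajectory_distance_matrix(cands)
        D2 = D * D
        _, idx = select_optimal_trajectories(cands, 6, return_indices=True)
        chosen = _spread(D2, np.asarray(idx))
        for _ in range(200):
            rand = rng.choice(60, size=6, replace=False)
            assert chosen >= _spread(D2, rand) - 1e-12


class TestElementaryEffects:
    def test_constant_output_gives_zero_effects(self):
        space = small_space(3)
        design = MorrisDesign(p=4, R=5, r=5, seed=2)
        trajs = generate_candidate_trajectories(space, design)
        for T in trajs:
            ee = elementary_effects(T, np.ones(4), design.delta)
            np.testing.assert_allclose(ee, 0.0)

    def test_linear_function_recovers_coefficients_with_zero_sigma(self):
        space = small_space(4)
        design = MorrisDesign(p=4, R=8, r=8, seed=9)
        trajs = generate_candidate_trajectories(space, design)
        coefs = np.array([3.0, -2.0, 0.5, 0.0])
        ee = np.stack([
            elementary_effects(T, T @ coefs, design.delta) for T in trajs
        ])
        res = aggregate_and_normalise(ee, space.names, outputs=("y",))
        np.testing.assert_allclose(res.mu[:, 0], coefs, atol=1e-12)
        np.testing.assert_allclose(res.mu_star[:, 0], np.abs(coefs), atol=1e-12)
        np.testing.assert_allclose(res.sigma[:3, 0], 0.0, atol=1e-12)

    def test_interaction_term_produces_effect_dispersion(self):
        space = small_space(2)
        design = MorrisDesign(p=4, R=12, r=12, seed=4)
        trajs = generate_candidate_trajectories(space, design)
        ee = np.stack([
            elementary_effects(T, T[:, 0] * T[:, 1], design.delta) for T in trajs
        ])
        res = aggregate_and_normalise(ee, space.names, outputs=("y",))
        assert res.sigma[0, 0] > 0 and res.sigma[1, 0] > 0

    def test_missing_endpoint_marks_effect_missing_not_zero(self):
        space = small_space(2)
        design = MorrisDesign(p=4, R=1, r=1, seed=1)
        T = generate_candidate_trajectories(space, design)[0]
        y = np.array([1.0, np.nan, 2.0])
        ee = elementary_effects(T, y, design.delta)
        assert np.isnan(ee).sum() == 2  # both steps touch the missing point


class TestAggregation:
    def test_two_effect_arithmetic(self):
        ee = np.array([[[1.0]], [[-1.0]]])  # r=2, k=1, one output
        res = aggregate_and_normalise(ee, ("S",), outputs=("y",))
        assert res.mu[0, 0] == pytest.approx(0.0)
        assert res.mu_star[0, 0] == pytest.approx(1.0)
        assert res.sigma[0, 0] == pytest.approx(np.sqrt(2.0))

    def test_normalised_columns_attain_one_and_stay_in_unit_interval(self, rng):
        ee = rng.normal(size=(6, 5, 3))
        res = aggregate_and_normalise(ee, tuple("abcde"), outputs=("u", "v", "w"))
        assert np.all(res.mu_star >= np.abs(res.mu) - 1e-12)
        assert np.all(res.mu_star_normalised <= 1.0 + 1e-12)
        np.testing.assert_allclose(res.mu_star_normalised.max(axis=0), 1.0)

    def test_missing_effects_excluded_with_counts(self):
        ee = np.array([[[1.0]], [[np.nan]], [[3.0]]])
        res = aggregate_and_normalise(ee, ("S",), outputs=("y",))
        assert res.n_effects[0, 0] == 2
        assert res.mu[0, 0] == pytest.approx(2.0)

    def test_cell_with_fewer_than_two_effects_is_an_error(self):
        ee = np.array([[[1.0]], [[np.nan]], [[np.nan]]])
        with pytest.raises(ValueError, match="fewer than 2"):
            aggregate_and_normalise(ee, ("S",), outputs=("y",))


class TestRanking:
    def test_tie_breaks_by_sigma_then_name(self):
        from atosense.morris import MorrisResult

        res = MorrisResult(
            parameters=("a", "b", "c"),
            outputs=("y",),
            mu=np.array([[1.0], [0.5], [0.5]]),
            mu_star=np.array([[1.0], [0.8], [0.8]]),
            sigma=np.array([[0.1], [0.9], [0.2]]),
            n_effects=np.full((3, 1), 5),
        )
        assert rank_parameters(res)["y"] == ["a", "b", "c"]

    def test_excluding_all_but_one_makes_it_top(self):
        from atosense.morris import MorrisResult

        res = MorrisResult(
            parameters=("a", "b", "c"),
            outputs=("y",),
            mu=np.array([[1.0], [2.0], [3.0]]),
            mu_star=np.array([[1.0], [2.0], [3.0]]),
            sigma=np.zeros((3, 1)),
            n_effects=np.full((3, 1), 5),
        )
        assert rank_parameters(res, exclude=("b", "c"))["y"] == ["a"]
        with pytest.raises(ValueError, match="unknown"):
            rank_parameters(res, exclude=("zz",))


class TestFeatureMap:
    def test_same_point_twice_gives_identical_features(self, default_params):
        space = small_space(2)
        pt = np.array([0.5, 0.5])
        grid = np.concatenate([[0.0], np.logspace(-3, 1, 8)])
        feats = evaluate_feature_map(
            np.stack([pt, pt]), space, default_params, grid
        )
        assert feats.shape == (2, len(FEATURES))
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_equal_leaky_and_induced_transcription_flattens_fold_change(
        self, default_params
    ):
        space = small_space(2)  # S and C only; transcription rates from base
        base = default_params.replace(k_pmgexp=default_params.k_lgexp)
        grid = np.concatenate([[0.0], np.logspace(-3, 1, 8)])
        feats = evaluate_feature_map(
            np.array([[0.2, 0.8], [0.7, 0.3]]), space, base, grid
        )
        fold = feats[:, FEATURES.index("fold_change")]
        np.testing.assert_allclose(fold, 1.0, atol=0.01)
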
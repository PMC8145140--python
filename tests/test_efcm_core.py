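"""Unit and property tests for the EFCM clustering core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fuzzyhotspots import (EFCMConfig, EFCMState, EventSet, PartitionMatrix,
                           compute_center, compute_covariance, compute_radius,
                           enlarge_radius, merge_step, prototype_distance,
                           run_efcm, similarity_matrix, update_memberships)
from fuzzyhotspots.efcm_core import (ClusterPrototype, ConfigError,
                                     DegenerateClusterError,
                                     InvalidCovarianceError,
                                     most_similar_pair)


def _partition(u):
    return PartitionMatrix(np.asarray(u, dtype=float))


# ---------------------------------------------------------------------------
# prototype estimation
# ---------------------------------------------------------------------------

class TestCenter:
    def test_uniform_weights_give_centroid(self, square_events):
        n = square_events.n_points
        part = _partition(np.full((2, n), 0.5))
        center = compute_center(part, square_events, m=2.0, i=0)
        assert np.allclose(center, square_events.points.mean(axis=0))

    def test_single_point_membership_returns_that_point(self):
        events = EventSet(np.array([[1.0, 2.0], [5.0, 5.0], [9.0, 1.0]]))
        part = _partition([[1, 0, 0], [0, 1, 1]])
        assert np.allclose(compute_center(part, events, 2.0, 0), [1.0, 2.0])

    def test_fuzzifier_weighting_hand_computed(self):
        # u = (0.8, 0.2), m = 2 on x-coords (0, 2): 2*0.04/(0.64+0.04)
        events = EventSet(np.array([[0.0, 0.0], [2.0, 0.0]]))
        part = _partition([[0.8, 0.2], [0.2, 0.8]])
        center = compute_center(part, events, 2.0, 0)
        assert center[0] == pytest.approx(0.11764705882, abs=1e-9)

    def test_zero_mass_row_raises(self):
        events = EventSet(np.array([[0.0, 0.0], [2.0, 0.0]]))
        part = _partition([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(DegenerateClusterError):
            compute_center(part, events, 2.0, 0)


class TestCovariance:
    def test_zero_when_all_points_at_center(self):
        events = EventSet(np.array([[3.0, 4.0], [3.0, 4.0]]))
        part = _partition(np.full((1, 2), 1.0))
        cov = compute_covariance(part, events, np.array([3.0, 4.0]), 2.0, 0)
        assert np.allclose(cov, 0.0)

    def test_two_symmetric_points_hand_computed(self):
        events = EventSet(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        part = _partition(np.full((1, 2), 1.0))
        cov = compute_covariance(part, events, np.zeros(2), 2.0, 0)
        assert np.allclose(cov, np.diag([1.0, 0.0]))

    def test_symmetric_for_random_inputs(self, rng):
        events = EventSet(rng.normal(size=(30, 2)))
        u = rng.random((3, 30))
        u /= u.sum(axis=0)
        part = _partition(u)
        center = compute_center(part, events, 2.0, 1)
        cov = compute_covariance(part, events, center, 2.0, 1)
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-12)


class TestRadius:
    @pytest.mark.parametrize("mode", ["as-printed", "half"])
    def test_identity_covariance_gives_unit_radius(self, mode):
        assert compute_radius(np.eye(2), mode) == pytest.approx(1.0)

    def test_as_printed_is_sqrt_det(self):
        assert compute_radius(np.diag([4.0, 1.0]), "as-printed") == \
            pytest.approx(2.0)

    def test_half_mode_is_fourth_root(self):
        assert compute_radius(np.diag([4.0, 1.0]), "half") == \
            pytest.approx(2.0 ** 0.5)

    def test_rank_deficient_covariance_gives_zero(self):
        assert compute_radius(np.diag([2.0, 0.0]), "as-printed") == 0.0

    def test_negative_determinant_rejected(self):
        with pytest.raises(InvalidCovarianceError):
            compute_radius(np.array([[0.0, 1.0], [1.0, 0.0]]), "as-printed")


class TestRadiusEnlargement:
    def test_full_beta_leaves_radius_unchanged(self):
        assert enlarge_radius(7.5, beta=5, n_clusters=5) == 7.5

    def test_fractional_schedule(self):
        assert enlarge_radius(10.0, beta=1, n_clusters=5) == pytest.approx(2.0)

    def test_linear_in_beta(self):
        values = [enlarge_radius(6.0, b, 6) for b in range(1, 7)]
        assert np.allclose(np.diff(values), values[0])


class TestPrototypeDistance:
    def test_outside_circle(self):
        proto = ClusterPrototype(center=np.zeros(2), radius=2.0,
                                 covariance=np.eye(2))
        assert prototype_distance([5.0, 0.0], proto) == pytest.approx(3.0)

    @pytest.mark.parametrize("point", [[1.0, 0.0], [2.0, 0.0], [0.0, 0.0]])
    def test_inside_or_on_boundary_is_zero(self, point):
        proto = ClusterPrototype(center=np.zeros(2), radius=2.0,
                                 covariance=np.eye(2))
        assert prototype_distance(point, proto) == 0.0


# ---------------------------------------------------------------------------
# membership update
# ---------------------------------------------------------------------------

class TestMembershipUpdate:
    def test_single_cluster_gets_full_membership(self):
        part = update_memberships(np.array([[3.0, 0.5]]), m=2.0)
        assert np.allclose(part.u, 1.0)

    def test_point_inside_one_cluster(self):
        delta = np.array([[0.0], [4.0], [2.0]])
        part = update_memberships(delta, m=2.0)
        assert np.allclose(part.u[:, 0], [1.0, 0.0, 0.0])

    def test_point_inside_two_clusters_splits_evenly(self):
        delta = np.array([[0.0], [0.0], [3.0]])
        part = update_memberships(delta, m=2.0)
        assert np.allclose(part.u[:, 0], [0.5, 0.5, 0.0])

    def test_equal_positive_distances_split_evenly(self):
        part = update_memberships(np.array([[2.0], [2.0]]), m=2.0)
        assert np.allclose(part.u[:, 0], [0.5, 0.5])

    def test_tiny_distance_takes_all_mass(self):
        # distances so small the inverse-power weights overflow
        delta = np.array([[1e-300], [1.0]])
        part = update_memberships(delta, m=2.0)
        assert np.allclose(part.u[:, 0], [1.0, 0.0])

    @given(delta=arrays(np.float64, (3, 5),
                        elements=st.floats(0.01, 100.0)),
           m=st.floats(1.2, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_columns_always_sum_to_one(self, delta, m):
        part = update_memberships(delta, m=m)
        assert np.allclose(part.u.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(part.u >= 0)

    def test_matches_numeric_constrained_minimizer(self, rng):
        """The closed-form update minimizes sum_i u^m delta^2 per column."""
        from scipy.optimize import minimize
        for _ in range(5):
            c, n = int(rng.integers(2, 4)), int(rng.integers(2, 7))
            m = float(rng.uniform(1.5, 3.0))
            delta = rng.uniform(0.1, 5.0, size=(c, n))
            u = update_memberships(delta, m).u
            j = int(rng.integers(0, n))
            d2 = delta[:, j] ** 2
            res = minimize(lambda v: np.sum(np.abs(v) ** m * d2),
                           np.full(c, 1.0 / c), method="SLSQP",
                           bounds=[(0, 1)] * c,
                           constraints=[{"type": "eq",
                                         "fun": lambda v: v.sum() - 1}],
                           options={"ftol": 1e-14, "maxiter": 500})
            assert res.success
            assert np.allclose(res.x, u[:, j], atol=1e-6)


# ---------------------------------------------------------------------------
# similarity and merging
# ---------------------------------------------------------------------------

class TestSimilarity:
    def test_identical_rows_are_fully_similar(self):
        part = _partition([[0.5, 0.3], [0.5, 0.3], [0.0, 0.4]])
        s = similarity_matrix(part)
        assert s[0, 1] == pytest.approx(1.0)

    def test_disjoint_supports_have_zero_similarity(self):
        part = _partition([[1.0, 0.0], [0.0, 1.0]])
        assert similarity_matrix(part)[0, 1] == 0.0

    def test_inclusion_not_overlap(self):
        # the smaller profile is fully contained in the larger: S = 1
        part = _partition([[0.5, 0.5], [0.25, 0.25], [0.25, 0.25]])
        assert similarity_matrix(part)[0, 1] == pytest.approx(1.0)

    @given(u_raw=arrays(np.float64, (4, 6), elements=st.floats(0.01, 1.0)))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_with_unit_interval_entries(self, u_raw):
        u = u_raw / u_raw.sum(axis=0)
        s = similarity_matrix(_partition(u))
        assert np.allclose(s, s.T)
        assert np.all((s >= 0) & (s <= 1 + 1e-12))

    def test_degenerate_cluster_rejected(self):
        u = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(DegenerateClusterError):
            similarity_matrix(PartitionMatrix(u))

    def test_tie_breaks_to_lowest_pair(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 0.7
        s[1, 2] = s[2, 1] = 0.7
        assert most_similar_pair(s)[:2] == (0, 1)


class TestMergeStep:
    @staticmethod
    def _state(u, beta=1, s_star_prev=0.9):
        return EFCMState(partition=_partition(u), prototypes=[], beta=beta,
                         s_star_prev=s_star_prev)

    def test_merge_is_row_addition(self):
        u = [[0.3, 0.6], [0.2, 0.1], [0.5, 0.3]]
        sim = np.zeros((3, 3))
        sim[0, 1] = sim[1, 0] = 0.9
        new, merged = merge_step(self._state(u), sim, eta=0.05)
        assert merged
        assert np.allclose(new.partition.u[0], [0.5, 0.7])

    def test_merge_decrements_cluster_count_by_one(self):
        u = [[0.3, 0.6], [0.2, 0.1], [0.5, 0.3]]
        sim = np.zeros((3, 3))
        sim[0, 1] = sim[1, 0] = 0.9
        new, merged = merge_step(self._state(u), sim, eta=0.05)
        assert new.partition.n_clusters == 2

    def test_merge_preserves_column_sums(self, rng):
        u = rng.random((4, 8))
        u /= u.sum(axis=0)
        sim = similarity_matrix(_partition(u))
        _, _, s_star = most_similar_pair(sim)
        new, merged = merge_step(self._state(u, s_star_prev=s_star), sim,
                                 eta=0.05)
        assert merged  # alpha = 1/3 and random overlapping rows exceed it
        assert np.allclose(new.partition.u.sum(axis=0), 1.0, atol=1e-12)

    def test_no_merge_when_similarity_not_stable(self):
        u = [[0.3, 0.6], [0.2, 0.1], [0.5, 0.3]]
        sim = np.zeros((3, 3))
        sim[0, 1] = sim[1, 0] = 0.9
        new, merged = merge_step(self._state(u, s_star_prev=0.2), sim,
                                 eta=0.05)
        assert not merged and new.partition.n_clusters == 3

    def test_alpha_guard_blocks_merge_to_single_cluster(self):
        # at C = 2, alpha = 1 and similarity can never exceed it
        u = [[0.5, 0.5], [0.5, 0.5]]
        sim = np.zeros((2, 2))
        sim[0, 1] = sim[1, 0] = 1.0
        new, merged = merge_step(self._state(u, s_star_prev=1.0), sim,
                                 eta=0.05)
        assert not merged and new.partition.n_clusters == 2

    def test_beta_increment_below_threshold_pseudocode_mode(self):
        u = [[0.4, 0.1, 0.4], [0.3, 0.45, 0.3], [0.3, 0.45, 0.3]]
        sim = np.zeros((3, 3))
        sim[0, 1] = sim[1, 0] = 0.3  # below alpha = 0.5
        new, merged = merge_step(self._state(u, beta=1, s_star_prev=0.3),
                                 sim, eta=0.05, beta_update_mode="pseudocode")
        assert not merged and new.beta == 2


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

class TestRunEFCM:
    def test_recovers_two_separated_blobs(self, two_blob_run):
        cfg, events, _labels, result = two_blob_run
        assert result.converged
        assert result.n_clusters == 2
        means = np.array([c.mean for c in cfg.clusters])
        centers = np.array([p.center for p in result.prototypes])
        d = np.linalg.norm(centers[:, None, :] - means[None, :, :], axis=2)
        matched = d.argmin(axis=0)
        assert set(matched) == {0, 1}
        assert np.all(d[matched, [0, 1]] < 0.5 * cfg.clusters[0].std)

    def test_identical_seed_gives_identical_trace(self, two_blob_run):
        cfg, events, _labels, result = two_blob_run
        again = run_efcm(events, result.config)
        assert len(again.trace) == len(result.trace)
        for a, b in zip(again.trace, result.trace):
            assert a == b
        assert np.array_equal(again.partition.u, result.partition.u)

    def test_final_partition_columns_sum_to_one(self, two_blob_run):
        *_, result = two_blob_run
        assert np.allclose(result.partition.u.sum(axis=0), 1.0, atol=1e-9)

    def test_cluster_count_non_increasing(self, two_blob_run):
        *_, result = two_blob_run
        counts = [rec.n_clusters for rec in result.trace]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_beta_non_decreasing_at_fixed_cluster_count(self, two_blob_run):
        *_, result = two_blob_run
        for a, b in zip(result.trace, result.trace[1:]):
            if a.n_clusters == b.n_clusters:
                assert b.beta >= a.beta

    def test_too_few_points_rejected(self):
        events = EventSet(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        with pytest.raises(ConfigError):
            run_efcm(events, EFCMConfig(c0=4))

    def test_iteration_cap_flags_unconverged(self, rng):
        events = EventSet(rng.normal(size=(50, 2)) * 100)
        cfg = EFCMConfig(c0=4, max_iterations=2, rng_seed=0)
        result = run_efcm(events, cfg)
        assert not result.converged
        assert len(result.trace) == 2


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"m": 1.0}, {"epsilon": 0.0}, {"eta": -1.0}, {"c0": 1},
        {"radius_exponent_mode": "cubed"}, {"beta_update_mode": "magic"},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            EFCMConfig(**kwargs)
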
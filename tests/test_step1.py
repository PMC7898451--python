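import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellsorter.step1 import (
    StepOneState,
    assignment_cost,
    fit_marker_params,
    run_step1,
    step1_total_cost,
    update_assignments,
    update_nonmarker_centroids,
)
from conftest import make_instance, single_marker_instance
from oracles import (
    exact_gene_cost,
    exact_gene_cost_full,
    global_optimum,
    lloyd_kmeans,
    random_tiny_instance,
)


def make_state(instance, assignment, mu_base=None, delta=None, centroids=None):
    g, h, K = instance.g, instance.h, instance.K
    return StepOneState(
        assignment=np.asarray(assignment, int),
        mu_base=np.zeros(g) if mu_base is None else np.asarray(mu_base, float),
        delta=np.zeros((g, K)) if delta is None else np.asarray(delta, float),
        mu_nonmarker=(
            np.zeros((h, K)) if centroids is None else np.asarray(centroids, float)
        ),
    )


def attained_gene_cost(instance, assignment, gene, mu, delta):
    """Objective contribution of one marker gene at given parameters."""
    x = instance.x_marker[gene]
    gamma = instance.spec.gamma[gene]
    w = instance.spec.weights[gene]
    total = 0.0
    for j in range(instance.N):
        k = assignment[j]
        base = (x[j] - mu) ** 2
        if gamma[k]:
            base = min(base, (x[j] - mu - delta[k]) ** 2)
        total += w[k] * base
    return total


class TestAssignmentCost:
    def test_zero_distance_nonmarker(self):
        inst = single_marker_instance([1.0, 1.0], [True, True], [1.0, 1.0],
                                      extra_nonmarker=[2.0, 2.0])
        state = make_state(inst, [0, 1], mu_base=[1.0, 0.0],
                           centroids=[[2.0, 2.0]])
        # all genes exactly at their cluster parameters
        assert assignment_cost(inst, state, 0, 0) == pytest.approx(0.0)

    def test_base_level_exact_match_costs_nothing(self):
        inst = single_marker_instance([3.0, 0.0], [True, False], [1.0, 1.0])
        state = make_state(inst, [0, 1], mu_base=[3.0, 0.0],
                           delta=[[5.0, 0.0], [0.0, 0.0]],
                           centroids=[[1.0, 1.0]])
        # x equals mu exactly: min((x-mu-delta)^2, 0) = 0 despite delta > 0
        assert assignment_cost(inst, state, 0, 0) == pytest.approx(0.0)

    def test_min_of_squares_worked_value(self):
        # w=2, x=3, mu=1, delta=1 -> 2 * min((3-2)^2, (3-1)^2) = 2
        inst = single_marker_instance([3.0, 0.0], [True, False], [2.0, 2.0],
                                      extra_nonmarker=[1.0, 1.0])
        state = make_state(inst, [0, 1], mu_base=[1.0, 0.0],
                           delta=[[1.0, 0.0], [0.0, 0.0]],
                           centroids=[[1.0, 1.0]])
        assert assignment_cost(inst, state, 0, 0) == pytest.approx(2.0)

    def test_cluster_out_of_range(self):
        inst = single_marker_instance([1.0, 2.0], [True, True], [1.0, 1.0])
        state = make_state(inst, [0, 1])
        with pytest.raises(IndexError):
            assignment_cost(inst, state, 0, 5)


class TestUpdateAssignments:
    def test_already_optimal_assignment_is_fixed_point(self, separable_instance):
        inst, truth = separable_instance
        state = run_step1(inst, seed=0)
        again = update_assignments(inst, state)
        np.testing.assert_array_equal(again.assignment, state.assignment)

    def test_identical_clusters_tie_break_to_first(self):
        inst = single_marker_instance([1.0, 2.0, 3.0], [True, True],
                                      [1.0, 1.0])
        state = make_state(inst, [0, 1, 0])  # both clusters same parameters
        new = update_assignments(inst, state)
        assert set(new.assignment) == {0}

    @pytest.mark.parametrize("seed", range(10))
    def test_never_increases_objective(self, seed):
        rng = np.random.default_rng(seed)
        inst, _ = random_tiny_instance(rng, N=8, K=2, g=2, h=3)
        state = make_state(
            inst,
            rng.integers(0, 2, 8),
            mu_base=rng.normal(1, 1, 2),
            delta=np.abs(rng.normal(0, 1, (2, 2))),
            centroids=rng.normal(1, 1, (3, 2)),
        )
        before = step1_total_cost(inst, state)
        after = step1_total_cost(inst, update_assignments(inst, state))
        assert after <= before + 1e-9


class TestNonmarkerCentroids:
    def test_centroid_is_arithmetic_mean(self):
        inst = single_marker_instance([0.0] * 4, [True, True], [1.0, 1.0],
                                      extra_nonmarker=[2.0, 4.0, 7.0, 7.0])
        state = make_state(inst, [0, 0, 1, 1])
        new = update_nonmarker_centroids(inst, state)
        assert new.mu_nonmarker[0, 0] == pytest.approx(3.0)
        assert new.mu_nonmarker[0, 1] == pytest.approx(7.0)

    def test_singleton_and_empty_cluster(self):
        inst = single_marker_instance([0.0, 0.0], [True, True], [1.0, 1.0],
                                      extra_nonmarker=[5.0, 9.0])
        state = make_state(inst, [0, 0], centroids=[[1.0, 42.0]])
        new = update_nonmarker_centroids(inst, state)
        assert new.mu_nonmarker[0, 0] == pytest.approx(7.0)
        assert new.mu_nonmarker[0, 1] == 42.0  # empty cluster untouched

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        inst, _ = random_tiny_instance(rng, N=8, K=2, g=2, h=3)
        state = make_state(inst, rng.integers(0, 2, 8))
        once = update_nonmarker_centroids(inst, state)
        twice = update_nonmarker_centroids(inst, once)
        np.testing.assert_allclose(once.mu_nonmarker, twice.mu_nonmarker)


class TestFitMarkerParams:
    def test_worked_case_exact(self):
        # own-type values {0,0,4,4}, other cluster {0,0}: mu=0, delta=4
        inst = single_marker_instance([0, 0, 4, 4, 0, 0], [True, False],
                                      [1.0, 1.0])
        mu, delta = fit_marker_params(inst, np.array([0, 0, 0, 0, 1, 1]), 0)
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert delta[0] == pytest.approx(4.0, abs=1e-12)
        assert delta[1] == 0.0

    def test_constant_gene_gives_zero_elevation(self):
        inst = single_marker_instance([2.0] * 6, [True, False], [1.0, 1.0])
        mu, delta = fit_marker_params(inst, np.array([0, 0, 0, 1, 1, 1]), 0)
        assert mu == pytest.approx(2.0)
        np.testing.assert_allclose(delta, 0.0)

    def test_weight_scaling_invariance(self):
        x = np.array([0.1, 0.5, 3.0, 3.5, 0.2, 0.4])
        a = np.array([0, 0, 0, 0, 1, 1])
        r1 = fit_marker_params(
            single_marker_instance(x, [True, False], [1.0, 1.0]), a, 0)
        r2 = fit_marker_params(
            single_marker_instance(x, [True, False], [2.0, 2.0]), a, 0)
        assert r1[0] == pytest.approx(r2[0])
        np.testing.assert_allclose(r1[1], r2[1])

    def test_delta_always_nonnegative_and_matches_subset_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            x = rng.normal(0, 2, 8)
            x -= x.min() - 0.1
            a = rng.integers(0, 2, 8)
            gamma_row = [True, bool(rng.random() < 0.5)]
            w_row = [2.0, 2.0]
            inst = single_marker_instance(x, gamma_row, w_row)
            mu, delta = fit_marker_params(inst, a, 0)
            assert np.all(delta >= 0)
            attained = attained_gene_cost(inst, a, 0, mu, delta)
            expected = exact_gene_cost(x, a, 2, np.array(gamma_row),
                                       np.array(w_row))
            assert attained == pytest.approx(expected, abs=1e-8)

    def test_topm_reduction_equals_full_subset_enumeration(self):
        # certifies the oracle itself: top-m elevated sets lose nothing
        rng = np.random.default_rng(5)
        for _ in range(30):
            x = rng.normal(0, 2, 6)
            a = rng.integers(0, 2, 6)
            gamma_row = np.array([True, bool(rng.random() < 0.5)])
            w_row = np.array([2.0, 3.0])
            fast = exact_gene_cost(x, a, 2, gamma_row, w_row)
            full = exact_gene_cost_full(x, a, 2, gamma_row, w_row)
            assert fast == pytest.approx(full, abs=1e-9)


class TestTotalCost:
    def test_perfect_fit_costs_zero(self):
        inst = single_marker_instance([5.0, 0.0], [True, False], [2.0, 2.0],
                                      extra_nonmarker=[1.0, 3.0])
        state = make_state(inst, [0, 1], mu_base=[0.0, 0.0],
                           delta=[[5.0, 0.0], [0.0, 0.0]],
                           centroids=[[1.0, 3.0]])
        assert step1_total_cost(inst, state) == pytest.approx(0.0)

    def test_no_markers_reduces_to_kmeans_ss(self):
        x = np.array([[1.0, 2.0, 10.0, 11.0]])
        inst = make_instance(x, np.zeros((0, 2), bool), np.zeros((0, 2)), g=0)
        state = make_state(inst, [0, 0, 1, 1], centroids=[[1.5, 10.5]])
        assert step1_total_cost(inst, state) == pytest.approx(0.5 + 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_decomposes_into_per_cell_assignment_costs(self, seed):
        rng = np.random.default_rng(seed)
        inst, _ = random_tiny_instance(rng, N=8, K=2, g=2, h=3)
        state = make_state(
            inst,
            rng.integers(0, 2, 8),
            mu_base=rng.normal(1, 1, 2),
            delta=np.abs(rng.normal(0, 1, (2, 2))),
            centroids=rng.normal(1, 1, (3, 2)),
        )
        total = step1_total_cost(inst, state)
        decomposed = sum(
            assignment_cost(inst, state, j, state.assignment[j])
            for j in range(inst.N)
        )
        assert total == pytest.approx(decomposed, rel=1e-9)


class TestRunStep1:
    def test_single_cluster(self):
        inst = single_marker_instance([1.0, 2.0, 3.0], [True], [1.0])
        state = run_step1(inst, seed=0)
        assert set(state.assignment) == {0} and state.converged

    def test_fewer_cells_than_types_errors(self):
        inst = single_marker_instance([1.0], [True, True], [1.0, 1.0])
        with pytest.raises(ValueError, match="fewer cells"):
            run_step1(inst, seed=0)

    def test_separable_toy_recovers_truth(self, separable_instance):
        inst, truth = separable_instance
        best = min((run_step1(inst, seed=s) for s in range(10)),
                   key=lambda s: s.cost)
        # labels may be permuted only if markers were symmetric; they are not
        np.testing.assert_array_equal(best.assignment, truth)

    def test_separable_toy_attains_enumerated_optimum(self, separable_instance):
        inst, truth = separable_instance
        opt_cost, opt_assign = global_optimum(inst)
        np.testing.assert_array_equal(opt_assign, truth)
        best = min(run_step1(inst, seed=s).cost for s in range(10))
        assert best == pytest.approx(opt_cost, abs=1e-6)

    def test_seeded_determinism(self, separable_instance):
        inst, _ = separable_instance
        a = run_step1(inst, seed=7)
        b = run_step1(inst, seed=7)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        np.testing.assert_array_equal(a.mu_base, b.mu_base)
        np.testing.assert_array_equal(a.delta, b.delta)
        assert a.cost == b.cost and a.cost_trace == b.cost_trace

    @pytest.mark.parametrize("seed", range(8))
    def test_cost_trace_monotone_and_delta_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        inst, _ = random_tiny_instance(rng, N=10, K=2, g=3, h=3)
        state = run_step1(inst, seed=seed)
        trace = np.array(state.cost_trace)
        assert np.all(np.diff(trace) <= 1e-7 * (1 + np.abs(trace[:-1])))
        assert np.all(state.delta >= 0)
        assert state.cost == pytest.approx(
            step1_total_cost(inst, state), rel=1e-9)

    def test_kmeans_reduction_matches_lloyd_trajectory(self):
        # no marker genes: the procedure must be exactly Lloyd's algorithm
        rng = np.random.default_rng(2)
        x = np.vstack([
            np.concatenate([rng.normal(0, 1, 6), rng.normal(5, 1, 6)]),
            np.concatenate([rng.normal(2, 1, 6), rng.normal(-3, 1, 6)]),
        ])
        inst = make_instance(x, np.zeros((0, 2), bool), np.zeros((0, 2)), g=0)
        init = rng.integers(0, 2, 12)
        state = run_step1(inst, seed=0, init_assignment=init)
        _, lloyd_trace = lloyd_kmeans(x, init)
        np.testing.assert_allclose(state.cost_trace, lloyd_trace, rtol=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_objective_nonnegative_and_monotone_any_seed(seed):
    rng = np.random.default_rng(seed)
    inst, _ = random_tiny_instance(rng, N=8, K=2, g=2, h=2,
                                   separation=float(rng.uniform(0, 4)))
    state = run_step1(inst, seed=seed % 100)
    trace = np.array(state.cost_trace)
    assert np.all(trace >= -1e-12)
    assert np.all(np.diff(trace) <= 1e-7 * (1 + np.abs(trace[:-1])))
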
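"""Observation reduction, state clustering, BCQ learning, policy heatmaps."""

import numpy as np
import pandas as pd
import pytest

from healthgym.schema import (
    CohortSchema,
    LongitudinalDataset,
    SchemaError,
    VariableSpec,
)
from healthgym.simulator import default_config, simulate_cohort
from healthgym.utility import (
    ObservationReducer,
    PolicyHeatmap,
    RLProblemSpec,
    TransitionBatch,
    action_heatmap,
    bcq_train,
    build_transitions,
    cluster_states,
    compare_heatmaps,
    default_problem,
    discretize_actions,
    n_actions_of,
    plain_q_train,
    reward_hiv,
    reward_hypotension,
    verify_utility,
)


class TestProblemSpecs:
    def test_published_action_space_sizes(self):
        from healthgym.schema import bundled_schema

        hypo = default_problem(bundled_schema("hypotension"))
        assert len(hypo.observation_variables) == 18
        ds = simulate_cohort(default_config("hypotension", 4, seed=0))
        _, lists, _ = discretize_actions(ds, hypo)
        assert n_actions_of(lists) == 16  # 4 x 4

        hiv = default_problem(bundled_schema("hiv"))
        assert len(hiv.observation_variables) == 11
        ds = simulate_cohort(default_config("hiv", 4, seed=0))
        _, lists, _ = discretize_actions(ds, hiv)
        assert n_actions_of(lists) == 24  # 6 x 4

    def test_numeric_actions_quantile_binned_to_four(self):
        from healthgym.schema import bundled_schema

        spec = default_problem(bundled_schema("sepsis"))
        ds = simulate_cohort(default_config("sepsis", 30, seed=1))
        idx, lists, edges = discretize_actions(ds, spec)
        assert n_actions_of(lists) == 16
        assert set(edges) == {"Input 4H", "Max Vaso"}
        assert idx.min() >= 0 and idx.max() < 16

    def test_overlapping_split_rejected(self, toy_schema):
        spec = RLProblemSpec(["alpha", "grade"], ["grade"])
        with pytest.raises(SchemaError, match="overlap"):
            spec.validate(toy_schema)

    def test_first_class_tuple_is_index_zero(self, toy_cohort):
        spec = RLProblemSpec(["alpha", "beta", "gamma"], ["grade", "alpha (M)"])
        idx, lists, _ = discretize_actions(toy_cohort, spec)
        first = (toy_cohort.column("grade") == "low") & (
            toy_cohort.column("alpha (M)") == "False")
        assert np.array_equal(idx == 0, first)
        # mixed-radix bijectivity: decode back
        k2 = len(lists[1])
        codes0 = toy_cohort.coded_column("grade").astype(int)
        codes1 = toy_cohort.coded_column("alpha (M)").astype(int)
        assert np.array_equal(idx, codes0 * k2 + codes1)


class TestObservationReduction:
    def test_full_rank_reduction_preserves_subspace(self, toy_cohort):
        spec = RLProblemSpec(["alpha", "beta", "gamma"], ["grade"],
                             n_state_components=3)
        actions, _, _ = discretize_actions(toy_cohort, spec)
        red = ObservationReducer(spec, toy_cohort.schema)
        scores = red.fit(toy_cohort, actions)
        X = red._obs_matrix(toy_cohort)
        # with as many components as channels, reconstruction is lossless
        beta, _, _, _ = np.linalg.lstsq(scores - scores.mean(0),
                                        X - X.mean(0), rcond=None)
        resid = (X - X.mean(0)) - (scores - scores.mean(0)) @ beta
        r2 = 1 - resid.var() / (X - X.mean(0)).var()
        assert r2 >= 0.999

    def test_rank_deficient_requests_warn(self):
        sch = CohortSchema(
            "thin",
            (VariableSpec("x", "numeric"), VariableSpec("y", "numeric"),
             VariableSpec("a", "binary", classes=("False", "True"))),
            "pid", "t", 4,
        )
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        frame = pd.DataFrame({
            "x": x, "y": 2 * x,  # rank-1 observation block
            "a": rng.choice(["False", "True"], size=40),
            "pid": np.repeat([f"p{i}" for i in range(10)], 4),
            "t": np.tile(range(4), 10),
        })
        ds = LongitudinalDataset(sch, frame)
        spec = RLProblemSpec(["x", "y"], ["a"], n_state_components=5)
        actions, _, _ = discretize_actions(ds, spec)
        red = ObservationReducer(spec, sch)
        with pytest.warns(UserWarning, match="rank"):
            red.fit(ds, actions)

    def test_action_predictive_channel_dominates_first_component(self):
        rng = np.random.default_rng(1)
        n = 400
        sch = CohortSchema(
            "pred",
            (VariableSpec("signal", "numeric"), VariableSpec("noise", "numeric"),
             VariableSpec("act", "binary", classes=("False", "True"))),
            "pid", "t", 1,
        )
        signal = rng.normal(size=n)
        frame = pd.DataFrame({
            "signal": signal, "noise": rng.normal(size=n),
            "act": np.where(signal > 0, "True", "False"),
            "pid": [f"p{i}" for i in range(n)], "t": 0,
        })
        ds = LongitudinalDataset(sch, frame)
        spec = RLProblemSpec(["signal", "noise"], ["act"], n_state_components=2)
        actions, _, _ = discretize_actions(ds, spec)
        red = ObservationReducer(spec, sch)
        red.fit(ds, actions)
        w = np.abs(red.loadings[:, 0])
        assert w[0] == w.max()  # the predictive channel carries component 1


class TestClustering:
    def test_distinct_repeated_points_zero_inertia(self):
        pts = np.repeat(np.arange(20.0).reshape(10, 2), 5, axis=0)
        space = cluster_states(pts, 10, seed=0)
        assert space.inertia == pytest.approx(0.0, abs=1e-12)

    def test_more_clusters_than_points_rejected(self):
        with pytest.raises(SchemaError, match="distinct"):
            cluster_states(np.zeros((5, 2)), 10, seed=0)

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.1, size=(50, 2))
        b = rng.normal(5, 0.1, size=(50, 2))
        space = cluster_states(np.vstack([a, b]), 2, seed=0)
        la, lb = set(space.labels[:50]), set(space.labels[50:])
        assert len(la) == 1 and len(lb) == 1 and la != lb

    def test_out_of_sample_assignment_nearest_centroid(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(60, 2))
        space = cluster_states(pts, 4, seed=0)
        assert np.array_equal(space.assign(pts), space.labels)


class TestTransitions:
    def test_counts(self, toy_cohort):
        spec = RLProblemSpec(["alpha"], ["grade"])
        n, T = toy_cohort.n_patients, 8
        states = np.zeros(n * T, dtype=int)
        actions, _, _ = discretize_actions(toy_cohort, spec)
        batch = build_transitions(toy_cohort, spec, states, actions, 1, 3)
        assert len(batch) == n * (T - 1)
        assert batch.terminal.sum() == n

    def test_empty_dataset(self, toy_schema):
        ds = simulate_cohort(default_config(toy_schema, 0, seed=0))
        spec = RLProblemSpec(["alpha"], ["grade"])
        batch = build_transitions(ds, spec, np.zeros(0, int), np.zeros(0, int), 1, 3)
        assert len(batch) == 0


class TestRewards:
    def test_hypotension_map_rule(self):
        assert reward_hypotension({}, {"MAP": 70.0}, {}) == 1.0
        assert reward_hypotension({}, {"MAP": 65.0}, {}) == 1.0  # >= convention
        assert reward_hypotension({}, {"MAP": 55.0}, {}) == pytest.approx(-1.0)

    def test_hiv_viral_load_rule(self):
        assert reward_hiv({}, {"VL": 100.0}, {}) == 1.0
        assert reward_hiv({}, {"VL": 5000.0}, {}) == pytest.approx(-0.7)

    def test_constant_zero_reward_fixed_point(self):
        # all-zero rewards leave Q identically zero after training
        batch = TransitionBatch(
            state=np.array([0, 1, 0, 1]), action=np.array([0, 1, 1, 0]),
            reward=np.zeros(4), next_state=np.array([1, 0, 1, 0]),
            terminal=np.array([False, True, False, True]),
            n_states=2, n_actions=2,
        )
        spec = RLProblemSpec(["x"], ["a"], n_iterations=100)
        pol = bcq_train(batch, spec)
        assert np.abs(pol.Q).max() == 0.0


def chain_batch(repeats=1):
    """2-state 2-action deterministic chain: action 0 pays 1, action 1 pays 0."""
    s, a, r, ns, term = [], [], [], [], []
    for _ in range(repeats):
        for st in (0, 1):
            for ac in (0, 1):
                s.append(st)
                a.append(ac)
                r.append(1.0 if ac == 0 else 0.0)
                ns.append(1 - st)
                term.append(False)
    return TransitionBatch(np.array(s), np.array(a), np.array(r, float),
                           np.array(ns), np.array(term), 2, 2)


def hand_bcq(batch, gamma, lr, sweeps, eligible):
    Q = np.zeros((2, 2))
    for _ in range(sweeps):
        for s, a, r, ns, term in zip(batch.state, batch.action, batch.reward,
                                     batch.next_state, batch.terminal):
            m = max(Q[ns][k] for k in range(2) if eligible[ns][k])
            tgt = r if term else r + gamma * m
            Q[s, a] += lr * (tgt - Q[s, a])
    return Q


class TestBCQ:
    def test_matches_hand_iteration_on_chain(self):
        batch = chain_batch()
        spec = RLProblemSpec(["x"], ["a"], discount=0.9, n_iterations=100,
                             step_size=0.01)
        pol = bcq_train(batch, spec)
        hand = hand_bcq(batch, 0.9, 0.01, 100,
                        np.ones((2, 2), dtype=bool))
        assert np.abs(pol.Q - hand).max() < 1e-10
        assert np.array_equal(pol.greedy, [0, 0])  # argmax action everywhere

    def test_gamma_zero_converges_to_mean_immediate_reward(self):
        batch = chain_batch(repeats=3)
        spec = RLProblemSpec(["x"], ["a"], discount=0.0, n_iterations=2000,
                             step_size=0.05)
        pol = bcq_train(batch, spec)
        # closed-form fixed point: Q(s,a) -> immediate reward of (s,a)
        expected = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert np.abs(pol.Q - expected).max() < 1e-6

    def test_saturated_constraint_returns_behaviour_majority(self):
        # state 0 mostly plays action 1; a high threshold leaves only it
        s = np.zeros(10, int)
        a = np.array([1] * 8 + [0] * 2)
        batch = TransitionBatch(s, a, np.where(a == 0, 5.0, 0.0), s,
                                np.ones(10, bool), 1, 2)
        spec = RLProblemSpec(["x"], ["a"], bcq_threshold=0.5, n_iterations=50)
        pol = bcq_train(batch, spec)
        assert not pol.eligible[0, 0] and pol.greedy[0] == 1

    def test_threshold_zero_everything_observed_equals_plain_q(self):
        batch = chain_batch(repeats=2)
        spec = RLProblemSpec(["x"], ["a"], bcq_threshold=0.0, discount=0.8,
                             n_iterations=60, step_size=0.02)
        pol = bcq_train(batch, spec)
        assert np.array_equal(pol.Q, plain_q_train(batch, spec))

    def test_greedy_maximises_q_over_eligible(self):
        rng = np.random.default_rng(4)
        n = 300
        batch = TransitionBatch(
            rng.integers(0, 5, n), rng.integers(0, 3, n),
            rng.normal(size=n), rng.integers(0, 5, n),
            rng.random(n) < 0.2, 5, 3,
        )
        spec = RLProblemSpec(["x"], ["a"], n_iterations=30)
        pol = bcq_train(batch, spec)
        for s in range(5):
            if pol.greedy[s] < 0:
                continue
            qs = np.where(pol.eligible[s], pol.Q[s], -np.inf)
            assert pol.Q[s, pol.greedy[s]] == qs.max()

    def test_unvisited_state_policy_undefined(self):
        batch = chain_batch()
        batch = TransitionBatch(batch.state, batch.action, batch.reward,
                                batch.next_state, batch.terminal, 3, 2)
        spec = RLProblemSpec(["x"], ["a"], n_iterations=10)
        pol = bcq_train(batch, spec)
        assert pol.greedy[2] == -1 and pol.n_undefined == 1
        with pytest.raises(SchemaError, match="undefined"):
            pol.action(2)


class TestHeatmaps:
    def test_constant_policy_single_tile(self):
        pol = bcq_train(chain_batch(), RLProblemSpec(["x"], ["a"],
                                                     n_iterations=50))
        states = np.zeros(40, int)
        h = action_heatmap(pol, states, [("a0", "a1"), ("b0",)], ["A", "B"])
        assert h.grid.shape == (2, 1)
        assert h.grid[0, 0] == 100.0 and h.grid.sum() == 100.0

    def test_uniform_sixteen_tiles(self):
        grid = np.full((4, 4), 6.25)
        h = PolicyHeatmap(grid, [tuple("abcd"), tuple("wxyz")], ["r", "c"])
        assert np.allclose(h.flat, 6.25) and h.grid.sum() == pytest.approx(100)

    def test_normalisation_enforced(self):
        with pytest.raises(SchemaError, match="sum"):
            PolicyHeatmap(np.full((2, 2), 10.0), [("a", "b"), ("c", "d")],
                          ["r", "c"])

    def test_manual_tally_three_states(self):
        # greedy: state0 -> action 0, state1 -> action 1, state2 -> action 3
        pol_greedy = np.array([0, 1, 3])
        pol = bcq_train(chain_batch(), RLProblemSpec(["x"], ["a"],
                                                     n_iterations=1))
        pol.greedy = pol_greedy
        states = np.array([0, 0, 1, 2, 2, 2, 1, 0])
        h = action_heatmap(pol, states, [("p", "q"), ("u", "v")], ["A", "B"])
        assert h.grid[0, 0] == pytest.approx(100 * 3 / 8)   # action 0
        assert h.grid[0, 1] == pytest.approx(100 * 2 / 8)   # action 1
        assert h.grid[1, 1] == pytest.approx(100 * 3 / 8)   # action 3

    def test_total_variation_cases(self):
        a = PolicyHeatmap(np.array([[100.0, 0.0]]), [("r",), ("x", "y")],
                          ["R", "C"])
        b = PolicyHeatmap(np.array([[0.0, 100.0]]), [("r",), ("x", "y")],
                          ["R", "C"])
        assert compare_heatmaps(a, a).total_variation == 0.0
        assert compare_heatmaps(a, b).total_variation == 1.0

    def test_hand_summed_tv(self):
        ga = np.array([[60.0, 20.0], [20.0, 0.0]])
        gb = np.array([[20.0, 60.0], [0.0, 20.0]])
        a = PolicyHeatmap(ga, [("1", "2"), ("x", "y")], ["R", "C"])
        b = PolicyHeatmap(gb, [("1", "2"), ("x", "y")], ["R", "C"])
        cmpres = compare_heatmaps(a, b)
        assert cmpres.total_variation == pytest.approx(0.6)
        assert cmpres.largest_gaps[0][0] in ((("1", "x")), (("1", "y")))


class TestEndToEnd:
    def test_real_vs_bootstrap_synthetic_policies_agree(self, toy_cohort_large):
        # a bootstrap resample stands in for a well-trained generator: the
        # two agents should take near-identical actions (desk-scale analogue
        # of the published real-vs-synthetic heatmap agreement)
        rng = np.random.default_rng(5)
        T = toy_cohort_large.schema.timesteps_per_patient
        idx = rng.integers(0, toy_cohort_large.n_patients,
                           toy_cohort_large.n_patients)
        rows = np.concatenate([np.arange(i * T, (i + 1) * T) for i in idx])
        frame = toy_cohort_large.frame.iloc[rows].copy()
        frame["pid"] = np.repeat([f"b{i:04d}" for i in range(len(idx))], T)
        syn = LongitudinalDataset(toy_cohort_large.schema, frame)

        spec = RLProblemSpec(
            ["alpha", "beta", "gamma", "alpha (M)"], ["grade"],
            n_state_components=3, n_clusters=12, reward="zero",
            n_iterations=30,
        )
        report = verify_utility(toy_cohort_large, syn, spec, seed=0)
        assert report.comparison.total_variation <= 0.25
        assert report.heatmap_real.grid.sum() == pytest.approx(100.0, abs=0.01)
        assert report.heatmap_syn.grid.sum() == pytest.approx(100.0, abs=0.01)

    def test_end_to_end_deterministic(self, toy_cohort):
        spec = RLProblemSpec(
            ["alpha", "beta", "gamma", "alpha (M)"], ["grade"],
            n_state_components=2, n_clusters=6, n_iterations=10,
        )
        r1 = verify_utility(toy_cohort, toy_cohort, spec, seed=3)
        r2 = verify_utility(toy_cohort, toy_cohort, spec, seed=3)
        assert np.array_equal(r1.heatmap_real.grid, r2.heatmap_real.grid)
        assert np.array_equal(r1.heatmap_syn.grid, r2.heatmap_syn.grid)
        assert r1.comparison.total_variation == r2.comparison.total_variation
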
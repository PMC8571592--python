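import numpy as np
import pytest
import scipy.stats

import arbormap as am
from arbormap import mk, simmap
from arbormap.treeio import TaxonCharacterTable

from _oracles import enumeration_marginals, jump_count_distribution


class TestNodeStateSampling:
    def test_deterministic_given_seed(self, mapping_fixture):
        f = mapping_fixture
        a = am.sample_joint_node_states(f["tree"], f["table"], f["spec"],
                                        f["params"], "equal",
                                        np.random.default_rng(7))
        b = am.sample_joint_node_states(f["tree"], f["table"], f["spec"],
                                        f["params"], "equal",
                                        np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_tiny_rates_pin_root(self):
        t = am.parse_tree("(A:1,B:1);")
        tbl = TaxonCharacterTable(states={"A": "arboreal", "B": "arboreal"})
        rng = np.random.default_rng(1)
        draws = [
            am.sample_joint_node_states(t, tbl, am.build_model_spec("ard"),
                                        np.full(6, 1e-7), "equal", rng)[t.root]
            for _ in range(200)
        ]
        assert np.mean(np.array(draws) == 0) > 0.99

    def test_sampling_frequencies_match_marginals(self, five_tip_tree, five_tip_table):
        spec = am.build_model_spec("two_rate")
        params = np.array([0.15, 0.07])
        rng = np.random.default_rng(42)
        n = 20000
        counts = np.zeros((five_tip_tree.n_nodes, 3))
        for _ in range(n):
            s = am.sample_joint_node_states(five_tip_tree, five_tip_table,
                                            spec, params, "equal", rng)
            for v in range(five_tip_tree.n_nodes):
                counts[v, s[v] % 3] += 1
        freqs = counts / n
        want = enumeration_marginals(five_tip_tree, five_tip_table, spec, params)
        assert np.max(np.abs(freqs - want)) < 0.01


class TestBranchHistory:
    def test_zero_rate_single_segment(self):
        segs = am.sample_branch_history(1, 1, 4.0, np.zeros((3, 3)),
                                        np.random.default_rng(0))
        assert segs == [(1, 4.0)]

    def test_zero_rate_impossible_endpoints(self):
        with pytest.raises(ValueError):
            am.sample_branch_history(0, 2, 4.0, np.zeros((3, 3)),
                                     np.random.default_rng(0))

    def test_structural_zero_path_forced_through_intermediate(self):
        q = am.assemble_q(am.build_model_spec("four_rate"),
                          [0.3, 0.2, 0.25, 0.15])
        rng = np.random.default_rng(3)
        sampler = simmap.BridgeSampler(q)
        for _ in range(200):
            segs = sampler.sample_path(0, 2, 5.0, rng)
            states = [s for s, _ in segs]
            assert len(segs) >= 3  # A ... S ... N needs >= 2 jumps
            assert 1 in states

    def test_durations_sum_and_adjacent_differ(self):
        q = am.assemble_q(am.build_model_spec("ard"), np.linspace(0.1, 0.6, 6))
        rng = np.random.default_rng(4)
        sampler = simmap.BridgeSampler(q)
        for _ in range(300):
            a, b = rng.integers(3, size=2)
            t = float(rng.uniform(0.1, 8.0))
            segs = sampler.sample_path(int(a), int(b), t, rng)
            assert segs[0][0] == a and segs[-1][0] == b
            assert sum(d for _, d in segs) == pytest.approx(t, abs=1e-9)
            for (s1, _), (s2, _) in zip(segs, segs[1:]):
                assert s1 != s2

    def test_jump_count_distribution_matches_counting_oracle(self):
        q = am.assemble_q(am.build_model_spec("ard"),
                          [0.2, 0.1, 0.15, 0.25, 0.05, 0.3])
        a, b, t = 0, 2, 5.0
        want = jump_count_distribution(q, a, b, t)
        rng = np.random.default_rng(11)
        sampler = simmap.BridgeSampler(q)
        nsamp = 20000
        counts = np.zeros(len(want))
        for _ in range(nsamp):
            counts[len(sampler.sample_path(a, b, t, rng)) - 1] += 1
        exp = want * nsamp
        mask = exp >= 5
        obs = np.append(counts[mask], counts[~mask].sum())
        ex = np.append(exp[mask], exp[~mask].sum())
        _, p = scipy.stats.chisquare(obs, ex * obs.sum() / ex.sum())
        assert p > 0.001

    def test_mean_jumps_match_conditional_expectation(self):
        q = am.assemble_q(am.build_model_spec("ard"), np.full(6, 0.2))
        a = b = 0
        t = 5.0
        want = jump_count_distribution(q, a, b, t)
        expected_mean = float(want @ np.arange(len(want)))
        rng = np.random.default_rng(9)
        sampler = simmap.BridgeSampler(q)
        nsamp = 20000
        jumps = np.array([
            len(sampler.sample_path(a, b, t, rng)) - 1 for _ in range(nsamp)
        ])
        se = jumps.std() / np.sqrt(nsamp)
        assert abs(jumps.mean() - expected_mean) < 2 * se + 1e-9


class TestGenerateMaps:
    def test_zero_maps(self, mapping_fixture):
        f = mapping_fixture
        assert am.generate_maps(f["tree"], f["table"], f["spec"], f["params"],
                                0, seed=1) == []

    def test_map_invariants(self, mapping_fixture):
        f = mapping_fixture
        maps = am.generate_maps(f["tree"], f["table"], f["spec"], f["params"],
                                25, seed=2)
        tree = f["tree"]
        for smap in maps:
            for v in range(tree.n_nodes):
                if v == tree.root:
                    continue
                segs = smap.segments[v]
                assert sum(d for _, d in segs) == pytest.approx(
                    float(tree.edge_length[v]), abs=1e-9)
                assert segs[0][0] == smap.node_states[tree.parent[v]]
                assert segs[-1][0] == smap.node_states[v]
            # tip end states agree with the data
            for v in tree.tip_indices:
                s = f["table"].states[tree.labels[int(v)]]
                assert smap.node_states[int(v)] % 3 == am.STATES.index(s)

    def test_seed_reproducibility(self, mapping_fixture):
        f = mapping_fixture
        a = am.generate_maps(f["tree"], f["table"], f["spec"], f["params"], 5, seed=3)
        b = am.generate_maps(f["tree"], f["table"], f["spec"], f["params"], 5, seed=3)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.node_states, mb.node_states)
            assert ma.segments == mb.segments

    def test_refit_per_tree_records_distinct_q(self, mapping_fixture):
        f = mapping_fixture
        trees = am.perturb_tree_set(f["tree"], 4, branch_jitter_sd=0.15,
                                    n_nni=1, seed=5)
        run = am.generate_maps_over_trees(
            trees, f["table"], f["spec"], 3, seed=6, q_source="refit",
            optimizer=mk.OptimizerConfig(n_restarts=1, seed=0),
        )
        qs = [run.q_by_tree[ti] for ti, _ in run.maps_by_tree]
        assert len(qs) == 4
        for i in range(len(qs)):
            for j in range(i + 1, len(qs)):
                assert not np.allclose(qs[i], qs[j])


class TestCountsAndSummary:
    def test_hand_built_counts(self, toy_tree):
        # history with events A->S on one edge and S->N twice elsewhere
        segs = [()] * toy_tree.n_nodes
        states = np.zeros(toy_tree.n_nodes, dtype=np.int64)
        tips = list(toy_tree.tip_indices)
        inner = [v for v in range(toy_tree.n_nodes)
                 if toy_tree.children[v] and v != toy_tree.root][0]
        segs[inner] = ((0, 0.5), (1, 0.5))
        states[inner] = 1
        segs[tips[0]] = ((1, 0.4), (2, 0.6))
        segs[tips[1]] = ((1, 0.4), (2, 0.6))
        states[tips[0]] = states[tips[1]] = 2
        segs[tips[2]] = ((0, 2.0),)
        smap = simmap.StochasticMap(tree=toy_tree, node_states=states,
                                    segments=tuple(segs))
        tc = am.count_transitions(smap)
        assert tc.counts[0, 1] == 1 and tc.counts[1, 2] == 2
        assert tc.total == 3

    def test_truth_counts_self_consistent(self, mapping_fixture):
        truth = mapping_fixture["truth"]
        tc = am.count_transitions(truth.history)
        assert np.array_equal(tc.counts, truth.transition_counts)

    def test_class_switches_separated(self):
        t = am.parse_tree("(A:1,B:1);")
        states = np.array([3, 0, 0])  # expanded: class 2 state A at a tip
        segs = [((0, 0.4), (3, 0.6)), ((0, 1.0),), ()]
        # order: tips first, root last
        smap = simmap.StochasticMap(tree=t, node_states=states,
                                    segments=(segs[0], segs[1], ()))
        tc = am.count_transitions(smap)
        assert tc.total == 0
        assert tc.class_switches == 1

    def test_summary_on_reference_tree(self, mapping_fixture):
        f = mapping_fixture
        maps = am.generate_maps(f["tree"], f["table"], f["spec"], f["params"],
                                400, seed=8)
        summary = am.summarize_maps(maps, f["tree"])
        assert np.allclose(summary.node_freqs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(summary.clade_freq == 1.0)
        marg = am.marginal_asr(f["tree"], f["table"], f["spec"], f["params"])
        assert np.max(np.abs(summary.node_freqs - marg.probs)) < 0.08

    def test_posterior_summary_excludes_missing_clades(self):
        ref = am.parse_tree("(((A:1,B:1):1,C:2):1,D:3);")
        alt = am.parse_tree("(((A:1,C:1):1,B:2):1,D:3);")
        tbl = TaxonCharacterTable(states=dict(
            A="arboreal", B="arboreal", C="nonarboreal", D="nonarboreal"))
        spec = am.build_model_spec("two_rate")
        params = np.array([0.1, 0.05])
        maps_ref = am.generate_maps(ref, tbl, spec, params, 10, seed=1)
        maps_alt = am.generate_maps(alt, tbl, spec, params, 10, seed=2)
        match = am.match_nodes(ref, [ref, alt])
        summary = am.summarize_maps(
            [(0, maps_ref), (1, maps_alt)], ref, match=match, trees=[ref, alt])
        keys = {frozenset(k): v for v, k in match.keys.items()}
        ab = keys[frozenset("AB")]
        assert summary.clade_freq[ab] == 0.5
        root = keys[frozenset("ABCD")]
        assert summary.clade_freq[root] == 1.0

    def test_empty_summary_rejected(self, mapping_fixture):
        with pytest.raises(ValueError):
            am.summarize_maps([], mapping_fixture["tree"])


class TestUnconditionalConsistency:
    def test_expected_counts_from_stationary_rates(self):
        """Forward-simulated histories: E[count i->j] = pi_i q_ij L."""
        tree = am.simulate_birth_death_tree(60, 40.0, seed=17)
        spec = am.build_model_spec("ard")
        params = np.full(6, 0.04)  # symmetric chain, stationary = 1/3
        q = am.assemble_q(spec, params)
        rng = np.random.default_rng(18)
        nrep = 300
        totals = np.zeros((nrep, 3, 3))
        for r in range(nrep):
            truth = am.simulate_character_history(
                tree, spec, params, root_state=rng.integers(3), rng=rng)
            totals[r] = truth.transition_counts
        L = tree.total_length
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                expect = q[i, j] / 3 * L
                se = totals[:, i, j].std() / np.sqrt(nrep)
                assert abs(totals[:, i, j].mean() - expect) <= 3 * se + 1e-9
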
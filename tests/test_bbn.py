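"""Core engine: structure validation, CPT learning, exact inference."""

import numpy as np
import pytest

from tillage_bbn.bbn import (Cpt, CycleError, DataError,
                             ImpossibleEvidenceError, NetworkSpec, NodeSpec,
                             Posterior, ValidationError, build_network,
                             joint_probability, learn_cpts, posterior,
                             predict_state)
from conftest import ancestral_sample, enum_posterior, random_evidence, random_network


def _chain_ab(p_a1=0.5, p_b1_a1=0.9, p_b1_a2=0.1):
    spec = NetworkSpec(
        (NodeSpec("A", ("a1", "a2")), NodeSpec("B", ("b1", "b2"))),
        (("A", "B"),),
    )
    net = build_network(spec)
    net.set_cpt(Cpt("A", (), np.array([[p_a1, 1 - p_a1]])))
    net.set_cpt(Cpt("B", ("A",), np.array([[p_b1_a1, 1 - p_b1_a1],
                                           [p_b1_a2, 1 - p_b1_a2]])))
    return net


class TestStructure:
    def test_single_edge_topological_order(self):
        net = _chain_ab()
        assert net.order == ["A", "B"]
        assert net.parents("B") == ("A",)
        assert net.children("A") == ("B",)

    def test_two_cycle_rejected_with_cycle_named(self):
        with pytest.raises(CycleError) as exc:
            build_network(NetworkSpec(
                (NodeSpec("A", ("a1", "a2")), NodeSpec("B", ("b1", "b2"))),
                (("A", "B"), ("B", "A")),
            ))
        assert set(exc.value.cycle) >= {"A", "B"}

    def test_unknown_node_in_link_rejected(self):
        with pytest.raises(ValidationError):
            NetworkSpec((NodeSpec("A", ("a1", "a2")),), (("A", "Z"),))

    def test_self_link_and_duplicate_link_rejected(self):
        a, b = NodeSpec("A", ("a1", "a2")), NodeSpec("B", ("b1", "b2"))
        with pytest.raises(ValidationError):
            NetworkSpec((a,), (("A", "A"),))
        with pytest.raises(ValidationError):
            NetworkSpec((a, b), (("A", "B"), ("A", "B")))

    def test_acyclicity_matches_independent_dfs(self):
        # random graphs: build_network succeeds iff an independent DFS
        # finds no back edge
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = int(rng.integers(2, 7))
            names = [f"n{i}" for i in range(k)]
            links = [(names[i], names[j]) for i in range(k) for j in range(k)
                     if i != j and rng.random() < 0.3]
            links = list(dict.fromkeys(links))
            adj = {n: [c for p, c in links if p == n] for n in names}

            def has_cycle():
                color = {n: 0 for n in names}

                def dfs(u):
                    color[u] = 1
                    for v in adj[u]:
                        if color[v] == 1 or (color[v] == 0 and dfs(v)):
                            return True
                    color[u] = 2
                    return False

                return any(color[n] == 0 and dfs(n) for n in names)

            nodes = tuple(NodeSpec(n, ("s0", "s1")) for n in names)
            if has_cycle():
                with pytest.raises(CycleError):
                    build_network(NetworkSpec(nodes, tuple(links)))
            else:
                net = build_network(NetworkSpec(nodes, tuple(links)))
                pos = {n: i for i, n in enumerate(net.order)}
                assert all(pos[p] < pos[c] for p, c in links)


class TestLearning:
    def _root_net(self):
        return build_network(NetworkSpec((NodeSpec("A", ("a1", "a2")),), ()))

    def test_maximum_likelihood_counting(self):
        net = learn_cpts(self._root_net(),
                         [{"A": "a1"}, {"A": "a1"}, {"A": "a2"}], 0.0)
        assert net.cpts["A"].table[0, 0] == pytest.approx(2 / 3)

    def test_laplace_smoothing(self):
        net = learn_cpts(self._root_net(),
                         [{"A": "a1"}, {"A": "a1"}, {"A": "a2"}], 1.0)
        assert net.cpts["A"].table[0, 0] == pytest.approx(0.6)

    def test_conditional_rows_match_independent_tally(self):
        rng = np.random.default_rng(11)
        gen = _chain_ab(0.4, 0.8, 0.3)
        cases = ancestral_sample(gen, 20, rng)
        net = learn_cpts(_chain_ab(), cases, 0.0)
        # independent hand tally
        for ai, a in enumerate(("a1", "a2")):
            sub = [c for c in cases if c["A"] == a]
            if not sub:
                continue
            freq = sum(c["B"] == "b1" for c in sub) / len(sub)
            assert net.cpts["B"].table[ai, 0] == pytest.approx(freq)

    def test_unknown_state_label_names_row_and_node(self):
        with pytest.raises(DataError, match="case 1.*A"):
            learn_cpts(self._root_net(), [{"A": "a1"}, {"A": "oops"}], 1.0)

    def test_unseen_row_uniform_fallback_at_zero_prior(self):
        net = learn_cpts(_chain_ab(), [{"A": "a1", "B": "b1"}] * 3, 0.0)
        assert net.cpts["B"].table[1] == pytest.approx([0.5, 0.5])

    def test_learning_consistency_at_large_n(self):
        # rows converge to the generating CPT (stochastic, fixed seed)
        rng = np.random.default_rng(101)
        gen = _chain_ab(0.35, 0.75, 0.2)
        cases = ancestral_sample(gen, 10_000, rng)
        net = learn_cpts(_chain_ab(), cases, 0.0)
        for name in ("A", "B"):
            dev = np.abs(net.cpts[name].table - gen.cpts[name].table).max()
            assert dev <= 0.03

    def test_increasing_prior_moves_rows_toward_uniform(self):
        rng = np.random.default_rng(3)
        gen = _chain_ab(0.2, 0.95, 0.05)
        cases = ancestral_sample(gen, 200, rng)
        prev = None
        for pw in (0.0, 0.5, 1.0, 2.0, 10.0, 100.0):
            net = learn_cpts(_chain_ab(), cases, pw)
            dev = max(np.abs(net.cpts[n].table - 0.5).max() for n in ("A", "B"))
            if prev is not None:
                assert dev <= prev + 1e-12
            prev = dev

    def test_negative_prior_rejected(self):
        with pytest.raises(ValidationError):
            learn_cpts(self._root_net(), [{"A": "a1"}], -1.0)


class TestInference:
    def test_root_prior_with_empty_evidence(self):
        net = _chain_ab(0.7)
        assert posterior(net, "A").probs == pytest.approx([0.7, 0.3])

    def test_bayes_rule_on_two_node_chain(self):
        # P(a1|b1) = 0.5*0.9 / (0.5*0.9 + 0.5*0.1) = 0.9
        net = _chain_ab(0.5, 0.9, 0.1)
        assert posterior(net, "A", {"B": "b1"})["a1"] == pytest.approx(0.9)

    def test_joint_probability_is_cpt_product(self):
        net = _chain_ab(0.7, 0.9, 0.1)
        assert joint_probability(net, {"A": "a1", "B": "b2"}) == \
            pytest.approx(0.7 * 0.1)
        with pytest.raises(ValidationError):
            joint_probability(net, {"A": "a1"})

    def test_impossible_evidence_raises(self):
        net = _chain_ab(1.0, 1.0, 1.0)  # a2 and b2 unreachable
        with pytest.raises(ImpossibleEvidenceError):
            posterior(net, "B", {"A": "a2"})

    def test_target_in_evidence_rejected(self):
        net = _chain_ab()
        with pytest.raises(ValidationError):
            posterior(net, "A", {"A": "a1"})

    def test_predict_argmax_and_first_state_tie_break(self):
        net = _chain_ab(0.7)
        assert predict_state(net, "A") == "a1"
        tie = _chain_ab(0.5)
        assert predict_state(tie, "A") == "a1"  # first declared wins

    def test_posteriors_match_enumeration_on_random_networks(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            net = random_network(rng)
            for _ in range(5):
                target, evidence = random_evidence(rng, net)
                ve = posterior(net, target, evidence).probs
                brute = enum_posterior(net, target, evidence)
                assert np.abs(ve - brute).max() < 1e-9
                assert predict_state(net, target, evidence) == \
                    net.node(target).states[int(np.argmax(brute))]

    def test_posterior_normalized(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            net = random_network(rng)
            target, evidence = random_evidence(rng, net)
            p = posterior(net, target, evidence).probs
            assert abs(p.sum() - 1.0) < 1e-9
            assert (p >= 0).all()


def test_node_spec_invariants():
    with pytest.raises(ValidationError):
        NodeSpec("A", ("only",))
    with pytest.raises(ValidationError):
        NodeSpec("A", ("x", "x"))
    with pytest.raises(ValidationError):
        NodeSpec("A", ("x", "y"), midpoints=(2.0, 1.0))
    with pytest.raises(ValidationError):
        NodeSpec("A", ("x", "y"), midpoints=(1.0,))


def test_cpt_row_normalization_enforced():
    net = build_network(NetworkSpec((NodeSpec("A", ("a1", "a2")),), ()))
    with pytest.raises(ValidationError):
        net.set_cpt(Cpt("A", (), np.array([[0.6, 0.6]])))
    with pytest.raises(ValidationError):
        Posterior("A", ("a1", "a2"), np.array([0.6, 0.6]))
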
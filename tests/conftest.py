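"""Shared fixtures and independent oracles.

The enumeration oracle computes posteriors by brute force over the full
joint (its own CPT row arithmetic, no variable elimination), so it checks
the inference engine along a fully independent path.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from tillage_bbn.bbn import Network, NetworkSpec, NodeSpec, build_network


# ---------------------------------------------------------------------------
# Independent inference oracle
# ---------------------------------------------------------------------------

def enum_posterior(network: Network, target: str, evidence: dict[str, str]):
    """Marginal of target by summing the full joint, assignment by
    assignment, with direct CPT lookups."""
    names = network.node_names
    state_lists = [network.node(n).states for n in names]
    t_node = network.node(target)
    probs = np.zeros(t_node.n_states)
    for combo in itertools.product(*state_lists):
        assign = dict(zip(names, combo))
        if any(assign[k] != v for k, v in evidence.items()):
            continue
        p = 1.0
        for n in names:
            node = network.node(n)
            parents = network.parents(n)
            row = 0
            for q in parents:
                qn = network.node(q)
                row = row * qn.n_states + qn.states.index(assign[q])
            p *= network.cpts[n].table[row, node.states.index(assign[n])]
        probs[t_node.states.index(assign[target])] += p
    z = probs.sum()
    return probs / z if z > 0 else probs


def random_network(rng: np.random.Generator, max_nodes: int = 6,
                   max_states: int = 4) -> Network:
    """Random DAG with random Dirichlet CPTs (all entries positive)."""
    k = int(rng.integers(2, max_nodes + 1))
    names = [f"n{i}" for i in range(k)]
    cards = rng.integers(2, max_states + 1, size=k)
    links = [(names[i], names[j]) for i in range(k) for j in range(i + 1, k)
             if rng.random() < 0.45]
    nodes = tuple(NodeSpec(names[i], tuple(f"s{t}" for t in range(cards[i])))
                  for i in range(k))
    net = build_network(NetworkSpec(nodes, tuple(links)))
    from tillage_bbn.bbn import Cpt
    for i, name in enumerate(names):
        n_rows = int(np.prod([cards[names.index(p)]
                              for p in net.parents(name)])) if net.parents(name) else 1
        table = rng.dirichlet(np.ones(cards[i]), size=n_rows)
        net.set_cpt(Cpt(name, net.parents(name), table))
    return net


def random_evidence(rng: np.random.Generator, net: Network):
    """A random target plus random evidence on a random subset of the
    remaining nodes."""
    names = net.node_names
    target = names[int(rng.integers(len(names)))]
    others = [n for n in names if n != target]
    n_ev = int(rng.integers(0, len(others) + 1))
    ev_nodes = list(rng.choice(others, size=n_ev, replace=False)) if n_ev else []
    evidence = {n: net.node(n).states[int(rng.integers(net.node(n).n_states))]
                for n in ev_nodes}
    return target, evidence


def ancestral_sample(net: Network, n: int, rng: np.random.Generator):
    """Forward-sample complete cases from a fitted network."""
    cases = []
    for _ in range(n):
        assign: dict[str, str] = {}
        for name in net.order:
            node = net.node(name)
            pstates = tuple(assign[p] for p in net.parents(name))
            row = net.cpt_row_index(name, pstates)
            probs = net.cpts[name].table[row]
            assign[name] = node.states[int(rng.choice(node.n_states, p=probs))]
        cases.append(assign)
    return cases


# ---------------------------------------------------------------------------
# Study-condition fixtures (default generator configuration)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_cases() -> pd.DataFrame:
    from tillage_bbn.simulate import SimConfig, simulate_dataset
    return simulate_dataset(SimConfig())


@pytest.fixture(scope="session")
def holdout_fit(default_cases):
    """Model fitted on the holdout training years (1975-2011)."""
    from tillage_bbn.tillage import fit_tillage_model
    from tillage_bbn.validate import HOLDOUT_PLAN, split
    parts = split(default_cases, HOLDOUT_PLAN)
    net, schemes = fit_tillage_model(parts["train"], prior_weight=1.0)
    return net, schemes, parts
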
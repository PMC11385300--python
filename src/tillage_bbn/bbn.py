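"""Discrete Bayesian belief network engine.

Structure (a DAG over named nodes with ordered, labelled states), conditional
probability tables learned from complete discretized case data by Dirichlet
(pseudo-count) counting, and exact posterior inference by variable elimination.

The engine is generic; the tillage–wheat network is assembled on top of it by
:mod:`tillage_bbn.tillage`.  State order as declared is authoritative
throughout: CPT row layout, posterior vectors, confusion-matrix axes and
argmax tie-breaking all follow it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NodeSpec",
    "NetworkSpec",
    "Cpt",
    "Posterior",
    "Network",
    "CycleError",
    "ValidationError",
    "DataError",
    "ImpossibleEvidenceError",
    "build_network",
    "learn_cpts",
    "posterior",
    "joint_probability",
    "predict_state",
]

PROB_TOL = 1e-9


class ValidationError(ValueError):
    """A structural or argument contract was violated."""


class CycleError(ValidationError):
    """The proposed link set contains a directed cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__("directed cycle detected: " + " -> ".join(cycle))


class DataError(ValueError):
    """A case record is inconsistent with the network's node/state roster."""


class ImpossibleEvidenceError(ValueError):
    """The supplied evidence has probability zero under the fitted model."""


@dataclass(frozen=True)
class NodeSpec:
    """One network variable: name, ordered state labels and role.

    ``midpoints``, when given, attach a representative real value (in the
    variable's physical units) to each ordered band; variance-based
    sensitivity analysis needs them, categorical nodes do not.
    """

    name: str
    states: tuple[str, ...]
    kind: str = "intermediary"  # input | intermediary | output
    midpoints: tuple[float, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise ValidationError(f"node {self.name!r}: needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise ValidationError(f"node {self.name!r}: duplicate state labels")
        if self.kind not in ("input", "intermediary", "output"):
            raise ValidationError(f"node {self.name!r}: bad kind {self.kind!r}")
        if self.midpoints is not None:
            mp = tuple(float(m) for m in self.midpoints)
            object.__setattr__(self, "midpoints", mp)
            if len(mp) != len(self.states):
                raise ValidationError(
                    f"node {self.name!r}: {len(mp)} midpoints for "
                    f"{len(self.states)} states"
                )
            if any(b <= a for a, b in zip(mp, mp[1:])):
                raise ValidationError(
                    f"node {self.name!r}: midpoints must be strictly increasing"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise DataError(
                f"node {self.name!r}: unknown state {label!r} "
                f"(legal: {list(self.states)})"
            ) from None


@dataclass(frozen=True)
class NetworkSpec:
    """The DAG: nodes plus directed (parent, child) links."""

    nodes: tuple[NodeSpec, ...]
    links: tuple[tuple[str, str], ...]

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(
            self, "links", tuple((str(p), str(c)) for p, c in self.links)
        )
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate node names")
        known = set(names)
        seen = set()
        for p, c in self.links:
            if p not in known:
                raise ValidationError(f"link {p}->{c}: unknown parent {p!r}")
            if c not in known:
                raise ValidationError(f"link {p}->{c}: unknown child {c!r}")
            if p == c:
                raise ValidationError(f"self-link on {p!r}")
            if (p, c) in seen:
                raise ValidationError(f"duplicate link {p}->{c}")
            seen.add((p, c))

    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise ValidationError(f"unknown node {name!r}")


@dataclass
class Cpt:
    """Conditional probability table for one node.

    ``table`` has one row per combination of parent states, in
    row-major order over the parents as listed (last parent varies
    fastest), and one column per node state in declared order.
    """

    node: str
    parents: tuple[str, ...]
    table: np.ndarray  # shape (n_parent_combos, n_states)

    def validate(self) -> None:
        if np.any(self.table < 0) or np.any(self.table > 1 + PROB_TOL):
            raise ValidationError(f"CPT {self.node!r}: probabilities outside [0,1]")
        sums = self.table.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > PROB_TOL):
            raise ValidationError(f"CPT {self.node!r}: rows do not sum to 1")


@dataclass
class Posterior:
    """Marginal distribution of one node, states in declared order."""

    node: str
    states: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or len(self.probs) != len(self.states):
            raise ValidationError("posterior shape mismatch")
        if np.any(self.probs < -PROB_TOL):
            raise ValidationError("negative posterior probability")
        if abs(self.probs.sum() - 1.0) > PROB_TOL:
            raise ValidationError("posterior does not sum to 1")

    def __getitem__(self, state: str) -> float:
        return float(self.probs[self.states.index(state)])

    def argmax_state(self) -> str:
        # np.argmax returns the first maximal index, which is exactly the
        # documented tie-break (first declared state wins).
        return self.states[int(np.argmax(self.probs))]


def _toposort(names: list[str], links: tuple[tuple[str, str], ...]) -> list[str]:
    """Kahn topological sort; raises CycleError naming one cycle."""
    children: dict[str, list[str]] = {n: [] for n in names}
    indeg = {n: 0 for n in names}
    for p, c in links:
        children[p].append(c)
        indeg[c] += 1
    order = []
    ready = [n for n in names if indeg[n] == 0]
    while ready:
        n = ready.pop(0)
        order.append(n)
        for c in children[n]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(order) < len(names):
        # Exhibit one concrete cycle: every leftover node has a leftover
        # parent, so walking parent edges must revisit a node.
        residual = {n for n in names if n not in order}
        parents = {n: [p for p, c in links if c == n and p in residual]
                   for n in residual}
        path = [next(iter(sorted(residual)))]
        seen = {path[0]}
        while True:
            nxt = sorted(parents[path[-1]])[0]
            if nxt in seen:
                cycle = path[path.index(nxt):] + [nxt]
                raise CycleError(list(reversed(cycle)))
            path.append(nxt)
            seen.add(nxt)
    return order


class Network:
    """A built (and optionally fitted) Bayesian network."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        names = [n.name for n in spec.nodes]
        self.order: list[str] = _toposort(names, spec.links)
        self._nodes: dict[str, NodeSpec] = {n.name: n for n in spec.nodes}
        self._parents: dict[str, tuple[str, ...]] = {n: () for n in names}
        self._children: dict[str, tuple[str, ...]] = {n: () for n in names}
        par: dict[str, list[str]] = {n: [] for n in names}
        chi: dict[str, list[str]] = {n: [] for n in names}
        for p, c in spec.links:
            par[c].append(p)
            chi[p].append(c)
        for n in names:
            self._parents[n] = tuple(par[n])
            self._children[n] = tuple(chi[n])
        self.cpts: dict[str, Cpt] = {}

    # -- structure queries -------------------------------------------------
    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.spec.nodes]

    def node(self, name: str) -> NodeSpec:
        if name not in self._nodes:
            raise ValidationError(f"unknown node {name!r}")
        return self._nodes[name]

    def parents(self, name: str) -> tuple[str, ...]:
        self.node(name)
        return self._parents[name]

    def children(self, name: str) -> tuple[str, ...]:
        self.node(name)
        return self._children[name]

    @property
    def fitted(self) -> bool:
        return len(self.cpts) == len(self.spec.nodes)

    def _require_fitted(self) -> None:
        if not self.fitted:
            missing = [n for n in self.node_names if n not in self.cpts]
            raise ValidationError(f"CPTs not fitted for: {missing}")

    def check_evidence(self, evidence: dict[str, str]) -> None:
        for name, state in evidence.items():
            self.node(name).state_index(state)

    # -- CPT helpers -------------------------------------------------------
    def parent_combos(self, name: str) -> list[tuple[str, ...]]:
        """Parent-state combinations in CPT row order (last parent fastest)."""
        pstates = [self._nodes[p].states for p in self._parents[name]]
        return [tuple(c) for c in itertools.product(*pstates)]

    def cpt_row_index(self, name: str, parent_states: tuple[str, ...]) -> int:
        idx = 0
        for p, s in zip(self._parents[name], parent_states):
            idx = idx * self._nodes[p].n_states + self._nodes[p].state_index(s)
        return idx

    def set_cpt(self, cpt: Cpt) -> None:
        node = self.node(cpt.node)
        expected_rows = int(
            np.prod([self._nodes[p].n_states for p in self._parents[cpt.node]])
        ) if self._parents[cpt.node] else 1
        tab = np.asarray(cpt.table, dtype=float)
        if tab.shape != (expected_rows, node.n_states):
            raise ValidationError(
                f"CPT {cpt.node!r}: shape {tab.shape}, expected "
                f"({expected_rows}, {node.n_states})"
            )
        cpt = Cpt(cpt.node, self._parents[cpt.node], tab)
        cpt.validate()
        self.cpts[cpt.node] = cpt

    def cpt_factor(self, name: str) -> "Factor":
        """The node's CPT as a factor over (parents..., node)."""
        self._require_fitted()
        pnames = self._parents[name]
        shape = [self._nodes[p].n_states for p in pnames] + [self._nodes[name].n_states]
        arr = self.cpts[name].table.reshape(shape)
        return Factor(tuple(pnames) + (name,), arr)


# ---------------------------------------------------------------------------
# Factors and variable elimination
# ---------------------------------------------------------------------------


@dataclass
class Factor:
    """A non-negative table over a tuple of named discrete variables."""

    vars: tuple[str, ...]
    values: np.ndarray

    def reduce(self, var: str, index: int) -> "Factor":
        ax = self.vars.index(var)
        return Factor(
            self.vars[:ax] + self.vars[ax + 1:],
            np.take(self.values, index, axis=ax),
        )

    def marginalize(self, var: str) -> "Factor":
        ax = self.vars.index(var)
        return Factor(self.vars[:ax] + self.vars[ax + 1:], self.values.sum(axis=ax))

    @staticmethod
    def multiply(a: "Factor", b: "Factor") -> "Factor":
        out_vars = a.vars + tuple(v for v in b.vars if v not in a.vars)
        av = a.values.reshape(a.values.shape + (1,) * (len(out_vars) - len(a.vars)))
        # move b's axes into out_vars positions
        perm = [b.vars.index(v) if v in b.vars else None for v in out_vars]
        bshape, src_axes, dst_axes = [], [], []
        for i, p in enumerate(perm):
            if p is None:
                bshape.append(1)
            else:
                bshape.append(b.values.shape[p])
                src_axes.append(p)
                dst_axes.append(i)
        bv = np.moveaxis(b.values, src_axes, range(len(src_axes))).reshape(bshape)
        return Factor(out_vars, av * bv)


def _min_degree_order(hidden: set[str], factors: list[Factor]) -> list[str]:
    """Greedy min-degree elimination order on the factor interaction graph."""
    adj: dict[str, set[str]] = {v: set() for v in hidden}
    for f in factors:
        vs = [v for v in f.vars if v in hidden]
        for v in vs:
            adj[v].update(u for u in f.vars if u != v)
    order = []
    remaining = set(hidden)
    while remaining:
        v = min(remaining, key=lambda u: (len(adj[u] & remaining), u))
        order.append(v)
        neigh = adj[v] & remaining
        for u in neigh:
            adj[u].update(neigh - {u})
        remaining.discard(v)
    return order


def build_network(spec: NetworkSpec) -> Network:
    """Validate a network spec and return the structural network object.

    Raises :class:`CycleError` (naming one concrete cycle) if the links are
    cyclic, :class:`ValidationError` for unknown/duplicate links.
    """
    return Network(spec)


def learn_cpts(network: Network, cases, prior_weight: float = 1.0) -> Network:
    """Fit every CPT from complete discretized cases by pseudo-count counting.

    For each node and each parent-state combination::

        P(state | parents) = (count + prior_weight) /
                             (row_total + prior_weight * n_states)

    ``prior_weight`` is a uniform Dirichlet pseudo-count (Laplace smoothing at
    1, maximum likelihood at 0).  Rows never observed with prior_weight 0 fall
    back to the uniform distribution.  Cases may be dicts or anything with a
    ``__getitem__`` by node name (e.g. pandas rows).
    """
    if prior_weight < 0:
        raise ValidationError("prior_weight must be non-negative")
    cases = list(cases)
    names = network.node_names
    # pre-extract state indices once; validates all labels up front
    idx: dict[str, np.ndarray] = {}
    for name in names:
        node = network.node(name)
        col = np.empty(len(cases), dtype=np.intp)
        for i, case in enumerate(cases):
            try:
                label = case[name]
            except (KeyError, IndexError):
                raise DataError(f"case {i}: missing value for node {name!r}") from None
            try:
                col[i] = node.state_index(label)
            except DataError as e:
                raise DataError(f"case {i}: {e}") from None
        idx[name] = col

    for name in names:
        node = network.node(name)
        parents = network.parents(name)
        pcard = [network.node(p).n_states for p in parents]
        n_rows = int(np.prod(pcard)) if parents else 1
        counts = np.zeros((n_rows, node.n_states))
        row = np.zeros(len(cases), dtype=np.intp)
        for p, card in zip(parents, pcard):
            row = row * card + idx[p]
        np.add.at(counts, (row, idx[name]), 1.0)
        table = counts + prior_weight
        totals = table.sum(axis=1, keepdims=True)
        empty = totals[:, 0] == 0  # only possible when prior_weight == 0
        table[empty] = 1.0
        totals[empty] = node.n_states
        network.set_cpt(Cpt(name, parents, table / totals))
    return network


def posterior(network: Network, target: str, evidence: dict[str, str] | None = None) -> Posterior:
    """Exact marginal of ``target`` given ``evidence`` by variable elimination.

    Uses a greedy min-degree elimination order; the result is renormalized to
    absorb float drift.  Raises :class:`ImpossibleEvidenceError` when the
    evidence has probability zero under the fitted model.
    """
    network._require_fitted()
    evidence = dict(evidence or {})
    network.check_evidence(evidence)
    if target in evidence:
        raise ValidationError(f"target {target!r} is in the evidence")
    network.node(target)

    factors = []
    for name in network.node_names:
        f = network.cpt_factor(name)
        for ev, state in evidence.items():
            if ev in f.vars:
                f = f.reduce(ev, network.node(ev).state_index(state))
        factors.append(f)

    hidden = {n for n in network.node_names if n != target and n not in evidence}
    for var in _min_degree_order(hidden, factors):
        related = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        prod = related[0]
        for f in related[1:]:
            prod = Factor.multiply(prod, f)
        factors.append(prod.marginalize(var))

    result = factors[0]
    for f in factors[1:]:
        result = Factor.multiply(result, f)
    assert set(result.vars) <= {target}
    probs = np.asarray(result.values, dtype=float).reshape(-1)
    if probs.size == 1:  # target factor was fully scalar — cannot happen, guard
        raise ValidationError("internal elimination error")
    z = probs.sum()
    if z <= 0:
        raise ImpossibleEvidenceError(
            f"evidence {evidence} has probability 0 under the model"
        )
    return Posterior(target, network.node(target).states, probs / z)


def joint_probability(network: Network, assignment: dict[str, str]) -> float:
    """Chain-rule probability of a full assignment (every node assigned)."""
    network._require_fitted()
    missing = [n for n in network.node_names if n not in assignment]
    if missing:
        raise ValidationError(f"assignment missing nodes: {missing}")
    network.check_evidence(assignment)
    p = 1.0
    for name in network.node_names:
        node = network.node(name)
        pstates = tuple(assignment[q] for q in network.parents(name))
        row = network.cpt_row_index(name, pstates)
        p *= float(network.cpts[name].table[row, node.state_index(assignment[name])])
    return p


def predict_state(network: Network, target: str, evidence: dict[str, str] | None = None) -> str:
    """Argmax state of the posterior; ties break to the first declared state."""
    return posterior(network, target, evidence).argmax_state()
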
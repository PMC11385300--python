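"""Sensitivity-to-findings and scenario influence analysis.

"Sensitivity to findings" ranks, for a chosen target node, how much
observing each other node would reduce uncertainty about the target.
Three statistics are computed from exact inference:

* variance reduction  V(Q) − Σ_f P(f) V(Q|f), with the target's band
  midpoints as real values (units of the target squared);
* mutual information  Σ P(q,f) log2[P(q,f)/(P(q)P(f))], in bits;
* variance of beliefs  Σ_f P(f) Σ_q [P(q|f) − P(q)]² — a reconstruction of
  the third column of the classic Netica report, whose exact formula is not
  published; it is isolated here so it can be swapped.

Scenario influence compares posterior band distributions under named
evidence presets against the no-evidence baseline, reporting the change in
percentage points per band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bbn import Network, posterior

__all__ = ["SensitivityRow", "variance_reduction", "mutual_information",
           "variance_of_beliefs", "rank_findings", "scenario_influence"]

_TOL = 1e-9


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class SensitivityRow:
    finding: str
    variance_reduction: float
    mutual_information: float
    variance_of_beliefs: float


def _joint(network: Network, target: str, finding: str):
    """P(f), P(q|f) rows, and P(q) for a target/finding pair, all by exact
    inference (conditionals for zero-probability findings are left uniform —
    they carry zero weight)."""
    f_node = network.node(finding)
    q_node = network.node(target)
    p_f = posterior(network, finding).probs
    p_q = posterior(network, target).probs
    cond = np.full((f_node.n_states, q_node.n_states), 1.0 / q_node.n_states)
    for i, state in enumerate(f_node.states):
        if p_f[i] > 0:
            cond[i] = posterior(network, target, {finding: state}).probs
    return p_f, cond, p_q


def variance_reduction(network: Network, target: str, finding: str) -> float:
    """Expected reduction in the target's variance from observing the
    finding, using the target's state midpoints as real values."""
    q_node = network.node(target)
    if q_node.midpoints is None:
        raise SensitivityError(
            f"target {target!r} has no state midpoints; variance-based "
            "sensitivity needs a banded (ordered) target")
    if finding == target:
        # observing the target removes all of its variance
        p_q = posterior(network, target).probs
        mids = np.asarray(q_node.midpoints)
        return float(p_q @ mids ** 2 - (p_q @ mids) ** 2)
    mids = np.asarray(q_node.midpoints)
    p_f, cond, p_q = _joint(network, target, finding)
    v_prior = float(p_q @ mids ** 2 - (p_q @ mids) ** 2)
    v_cond = float(np.sum(p_f * ((cond @ mids ** 2) - (cond @ mids) ** 2)))
    vr = v_prior - v_cond
    return 0.0 if abs(vr) < _TOL else vr


def mutual_information(network: Network, target: str, finding: str) -> float:
    """Mutual information between target and finding, in bits, from the
    exact joint distribution; symmetric in its arguments."""
    if finding == target:
        p = posterior(network, target).probs
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())
    p_f, cond, p_q = _joint(network, target, finding)
    joint = p_f[:, None] * cond
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (p_f[:, None] * p_q[None, :])
        terms = np.where(joint > 0, joint * np.log2(ratio), 0.0)
    mi = float(terms.sum())
    return max(mi, 0.0)


def variance_of_beliefs(network: Network, target: str, finding: str) -> float:
    """Expected squared shift of the target's belief vector on observing the
    finding (reconstruction of the classic report's third column)."""
    if finding == target:
        p_q = posterior(network, target).probs
        eye = np.eye(len(p_q))
        return float(np.sum(p_q * ((eye - p_q[None, :]) ** 2).sum(axis=1)))
    p_f, cond, p_q = _joint(network, target, finding)
    return float(np.sum(p_f * ((cond - p_q[None, :]) ** 2).sum(axis=1)))


def rank_findings(network: Network, target: str) -> list[SensitivityRow]:
    """All other nodes ranked by variance reduction (descending), ties by
    mutual information then name."""
    rows = []
    for name in network.node_names:
        if name == target:
            continue
        rows.append(SensitivityRow(
            name,
            variance_reduction(network, target, name),
            mutual_information(network, target, name),
            variance_of_beliefs(network, target, name),
        ))
    rows.sort(key=lambda r: (-r.variance_reduction, -r.mutual_information,
                             r.finding))
    return rows


def rank_findings_frame(network: Network, target: str) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rank_findings(network, target)])


def scenario_influence(
    network: Network,
    presets: dict[str, dict[str, str]],
    targets: list[str],
) -> pd.DataFrame:
    """Posterior band distributions under each evidence preset vs the
    no-evidence baseline.

    One row per (preset, target, band) with the baseline and scenario
    probabilities (percent) and their difference in percentage points.
    """
    rows = []
    for target in targets:
        node = network.node(target)
        baseline = posterior(network, target).probs
        for name, evidence in presets.items():
            ev = {k: v for k, v in evidence.items() if k != target}
            scenario = posterior(network, target, ev).probs
            for j, band in enumerate(node.states):
                rows.append({
                    "preset": name, "target": target, "band": band,
                    "baseline_pct": 100.0 * baseline[j],
                    "scenario_pct": 100.0 * scenario[j],
                    "change_pp": 100.0 * (scenario[j] - baseline[j]),
                })
    return pd.DataFrame(rows)
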
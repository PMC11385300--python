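"""Holdout and K-fold evaluation: confusion matrices, error rates, scoring rules.

Splits are always chronological (by season year), never random: the holdout
plan trains on 1975–2011 and tests on 2012–2022, and K-fold cross-validation
uses contiguous decade blocks (K1 1975–1984 … K5 2015–2022).  For each test
case the evidence is, by default, every variable except the target; the
predicted band is the posterior argmax, and the three proper scoring rules
are accumulated from the full posterior vector with P_c the probability of
the actual band:

* logarithmic loss  mean(−ln P_c),            range [0, inf), 0 best
* quadratic (Brier) loss  mean(1 − 2 P_c + Σ_j P_j²), range [0, 2], 0 best
* spherical payoff  mean(P_c / sqrt(Σ_j P_j²)),       range [0, 1], 1 best
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bbn import Network, posterior
from .discretize import OUTPUT_LABELS
from .tillage import ALL_VARS

__all__ = [
    "SplitPlan", "HOLDOUT_PLAN", "KFOLD_PLAN", "ConfusionMatrix",
    "ScoreReport", "split", "kfold_split", "evaluate", "error_rate",
    "kfold_report", "REFERENCE_CONFUSION_MATRICES",
]

LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class SplitPlan:
    """Chronological split: named blocks of inclusive year ranges."""

    name: str
    blocks: tuple[tuple[str, int, int], ...]  # (label, first_year, last_year)

    def __post_init__(self):
        seen: set[int] = set()
        for label, y0, y1 in self.blocks:
            if y1 < y0:
                raise ValueError(f"block {label}: empty year range")
            years = set(range(y0, y1 + 1))
            if years & seen:
                raise ValueError(f"block {label}: overlapping years")
            seen |= years

    def years(self, label: str) -> set[int]:
        for lab, y0, y1 in self.blocks:
            if lab == label:
                return set(range(y0, y1 + 1))
        raise KeyError(label)

    @property
    def all_years(self) -> set[int]:
        out: set[int] = set()
        for lab, *_ in self.blocks:
            out |= self.years(lab)
        return out


HOLDOUT_PLAN = SplitPlan("holdout", (("train", 1975, 2011), ("test", 2012, 2022)))
KFOLD_PLAN = SplitPlan("kfold", (
    ("K1", 1975, 1984), ("K2", 1985, 1994), ("K3", 1995, 2004),
    ("K4", 2005, 2014), ("K5", 2015, 2022),
))


def split(cases: pd.DataFrame, plan: SplitPlan) -> dict[str, pd.DataFrame]:
    """Partition cases by year into the plan's blocks.

    Every case year must fall inside the plan; every block must be non-empty.
    """
    years = cases["year"].astype(int)
    outside = set(years.unique()) - plan.all_years
    if outside:
        raise ValueError(f"case years outside plan {plan.name!r}: {sorted(outside)}")
    parts = {}
    for label, *_ in plan.blocks:
        block = cases[years.isin(plan.years(label))]
        if block.empty:
            raise ValueError(f"plan {plan.name!r}: block {label!r} has no cases")
        parts[label] = block
    return parts


def kfold_split(cases: pd.DataFrame, plan: SplitPlan = KFOLD_PLAN):
    return split(cases, plan)


@dataclass
class ConfusionMatrix:
    """Actual (rows) x predicted (columns) counts, axes in declared state
    order (Very low … Very high for the output variables)."""

    target: str
    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be square over the labels")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


def error_rate(cm: ConfusionMatrix) -> float:
    """Misclassification percentage 100 x (1 - trace/total), to 2 decimals."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return round(100.0 * (1.0 - np.trace(cm.counts) / cm.total), 2)


@dataclass
class ScoreReport:
    """Prediction-quality summary for one target node on one test set."""

    target: str
    n_cases: int
    error_rate: float            # percent
    logarithmic_loss: float      # nats, [0, inf)
    quadratic_loss: float        # [0, 2]
    spherical_payoff: float      # [0, 1]
    n_floored: int = 0           # cases where P(actual) hit the log floor

    def as_dict(self) -> dict:
        return {
            "target": self.target, "n_cases": self.n_cases,
            "error_rate": self.error_rate,
            "logarithmic_loss": self.logarithmic_loss,
            "quadratic_loss": self.quadratic_loss,
            "spherical_payoff": self.spherical_payoff,
            "n_floored": self.n_floored,
        }


def score_posteriors(posteriors: np.ndarray, actual_idx: np.ndarray) -> dict:
    """The three scoring rules from per-case posterior vectors.

    Exposed separately so hand-written posteriors can be scored in tests.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    n = len(actual_idx)
    p_c = posteriors[np.arange(n), actual_idx]
    floored = p_c < LOG_FLOOR
    log_loss = float(np.mean(-np.log(np.maximum(p_c, LOG_FLOOR))))
    sq = (posteriors ** 2).sum(axis=1)
    quad = float(np.mean(1.0 - 2.0 * p_c + sq))
    sph = float(np.mean(p_c / np.sqrt(sq)))
    return {"logarithmic_loss": log_loss, "quadratic_loss": quad,
            "spherical_payoff": sph, "n_floored": int(floored.sum())}


def evaluate(
    network: Network,
    test_cases: pd.DataFrame,
    target: str,
    evidence_policy: str = "all",
) -> tuple[ConfusionMatrix, ScoreReport]:
    """Confusion matrix and scoring rules for one target on discretized
    test cases.

    ``evidence_policy`` "all" observes every variable except the target
    (the default case-testing configuration); "inputs_only" observes only
    the four input variables.
    """
    node = network.node(target)
    if evidence_policy == "all":
        ev_vars = [v for v in ALL_VARS if v != target and v in test_cases.columns]
    elif evidence_policy == "inputs_only":
        ev_vars = [v for v in ALL_VARS
                   if network.node(v).kind == "input" and v != target]
    else:
        raise ValueError(f"unknown evidence policy {evidence_policy!r}")

    k = node.n_states
    counts = np.zeros((k, k), dtype=int)
    posts = np.empty((len(test_cases), k))
    actual = np.empty(len(test_cases), dtype=int)
    for i, (_, row) in enumerate(test_cases.iterrows()):
        evidence = {v: row[v] for v in ev_vars}
        post = posterior(network, target, evidence)
        a = node.state_index(row[target])
        p = int(np.argmax(post.probs))
        counts[a, p] += 1
        posts[i] = post.probs
        actual[i] = a

    cm = ConfusionMatrix(target, node.states, counts)
    scores = score_posteriors(posts, actual)
    report = ScoreReport(target, cm.total, error_rate(cm), **scores)
    return cm, report


def kfold_report(
    network_factory,
    cases: pd.DataFrame,
    target: str,
    plan: SplitPlan = KFOLD_PLAN,
    evidence_policy: str = "all",
) -> pd.DataFrame:
    """Decade-block cross-validation for one target.

    For each of K1–K4 the model is refit (via ``network_factory(train_df)``,
    which must return a fitted network and the banding schemes) on all other
    blocks' years and tested on the block; the final row trains on K1–K4 and
    tests on K5.  Returns per-fold error rates plus their K1–K4 mean.
    """
    from .tillage import cases_to_states

    folds = split(cases, plan)
    labels = [lab for lab, *_ in plan.blocks]
    rows = []
    for test_label in labels[:-1]:
        train = pd.concat([folds[l] for l in labels if l != test_label])
        net, schemes = network_factory(train)
        test_states = cases_to_states(folds[test_label], schemes)
        _, rep = evaluate(net, test_states, target, evidence_policy)
        rows.append({"fold": test_label, "role": "cv",
                     "n_test": rep.n_cases, "error_rate": rep.error_rate})
    mean_err = round(float(np.mean([r["error_rate"] for r in rows])), 2)
    rows.append({"fold": "average", "role": "cv",
                 "n_test": sum(r["n_test"] for r in rows),
                 "error_rate": mean_err})
    # final test: train K1..K4, test K5
    train = pd.concat([folds[l] for l in labels[:-1]])
    net, schemes = network_factory(train)
    test_states = cases_to_states(folds[labels[-1]], schemes)
    _, rep = evaluate(net, test_states, target, evidence_policy)
    rows.append({"fold": labels[-1], "role": "final_test",
                 "n_test": rep.n_cases, "error_rate": rep.error_rate})
    return pd.DataFrame(rows)


# Reference holdout confusion matrices for the three output variables from
# the original Netica-based evaluation of this system (330 test cases each;
# rows = actual band, columns = predicted band, Very low ... Very high).
REFERENCE_CONFUSION_MATRICES: dict[str, ConfusionMatrix] = {
    "ghg": ConfusionMatrix("ghg", OUTPUT_LABELS, np.array([
        [220, 8, 4, 0, 0],
        [60, 10, 0, 0, 0],
        [17, 1, 3, 0, 0],
        [3, 1, 1, 0, 0],
        [1, 1, 0, 0, 0],
    ])),
    "runoff": ConfusionMatrix("runoff", OUTPUT_LABELS, np.array([
        [168, 33, 0, 0, 0],
        [45, 50, 0, 0, 0],
        [1, 23, 1, 0, 0],
        [0, 3, 1, 0, 0],
        [0, 4, 1, 0, 0],
    ])),
    "yield": ConfusionMatrix("yield", OUTPUT_LABELS, np.array([
        [29, 6, 0, 0, 0],
        [8, 72, 16, 0, 0],
        [0, 29, 36, 26, 0],
        [0, 0, 26, 48, 0],
        [0, 0, 1, 33, 0],
    ])),
}
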
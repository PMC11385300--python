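"""Case-file and configuration I/O, CPT export, manifest and pipeline.

Case files are delimited text (tab or comma), one header row of variable
names and one cropping season per row; a Netica-style ``//`` comment first
line is tolerated.  Network structure and banding schemes round-trip
through a single YAML document.  ``run_pipeline`` chains the whole study:
simulate → discretize → learn → validate → sensitivity → scenarios, from
one seed, and writes its report tables to an output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bbn import Network, NetworkSpec, NodeSpec, build_network
from .discretize import BinningScheme
from .tillage import ALL_VARS, CATEGORICAL_VARS

log = logging.getLogger("tillage_bbn")

__all__ = ["read_cases", "write_cases", "spec_to_yaml", "spec_from_yaml",
           "cpts_to_frame", "RunManifest", "PipelineConfig", "run_pipeline"]

CASE_COLUMNS = ("experiment", "year") + ALL_VARS


class CaseFileError(ValueError):
    pass


def read_cases(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a case file into a typed DataFrame.

    ``dialect`` is "comma", "tab" or None (sniff from the header line).
    Columns are validated strictly against the 11-variable roster plus
    ``experiment`` and ``year``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        skip = 1 if first.startswith("//") else 0
    header = first if not skip else open(path).readlines()[1]
    if dialect is None:
        dialect = "tab" if header.count("\t") >= header.count(",") else "comma"
    sep = "\t" if dialect == "tab" else ","
    df = pd.read_csv(path, sep=sep, skiprows=skip)
    missing = [c for c in CASE_COLUMNS if c not in df.columns]
    if missing:
        raise CaseFileError(f"{path.name}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in CASE_COLUMNS]
    if extra:
        raise CaseFileError(f"{path.name}: unexpected column(s) {extra}")
    for col in CASE_COLUMNS:
        if col in ("experiment",) + CATEGORICAL_VARS:
            df[col] = df[col].astype(str)
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise CaseFileError(
                f"{path.name}: unparseable number in column {col!r}, row {row}")
        df[col] = numeric.astype(int) if col == "year" else numeric.astype(float)
    return df[list(CASE_COLUMNS)]


def write_cases(df: pd.DataFrame, path, dialect: str = "comma",
                comment: str | None = None) -> None:
    path = Path(path)
    sep = "\t" if dialect == "tab" else ","
    with open(path, "w") as fh:
        if comment:
            fh.write(f"// {comment}\n")
        df[list(CASE_COLUMNS)].to_csv(fh, sep=sep, index=False,
                                      float_format="%.10g")


# ---------------------------------------------------------------------------
# Model configuration (network structure + banding schemes) as YAML
# ---------------------------------------------------------------------------


def spec_to_yaml(spec: NetworkSpec,
                 schemes: dict[str, BinningScheme] | None = None) -> str:
    doc = {
        "nodes": [
            {
                "name": n.name,
                "states": list(n.states),
                "kind": n.kind,
                **({"midpoints": [float(m) for m in n.midpoints]}
                   if n.midpoints is not None else {}),
            }
            for n in spec.nodes
        ],
        "links": [f"{p} -> {c}" for p, c in spec.links],
    }
    if schemes:
        doc["schemes"] = {v: s.to_dict() for v, s in sorted(schemes.items())}
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_yaml(text: str) -> tuple[NetworkSpec, dict[str, BinningScheme]]:
    doc = yaml.safe_load(text)
    nodes = tuple(
        NodeSpec(d["name"], tuple(d["states"]), d.get("kind", "intermediary"),
                 tuple(d["midpoints"]) if d.get("midpoints") else None)
        for d in doc["nodes"]
    )
    links = []
    for item in doc["links"]:
        p, c = (s.strip() for s in item.split("->"))
        links.append((p, c))
    schemes = {v: BinningScheme.from_dict(d)
               for v, d in (doc.get("schemes") or {}).items()}
    return NetworkSpec(nodes, tuple(links)), schemes


def cpts_to_frame(network: Network) -> pd.DataFrame:
    """Fitted CPTs as a flat table: node, parent-state tuple, state, prob."""
    rows = []
    for name in network.node_names:
        cpt = network.cpts[name]
        node = network.node(name)
        for r, combo in enumerate(network.parent_combos(name)):
            for j, state in enumerate(node.states):
                rows.append({
                    "node": name,
                    "parents": "|".join(f"{p}={s}" for p, s in
                                        zip(cpt.parents, combo)),
                    "state": state,
                    "probability": float(cpt.table[r, j]),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 20_240_827
    years: tuple[int, int] = (1975, 2022)
    prior_weight: float = 1.0
    n_bins: int = 5
    evidence_policy: str = "all"
    run_kfold: bool = True

    def as_dict(self) -> dict:
        return {
            "seed": self.seed, "years": list(self.years),
            "prior_weight": self.prior_weight, "n_bins": self.n_bins,
            "evidence_policy": self.evidence_policy,
            "run_kfold": self.run_kfold,
        }


@dataclass
class RunManifest:
    """Traceability record for one pipeline run."""

    config: dict
    seed: int
    split_plan: str
    outputs: list[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()).hexdigest()[:16]

    def write(self, path) -> None:
        doc = {"config": self.config, "seed": self.seed,
               "split_plan": self.split_plan, "config_hash": self.config_hash,
               "outputs": self.outputs, "version": self.version,
               "timestamp": self.timestamp}
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full analysis chain from one seed and write report files.

    Returns a bundle with the fitted network, schemes, confusion matrices,
    score reports, sensitivity rankings, scenario influence table and
    calibration report.  Report files carry no wall-clock content, so two
    runs with the same config are byte-identical; the manifest records the
    configuration hash.
    """
    from . import __version__
    from .sensitivity import rank_findings_frame, scenario_influence
    from .simulate import SimConfig, calibration_report, simulate_dataset
    from .tillage import (OUTPUT_VARS, cases_to_states, fit_tillage_model,
                          scenario_presets)
    from .validate import HOLDOUT_PLAN, evaluate, kfold_report, split

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.as_dict(), config.seed, "holdout+kfold",
                           version=__version__,
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def _stage(name):
        log.info("stage %s", name)
        return time.time()

    t = _stage("simulate")
    cases = simulate_dataset(SimConfig(years=config.years, seed=config.seed))
    calib = calibration_report(cases)
    log.info("simulate: %d cases in %.1fs", len(cases), time.time() - t)

    t = _stage("fit")
    parts = split(cases, HOLDOUT_PLAN)
    net, schemes = fit_tillage_model(parts["train"], config.prior_weight,
                                     config.n_bins)
    test_states = cases_to_states(parts["test"], schemes)
    log.info("fit: %d train / %d test in %.1fs", len(parts["train"]),
             len(parts["test"]), time.time() - t)

    t = _stage("validate")
    matrices, scores = {}, {}
    for target in OUTPUT_VARS:
        cm, rep = evaluate(net, test_states, target, config.evidence_policy)
        matrices[target] = cm
        scores[target] = rep
    kfold = {}
    if config.run_kfold:
        def factory(train):
            return fit_tillage_model(train, config.prior_weight, config.n_bins)
        for target in OUTPUT_VARS:
            kfold[target] = kfold_report(factory, cases, target,
                                         evidence_policy=config.evidence_policy)
    log.info("validate: %.1fs", time.time() - t)

    t = _stage("sensitivity")
    rankings = {target: rank_findings_frame(net, target)
                for target in OUTPUT_VARS}
    presets = scenario_presets(net.node("soilscape").states)
    influence = scenario_influence(net, presets, list(OUTPUT_VARS))
    log.info("sensitivity: %.1fs", time.time() - t)

    # --- write reports ----------------------------------------------------
    files = {
        "calibration.csv": calib,
        "scenario_influence.csv": influence,
    }
    for target, cm in matrices.items():
        files[f"confusion_{target}.csv"] = cm.to_frame()
    files["scores.csv"] = pd.DataFrame([r.as_dict() for r in scores.values()])
    for target, df in kfold.items():
        files[f"kfold_{target}.csv"] = df
    for target, df in rankings.items():
        files[f"sensitivity_{target}.csv"] = df
    for name, df in files.items():
        df.to_csv(outdir / name, float_format="%.6g")
        manifest.outputs.append(name)
    summary = _summary_text(scores, matrices, kfold)
    (outdir / "summary.txt").write_text(summary)
    manifest.outputs.append("summary.txt")
    manifest.write(outdir / "manifest.json")

    return {"cases": cases, "network": net, "schemes": schemes,
            "matrices": matrices, "scores": scores, "kfold": kfold,
            "rankings": rankings, "influence": influence,
            "calibration": calib, "manifest": manifest}


def _summary_text(scores, matrices, kfold) -> str:
    lines = ["Holdout validation (train 1975-2011, test 2012-2022)", ""]
    lines.append(f"{'target':<8}{'n':>6}{'error%':>9}{'logloss':>10}"
                 f"{'quadratic':>11}{'spherical':>11}")
    for t, r in scores.items():
        lines.append(f"{t:<8}{r.n_cases:>6}{r.error_rate:>9.2f}"
                     f"{r.logarithmic_loss:>10.4f}{r.quadratic_loss:>11.4f}"
                     f"{r.spherical_payoff:>11.4f}")
    for t, cm in matrices.items():
        lines += ["", f"Confusion matrix ({t}), actual rows x predicted cols:",
                  cm.to_frame().to_string()]
    if kfold:
        lines.append("")
        lines.append("K-fold cross-validation error rates (%):")
        for t, df in kfold.items():
            parts = ", ".join(f"{r.fold}={r.error_rate:.2f}"
                              for r in df.itertuples())
            lines.append(f"  {t}: {parts}")
    return "\n".join(lines) + "\n"
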
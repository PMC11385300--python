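"""The 11-node tillage–winter-wheat network and case mapping.

Variable roster (4 inputs, 4 intermediaries, 3 outputs):

========== ============== ======================= =====================
node       role           meaning                 units
========== ============== ======================= =====================
tillage    input          tillage system          NT / CT
soilscape  input          soil profile            PDPG6/7/8 x OC level
rainfall   input          seasonal rainfall       mm
temperature input         seasonal mean temp      deg C
csom       intermediary   carbon in soil OM stock kg/ha
aws        intermediary   available water space   cm3 cm-3
interception intermediary precipitation interception  % of rainfall
biomass    intermediary   above-ground biomass    kg/ha
yield      output         wheat grain yield       kg/ha
runoff     output         seasonal surface runoff mm
ghg        output         GHG-CO2 emissions       kgCO2eqv/ha
========== ============== ======================= =====================

No-till (NT) limits soil disturbance; conventional tillage (CT) inverts the
topsoil each season.  Tillage acts on the outputs only through the soil-carbon
and water intermediaries.  Available water space carries the most links of
any node in the default structure.
"""

from __future__ import annotations

import pandas as pd

from .bbn import Network, NetworkSpec, NodeSpec, build_network
from .discretize import BinningScheme, OUTPUT_LABELS, apply_bins

__all__ = [
    "INPUT_VARS", "INTERMEDIARY_VARS", "OUTPUT_VARS", "ALL_VARS",
    "CATEGORICAL_VARS", "CONTINUOUS_VARS", "DEFAULT_LINKS",
    "TILLAGE_STATES", "default_soil_states", "default_structure",
    "cases_to_states", "fit_tillage_model", "scenario_presets",
]

INPUT_VARS = ("tillage", "soilscape", "rainfall", "temperature")
INTERMEDIARY_VARS = ("csom", "aws", "interception", "biomass")
OUTPUT_VARS = ("yield", "runoff", "ghg")
ALL_VARS = INPUT_VARS + INTERMEDIARY_VARS + OUTPUT_VARS

CATEGORICAL_VARS = ("tillage", "soilscape")
CONTINUOUS_VARS = tuple(v for v in ALL_VARS if v not in CATEGORICAL_VARS)

TILLAGE_STATES = ("NT", "CT")

SOILSCAPES = ("PDPG6", "PDPG7", "PDPG8")
NATIVE_OC = {"PDPG6": 2.6, "PDPG7": 4.4, "PDPG8": 3.9}
MODELED_OC = (1.0, 3.0, 5.0, 7.0)

# 17 directed links.  Tillage and soilscape act through the soil carbon and
# water intermediaries; aws ends up with the largest link count (6).
DEFAULT_LINKS: tuple[tuple[str, str], ...] = (
    ("tillage", "csom"),
    ("tillage", "aws"),
    ("soilscape", "csom"),
    ("soilscape", "aws"),
    ("rainfall", "aws"),
    ("rainfall", "biomass"),
    ("rainfall", "runoff"),
    ("temperature", "biomass"),
    ("temperature", "ghg"),
    ("csom", "aws"),
    ("csom", "yield"),
    ("csom", "ghg"),
    ("aws", "biomass"),
    ("aws", "runoff"),
    ("biomass", "interception"),
    ("biomass", "yield"),
    ("interception", "runoff"),
)


def _fmt_oc(oc: float) -> str:
    return f"{oc:g}"


def soil_id(soilscape: str, oc_percent: float) -> str:
    """Canonical soil-profile label, e.g. ``OC-7%PDPG8``."""
    return f"OC-{_fmt_oc(oc_percent)}%{soilscape}"


def experiment_id(tillage: str, soilscape: str, oc_percent: float) -> str:
    """Experiment label in the field's style, e.g. ``NT.OC-7%PDPG8``."""
    return f"{tillage}.{soil_id(soilscape, oc_percent)}"


def default_soil_states() -> tuple[str, ...]:
    """The 15 soil-profile states: native OC plus 4 modeled levels per
    soilscape, ordered by soilscape then OC level."""
    states = []
    for scape in SOILSCAPES:
        for oc in sorted(set(MODELED_OC) | {NATIVE_OC[scape]}):
            states.append(soil_id(scape, oc))
    return tuple(states)


def default_structure(
    soil_states: tuple[str, ...] | None = None,
    n_bands: int = 5,
    schemes: dict[str, BinningScheme] | None = None,
) -> NetworkSpec:
    """The default 11-node / 17-link DAG.

    Band labels (and midpoints, for sensitivity analysis) of the continuous
    nodes come from fitted ``schemes`` when given; otherwise the canonical
    5-band labels are used unfitted.  The three output nodes always have 5
    states.
    """
    if soil_states is None:
        soil_states = default_soil_states()
    kinds = {v: "input" for v in INPUT_VARS}
    kinds.update({v: "intermediary" for v in INTERMEDIARY_VARS})
    kinds.update({v: "output" for v in OUTPUT_VARS})

    nodes = [
        NodeSpec("tillage", TILLAGE_STATES, "input"),
        NodeSpec("soilscape", tuple(soil_states), "input"),
    ]
    for var in ALL_VARS:
        if var in CATEGORICAL_VARS:
            continue
        nb = 5 if var in OUTPUT_VARS else n_bands
        if schemes is not None and var in schemes:
            sch = schemes[var]
            nodes.append(NodeSpec(var, sch.labels, kinds[var], sch.midpoints))
        else:
            labels = OUTPUT_LABELS if nb == 5 else tuple(f"B{i+1}" for i in range(nb))
            nodes.append(NodeSpec(var, labels, kinds[var]))
    # keep declared node order = roster order
    order = {v: i for i, v in enumerate(ALL_VARS)}
    nodes.sort(key=lambda n: order[n.name])
    return NetworkSpec(tuple(nodes), DEFAULT_LINKS)


def cases_to_states(records: pd.DataFrame, schemes: dict[str, BinningScheme]) -> pd.DataFrame:
    """Discretize continuous variables to band labels; categoricals pass
    through; ``year`` and ``experiment`` are preserved for splitting."""
    missing = [c for c in ALL_VARS if c not in records.columns]
    if missing:
        raise ValueError(f"case table missing columns: {missing}")
    if records[list(ALL_VARS)].isna().any().any():
        bad = records[records[list(ALL_VARS)].isna().any(axis=1)].index[0]
        raise ValueError(f"missing value in case row {bad}")
    out = {}
    for col in ("experiment", "year"):
        if col in records.columns:
            out[col] = records[col].to_numpy()
    for var in ALL_VARS:
        if var in CATEGORICAL_VARS:
            out[var] = records[var].astype(str).to_numpy()
        else:
            out[var] = apply_bins(records[var].to_numpy(), schemes[var])
    return pd.DataFrame(out, index=records.index)


def fit_schemes(train: pd.DataFrame, n_bins: int = 5) -> dict[str, BinningScheme]:
    """Quantile banding schemes for all continuous variables, fitted on the
    training rows only (outputs always get the canonical 5 bands)."""
    from .discretize import fit_bins, scheme_for_output

    schemes = {}
    for var in CONTINUOUS_VARS:
        if var in OUTPUT_VARS:
            schemes[var] = scheme_for_output(var, train[var].to_numpy())
        else:
            schemes[var] = fit_bins(train[var].to_numpy(), n_bins, "quantile",
                                    variable=var)
    return schemes


def fit_tillage_model(
    train: pd.DataFrame,
    prior_weight: float = 1.0,
    n_bins: int = 5,
) -> tuple[Network, dict[str, BinningScheme]]:
    """Fit the whole model on raw training cases: band schemes, then CPTs.

    Returns the fitted network and the schemes needed to discretize test
    cases.  Nothing from outside ``train`` enters the fit.
    """
    from .bbn import learn_cpts

    schemes = fit_schemes(train, n_bins=n_bins)
    observed = train["soilscape"].astype(str).unique()

    def _soil_key(s: str):
        try:  # canonical "OC-<x>%<scape>" ids sort by scape then OC level
            oc, scape = s.split("%", 1)
            return (0, scape, float(oc[3:]))
        except (ValueError, IndexError):
            return (1, s, 0.0)

    soil_states = tuple(sorted(observed, key=_soil_key))
    spec = default_structure(soil_states, n_bands=n_bins, schemes=schemes)
    net = build_network(spec)
    states = cases_to_states(train, schemes)
    learn_cpts(net, states[list(ALL_VARS)].to_dict("records"), prior_weight)
    return net, schemes


def scenario_presets(soil_states: tuple[str, ...] | None = None) -> dict[str, dict[str, str]]:
    """Named evidence sets for influence analysis.

    ``favorable`` pairs no-till with the highest-carbon soil under moderate
    rainfall; ``unfavorable`` pairs conventional tillage with the
    lowest-carbon soil under extreme rainfall.
    """
    if soil_states is None:
        soil_states = default_soil_states()
    high_oc = soil_id("PDPG8", 7.0)
    low_oc = soil_id("PDPG6", 1.0)
    if high_oc not in soil_states:
        high_oc = soil_states[-1]
    if low_oc not in soil_states:
        low_oc = soil_states[0]
    return {
        "NT": {"tillage": "NT"},
        "CT": {"tillage": "CT"},
        "favorable": {"tillage": "NT", "soilscape": high_oc, "rainfall": "Medium"},
        "unfavorable": {"tillage": "CT", "soilscape": low_oc, "rainfall": "Very high"},
    }
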
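"""Banding of continuous variables into ordered states.

The network operates on ordered bands ("Very low" … "Very high") cut from the
statistical distribution of each continuous variable on the *training* data.
The default method places boundaries at empirical quantiles (linear
interpolation between order statistics), so bands are near-equally populated
on the fitting data; equal-width and explicit boundaries are also available.

Interval convention: half-open ``[b_{k-1}, b_k)`` with the last band closed
above; values outside the fitted range clamp to the outermost bands (test
seasons can exceed the training range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BinningScheme", "fit_bins", "apply_bins", "scheme_for_output",
           "OUTPUT_LABELS", "default_labels"]

OUTPUT_LABELS = ("Very low", "Low", "Medium", "High", "Very high")


class BinningError(ValueError):
    pass


def default_labels(n: int) -> tuple[str, ...]:
    if n == 1:
        return ("All",)
    if n == 5:
        return OUTPUT_LABELS
    return tuple(f"B{i + 1}" for i in range(n))


@dataclass(frozen=True)
class BinningScheme:
    """Fitted banding for one variable.

    ``boundaries`` are the n_bands-1 strictly increasing interior cut points
    (variable units); ``midpoints`` are the within-band medians of the fitting
    data and serve as the band's representative real value for variance-based
    sensitivity analysis.
    """

    variable: str
    method: str  # quantile | equal_width | explicit
    boundaries: tuple[float, ...]
    labels: tuple[str, ...]
    midpoints: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "boundaries", tuple(float(b) for b in self.boundaries))
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "midpoints", tuple(float(m) for m in self.midpoints))
        if len(self.labels) != len(self.boundaries) + 1:
            raise BinningError(
                f"{self.variable}: {len(self.labels)} labels need "
                f"{len(self.labels) - 1} boundaries, got {len(self.boundaries)}"
            )
        if any(b <= a for a, b in zip(self.boundaries, self.boundaries[1:])):
            raise BinningError(f"{self.variable}: boundaries not strictly increasing")
        if len(self.midpoints) != len(self.labels):
            raise BinningError(f"{self.variable}: one midpoint per band required")
        if any(b <= a for a, b in zip(self.midpoints, self.midpoints[1:])):
            raise BinningError(f"{self.variable}: midpoints not strictly increasing")

    @property
    def n_bands(self) -> int:
        return len(self.labels)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "method": self.method,
            "boundaries": list(self.boundaries),
            "labels": list(self.labels),
            "midpoints": list(self.midpoints),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        return cls(d["variable"], d["method"], tuple(d["boundaries"]),
                   tuple(d["labels"]), tuple(d["midpoints"]))


def _band_midpoints(values: np.ndarray, boundaries: tuple[float, ...]) -> list[float]:
    """Within-band medians of the fitting data; jittered if bands collide."""
    idx = np.searchsorted(boundaries, values, side="right")
    mids: list[float] = []
    for k in range(len(boundaries) + 1):
        band = values[idx == k]
        if band.size:
            mids.append(float(np.median(band)))
        elif mids:
            mids.append(mids[-1])
        else:
            mids.append(float(values.min()))
    # strict monotonicity (bands dominated by ties can repeat a median)
    for i in range(1, len(mids)):
        if mids[i] <= mids[i - 1]:
            mids[i] = np.nextafter(mids[i - 1], np.inf)
    return mids


def fit_bins(values, n_bins: int, method: str = "quantile",
             labels: tuple[str, ...] | None = None,
             boundaries: tuple[float, ...] | None = None,
             variable: str = "x") -> BinningScheme:
    """Fit a banding scheme to training values.

    quantile: interior boundaries at the k/n_bins empirical quantiles
    (numpy's linear-interpolation definition).  equal_width: [min, max]
    divided evenly.  explicit: boundaries given by the caller.  Duplicate
    boundaries collapse (with a warning) to fewer bands; a constant vector
    yields a single band.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise BinningError(f"{variable}: empty input")
    if n_bins < 1:
        raise BinningError(f"{variable}: n_bins must be >= 1")

    if method == "quantile":
        qs = np.arange(1, n_bins) / n_bins
        cuts = np.quantile(values, qs) if n_bins > 1 else np.array([])
    elif method == "equal_width":
        cuts = np.linspace(values.min(), values.max(), n_bins + 1)[1:-1]
    elif method == "explicit":
        if boundaries is None:
            raise BinningError(f"{variable}: explicit method needs boundaries")
        cuts = np.asarray(boundaries, dtype=float)
        if len(cuts) != n_bins - 1:
            raise BinningError(f"{variable}: need {n_bins - 1} explicit boundaries")
    else:
        raise BinningError(f"{variable}: unknown method {method!r}")

    vmin, vmax = float(values.min()), float(values.max())
    uniq = []
    for c in cuts:
        # a cut must split the fitting data: strictly above the minimum
        # (else the lowest band is empty) and not above the maximum
        if c <= vmin or c > vmax:
            continue
        if not uniq or c > uniq[-1]:
            uniq.append(float(c))
    if len(uniq) < len(cuts):
        warnings.warn(
            f"{variable}: collapsed {len(cuts) - len(uniq)} duplicate boundaries; "
            f"{len(uniq) + 1} bands instead of {n_bins}",
            stacklevel=2,
        )
    n_eff = len(uniq) + 1
    if labels is None:
        labels = default_labels(n_eff)
    elif n_eff != len(labels):
        labels = labels[:n_eff] if n_eff < len(labels) else default_labels(n_eff)
    mids = _band_midpoints(values, tuple(uniq))
    return BinningScheme(variable, method, tuple(uniq), tuple(labels), tuple(mids))


def apply_bins(values, scheme: BinningScheme):
    """Map values to band labels under the scheme's interval convention.

    A value exactly on a boundary goes to the higher band; out-of-range
    values clamp to the outermost bands.  Scalar in, scalar out.
    """
    scalar = np.isscalar(values)
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    idx = np.searchsorted(np.asarray(scheme.boundaries), arr, side="right")
    labels = np.asarray(scheme.labels, dtype=object)[idx]
    return labels[0] if scalar else list(labels)


def scheme_for_output(variable: str, training_values) -> BinningScheme:
    """Canonical 5-band quantile scheme (Very low … Very high) for an output
    variable, fitted on training data only."""
    return fit_bins(training_values, 5, "quantile", OUTPUT_LABELS, variable=variable)
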
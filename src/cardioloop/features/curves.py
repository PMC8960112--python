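"""Time-resolved feature curves and global-function parameters."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

AGGREGATES = ("min", "max", "median", "mean")


@dataclass
class FeatureCurve:
    """One named scalar feature sampled at every cardiac phase.

    Missing per-phase values are NaN; aggregates are NaN-aware and always
    recomputable from ``values``.
    """

    name: str
    values: np.ndarray
    units: str = ""
    aggregates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.aggregates:
            self.aggregates = compute_aggregates(self.values)

    def __len__(self) -> int:
        return len(self.values)


def compute_aggregates(values: np.ndarray) -> dict[str, float]:
    values = np.asarray(values, dtype=float)
    if np.all(np.isnan(values)):
        return {agg: float("nan") for agg in AGGREGATES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {
            "min": float(np.nanmin(values)),
            "max": float(np.nanmax(values)),
            "median": float(np.nanmedian(values)),
            "mean": float(np.nanmean(values)),
        }


def function_parameters(volume_curve: FeatureCurve | np.ndarray) -> dict[str, float]:
    """EDV/ESV/EF and their phases from an LV blood-pool volume curve.

    End-diastole is the curve maximum, end-systole the minimum (first
    occurrence on ties); EF = (EDV - ESV) / EDV, 0 for a flat or empty
    curve.
    """
    values = volume_curve.values if isinstance(volume_curve, FeatureCurve) else np.asarray(
        volume_curve, dtype=float)
    if len(values) == 0 or np.all(np.isnan(values)):
        nan = float("nan")
        return {"edv_ml": nan, "esv_ml": nan, "ef": nan, "ed_phase": -1, "es_phase": -1}
    ed_phase = int(np.nanargmax(values))
    es_phase = int(np.nanargmin(values))
    edv = float(values[ed_phase])
    esv = float(values[es_phase])
    ef = 0.0 if edv <= 0 else (edv - esv) / edv
    return {"edv_ml": edv, "esv_ml": esv, "ef": ef,
            "ed_phase": ed_phase, "es_phase": es_phase}
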
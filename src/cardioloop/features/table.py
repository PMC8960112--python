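"""Cohort feature tables: per-phase curves aggregated to one row per case-session."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..datamodel import Case, Patient, Session, feature_row_id, iter_cases
from . import shape, texture
from .curves import AGGREGATES, FeatureCurve, function_parameters

log = logging.getLogger(__name__)

ID_COLUMNS = ("row_id", "case_id", "session_id", "class_label")


@dataclass(frozen=True)
class BaseFeature:
    key: str
    structure: str | None
    group: str
    units: str = ""
    time_resolved: bool = True


# The shipped presets.  "default" is the documented full set; "fast" keeps
# the cheap, strongly class-separating features for large simulated cohorts.
FEATURE_PRESETS: dict[str, list[BaseFeature]] = {
    "default": [
        BaseFeature("volume", "lv_bloodpool", "shape", "ml"),
        BaseFeature("volume", "lv_myocardium", "shape", "ml"),
        BaseFeature("volume", "rv_bloodpool", "shape", "ml"),
        BaseFeature("surface_area", "lv_bloodpool", "shape", "mm2"),
        BaseFeature("surface_area", "lv_myocardium", "shape", "mm2"),
        BaseFeature("sphericity", "lv_bloodpool", "shape"),
        BaseFeature("sphericity", "lv_myocardium", "shape"),
        BaseFeature("tortuosity", "lv_bloodpool", "shape"),
        BaseFeature("fractal_dimension", "lv_myocardium", "shape"),
        BaseFeature("glcm_contrast", "lv_myocardium", "glcm"),
        BaseFeature("glcm_difference_entropy", "lv_myocardium", "glcm"),
        BaseFeature("glcm_cluster_tendency", "lv_myocardium", "glcm"),
        BaseFeature("ngtdm_coarseness", "lv_myocardium", "ngtdm"),
        BaseFeature("ngtdm_complexity", "lv_myocardium", "ngtdm"),
        BaseFeature("ngtdm_coarseness", "lv_bloodpool", "ngtdm"),
        BaseFeature("intensity_mean", "lv_myocardium", "first_order"),
        BaseFeature("intensity_std", "lv_myocardium", "first_order"),
        BaseFeature("intensity_mean", "lv_bloodpool", "first_order"),
        BaseFeature("intensity_std", "lv_bloodpool", "first_order"),
        BaseFeature("septum_thickness", None, "cardiac", "mm"),
        BaseFeature("relative_septum_thickness", None, "cardiac"),
        BaseFeature("edv_ml", None, "cardiac", "ml", time_resolved=False),
        BaseFeature("esv_ml", None, "cardiac", "ml", time_resolved=False),
        BaseFeature("ef", None, "cardiac", time_resolved=False),
    ],
    "fast": [
        BaseFeature("volume", "lv_bloodpool", "shape", "ml"),
        BaseFeature("volume", "lv_myocardium", "shape", "ml"),
        BaseFeature("volume", "rv_bloodpool", "shape", "ml"),
        BaseFeature("intensity_mean", "lv_myocardium", "first_order"),
        BaseFeature("intensity_std", "lv_myocardium", "first_order"),
        BaseFeature("intensity_mean", "lv_bloodpool", "first_order"),
        BaseFeature("intensity_std", "lv_bloodpool", "first_order"),
        BaseFeature("septum_thickness", None, "cardiac", "mm"),
        BaseFeature("relative_septum_thickness", None, "cardiac"),
        BaseFeature("edv_ml", None, "cardiac", "ml", time_resolved=False),
        BaseFeature("esv_ml", None, "cardiac", "ml", time_resolved=False),
        BaseFeature("ef", None, "cardiac", time_resolved=False),
    ],
}


def _feature_name(feat: BaseFeature) -> str:
    return f"{feat.structure}.{feat.key}" if feat.structure else feat.key


@dataclass
class FeatureTable:
    """Cohort matrix: aggregated feature columns + clinical scalars per row."""

    data: pd.DataFrame
    schema: list[dict] = field(default_factory=list)

    @property
    def feature_columns(self) -> list[str]:
        return [entry["column"] for entry in self.schema]

    def columns_by_group(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for entry in self.schema:
            groups.setdefault(entry["group"], []).append(entry["column"])
        return groups

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False, na_rep="NA")
        Path(str(path) + ".schema.json").write_text(
            json.dumps(self.schema, indent=2) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        data = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
        schema_path = Path(str(path) + ".schema.json")
        schema = json.loads(schema_path.read_text()) if schema_path.exists() else [
            {"column": c, "group": "unknown"} for c in data.columns
            if c not in ID_COLUMNS
        ]
        return cls(data=data, schema=schema)


def _slice_mean(values: list[float | None]) -> float:
    present = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.mean(present)) if present else float("nan")


def extract_case_curves(
    case: Case, session: Session, feature_set: str | list[BaseFeature] = "default",
    bins: int = 32,
) -> tuple[dict[str, FeatureCurve], dict[str, float]]:
    """Per-phase feature curves and scalar features for one case-session.

    Slice-wise features (tortuosity, fractal dimension, septum thickness)
    enter the curve as the mean over the slices on which they are defined.
    Features of absent structures are NaN per phase (logged), never zero.
    """
    feats = FEATURE_PRESETS[feature_set] if isinstance(feature_set, str) else feature_set
    mask = session.mask
    image = case.image
    phases = mask.phase_count
    n_slices = mask.grid_shape[0]

    curve_feats = [f for f in feats if f.time_resolved]
    raw = {_feature_name(f): np.full(phases, np.nan) for f in curve_feats}

    # volumes vectorized across all phases
    for feat in curve_feats:
        if feat.key == "volume":
            counts = mask.structure(feat.structure).sum(axis=(1, 2, 3))
            raw[_feature_name(feat)] = counts * mask.voxel_volume_mm3 / 1000.0

    texture_cache: dict[tuple[str, str, int], dict | None] = {}

    def _texture(kind: str, structure: str, phase: int) -> dict | None:
        key = (kind, structure, phase)
        if key not in texture_cache:
            fn = {"glcm": texture.glcm_features,
                  "ngtdm": texture.ngtdm_features,
                  "first_order": texture.first_order_features}[kind]
            if kind == "first_order":
                texture_cache[key] = fn(image, mask, structure, phase)
            else:
                texture_cache[key] = fn(image, mask, structure, phase, bins=bins)
        return texture_cache[key]

    for p in range(phases):
        septum_vals: list | None = None
        for feat in curve_feats:
            name = _feature_name(feat)
            key, struct = feat.key, feat.structure
            if key == "volume":
                continue
            value: float | None = None
            if key == "surface_area":
                value = shape.surface_area(mask, struct, p)
            elif key == "sphericity":
                value = shape.sphericity(mask, struct, p)
            elif key == "tortuosity":
                value = _slice_mean([shape.lv_tortuosity(mask, p, s) for s in range(n_slices)])
            elif key == "fractal_dimension":
                value = _slice_mean(
                    [shape.fractal_dimension(mask, struct, p, s) for s in range(n_slices)])
            elif key.startswith("glcm_"):
                out = _texture("glcm", struct, p)
                value = out[key[len("glcm_"):]] if out else None
            elif key.startswith("ngtdm_"):
                out = _texture("ngtdm", struct, p)
                value = out[key[len("ngtdm_"):]] if out else None
            elif key in ("intensity_mean", "intensity_std"):
                out = _texture("first_order", struct, p)
                value = out[key] if out else None
            elif key in ("septum_thickness", "relative_septum_thickness"):
                if septum_vals is None:
                    septum_vals = [shape.septum_thickness(mask, p, s) for s in range(n_slices)]
                idx = 0 if key == "septum_thickness" else 1
                value = _slice_mean([v[idx] if v else None for v in septum_vals])
            else:
                raise ValueError(f"unknown base feature {key!r}")
            if value is None or not np.isfinite(value):
                log.info("case %s: feature %s missing at phase %d", case.case_id, name, p)
                value = float("nan")
            raw[name][p] = value

    curves = {
        name: FeatureCurve(name=name, values=vals,
                           units=next(f.units for f in curve_feats if _feature_name(f) == name))
        for name, vals in raw.items()
    }

    scalars: dict[str, float] = {}
    scalar_keys = {f.key for f in feats if not f.time_resolved}
    if scalar_keys & {"edv_ml", "esv_ml", "ef"}:
        vol_curve = raw.get("lv_bloodpool.volume")
        if vol_curve is None:
            counts = mask.structure("lv_bloodpool").sum(axis=(1, 2, 3))
            vol_curve = counts * mask.voxel_volume_mm3 / 1000.0
        fn = function_parameters(np.asarray(vol_curve))
        for key in ("edv_ml", "esv_ml", "ef"):
            if key in scalar_keys:
                scalars[key] = fn[key]
    return curves, scalars


def extract_feature_table(
    cohort: list[Patient],
    feature_set: str | list[BaseFeature] = "default",
    clinical_keys: tuple[str, ...] = ("height_cm", "weight_kg"),
    sessions: dict[str, str] | None = None,
    bins: int = 32,
) -> FeatureTable:
    """One row per (case, session): aggregated curves + clinical scalars.

    By default the latest session of each case is used; ``sessions`` maps
    case ids to explicit session ids.  Column order is deterministic and
    identical across rows; missing values are NaN (written as ``NA``).
    """
    feats = FEATURE_PRESETS[feature_set] if isinstance(feature_set, str) else feature_set
    schema: list[dict] = []
    for feat in feats:
        name = _feature_name(feat)
        if feat.time_resolved:
            for agg in AGGREGATES:
                schema.append({"column": f"{name}.{agg}", "base_feature": feat.key,
                               "structure": feat.structure, "aggregate": agg,
                               "units": feat.units, "group": feat.group})
        else:
            schema.append({"column": name, "base_feature": feat.key,
                           "structure": feat.structure, "aggregate": None,
                           "units": feat.units, "group": feat.group})
    for key in clinical_keys:
        schema.append({"column": key, "base_feature": key, "structure": None,
                       "aggregate": None, "units": "", "group": "clinical"})

    rows = []
    for case in iter_cases(cohort):
        if sessions and case.case_id in sessions:
            session = case.session(sessions[case.case_id])
        else:
            session = case.latest_session()
        curves, scalars = extract_case_curves(case, session, feats, bins=bins)
        row: dict = {
            "row_id": feature_row_id(case.case_id, session.session_id),
            "case_id": case.case_id,
            "session_id": session.session_id,
            "class_label": case.class_label,
        }
        for name, curve in curves.items():
            for agg in AGGREGATES:
                row[f"{name}.{agg}"] = curve.aggregates[agg]
        row.update(scalars)
        for key in clinical_keys:
            row[key] = case.clinical.get(key, float("nan"))
        rows.append(row)

    columns = list(ID_COLUMNS) + [entry["column"] for entry in schema]
    data = pd.DataFrame(rows, columns=columns)
    if data["case_id"].duplicated().any() and sessions is None:
        raise ValueError("duplicate case ids in cohort")
    return FeatureTable(data=data, schema=schema)
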
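"""Automated outlier triage: the scripted stand-in for interactive brushing.

Three rule families flag cases whose features or slice geometry indicate a
segmentation or acquisition failure:

``feature_outliers``
    Robust z-score (median/MAD) range exclusion per feature axis of the
    cohort feature table — the automated equivalent of excluding extreme
    tails with parallel-coordinate brushes.
``slice_misalignment``
    Breath-motion detector: maximum adjacent-slice displacement of the LV
    blood-pool centroid at end-diastole, normalized by the pool's
    equivalent radius so the score is resolution-independent.
``curve_discontinuity``
    Single-phase failure detector: relative residual of each structure's
    volume curve against a circular 4-point cubic interpolation of its
    neighbours.  A smooth cyclic contraction has tiny residuals; a dropout
    or dilation at one phase leaves an isolated spike.

Thresholds are package defaults validated on phantom cohorts (see methods
note); flagged cases are merged into a deterministic, score-ordered
correction worklist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .datamodel import STRUCTURES, Session
from .features.table import FeatureTable

log = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # MAD -> sigma for normal data

#: Feature axes watched by default, mirroring typical brushing choices:
#: texture of the myocardium and blood pool, septal geometry, endocardial
#: contour complexity.  Matching aggregate columns are selected per table.
DEFAULT_WATCH_FEATURES = (
    "septum_thickness",
    "lv_bloodpool.tortuosity",
    "lv_myocardium.glcm_cluster_tendency",
    "lv_myocardium.glcm_contrast",
    "lv_myocardium.ngtdm_complexity",
    "lv_bloodpool.ngtdm_coarseness",
)

MISALIGNMENT_THRESHOLD = 0.5
CURVE_JUMP_THRESHOLD = 0.08


@dataclass(frozen=True)
class Flag:
    rule: str
    subject: str          # triggering feature column, or structure/slice
    score: float
    threshold: float

    @property
    def severity(self) -> float:
        """Score in units of its threshold (comparable across rules)."""
        return self.score / self.threshold if self.threshold > 0 else self.score


@dataclass
class OutlierReport:
    per_case: dict[str, list[Flag]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add(self, case_id: str, flag: Flag) -> None:
        self.per_case.setdefault(case_id, []).append(flag)

    def is_flagged(self, case_id: str) -> bool:
        return bool(self.per_case.get(case_id))

    @property
    def flagged_cases(self) -> list[str]:
        return sorted(cid for cid, flags in self.per_case.items() if flags)

    def summary(self) -> dict:
        return {
            "n_flagged": len(self.flagged_cases),
            "flags_per_rule": _rule_counts(self.per_case),
            "warnings": list(self.warnings),
        }

    def to_dict(self) -> dict:
        return {
            "cases": {
                cid: [{"rule": f.rule, "subject": f.subject, "score": f.score,
                       "threshold": f.threshold} for f in flags]
                for cid, flags in sorted(self.per_case.items())
            },
            "summary": self.summary(),
        }


def _rule_counts(per_case: dict[str, list[Flag]]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for flags in per_case.values():
        for f in flags:
            counts[f.rule] = counts.get(f.rule, 0) + 1
    return counts


def feature_outliers(
    table: FeatureTable | pd.DataFrame,
    features: list[str] | None = None,
    z_threshold: float = 3.0,
) -> OutlierReport:
    """Flag cases with |robust z| > threshold on any watched feature axis.

    Robust z = (x - median) / (1.4826 * MAD).  Features whose MAD is zero
    are skipped with a warning; NaN values are never flagged.
    """
    df = table.data if isinstance(table, FeatureTable) else table
    if features is None:
        features = [c for c in df.columns
                    if any(c.startswith(w) for w in DEFAULT_WATCH_FEATURES)]
    report = OutlierReport()
    if not features:
        report.warnings.append("no watched feature columns present; nothing checked")
        return report
    for col in features:
        if col not in df.columns:
            report.warnings.append(f"feature {col!r} not in table; skipped")
            continue
        x = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        finite = np.isfinite(x)
        if finite.sum() < 3:
            report.warnings.append(f"feature {col!r} has < 3 finite values; skipped")
            continue
        med = float(np.median(x[finite]))
        mad = float(np.median(np.abs(x[finite] - med)))
        if mad == 0.0:
            report.warnings.append(f"feature {col!r} has zero MAD; skipped")
            log.warning("feature %s has zero MAD; skipped", col)
            continue
        z = np.abs(x - med) / (MAD_SCALE * mad)
        for idx in np.nonzero(finite & (z > z_threshold))[0]:
            case_id = str(df.iloc[idx]["case_id"]) if "case_id" in df.columns else str(idx)
            report.add(case_id, Flag("robust_z", col, float(z[idx]), z_threshold))
    return report


def slice_misalignment(
    session: Session, threshold: float = MISALIGNMENT_THRESHOLD,
    ed_phase: int | None = None,
) -> dict:
    """Adjacent-slice LV blood-pool centroid displacement score at ED.

    Score = max over adjacent slice pairs of centroid displacement divided
    by the pool's equivalent radius; also reports the maximum inter-slice
    area jump ratio.  A single-slice (or empty) pool scores 0.
    """
    mask = session.mask
    pool4 = mask.structure("lv_bloodpool")
    if ed_phase is None:
        ed_phase = int(np.argmax(pool4.sum(axis=(1, 2, 3))))
    pool = pool4[ed_phase]
    row_mm, col_mm = mask.spacing[1], mask.spacing[2]
    centroids, areas = [], []
    for s in range(pool.shape[0]):
        if pool[s].any():
            c = np.array(ndimage.center_of_mass(pool[s])) * [row_mm, col_mm]
            centroids.append(c)
            areas.append(float(pool[s].sum()) * row_mm * col_mm)
        else:
            centroids.append(None)
            areas.append(0.0)
    score = 0.0
    area_jump = 0.0
    present = [i for i, c in enumerate(centroids) if c is not None]
    for a, b in zip(present[:-1], present[1:]):
        if b - a != 1:
            continue
        disp = float(np.linalg.norm(centroids[a] - centroids[b]))
        r_eq = float(np.sqrt(0.5 * (areas[a] + areas[b]) / np.pi))
        if r_eq > 0:
            score = max(score, disp / r_eq)
        denom = max(areas[a], areas[b])
        if denom > 0:
            area_jump = max(area_jump, abs(areas[a] - areas[b]) / denom)
    return {
        "case_id": session.case_id,
        "score": score,
        "flag": score >= threshold,
        "threshold": threshold,
        "area_jump_ratio": area_jump,
        "ed_phase": ed_phase,
    }


def curve_discontinuity(
    session: Session, threshold: float = CURVE_JUMP_THRESHOLD,
    structures: tuple[str, ...] = STRUCTURES,
) -> dict:
    """Spike score of per-structure volume curves (cyclic cubic residual).

    For each phase t the expected volume is the 4-point cubic interpolation
    of its circular neighbours, (-V[t-2] + 4V[t-1] + 4V[t+1] - V[t+2]) / 6;
    the score is the maximum relative residual over phases and structures.
    Needs >= 5 phases (else 0: a spike cannot be told from contraction).
    """
    mask = session.mask
    phases = mask.phase_count
    best = 0.0
    subject = ""
    if phases >= 5:
        for structure in structures:
            v = mask.structure(structure).sum(axis=(1, 2, 3)).astype(float)
            if v.max() <= 0:
                continue
            predicted = (-np.roll(v, 2) + 4 * np.roll(v, 1)
                         + 4 * np.roll(v, -1) - np.roll(v, -2)) / 6.0
            floor = 0.05 * v.max()
            resid = np.abs(v - predicted) / np.maximum(np.abs(predicted), floor)
            s = float(resid.max())
            if s > best:
                best, subject = s, f"{structure}@phase{int(resid.argmax())}"
    return {
        "case_id": session.case_id,
        "score": best,
        "flag": best > threshold,
        "threshold": threshold,
        "subject": subject,
    }


def mask_outlier_report(
    cohort,
    misalignment_threshold: float = MISALIGNMENT_THRESHOLD,
    curve_threshold: float = CURVE_JUMP_THRESHOLD,
) -> OutlierReport:
    """Run the mask-based rules on the latest session of every case."""
    from .datamodel import iter_cases

    report = OutlierReport()
    for case in iter_cases(cohort):
        if not case.sessions:
            report.warnings.append(f"case {case.case_id} has no sessions; skipped")
            continue
        session = case.latest_session()
        mis = slice_misalignment(session, misalignment_threshold)
        if mis["flag"]:
            report.add(case.case_id, Flag("slice_misalignment", "lv_bloodpool",
                                          mis["score"], mis["threshold"]))
        jump = curve_discontinuity(session, curve_threshold)
        if jump["flag"]:
            report.add(case.case_id, Flag("curve_discontinuity", jump["subject"],
                                          jump["score"], jump["threshold"]))
    return report


@dataclass(frozen=True)
class WorklistItem:
    case_id: str
    severity: float
    reasons: tuple[str, ...]


def build_worklist(*reports: OutlierReport) -> list[WorklistItem]:
    """Merge reports into a correction worklist, worst cases first.

    Ordered by maximum flag severity (score over threshold) descending,
    ties broken by case id, so identical inputs always yield the same list.
    """
    merged: dict[str, list[Flag]] = {}
    for report in reports:
        for case_id, flags in report.per_case.items():
            merged.setdefault(case_id, []).extend(flags)
    items = [
        WorklistItem(
            case_id=cid,
            severity=max(f.severity for f in flags),
            reasons=tuple(sorted({f"{f.rule}:{f.subject}" for f in flags})),
        )
        for cid, flags in merged.items() if flags
    ]
    return sorted(items, key=lambda it: (-it.severity, it.case_id))


def render_pcp(
    table: FeatureTable | pd.DataFrame,
    features: list[str],
    flagged: set[str] | None = None,
    path: str | None = None,
):
    """Static parallel-coordinates plot (SVG) of the cohort feature table.

    Each line is one case; flagged cases are drawn in red on top — a
    non-interactive rendering of the brushing view.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.data if isinstance(table, FeatureTable) else table
    features = [f for f in features if f in df.columns]
    if not features:
        raise ValueError("no plottable features")
    flagged = flagged or set()
    x = np.arange(len(features))
    fig, ax = plt.subplots(figsize=(max(6, 1.5 * len(features)), 4))
    norm = {}
    for f in features:
        col = pd.to_numeric(df[f], errors="coerce")
        lo, hi = np.nanmin(col), np.nanmax(col)
        norm[f] = (col - lo) / (hi - lo) if hi > lo else col * 0 + 0.5
    for _, row in df.iterrows():
        ys = [norm[f].loc[row.name] for f in features]
        is_flagged = str(row.get("case_id", "")) in flagged
        ax.plot(x, ys, color="crimson" if is_flagged else "steelblue",
                alpha=0.9 if is_flagged else 0.3, lw=1.5 if is_flagged else 0.8,
                zorder=3 if is_flagged else 2)
    ax.set_xticks(x)
    ax.set_xticklabels(features, rotation=30, ha="right", fontsize=7)
    ax.set_yticks([])
    for xi in x:
        ax.axvline(xi, color="0.8", lw=0.5, zorder=1)
    fig.tight_layout()
    if path:
        fig.savefig(path, format="svg")
        plt.close(fig)
        return None
    return fig
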
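"""Synthetic short-axis cardiac phantom cohorts with known ground truth.

Each case is a stacked-disc left ventricle: per slice the endocardial and
epicardial borders are concentric circles whose radius tapers linearly by
40% from base to apex, mirroring short-axis acquisition geometry and keeping
per-slice analytic volumes exact.  The right ventricle is a crescent
adjacent to the LV at a fixed angular position.  Contraction scales the
endocardial radius by ``1 - c*s(t)`` with a piecewise-cosine activation
``s`` peaking at end-systole (phase ``round(0.4*phases)``), so the
programmed ejection fraction is ``1 - (1 - c)**2`` exactly (volume scales
with radius squared at fixed slice thickness).

Disease classes are separable by construction (synthetic defaults, not
clinical claims): DCM dilates the LV cavity, HCM thickens the wall, RVA
enlarges the RV, and SCAR adds a bright transmural 60-degree sector at the
inferior wall (pseudo-LGE).  Segmentation corruptions (``slice_shift``,
``mask_dilate``, ``mask_dropout``) reproduce the failure modes an expert
reviewer flags in real cohorts: slice misalignment from breathing motion and
single-phase over/under-segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datamodel import (
    Case,
    CohortError,
    ImageVolume,
    LabelMask,
    LABEL_IDS,
    Patient,
    Session,
    STRUCTURES,
    Study,
    add_session,
)

CLASSES = ("NOR", "DCM", "HCM", "RVA", "SCAR")
CORRUPTION_KINDS = ("slice_shift", "mask_dilate", "mask_dropout")


@dataclass(frozen=True)
class GeometryPrior:
    """Per-class (mean, sd) geometry priors; samples are clipped to +/-2 sd."""

    lv_endo_radius_mm: tuple[float, float]
    wall_thickness_mm: tuple[float, float]
    rv_scale: tuple[float, float]
    contraction_fraction: tuple[float, float]


# Synthetic morphology defaults.  HCM wall and DCM cavity priors do not
# overlap NOR even at the 2-sd clip, so class separation holds for every
# sampled pair -- a property the classifier experiments rely on.
DEFAULT_PRIORS: dict[str, GeometryPrior] = {
    "NOR": GeometryPrior((25.0, 1.5), (8.0, 0.8), (1.00, 0.05), (0.33, 0.03)),
    "DCM": GeometryPrior((33.0, 1.5), (6.0, 0.6), (1.00, 0.05), (0.15, 0.03)),
    "HCM": GeometryPrior((24.0, 1.5), (14.0, 1.0), (1.00, 0.05), (0.36, 0.03)),
    "RVA": GeometryPrior((25.0, 1.5), (8.0, 0.8), (1.45, 0.08), (0.30, 0.03)),
    "SCAR": GeometryPrior((25.0, 1.5), (8.5, 0.8), (1.00, 0.05), (0.28, 0.03)),
}


@dataclass(frozen=True)
class IntensityModel:
    bloodpool_mean: float = 400.0
    myocardium_mean: float = 150.0
    background_mean: float = 60.0
    texture_sd: float = 30.0
    noise_sd: float = 10.0


@dataclass(frozen=True)
class CorruptionModel:
    rate: float = 0.0
    mix: dict[str, float] = field(default_factory=lambda: {
        "slice_shift": 1 / 3, "mask_dilate": 1 / 3, "mask_dropout": 1 / 3,
    })
    shift_px: tuple[int, int] = (8, 14)   # sampled magnitude range (inclusive)
    dilate_radius: int = 3


@dataclass(frozen=True)
class PhantomConfig:
    n_cases: int = 20
    class_mix: dict[str, float] = field(default_factory=lambda: {c: 0.2 for c in CLASSES})
    phases: int = 25
    slices: int = 10
    grid: tuple[int, int] = (128, 128)
    spacing_mm: tuple[float, float, float] = (8.0, 1.5, 1.5)
    seed: int = 0
    geometry_priors: dict[str, GeometryPrior] = field(
        default_factory=lambda: dict(DEFAULT_PRIORS))
    intensity: IntensityModel = field(default_factory=IntensityModel)
    corruption: CorruptionModel = field(default_factory=CorruptionModel)
    apex_taper: float = 0.4

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_cases < 1:
            problems.append(f"n_cases must be >= 1, got {self.n_cases}")
        if self.phases < 2:
            problems.append(f"phases must be >= 2, got {self.phases}")
        if self.slices < 1:
            problems.append(f"slices must be >= 1, got {self.slices}")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-6:
            problems.append(f"class_mix proportions must sum to 1, got {self.class_mix}")
        unknown = set(self.class_mix) - set(CLASSES)
        if unknown:
            problems.append(f"unknown classes in mix: {sorted(unknown)}")
        if any(s <= 0 for s in self.spacing_mm):
            problems.append(f"spacing must be positive, got {self.spacing_mm}")
        for cls, prior in self.geometry_priors.items():
            if prior.lv_endo_radius_mm[0] <= 0 or prior.wall_thickness_mm[0] <= 0:
                problems.append(f"{cls}: radii and thicknesses must be positive")
        priors = self.geometry_priors
        if {"NOR", "HCM"} <= priors.keys():
            if not priors["HCM"].wall_thickness_mm[0] > priors["NOR"].wall_thickness_mm[0]:
                problems.append("HCM wall thickness prior mean must exceed NOR's")
        if {"NOR", "DCM"} <= priors.keys():
            if not priors["DCM"].lv_endo_radius_mm[0] > priors["NOR"].lv_endo_radius_mm[0]:
                problems.append("DCM endo radius prior mean must exceed NOR's")
        if "RVA" in priors and not priors["RVA"].rv_scale[0] > 1.0:
            problems.append("RVA rv_scale prior mean must exceed 1")
        if not 0.0 <= self.corruption.rate <= 1.0:
            problems.append(f"corruption rate must be in [0, 1], got {self.corruption.rate}")
        if problems:
            raise CohortError("invalid phantom config: " + "; ".join(problems))


@dataclass
class CorruptionRecord:
    kind: str
    phase: int | None
    slice: int | None
    params: dict


@dataclass
class CaseTruth:
    """Programmed ground truth for one phantom case."""

    case_id: str
    class_label: str
    edv_ml: float
    esv_ml: float
    ef: float
    ed_phase: int
    es_phase: int
    wall_thickness_mm: np.ndarray          # per phase, at the basal slice
    lv_endo_radius_mm: float
    rv_scale: float
    contraction_fraction: float
    corruption: CorruptionRecord | None
    true_mask: LabelMask


def contraction_activation(phases: int) -> tuple[np.ndarray, int]:
    """Activation s(t) in [0, 1]: 0 at ED (t=0), 1 at ES, C1-smooth.

    Piecewise half-cosine ramps up to ES at ``round(0.4*phases)`` and back
    down toward end-diastole at the cycle end; both half-waves have zero
    slope at ES, so the volume curve is continuously differentiable.
    """
    es = int(round(0.4 * phases))
    es = min(max(es, 1), phases - 1)
    t = np.arange(phases, dtype=float)
    s = np.where(
        t <= es,
        0.5 * (1 - np.cos(np.pi * t / es)),
        0.5 * (1 - np.cos(np.pi * (phases - t) / (phases - es))),
    )
    return s, es


def _clipped_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(np.clip(rng.normal(mean, sd), mean - 2 * sd, mean + 2 * sd))


def _render_case(config: PhantomConfig, rng: np.random.Generator, class_label: str):
    """Rasterize one case; returns (image, true labels, truth scalars)."""
    prior = config.geometry_priors[class_label]
    r_base = _clipped_normal(rng, *prior.lv_endo_radius_mm)
    wall = _clipped_normal(rng, *prior.wall_thickness_mm)
    rv_scale = max(0.3, _clipped_normal(rng, *prior.rv_scale))
    cfrac = float(np.clip(_clipped_normal(rng, *prior.contraction_fraction), 0.02, 0.6))

    phases, slices = config.phases, config.slices
    rows, cols = config.grid
    slice_mm, row_mm, col_mm = config.spacing_mm
    s_act, es = contraction_activation(phases)

    center = np.array([rows / 2.0, cols / 2.0]) + rng.uniform(-3, 3, size=2)
    yy, xx = np.mgrid[0:rows, 0:cols]
    dy_mm = (yy - center[0]) * row_mm
    dx_mm = (xx - center[1]) * col_mm
    gap_mm = max(row_mm, col_mm)

    taper = (1.0 - config.apex_taper * np.arange(slices) / max(slices - 1, 1))
    labels = np.zeros((phases, slices, rows, cols), dtype=np.int16)
    scar_angle = None
    if class_label == "SCAR":
        # transmural 60-degree wedge centred on the inferior wall (+row axis)
        scar_angle = (math.pi / 2 - math.pi / 6, math.pi / 2 + math.pi / 6)

    for p in range(phases):
        scale = 1.0 - cfrac * s_act[p]
        for s in range(slices):
            r_endo = r_base * taper[s] * scale
            r_epi = r_base * taper[s] + wall
            r_rv = 0.85 * rv_scale * r_base * taper[s] * scale
            rv_off = r_epi + 0.4 * (0.85 * rv_scale * r_base * taper[s])
            d2_lv = dy_mm ** 2 + dx_mm ** 2
            d2_rv = dy_mm ** 2 + (dx_mm + rv_off) ** 2
            pool = d2_lv <= r_endo ** 2
            epi = d2_lv <= r_epi ** 2
            rv = (d2_rv <= r_rv ** 2) & (d2_lv > (r_epi + gap_mm) ** 2)
            sl = labels[p, s]
            sl[rv] = LABEL_IDS["rv_bloodpool"]
            sl[epi & ~pool] = LABEL_IDS["lv_myocardium"]
            sl[pool] = LABEL_IDS["lv_bloodpool"]

    inten = config.intensity
    image = rng.normal(inten.background_mean, inten.texture_sd * 0.5,
                       size=labels.shape)
    blood = (labels == LABEL_IDS["lv_bloodpool"]) | (labels == LABEL_IDS["rv_bloodpool"])
    myo = labels == LABEL_IDS["lv_myocardium"]
    image[blood] = rng.normal(inten.bloodpool_mean, inten.texture_sd, size=int(blood.sum()))
    image[myo] = rng.normal(inten.myocardium_mean, inten.texture_sd, size=int(myo.sum()))
    if scar_angle is not None:
        ang = np.arctan2(dy_mm, dx_mm)
        wedge = (ang >= scar_angle[0]) & (ang <= scar_angle[1])
        scar = myo & wedge[None, None]
        image[scar] = rng.normal(inten.bloodpool_mean, inten.texture_sd, size=int(scar.sum()))
    image += rng.normal(0.0, inten.noise_sd, size=image.shape)

    edv = float(np.sum(np.pi * (r_base * taper) ** 2) * slice_mm / 1000.0)
    esv = edv * (1.0 - cfrac) ** 2
    truth = {
        "edv_ml": edv,
        "esv_ml": esv,
        "ef": 1.0 - (1.0 - cfrac) ** 2,
        "ed_phase": 0,
        "es_phase": es,
        "wall_thickness_mm": wall + r_base * cfrac * s_act,
        "lv_endo_radius_mm": r_base,
        "rv_scale": rv_scale,
        "contraction_fraction": cfrac,
    }
    return image.astype(np.float32), labels, truth


def corrupt_mask(
    mask: LabelMask,
    kind: str,
    params: dict | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[LabelMask, CorruptionRecord]:
    """Apply one corruption to a copy of ``mask``; the input is untouched."""
    if kind not in CORRUPTION_KINDS:
        raise CohortError(f"unknown corruption kind {kind!r}; allowed: {CORRUPTION_KINDS}")
    rng = rng or np.random.default_rng(0)
    params = dict(params or {})
    phases, slices, rows, cols = mask.labels.shape
    labels = mask.labels.copy()

    if kind == "slice_shift":
        sl = int(params.get("slice", rng.integers(0, slices)))
        if "shift" in params:
            dr, dc = (int(v) for v in params["shift"])
        else:
            mag = int(rng.integers(8, 15))
            dr, dc = ((mag, 0) if rng.random() < 0.5 else (0, mag))
            if rng.random() < 0.5:
                dr, dc = -dr, -dc
        if abs(dr) >= rows or abs(dc) >= cols:
            raise CohortError(f"shift ({dr}, {dc}) exceeds grid {mask.grid_shape[1:]}")
        for p in range(phases):
            shifted = np.zeros((rows, cols), dtype=labels.dtype)
            src = labels[p, sl]
            r0, r1 = max(dr, 0), rows + min(dr, 0)
            c0, c1 = max(dc, 0), cols + min(dc, 0)
            shifted[r0:r1, c0:c1] = src[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
            labels[p, sl] = shifted
        record = CorruptionRecord("slice_shift", None, sl, {"shift": (dr, dc)})

    elif kind == "mask_dilate":
        structure = params.get("structure", "lv_myocardium")
        phase = int(params.get("phase", rng.integers(0, phases)))
        radius = int(params.get("radius", 3))
        footprint = _disk(radius)
        sid = LABEL_IDS[structure]
        for s in range(slices):
            grown = ndimage.binary_dilation(labels[phase, s] == sid, structure=footprint)
            labels[phase, s][grown] = sid
        record = CorruptionRecord("mask_dilate", phase, None,
                                  {"structure": structure, "radius": radius})

    else:  # mask_dropout
        structure = params.get("structure", str(rng.choice(STRUCTURES)))
        phase = int(params.get("phase", rng.integers(0, phases)))
        if "slice" in params:
            sl = int(params["slice"])
        else:  # mid-ventricular slices carry the most volume
            lo, hi = slices // 3, max(slices // 3 + 1, 2 * slices // 3)
            sl = int(rng.integers(lo, hi))
        sid = LABEL_IDS[structure]
        labels[phase, sl][labels[phase, sl] == sid] = 0
        record = CorruptionRecord("mask_dropout", phase, sl, {"structure": structure})

    return LabelMask(labels, mask.spacing), record


def inject_corruption(
    session: Session, kind: str, params: dict | None = None, seed: int = 0
) -> tuple[Session, CorruptionRecord]:
    """Return a NEW automatic session with a corrupted copy of the mask."""
    new_mask, record = corrupt_mask(session.mask, kind, params,
                                    np.random.default_rng(seed))
    from .datamodel import session_fingerprint
    new = Session(
        session_id=session_fingerprint(new_mask, "automatic", f"corrupt:{kind}:{seed}"),
        case_id=session.case_id,
        mask=new_mask,
        origin="automatic",
    )
    return new, record


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return yy ** 2 + xx ** 2 <= radius ** 2


def generate_cohort(config: PhantomConfig) -> tuple[list[Patient], list[CaseTruth]]:
    """Generate a class-labelled phantom cohort plus its truth records.

    Deterministic given ``config.seed``; each case draws from its own RNG
    stream ``default_rng([seed, case_index])`` so cohorts are stable under
    changes of ``n_cases``.  Each case carries a 4D cine (or pseudo-LGE)
    image and exactly one ``origin='automatic'`` session whose mask is the
    true geometry unless a corruption was injected (recorded in the truth).
    """
    config.validate()
    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    cohort: list[Patient] = []
    truths: list[CaseTruth] = []
    for idx in range(config.n_cases):
        rng = np.random.default_rng([config.seed, idx])
        class_label = str(rng.choice(classes, p=probs))
        image, labels, truth_vals = _render_case(config, rng, class_label)
        case_id = f"case{idx:04d}"
        true_mask = LabelMask(labels, config.spacing_mm)

        record: CorruptionRecord | None = None
        session_mask = true_mask
        if config.corruption.rate > 0 and rng.random() < config.corruption.rate:
            mix_kinds = sorted(config.corruption.mix)
            mix_p = np.array([config.corruption.mix[k] for k in mix_kinds], dtype=float)
            kind = str(rng.choice(mix_kinds, p=mix_p / mix_p.sum()))
            session_mask, record = corrupt_mask(true_mask, kind, None, rng)

        modality = "lge" if class_label == "SCAR" else "cine"
        height = _clipped_normal(rng, 172.0, 9.0)
        bmi = _clipped_normal(rng, 26.0, 3.5)
        case = Case(
            case_id=case_id,
            images=[ImageVolume(image, config.spacing_mm, modality=modality)],
            clinical={"height_cm": round(height, 1),
                      "weight_kg": round(bmi * (height / 100.0) ** 2, 1)},
            class_label=class_label,
        )
        add_session(case, session_mask, "automatic")
        patient = Patient(patient_id=f"pat{idx:04d}",
                          studies=[Study(study_id=f"study{idx:04d}", cases=[case])])
        cohort.append(patient)
        truths.append(CaseTruth(
            case_id=case_id,
            class_label=class_label,
            corruption=record,
            true_mask=true_mask,
            **truth_vals,
        ))
    return cohort, truths


def truth_table(truths: list[CaseTruth]):
    """Truth records as a flat pandas DataFrame (for CSV export)."""
    import pandas as pd

    rows = []
    for t in truths:
        rows.append({
            "case_id": t.case_id,
            "class_label": t.class_label,
            "edv_ml": t.edv_ml,
            "esv_ml": t.esv_ml,
            "ef": t.ef,
            "ed_phase": t.ed_phase,
            "es_phase": t.es_phase,
            "lv_endo_radius_mm": t.lv_endo_radius_mm,
            "rv_scale": t.rv_scale,
            "contraction_fraction": t.contraction_fraction,
            "wall_thickness_ed_mm": float(t.wall_thickness_mm[0]),
            "wall_thickness_es_mm": float(t.wall_thickness_mm[t.es_phase]),
            "corruption_kind": t.corruption.kind if t.corruption else "",
            "corruption_phase": "" if t.corruption is None or t.corruption.phase is None
                                 else t.corruption.phase,
            "corruption_slice": "" if t.corruption is None or t.corruption.slice is None
                                 else t.corruption.slice,
        })
    return pd.DataFrame(rows)
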
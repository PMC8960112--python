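"""Shared fixtures: analytic masks and small phantom cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from cardioloop.datamodel import LABEL_IDS, LabelMask
from cardioloop.phantom import PhantomConfig, generate_cohort


def make_ring_slice(grid: int = 96, center=(48, 48), r_endo: float = 20.0,
                    r_epi: float = 30.0, rv_radius: float = 14.0,
                    rv_offset: float | None = None) -> np.ndarray:
    """One short-axis slice: LV pool + myocardial ring + RV crescent."""
    yy, xx = np.mgrid[0:grid, 0:grid]
    d = np.hypot(yy - center[0], xx - center[1])
    sl = np.zeros((grid, grid), np.int16)
    sl[d <= r_epi] = LABEL_IDS["lv_myocardium"]
    sl[d <= r_endo] = LABEL_IDS["lv_bloodpool"]
    if rv_radius > 0:
        off = rv_offset if rv_offset is not None else r_epi + 0.5 * rv_radius
        drv = np.hypot(yy - center[0], xx - (center[1] - off))
        sl[(drv <= rv_radius) & (d > r_epi + 1)] = LABEL_IDS["rv_bloodpool"]
    return sl


@pytest.fixture(scope="session")
def shell_mask() -> LabelMask:
    """Analytic septum phantom: endo r=30 mm, epi r=40 mm, 1 mm in-plane."""
    sl = make_ring_slice(grid=128, center=(64, 64), r_endo=30, r_epi=40,
                         rv_radius=12, rv_offset=55)
    return LabelMask(sl[None, None], (8.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def ball_mask() -> LabelMask:
    """Digitized ball, r = 10 mm at 1 mm isotropic."""
    zz, yy, xx = np.mgrid[-15:16, -15:16, -15:16]
    ball = zz ** 2 + yy ** 2 + xx ** 2 <= 10 ** 2
    return LabelMask((ball[None] * LABEL_IDS["lv_bloodpool"]).astype(np.int16),
                     (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_cohort():
    """Six-case two-class phantom cohort (shared, read-only)."""
    config = PhantomConfig(n_cases=6, phases=8, slices=5, grid=(64, 64), seed=42,
                           class_mix={"NOR": 0.5, "HCM": 0.5})
    return generate_cohort(config)


@pytest.fixture(scope="session")
def mixed_cohort():
    """Eight-case four-class phantom cohort (shared, read-only)."""
    config = PhantomConfig(
        n_cases=8, phases=10, slices=6, grid=(96, 96), seed=5,
        class_mix={"NOR": 0.25, "DCM": 0.25, "HCM": 0.25, "RVA": 0.25})
    return generate_cohort(config)
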
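"""GLCM and NGTDM texture features (IBSI formulations), 2D per slice.

Texture is computed slice-wise in-plane and pooled across slices, because
short-axis cine slices are thick (5-10 mm) and through-plane co-occurrence
would mix physically inhomogeneous tissue.  Pooling merges the raw
co-occurrence / gray-tone-difference counts over slices (and, for the GLCM,
over the four in-plane directions), which weights every voxel pair equally.

Gray levels are quantized to a fixed bin count (default 32) by min-max
within the structure at the given phase; a constant-intensity structure
falls into a single bin, for which contrast, difference entropy and cluster
tendency are 0 and coarseness is capped.

IBSI identifiers: GLCM contrast (ACUI), difference entropy (NTRS), cluster
tendency (DG8W); NGTDM coarseness (QCDE), complexity (HDEZ).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix

from ..datamodel import ImageVolume, LabelMask

COARSENESS_CAP = 1.0e6
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def quantize(values: np.ndarray, bins: int = 32) -> np.ndarray:
    """Min-max quantization to integer levels 0..bins-1 (single level if flat)."""
    lo = float(values.min())
    hi = float(values.max())
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int32)
    levels = np.floor((values - lo) / (hi - lo) * bins).astype(np.int32)
    return np.clip(levels, 0, bins - 1)


def _quantized_slices(
    image: ImageVolume | np.ndarray, mask: LabelMask, structure: str, phase: int,
    bins: int,
) -> tuple[np.ndarray, np.ndarray]:
    voxels = image.voxels if isinstance(image, ImageVolume) else np.asarray(image)
    if voxels.ndim == 3:
        voxels = voxels[None]
    img3 = voxels[phase].astype(float)
    m3 = mask.structure(structure, phase)
    levels = np.zeros(img3.shape, dtype=np.int32)
    if m3.any():
        levels[m3] = quantize(img3[m3], bins)
    return levels, m3


def glcm_features(
    image: ImageVolume | np.ndarray, mask: LabelMask, structure: str, phase: int,
    bins: int = 32,
) -> dict[str, float] | None:
    """Contrast, difference entropy and cluster tendency from the pooled GLCM.

    Symmetric co-occurrences at distance 1 along the four in-plane
    directions, restricted to structure voxels, counts merged over slices
    and directions and normalized once.  None if the structure has < 2
    voxels.
    """
    levels, m3 = _quantized_slices(image, mask, structure, phase, bins)
    if m3.sum() < 2:
        return None
    masked_level = bins  # sentinel level for out-of-structure pixels
    counts = np.zeros((bins, bins), dtype=np.float64)
    for s in range(levels.shape[0]):
        if not m3[s].any():
            continue
        arr = np.where(m3[s], levels[s], masked_level).astype(np.uint8 if bins < 255 else np.int32)
        glcm = graycomatrix(arr, distances=[1], angles=list(GLCM_ANGLES),
                            levels=bins + 1, symmetric=True, normed=False)
        counts += glcm[:bins, :bins, 0, :].sum(axis=2)
    total = counts.sum()
    if total == 0:
        return {"contrast": 0.0, "difference_entropy": 0.0, "cluster_tendency": 0.0}
    return glcm_matrix_features(counts / total)


def glcm_matrix_features(p: np.ndarray) -> dict[str, float]:
    """IBSI features of a normalized symmetric co-occurrence matrix."""
    n = p.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    contrast = float(((i - j) ** 2 * p).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    cluster_tendency = float(((i + j - mu_i - mu_j) ** 2 * p).sum())
    p_diff = np.array([p[np.abs(i - j) == k].sum() for k in range(n)])
    nz = p_diff[p_diff > 0]
    difference_entropy = float(-(nz * np.log2(nz)).sum() + 0.0)
    return {
        "contrast": contrast,
        "difference_entropy": difference_entropy,
        "cluster_tendency": cluster_tendency,
    }


def ngtdm_features(
    image: ImageVolume | np.ndarray, mask: LabelMask, structure: str, phase: int,
    bins: int = 32,
) -> dict[str, float] | None:
    """Coarseness and complexity from the pooled NGTDM (2D 8-neighbourhood).

    For every structure voxel the absolute difference between its gray level
    and the mean level of its in-slice structure neighbours is accumulated
    per level; level counts and difference sums are pooled over slices.
    Coarseness is capped at 1e6 (flat regions); complexity is 0 for a
    single-level structure.
    """
    levels, m3 = _quantized_slices(image, mask, structure, phase, bins)
    if not m3.any():
        return None
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    n_i = np.zeros(bins, dtype=np.float64)
    s_i = np.zeros(bins, dtype=np.float64)
    for s in range(levels.shape[0]):
        valid = m3[s].astype(float)
        if not valid.any():
            continue
        nbr_sum = ndimage.convolve(levels[s] * valid, kernel, mode="constant", cval=0.0)
        nbr_cnt = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
        use = m3[s] & (nbr_cnt > 0)
        diff = np.zeros(levels[s].shape)
        diff[use] = np.abs(levels[s][use] - nbr_sum[use] / nbr_cnt[use])
        for lvl in np.unique(levels[s][use]):
            sel = use & (levels[s] == lvl)
            n_i[lvl] += sel.sum()
            s_i[lvl] += diff[sel].sum()
    return ngtdm_matrix_features(n_i, s_i)


def ngtdm_matrix_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    """Coarseness and complexity from pooled NGTDM level counts/differences."""
    total = n_i.sum()
    if total == 0:
        return {"coarseness": COARSENESS_CAP, "complexity": 0.0}
    p_i = n_i / total
    denom = float((p_i * s_i).sum())
    coarseness = COARSENESS_CAP if denom <= 1.0 / COARSENESS_CAP else min(1.0 / denom, COARSENESS_CAP)
    present = np.nonzero(n_i)[0]
    complexity = 0.0
    for a, i in enumerate(present):
        for jdx in present[a + 1:]:
            num = abs(int(i) - int(jdx)) * (p_i[i] * s_i[i] + p_i[jdx] * s_i[jdx])
            complexity += 2.0 * num / (p_i[i] + p_i[jdx])
    complexity /= total
    return {"coarseness": float(coarseness), "complexity": float(complexity)}


def first_order_features(
    image: ImageVolume | np.ndarray, mask: LabelMask, structure: str, phase: int
) -> dict[str, float] | None:
    """Mean and standard deviation of intensities within the structure."""
    voxels = image.voxels if isinstance(image, ImageVolume) else np.asarray(image)
    if voxels.ndim == 3:
        voxels = voxels[None]
    m3 = mask.structure(structure, phase)
    if not m3.any():
        return None
    vals = voxels[phase][m3]
    return {"intensity_mean": float(vals.mean()), "intensity_std": float(vals.std())}
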
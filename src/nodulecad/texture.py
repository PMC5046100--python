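"""Intensity features fi1-fi8 and texture features ft1-ft16.

Intensity block (3D, over foreground voxels): first-order statistics, the
inside-to-outside intensity gradient score built from successive
morphological erosions, and the mean/range of a discrete-Laplacian response
(LDM/LDD).  Bright-core nodules erode into progressively brighter shells,
which the gradient score captures; vessels and plates do not.

Texture block (on the representative 2D slice): Tamura contrast,
directionality and coarseness, plus 13 Haralick statistics of a gray-level
co-occurrence matrix (distance 1, four directions averaged, symmetric).
Texture is computed inside the ROI bounding-box crop with out-of-mask pixels
replaced by the ROI mean so background never enters the co-occurrence
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix

from .roi import RoiSlice, RoiVolume, representative_slice

# zero-sum discrete Laplacians: 6-neighbor (3D) and 4-neighbor (2D)
LAPLACIAN_3D = np.zeros((3, 3, 3))
LAPLACIAN_3D[1, 1, 1] = -6
for _off in [(0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)]:
    LAPLACIAN_3D[_off] = 1
LAPLACIAN_2D = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# first-order intensity statistics (fi1..fi5)
# ---------------------------------------------------------------------------

def first_order_stats(roi: RoiVolume) -> np.ndarray:
    """Mean, population variance, max-min range, skewness, Pearson kurtosis
    of the foreground intensities.  Constant regions get skewness and
    kurtosis 0 by convention."""
    vals = roi.intensities[roi.mask]
    mean = vals.mean()
    var = vals.var()  # ddof=0
    rng = float(vals.max() - vals.min())
    if var > 0:
        centered = vals - mean
        skew = float(np.mean(centered**3) / var**1.5)
        kurt = float(np.mean(centered**4) / var**2)
    else:
        skew = 0.0
        kurt = 0.0
    return np.array([mean, var, rng, skew, kurt], dtype=float)


# ---------------------------------------------------------------------------
# erosion intensity gradient (fi6)
# ---------------------------------------------------------------------------

@dataclass
class ErosionTrace:
    """Record of the successive-erosion shell analysis.

    ``shell_means[k]`` is the mean intensity of the voxels removed by erosion
    step k; ``ratios[k]`` compares it to the previous shell (the first ratio
    is defined as 1).  ``n`` is the number of steps until the mask empties;
    ``K`` counts steps whose ratio exceeds 1, i.e. steps where the region
    gets brighter toward the inside.
    """

    shell_means: List[float] = field(default_factory=list)
    ratios: List[float] = field(default_factory=list)
    n: int = 0
    K: int = 0


def intensity_gradient(roi: RoiVolume, mode: str = "ratio_gt1") -> Tuple[float, ErosionTrace]:
    """E4 = K/n from repeated 6-connected erosion of the mask.

    Each step peels the current surface shell; the ratio of the new shell's
    mean intensity to the previous shell's measures whether intensity rises
    toward the center.  ``mode='ratio_gt1'`` counts K as the number of steps
    with ratio > 1 (default); ``mode='last_nonzero'`` instead takes K as the
    index of the last step with a nonzero ratio.
    """
    if mode not in ("ratio_gt1", "last_nonzero"):
        raise ValueError(f"unknown intensity_gradient mode {mode!r}")
    trace = ErosionTrace()
    current = roi.mask.copy()
    prev_mean = None
    while current.any():
        nxt = ndimage.binary_erosion(current, _STRUCT6, border_value=0)
        shell = current & ~nxt
        m = float(roi.intensities[shell].mean())
        if prev_mean is None:
            ratio = 1.0
        elif prev_mean != 0:
            ratio = m / prev_mean
        else:
            ratio = np.inf if m > 0 else 1.0
        trace.shell_means.append(m)
        trace.ratios.append(ratio)
        trace.n += 1
        if ratio > 1:
            trace.K += 1
        prev_mean = m
        current = nxt
    if mode == "last_nonzero":
        nz = [k for k, r in enumerate(trace.ratios, start=1) if r != 0]
        trace.K = nz[-1] if nz else 0
    e4 = trace.K / trace.n
    return e4, trace


# ---------------------------------------------------------------------------
# Laplace divergence (fi7, fi8)
# ---------------------------------------------------------------------------

def _laplace_response(roi: RoiVolume) -> np.ndarray:
    resp = ndimage.convolve(roi.intensities, LAPLACIAN_3D, mode="constant", cval=0.0)
    return resp[roi.mask]


def laplace_divergence_mean(roi: RoiVolume) -> float:
    """E5 (LDM): mean 6-neighbor Laplacian response over foreground voxels."""
    return float(_laplace_response(roi).mean())


def laplace_divergence_distance(roi: RoiVolume) -> float:
    """E6 (LDD): max - min of the Laplacian response over foreground voxels."""
    resp = _laplace_response(roi)
    return float(resp.max() - resp.min())


# ---------------------------------------------------------------------------
# Tamura texture (ft1..ft3)
# ---------------------------------------------------------------------------

def _masked_crop(slc: RoiSlice) -> np.ndarray:
    """ROI bounding-box crop with out-of-mask pixels set to the ROI mean."""
    ys, xs = np.nonzero(slc.mask)
    crop = slc.intensities[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1].copy()
    cmask = slc.mask[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    crop[~cmask] = slc.intensities[slc.mask].mean()
    return crop


def tamura_coarseness(img: np.ndarray, kmax: int = 5) -> float:
    """Tamura-style coarseness: mean best window size 2^k per pixel.

    For each pixel, neighborhood averages over windows of size 2^k are
    compared between *adjacent* windows (offset 2^k) horizontally and
    vertically; the k maximizing the larger difference wins, and the mean of
    2^k_best over pixels is the coarseness.  Fine textures (period-2
    checkerboards) respond at window size 1; blocky textures respond at the
    block size.  A flat image gives the smallest window, 1.
    """
    img = np.asarray(img, dtype=float)
    kmax = max(0, min(kmax, int(np.log2(max(2, min(img.shape))))))
    h, w = img.shape
    e_best = np.zeros((kmax + 1, h, w))
    for k in range(0, kmax + 1):
        size = 2**k
        avg = img if size == 1 else ndimage.uniform_filter(img, size=size, mode="nearest")
        d = size
        e_h = np.abs(np.roll(avg, -d, axis=1) - avg)
        e_v = np.abs(np.roll(avg, -d, axis=0) - avg)
        # rolled wrap-around rows/cols are invalid: zero them out
        e_v[-d:, :] = 0
        e_h[:, -d:] = 0
        e_best[k] = np.maximum(e_h, e_v)
    best_k = np.argmax(e_best, axis=0)  # first (finest) scale wins ties
    return float(np.mean(2.0**best_k))


def tamura_contrast(img: np.ndarray) -> float:
    """Tamura contrast sigma / alpha4^(1/4) with alpha4 the Pearson kurtosis;
    0 for a flat image."""
    img = np.asarray(img, dtype=float)
    var = img.var()
    if var <= 0:
        return 0.0
    alpha4 = np.mean((img - img.mean()) ** 4) / var**2
    return float(np.sqrt(var) / alpha4**0.25)


def tamura_directionality(img: np.ndarray, n_bins: int = 16) -> float:
    """Orientation-histogram energy as a directionality measure.

    Gradient orientations (Prewitt) of pixels with non-negligible gradient
    magnitude are binned modulo pi; the histogram energy sum(p_i^2) is 1/n
    for an isotropic field and approaches 1 for a single dominant
    orientation.  Flat images give 0.
    """
    img = np.asarray(img, dtype=float)
    gy = ndimage.prewitt(img, axis=0, mode="nearest")
    gx = ndimage.prewitt(img, axis=1, mode="nearest")
    mag = np.hypot(gx, gy)
    if mag.max() <= 0:
        return 0.0
    keep = mag > 0.1 * mag.max()
    if not keep.any():
        return 0.0
    theta = np.mod(np.arctan2(gy[keep], gx[keep]), np.pi)
    hist, _ = np.histogram(theta, bins=n_bins, range=(0, np.pi))
    p = hist / hist.sum()
    return float(np.sum(p**2))


def tamura_features(slc: RoiSlice) -> Tuple[float, float, float]:
    """(contrast, directionality, coarseness) of the masked crop."""
    crop = _masked_crop(slc)
    return (
        tamura_contrast(crop),
        tamura_directionality(crop),
        tamura_coarseness(crop),
    )


# ---------------------------------------------------------------------------
# GLCM / Haralick texture (ft4..ft16)
# ---------------------------------------------------------------------------

#: slot order of the 13 co-occurrence statistics in the feature schema
GLCM_FEATURE_NAMES = (
    "asm",
    "contrast",
    "inverse_difference_moment",
    "sum_average",
    "variance",
    "sum_variance",
    "difference_variance",
    "entropy",
    "sum_entropy",
    "difference_entropy",
    "information_measure_1",
    "correlation",
    "max_correlation_coefficient",
)


def quantize(img: np.ndarray, levels: int = 16) -> np.ndarray:
    """Min-max linear quantization to integer levels 0..levels-1."""
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_matrix(
    img: np.ndarray,
    levels: int = 16,
    distances: Tuple[int, ...] = (1,),
    angles: Tuple[float, ...] = (0, np.pi / 4, np.pi / 2, 3 * np.pi / 4),
) -> np.ndarray:
    """Normalized symmetric co-occurrence matrices, shape (G, G, n_angles)."""
    q = quantize(img, levels)
    p = graycomatrix(
        q, distances=list(distances), angles=list(angles), levels=levels,
        symmetric=True, normed=True,
    )
    return p[:, :, 0, :]


def _haralick13(p: np.ndarray) -> np.ndarray:
    """13 Haralick statistics of one normalized symmetric GLCM (log base 2)."""
    g = p.shape[0]
    i_idx, j_idx = np.indices((g, g))
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((np.arange(g) * px).sum())
    mu_y = float((np.arange(g) * py).sum())
    sd_x = float(np.sqrt(((np.arange(g) - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((np.arange(g) - mu_y) ** 2 * py).sum()))

    # sum / difference distributions
    p_sum = np.zeros(2 * g - 1)
    np.add.at(p_sum, (i_idx + j_idx).ravel(), p.ravel())
    p_diff = np.zeros(g)
    np.add.at(p_diff, np.abs(i_idx - j_idx).ravel(), p.ravel())

    def _entropy(q_arr: np.ndarray) -> float:
        q_arr = q_arr[q_arr > 0]
        return float(-(q_arr * np.log2(q_arr)).sum())

    asm = float((p**2).sum())
    contrast = float(((i_idx - j_idx) ** 2 * p).sum())
    idm = float((p / (1.0 + (i_idx - j_idx) ** 2)).sum())
    ks = np.arange(2 * g - 1)
    sum_avg = float((ks * p_sum).sum())
    variance = float(((i_idx - mu_x) ** 2 * p).sum())
    sum_var = float(((ks - sum_avg) ** 2 * p_sum).sum())
    kd = np.arange(g)
    diff_avg = float((kd * p_diff).sum())
    diff_var = float(((kd - diff_avg) ** 2 * p_diff).sum())
    entropy = _entropy(p)
    sum_entropy = _entropy(p_sum)
    diff_entropy = _entropy(p_diff)

    # information measure of correlation 1
    hx = _entropy(px)
    hy = _entropy(py)
    outer = np.outer(px, py)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = float(-(p * log_outer).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0

    if sd_x > 0 and sd_y > 0:
        correlation = float(((i_idx * j_idx * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0

    # maximal correlation coefficient: sqrt of second eigenvalue of Q
    active = px > 0
    if active.sum() < 2:
        mcc = 0.0
    else:
        pa = p[np.ix_(active, active)]
        pxa = px[active]
        pya = py[active]
        q_mat = (pa / pxa[:, None]) @ (pa / pya[:, None]).T
        eig = np.sort(np.abs(np.linalg.eigvals(q_mat)))[::-1]
        mcc = float(np.sqrt(max(eig[1].real, 0.0))) if len(eig) > 1 else 0.0

    return np.array(
        [asm, contrast, idm, sum_avg, variance, sum_var, diff_var,
         entropy, sum_entropy, diff_entropy, imc1, correlation, mcc]
    )


def glcm_features(slc: RoiSlice, levels: int = 16) -> np.ndarray:
    """13 Haralick statistics averaged over the four distance-1 directions."""
    crop = _masked_crop(slc)
    mats = glcm_matrix(crop, levels=levels)
    feats = np.stack([_haralick13(mats[:, :, a]) for a in range(mats.shape[2])])
    return feats.mean(axis=0)


# ---------------------------------------------------------------------------
# block assembly
# ---------------------------------------------------------------------------

def intensity_texture_block(roi: RoiVolume, glcm_levels: int = 16) -> np.ndarray:
    """Assemble fi1..fi8 (3D intensity) and ft1..ft16 (slice texture)."""
    e4, _ = intensity_gradient(roi)
    fi = np.concatenate(
        [
            first_order_stats(roi),
            [e4, laplace_divergence_mean(roi), laplace_divergence_distance(roi)],
        ]
    )
    slc = representative_slice(roi)
    ft = np.concatenate([tamura_features(slc), glcm_features(slc, levels=glcm_levels)])
    return np.concatenate([fi, ft])
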
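"""Full-reference quality, mask-overlap, and correlation metrics.

The segmentation evaluation protocol scores a class-mean reconstruction
against the original image with PSNR, mean SSIM (11x11 Gaussian window,
sigma 1.5, K1=0.01, K2=0.03) and FSIM (phase-congruency-weighted product
of phase and gradient similarity, T1=0.85, T2=160).  When a ground-truth
binary mask exists, Dice, Jaccard and the symmetric Hausdorff distance
compare the binarized segmentation against it.  Pixel and neighbor-pixel
Pearson/Spearman correlations quantify how much of the intensity ordering
and local spatial structure the reconstruction preserves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from scipy.ndimage import convolve, gaussian_filter
from scipy.spatial.distance import directed_hausdorff

from ._phasecong import phase_congruency

__all__ = [
    "MetricReport",
    "psnr",
    "ssim",
    "fsim",
    "overlap_metrics",
    "hausdorff_distance",
    "correlation_diagnostics",
]

#: Cap reported for identical images (MSE = 0), so tables stay finite.
PSNR_CAP_DB = 100.0


@dataclass
class MetricReport:
    """Flat record of all metric values for one (image, thresholds) pair."""

    psnr: float
    ssim: float
    fsim: float
    dice: float | None = None
    jaccard: float | None = None
    hausdorff: float | None = None
    pearson_r: float | None = None
    spearman_rho: float | None = None
    neighbor_pearson: float | None = None
    neighbor_spearman: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(d.pop("extra"))
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _pair(ref, test) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(ref, dtype=float)
    b = np.asarray(test, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch between reference and test images")
    return a, b


def psnr(ref: np.ndarray, test: np.ndarray, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB (capped at 100 for identical inputs)."""
    a, b = _pair(ref, test)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(10.0 * np.log10(max_value**2 / mse), PSNR_CAP_DB)


def ssim(
    ref: np.ndarray,
    test: np.ndarray,
    data_range: float = 255.0,
    k1: float = 0.01,
    k2: float = 0.03,
    sigma: float = 1.5,
) -> float:
    """Mean structural similarity (Gaussian 11x11 window, sigma 1.5).

    Local means/variances/covariance come from Gaussian-weighted windows
    (truncated at 3.5 sigma, i.e. an 11-tap kernel); the SSIM map is
    averaged over the interior, excluding the filter-radius border.
    """
    x, y = _pair(ref, test)
    win = 2 * int(3.5 * sigma + 0.5) + 1  # 11 for sigma = 1.5
    if min(x.shape) < win:
        raise ValueError(f"image smaller than the {win}x{win} SSIM window")
    blur = lambda im: gaussian_filter(im, sigma, truncate=3.5, mode="reflect")
    ux, uy = blur(x), blur(y)
    vx = blur(x * x) - ux * ux
    vy = blur(y * y) - uy * uy
    vxy = blur(x * y) - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2)
    )
    pad = (win - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean(dtype=np.float64))


_SCHARR_X = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]], dtype=float) / 16.0


def _scharr_magnitude(img: np.ndarray) -> np.ndarray:
    gx = convolve(img, _SCHARR_X, mode="nearest")
    gy = convolve(img, _SCHARR_X.T, mode="nearest")
    return np.sqrt(gx * gx + gy * gy)


def fsim(
    ref: np.ndarray,
    test: np.ndarray,
    t1: float = 0.85,
    t2: float = 160.0,
) -> float:
    """Feature similarity index: phase-congruency and gradient similarity.

    S(x) = S_PC(x) * S_G(x) is pooled with the pointwise maximum of the
    two phase-congruency maps as weight.  If both maps are identically
    zero (e.g. two constant images) the unweighted mean of S is returned,
    which is 1.0 for identical inputs.
    """
    a, b = _pair(ref, test)
    if min(a.shape) < 32:
        raise ValueError("FSIM requires images of at least 32x32 pixels")
    pc_a = phase_congruency(a)
    pc_b = phase_congruency(b)
    g_a = _scharr_magnitude(a)
    g_b = _scharr_magnitude(b)
    s_pc = (2 * pc_a * pc_b + t1) / (pc_a**2 + pc_b**2 + t1)
    s_g = (2 * g_a * g_b + t2) / (g_a**2 + g_b**2 + t2)
    s = s_pc * s_g
    pc_max = np.maximum(pc_a, pc_b)
    denom = float(pc_max.sum())
    if denom == 0.0:
        return float(s.mean())  # degenerate featureless pair
    return float((s * pc_max).sum() / denom)


def overlap_metrics(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    compute_hausdorff: bool = True,
) -> tuple[float, float, float | None]:
    """Dice, Jaccard and symmetric Hausdorff distance for binary masks.

    Two empty masks are defined as identical: (1, 1, 0).  If exactly one
    mask is empty, Dice and Jaccard are 0 and the Hausdorff distance is
    undefined — an error unless ``compute_hausdorff=False``.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch between masks")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0, 1.0, 0.0
    inter = int(np.logical_and(a, b).sum())
    union = na + nb - inter
    dice = 2.0 * inter / (na + nb)
    jaccard = inter / union
    if na == 0 or nb == 0:
        if compute_hausdorff:
            raise ValueError("Hausdorff distance undefined for an empty mask")
        return dice, jaccard, None
    hd = hausdorff_distance(a, b) if compute_hausdorff else None
    return dice, jaccard, hd


def hausdorff_distance(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between foreground pixel sets (pixels)."""
    pts_a = np.argwhere(np.asarray(mask_a).astype(bool))
    pts_b = np.argwhere(np.asarray(mask_b).astype(bool))
    if pts_a.size == 0 or pts_b.size == 0:
        raise ValueError("Hausdorff distance undefined for an empty mask")
    d_ab = directed_hausdorff(pts_a, pts_b)[0]
    d_ba = directed_hausdorff(pts_b, pts_a)[0]
    return float(max(d_ab, d_ba))


def _corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "correlation undefined for a constant input vector", stacklevel=3
        )
        return float("nan"), float("nan")
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return r, rho


def correlation_diagnostics(
    original: np.ndarray,
    segmented: np.ndarray,
    include_vertical: bool = False,
) -> tuple[float, float, float, float]:
    """Pixel and neighbor-pixel correlations between original and output.

    Returns (pearson_r, spearman_rho, neighbor_pearson, neighbor_spearman).
    The pixel correlations pair the flattened original against the
    segmented image.  The neighbor correlations pair each pixel of the
    segmented image with its horizontal right neighbor (optionally pooled
    with vertical pairs), measuring preserved spatial dependency.
    Spearman uses average ranks for ties.
    """
    a, b = _pair(original, segmented)
    r, rho = _corr(a.ravel(), b.ravel())
    left = [b[:, :-1].ravel()]
    right = [b[:, 1:].ravel()]
    if include_vertical:
        left.append(b[:-1, :].ravel())
        right.append(b[1:, :].ravel())
    nr, nrho = _corr(np.concatenate(left), np.concatenate(right))
    return r, rho, nr, nrho
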
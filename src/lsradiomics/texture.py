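"""Mazda-style texture features over a masked ROI.

Six feature families are extracted from a gray-standardized, quantized ROI:
gray-level histogram, co-occurrence matrices (GLCM, 11 features per
distance/direction), run-length matrices (RLM, 5 per direction), absolute
gradient, a causal autoregressive model, and wavelet sub-band energies.
Gray-level standardization (clipping to mean +/- 3 SD by default, then linear
quantization) is applied first to suppress brightness/contrast differences
between images.

Feature names follow ``family.feature[.dN][.direction]`` and the schema for
a given configuration is fixed; with the defaults the vector has 271 entries
(220 GLCM + 20 RLM + 9 histogram + 5 gradient + 5 AR + 12 wavelet).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage as ndi
from skimage.feature import graycomatrix

from .errors import ConfigurationError
from .io import GrayImage, SegMask

logger = logging.getLogger(__name__)

#: The four in-plane directions, as (row, col) steps for distance 1.
DIRECTIONS: dict[str, tuple[int, int]] = {
    "0": (0, 1),
    "45": (-1, 1),
    "90": (-1, 0),
    "135": (-1, -1),
}
_SKIMAGE_ANGLES = {"0": 0.0, "45": np.pi / 4, "90": np.pi / 2, "135": 3 * np.pi / 4}

GLCM_FEATURES = (
    "AngScMom",
    "Contrast",
    "Correlat",
    "SumOfSqs",
    "InvDfMom",
    "SumAverg",
    "SumVarnc",
    "SumEntrp",
    "Entropy",
    "DifVarnc",
    "DifEntrp",
)
RLM_FEATURES = ("ShrtREmp", "LngREmph", "GLevNonUni", "RLNonUni", "Fraction")


@dataclass
class TextureConfig:
    gray_levels: int = 64
    standardization: str = "mu3sigma"  # or "minmax"
    glcm_distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    wavelet: str = "haar"
    wavelet_levels: int = 3
    erode: int = 0  # optional margin erosion (iterations) before extraction

    def __post_init__(self) -> None:
        if self.gray_levels < 2:
            raise ConfigurationError("gray_levels must be >= 2")
        if any(d < 1 for d in self.glcm_distances):
            raise ConfigurationError("GLCM distances must be >= 1")
        if self.standardization not in ("minmax", "mu3sigma"):
            raise ConfigurationError(f"unknown standardization {self.standardization!r}")
        if self.wavelet_levels < 1:
            raise ConfigurationError("wavelet_levels must be >= 1")
        if self.erode < 0:
            raise ConfigurationError("erode must be >= 0")


def _as_pixels(img: GrayImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, GrayImage) else np.asarray(img, np.float64)


def _as_mask(mask: SegMask | np.ndarray) -> np.ndarray:
    return mask.as_bool() if isinstance(mask, SegMask) else np.asarray(mask).astype(bool)


def standardize_gray(
    img: GrayImage | np.ndarray,
    mask: SegMask | np.ndarray,
    config: TextureConfig | None = None,
) -> np.ndarray:
    """Clip + quantize in-mask intensities; returns the bounding-box crop.

    Output is an int array over the mask's bounding box with quantized levels
    ``0 .. gray_levels-1`` inside the mask and ``-1`` outside.
    """
    config = config or TextureConfig()
    pixels = _as_pixels(img)
    m = _as_mask(mask)
    if pixels.shape != m.shape:
        raise ConfigurationError("image and mask shapes must match")
    if config.erode:
        m = ndi.binary_erosion(m, iterations=config.erode)
    if not m.any():
        raise ConfigurationError("mask is empty")

    rows, cols = np.nonzero(m)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    crop = pixels[r0:r1, c0:c1]
    mcrop = m[r0:r1, c0:c1]
    vals = crop[mcrop]

    g = config.gray_levels
    out = np.full(crop.shape, -1, dtype=np.int64)
    if config.standardization == "minmax":
        lo, hi = float(vals.min()), float(vals.max())
        if hi == lo:
            out[mcrop] = 0
            return out
    else:
        mu, sd = float(vals.mean()), float(vals.std())
        if sd == 0.0:
            logger.warning("constant ROI under mu3sigma: mapping all pixels to mid-level")
            out[mcrop] = g // 2
            return out
        lo, hi = mu - 3 * sd, mu + 3 * sd
    q = np.floor((np.clip(vals, lo, hi) - lo) / (hi - lo) * g).astype(np.int64)
    out[mcrop] = np.clip(q, 0, g - 1)
    return out


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(qroi: np.ndarray, distance: int, direction: str, levels: int) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix; empty matrices return None.

    Out-of-mask pixels (level -1) are mapped to a sentinel level that is
    stripped afterwards, so only in-mask pairs are counted.
    """
    sentinel = levels
    img = np.where(qroi >= 0, qroi, sentinel).astype(np.uint16)
    p = graycomatrix(
        img,
        distances=[distance],
        angles=[_SKIMAGE_ANGLES[direction]],
        levels=levels + 1,
        symmetric=True,
        normed=False,
    )[:levels, :levels, 0, 0].astype(np.float64)
    total = p.sum()
    if total == 0:
        return None
    return p / total


def _glcm_stats(p: np.ndarray) -> dict[str, float]:
    g = p.shape[0]
    idx = np.arange(g, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    px = p.sum(axis=1)
    mu = float((idx * px).sum())
    var = float(((idx - mu) ** 2 * px).sum())
    sd = np.sqrt(var)

    diff = np.abs(ii - jj).astype(np.int64)
    p_sum = np.bincount((ii + jj).astype(np.int64).ravel(), weights=p.ravel(), minlength=2 * g - 1)
    p_diff = np.bincount(diff.ravel(), weights=p.ravel(), minlength=g)
    ks = np.arange(len(p_sum), dtype=np.float64)
    kd = np.arange(len(p_diff), dtype=np.float64)
    sum_avg = float((ks * p_sum).sum())
    dif_avg = float((kd * p_diff).sum())

    def _entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    if sd > 0:
        correlation = float(((ii * jj * p).sum() - mu * mu) / (sd * sd))
    else:
        correlation = 0.0
    return {
        "AngScMom": float((p * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlat": correlation,
        "SumOfSqs": var,
        "InvDfMom": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "SumAverg": sum_avg,
        "SumVarnc": float(((ks - sum_avg) ** 2 * p_sum).sum()),
        "SumEntrp": _entropy(p_sum),
        "Entropy": _entropy(p.ravel()),
        "DifVarnc": float(((kd - dif_avg) ** 2 * p_diff).sum()),
        "DifEntrp": _entropy(p_diff),
    }


def glcm_features(qroi: np.ndarray, config: TextureConfig | None = None) -> dict[str, float]:
    """11 co-occurrence features per (distance, direction) matrix."""
    config = config or TextureConfig()
    out: dict[str, float] = {}
    for d in config.glcm_distances:
        for direction in DIRECTIONS:
            p = glcm_matrix(qroi, d, direction, config.gray_levels)
            if p is None:
                logger.warning("GLCM d=%d dir=%s: no valid pairs, matrix skipped", d, direction)
                continue
            for name, val in _glcm_stats(p).items():
                out[f"glcm.{name}.d{d}.{direction}"] = val
    return out


# ---------------------------------------------------------------------------
# Run-length matrix


def _direction_lines(qroi: np.ndarray, direction: str):
    """Yield 1-D level sequences along the given direction."""
    if direction == "0":
        yield from qroi
    elif direction == "90":
        yield from qroi.T
    elif direction == "135":  # main diagonals
        for off in range(-qroi.shape[0] + 1, qroi.shape[1]):
            yield np.diagonal(qroi, offset=off)
    else:  # 45: anti-diagonals
        flipped = np.fliplr(qroi)
        for off in range(-flipped.shape[0] + 1, flipped.shape[1]):
            yield np.diagonal(flipped, offset=off)


def _runs(line: np.ndarray):
    """(level, length) runs of in-mask values, broken at out-of-mask pixels."""
    start = 0
    n = len(line)
    while start < n:
        if line[start] < 0:
            start += 1
            continue
        end = start + 1
        while end < n and line[end] == line[start]:
            end += 1
        yield int(line[start]), end - start
        start = end


def rlm_features(qroi: np.ndarray, config: TextureConfig | None = None) -> dict[str, float]:
    """5 run-length features per direction."""
    config = config or TextureConfig()
    n_pixels = int((qroi >= 0).sum())
    out: dict[str, float] = {}
    for direction in DIRECTIONS:
        by_level: dict[int, int] = {}
        by_length: dict[int, int] = {}
        n_runs = 0
        sre = lre = 0.0
        for line in _direction_lines(qroi, direction):
            for level, length in _runs(np.asarray(line)):
                n_runs += 1
                sre += 1.0 / (length * length)
                lre += float(length * length)
                by_level[level] = by_level.get(level, 0) + 1
                by_length[length] = by_length.get(length, 0) + 1
        if n_runs == 0:
            logger.warning("RLM dir=%s: no runs, direction skipped", direction)
            continue
        out[f"rlm.ShrtREmp.{direction}"] = sre / n_runs
        out[f"rlm.LngREmph.{direction}"] = lre / n_runs
        out[f"rlm.GLevNonUni.{direction}"] = sum(v * v for v in by_level.values()) / n_runs
        out[f"rlm.RLNonUni.{direction}"] = sum(v * v for v in by_length.values()) / n_runs
        out[f"rlm.Fraction.{direction}"] = n_runs / n_pixels
    return out


# ---------------------------------------------------------------------------
# Histogram / gradient / AR / wavelet


def _moments(v: np.ndarray) -> tuple[float, float, float, float]:
    mean = float(v.mean())
    var = float(v.var())
    if var == 0.0:
        return mean, 0.0, 0.0, 0.0
    z = (v - mean) / np.sqrt(var)
    return mean, var, float((z**3).mean()), float((z**4).mean() - 3.0)


def histogram_features(qroi: np.ndarray) -> dict[str, float]:
    """First-order statistics of the quantized in-mask levels."""
    v = qroi[qroi >= 0].astype(np.float64)
    mean, var, skew, kurt = _moments(v)
    p = np.percentile(v, [1, 10, 50, 90, 99])
    return {
        "hist.Mean": mean,
        "hist.Variance": var,
        "hist.Skewness": skew,
        "hist.Kurtosis": kurt,
        "hist.Perc01": float(p[0]),
        "hist.Perc10": float(p[1]),
        "hist.Perc50": float(p[2]),
        "hist.Perc90": float(p[3]),
        "hist.Perc99": float(p[4]),
    }


def gradient_features(qroi: np.ndarray) -> dict[str, float]:
    """Absolute-gradient statistics over pixels whose 4-neighbours are in-mask."""
    m = qroi >= 0
    inner = m & ndi.binary_erosion(m, structure=ndi.generate_binary_structure(2, 1))
    inner[[0, -1], :] = False
    inner[:, [0, -1]] = False
    if not inner.any():
        logger.warning("gradient family skipped: ROI too thin for central differences")
        return {}
    f = qroi.astype(np.float64)
    gy = (np.roll(f, -1, axis=0) - np.roll(f, 1, axis=0)) / 2.0
    gx = (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / 2.0
    grad = np.sqrt(gx * gx + gy * gy)[inner]
    mean, var, skew, kurt = _moments(grad)
    return {
        "grad.GrMean": mean,
        "grad.GrVariance": var,
        "grad.GrSkewness": skew,
        "grad.GrKurtosis": kurt,
        "grad.GrNonZeros": float((grad > 0).mean()),
    }


#: Causal neighbourhood of the AR model: W, NW, N, NE.
AR_NEIGHBORS = ((0, -1), (-1, -1), (-1, 0), (-1, 1))


def ar_features(qroi: np.ndarray) -> dict[str, float]:
    """Least-squares parameters theta1..theta4 (+ residual SD) of the causal
    autoregressive model x[i,j] ~ sum_k theta_k * x[neighbour_k] + const."""
    m = qroi >= 0
    f = qroi.astype(np.float64)
    h, w = f.shape
    rows, cols = np.nonzero(m)
    keep = (rows >= 1) & (cols >= 1) & (cols < w - 1)
    rows, cols = rows[keep], cols[keep]
    design = []
    target = []
    for r, c in zip(rows, cols):
        if all(m[r + dr, c + dc] for dr, dc in AR_NEIGHBORS):
            design.append([f[r + dr, c + dc] for dr, dc in AR_NEIGHBORS] + [1.0])
            target.append(f[r, c])
    if len(target) < 8:
        logger.warning("AR family skipped: ROI too small for the causal neighbourhood")
        return {}
    a = np.asarray(design)
    b = np.asarray(target)
    theta, *_ = np.linalg.lstsq(a, b, rcond=None)
    resid = b - a @ theta
    out = {f"ar.Teta{k + 1}": float(theta[k]) for k in range(4)}
    out["ar.Sigma"] = float(np.sqrt(np.mean(resid**2)))
    return out


def wavelet_features(qroi: np.ndarray, config: TextureConfig | None = None) -> dict[str, float]:
    """Per-level sub-band energies of a 2-D discrete wavelet transform.

    The bounding box is mean-filled outside the mask to limit leakage from
    the background; energy is the mean squared coefficient per sub-band.
    """
    config = config or TextureConfig()
    m = qroi >= 0
    f = qroi.astype(np.float64)
    f[~m] = f[m].mean()
    out: dict[str, float] = {}
    ll = f
    for level in range(1, config.wavelet_levels + 1):
        if min(ll.shape) < 2:
            logger.warning("wavelet level %d skipped: ROI too small", level)
            break
        ll, (lh, hl, hh) = pywt.dwt2(ll, config.wavelet)
        for band, coef in (("LL", ll), ("LH", lh), ("HL", hl), ("HH", hh)):
            out[f"wavelet.En{band}.l{level}"] = float(np.mean(coef**2))
    return out


# ---------------------------------------------------------------------------


def extract_all(
    img: GrayImage | np.ndarray,
    mask: SegMask | np.ndarray,
    config: TextureConfig | None = None,
) -> pd.Series:
    """Standardize the ROI and concatenate all feature families."""
    config = config or TextureConfig()
    qroi = standardize_gray(img, mask, config)
    features: dict[str, float] = {}
    features.update(histogram_features(qroi))
    features.update(glcm_features(qroi, config))
    features.update(rlm_features(qroi, config))
    features.update(gradient_features(qroi))
    features.update(ar_features(qroi))
    features.update(wavelet_features(qroi, config))
    return pd.Series(features, dtype=np.float64)


def feature_names(config: TextureConfig | None = None) -> list[str]:
    """The full schema for a configuration (no families skipped)."""
    config = config or TextureConfig()
    names = list(histogram_features(np.zeros((8, 8), dtype=np.int64)))
    for d in config.glcm_distances:
        for direction in DIRECTIONS:
            names += [f"glcm.{f}.d{d}.{direction}" for f in GLCM_FEATURES]
    for direction in DIRECTIONS:
        names += [f"rlm.{f}.{direction}" for f in RLM_FEATURES]
    names += ["grad.GrMean", "grad.GrVariance", "grad.GrSkewness", "grad.GrKurtosis", "grad.GrNonZeros"]
    names += [f"ar.Teta{k}" for k in (1, 2, 3, 4)] + ["ar.Sigma"]
    for level in range(1, config.wavelet_levels + 1):
        names += [f"wavelet.En{band}.l{level}" for band in ("LL", "LH", "HL", "HH")]
    return names
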
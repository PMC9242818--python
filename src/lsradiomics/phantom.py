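"""Synthetic phantoms and feature tables.

Two generators drive the whole test surface of the package:

* :func:`generate_phantom` builds a two-region lesion slice (lesion on
  background) with a Gaussian-soft boundary, an optional weak-contrast
  boundary arc, and additive Gaussian noise. It emulates the situation the
  segmentation algorithm targets: a lesion whose boundary-gradient magnitude
  varies along the contour, including arcs weak enough for a classical edge
  indicator to leak through.
* :func:`generate_feature_table` builds labelled feature tables with planted
  class-informative columns, mimicking texture-feature exports with a known
  ground truth for selection and classification tests.

Both are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .io import GrayImage, SegMask
from .tables import FeatureTable


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast, and noise of a two-region lesion phantom.

    ``boundary_softness`` is the Gaussian sigma (pixels) blurring the ideal
    step edge; ``weak_arc_fraction`` of the boundary (a contiguous angular
    sector starting at ``weak_arc_start`` radians) has its lesion/background
    contrast multiplied by ``weak_contrast_factor``.
    """

    height: int = 128
    width: int = 128
    lesion_shape: str = "disk"
    lesion_center: tuple[float, float] = (64.0, 64.0)
    lesion_radius: float | tuple[float, float] = 20.0
    background_level: float = 100.0
    lesion_level: float = 200.0
    boundary_softness: float = 1.0
    weak_arc_fraction: float = 0.0
    weak_arc_start: float = 0.0
    weak_contrast_factor: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_shape not in ("disk", "ellipse", "blob"):
            raise ConfigurationError(f"unknown lesion_shape {self.lesion_shape!r}")
        if not (0.0 <= self.weak_arc_fraction < 1.0):
            raise ConfigurationError("weak_arc_fraction must be in [0, 1)")
        if not (0.0 < self.weak_contrast_factor <= 1.0):
            raise ConfigurationError("weak_contrast_factor must be in (0, 1]")
        if self.boundary_softness < 0 or self.noise_sd < 0:
            raise ConfigurationError("boundary_softness and noise_sd must be >= 0")
        r_max = self._max_radius()
        cy, cx = self.lesion_center
        if not (
            cy - r_max > 0
            and cx - r_max > 0
            and cy + r_max < self.height - 1
            and cx + r_max < self.width - 1
        ):
            raise ConfigurationError("lesion does not fit strictly inside the image")

    @property
    def contrast(self) -> float:
        return self.lesion_level - self.background_level

    def _radii(self) -> tuple[float, float]:
        if isinstance(self.lesion_radius, (int, float)):
            return float(self.lesion_radius), float(self.lesion_radius)
        ry, rx = self.lesion_radius
        return float(ry), float(rx)

    def _max_radius(self) -> float:
        ry, rx = self._radii()
        r = max(ry, rx)
        if self.lesion_shape == "blob":
            r *= 1.0 + _BLOB_AMP_TOTAL
        return r


# Blob radial modulation amplitudes (fractions of the nominal radius).
_BLOB_AMPS = (0.12, 0.06)
_BLOB_LOBES = (3, 5)
_BLOB_AMP_TOTAL = sum(_BLOB_AMPS)


def _lesion_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (inside mask, boundary angle map) for the lesion shape."""
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cy, cx = spec.lesion_center
    dy = yy - cy
    dx = xx - cx
    theta = np.arctan2(dy, dx)
    ry, rx = spec._radii()
    if spec.lesion_shape == "disk":
        inside = dy * dy + dx * dx <= ry * ry
    elif spec.lesion_shape == "ellipse":
        inside = (dy / ry) ** 2 + (dx / rx) ** 2 <= 1.0
    else:  # blob: radius modulated by two low-order harmonics, seeded phases
        rng = np.random.default_rng(spec.seed ^ 0x5EED)
        phases = rng.uniform(0, 2 * np.pi, size=len(_BLOB_AMPS))
        r_theta = ry * (
            1.0
            + sum(
                a * np.sin(k * theta + p)
                for a, k, p in zip(_BLOB_AMPS, _BLOB_LOBES, phases)
            )
        )
        inside = np.hypot(dy, dx) <= r_theta
    return inside, theta


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, SegMask]:
    """Generate a lesion phantom and its ground-truth mask.

    The noiseless image before blurring has exactly two intensity values
    (three when a weak arc is present); the returned mask is the exact
    rasterisation of the lesion shape, independent of blur and noise.
    """
    inside, theta = _lesion_geometry(spec)

    contrast_map = np.full(inside.shape, spec.contrast, dtype=np.float64)
    if spec.weak_arc_fraction > 0:
        arc = (theta - spec.weak_arc_start) % (2 * np.pi)
        weak = arc < 2 * np.pi * spec.weak_arc_fraction
        contrast_map[weak] *= spec.weak_contrast_factor

    img = spec.background_level + contrast_map * inside
    if spec.boundary_softness > 0:
        img = gaussian_filter(img, spec.boundary_softness, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    return (
        GrayImage(pixels=img, intensity_units="arbitrary"),
        SegMask(pixels=inside.astype(np.uint8)),
    )


def analytic_boundary_gradient(
    spec: PhantomSpec, sigma: float = 0.0, *, weak: bool = False
) -> float:
    """Peak gradient magnitude of the (noiseless) blurred step edge.

    A step of height ``h`` blurred with total Gaussian scale ``s`` has peak
    derivative ``h / (s * sqrt(2*pi))``; blur scales add in quadrature, so an
    extra detector smoothing ``sigma`` combines with ``boundary_softness``.
    With ``weak=True`` the weak-arc contrast is used.
    """
    s = math.hypot(spec.boundary_softness, sigma)
    if s == 0:
        raise ConfigurationError("boundary gradient undefined for a hard step (s=0)")
    h = abs(spec.contrast) * (spec.weak_contrast_factor if weak else 1.0)
    return h / (s * math.sqrt(2 * math.pi))


@dataclass(frozen=True)
class FeatureTableSpec:
    """Planted-effect feature-table generator settings.

    Informative columns differ between classes by ``effect_size`` standard
    deviations and are equicorrelated with coefficient ``correlation``;
    noise columns are i.i.d. standard normal, independent of the label.
    """

    n_samples: int = 50  # per class
    n_informative: int = 10
    n_noise: int = 90
    effect_size: float = 5.0
    correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("need >= 2 samples per class")
        if self.n_informative < 0 or self.n_noise < 0:
            raise ConfigurationError("feature counts must be >= 0")
        if self.n_informative + self.n_noise == 0:
            raise ConfigurationError("need at least one feature")
        if not (0.0 <= self.correlation < 1.0):
            raise ConfigurationError("correlation must be in [0, 1)")


def generate_feature_table(spec: FeatureTableSpec) -> FeatureTable:
    """Draw a balanced two-class table with planted informative features."""
    rng = np.random.default_rng(spec.seed)
    n, p_inf, p_noise = spec.n_samples, spec.n_informative, spec.n_noise

    blocks = []
    names: list[str] = []
    if p_inf > 0:
        cov = np.full((p_inf, p_inf), spec.correlation)
        np.fill_diagonal(cov, 1.0)
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((2 * n, p_inf)) @ chol.T
        z[n:] += spec.effect_size  # class 2 shifted by the planted effect
        blocks.append(z)
        names += [f"inf_{i + 1:02d}" for i in range(p_inf)]
    if p_noise > 0:
        blocks.append(rng.standard_normal((2 * n, p_noise)))
        names += [f"noise_{i + 1:02d}" for i in range(p_noise)]

    x = np.hstack(blocks)
    labels = np.r_[np.ones(n, dtype=int), np.full(n, 2, dtype=int)]
    return FeatureTable(pd.DataFrame(x, columns=names), labels)
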
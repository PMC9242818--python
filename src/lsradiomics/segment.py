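"""High-level lesion segmentation: ROI -> edge map -> evolved contour -> mask.

Ties the edge indicator and the level-set evolution together the way the
method is used in practice: crop a rectangular ROI around the lesion, set or
estimate the boundary gradient I0, seed any closed curve (e.g. a triangle)
inside the lesion, and evolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import edges, levelset
from .errors import ConfigurationError
from .io import GrayImage, SegMask, validate_roi


@dataclass
class SegmentResult:
    mask: SegMask  # on the full image raster
    mask_roi: SegMask  # on the ROI raster
    phi: np.ndarray
    edge_map: edges.EdgeMap
    i0: float  # raw gradient units actually used
    iterations: int
    converged: bool
    roi: tuple[int, int, int, int]


def triangle_seed(center: tuple[float, float], radius: float) -> np.ndarray:
    """Equilateral triangle around ``center`` -- a convenient seed contour."""
    cy, cx = center
    angles = np.deg2rad([90.0, 210.0, 330.0])
    return np.column_stack([cy - radius * np.sin(angles), cx + radius * np.cos(angles)])


def segment(
    img: GrayImage,
    seed_polygon: np.ndarray,
    *,
    roi: tuple[int, int, int, int] | None = None,
    sigma: float = 1.0,
    i0: float | str = "auto",
    i0_window: tuple[int, int, int, int] | None = None,
    indicator: str = "enhanced",
    normalization: str = "percentile",
    percentile: float = 99.0,
    evolve_params: levelset.EvolveParams | None = None,
) -> SegmentResult:
    """Segment one lesion.

    All coordinates (ROI, seed polygon, I0 window) are in full-image pixel
    coordinates. ``i0="auto"`` estimates the boundary gradient from
    ``i0_window`` (default: the whole ROI) with the mean + SD threshold rule;
    a float fixes it in raw gradient units.
    """
    if roi is None:
        roi = (0, 0, img.shape[0], img.shape[1])
    validate_roi(roi, img.shape)
    r0, c0, r1, c1 = roi
    crop = img.pixels[r0:r1, c0:c1]

    if i0 == "auto":
        win = i0_window if i0_window is not None else roi
        i0_value = edges.estimate_boundary_gradient(img, win, sigma)
    else:
        i0_value = float(i0)
        if i0_value <= 0:
            raise ConfigurationError("I0 must be > 0")

    params = edges.EdgeParams(
        sigma=sigma, i0=i0_value, normalization=normalization, percentile=percentile
    )
    edge_map = edges.compute_edge_map(crop, params, kind=indicator)

    poly = np.asarray(seed_polygon, dtype=np.float64) - np.array([r0, c0])
    phi0 = levelset.initialize(crop.shape, poly)
    result = levelset.evolve(phi0, edge_map.g, evolve_params or levelset.EvolveParams())

    mask_roi = levelset.extract_mask(result.phi)
    full = np.zeros(img.shape, dtype=np.uint8)
    full[r0:r1, c0:c1] = mask_roi.pixels
    return SegmentResult(
        mask=SegMask(pixels=full),
        mask_roi=mask_roi,
        phi=result.phi,
        edge_map=edge_map,
        i0=i0_value,
        iterations=result.iterations,
        converged=result.converged,
        roi=roi,
    )
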
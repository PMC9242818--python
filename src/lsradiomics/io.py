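"""Image and mask I/O with CT windowing.

Conventions used throughout the package: pixel coordinates are row-major and
0-based; a rectangular ROI is the half-open box ``(r0, c0, r1, c1)`` covering
rows ``r0..r1-1`` and columns ``c0..c1-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ImageFormatError

#: Clinical window presets as (center, width) in HU. The narrow soft-tissue
#: preset follows the acquisition protocol this pipeline targets; the bone
#: window is the default for phantom work because it is numerically benign.
WINDOW_PRESETS: dict[str, tuple[float, float]] = {
    "soft_tissue": (40.0, 20.0),
    "bone": (40.0, 1500.0),
}


@dataclass
class GrayImage:
    """A single 2-D grayscale slice.

    Parameters
    ----------
    pixels
        2-D array of finite scalars.
    intensity_units
        ``"HU"`` for calibrated CT data, ``"arbitrary"`` otherwise.
    pixel_spacing
        Optional (row, col) spacing in mm.
    roi
        Optional half-open rectangle ``(r0, c0, r1, c1)``.
    """

    pixels: np.ndarray
    intensity_units: str = "arbitrary"
    pixel_spacing: tuple[float, float] | None = None
    roi: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ImageFormatError(f"expected a 2-D image, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ImageFormatError("image contains non-finite values")
        if self.roi is not None:
            validate_roi(self.roi, self.pixels.shape)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def roi_view(self) -> np.ndarray:
        """Return the pixel block covered by ``roi`` (the full image if unset)."""
        if self.roi is None:
            return self.pixels
        r0, c0, r1, c1 = self.roi
        return self.pixels[r0:r1, c0:c1]

    def with_roi(self, roi: tuple[int, int, int, int]) -> "GrayImage":
        validate_roi(roi, self.pixels.shape)
        return replace(self, roi=roi)


@dataclass
class SegMask:
    """Binary mask over an analysis region C_d (its own raster)."""

    pixels: np.ndarray
    domain: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ConfigurationError("mask must be 2-D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ConfigurationError("mask values must be in {0, 1}")
        self.pixels = arr.astype(np.uint8)
        if self.domain is None:
            self.domain = self.pixels.shape
        elif tuple(self.domain) != self.pixels.shape:
            raise ConfigurationError("mask shape does not match its domain")

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def as_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)


def validate_roi(roi: tuple[int, int, int, int], shape: tuple[int, int]) -> None:
    r0, c0, r1, c1 = roi
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ConfigurationError(f"ROI {roi} outside image bounds {shape}")


def read_image(path: str | Path, format: str | None = None) -> GrayImage:
    """Read a single-frame grayscale DICOM/PNG/TIFF slice.

    DICOM rescale slope/intercept are applied so pixel values are in HU.
    Color or multi-frame inputs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("dcm", "dicom"):
        return _read_dicom(path)
    if fmt in ("png", "tif", "tiff"):
        return _read_raster(path)
    raise ImageFormatError(f"unsupported format {fmt!r} for {path}")


def _read_dicom(path: Path) -> GrayImage:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:  # pragma: no cover - exercised via truncated-file test
        raise ImageFormatError(f"cannot parse DICOM {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: multi-frame or color DICOM not supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    spacing = None
    if getattr(ds, "PixelSpacing", None) is not None:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return GrayImage(
        pixels=arr.astype(np.float64) * slope + intercept,
        intensity_units="HU",
        pixel_spacing=spacing,
    )


def _read_raster(path: Path) -> GrayImage:
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ImageFormatError(f"cannot read {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: color or multi-frame raster not supported")
    return GrayImage(pixels=arr.astype(np.float64), intensity_units="arbitrary")


def write_image(path: str | Path, img: GrayImage | np.ndarray, *, dtype: str = "uint16") -> None:
    """Write an image as 16-bit (default) or 8-bit PNG/TIFF, min-max scaled."""
    import imageio.v3 as iio

    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    span = hi - lo if hi > lo else 1.0
    scaled = (arr - lo) / span
    if dtype == "uint16":
        out = np.round(scaled * 65535).astype(np.uint16)
    elif dtype == "uint8":
        out = np.round(scaled * 255).astype(np.uint8)
    else:
        raise ConfigurationError(f"unsupported dtype {dtype!r}")
    iio.imwrite(Path(path), out)


def write_mask(path: str | Path, mask: SegMask) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.pixels * 255).astype(np.uint8))


def read_mask(path: str | Path) -> SegMask:
    """Read a {0,255} (or {0,1}) PNG mask back to a SegMask."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: mask must be single-channel")
    return SegMask(pixels=(arr > 0).astype(np.uint8))


def apply_window(img: GrayImage, center: float, width: float) -> GrayImage:
    """Linearly map ``[center - width/2, center + width/2]`` to [0, 1], clipping outside.

    The standard display transform for CT: ``width`` must be positive.
    """
    if width <= 0:
        raise ConfigurationError(f"window width must be > 0, got {width}")
    lo = center - width / 2.0
    out = np.clip((img.pixels - lo) / width, 0.0, 1.0)
    return GrayImage(
        pixels=out,
        intensity_units="arbitrary",
        pixel_spacing=img.pixel_spacing,
        roi=img.roi,
    )
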
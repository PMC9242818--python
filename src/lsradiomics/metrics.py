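"""Volume-fraction metrics for segmentation quality.

With C_o the produced mask, C_t the reference (gold standard) mask and C_d
the analysis region:

    TPVF = 100 * |C_o  intersect C_t| / |C_t|
    FPVF = 100 * |C_o \\ C_t| / (|C_d| - |C_t|)

TPVF is the percentage of reference tissue correctly captured; FPVF is the
fraction of the non-reference analysis region wrongly included
(over-segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, MetricError
from .io import SegMask


@dataclass
class EvalResult:
    tpvf: float
    fpvf: float
    n_overlap: int
    n_false_pos: int
    n_truth: int
    n_domain: int

    def to_dict(self) -> dict:
        return {
            "TPVF": self.tpvf,
            "FPVF": self.fpvf,
            "overlap": self.n_overlap,
            "false_positive": self.n_false_pos,
            "truth_size": self.n_truth,
            "domain_size": self.n_domain,
        }


def _as_bool(mask: SegMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, SegMask):
        return mask.as_bool()
    return np.asarray(mask).astype(bool)


def _check_shapes(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ConfigurationError(f"masks live on different domains: {shapes}")


def tpvf(pred: SegMask | np.ndarray, truth: SegMask | np.ndarray) -> float:
    """True-positive volume fraction, percent."""
    p, t = _as_bool(pred), _as_bool(truth)
    _check_shapes(p, t)
    n_truth = int(t.sum())
    if n_truth == 0:
        raise MetricError("TPVF undefined: reference mask is empty")
    return 100.0 * int((p & t).sum()) / n_truth


def fpvf(
    pred: SegMask | np.ndarray,
    truth: SegMask | np.ndarray,
    domain: SegMask | np.ndarray | None = None,
) -> float:
    """False-positive volume fraction over the analysis region, percent.

    ``domain`` defaults to the full raster the masks live on.
    """
    p, t = _as_bool(pred), _as_bool(truth)
    _check_shapes(p, t)
    d = np.ones_like(t) if domain is None else _as_bool(domain)
    _check_shapes(p, d)
    n_truth = int((t & d).sum())
    n_domain = int(d.sum())
    if n_domain <= n_truth:
        raise MetricError("FPVF undefined: analysis region no larger than reference")
    n_fp = int((p & ~t & d).sum())
    return 100.0 * n_fp / (n_domain - n_truth)


def evaluate(
    pred: SegMask | np.ndarray,
    truth: SegMask | np.ndarray,
    domain: SegMask | np.ndarray | None = None,
) -> EvalResult:
    """Both metrics plus the raw pixel counts."""
    p, t = _as_bool(pred), _as_bool(truth)
    _check_shapes(p, t)
    d = np.ones_like(t) if domain is None else _as_bool(domain)
    _check_shapes(p, d)
    return EvalResult(
        tpvf=tpvf(pred, truth),
        fpvf=fpvf(pred, truth, domain),
        n_overlap=int((p & t & d).sum()),
        n_false_pos=int((p & ~t & d).sum()),
        n_truth=int((t & d).sum()),
        n_domain=int(d.sum()),
    )
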
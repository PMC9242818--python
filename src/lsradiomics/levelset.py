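"""Edge-driven level-set curve evolution.

The contour is the zero level set of a signed field Phi (negative inside).
Evolution minimises the geodesic energy

    E(Phi) = lambda * Int g * delta_eps(Phi) * |grad Phi|   (length term)
           + v      * Int g * H_eps(-Phi)                   (area term)

by explicit gradient descent, with a distance-regularisation term R(Phi)
(double-well potential, weight mu) that keeps Phi close to a signed distance
function and removes the need for re-initialisation:

    dPhi/dt = mu * R(Phi)
            + lambda * delta_eps(Phi) * div(g * grad Phi / |grad Phi|)
            + v * g * delta_eps(Phi)

With v < 0 the area term inflates the contour (seeds are placed inside the
lesion), and the edge indicator g throttles the inflation and anchors the
contour on the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon2mask

from .errors import ConfigurationError, NumericalError
from .io import SegMask


@dataclass
class EvolveParams:
    """Weights and numerics of the descent.

    lam (lambda) weights the length term and must be positive; v weights the
    area (balloon) term, negative for expansion; mu weights distance
    regularisation with the explicit-scheme stability bound tau*mu < 0.25;
    epsilon is the smoothing width (pixels) of the Dirac/Heaviside pair; tol
    is the mean |dPhi| per pixel declaring convergence.
    """

    lam: float = 5.0
    v: float = -2.5
    mu: float = 0.2
    epsilon: float = 1.5
    tau: float = 1.0
    max_iters: int = 1000
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ConfigurationError("lambda must be > 0")
        if self.mu < 0:
            raise ConfigurationError("mu must be >= 0")
        if self.epsilon <= 0 or self.tau <= 0:
            raise ConfigurationError("epsilon and tau must be > 0")
        if self.tau * self.mu >= 0.25:
            raise ConfigurationError("stability requires tau*mu < 0.25")
        if self.max_iters < 1:
            raise ConfigurationError("max_iters must be >= 1")


@dataclass
class EvolveResult:
    phi: np.ndarray
    iterations: int
    converged: bool
    energies: np.ndarray | None = None


def dirac(z: np.ndarray, epsilon: float) -> np.ndarray:
    """Smoothed Dirac delta: (1/pi) * eps / (eps^2 + z^2)."""
    return (epsilon / np.pi) / (epsilon**2 + z * z)


def heaviside(z: np.ndarray, epsilon: float) -> np.ndarray:
    """Smoothed Heaviside matching :func:`dirac` (its antiderivative)."""
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(z / epsilon))


def initialize(shape: tuple[int, int], seed_polygon: np.ndarray) -> np.ndarray:
    """Signed distance field for a closed seed polygon, negative inside.

    ``seed_polygon`` is an (N, 2) array of (row, col) vertices; a repeated
    final vertex is accepted. Any closed curve inside the ROI works as a
    seed -- a triangle is enough.
    """
    poly = np.asarray(seed_polygon, dtype=np.float64)
    if poly.ndim != 2 or poly.shape[1] != 2:
        raise ConfigurationError("seed polygon must be an (N, 2) array of (row, col)")
    if len(poly) >= 2 and np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    if len(poly) < 3:
        raise ConfigurationError("seed polygon needs at least 3 distinct vertices")
    if poly.min() < 0 or np.any(poly.max(axis=0) >= np.asarray(shape)):
        raise ConfigurationError("seed polygon outside the ROI")
    mask = polygon2mask(shape, poly)
    if not mask.any():
        raise ConfigurationError("seed polygon rasterises to an empty region")
    # Half-pixel offset puts the zero crossing on the polygon boundary.
    inside = ndi.distance_transform_edt(mask) - 0.5
    outside = ndi.distance_transform_edt(~mask) - 0.5
    return np.where(mask, -inside, outside)


def _neumann(phi: np.ndarray) -> np.ndarray:
    """Mirror the border so boundary derivatives vanish."""
    out = phi.copy()
    out[0, :] = out[2, :]
    out[-1, :] = out[-3, :]
    out[:, 0] = out[:, 2]
    out[:, -1] = out[:, -3]
    return out


def _div(fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
    return np.gradient(fx, axis=1) + np.gradient(fy, axis=0)


def _dist_reg(phi: np.ndarray) -> np.ndarray:
    """Double-well distance regularisation: drives |grad Phi| toward 1."""
    py, px = np.gradient(phi)
    s = np.sqrt(px * px + py * py)
    a = (s >= 0) & (s <= 1)
    b = s > 1
    ps = a * np.sin(2 * np.pi * s) / (2 * np.pi) + b * (s - 1)
    dps = np.where(ps != 0, ps, 1.0) / np.where(s != 0, s, 1.0)
    lap = ndi.laplace(phi, mode="nearest")
    return _div(dps * px - px, dps * py - py) + lap


def energy(phi: np.ndarray, g: np.ndarray, params: EvolveParams) -> float:
    """Discrete geodesic energy (length + area terms) of the current field."""
    py, px = np.gradient(phi)
    grad = np.sqrt(px * px + py * py)
    length = np.sum(g * dirac(phi, params.epsilon) * grad)
    area = np.sum(g * heaviside(-phi, params.epsilon))
    return float(params.lam * length + params.v * area)


def evolve(
    phi: np.ndarray,
    g: np.ndarray,
    params: EvolveParams,
    *,
    record_energy: bool = False,
) -> EvolveResult:
    """Run the explicit descent until mean |dPhi| < tol or max_iters.

    Raises :class:`NumericalError` (naming the iteration) if Phi leaves the
    finite range.
    """
    phi = np.asarray(phi, dtype=np.float64).copy()
    g = np.asarray(g, dtype=np.float64)
    if phi.shape != g.shape:
        raise ConfigurationError("phi and g shapes must match")

    gy, gx = np.gradient(g)
    energies = [] if record_energy else None
    tiny = 1e-10
    converged = False
    it = 0
    for it in range(1, params.max_iters + 1):
        with np.errstate(over="ignore", invalid="ignore"):
            phi = _neumann(phi)
            py, px = np.gradient(phi)
            s = np.sqrt(px * px + py * py) + tiny
            nx, ny = px / s, py / s
            curvature = _div(nx, ny)
            d = dirac(phi, params.epsilon)
            # div(g * N) = grad g . N + g * div(N)
            length_force = d * (gx * nx + gy * ny + g * curvature)
            area_force = params.v * g * d
            dphi = params.mu * _dist_reg(phi) + params.lam * length_force + area_force
            phi = phi + params.tau * dphi
        if not np.all(np.isfinite(phi)):
            raise NumericalError(f"level-set evolution diverged at iteration {it}")
        if record_energy:
            energies.append(energy(phi, g, params))
        if float(np.mean(np.abs(params.tau * dphi))) < params.tol:
            converged = True
            break
    return EvolveResult(
        phi=phi,
        iterations=it,
        converged=converged,
        energies=np.asarray(energies) if record_energy else None,
    )


def extract_mask(phi: np.ndarray) -> SegMask:
    """Binary mask of the interior (Phi < 0) of the current contour."""
    phi = np.asarray(phi)
    if not np.all(np.isfinite(phi)):
        raise NumericalError("phi contains non-finite values")
    return SegMask(pixels=(phi < 0).astype(np.uint8))
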
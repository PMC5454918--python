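"""Super-resolution image rendering from localization point clouds.

Three renderings are supported:

* **pointillist** — a binary map; a pixel is set iff at least one
  localization falls into it.
* **density** — each point is weighted by the number of further points
  within a fixed radius R; every point with weight > 0 contributes a
  unit-integral Gaussian of a fixed sigma, scaled by its weight.
* **localization** — every point contributes a unit-integral Gaussian
  whose per-axis sigma is that point's localization precision, so the
  image integral approximates the number of points.

All Gaussians are truncated at 4 sigma (mass error < 1e-4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import erf

from .localizer import LocalizationSet

__all__ = [
    "RenderConfig",
    "RenderedImage",
    "neighbor_counts",
    "render_density_image",
    "render_localization_image",
    "render_pointillist",
]


@dataclass
class RenderConfig:
    """Rendering parameters: output pixel pitch, density radius R, blur sigma."""

    pixel_size_nm: float = 10.0
    radius_nm: float = 1000.0
    gauss_sigma_nm: float = 50.0

    def __post_init__(self) -> None:
        if min(self.pixel_size_nm, self.radius_nm, self.gauss_sigma_nm) <= 0:
            raise ValueError("all render parameters must be positive")


@dataclass
class RenderedImage:
    pixels: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float]  # (x, y) of the top-left pixel corner
    kind: str

    @property
    def extent_nm(self) -> tuple[float, float]:
        h, w = self.pixels.shape
        return (w * self.pixel_size_nm, h * self.pixel_size_nm)


def _coords(points) -> np.ndarray:
    if isinstance(points, LocalizationSet):
        return points.coords()
    return np.asarray(points, dtype=float).reshape(-1, 2)


def neighbor_counts(points, radius_nm: float) -> np.ndarray:
    """Number of *other* points within ``radius_nm`` of each point."""
    if radius_nm <= 0:
        raise ValueError("radius_nm must be positive")
    xy = _coords(points)
    if len(xy) == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(xy)
    # query_ball_point includes the point itself; subtract it
    counts = np.array([len(nb) - 1 for nb in tree.query_ball_point(xy, radius_nm)])
    return counts


def _field_geometry(xy: np.ndarray, pixel_size_nm: float, pad_nm: float,
                    fov: tuple[float, float, float, float] | None):
    """Image origin and shape. fov = (x0, y0, width, height) in nm, optional."""
    if fov is not None:
        x0, y0, w_nm, h_nm = fov
        shape = (max(1, math.ceil(h_nm / pixel_size_nm)),
                 max(1, math.ceil(w_nm / pixel_size_nm)))
    else:
        if len(xy) == 0:
            return (0.0, 0.0), (1, 1)
        x0 = xy[:, 0].min() - pad_nm
        y0 = xy[:, 1].min() - pad_nm
        w_nm = xy[:, 0].max() + pad_nm - x0
        h_nm = xy[:, 1].max() + pad_nm - y0
        # one extra pixel so the maximal coordinate falls inside the grid
        shape = (int(h_nm / pixel_size_nm) + 1, int(w_nm / pixel_size_nm) + 1)
    return (x0, y0), shape


def _splat_gaussians(xy: np.ndarray, sx: np.ndarray, sy: np.ndarray,
                     weights: np.ndarray, pixel_size_nm: float,
                     origin: tuple[float, float], shape: tuple[int, int]) -> np.ndarray:
    """Sum of pixel-integrated 2D Gaussians, each truncated at 4 sigma."""
    img = np.zeros(shape, dtype=float)
    h, w = shape
    x0, y0 = origin
    sqrt2 = math.sqrt(2.0)
    for (px, py), sigx, sigy, wt in zip(xy, sx, sy, weights):
        if wt == 0:
            continue
        cx = (px - x0) / pixel_size_nm
        cy = (py - y0) / pixel_size_nm
        rx = max(1.0, 4.0 * sigx / pixel_size_nm)
        ry = max(1.0, 4.0 * sigy / pixel_size_nm)
        j0, j1 = max(0, int(cx - rx)), min(w, int(cx + rx) + 2)
        i0, i1 = max(0, int(cy - ry)), min(h, int(cy + ry) + 2)
        if j0 >= j1 or i0 >= i1:
            continue
        # pixel-integrated profile: difference of error functions per axis
        xe = (np.arange(j0, j1 + 1) * pixel_size_nm + x0 - px)
        ye = (np.arange(i0, i1 + 1) * pixel_size_nm + y0 - py)
        if sigx > 0:
            fx = np.diff(0.5 * (1 + erf(xe / (sqrt2 * sigx))))
        else:  # degenerate: all mass in one pixel column
            fx = np.diff((xe >= 0).astype(float))
        if sigy > 0:
            fy = np.diff(0.5 * (1 + erf(ye / (sqrt2 * sigy))))
        else:
            fy = np.diff((ye >= 0).astype(float))
        img[i0:i1, j0:j1] += wt * np.outer(fy, fx)
    return img


def render_density_image(points, cfg: RenderConfig,
                         fov: tuple[float, float, float, float] | None = None,
                         ) -> RenderedImage:
    """Neighborhood-density rendering.

    Each point's weight is the count of further points within
    ``cfg.radius_nm``; points with weight zero contribute nothing; each
    contributing point adds a unit-integral Gaussian of
    ``cfg.gauss_sigma_nm`` scaled by its weight.
    """
    xy = _coords(points)
    counts = neighbor_counts(xy, cfg.radius_nm) if len(xy) else np.zeros(0)
    origin, shape = _field_geometry(xy, cfg.pixel_size_nm, 4 * cfg.gauss_sigma_nm, fov)
    sig = np.full(len(xy), float(cfg.gauss_sigma_nm))
    img = _splat_gaussians(xy, sig, sig, counts.astype(float),
                           cfg.pixel_size_nm, origin, shape)
    return RenderedImage(img, cfg.pixel_size_nm, origin, "density")


def render_localization_image(points: LocalizationSet, pixel_size_nm: float = 10.0,
                              fov: tuple[float, float, float, float] | None = None,
                              ) -> RenderedImage:
    """Standard localization rendering: one Gaussian per point, sigma = its precision."""
    xy = points.coords()
    prec = points.precisions()
    if len(xy) and np.any(prec <= 0):
        raise ValueError("every localization needs a positive precision")
    pad = 4 * (prec.max() if len(xy) else 0.0)
    origin, shape = _field_geometry(xy, pixel_size_nm, pad, fov)
    img = _splat_gaussians(xy, prec[:, 0] if len(xy) else np.zeros(0),
                           prec[:, 1] if len(xy) else np.zeros(0),
                           np.ones(len(xy)), pixel_size_nm, origin, shape)
    return RenderedImage(img, pixel_size_nm, origin, "localization")


def render_pointillist(points, pixel_size_nm: float = 10.0,
                       fov: tuple[float, float, float, float] | None = None,
                       ) -> RenderedImage:
    """Binary occupancy map: pixel = 1 iff >= 1 localization falls in it.

    A coordinate belongs to pixel floor((coord - origin)/pixel_size)
    (half-open bins).
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    xy = _coords(points)
    origin, shape = _field_geometry(xy, pixel_size_nm, 0.0, fov)
    img = np.zeros(shape, dtype=float)
    if len(xy):
        cols = np.floor((xy[:, 0] - origin[0]) / pixel_size_nm).astype(int)
        rows = np.floor((xy[:, 1] - origin[1]) / pixel_size_nm).astype(int)
        ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
        img[rows[ok], cols[ok]] = 1.0
    return RenderedImage(img, pixel_size_nm, origin, "pointillist")
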
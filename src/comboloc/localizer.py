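"""Single-molecule spot detection and centroid localization.

A localization-microscopy acquisition is a stack of camera frames in which
only a sparse, stochastically changing subset of fluorophores is bright
("blinking").  Each bright spot is an image of a single emitter through the
point-spread function.  This module detects those spots frame by frame and
estimates, for each, the emitter position by an intensity-weighted centroid
(center of gravity), together with the photon sum Q, the signal widths
sigma_x/sigma_y and the localization precision.

The estimators, per spot, with q_i the background-subtracted photon count of
pixel i at (pixel-unit) coordinate x_i and N_B the per-pixel background:

    Q        = sum_i q_i
    mu_x     = sum_i q_i x_i / Q
    sigma_x^2 = sum_i q_i (x_i - mu_x)^2 / Q
    dmu_x    = sqrt( 1/(12 Q) + sum_i ((x_i - mu_x)/Q)^2 (q_i + N_B) )

The 1/(12Q) term is the finite-pixel contribution (variance of a unit
uniform distribution per photon); the second term propagates shot noise of
signal plus background through the centroid.  All moments are computed in
pixel units and converted to nm via the camera pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Frame",
    "Roi",
    "Localization",
    "LocalizationSet",
    "LOCALIZATION_COLUMNS",
    "estimate_background",
    "detect_spots",
    "localize_roi",
    "localize_stack",
    "weighted_moments",
    "localization_precision",
]

#: interchange column order for localization tables (the "coordinate matrix")
LOCALIZATION_COLUMNS = [
    "frame",
    "channel",
    "x_nm",
    "y_nm",
    "photons",
    "sigma_x_nm",
    "sigma_y_nm",
    "precision_x_nm",
    "precision_y_nm",
    "background",
]


@dataclass
class Frame:
    """One raw camera frame: a rectangular non-negative intensity grid."""

    pixels: np.ndarray
    pixel_size_nm: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("frame must be a non-empty 2D grid")
        if np.any(self.pixels < 0):
            raise ValueError("frame intensities must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


@dataclass
class Roi:
    """A square, odd-sided cutout around one candidate spot.

    ``qi`` holds intensities after subtraction of twice the background,
    clamped at zero; ``nb`` is the per-pixel background level *before*
    that subtraction, which enters the precision formula.
    """

    origin: tuple[int, int]  # (row, col) of top-left pixel in the frame
    qi: np.ndarray
    nb: float

    def __post_init__(self) -> None:
        self.qi = np.asarray(self.qi, dtype=float)
        side = self.qi.shape[0]
        if self.qi.ndim != 2 or self.qi.shape[1] != side or side % 2 == 0:
            raise ValueError("roi must be square with odd side length")
        if np.any(self.qi < 0):
            raise ValueError("roi intensities must be >= 0 (clamped)")
        if self.qi.sum() <= 0:
            raise ValueError("roi must contain signal (sum of qi > 0)")
        if self.nb < 0:
            raise ValueError("background must be >= 0")

    @property
    def side(self) -> int:
        return self.qi.shape[0]


@dataclass
class Localization:
    """One detected fluorophore with position and quality metrics (nm)."""

    x: float
    y: float
    q_total: float
    sigma_x: float
    sigma_y: float
    precision_x: float
    precision_y: float
    frame_index: int
    channel: str
    background: float = 0.0


@dataclass
class LocalizationSet:
    """The coordinate matrix: one row per detected fluorophore.

    Thin wrapper around a DataFrame with the interchange columns of
    :data:`LOCALIZATION_COLUMNS`; ``meta`` carries provenance (source file,
    parameters).
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in LOCALIZATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"localization table missing columns: {missing}")
        self.df = self.df[LOCALIZATION_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[Localization], meta: dict | None = None) -> "LocalizationSet":
        rows = [
            (r.frame_index, r.channel, r.x, r.y, r.q_total, r.sigma_x, r.sigma_y,
             r.precision_x, r.precision_y, r.background)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)
        return cls(df, meta or {})

    @classmethod
    def from_coords(cls, xy: np.ndarray, channel: str = "points",
                    precision_nm: float = 10.0, meta: dict | None = None) -> "LocalizationSet":
        """Build a set from bare (n, 2) nm coordinates (analysis entry point)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if xy.size == 0:
            xy = xy.reshape(0, 2)
        df = pd.DataFrame({
            "frame": 0,
            "channel": channel,
            "x_nm": xy[:, 0] if len(xy) else [],
            "y_nm": xy[:, 1] if len(xy) else [],
            "photons": 1.0,
            "sigma_x_nm": 0.0,
            "sigma_y_nm": 0.0,
            "precision_x_nm": precision_nm,
            "precision_y_nm": precision_nm,
            "background": 0.0,
        })
        return cls(df, meta or {})

    def __len__(self) -> int:
        return len(self.df)

    @property
    def channels(self) -> list[str]:
        return sorted(self.df["channel"].unique())

    def select(self, channel: str) -> "LocalizationSet":
        if channel not in set(self.df["channel"]):
            raise KeyError(f"unknown channel {channel!r}; have {self.channels}")
        return LocalizationSet(self.df[self.df["channel"] == channel].copy(), dict(self.meta))

    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) in nm."""
        return self.df[["x_nm", "y_nm"]].to_numpy(dtype=float)

    def precisions(self) -> np.ndarray:
        return self.df[["precision_x_nm", "precision_y_nm"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# moment estimators


def weighted_moments(q: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Return (Q, mu, sigma^2): total weight, weighted mean and variance.

    ``q`` and ``x`` are broadcast-compatible arrays of weights (photon
    counts) and coordinates; any dimensionality is accepted.
    """
    q = np.asarray(q, dtype=float)
    x = np.asarray(x, dtype=float)
    Q = float(q.sum())
    if Q <= 0:
        raise ValueError("total intensity must be positive")
    mu = float((q * x).sum() / Q)
    var = float((q * (x - mu) ** 2).sum() / Q)
    return Q, mu, var


def localization_precision(q: np.ndarray, x: np.ndarray, mu: float, nb: float) -> float:
    """Localization precision along one axis, in the units of ``x``.

    dmu = sqrt( 1/(12 Q) + sum_i ((x_i - mu)/Q)^2 (q_i + N_B) )
    """
    q = np.asarray(q, dtype=float)
    x = np.asarray(x, dtype=float)
    Q = q.sum()
    if Q <= 0:
        raise ValueError("total intensity must be positive")
    term = float((((x - mu) / Q) ** 2 * (q + nb)).sum())
    return math.sqrt(1.0 / (12.0 * Q) + term)


# ---------------------------------------------------------------------------
# detection


def estimate_background(frame: Frame) -> float:
    """Robust per-frame background level: the median pixel intensity."""
    return float(np.median(frame.pixels))


def detect_spots(frame: Frame, background: float, roi_side: int = 7,
                 threshold_factor: float = 4.0) -> list[Roi]:
    """Find candidate single-emitter spots in one frame.

    A pixel is a candidate when it is a local intensity maximum and at
    least ``threshold_factor`` (default 4) times brighter than the
    background.  The spot must fit entirely inside the frame as a
    ``roi_side`` square.  Twice the background is subtracted from every
    ROI pixel (clamped at zero).  Overlapping candidates (closer than
    ``roi_side`` pixels) are resolved by keeping the brighter peak.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    if roi_side < 3 or roi_side % 2 == 0:
        raise ValueError("roi_side must be odd and >= 3")
    img = frame.pixels
    half = roi_side // 2

    local_max = img == ndimage.maximum_filter(img, size=3, mode="constant", cval=-1.0)
    threshold = max(threshold_factor * background, np.finfo(float).tiny)
    candidates = np.argwhere(local_max & (img >= threshold))
    if candidates.size == 0:
        return []

    # must fit inside the frame
    h, w = img.shape
    keepable = [
        (int(r), int(c)) for r, c in candidates
        if half <= r < h - half and half <= c < w - half
    ]
    # brighter peaks first; ties broken row-major for determinism
    keepable.sort(key=lambda rc: (-img[rc], rc))

    kept: list[tuple[int, int]] = []
    for r, c in keepable:
        if all(max(abs(r - kr), abs(c - kc)) >= roi_side for kr, kc in kept):
            kept.append((r, c))

    rois = []
    for r, c in sorted(kept):
        cut = img[r - half: r + half + 1, c - half: c + half + 1] - 2.0 * background
        qi = np.clip(cut, 0.0, None)
        if qi.sum() > 0:
            rois.append(Roi(origin=(r - half, c - half), qi=qi, nb=background))
    return rois


def localize_roi(roi: Roi, pixel_size_nm: float, frame_index: int = 0,
                 channel: str = "points") -> Localization:
    """Estimate position, widths and precision for one spot.

    Pixel (r, c) of the ROI has center coordinates
    (origin_col + c + 0.5, origin_row + r + 0.5) in pixel units; x is the
    column axis, y the row axis, origin at the frame's top-left corner.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    side = roi.side
    r0, c0 = roi.origin
    rows, cols = np.mgrid[0:side, 0:side]
    x = c0 + cols + 0.5  # pixel units
    y = r0 + rows + 0.5

    Q, mu_x, var_x = weighted_moments(roi.qi, x)
    _, mu_y, var_y = weighted_moments(roi.qi, y)
    dmu_x = localization_precision(roi.qi, x, mu_x, roi.nb)
    dmu_y = localization_precision(roi.qi, y, mu_y, roi.nb)

    s = pixel_size_nm
    return Localization(
        x=mu_x * s, y=mu_y * s, q_total=Q,
        sigma_x=math.sqrt(var_x) * s, sigma_y=math.sqrt(var_y) * s,
        precision_x=dmu_x * s, precision_y=dmu_y * s,
        frame_index=frame_index, channel=channel, background=roi.nb,
    )


def localize_stack(stack, channel: str = "points", roi_side: int = 7,
                   threshold_factor: float = 4.0, pixel_size_nm: float | None = None,
                   ) -> LocalizationSet:
    """Run detection + localization over a whole frame stack.

    ``stack`` is a sequence of :class:`Frame` sharing shape and pixel size.
    ``threshold_factor`` scales the peak-over-background acceptance rule
    (default 4).  Deterministic for fixed input.
    """
    frames = list(stack)
    if not frames:
        raise ValueError("stack must be non-empty")
    shape = frames[0].pixels.shape
    px = pixel_size_nm if pixel_size_nm is not None else frames[0].pixel_size_nm
    records: list[Localization] = []
    for fr in frames:
        if fr.pixels.shape != shape:
            raise ValueError("all frames must share the same dimensions")
        bg = estimate_background(fr)
        for roi in detect_spots(fr, bg, roi_side, threshold_factor):
            records.append(localize_roi(roi, px, fr.frame_index, channel))
    meta = {
        "channel": channel,
        "roi_side": roi_side,
        "threshold_factor": threshold_factor,
        "pixel_size_nm": px,
        "n_frames": len(frames),
    }
    return LocalizationSet.from_records(records, meta)
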
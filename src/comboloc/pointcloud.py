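"""DBSCAN cluster detection, hull centroids, and shell density profiles.

ALU-dense regions are identified in the COMBO-FISH localization channel
with DBSCAN: a point is a *cluster point* (core) when at least
``min_points`` localizations — the point itself included — lie within
``radius_nm`` of it; cluster points closer than the radius belong to one
cluster, and noise points within the radius of a cluster point join that
cluster as border points.  The parameters used throughout are a 100 nm
radius and a 10-point minimum.

Each cluster's center is the centroid of the convex hull polygon of its
members, evaluated with the Surveyor's (shoelace) formula.  Around these
centers, the density of a second channel (heterochromatin, H3K9me3) is
profiled in concentric annuli of fixed width (10 nm): shell k covers
distances [k*w, (k+1)*w) and its density is the point count divided by
the annulus area pi*((k+1)^2 - k^2)*w^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from sklearn.cluster import DBSCAN

from .localizer import LocalizationSet

__all__ = [
    "DbscanParams",
    "Cluster",
    "ShellProfile",
    "dbscan",
    "find_clusters",
    "cluster_center",
    "shell_density_profile",
    "mean_shell_profile",
    "colocalization_fraction",
]

NOISE = -1


@dataclass
class DbscanParams:
    """Neighborhood radius (nm) and minimum point count for a core point.

    The minimum count includes the point itself, so a tight blob of
    exactly ``min_points`` localizations forms a cluster.
    """

    radius_nm: float = 100.0
    min_points: int = 10

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be positive")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


@dataclass
class Cluster:
    member_indices: np.ndarray
    hull: np.ndarray           # (m, 2) CCW vertices of the convex hull, nm
    center: tuple[float, float]
    label: int = 0

    @property
    def n_points(self) -> int:
        return len(self.member_indices)


@dataclass
class ShellProfile:
    """Per-annulus point densities around one or many centers."""

    shell_width_nm: float
    radii: np.ndarray      # outer edge of each shell, nm
    counts: np.ndarray     # mean count per shell (per center)
    densities: np.ndarray  # points / nm^2 per shell
    n_clusters_averaged: int = 1

    def __post_init__(self) -> None:
        if not (len(self.radii) == len(self.counts) == len(self.densities)):
            raise ValueError("radii, counts and densities must align")


def _as_xy(points) -> np.ndarray:
    if isinstance(points, LocalizationSet):
        return points.coords()
    xy = np.asarray(points, dtype=float)
    return xy.reshape(-1, 2)


def dbscan(points, params: DbscanParams | None = None) -> np.ndarray:
    """Label each point with a cluster id (0, 1, ...) or -1 for noise.

    Deterministic for a fixed input order: clusters are numbered in order
    of their first core point, and a border point reachable from several
    clusters joins the one discovered first.
    """
    params = params or DbscanParams()
    xy = _as_xy(points)
    if len(xy) == 0:
        return np.zeros(0, dtype=int)
    model = DBSCAN(eps=params.radius_nm, min_samples=params.min_points)
    return model.fit_predict(xy)


def cluster_center(points) -> tuple[float, float]:
    """Centroid of the convex hull of a point set via the shoelace formula.

    C = (1/6A) * sum_i (v_i + v_{i+1}) * (x_i*y_{i+1} - x_{i+1}*y_i)

    Degenerate sets (fewer than 3 points, collinear, zero hull area) fall
    back to the arithmetic mean.
    """
    xy = _as_xy(points)
    if len(xy) == 0:
        raise ValueError("cannot compute the center of an empty cluster")
    hull = _convex_hull(xy)
    if hull is None:
        m = xy.mean(axis=0)
        return float(m[0]), float(m[1])
    return _shoelace_centroid(hull)


def _convex_hull(xy: np.ndarray) -> np.ndarray | None:
    """CCW hull vertices, or None when the set is degenerate."""
    if len(xy) < 3:
        return None
    try:
        h = ConvexHull(xy)
    except QhullError:
        return None
    return xy[h.vertices]  # scipy returns vertices in CCW order for 2D


def _shoelace_centroid(v: np.ndarray) -> tuple[float, float]:
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if area == 0:
        m = v.mean(axis=0)
        return float(m[0]), float(m[1])
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return float(cx), float(cy)


def find_clusters(points, params: DbscanParams | None = None) -> list[Cluster]:
    """DBSCAN + hull + Surveyor centroid for every detected cluster."""
    params = params or DbscanParams()
    xy = _as_xy(points)
    labels = dbscan(xy, params)
    clusters = []
    for lab in sorted(set(labels) - {NOISE}):
        idx = np.flatnonzero(labels == lab)
        members = xy[idx]
        hull = _convex_hull(members)
        center = cluster_center(members)
        clusters.append(Cluster(
            member_indices=idx,
            hull=hull if hull is not None else members,
            center=center,
            label=int(lab),
        ))
    return clusters


def shell_density_profile(center: tuple[float, float], targets,
                          shell_width_nm: float = 10.0,
                          max_radius_nm: float = 1000.0) -> ShellProfile:
    """Target-point density in concentric half-open annuli around a center."""
    if shell_width_nm <= 0:
        raise ValueError("shell_width_nm must be positive")
    if max_radius_nm < shell_width_nm:
        raise ValueError("max_radius_nm must be >= shell_width_nm")
    xy = _as_xy(targets)
    n_shells = int(np.ceil(max_radius_nm / shell_width_nm))
    edges = np.arange(n_shells + 1) * shell_width_nm
    if len(xy):
        d = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
        counts, _ = np.histogram(d, bins=edges)  # half-open [r, r+w)
    else:
        counts = np.zeros(n_shells, dtype=int)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    return ShellProfile(
        shell_width_nm=shell_width_nm,
        radii=edges[1:],
        counts=counts.astype(float),
        densities=counts / areas,
        n_clusters_averaged=1,
    )


def mean_shell_profile(centers, targets, shell_width_nm: float = 10.0,
                       max_radius_nm: float = 1000.0) -> ShellProfile:
    """Arithmetic mean of per-center shell profiles.

    ``centers`` is an iterable of (x, y) tuples or :class:`Cluster`
    objects; the per-cluster densities are averaged shell by shell, so
    pooling several nuclei is a matter of concatenating their centers.
    """
    ctrs = [c.center if isinstance(c, Cluster) else tuple(c) for c in centers]
    if not ctrs:
        raise ValueError("need at least one cluster center")
    profiles = [shell_density_profile(c, targets, shell_width_nm, max_radius_nm)
                for c in ctrs]
    return ShellProfile(
        shell_width_nm=shell_width_nm,
        radii=profiles[0].radii,
        counts=np.mean([p.counts for p in profiles], axis=0),
        densities=np.mean([p.densities for p in profiles], axis=0),
        n_clusters_averaged=len(ctrs),
    )


def colocalization_fraction(set_a, set_b, threshold_nm: float) -> float:
    """Fraction of points in A with a neighbor in B within ``threshold_nm``.

    The measure is asymmetric; call it twice to report both directions.
    """
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be positive")
    a = _as_xy(set_a)
    b = _as_xy(set_b)
    if len(b) == 0:
        raise ValueError("reference set B must be non-empty")
    if len(a) == 0:
        return 0.0
    d, _ = cKDTree(b).query(a)
    return float(np.mean(d <= threshold_nm))
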
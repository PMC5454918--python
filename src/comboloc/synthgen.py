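"""Synthetic data generators with ground truth for every analysis stage.

Four generators emulate the data this pipeline consumes:

* **image stacks** — blinking point emitters imaged through a Gaussian
  point-spread function onto Poisson background, frame by frame;
* **nuclei** — two-channel point clouds: the ALU channel is a
  Neyman-Scott-type clustered process (Gaussian offspring around
  uniformly placed parents inside a circular nucleus) plus uniform
  noise; the heterochromatin channel is an inhomogeneous Poisson process
  whose intensity is suppressed inside each cluster core, elevated in an
  annulus around it, and baseline elsewhere — association without
  co-localization;
* **genomes** — i.i.d. background sequence with non-overlapping, point-
  mutated copies of a repeat consensus planted at known positions;
* **dose series** — per-nucleus counts following the linear-quadratic
  dose-response N(D) = a*D^2 + b*D + c with additive Gaussian noise.

Every generator is bit-reproducible for a fixed seed and returns its
ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .localizer import LOCALIZATION_COLUMNS, LocalizationSet
from .probe_design import ALU_CONSENSUS

__all__ = [
    "EmitterModel",
    "NucleusModel",
    "RepeatGenomeModel",
    "generate_stack",
    "generate_nucleus",
    "generate_genome",
    "generate_dose_series",
    "DOSE_COEFF_A",
    "DOSE_COEFF_B",
    "DOSE_COEFF_C",
    "DEFAULT_DOSES_GY",
]

# reference linear-quadratic calibration coefficients (counts vs Gy)
DOSE_COEFF_A = 3054.0
DOSE_COEFF_B = -1.148e4
DOSE_COEFF_C = 2.139e4
DEFAULT_DOSES_GY = (0.0, 0.1, 0.5, 1.0, 2.0)


# ---------------------------------------------------------------------------
# blinking emitter stacks


@dataclass
class EmitterModel:
    """Stochastic blinking emitters for raw-stack simulation.

    Each emitter is ON in a frame with probability ``blink_prob``; an ON
    emitter deposits a Poisson number of photons (mean ``mean_photons``)
    whose positions scatter around the true position with the PSF sigma,
    binned into camera pixels on top of Poisson background.
    """

    positions_nm: list[tuple[float, float]]
    mean_photons: float = 3000.0
    blink_prob: float = 0.02
    background_mean: float = 10.0
    psf_sigma_nm: float = 150.0
    frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.blink_prob <= 1):
            raise ValueError("blink_prob must be in (0, 1]")
        if min(self.mean_photons, self.psf_sigma_nm) <= 0 or self.background_mean < 0:
            raise ValueError("rates and widths must be positive")
        if self.frames < 1:
            raise ValueError("frames must be >= 1")


def generate_stack(model: EmitterModel, frame_shape: tuple[int, int] = (64, 64),
                   pixel_size_nm: float = 100.0) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a multi-frame acquisition.

    Returns (stack, truth): ``stack`` is a uint16 array of shape
    (frames, h, w); ``truth`` lists one row per ON event with columns
    frame, emitter, x_nm, y_nm, photons.
    """
    rng = np.random.default_rng(model.seed)
    h, w = frame_shape
    pos = np.asarray(model.positions_nm, dtype=float).reshape(-1, 2)
    if np.any(pos < 0) or np.any(pos[:, 0] >= w * pixel_size_nm) \
            or np.any(pos[:, 1] >= h * pixel_size_nm):
        raise ValueError("emitter positions must lie inside the field of view")
    stack = np.empty((model.frames, h, w), dtype=np.uint16)
    truth_rows = []
    xedges = np.arange(w + 1) * pixel_size_nm
    yedges = np.arange(h + 1) * pixel_size_nm
    for f in range(model.frames):
        img = rng.poisson(model.background_mean, size=(h, w)).astype(float)
        on = rng.random(len(pos)) < model.blink_prob
        for e in np.flatnonzero(on):
            n_ph = rng.poisson(model.mean_photons)
            if n_ph == 0:
                continue
            pts = pos[e] + rng.normal(0.0, model.psf_sigma_nm, size=(n_ph, 2))
            counts, _, _ = np.histogram2d(pts[:, 1], pts[:, 0], bins=(yedges, xedges))
            img += counts
            truth_rows.append((f, int(e), pos[e, 0], pos[e, 1], int(n_ph)))
        stack[f] = np.clip(img, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    truth = pd.DataFrame(truth_rows,
                         columns=["frame", "emitter", "x_nm", "y_nm", "photons"])
    return stack, truth


# ---------------------------------------------------------------------------
# two-channel nuclei


@dataclass
class NucleusModel:
    """Two-channel nuclear point cloud with planted structure.

    ALU channel: ``n_clusters`` parents placed uniformly in a disc of
    ``nucleus_radius_nm`` with a hard-core minimum separation so planted
    clusters stay individually resolvable; each parent receives a
    Poisson(``points_per_cluster_mean``) number of Gaussian offspring
    (sigma ``cluster_sigma_nm``), floored at ``points_per_cluster_min``;
    a fraction ``alu_noise_fraction`` of all ALU points is uniform noise.

    Heterochromatin channel: baseline intensity
    ``het_background_per_nm2`` multiplied by ``het_suppression`` within
    ``het_annulus[0]`` of the nearest cluster center, by
    ``het_annulus[2]`` between the inner and outer annulus radii, and by
    1 elsewhere.

    All emitted coordinates get Gaussian localization jitter
    (``localization_jitter_nm``).
    """

    n_clusters: int = 200
    points_per_cluster_mean: float = 30.0
    points_per_cluster_min: int = 10
    cluster_sigma_nm: float = 40.0
    nucleus_radius_nm: float = 5000.0
    min_separation_nm: float = 400.0
    alu_noise_fraction: float = 0.05
    het_annulus: tuple[float, float, float] = (100.0, 300.0, 3.0)
    het_suppression: float = 0.05
    het_background_per_nm2: float = 2e-5
    localization_jitter_nm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        inner, outer, ratio = self.het_annulus
        if not (0 <= inner < outer):
            raise ValueError("annulus must satisfy 0 <= inner < outer")
        if ratio <= 0 or self.het_suppression < 0 or self.het_background_per_nm2 < 0:
            raise ValueError("intensities must be non-negative")
        if not (0 <= self.alu_noise_fraction < 1):
            raise ValueError("alu_noise_fraction must be in [0, 1)")
        if self.points_per_cluster_min < 1:
            raise ValueError("points_per_cluster_min must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _place_parents(rng, n, radius, min_sep, max_tries=200_000) -> np.ndarray:
    out: list[np.ndarray] = []
    tries = 0
    while len(out) < n:
        if tries >= max_tries:
            raise ValueError(
                "could not place cluster centers with the requested separation")
        tries += 1
        cand = _uniform_disc(rng, 1, radius)[0]
        if all(np.hypot(*(cand - p)) >= min_sep for p in out):
            out.append(cand)
    return np.array(out)


def generate_nucleus(model: NucleusModel) -> tuple[LocalizationSet, dict]:
    """Simulate one nucleus; channels are 'alu' and 'het'.

    Returns (points, truth) where truth holds 'centers' (n_clusters, 2),
    'alu_labels' (cluster index per ALU point, -1 for noise) and the
    model itself.
    """
    rng = np.random.default_rng(model.seed)
    R = model.nucleus_radius_nm
    centers = _place_parents(rng, model.n_clusters, R, model.min_separation_nm)

    # ALU offspring
    sizes = rng.poisson(model.points_per_cluster_mean, size=model.n_clusters)
    sizes = np.maximum(sizes, model.points_per_cluster_min)
    alu_parts, labels = [], []
    for i, (c, m) in enumerate(zip(centers, sizes)):
        alu_parts.append(c + rng.normal(0.0, model.cluster_sigma_nm, size=(m, 2)))
        labels.extend([i] * m)
    n_signal = int(sizes.sum())
    f = model.alu_noise_fraction
    n_noise = int(round(f / (1 - f) * n_signal)) if f > 0 else 0
    if n_noise:
        alu_parts.append(_uniform_disc(rng, n_noise, R))
        labels.extend([-1] * n_noise)
    alu = np.concatenate(alu_parts)

    # heterochromatin: thinned homogeneous Poisson at the annulus intensity
    inner, outer, ratio = model.het_annulus
    lam_max = model.het_background_per_nm2 * max(ratio, 1.0, model.het_suppression)
    n_max = rng.poisson(lam_max * np.pi * R ** 2)
    het_cand = _uniform_disc(rng, n_max, R)
    if len(het_cand):
        from scipy.spatial import cKDTree
        d, _ = cKDTree(centers).query(het_cand)
        mult = np.ones(len(het_cand))
        mult[d < inner] = model.het_suppression
        mult[(d >= inner) & (d <= outer)] = ratio
        keep = rng.random(len(het_cand)) < mult * model.het_background_per_nm2 / lam_max
        het = het_cand[keep]
    else:
        het = het_cand

    if model.localization_jitter_nm > 0:
        alu = alu + rng.normal(0.0, model.localization_jitter_nm, size=alu.shape)
        het = het + rng.normal(0.0, model.localization_jitter_nm, size=het.shape)

    jitter = model.localization_jitter_nm if model.localization_jitter_nm > 0 else 10.0
    frames = [
        LocalizationSet.from_coords(alu, "alu", precision_nm=jitter).df,
        LocalizationSet.from_coords(het, "het", precision_nm=jitter).df,
    ]
    points = LocalizationSet(pd.concat(frames, ignore_index=True)[LOCALIZATION_COLUMNS],
                             meta={"generator": "nucleus", "seed": model.seed})
    truth = {"centers": centers, "alu_labels": np.array(labels), "model": model}
    return points, truth


# ---------------------------------------------------------------------------
# planted-repeat genomes


@dataclass
class RepeatGenomeModel:
    """Random genome with planted, point-mutated repeat copies."""

    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 200_000})
    consensus: str = ALU_CONSENSUS
    n_copies: int = 25
    substitution_rate: float = 0.0
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate <= 0.3):
            raise ValueError("substitution_rate must be in [0, 0.3]")
        if abs(sum(self.base_probs) - 1) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        for chrom, length in self.chrom_lengths.items():
            if self.n_copies * len(self.consensus) >= length:
                raise ValueError(
                    f"planted copies do not fit in {chrom} (length {length})")


_BASES = np.array(list("ACGT"))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        arr[i] = rng.choice(_BASES[_BASES != arr[i]])
    return "".join(arr)


def generate_genome(model: RepeatGenomeModel,
                    ) -> tuple[dict[str, str], list[tuple[str, int, int, str]]]:
    """Background sequence with ``n_copies`` planted per chromosome.

    Returns (genome dict, BED-style truth intervals of the planted
    copies).  Copies never overlap; placement failure after bounded
    retries raises.
    """
    rng = np.random.default_rng(model.seed)
    L = len(model.consensus)
    genome: dict[str, str] = {}
    bed: list[tuple[str, int, int, str]] = []
    for chrom, length in model.chrom_lengths.items():
        seq = rng.choice(_BASES, size=length, p=list(model.base_probs))
        placed: list[int] = []
        tries = 0
        while len(placed) < model.n_copies:
            if tries > 10_000 * max(1, model.n_copies):
                raise ValueError(f"could not place copies without overlap on {chrom}")
            tries += 1
            s = int(rng.integers(0, length - L + 1))
            if all(abs(s - p) >= L for p in placed):
                placed.append(s)
        for i, s in enumerate(sorted(placed)):
            copy = _mutate(rng, model.consensus, model.substitution_rate)
            seq[s:s + L] = list(copy)
            bed.append((chrom, s, s + L, f"{chrom}_copy{i}"))
        genome[chrom] = "".join(seq)
    return genome, bed


# ---------------------------------------------------------------------------
# dose-response count series


def generate_dose_series(a: float = DOSE_COEFF_A, b: float = DOSE_COEFF_B,
                         c: float = DOSE_COEFF_C,
                         doses=DEFAULT_DOSES_GY, n_cells_per_dose: int = 35,
                         noise_sigma: float = 500.0, seed: int = 0,
                         noise: str = "gaussian") -> pd.DataFrame:
    """Per-nucleus counts at each dose: round(N(D) + Gaussian(0, sigma)), >= 0.

    ``noise='poisson'`` draws Poisson(N(D)) instead, for sensitivity
    checks.  A negative predicted mean at any dose raises.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        mean = a * d ** 2 + b * d + c
        if mean < 0:
            raise ValueError(f"predicted mean count is negative at {d} Gy")
        if noise == "gaussian":
            vals = np.round(mean + rng.normal(0.0, noise_sigma, n_cells_per_dose))
        elif noise == "poisson":
            vals = rng.poisson(mean, n_cells_per_dose).astype(float)
        else:
            raise ValueError("noise must be 'gaussian' or 'poisson'")
        for cell, v in enumerate(np.maximum(vals, 0).astype(int)):
            rows.append((float(d), cell, int(v)))
    return pd.DataFrame(rows, columns=["dose_gy", "cell_id", "count"])
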
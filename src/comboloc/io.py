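"""File formats: localization tables, TIFF stacks, FASTA, BED, CSV outputs.

The interchange format between pipeline stages is a TSV localization
table ("coordinate matrix") with a fixed header::

    frame  channel  x_nm  y_nm  photons  sigma_x_nm  sigma_y_nm
    precision_x_nm  precision_y_nm  background

All genomic coordinates are 0-based half-open (BED convention); FASTA
headers are truncated at the first whitespace.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .localizer import LOCALIZATION_COLUMNS, Frame, LocalizationSet
from .pointcloud import Cluster, ShellProfile
from .probe_design import AnnotationSet, BinDensityMap, KmerHitList

__all__ = [
    "read_localization_table",
    "write_localization_table",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_stack",
    "write_stack",
    "write_hits_bed",
    "write_bin_density",
    "write_clusters",
    "write_shell_profile",
    "write_rendered_image",
]

_NUMERIC = [c for c in LOCALIZATION_COLUMNS if c != "channel"]


def read_localization_table(path) -> LocalizationSet:
    """Read a TSV localization table, validating schema and invariants.

    Malformed rows (non-numeric fields, non-positive photons or
    precision) are rejected with their 1-based line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"channel": str})
    missing = [c for c in LOCALIZATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}:{line}: non-numeric value in column {col!r}")
        df[col] = vals
    for col in ("photons", "precision_x_nm", "precision_y_nm"):
        bad = df[col] <= 0
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}:{line}: {col} must be positive")
    for col in ("sigma_x_nm", "sigma_y_nm", "background"):
        bad = df[col] < 0
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}:{line}: {col} must be >= 0")
    return LocalizationSet(df, {"source": str(path)})


def write_localization_table(points: LocalizationSet, path) -> None:
    points.df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """FASTA records as {id: uppercase-preserved sequence}; id = first token."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_bed(path) -> AnnotationSet:
    """BED with 4-6 columns (3 tolerated; name defaults to the row index)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else str(lineno)
            intervals.append((chrom, start, end, name))
    return AnnotationSet(intervals)


def write_bed(annotation: AnnotationSet | list, path) -> None:
    intervals = annotation.intervals if isinstance(annotation, AnnotationSet) \
        else annotation
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_hits_bed(hits: KmerHitList, path) -> None:
    """Hits as BED6: name = probe sequence, score = 0."""
    k = hits.probe.k
    with open(path, "w") as fh:
        for h in hits.hits:
            fh.write(f"{h.chrom}\t{h.start}\t{h.start + k}\t"
                     f"{hits.probe.sequence}\t0\t{h.strand}\n")


def read_stack(path, pixel_size_nm: float) -> list[Frame]:
    """Multi-page grayscale TIFF as a list of Frames."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected grayscale multi-frame TIFF, "
                         f"got shape {arr.shape}")
    return [Frame(pixels=arr[i].astype(float), pixel_size_nm=pixel_size_nm,
                  frame_index=i) for i in range(arr.shape[0])]


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(stack))


def write_bin_density(dmap: BinDensityMap, path) -> None:
    rows = [
        (chrom, i * dmap.bin_size_bp, int(n))
        for chrom, counts in sorted(dmap.counts.items())
        for i, n in enumerate(counts)
    ]
    pd.DataFrame(rows, columns=["chrom", "bin_start", "count"]).to_csv(path, index=False)


def write_clusters(clusters: list[Cluster], path) -> None:
    from shapely.geometry import Polygon, Point

    rows = []
    for cl in clusters:
        if len(cl.hull) >= 3:
            wkt = Polygon(cl.hull).wkt
        else:
            wkt = Point(cl.center).wkt
        rows.append((cl.label, cl.n_points, cl.center[0], cl.center[1], wkt))
    pd.DataFrame(rows, columns=["cluster_id", "n_points", "center_x_nm",
                                "center_y_nm", "hull_wkt"]).to_csv(path, index=False)


def write_shell_profile(profile: ShellProfile, path) -> None:
    w = profile.shell_width_nm
    pd.DataFrame({
        "shell_inner_nm": profile.radii - w,
        "shell_outer_nm": profile.radii,
        "mean_density_per_nm2": profile.densities,
        "n_clusters": profile.n_clusters_averaged,
    }).to_csv(path, index=False)


def write_rendered_image(image, path, params: dict | None = None) -> None:
    """32-bit float TIFF plus a JSON sidecar with the render parameters."""
    path = Path(path)
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))
    sidecar = {
        "kind": image.kind,
        "pixel_size_nm": image.pixel_size_nm,
        "origin_nm": list(image.origin_nm),
        **(params or {}),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
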
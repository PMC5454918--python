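"""End-to-end pipeline runner with a reproducibility manifest.

Stages run in dependency order: simulate → localize → cluster → shells →
dose; probe is independent.  A shells stage without a cluster source, or
a cluster stage without a point source, fails validation before any
computation.  Every run writes a JSON manifest with the tool version, a
config hash, output digests and per-stage record counts; identical
config + seed yields identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .dosimetry import DoseRecord, fit_dose_response
from .pointcloud import DbscanParams, find_clusters, mean_shell_profile
from .probe_design import design_probe, scan_kmer, bin_density
from .synthgen import NucleusModel, generate_nucleus
from . import io as cio

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]

_STAGE_ORDER = ["simulate", "localize", "cluster", "shells", "dose", "probe"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclasses.dataclass
class RunManifest:
    version: str
    config_hash: str
    started: float
    finished: float = 0.0
    stages: dict = dataclasses.field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], n_records: int) -> None:
        self.stages[stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "n_records": n_records,
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _validate(cfg: PipelineConfig) -> list[str]:
    stages = [s for s in _STAGE_ORDER if s in cfg.stages]
    have_points = "simulate" in stages or "localize" in stages \
        or cfg.cluster.points is not None
    if "cluster" in stages and not have_points:
        raise PipelineError("cluster", "needs a point source: a simulate/localize "
                            "stage or cluster.points")
    if "shells" in stages and "cluster" not in stages:
        raise PipelineError("shells", "requires the cluster stage")
    if "localize" in stages and cfg.localizer.stack is None:
        raise PipelineError("localize", "localizer.stack path is required")
    if "dose" in stages and cfg.dose.counts is None:
        raise PipelineError("dose", "dose.counts path is required")
    if "probe" in stages and (cfg.probe.genome is None or cfg.probe.bed is None):
        raise PipelineError("probe", "probe.genome and probe.bed are required")
    return stages


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the configured stages; returns (and writes) the manifest."""
    stages = _validate(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(cfg.model_dump(), sort_keys=True)
    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        started=time.time(),
    )

    points = None
    clusters = None
    try:
        if "simulate" in stages:
            if cfg.simulate.kind != "nucleus":
                raise PipelineError("simulate", "only kind='nucleus' runs inside "
                                    "the pipeline; use the simulate CLI otherwise")
            model = NucleusModel(
                n_clusters=cfg.simulate.n_clusters,
                points_per_cluster_mean=cfg.simulate.points_per_cluster_mean,
                cluster_sigma_nm=cfg.simulate.cluster_sigma_nm,
                nucleus_radius_nm=cfg.simulate.nucleus_radius_nm,
                alu_noise_fraction=cfg.simulate.alu_noise_fraction,
                seed=cfg.seed,
            )
            points, _ = generate_nucleus(model)
            p = out / "points.tsv"
            cio.write_localization_table(points, p)
            manifest.record("simulate", [p], len(points))

        if "localize" in stages:
            from .localizer import localize_stack
            frames = cio.read_stack(cfg.localizer.stack, cfg.localizer.pixel_size_nm)
            points = localize_stack(frames, channel=cfg.localizer.channel,
                                    roi_side=cfg.localizer.roi_side,
                                    threshold_factor=cfg.localizer.threshold_factor)
            p = out / "localizations.tsv"
            cio.write_localization_table(points, p)
            manifest.record("localize", [p], len(points))

        if "cluster" in stages:
            if points is None:
                points = cio.read_localization_table(cfg.cluster.points)
            alu = points.select(cfg.cluster.channel) \
                if cfg.cluster.channel in points.channels else points
            clusters = find_clusters(alu, DbscanParams(cfg.cluster.radius_nm,
                                                       cfg.cluster.min_points))
            p = out / "clusters.csv"
            cio.write_clusters(clusters, p)
            manifest.record("cluster", [p], len(clusters))

        if "shells" in stages:
            if not clusters:
                raise PipelineError("shells", "no clusters were detected")
            targets = points.select(cfg.shells.targets_channel)
            profile = mean_shell_profile(clusters, targets,
                                         cfg.shells.shell_width_nm,
                                         cfg.shells.max_radius_nm)
            p = out / "shell_profile.csv"
            cio.write_shell_profile(profile, p)
            manifest.record("shells", [p], len(profile.radii))

        if "dose" in stages:
            import pandas as pd
            df = pd.read_csv(cfg.dose.counts)
            records = [DoseRecord(dose_gy=d, counts=list(g["count"]))
                       for d, g in df.groupby("dose_gy")]
            fit = fit_dose_response(records, per_cell=cfg.dose.per_cell)
            p = out / "dose_fit.json"
            p.write_text(json.dumps({
                "a": fit.a, "b": fit.b, "c": fit.c, "rss": fit.rss,
                "doses": fit.doses,
                "n_per_dose": {str(r.dose_gy): r.n_cells for r in records},
            }, indent=2))
            manifest.record("dose", [p], len(records))

        if "probe" in stages:
            genome = cio.read_fasta(cfg.probe.genome)
            annotation = cio.read_bed(cfg.probe.bed)
            outputs = []
            if cfg.probe.consensus:
                cons_path = Path(cfg.probe.consensus)
                consensus = next(iter(cio.read_fasta(cons_path).values())) \
                    if cons_path.exists() else cfg.probe.consensus
                ranking = design_probe(consensus, genome, annotation,
                                       k=cfg.probe.k,
                                       strand_policy=cfg.probe.strand,
                                       specificity_floor=cfg.probe.specificity_floor)
                import pandas as pd
                p = out / "probe_ranking.csv"
                pd.DataFrame(
                    [(r.probe.sequence, r.probe.source_offset, r.total_hits,
                      r.overlap_fraction) for r in ranking],
                    columns=["probe", "offset", "total_hits", "overlap_fraction"],
                ).to_csv(p, index=False)
                outputs.append(p)
                best = ranking[0].probe
            else:
                from .probe_design import ALU_PROBE, ProbeCandidate
                best = ProbeCandidate(ALU_PROBE)
            hits = scan_kmer(genome, best, strand_policy=cfg.probe.strand)
            dmap = bin_density(hits, {c: len(s) for c, s in genome.items()})
            p_hits, p_bins = out / "probe_hits.bed", out / "probe_bins.csv"
            cio.write_hits_bed(hits, p_hits)
            cio.write_bin_density(dmap, p_bins)
            outputs += [p_hits, p_bins]
            manifest.record("probe", outputs, len(hits))
    except PipelineError:
        manifest.finished = time.time()
        manifest.write(out / "manifest.json")
        raise
    except Exception as exc:  # annotate with the failing stage, keep outputs
        failing = next((s for s in stages if s not in manifest.stages), stages[-1])
        manifest.finished = time.time()
        manifest.write(out / "manifest.json")
        raise PipelineError(failing, str(exc)) from exc

    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return manifest
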
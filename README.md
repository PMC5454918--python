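# comboloc

Analysis toolkit for combined **COMBO-FISH + immunostaining localization
microscopy**: single-molecule localization from raw camera stacks,
super-resolution rendering, DBSCAN-based detection of ALU-repeat clusters
with concentric-shell heterochromatin density profiling, oligonucleotide
probe design by exact k-mer genome scanning, and per-nucleus ALU-count
dose–response fitting for biological dosimetry.

## Who this is for

Localization microscopy (SPDM/STORM-style imaging) reduces a fluorescence
acquisition to a *coordinate matrix* — one row per detected fluorophore
with nanometre position and quality metrics.  When the fluorophores are
COMBO-FISH oligonucleotide probes bound to ALU elements (a ~300-bp SINE
repeat present in roughly a million copies in primate genomes) and
H3K9me3 antibodies marking heterochromatin, those point clouds describe
the nanoscale arrangement of repetitive DNA and compact chromatin in a
nucleus.  This package implements the complete computational chain for
such experiments, and ships synthetic-data generators with ground truth
for every stage so the chain is testable end to end.

## The models at the core

**Localization.**  A spot whose peak is at least 4× the background is cut
out as a square ROI, twice the background is subtracted (clamped at 0),
and position and precision follow from intensity moments over the ROI
pixels *i* with photon counts *q_i*:

    Q    = Σ q_i            μ_x  = Σ q_i x_i / Q
    σ_x² = Σ q_i (x_i − μ_x)² / Q
    Δμ_x = sqrt( 1/(12Q) + Σ ((x_i − μ_x)/Q)² (q_i + N_B) )

with *N_B* the per-pixel background.  Typical precision at a few
thousand photons is in the 10 nm regime.

**Cluster analysis.**  ALU-dense regions are DBSCAN clusters (radius
100 nm, minimum 10 points, the point itself included).  Each cluster
center is the centroid of the convex hull of its members via the
Surveyor's (shoelace) formula.  Heterochromatin density is profiled in
concentric 10-nm annuli around these centers:
density(shell k) = count / (π·((k+1)² − k²)·w²).

**Probe design.**  Candidate probes are all k-mers (default k = 17) of
the ALU consensus; each is scored by its exact occurrence count in a
genome (both orientations by default) and by the fraction of occurrences
inside annotated ALU elements.  The shipped reference probe is
`TAATCCCAGCACTTTGG`, which occurs exactly once in the built-in consensus.

**Dosimetry.**  The per-nucleus ALU signal count falls with absorbed
dose *D* (Gy) as a linear-quadratic curve N(D) = a·D² + b·D + c, fitted
by OLS to per-dose mean counts; inverting the decreasing branch maps an
observed count back to a dose.

## Worked example

```python
from comboloc import (NucleusModel, generate_nucleus, DbscanParams, find_clusters,
                      mean_shell_profile, colocalization_fraction,
                      generate_dose_series, fit_dose_response, estimate_dose)
from comboloc.dosimetry import DoseRecord

points, truth = generate_nucleus(NucleusModel(seed=42))
alu, het = points.select("alu"), points.select("het")
clusters = find_clusters(alu, DbscanParams(radius_nm=100.0, min_points=10))
profile = mean_shell_profile(clusters, het, shell_width_nm=10.0, max_radius_nm=600.0)

df = generate_dose_series(seed=42)
records = [DoseRecord(float(d), list(g["count"])) for d, g in df.groupby("dose_gy")]
fit = fit_dose_response(records)
```

prints (via the obvious summaries):

```
ALU localizations      : 6334
heterochromatin points : 3135
detected ALU clusters  : 200
het density <100 nm    : 3.98e-06 /nm^2
het density 100-300 nm : 5.46e-05 /nm^2
het density >400 nm    : 3.47e-05 /nm^2
ALU-het colocalization : 0.008
dose fit a, b, c       : 3071, -11571, 21403
dose at count 15000    : 0.67 Gy
```

DBSCAN recovers all 200 planted ALU clusters.  The shell profile shows
the planted chromatin architecture: heterochromatin density is an order
of magnitude *lower* inside cluster cores (< 100 nm) than in the
100–300 nm band around them — spatial association without
co-localization (nearest-neighbor colocalization fraction 0.8% at
20 nm).  The far-field density sits between band and baseline because
annuli of neighboring clusters overlap the 400–600 nm range.  The
dose–response fit on one noisy simulated series recovers the generating
coefficients (3054, −11480, 21390) to about 1%, and inverting it turns a
count into a dose estimate.

## Command line

Every stage is also a subcommand of the `comboloc` CLI:

```bash
comboloc simulate nucleus --seed 1 --out sim/n1
comboloc cluster --points sim/n1_points.tsv --channel alu --out clusters.csv
comboloc shells --clusters clusters.csv --targets sim/n1_points.tsv --out profile.csv
comboloc probe scan --genome genome.fa --out hits.bed
comboloc dose fit --counts counts.csv --out fit.json
comboloc run --config pipeline.yaml     # multi-stage run with manifest
```

Exit codes: 0 success, 2 validation error, 1 runtime failure.

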
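"""Offline genome-scale probe evaluation (not part of the automated suite).

Evaluates the built-in 17-mer ALU probe against a locally supplied genome
assembly and a RepeatMasker-derived ALU annotation:

* total exact occurrences of the probe (both orientations),
* fraction of occurrences fully contained in annotated ALU elements,
* fraction of ALU elements covered by at least one occurrence,
* per-chromosome 500-kb occurrence map (CSV).

Genome-wide totals depend strongly on the assembly version and on
whether one or both strands are counted, which is why this comparison is
documented here instead of being asserted in the test suite.  Run it
against your local assembly and compare with whatever reference totals
apply to that assembly.

Usage:
    python scripts/probe_genome_comparison.py \
        --genome hg38.fa --repeats alu_repeats.bed --out-prefix results/hg38
"""

from __future__ import annotations

import argparse
from pathlib import Path

from comboloc.io import read_bed, read_fasta, write_bin_density
from comboloc.probe_design import (ALU_PROBE, ProbeCandidate,
                                   annotation_overlap_fraction, bin_density,
                                   covered_element_fraction, scan_kmer)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--genome", required=True, type=Path)
    parser.add_argument("--repeats", required=True, type=Path,
                        help="BED of annotated ALU elements (e.g. RepeatMasker)")
    parser.add_argument("--probe", default=ALU_PROBE)
    parser.add_argument("--strand", choices=["forward", "both"], default="both")
    parser.add_argument("--out-prefix", type=Path, default=Path("probe_genome"))
    args = parser.parse_args()

    genome = read_fasta(args.genome)
    annotation = read_bed(args.repeats)
    hits = scan_kmer(genome, ProbeCandidate(args.probe),
                     strand_policy=args.strand)
    overlap = annotation_overlap_fraction(hits, annotation)
    coverage = covered_element_fraction(annotation, hits)
    dmap = bin_density(hits, {c: len(s) for c, s in genome.items()})

    args.out_prefix.parent.mkdir(parents=True, exist_ok=True)
    write_bin_density(dmap, f"{args.out_prefix}_bins500kb.csv")
    print(f"probe                 : {args.probe} ({args.strand})")
    print(f"total occurrences     : {len(hits)}")
    print(f"fraction inside ALU   : {overlap:.4%}")
    print(f"ALU elements covered  : {coverage:.4%}")
    print(f"bin map written to    : {args.out_prefix}_bins500kb.csv")


if __name__ == "__main__":
    main()
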
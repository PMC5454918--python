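"""COMBO-FISH oligonucleotide probe design by exact k-mer genome scanning.

A COMBO-FISH probe is a short (default 17 nt) oligonucleotide drawn from
the consensus sequence of a repeat family (here ALU, a ~300 bp SINE
present in very high copy number in primate genomes).  A good probe has
as many exact binding sites in the genome as possible, but essentially
only inside the annotated repeat elements.  This module provides

* exact occurrence scanning of a probe (and of its reverse complement)
  over a genome,
* 500-kb binned per-chromosome occurrence maps,
* specificity scores against a repeat annotation (fraction of hits inside
  elements; fraction of elements covered by a hit),
* exhaustive candidate ranking over all k-mers of a consensus.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProbeCandidate",
    "KmerHit",
    "KmerHitList",
    "BinDensityMap",
    "AnnotationSet",
    "ALU_CONSENSUS",
    "ALU_PROBE",
    "L1_PROBE",
    "reverse_complement",
    "scan_kmer",
    "bin_density",
    "annotation_overlap_fraction",
    "covered_element_fraction",
    "design_probe",
]

#: ~300 bp ALU consensus sequence (5'->3')
ALU_CONSENSUS = (
    "GGCCGGGCGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGAGGCGGGCGGATCACCTGAGG"
    "TCAGGAGTTCGAGACCAGCCTGGCCAACATGGTGAAACCCCGTCTCTACTAAAAATACAAAAATTAGCCG"
    "GGGCGTGGTGGCGCGCGCCTGTAATCCCAGCTACTCGGGAGGCTGAGGCAGGAGAATCGCTTGAACCCGG"
    "GAGGCGGAGGTTGCAGTGAGCCGAGATCGCGCCACTGCACTCCAGCCTGGGCGACAGAGCGAGACTCCGT"
    "CTC"
)

#: the 17-mer ALU probe (a substring of the consensus)
ALU_PROBE = "TAATCCCAGCACTTTGG"

#: 17-mer drawn from the L1 LINE element, used as a distribution contrast
L1_PROBE = "GGTGATTTCTGCATTTC"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ProbeCandidate:
    """A candidate oligonucleotide: uppercase A/C/G/T, no ambiguity codes."""

    sequence: str
    source_offset: int = 0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError("probe must be a non-empty string over A/C/G/T")

    @property
    def k(self) -> int:
        return len(self.sequence)


@dataclass
class KmerHit:
    chrom: str
    start: int  # 0-based
    strand: str  # '+' or '-'


@dataclass
class KmerHitList:
    hits: list[KmerHit]
    probe: ProbeCandidate
    genome_id: str = ""

    def __len__(self) -> int:
        return len(self.hits)


@dataclass
class BinDensityMap:
    """Per-chromosome hit counts in fixed-width genomic bins."""

    bin_size_bp: int
    counts: dict[str, np.ndarray]

    def total(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.counts[chrom].sum())
        return int(sum(v.sum() for v in self.counts.values()))


class AnnotationSet:
    """Genomic intervals (chrom, start, end, name), 0-based half-open.

    Intervals are sorted per chromosome at construction; containment
    queries use a prefix-maximum of interval ends so overlapping
    annotations are handled correctly.
    """

    def __init__(self, intervals: list[tuple[str, int, int, str]]):
        for chrom, start, end, _ in intervals:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        self.intervals = sorted(intervals, key=lambda iv: (iv[0], iv[1], iv[2]))
        self._by_chrom: dict[str, tuple[list[int], list[int], np.ndarray]] = {}
        by: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.intervals:
            by.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by.items():
            starts = [s for s, _ in ivs]
            ends = [e for _, e in ivs]
            self._by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends))

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True iff some single annotation interval contains [start, end)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, _, maxend = entry
        i = bisect.bisect_right(starts, start)  # intervals with start <= start
        return i > 0 and maxend[i - 1] >= end


def _normalize_genome(genome) -> dict[str, str]:
    if isinstance(genome, str):
        return {"seq": genome}
    return dict(genome)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)  # overlapping occurrences included
    return out


def scan_kmer(genome, probe: ProbeCandidate | str, strand_policy: str = "both",
              genome_id: str = "", mask_lowercase: bool = False) -> KmerHitList:
    """All exact occurrences of a probe in a genome.

    ``genome`` is a dict {chrom: sequence} or a bare sequence string.
    ``strand_policy``: 'forward' reports occurrences of the probe itself;
    'both' additionally reports occurrences of its reverse complement
    (strand '-'), i.e. sites where the probe binds the forward strand.
    'N' never matches; lowercase (soft-masked) bases match unless
    ``mask_lowercase`` is set.  Start coordinates are 0-based, on the
    forward strand, for both orientations.
    """
    if strand_policy not in ("forward", "both"):
        raise ValueError("strand_policy must be 'forward' or 'both'")
    if isinstance(probe, str):
        probe = ProbeCandidate(probe)
    seqs = _normalize_genome(genome)
    hits: list[KmerHit] = []
    rc = reverse_complement(probe.sequence)
    palindromic = rc == probe.sequence
    for chrom, seq in seqs.items():
        if mask_lowercase:
            # soft-masked bases are excluded from matching
            s = "".join(c if c.isupper() else "N" for c in seq)
        else:
            s = seq.upper()
        if probe.k > len(s):
            continue
        for pos in _find_all(s, probe.sequence):
            hits.append(KmerHit(chrom, pos, "+"))
        if strand_policy == "both" and not palindromic:
            for pos in _find_all(s, rc):
                hits.append(KmerHit(chrom, pos, "-"))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return KmerHitList(hits=hits, probe=probe, genome_id=genome_id)


def bin_density(hits: KmerHitList, chrom_lengths: dict[str, int],
                bin_size_bp: int = 500_000) -> BinDensityMap:
    """Hit counts per fixed-width bin: a hit at start s lands in bin s // width."""
    if bin_size_bp <= 0:
        raise ValueError("bin_size_bp must be positive")
    counts = {
        chrom: np.zeros(max(1, -(-length // bin_size_bp)), dtype=int)
        for chrom, length in chrom_lengths.items()
    }
    for h in hits.hits:
        if h.chrom not in counts:
            raise ValueError(f"hit on unknown chromosome {h.chrom!r}")
        if h.start >= chrom_lengths[h.chrom]:
            raise ValueError(
                f"hit at {h.chrom}:{h.start} beyond chromosome end "
                f"{chrom_lengths[h.chrom]}")
        counts[h.chrom][h.start // bin_size_bp] += 1
    return BinDensityMap(bin_size_bp=bin_size_bp, counts=counts)


def annotation_overlap_fraction(hits: KmerHitList, annotation: AnnotationSet) -> float:
    """Fraction of hits whose full [start, start+k) lies inside an annotation."""
    if len(hits) == 0:
        return 0.0
    k = hits.probe.k
    inside = sum(annotation.contains(h.chrom, h.start, h.start + k) for h in hits.hits)
    return inside / len(hits)


def covered_element_fraction(annotation: AnnotationSet, hits: KmerHitList) -> float:
    """Fraction of annotation intervals that fully contain >= 1 hit."""
    if len(annotation) == 0:
        raise ValueError("annotation must be non-empty")
    k = hits.probe.k
    starts_by_chrom: dict[str, list[int]] = {}
    for h in hits.hits:
        starts_by_chrom.setdefault(h.chrom, []).append(h.start)
    for v in starts_by_chrom.values():
        v.sort()
    covered = 0
    for chrom, a, b, _ in annotation.intervals:
        starts = starts_by_chrom.get(chrom)
        if not starts:
            continue
        i = bisect.bisect_left(starts, a)  # smallest hit start >= a
        if i < len(starts) and starts[i] + k <= b:
            covered += 1
    return covered / len(annotation)


@dataclass
class RankedProbe:
    probe: ProbeCandidate
    total_hits: int
    overlap_fraction: float
    meets_floor: bool = field(default=False)


def design_probe(consensus: str, genome, annotation: AnnotationSet, k: int = 17,
                 strand_policy: str = "both",
                 specificity_floor: float = 0.99) -> list[RankedProbe]:
    """Rank every k-mer of a consensus as a probe candidate.

    Candidates meeting the specificity floor (hit overlap fraction with
    the annotation >= ``specificity_floor``) rank above all others; within
    each group, more genome hits rank higher, ties broken by consensus
    offset.  A duplicated k-mer is scored once, at its first offset.
    """
    consensus = consensus.upper()
    if len(consensus) < k:
        raise ValueError("consensus shorter than the probe length k")
    seen: dict[str, int] = {}
    for off in range(len(consensus) - k + 1):
        kmer = consensus[off:off + k]
        if set(kmer) - set("ACGT"):
            continue  # ambiguous consensus positions yield no candidate
        seen.setdefault(kmer, off)
    ranked = []
    for kmer, off in seen.items():
        cand = ProbeCandidate(kmer, source_offset=off)
        hits = scan_kmer(genome, cand, strand_policy=strand_policy)
        frac = annotation_overlap_fraction(hits, annotation)
        ranked.append(RankedProbe(
            probe=cand, total_hits=len(hits), overlap_fraction=frac,
            meets_floor=frac >= specificity_floor,
        ))
    ranked.sort(key=lambda r: (not r.meets_floor, -r.total_hits, r.probe.source_offset))
    return ranked
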
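"""Exact-match (zero-mismatch) mapping of small-RNA tags to a genome.

A k-mer hash over the plus strand (default k = 18, the minimum tag
length) seeds candidate loci; every candidate is verified by direct
string comparison, and minus-strand hits are found by looking up the
reverse complement, so both strands are covered exhaustively.  All hit
loci are reported — multi-mappers are not collapsed here; downstream
stages apply their own copy-number rules.

Coordinates are 1-based inclusive with start < end for both strands
(minus-strand hits carry a strand flag rather than swapped coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import revcomp, validate_nucleotides

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30


@dataclass(frozen=True, order=True)
class AlignmentHit:
    """One exact genomic match of a tag."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def region_string(self) -> str:
        """`chrom:start:end:strand` notation."""
        return f"{self.chromosome}:{self.start}:{self.end}:{self.strand}"

    def to_bed(self, name: str = ".", score: int = 0) -> str:
        """BED6 line (0-based half-open)."""
        return "\t".join(
            [self.chromosome, str(self.start - 1), str(self.end), name, str(score), self.strand]
        )


class GenomeIndex:
    """k-mer seed index over the plus strand of every chromosome."""

    def __init__(self, chromosomes: dict[str, str], k: int = 18):
        if k < 8:
            raise ValueError("seed length k < 8 gives a degenerate index")
        if not chromosomes or all(len(s) == 0 for s in chromosomes.values()):
            raise ValueError("genome is empty")
        self.k = k
        self.chromosomes = {name: seq.upper() for name, seq in chromosomes.items()}
        self.lengths = {name: len(seq) for name, seq in self.chromosomes.items()}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name in sorted(self.chromosomes):
            seq = self.chromosomes[name]
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((name, i + 1))

    @property
    def n_positions(self) -> int:
        """Number of indexed plus-strand k-mer positions (with multiplicity)."""
        return sum(len(v) for v in self._index.values())

    def _seed_hits(self, probe: str) -> list[tuple[str, int]]:
        return self._index.get(probe[: self.k], [])

    def map_tag(self, tag: str) -> list[AlignmentHit]:
        """All loci where the tag matches perfectly on either strand.

        Results are sorted by (chromosome, start, strand).
        """
        tag = validate_nucleotides(tag, "tag")
        if not MIN_TAG_LEN <= len(tag) <= MAX_TAG_LEN:
            raise ValueError(f"tag length {len(tag)} outside [18, 30]")
        if len(tag) < self.k:
            raise ValueError(f"tag shorter than index seed length k={self.k}")
        n = len(tag)
        hits: list[AlignmentHit] = []
        for name, pos in self._seed_hits(tag):
            if self.chromosomes[name][pos - 1 : pos - 1 + n] == tag:
                hits.append(AlignmentHit(name, pos, pos + n - 1, "+"))
        rc = revcomp(tag)
        for name, pos in self._seed_hits(rc):
            if self.chromosomes[name][pos - 1 : pos - 1 + n] == rc:
                hits.append(AlignmentHit(name, pos, pos + n - 1, "-"))
        hits.sort(key=lambda h: (h.chromosome, h.start, h.strand))
        return hits


def build_index(chromosomes: dict[str, str], k: int = 18) -> GenomeIndex:
    return GenomeIndex(chromosomes, k=k)


@dataclass
class MappingResult:
    """Per-tag hits and per-chromosome/strand mapped-read tallies."""

    hits: dict[str, list[AlignmentHit]]
    unmapped: set[str]
    strand_tally: dict[tuple[str, str], int]

    @property
    def mapped(self) -> set[str]:
        return set(self.hits)


def map_library(
    index: GenomeIndex, tags: dict[str, int]
) -> MappingResult:
    """Map every tag; tally total read counts per (chromosome, strand).

    Multi-hit tags contribute their full count at every hit locus, so the
    tallies describe where reads *can* originate, mirroring an all-hits
    aligner report.
    """
    hits: dict[str, list[AlignmentHit]] = {}
    unmapped: set[str] = set()
    tally: dict[tuple[str, str], int] = {}
    for seq in sorted(tags):
        found = index.map_tag(seq)
        if not found:
            unmapped.add(seq)
            continue
        hits[seq] = found
        for h in found:
            key = (h.chromosome, h.strand)
            tally[key] = tally.get(key, 0) + tags[seq]
    return MappingResult(hits=hits, unmapped=unmapped, strand_tally=tally)


def naive_scan(chromosomes: dict[str, str], tag: str) -> list[AlignmentHit]:
    """Brute-force sliding-window mapper used as an independent oracle."""
    tag = validate_nucleotides(tag)
    n = len(tag)
    rc = revcomp(tag)
    out = []
    for name in sorted(chromosomes):
        seq = chromosomes[name].upper()
        for probe, strand in ((tag, "+"), (rc, "-")):
            start = seq.find(probe)
            while start != -1:
                out.append(AlignmentHit(name, start + 1, start + n, strand))
                start = seq.find(probe, start + 1)
    out.sort(key=lambda h: (h.chromosome, h.start, h.strand))
    return out
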
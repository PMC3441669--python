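"""Category annotation of mapped tags under a fixed priority rule.

Every unique tag receives exactly one category.  Across all of a tag's
genomic hits, the highest-priority containing annotation wins:

    housekeeping ncRNA (Genbank tier beats Rfam tier)
        > known miRNA > repeat > exon > intron > unannotated

Exon and intron assignments record sense/antisense orientation from the
agreement between the hit strand and the annotated strand.  A hit must be
fully contained in an annotation interval to count (the strict reading;
configurable).  siRNA is not part of this chain: duplex calling claims
tags afterwards, reassigning only tags that were unannotated or
exonic/intronic, so established ncRNA assignments never change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .cleaning import SmallRNATag
from .mapping import AlignmentHit

#: Housekeeping ncRNA categories annotated from sequence databases.
NCRNA_CATEGORIES = ("rRNA", "scRNA", "snRNA", "snoRNA", "tRNA")

#: Report row labels, in printed order.
SUMMARY_CATEGORIES = (
    "exon_antisense",
    "exon_sense",
    "intron_antisense",
    "intron_sense",
    "miRNA",
    "rRNA",
    "scRNA",
    "siRNA",
    "snRNA",
    "snoRNA",
    "tRNA",
    "unann",
)

SUMMARY_LABELS = {
    "exon_antisense": "Exon antisense",
    "exon_sense": "Exon sense",
    "intron_antisense": "Intron antisense",
    "intron_sense": "Intron sense",
    "miRNA": "miRNA",
    "rRNA": "rRNA",
    "scRNA": "scRNA",
    "siRNA": "siRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "tRNA": "tRNA",
    "unann": "unann",
}

GENBANK_TIER = 0
RFAM_TIER = 1

# Priority rank per base category (lower wins); ncRNA rank is tier-adjusted.
_RANK = {
    **{c: 0 for c in NCRNA_CATEGORIES},
    "miRNA": 2,
    "repeat": 3,
    "exon": 4,
    "intron": 5,
}
_UNANN_RANK = 99


@dataclass(frozen=True)
class AnnotationRecord:
    category: str  # base category: rRNA..tRNA, miRNA, repeat, exon, intron
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    tier: int = GENBANK_TIER  # provenance tier for ncRNA categories
    name: str = ""


@dataclass
class AnnotatedTag:
    tag: SmallRNATag
    category: str  # one of SUMMARY_CATEGORIES
    winning_hit: AlignmentHit | None = None
    record: AnnotationRecord | None = None


class AnnotationDB:
    """Interval sets per category with provenance tiers."""

    def __init__(self, records: list[AnnotationRecord], require_containment: bool = True):
        self.records = list(records)
        self.require_containment = require_containment
        self._trees: dict[str, IntervalTree] = {}
        for rec in self.records:
            if rec.start > rec.end:
                raise ValueError(f"bad interval {rec}")
            tree = self._trees.setdefault(rec.chromosome, IntervalTree())
            tree.addi(rec.start, rec.end + 1, rec)

    @classmethod
    def from_gff(cls, path, **kwargs) -> "AnnotationDB":
        """Load from GFF3; the feature-type column carries the category,
        the source column the provenance tier ('rfam' or Genbank-like)."""
        type_map = {
            "rRNA": "rRNA", "scRNA": "scRNA", "snRNA": "snRNA",
            "snoRNA": "snoRNA", "tRNA": "tRNA", "miRNA": "miRNA",
            "repeat": "repeat", "repeat_region": "repeat",
            "exon": "exon", "intron": "intron",
        }
        records = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 9:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                chrom, source, ftype, start, end, _score, strand, _phase, attrs = cols[:9]
                if ftype not in type_map:
                    continue
                name = ""
                for kv in attrs.split(";"):
                    if kv.startswith(("ID=", "Name=")):
                        name = kv.split("=", 1)[1]
                        break
                tier = RFAM_TIER if source.lower() == "rfam" else GENBANK_TIER
                records.append(
                    AnnotationRecord(
                        category=type_map[ftype], chromosome=chrom,
                        start=int(start), end=int(end), strand=strand,
                        tier=tier, name=name,
                    )
                )
        return cls(records, **kwargs)

    def lookup(self, hit: AlignmentHit) -> list[AnnotationRecord]:
        """Annotation records overlapping (by default: containing) a hit."""
        tree = self._trees.get(hit.chromosome)
        if tree is None:
            return []
        found = [iv.data for iv in tree.overlap(hit.start, hit.end + 1)]
        if self.require_containment:
            found = [r for r in found if r.start <= hit.start and hit.end <= r.end]
        return sorted(found, key=lambda r: (r.start, r.end, r.category, r.tier))


def _candidate_key(rec: AnnotationRecord, hit: AlignmentHit) -> tuple:
    """Sort key implementing the priority chain; lower sorts first."""
    rank = _RANK[rec.category]
    if rec.category in NCRNA_CATEGORIES:
        rank += rec.tier  # Genbank tier 0 beats Rfam tier 1
    # Within exon/intron, sense beats antisense (deterministic tie-break).
    sense_rank = 0 if hit.strand == rec.strand else 1
    if rec.category not in ("exon", "intron"):
        sense_rank = 0
    return (rank, sense_rank, rec.category, hit.chromosome, hit.start, hit.strand)


def annotate_tag(
    tag: SmallRNATag, hits: list[AlignmentHit], db: AnnotationDB
) -> AnnotatedTag:
    """Assign the single highest-priority category across all hits."""
    best: tuple | None = None
    best_pair: tuple[AnnotationRecord, AlignmentHit] | None = None
    for hit in sorted(hits, key=lambda h: (h.chromosome, h.start, h.strand)):
        for rec in db.lookup(hit):
            key = _candidate_key(rec, hit)
            if best is None or key < best:
                best = key
                best_pair = (rec, hit)
    if best_pair is None:
        return AnnotatedTag(tag=tag, category="unann")
    rec, hit = best_pair
    category = rec.category
    if category in ("exon", "intron"):
        suffix = "sense" if hit.strand == rec.strand else "antisense"
        category = f"{category}_{suffix}"
    elif category == "repeat":
        # Table rows carry no repeat category; repeat-claimed tags are
        # reported as unannotated but keep the winning record.
        category = "unann"
    return AnnotatedTag(tag=tag, category=category, winning_hit=hit, record=rec)


def annotate_library(
    tags: list[SmallRNATag],
    hits_by_seq: dict[str, list[AlignmentHit]],
    db: AnnotationDB,
) -> list[AnnotatedTag]:
    return [annotate_tag(t, hits_by_seq.get(t.sequence, []), db) for t in tags]


def apply_sirna_category(
    annotated: list[AnnotatedTag], sirna_sequences: set[str]
) -> list[AnnotatedTag]:
    """Reassign duplex-member tags to the siRNA category.

    Only tags that were unannotated or exon/intron degradation fragments
    may be claimed; housekeeping ncRNA and miRNA assignments are stable.
    """
    claimable = {"unann", "exon_sense", "exon_antisense", "intron_sense", "intron_antisense"}
    for at in annotated:
        if at.tag.sequence in sirna_sequences and at.category in claimable:
            at.category = "siRNA"
    return annotated


@dataclass
class CategorySummary:
    """Unique- and total-count composition table for both libraries."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)


def category_summary(annotated: list[AnnotatedTag]) -> pd.DataFrame:
    """Composition table: unique and total counts with percentages.

    Unique counts tally distinct tags present (count > 0) in each library;
    total counts tally reads.  Rows partition the tag set, so each column
    sums to its 'Total' row exactly.
    """
    zero = {c: 0 for c in SUMMARY_CATEGORIES}
    uniq_p, uniq_m = dict(zero), dict(zero)
    tot_p, tot_m = dict(zero), dict(zero)
    for at in annotated:
        if at.tag.count_plus > 0:
            uniq_p[at.category] += 1
            tot_p[at.category] += at.tag.count_plus
        if at.tag.count_minus > 0:
            uniq_m[at.category] += 1
            tot_m[at.category] += at.tag.count_minus

    def col(counts: dict[str, int]) -> list[int]:
        return [sum(counts.values())] + [counts[c] for c in SUMMARY_CATEGORIES]

    rows = ["Total"] + [SUMMARY_LABELS[c] for c in SUMMARY_CATEGORIES]
    df = pd.DataFrame(
        {
            "unique_plus": col(uniq_p),
            "unique_minus": col(uniq_m),
            "total_plus": col(tot_p),
            "total_minus": col(tot_m),
        },
        index=pd.Index(rows, name="category"),
    )
    for c in df.columns:
        denom = df.loc["Total", c]
        df[f"{c}_pct"] = (df[c] / denom * 100).round(2) if denom else 0.0
    return df
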
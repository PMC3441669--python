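"""Raw-read cleaning: the seven elimination steps and their accounting.

Raw reads pass, in order, through: (1) low-quality filtering, (2) removal
of 5'-adapter contaminants, (3) removal of reads lacking the 3' adapter,
(4) removal of empty inserts, (5) removal of poly-A inserts, (6) removal
of inserts shorter than 18 nt.  Surviving inserts of 18-30 nt are the
clean reads, collapsed to unique tags with counts; inserts longer than
30 nt are set aside in their own counter.  Each read is attributed to the
first filter it fails, which makes the accounting identity

    high_quality = adaptor3_null + insert_null + adaptor5_contaminants
                   + smaller_than_18nt + polyA + longer_than_30nt
                   + clean_reads

hold exactly on every run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from ._seq import DNA_ALPHABET

#: Printed row labels of the accounting report.
REPORT_ROWS = [
    ("total_reads", "Total reads"),
    ("high_quality", "High quality"),
    ("adaptor3_null", "Adaptor3 null"),
    ("insert_null", "Insert null"),
    ("adaptor5_contaminants", "Adaptor5 contaminants"),
    ("smaller_than_18nt", "Smaller than 18 nt"),
    ("polyA", "PolyA"),
    ("longer_than_30nt", "Longer than 30 nt"),
    ("clean_reads", "Clean reads"),
]

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30


class ReadParseError(ValueError):
    """A raw read record could not be interpreted."""


@dataclass(frozen=True)
class QualityConfig:
    """Definition of the 'high quality' read set.

    A read is low quality when more than ``max_low_fraction`` of its base
    calls are below Phred ``min_phred`` (Sanger +33 encoding).  These
    defaults are an explicit assumption: the filter separating raw from
    high-quality reads is rarely specified by sequencing reports.
    """

    min_phred: int = 20
    max_low_fraction: float = 0.5
    phred_offset: int = 33


@dataclass
class CleaningReport:
    """Per-library accounting of the elimination steps."""

    total_reads: int = 0
    high_quality: int = 0
    adaptor3_null: int = 0
    insert_null: int = 0
    adaptor5_contaminants: int = 0
    smaller_than_18nt: int = 0
    polyA: int = 0
    longer_than_30nt: int = 0
    clean_reads: int = 0

    REMOVAL_FIELDS = (
        "adaptor3_null",
        "insert_null",
        "adaptor5_contaminants",
        "smaller_than_18nt",
        "polyA",
        "longer_than_30nt",
    )

    @classmethod
    def from_removals(
        cls,
        high_quality: int,
        adaptor3_null: int = 0,
        insert_null: int = 0,
        adaptor5_contaminants: int = 0,
        smaller_than_18nt: int = 0,
        polyA: int = 0,
        longer_than_30nt: int = 0,
        total_reads: int | None = None,
    ) -> "CleaningReport":
        """Build a report from removal counters; clean reads follow by
        conservation."""
        removed = (
            adaptor3_null
            + insert_null
            + adaptor5_contaminants
            + smaller_than_18nt
            + polyA
            + longer_than_30nt
        )
        return cls(
            total_reads=high_quality if total_reads is None else total_reads,
            high_quality=high_quality,
            adaptor3_null=adaptor3_null,
            insert_null=insert_null,
            adaptor5_contaminants=adaptor5_contaminants,
            smaller_than_18nt=smaller_than_18nt,
            polyA=polyA,
            longer_than_30nt=longer_than_30nt,
            clean_reads=high_quality - removed,
        )

    def validate(self) -> None:
        removed = sum(getattr(self, f) for f in self.REMOVAL_FIELDS)
        if self.high_quality != removed + self.clean_reads:
            raise AssertionError(
                f"conservation violated: high_quality={self.high_quality} "
                f"!= removed {removed} + clean {self.clean_reads}"
            )

    def percentage(self, fieldname: str) -> float:
        """Percentage of a counter relative to high-quality reads, 2 dp."""
        if self.high_quality == 0:
            return 0.0
        return round(getattr(self, fieldname) / self.high_quality * 100, 2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fieldname, label in REPORT_ROWS:
            if fieldname == "longer_than_30nt" and self.longer_than_30nt == 0:
                continue
            pct = "" if fieldname == "total_reads" else f"{self.percentage(fieldname):.2f}%"
            if fieldname == "high_quality":
                pct = "100%"
            rows.append({"row": label, "count": getattr(self, fieldname), "pct": pct})
        return pd.DataFrame(rows)


@dataclass
class SmallRNATag:
    """A unique 18-30 nt clean-read sequence with per-library counts."""

    sequence: str
    count_plus: int = 0
    count_minus: int = 0

    def __post_init__(self):
        if not MIN_TAG_LEN <= len(self.sequence) <= MAX_TAG_LEN:
            raise ValueError(f"tag length {len(self.sequence)} outside [18, 30]")
        if set(self.sequence) - DNA_ALPHABET:
            raise ValueError(f"tag has invalid symbols: {self.sequence!r}")
        if self.count_plus < 0 or self.count_minus < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.count_plus + self.count_minus


def _is_low_quality(qual: str, cfg: QualityConfig) -> bool:
    if not qual:
        return False
    cutoff = cfg.min_phred + cfg.phred_offset
    low = sum(1 for c in qual if ord(c) < cutoff)
    return low / len(qual) > cfg.max_low_fraction


def clean_reads(
    reads,
    adapter3: str,
    adapter5: str,
    quality_config: QualityConfig | None = None,
    adapter_min_match: int = 6,
    polya_fraction: float = 0.8,
) -> tuple[dict[str, int], CleaningReport]:
    """Run the elimination steps over one raw library.

    Parameters
    ----------
    reads : iterable of (sequence, quality) pairs
        Quality may be None (e.g. collapsed FASTA input), in which case
        every read counts as high quality.
    adapter3, adapter5 : str
        Adapter sequences; the 3' adapter is located by exact match of its
        first ``adapter_min_match`` bases, a 5' contaminant is a read
        beginning with the first ``adapter_min_match`` bases of the 5'
        adapter.

    Returns
    -------
    (tags, report)
        ``tags`` maps each unique clean insert to its read count.
    """
    if not adapter3 or not adapter5:
        raise ValueError("adapters must be non-empty")
    cfg = quality_config or QualityConfig()
    key3 = adapter3[:adapter_min_match].upper()
    key5 = adapter5[:adapter_min_match].upper()
    report = CleaningReport()
    tags: Counter[str] = Counter()

    for idx, rec in enumerate(reads):
        try:
            seq, qual = rec
            seq = seq.upper()
        except (TypeError, ValueError):
            raise ReadParseError(f"unparseable read record at index {idx}") from None
        if not seq or set(seq) - (DNA_ALPHABET | {"N"}):
            raise ReadParseError(
                f"read record {idx} is not a nucleotide sequence: {seq[:40]!r}"
            )
        report.total_reads += 1
        # (1) quality: N calls count as failed bases
        if "N" in seq or _is_low_quality(qual or "", cfg):
            continue
        report.high_quality += 1
        # (2) 5' adapter contaminant
        if seq.startswith(key5):
            report.adaptor5_contaminants += 1
            continue
        # (3) 3' adapter must be present
        cut = seq.find(key3)
        if cut < 0:
            report.adaptor3_null += 1
            continue
        insert = seq[:cut]
        # (4) empty insert
        if not insert:
            report.insert_null += 1
            continue
        # (5) poly-A insert
        if insert.count("A") / len(insert) >= polya_fraction:
            report.polyA += 1
            continue
        # (6) length bounds
        if len(insert) < MIN_TAG_LEN:
            report.smaller_than_18nt += 1
            continue
        if len(insert) > MAX_TAG_LEN:
            report.longer_than_30nt += 1
            continue
        report.clean_reads += 1
        tags[insert] += 1

    report.validate()
    return dict(tags), report


def merge_libraries(
    tags_plus: dict[str, int], tags_minus: dict[str, int]
) -> list[SmallRNATag]:
    """Combine the per-library tag counters into SmallRNATag records,
    sorted by descending combined count then sequence."""
    seqs = set(tags_plus) | set(tags_minus)
    merged = [
        SmallRNATag(s, tags_plus.get(s, 0), tags_minus.get(s, 0)) for s in seqs
    ]
    merged.sort(key=lambda t: (-t.total, t.sequence))
    return merged


def length_histogram(tags: dict[str, int]) -> pd.DataFrame:
    """Unique- and total-count histograms over tag lengths 18..30."""
    idx = range(MIN_TAG_LEN, MAX_TAG_LEN + 1)
    unique = {n: 0 for n in idx}
    total = {n: 0 for n in idx}
    for seq, count in tags.items():
        unique[len(seq)] += 1
        total[len(seq)] += count
    return pd.DataFrame({"length": list(idx),
                         "unique": [unique[n] for n in idx],
                         "total": [total[n] for n in idx]}).set_index("length")


@dataclass
class OverlapSummary:
    """Common vs library-specific tag accounting (unique and total)."""

    unique_common: int
    unique_plus_specific: int
    unique_minus_specific: int
    total_common: int
    total_plus_specific: int
    total_minus_specific: int

    def unique_percentages(self) -> dict[str, float]:
        denom = self.unique_common + self.unique_plus_specific + self.unique_minus_specific
        if denom == 0:
            return {"common": 0.0, "plus_specific": 0.0, "minus_specific": 0.0}
        return {
            "common": round(self.unique_common / denom * 100, 2),
            "plus_specific": round(self.unique_plus_specific / denom * 100, 2),
            "minus_specific": round(self.unique_minus_specific / denom * 100, 2),
        }

    def total_percentages(self) -> dict[str, float]:
        denom = self.total_common + self.total_plus_specific + self.total_minus_specific
        if denom == 0:
            return {"common": 0.0, "plus_specific": 0.0, "minus_specific": 0.0}
        return {
            "common": round(self.total_common / denom * 100, 2),
            "plus_specific": round(self.total_plus_specific / denom * 100, 2),
            "minus_specific": round(self.total_minus_specific / denom * 100, 2),
        }


def library_overlap(
    tags_plus: dict[str, int], tags_minus: dict[str, int]
) -> OverlapSummary:
    """Common and library-specific tags between the two libraries.

    Unique counts are over distinct sequences (denominator: the union);
    total counts weight each sequence by its read counts summed over both
    libraries.
    """
    shared = set(tags_plus) & set(tags_minus)
    only_plus = set(tags_plus) - shared
    only_minus = set(tags_minus) - shared
    return OverlapSummary(
        unique_common=len(shared),
        unique_plus_specific=len(only_plus),
        unique_minus_specific=len(only_minus),
        total_common=sum(tags_plus[s] + tags_minus[s] for s in shared),
        total_plus_specific=sum(tags_plus[s] for s in only_plus),
        total_minus_specific=sum(tags_minus[s] for s in only_minus),
    )
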
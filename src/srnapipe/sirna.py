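"""siRNA duplex detection among genome-mapped tags.

An siRNA duplex is a pair of 22-24 nt strands, each 2 nt longer than the
other at its 3' end.  For perfectly genome-matched tags this geometry is
purely positional: a plus-strand tag spanning [a, b] and a minus-strand
tag spanning [a-2, b-2] form a duplex with a 2-nt 3' overhang on both
strands (which forces equal strand lengths).  The search therefore runs
in genome-coordinate space over the mapping results.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cleaning import SmallRNATag
from .mapping import AlignmentHit

MIN_SIRNA_LEN = 22
MAX_SIRNA_LEN = 24
OVERHANG = 2


@dataclass(frozen=True)
class SirnaPair:
    """A duplex: plus-strand tag at [a, b], minus-strand tag at [a-2, b-2]."""

    chromosome: str
    plus_start: int
    plus_end: int
    minus_start: int
    minus_end: int
    plus_tag: str
    minus_tag: str
    overhang: int = OVERHANG

    def locus(self) -> tuple[str, int, int]:
        return (self.chromosome, self.minus_start, self.plus_end)


def find_duplexes(
    hits_by_seq: dict[str, list[AlignmentHit]],
    tags: dict[str, SmallRNATag] | None = None,
) -> list[SirnaPair]:
    """Every duplex pair among the mapped tags, deduplicated by locus.

    Parameters
    ----------
    hits_by_seq : mapping from tag sequence to its alignment hits.
    tags : optional mapping to tag records (unused for geometry; callers
        typically join counts afterwards).
    """
    minus_lookup: dict[tuple[str, int, int], str] = {}
    for seq, hits in hits_by_seq.items():
        if not MIN_SIRNA_LEN <= len(seq) <= MAX_SIRNA_LEN:
            continue
        for h in hits:
            if h.strand == "-":
                minus_lookup[(h.chromosome, h.start, h.end)] = seq

    pairs: dict[tuple[str, int, int], SirnaPair] = {}
    for seq, hits in sorted(hits_by_seq.items()):
        if not MIN_SIRNA_LEN <= len(seq) <= MAX_SIRNA_LEN:
            continue
        for h in hits:
            if h.strand != "+":
                continue
            key = (h.chromosome, h.start - OVERHANG, h.end - OVERHANG)
            partner = minus_lookup.get(key)
            if partner is None:
                continue
            pair = SirnaPair(
                chromosome=h.chromosome,
                plus_start=h.start,
                plus_end=h.end,
                minus_start=h.start - OVERHANG,
                minus_end=h.end - OVERHANG,
                plus_tag=seq,
                minus_tag=partner,
            )
            pairs.setdefault(pair.locus(), pair)
    return [pairs[k] for k in sorted(pairs)]


def duplex_sequences(pairs: list[SirnaPair]) -> set[str]:
    """All tag sequences participating in at least one duplex."""
    out: set[str] = set()
    for p in pairs:
        out.add(p.plus_tag)
        out.add(p.minus_tag)
    return out


def brute_force_duplexes(
    hits_by_seq: dict[str, list[AlignmentHit]]
) -> list[SirnaPair]:
    """All-pairs oracle: check the offset identity over every hit pair."""
    flat = [
        (seq, h)
        for seq, hits in hits_by_seq.items()
        if MIN_SIRNA_LEN <= len(seq) <= MAX_SIRNA_LEN
        for h in hits
    ]
    pairs: dict[tuple[str, int, int], SirnaPair] = {}
    for seq_a, ha in flat:
        for seq_b, hb in flat:
            if (
                ha.strand == "+"
                and hb.strand == "-"
                and ha.chromosome == hb.chromosome
                and hb.start == ha.start - OVERHANG
                and hb.end == ha.end - OVERHANG
            ):
                pair = SirnaPair(
                    ha.chromosome, ha.start, ha.end, hb.start, hb.end, seq_a, seq_b
                )
                pairs.setdefault(pair.locus(), pair)
    return [pairs[k] for k in sorted(pairs)]
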
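"""Novel miRNA prediction from hairpin precursors, and known-miRNA counting.

For each unannotated mapped tag the predictor excises candidate precursor
windows around every genomic hit (tag as 5' arm and as 3' arm), folds
them, locates the miRNA* arm from the base pairs of the mature region
under the canonical 2-nt 3'-overhang duplex convention, and accepts a
candidate when all structural criteria hold:

* precursor MFE <= -18 kcal/mol,
* >= 16 paired bases between miRNA and miRNA*,
* largest bulge in the duplex <= 4,
* duplex asymmetry (|unpaired on one side - unpaired on the other|) <= 4,
* mature and star on opposite arms of one stem-loop,
* <= 300 nt between miRNA and miRNA*.

Thresholds are inclusive.  Tags hitting more than 20 genomic loci are
excluded.  Among a tag's accepted candidates the one with the lowest MFE
wins (ties: shorter precursor, then leftmost location).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from ._seq import revcomp, to_dna, to_rna
from .folding import FoldResult, fold, structure_energy
from .mapping import AlignmentHit


@dataclass(frozen=True)
class MireapParams:
    """Structural thresholds for hairpin-based miRNA prediction."""

    min_mirna_len: int = 18
    max_mirna_len: int = 25
    min_star_len: int = 20  # recorded star-length range; not an acceptance
    max_star_len: int = 23  # predicate (see docs/methods.md)
    max_copies: int = 20
    max_precursor_mfe: float = -18.0  # kcal/mol
    max_space: int = 300  # nt between miRNA and miRNA*
    min_duplex_pairs: int = 16
    max_bulge: int = 4
    max_asymmetry: int = 4
    flank: int = 20  # nt of flanking sequence kept around the duplex

    def __post_init__(self):
        if self.max_precursor_mfe >= 0:
            raise ValueError("max_precursor_mfe must be negative")


@dataclass
class HairpinCandidate:
    """Decision record for one candidate precursor."""

    chromosome: str
    start: int  # precursor span, 1-based inclusive, plus-strand space
    end: int
    strand: str
    precursor: str  # RNA alphabet, 5'->3' on the annotated strand
    fold: FoldResult
    mature_span: tuple[int, int]  # 0-based half-open within precursor
    star_span: tuple[int, int] | None
    duplex_pairs: int = 0
    max_bulge_found: int = 0
    asymmetry_found: int = 0
    copies: int = 1
    count_plus: int = 0
    count_minus: int = 0
    accepted: bool = False
    reasons: list[str] = field(default_factory=list)
    name: str = ""

    @property
    def length(self) -> int:
        return len(self.precursor)

    @property
    def mature_seq(self) -> str:
        return self.precursor[self.mature_span[0] : self.mature_span[1]]

    def region_string(self) -> str:
        return f"{self.chromosome}:{self.start}:{self.end}:{self.strand}"


def candidate_windows(
    hit: AlignmentHit, params: MireapParams, chrom_length: int
) -> list[tuple[int, int]]:
    """The two precursor windows around a hit (1-based inclusive, clipped).

    Tag as 5' arm: [start - flank, end + max_space + flank];
    tag as 3' arm: [start - max_space - flank, end + flank].
    """
    w5 = (hit.start - params.flank, hit.end + params.max_space + params.flank)
    w3 = (hit.start - params.max_space - params.flank, hit.end + params.flank)
    out = []
    for lo, hi in (w5, w3):
        lo = max(1, lo)
        hi = min(chrom_length, hi)
        if hi - lo + 1 >= 2 * params.min_mirna_len:
            out.append((lo, hi))
    # Clipping can collapse both windows onto the same span.
    deduped: list[tuple[int, int]] = []
    for w in out:
        if w not in deduped:
            deduped.append(w)
    return deduped


#: miRNA-miRNA* spacings scanned within the maximal windows: a long fold
#: over the full window is degenerate in GC-rich sequence, so candidate
#: precursors are also examined at tighter excisions around the tag.
SCAN_SPACES = (40, 80, 160, 300)


def _scan_windows(
    hit: AlignmentHit, params: MireapParams, chrom_length: int
) -> list[tuple[int, int]]:
    """Candidate precursor windows at several spacings, both arm roles.

    Every window is contained in the maximal spans of
    :func:`candidate_windows`; deduplicated, ordered small to large.
    """
    spaces = sorted({min(s, params.max_space) for s in SCAN_SPACES})
    out: list[tuple[int, int]] = []
    for space in spaces:
        for lo, hi in (
            (hit.start - params.flank, hit.end + space + params.flank),
            (hit.start - space - params.flank, hit.end + params.flank),
        ):
            lo = max(1, lo)
            hi = min(chrom_length, hi)
            w = (lo, hi)
            if hi - lo + 1 >= 2 * params.min_mirna_len and w not in out:
                out.append(w)
    return out


def _pair_partners(fr: FoldResult) -> dict[int, int]:
    partners: dict[int, int] = {}
    for i, j in fr.pairs():
        partners[i] = j
        partners[j] = i
    return partners


def _duplex_metrics(
    partners: dict[int, int], mature_lo: int, mature_hi: int, star_lo: int, star_hi: int
) -> tuple[int, int, int]:
    """(duplex_pairs, max_bulge, asymmetry) over the mature/star duplex.

    Bulges are runs of unpaired bases strictly inside the paired region of
    either strand; asymmetry is the absolute difference of the two interior
    unpaired totals.
    """
    paired_m = [
        i for i in range(mature_lo, mature_hi)
        if i in partners and star_lo <= partners[i] < star_hi
    ]
    if not paired_m:
        return 0, 0, 0
    n_pairs = len(paired_m)

    def interior_runs(lo: int, hi: int, idxs: list[int]) -> tuple[int, int]:
        first, last = min(idxs), max(idxs)
        longest = run = 0
        unpaired = 0
        for i in range(first, last + 1):
            if i in idxs_set:
                run = 0
            else:
                run += 1
                unpaired += 1
                longest = max(longest, run)
        return longest, unpaired

    idxs_set = set(paired_m)
    bulge_m, un_m = interior_runs(mature_lo, mature_hi, paired_m)
    paired_s = sorted(partners[i] for i in paired_m)
    idxs_set = set(paired_s)
    bulge_s, un_s = interior_runs(star_lo, star_hi, paired_s)
    return n_pairs, max(bulge_m, bulge_s), abs(un_m - un_s)


def _locate_star(fr: FoldResult, m_lo: int, m_hi: int, max_bulge: int = 4):
    """Find the star arm pairing with mature [m_lo, m_hi) in a fold.

    Returns (star_lo, star_hi, space, (duplex_pairs, bulge, asymmetry)),
    or None when the mature has no partners outside itself.  The star arm
    lies on the side holding the majority of the mature's partners; on
    that side, partner positions separated from the bulk by more than
    ``max_bulge`` unpaired bases (e.g. a stray pair into the hairpin
    loop) are discarded and the largest run kept.  Stray pairs never
    count as duplex pairs.  The star's 3' end carries the canonical 2-nt
    overhang.
    """
    n = len(fr.sequence)
    partners = _pair_partners(fr)
    p_list = [partners[i] for i in range(m_lo, m_hi) if i in partners]
    outside = [p for p in p_list if p < m_lo or p >= m_hi]
    if not outside:
        return None
    up = [p for p in outside if p >= m_hi]
    down = [p for p in outside if p < m_lo]
    side_up = len(up) > len(down)
    chosen = sorted(up if side_up else down)
    clusters: list[list[int]] = [[chosen[0]]]
    for p in chosen[1:]:
        if p - clusters[-1][-1] - 1 > max_bulge:
            clusters.append([p])
        else:
            clusters[-1].append(p)
    block = max(clusters, key=len)
    star_lo = max(0, block[0])
    star_hi = min(n, block[-1] + 2 + 1)  # exclusive
    space = star_lo - m_hi if side_up else m_lo - star_hi
    metrics = _duplex_metrics(partners, m_lo, m_hi, star_lo, star_hi)
    return star_lo, star_hi, space, metrics


def _restrict_fold(fr: FoldResult, lo: int, hi: int) -> FoldResult:
    """The structure induced on [lo, hi) by a larger fold.

    Pairs crossing the excision boundary are opened; the energy is that
    of the retained pairs, so the returned FoldResult is internally
    consistent (structure and energy describe the same object).
    """
    seq = fr.sequence[lo:hi]
    chars = ["."] * (hi - lo)
    for i, j in fr.pairs():
        if lo <= i and j < hi:
            chars[i - lo] = "("
            chars[j - lo] = ")"
    structure = "".join(chars)
    return FoldResult(seq, structure, structure_energy(seq, structure))


def evaluate_candidate(
    window_fold: FoldResult,
    mature_span: tuple[int, int],
    params: MireapParams,
    location: tuple[str, int, int, str] | None = None,
    refold=None,
) -> HairpinCandidate:
    """Locate the star arm in a folded window and apply the criteria.

    ``mature_span`` is 0-based half-open within the folded sequence.  The
    precursor reported is the duplex extent plus ``params.flank`` nt of
    flanking sequence on each side; its structure is the window structure
    restricted to that span and its energy is the energy of exactly that
    structure, so every reported metric describes the reported fold.
    ``refold`` is accepted for engine plumbing but unused by the default
    restriction-based excision.
    """
    chrom, w_start, w_end, strand = location or ("?", 1, len(window_fold.sequence), "+")
    m_lo, m_hi = mature_span
    n = len(window_fold.sequence)
    if not (0 <= m_lo < m_hi <= n):
        raise ValueError("mature interval not inside the folded window")

    def rejected(reasons: list[str], star=None, metrics=(0, 0, 0)) -> HairpinCandidate:
        dp, bulge, asym = metrics
        return HairpinCandidate(
            chromosome=chrom, start=w_start, end=w_end, strand=strand,
            precursor=to_rna(window_fold.sequence), fold=window_fold,
            mature_span=(m_lo, m_hi), star_span=star,
            duplex_pairs=dp, max_bulge_found=bulge, asymmetry_found=asym,
            accepted=False, reasons=reasons,
        )

    located = _locate_star(window_fold, m_lo, m_hi, params.max_bulge)
    if located is None:
        # Mature sits in a loop or pairs only with itself: no star arm.
        return rejected(["no_star"])
    star_lo, star_hi, space, metrics = located
    duplex_pairs, bulge, asym = metrics

    reasons = []
    if space > params.max_space:
        reasons.append("space")
    if duplex_pairs < params.min_duplex_pairs:
        reasons.append("pairs")
    if bulge > params.max_bulge:
        reasons.append("bulge")
    if asym > params.max_asymmetry:
        reasons.append("asymmetry")

    # Excise the precursor: duplex extent plus flanks.
    lo = max(0, min(m_lo, star_lo) - params.flank)
    hi = min(n, max(m_hi, star_hi) + params.flank)
    pre_fold = _restrict_fold(window_fold, lo, hi)
    if pre_fold.mfe > params.max_precursor_mfe:
        reasons.append("mfe")

    if strand == "+":
        g_start, g_end = w_start + lo, w_start + hi - 1
    else:
        # window_fold.sequence reads 5'->3' on the minus strand; convert
        # offsets back to plus-strand coordinates.
        g_start, g_end = w_end - (hi - 1), w_end - lo
    cand = HairpinCandidate(
        chromosome=chrom, start=g_start, end=g_end, strand=strand,
        precursor=to_rna(pre_fold.sequence), fold=pre_fold,
        mature_span=(m_lo - lo, m_hi - lo),
        star_span=(star_lo - lo, star_hi - lo),
        duplex_pairs=duplex_pairs, max_bulge_found=bulge,
        asymmetry_found=asym, accepted=not reasons, reasons=reasons,
    )
    return cand


def predict_novel(
    tags: dict[str, tuple[int, int]],
    hits_by_seq: dict[str, list[AlignmentHit]],
    chromosomes: dict[str, str],
    params: MireapParams | None = None,
    fold_engine=None,
) -> list[HairpinCandidate]:
    """Predict hairpin miRNAs from unannotated tags.

    Parameters
    ----------
    tags : mapping from tag sequence to (count_plus, count_minus).
    hits_by_seq : genomic hits per tag (only mapped tags are considered).
    chromosomes : the genome.
    fold_engine : optional replacement folding engine (see folding.fold).

    Returns
    -------
    Accepted candidates, one per tag at most (best across windows and
    hits by lowest MFE, then shortest precursor, then location), sorted
    by genomic location and named n001, n002, ...
    """
    params = params or MireapParams()

    def do_fold(seq: str) -> FoldResult:
        return fold(seq, engine=fold_engine)

    accepted: list[HairpinCandidate] = []
    for seq in sorted(tags):
        hits = hits_by_seq.get(seq, [])
        if not hits or len(hits) > params.max_copies:
            continue
        if not params.min_mirna_len <= len(seq) <= params.max_mirna_len:
            continue
        best: HairpinCandidate | None = None
        for hit in hits:
            chrom_seq = chromosomes[hit.chromosome]
            for w_lo, w_hi in _scan_windows(hit, params, len(chrom_seq)):
                window = chrom_seq[w_lo - 1 : w_hi]
                if hit.strand == "+":
                    m_lo = hit.start - w_lo
                else:
                    window = revcomp(window)
                    m_lo = w_hi - hit.end
                m_span = (m_lo, m_lo + len(seq))
                cand = evaluate_candidate(
                    do_fold(window), m_span, params,
                    location=(hit.chromosome, w_lo, w_hi, hit.strand),
                    refold=do_fold,
                )
                if not cand.accepted:
                    continue
                cand.copies = len(hits)
                cand.count_plus, cand.count_minus = tags[seq]
                key = (cand.fold.mfe, cand.length, cand.chromosome, cand.start)
                if best is None or key < (
                    best.fold.mfe, best.length, best.chromosome, best.start
                ):
                    best = cand
        if best is not None:
            accepted.append(best)

    accepted.sort(key=lambda c: (c.chromosome, c.start, c.end, c.strand))
    return [replace(c, name=f"n{i + 1:03d}") for i, c in enumerate(accepted)]


def candidates_table(candidates: list[HairpinCandidate]) -> pd.DataFrame:
    """Report table: name, mature sequence (RNA), length, location, MFE,
    per-library read counts, structure."""
    rows = [
        {
            "name": c.name,
            "sequence": to_rna(c.mature_seq),
            "length": c.mature_span[1] - c.mature_span[0],
            "location": c.region_string(),
            "mfe": round(c.fold.mfe, 1),
            "reads_plus": c.count_plus,
            "reads_minus": c.count_minus,
            "structure": c.fold.structure,
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=["name", "sequence", "length", "location", "mfe",
                 "reads_plus", "reads_minus", "structure"],
    )


def quantify_known(
    tags: dict[str, tuple[int, int]],
    mature: dict[str, str],
    precursors: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-miRNA read counts per library.

    A tag counts toward a known miRNA when it equals the mature sequence
    exactly or lies exactly within the precursor.  Tags matching several
    miRNAs count for each and are flagged multi-assigned.
    """
    precursors = precursors or {}
    names = sorted(set(mature) | set(precursors))
    counts = {n: [0, 0, False] for n in names}  # plus, minus, multi
    for seq, (cp, cm) in tags.items():
        dna = to_dna(seq)
        matched = [
            n for n in names
            if dna == to_dna(mature.get(n, ""))
            or (n in precursors and dna in to_dna(precursors[n]))
        ]
        for n in matched:
            counts[n][0] += cp
            counts[n][1] += cm
            if len(matched) > 1:
                counts[n][2] = True
    return pd.DataFrame(
        {
            "mirna": names,
            "count_plus": [counts[n][0] for n in names],
            "count_minus": [counts[n][1] for n in names],
            "multi_assigned": [counts[n][2] for n in names],
        }
    ).set_index("mirna")
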
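"""Synthetic two-condition small-RNA experiment with planted ground truth.

Builds a toy genome carrying planted miRNA hairpins, siRNA duplex loci,
housekeeping ncRNA genes (rRNA/tRNA/snRNA/snoRNA/scRNA), exons, introns and
repeats, then simulates raw sulfur-replete (+S) and sulfur-deprived (-S)
read libraries of 18-30 nt inserts with 3' adapters plus the contaminant
classes the cleaning stage must remove (missing 3' adapter, empty insert,
5'-adapter-prefixed reads, sub-18-nt inserts, poly-A inserts, low-quality
reads).

Everything is seeded: identical specs reproduce byte-identical files.
Coordinates are 1-based inclusive throughout; BED export converts to
0-based half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp, validate_nucleotides

FEATURE_KINDS = (
    "mirna_hairpin",
    "sirna_locus",
    "rrna",
    "trna",
    "snrna",
    "snorna",
    "scrna",
    "exon",
    "intron",
    "repeat",
)

#: GFF3 feature-type / annotation-category name per planted kind
KIND_TO_CATEGORY = {
    "rrna": "rRNA",
    "trna": "tRNA",
    "snrna": "snRNA",
    "snorna": "snoRNA",
    "scrna": "scRNA",
    "exon": "exon",
    "intron": "intron",
    "repeat": "repeat",
    "mirna_hairpin": "miRNA",
    "sirna_locus": "siRNA",
}

CONTAMINANT_CLASSES = (
    "low_quality",
    "adaptor3_null",
    "insert_null",
    "adaptor5_contaminants",
    "smaller_than_18nt",
    "polyA",
)

# Solexa-era small-RNA adapters used as simulation defaults.
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


@dataclass(frozen=True)
class GenomeSpec:
    """Shape of the synthetic genome background."""

    chromosome_lengths: tuple[int, ...] = (100_000,)
    gc_fraction: float = 0.64  # C. reinhardtii-like GC-rich background
    seed: int = 0

    def __post_init__(self):
        if any(n < 1000 for n in self.chromosome_lengths):
            raise ValueError("every chromosome length must be >= 1000")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")


@dataclass
class PlantedFeature:
    """One ground-truthed genomic feature.

    ``seq`` is the feature sequence read on ``strand``; when None it is
    generated from the background model at planting time.  ``tag_seqs``
    are the insert sequences this feature emits as reads.
    """

    kind: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    name: str = ""
    seq: str | None = None
    mature_seq: str | None = None
    star_seq: str | None = None
    known: bool = False  # known miRNA (annotated) vs novel (to be predicted)
    base_tpm_plus: float = 0.0
    base_tpm_minus: float = 0.0
    mature_offset: int = 0  # 0-based offset of mature within seq (miRNA only)
    tag_seqs: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.start > self.end or self.start < 1:
            raise ValueError(f"bad interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.base_tpm_plus < 0 or self.base_tpm_minus < 0:
            raise ValueError("abundances must be >= 0")
        if self.kind == "mirna_hairpin":
            if self.mature_seq is None:
                raise ValueError("mirna_hairpin requires mature_seq")
            if not 18 <= len(self.mature_seq) <= 25:
                raise ValueError("mature length must be in [18, 25]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def region_string(self) -> str:
        return f"{self.chromosome}:{self.start}:{self.end}:{self.strand}"


@dataclass(frozen=True)
class PlantedHairpin:
    """Constructed miRNA precursor with its planted duplex geometry.

    Spans are 0-based half-open offsets within ``precursor``.
    """

    precursor: str
    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    duplex_pairs: int


def _safe_base(avoid: str) -> str:
    """A base that cannot Watson-Crick or G:U pair with any base in `avoid`."""
    pair_partners = {"A": "T", "C": "G", "G": "CT", "T": "AG"}
    for cand in "ACTG":
        if not any(cand in pair_partners[b] for b in set(avoid) & set("ACGT")):
            return cand
    return "A"


def plant_hairpin(mature_seq: str, loop_len: int = 8, overhang: int = 2) -> PlantedHairpin:
    """Construct a stem-loop precursor around a mature miRNA.

    The precursor is ``mature + loop + star`` where the star arm is the
    reverse complement of the mature offset by ``overhang``, so the
    mature/star duplex carries ``len(mature) - overhang`` Watson-Crick
    pairs and each strand ends in an ``overhang``-nt 3' overhang — the
    geometry left by Dicer processing.  Loop and star-tail bases are
    chosen deterministically so they cannot pair with the adjacent
    mature bases.
    """
    mature = validate_nucleotides(mature_seq, "mature_seq")
    if not 18 <= len(mature) <= 25:
        raise ValueError(f"mature length must be in [18, 25], got {len(mature)}")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if overhang < 0 or overhang >= len(mature):
        raise ValueError("overhang out of range")
    n = len(mature)
    loop = _safe_base(mature[n - overhang :] + mature[: overhang]) * loop_len
    star_paired = revcomp(mature[: n - overhang])
    tail = _safe_base(mature[:overhang] + loop) * overhang
    star = star_paired + tail
    precursor = mature + loop + star
    return PlantedHairpin(
        precursor=precursor,
        mature_span=(0, n),
        star_span=(n + loop_len, n + loop_len + len(star)),
        duplex_pairs=n - overhang,
    )


def random_mature(rng: np.random.Generator, length: int = 21, gc: float = 0.55) -> str:
    """Random mature miRNA sequence with approximately the given GC content.

    Sequences that collide with the default adapter keys or look like
    poly-A inserts are rejected and redrawn, so planted tags always
    survive adapter trimming intact.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
        if DEFAULT_ADAPTER3[:6] in seq or seq.startswith(DEFAULT_ADAPTER5[:6]):
            continue
        if seq.count("A") / length >= 0.8:
            continue
        return seq


def _tag_ok(tag: str) -> bool:
    """Whether a planted tag survives default adapter trimming intact."""
    return (
        DEFAULT_ADAPTER3[:6] not in tag
        and not tag.startswith(DEFAULT_ADAPTER5[:6])
        and tag.count("A") / len(tag) < 0.8
    )


# ---------------------------------------------------------------------------
# Feature builders
# ---------------------------------------------------------------------------


def hairpin_feature(
    chromosome: str,
    start: int,
    mature_seq: str,
    strand: str = "+",
    name: str = "",
    loop_len: int = 8,
    known: bool = False,
    base_tpm_plus: float = 0.0,
    base_tpm_minus: float = 0.0,
) -> PlantedFeature:
    """A miRNA hairpin feature whose span is derived from the construction."""
    hp = plant_hairpin(mature_seq, loop_len=loop_len)
    return PlantedFeature(
        kind="mirna_hairpin",
        chromosome=chromosome,
        start=start,
        end=start + len(hp.precursor) - 1,
        strand=strand,
        name=name,
        seq=hp.precursor,
        mature_seq=validate_nucleotides(mature_seq),
        star_seq=hp.precursor[hp.star_span[0] : hp.star_span[1]],
        known=known,
        base_tpm_plus=base_tpm_plus,
        base_tpm_minus=base_tpm_minus,
        mature_offset=0,
        tag_seqs=[validate_nucleotides(mature_seq)],
    )


def sirna_feature(
    chromosome: str,
    start: int,
    guide_seq: str,
    name: str = "",
    base_tpm_plus: float = 0.0,
    base_tpm_minus: float = 0.0,
) -> PlantedFeature:
    """An siRNA duplex locus.

    The locus spans ``len(guide) + 2`` bases; the plus-strand tag occupies
    the last ``len(guide)`` bases and the minus-strand tag the first, so
    both carry the canonical 2-nt 3' overhang.
    """
    guide = validate_nucleotides(guide_seq, "guide_seq")
    if not 22 <= len(guide) <= 24:
        raise ValueError("siRNA strand length must be in [22, 24]")
    locus_len = len(guide) + 2
    return PlantedFeature(
        kind="sirna_locus",
        chromosome=chromosome,
        start=start,
        end=start + locus_len - 1,
        strand="+",
        name=name,
        seq=None,  # filled at planting: random locus sequence, tags derived
        mature_seq=None,
        base_tpm_plus=base_tpm_plus,
        base_tpm_minus=base_tpm_minus,
        tag_seqs=[guide],  # completed in make_genome with the minus tag
    )


def simple_feature(
    kind: str,
    chromosome: str,
    start: int,
    end: int,
    strand: str = "+",
    name: str = "",
    seq: str | None = None,
    base_tpm_plus: float = 0.0,
    base_tpm_minus: float = 0.0,
) -> PlantedFeature:
    return PlantedFeature(
        kind=kind,
        chromosome=chromosome,
        start=start,
        end=end,
        strand=strand,
        name=name,
        seq=seq,
        base_tpm_plus=base_tpm_plus,
        base_tpm_minus=base_tpm_minus,
    )


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenome:
    """Assembled toy genome with its planted ground truth."""

    chromosomes: dict[str, str]
    features: list[PlantedFeature]
    spec: GenomeSpec

    def extract(self, chromosome: str, start: int, end: int, strand: str = "+") -> str:
        """1-based inclusive, strand-aware subsequence."""
        seq = self.chromosomes[chromosome][start - 1 : end]
        return revcomp(seq) if strand == "-" else seq

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for f in self.features:
            rows.append(
                {
                    "name": f.name,
                    "kind": f.kind,
                    "chrom": f.chromosome,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "seq": f.seq,
                    "tag_seqs": ",".join(f.tag_seqs),
                    "known": int(f.known),
                    "base_tpm_plus": f.base_tpm_plus,
                    "base_tpm_minus": f.base_tpm_minus,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "name",
                "kind",
                "chrom",
                "start",
                "end",
                "strand",
                "seq",
                "tag_seqs",
                "known",
                "base_tpm_plus",
                "base_tpm_minus",
            ],
        )


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def make_genome(spec: GenomeSpec, features: list[PlantedFeature]) -> SyntheticGenome:
    """Build the genome, plant every feature, and fill in derived sequences.

    Features must fit their chromosome and must not overlap one another.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"chromosome_{i + 1}" for i in range(len(spec.chromosome_lengths))]
    lengths = dict(zip(names, spec.chromosome_lengths))
    arrays = {
        name: _random_genome(rng, n, spec.gc_fraction)
        for name, n in zip(names, spec.chromosome_lengths)
    }

    by_chrom: dict[str, list[PlantedFeature]] = {}
    for f in features:
        if f.chromosome not in arrays:
            raise ValueError(f"unknown chromosome {f.chromosome!r}")
        if f.end > lengths[f.chromosome]:
            raise ValueError(f"feature {f.name or f.kind} extends beyond chromosome end")
        by_chrom.setdefault(f.chromosome, []).append(f)
    for chrom, fs in by_chrom.items():
        fs.sort(key=lambda f: f.start)
        for a, b in zip(fs, fs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping features on {chrom}: "
                    f"{a.name or a.kind}@{a.start}..{a.end} and "
                    f"{b.name or b.kind}@{b.start}..{b.end}"
                )

    features = [dataclasses.replace(f, tag_seqs=list(f.tag_seqs)) for f in features]
    for f in features:
        if f.kind == "sirna_locus":
            # Plant the plus-strand guide in the last L bases of the locus;
            # the minus-strand tag is the revcomp of the first L bases.
            # Only the two 5'-terminal locus bases are free, so try every
            # dinucleotide for a minus tag that survives adapter trimming.
            guide = f.tag_seqs[0]
            locus = _random_genome(rng, f.length, spec.gc_fraction)
            locus[2:] = np.frombuffer(guide.encode(), dtype=np.uint8)
            for dinuc in ("".join((a, b)) for a in "CGTA" for b in "CGTA"):
                locus[:2] = np.frombuffer(dinuc.encode(), dtype=np.uint8)
                minus_tag = revcomp(locus[: len(guide)].tobytes().decode())
                if _tag_ok(minus_tag):
                    break
            else:
                raise ValueError(
                    f"siRNA guide {guide!r} cannot yield an adapter-safe minus tag"
                )
            f.seq = locus.tobytes().decode()
            f.tag_seqs = [guide, minus_tag]
        elif f.seq is None:
            f.seq = _random_genome(rng, f.length, spec.gc_fraction).tobytes().decode()
        if f.kind not in ("mirna_hairpin", "sirna_locus") and not f.tag_seqs:
            # Housekeeping/mRNA features emit one ~21-nt fragment, the first
            # window from the centre that survives adapter trimming intact.
            tag_len = min(21, f.length)
            tag = None
            for off in range(max(0, (f.length - tag_len) // 2), f.length - tag_len + 1):
                cand = f.seq[off : off + tag_len]
                if _tag_ok(cand):
                    tag = cand
                    break
            f.tag_seqs = [tag or f.seq[:tag_len]]
        planted = f.seq if f.strand == "+" else revcomp(f.seq)
        arrays[f.chromosome][f.start - 1 : f.end] = np.frombuffer(
            planted.encode(), dtype=np.uint8
        )

    chromosomes = {name: arr.tobytes().decode() for name, arr in arrays.items()}
    return SyntheticGenome(chromosomes=chromosomes, features=features, spec=spec)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadSimSpec:
    """Parameters of the two-library read simulation."""

    total_reads_plus: int = 50_000
    total_reads_minus: int = 50_000
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    read_length: int = 36
    contaminant_fractions: dict[str, float] = field(default_factory=dict)
    #: distinct genomic loci emitting background degradation fragments;
    #: real libraries show a bounded set of dominant degradation sites
    n_background_loci: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.total_reads_plus < 0 or self.total_reads_minus < 0:
            raise ValueError("read totals must be >= 0")
        if not self.adapter3 or not self.adapter5:
            raise ValueError("adapters must be non-empty")
        bad = set(self.contaminant_fractions) - set(CONTAMINANT_CLASSES)
        if bad:
            raise ValueError(f"unknown contaminant classes: {sorted(bad)}")
        fracs = list(self.contaminant_fractions.values())
        if any(not 0 <= v <= 1 for v in fracs) or sum(fracs) >= 1:
            raise ValueError("contaminant fractions must be in [0,1] and sum < 1")


@dataclass
class SimulatedLibrary:
    """One simulated raw read library."""

    reads: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    tag_counts: dict[tuple[str, int], int]  # (feature name, tag index) -> reads
    contaminant_counts: dict[str, int]
    filler_count: int


HIGH_Q = "I"  # Phred 40
LOW_Q = "#"  # Phred 2


def _finish(insert: str, adapter3: str, read_length: int) -> str:
    read = (insert + adapter3 + adapter3)[:read_length]
    return read


def _random_fragment(rng, genome: SyntheticGenome, lo=19, hi=26) -> str:
    chroms = sorted(genome.chromosomes)
    chrom = chroms[rng.integers(len(chroms))]
    seq = genome.chromosomes[chrom]
    n = int(rng.integers(lo, hi + 1))
    pos = int(rng.integers(0, len(seq) - n + 1))
    frag = seq[pos : pos + n]
    return revcomp(frag) if rng.integers(2) else frag


def _simulate_library(
    genome: SyntheticGenome,
    sim: ReadSimSpec,
    total: int,
    condition: str,
    rng: np.random.Generator,
) -> SimulatedLibrary:
    tags: list[tuple[str, int, str]] = []  # (feature name, tag index, tag seq)
    probs: list[float] = []
    for f in genome.features:
        tpm = f.base_tpm_plus if condition == "plus" else f.base_tpm_minus
        if tpm <= 0 or not f.tag_seqs:
            continue
        per_tag = tpm / len(f.tag_seqs) / 1e6
        for t_idx, tag in enumerate(f.tag_seqs):
            tags.append((f.name or f.kind, t_idx, tag))
            probs.append(per_tag)

    classes = [c for c in CONTAMINANT_CLASSES if sim.contaminant_fractions.get(c, 0) > 0]
    probs += [sim.contaminant_fractions[c] for c in classes]
    filler_p = 1.0 - sum(probs)
    if filler_p < 0:
        raise ValueError("feature abundances plus contaminant fractions exceed 1")
    probs.append(filler_p)

    counts = rng.multinomial(total, np.array(probs)) if total else np.zeros(len(probs), int)
    tag_counts = {
        (name, t_idx): int(c) for (name, t_idx, _), c in zip(tags, counts[: len(tags)])
    }
    contaminant_counts = {
        c: int(n) for c, n in zip(classes, counts[len(tags) : len(tags) + len(classes)])
    }
    filler_count = int(counts[-1])

    a3 = sim.adapter3
    reads: list[tuple[str, str, str]] = []

    def emit(seq: str, qual: str | None = None):
        rid = f"{condition}_{len(reads) + 1}"
        reads.append((rid, seq, qual or HIGH_Q * len(seq)))

    for (name, t_idx, tag), c in zip(tags, counts[: len(tags)]):
        read = _finish(tag, a3, sim.read_length)
        for _ in range(int(c)):
            emit(read)

    key6 = a3[:6]
    for cls in classes:
        for _ in range(contaminant_counts[cls]):
            if cls == "low_quality":
                seq = _finish(_random_fragment(rng, genome), a3, sim.read_length)
                n_low = int(0.6 * sim.read_length) + 1
                positions = rng.choice(sim.read_length, size=min(n_low, sim.read_length), replace=False)
                q = np.full(sim.read_length, ord(HIGH_Q), dtype=np.uint8)
                q[positions] = ord(LOW_Q)
                emit(seq, q.tobytes().decode())
            elif cls == "adaptor3_null":
                while True:
                    insert = _random_fragment(rng, genome)
                    pad = "".join(
                        rng.choice(list("ACGT"), size=sim.read_length - len(insert))
                    )
                    seq = insert + pad
                    if key6 not in seq and not seq.startswith(sim.adapter5[:6]):
                        break
                emit(seq)
            elif cls == "insert_null":
                emit(_finish("", a3, sim.read_length))
            elif cls == "adaptor5_contaminants":
                seq = (sim.adapter5 + _random_fragment(rng, genome) + a3)[: sim.read_length]
                emit(seq)
            elif cls == "smaller_than_18nt":
                n = int(rng.integers(10, 18))
                while True:
                    insert = _random_fragment(rng, genome)[:n]
                    if insert.count("A") / n < 0.8:
                        break
                emit(_finish(insert, a3, sim.read_length))
            elif cls == "polyA":
                emit(_finish("A" * 21, a3, sim.read_length))

    pool: list[str] = []
    while len(pool) < max(1, sim.n_background_loci):
        insert = _random_fragment(rng, genome)
        if key6 in insert or insert.count("A") / len(insert) >= 0.8:
            continue
        seq = _finish(insert, a3, sim.read_length)
        if seq.startswith(sim.adapter5[:6]):
            continue
        pool.append(seq)
    for which in rng.integers(0, len(pool), size=filler_count):
        emit(pool[which])

    return SimulatedLibrary(
        reads=reads,
        tag_counts=tag_counts,
        contaminant_counts={c: contaminant_counts.get(c, 0) for c in CONTAMINANT_CLASSES},
        filler_count=filler_count,
    )


def simulate_reads(
    genome: SyntheticGenome, sim: ReadSimSpec
) -> tuple[SimulatedLibrary, SimulatedLibrary]:
    """Simulate the +S and -S raw libraries.

    Per-feature read counts are multinomial with expectation
    ``base_tpm x total / 1e6``; each library's read count equals the
    requested total exactly.  Fixed seeds give byte-identical output.
    """
    rng_plus = np.random.default_rng(np.random.SeedSequence([sim.seed, 1]))
    rng_minus = np.random.default_rng(np.random.SeedSequence([sim.seed, 2]))
    lib_plus = _simulate_library(genome, sim, sim.total_reads_plus, "plus", rng_plus)
    lib_minus = _simulate_library(genome, sim, sim.total_reads_minus, "minus", rng_minus)
    return lib_plus, lib_minus


# ---------------------------------------------------------------------------
# A ready-made demonstration scenario
# ---------------------------------------------------------------------------


def demo_features(
    rng: np.random.Generator, chromosome: str = "chromosome_1", chrom_len: int = 100_000
) -> list[PlantedFeature]:
    """A standard mixed feature set: 10 miRNA hairpins (4 known, 6 novel,
    two of them -S specific), 5 siRNA duplex loci, housekeeping ncRNAs,
    exons, introns and a repeat, with condition-dependent abundances."""
    feats: list[PlantedFeature] = []
    pos = 1500
    step = 900

    def advance(n):
        nonlocal pos
        here = pos
        pos += n + step
        return here

    # miRNAs: fold changes spanning down-, un- and up-regulated, plus
    # condition-specific ones (zero in one library).
    mirna_tpms = [
        (400, 400),
        (300, 1200),
        (800, 200),
        (1500, 3000),  # known
        (250, 1000),
        (600, 600),
        (150, 1200),
        (900, 450),
        (0, 800),
        (0, 500),  # novel; last two -S specific
    ]
    for i, (tp, tm) in enumerate(mirna_tpms):
        known = i < 4
        mature = random_mature(rng, length=21, gc=0.55)
        feats.append(
            hairpin_feature(
                chromosome,
                advance(60),
                mature,
                strand="+" if i % 2 == 0 else "-",
                name=(f"mir_k{i + 1}" if known else f"mir_n{i - 3}"),
                known=known,
                base_tpm_plus=tp,
                base_tpm_minus=tm,
            )
        )
    for i in range(5):
        while True:
            guide = random_mature(rng, length=23, gc=0.6)
            if _tag_ok(revcomp(guide)):  # minus-strand tag must survive too
                break
        feats.append(
            sirna_feature(
                chromosome,
                advance(25),
                guide,
                name=f"sirna_{i + 1}",
                base_tpm_plus=2000,
                base_tpm_minus=2000,
            )
        )
    housekeeping = [
        ("rrna", 3000, 40_000, 40_000),
        ("trna", 90, 12_000, 12_000),
        ("snrna", 150, 1500, 1500),
        ("snorna", 120, 800, 800),
        ("scrna", 110, 300, 300),
    ]
    for kind, n, tp, tm in housekeeping:
        feats.append(
            simple_feature(
                kind, chromosome, advance(n), pos - step - 1, "+",
                name=kind, base_tpm_plus=tp, base_tpm_minus=tm,
            )
        )
    for kind, n, strand, tp, tm in [
        ("exon", 600, "+", 5000, 6000),
        ("exon", 500, "-", 3000, 2500),
        ("intron", 700, "+", 2500, 3500),
        ("intron", 400, "-", 1500, 1500),
        ("repeat", 300, "+", 1000, 1000),
    ]:
        start = advance(n)
        feats.append(
            simple_feature(
                kind, chromosome, start, start + n - 1, strand,
                name=f"{kind}_{start}", base_tpm_plus=tp, base_tpm_minus=tm,
            )
        )
    if pos >= chrom_len:
        raise ValueError("demo features exceed chromosome length")
    return feats


def demo_dataset(
    seed: int = 0,
    total_reads: int = 50_000,
    contaminant_fractions: dict[str, float] | None = None,
    n_background_loci: int = 300,
) -> tuple[SyntheticGenome, ReadSimSpec, SimulatedLibrary, SimulatedLibrary]:
    """Build the bundled demonstration dataset end to end."""
    if contaminant_fractions is None:
        contaminant_fractions = {
            "low_quality": 0.02,
            "adaptor3_null": 0.004,
            "insert_null": 0.003,
            "adaptor5_contaminants": 0.006,
            "smaller_than_18nt": 0.03,
            "polyA": 0.001,
        }
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    spec = GenomeSpec(chromosome_lengths=(100_000,), gc_fraction=0.64, seed=seed)
    features = demo_features(rng)
    genome = make_genome(spec, features)
    sim = ReadSimSpec(
        total_reads_plus=total_reads,
        total_reads_minus=total_reads,
        contaminant_fractions=contaminant_fractions,
        n_background_loci=n_background_loci,
        seed=seed,
    )
    lib_plus, lib_minus = simulate_reads(genome, sim)
    return genome, sim, lib_plus, lib_minus
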
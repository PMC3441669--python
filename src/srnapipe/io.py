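"""File formats: FASTA/FASTQ via Biopython, collapsed FASTA, GFF3, TSV.

Collapsed FASTA uses ``>tagN_xCOUNT`` headers, the conventional compact
representation of a small-RNA library after tag collapsing.
"""

from __future__ import annotations

import re
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import KIND_TO_CATEGORY, SimulatedLibrary, SyntheticGenome


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path):
    """Yield (sequence, quality-string) pairs."""
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        yield str(rec.seq).upper(), "".join(chr(q + 33) for q in quals)


def write_fastq(path, reads) -> None:
    """Write (read_id, sequence, quality) triples as FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


_COLLAPSED_RE = re.compile(r"^\S+_x(\d+)$")


def read_collapsed_fasta(path) -> dict[str, int]:
    """Read a collapsed library; returns tag sequence -> count."""
    tags: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COLLAPSED_RE.match(rec.id)
        if not m:
            raise ValueError(f"collapsed FASTA header without _xCOUNT suffix: {rec.id!r}")
        tags[str(rec.seq).upper()] = tags.get(str(rec.seq).upper(), 0) + int(m.group(1))
    return tags


def write_collapsed_fasta(path, tags: dict[str, int]) -> None:
    ordered = sorted(tags.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(ordered):
            fh.write(f">tag{i + 1}_x{count}\n{seq}\n")


def reads_as_cleaning_input(path):
    """Adapt a FASTQ or collapsed-FASTA file to (sequence, quality) pairs."""
    path = Path(path)
    if path.suffix in (".fq", ".fastq"):
        yield from read_fastq(path)
    else:
        for seq, count in read_collapsed_fasta(path).items():
            for _ in range(count):
                yield seq, None


def write_annotation_gff(path, genome: SyntheticGenome) -> None:
    """GFF3 with the annotation category in the feature-type column.

    Novel (unannotated) miRNA hairpins and siRNA loci are ground truth,
    not annotation, and are deliberately left out.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in sorted((n, len(s)) for n, s in genome.chromosomes.items()):
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for i, f in enumerate(genome.features):
            if f.kind == "sirna_locus":
                continue
            if f.kind == "mirna_hairpin" and not f.known:
                continue
            category = KIND_TO_CATEGORY[f.kind]
            attrs = f"ID={f.name or f.kind + str(i)}"
            fh.write(
                "\t".join(
                    [
                        f.chromosome, "genbank", category, str(f.start),
                        str(f.end), ".", f.strand, ".", attrs,
                    ]
                )
                + "\n"
            )


def write_known_mirna_fastas(prefix, genome: SyntheticGenome) -> tuple[Path, Path]:
    """Mature and precursor FASTA for the known planted miRNAs."""
    mature = {}
    precursor = {}
    for f in genome.features:
        if f.kind == "mirna_hairpin" and f.known:
            mature[f.name] = f.mature_seq
            precursor[f.name] = f.seq
    mature_path = Path(f"{prefix}_mature.fa")
    precursor_path = Path(f"{prefix}_precursor.fa")
    write_fasta(mature_path, mature)
    write_fasta(precursor_path, precursor)
    return mature_path, precursor_path


def write_simulated_dataset(outdir, genome: SyntheticGenome,
                            lib_plus: SimulatedLibrary, lib_minus: SimulatedLibrary) -> dict:
    """Write genome, annotation, truth table, known-miRNA FASTAs and the
    two raw FASTQ libraries; returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "truth": outdir / "truth.tsv",
        "reads_plus": outdir / "reads_plus.fastq",
        "reads_minus": outdir / "reads_minus.fastq",
    }
    write_fasta(paths["genome"], genome.chromosomes)
    write_annotation_gff(paths["annotation"], genome)
    genome.truth_table().to_csv(paths["truth"], sep="\t", index=False)
    write_fastq(paths["reads_plus"], lib_plus.reads)
    write_fastq(paths["reads_minus"], lib_minus.reads)
    mature, precursor = write_known_mirna_fastas(outdir / "known_mirna", genome)
    paths["known_mature"] = mature
    paths["known_precursor"] = precursor
    return {k: str(v) for k, v in paths.items()}
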
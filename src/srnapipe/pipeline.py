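"""End-to-end orchestration: clean -> map -> annotate -> siRNA -> predict
-> differential expression, with every intermediate written to disk and a
manifest recording parameters, so a fixed config and seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, annotation, cleaning, diffexp, hairpin, io, mapping, simulate, sirna
from ._seq import to_dna

log = logging.getLogger("srnapipe")


@dataclass
class PipelineConfig:
    """Configuration for a full run; YAML-serializable."""

    genome: str = ""
    annotation_gff: str = ""
    known_mature: str = ""
    known_precursor: str = ""
    reads_plus: str = ""
    reads_minus: str = ""
    outdir: str = "srnapipe_out"
    adapter3: str = simulate.DEFAULT_ADAPTER3
    adapter5: str = simulate.DEFAULT_ADAPTER5
    quality_min_phred: int = 20
    quality_max_low_fraction: float = 0.5
    mireap: dict = field(default_factory=dict)
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    min_specific_count: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def mireap_params(self) -> hairpin.MireapParams:
        return hairpin.MireapParams(**self.mireap)

    def quality_config(self) -> cleaning.QualityConfig:
        return cleaning.QualityConfig(
            min_phred=self.quality_min_phred,
            max_low_fraction=self.quality_max_low_fraction,
        )

    def check_inputs(self) -> None:
        for key in ("genome", "reads_plus", "reads_minus"):
            p = getattr(self, key)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config input {key!r} missing: {p!r}")


@dataclass
class PipelineResult:
    reports: dict[str, cleaning.CleaningReport]
    tags: list[cleaning.SmallRNATag]
    mapping_result: mapping.MappingResult
    annotated: list[annotation.AnnotatedTag]
    summary: pd.DataFrame
    sirna_pairs: list[sirna.SirnaPair]
    candidates: list[hairpin.HairpinCandidate]
    known_records: list[diffexp.ExpressionRecord]
    novel_records: list[diffexp.ExpressionRecord]


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run every stage, writing intermediates under ``config.outdir``."""
    config.check_inputs()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- clean -------------------------------------------------------------
    reports: dict[str, cleaning.CleaningReport] = {}
    by_lib: dict[str, dict[str, int]] = {}
    for lib, path in (("plus", config.reads_plus), ("minus", config.reads_minus)):
        tags, report = cleaning.clean_reads(
            io.reads_as_cleaning_input(path),
            adapter3=config.adapter3,
            adapter5=config.adapter5,
            quality_config=config.quality_config(),
        )
        reports[lib] = report
        by_lib[lib] = tags
        report.to_frame().to_csv(out / f"cleaning_{lib}.tsv", sep="\t", index=False)
        io.write_collapsed_fasta(out / f"clean_{lib}.fa", tags)
        log.info(
            "library %s: %d reads, %d high quality, %d clean (%d unique tags)",
            lib, report.total_reads, report.high_quality, report.clean_reads, len(tags),
        )
    tags = cleaning.merge_libraries(by_lib["plus"], by_lib["minus"])

    # --- map ---------------------------------------------------------------
    chromosomes = io.read_fasta(config.genome)
    index = mapping.build_index(chromosomes)
    counts = {t.sequence: t.total for t in tags}
    mapres = mapping.map_library(index, counts)
    log.info("mapped %d/%d unique tags", len(mapres.hits), len(tags))
    with open(out / "hits.bed", "w") as fh:
        for seq in sorted(mapres.hits):
            for h in mapres.hits[seq]:
                fh.write(h.to_bed(name=seq) + "\n")

    # --- annotate ----------------------------------------------------------
    if config.annotation_gff and Path(config.annotation_gff).exists():
        db = annotation.AnnotationDB.from_gff(config.annotation_gff)
    else:
        db = annotation.AnnotationDB([])
    mapped_tags = [t for t in tags if t.sequence in mapres.hits]
    annotated = annotation.annotate_library(mapped_tags, mapres.hits, db)

    # --- siRNA -------------------------------------------------------------
    pairs = sirna.find_duplexes(mapres.hits)
    annotation.apply_sirna_category(annotated, sirna.duplex_sequences(pairs))
    summary = annotation.category_summary(annotated)
    summary.to_csv(out / "annotation_summary.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "chrom": p.chromosome,
                "plus_span": f"{p.plus_start}-{p.plus_end}",
                "minus_span": f"{p.minus_start}-{p.minus_end}",
                "plus_tag": p.plus_tag,
                "minus_tag": p.minus_tag,
            }
            for p in pairs
        ]
    ).to_csv(out / "sirna_pairs.tsv", sep="\t", index=False)
    log.info("annotation summary:\n%s", summary.to_string())

    # --- predict novel miRNAs ---------------------------------------------
    params = config.mireap_params()
    unann = {
        at.tag.sequence: (at.tag.count_plus, at.tag.count_minus)
        for at in annotated
        if at.category == "unann"
    }
    candidates = hairpin.predict_novel(unann, mapres.hits, chromosomes, params)
    hairpin.candidates_table(candidates).to_csv(
        out / "novel_candidates.tsv", sep="\t", index=False
    )
    log.info("accepted %d novel hairpin candidates", len(candidates))

    # --- differential expression -------------------------------------------
    totals = diffexp.LibraryTotals(
        n1=max(1, reports["plus"].clean_reads), n2=max(1, reports["minus"].clean_reads)
    )
    known_records: list[diffexp.ExpressionRecord] = []
    if config.known_mature and Path(config.known_mature).exists():
        mature = io.read_fasta(config.known_mature)
        precursors = (
            io.read_fasta(config.known_precursor)
            if config.known_precursor and Path(config.known_precursor).exists()
            else {}
        )
        tag_counts = {
            t.sequence: (t.count_plus, t.count_minus) for t in tags
        }
        known = hairpin.quantify_known(tag_counts, mature, precursors)
        known_records = diffexp.diff_table(
            known["count_plus"].to_dict(),
            known["count_minus"].to_dict(),
            totals,
            fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold,
            min_specific_count=config.min_specific_count,
        )
        diffexp.expression_frame(known_records).to_csv(
            out / "known_diffexp.tsv", sep="\t", index=False
        )
    novel_records = diffexp.diff_table(
        {c.name: c.count_plus for c in candidates},
        {c.name: c.count_minus for c in candidates},
        totals,
        fc_threshold=config.fc_threshold,
        p_threshold=config.p_threshold,
        min_specific_count=config.min_specific_count,
    )
    diffexp.expression_frame(novel_records).to_csv(
        out / "novel_diffexp.tsv", sep="\t", index=False
    )

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "clean_reads": {k: r.clean_reads for k, r in reports.items()},
        "unique_tags": len(tags),
        "mapped_tags": len(mapres.hits),
        "sirna_pairs": len(pairs),
        "novel_candidates": len(candidates),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        reports=reports,
        tags=tags,
        mapping_result=mapres,
        annotated=annotated,
        summary=summary,
        sirna_pairs=pairs,
        candidates=candidates,
        known_records=known_records,
        novel_records=novel_records,
    )


def simulate_dataset(
    outdir,
    seed: int = 0,
    total_reads: int = 50_000,
    contaminant_fractions: dict[str, float] | None = None,
    n_background_loci: int = 300,
) -> dict:
    """Generate the demonstration dataset on disk; returns the path manifest."""
    genome, sim, lib_plus, lib_minus = simulate.demo_dataset(
        seed=seed,
        total_reads=total_reads,
        contaminant_fractions=contaminant_fractions,
        n_background_loci=n_background_loci,
    )
    paths = io.write_simulated_dataset(outdir, genome, lib_plus, lib_minus)
    truth_counts = []
    for lib_name, lib in (("plus", lib_plus), ("minus", lib_minus)):
        for (feat, t_idx), c in sorted(lib.tag_counts.items()):
            truth_counts.append(
                {"library": lib_name, "feature": feat, "tag_index": t_idx, "count": c}
            )
    pd.DataFrame(truth_counts).to_csv(
        Path(outdir) / "truth_counts.tsv", sep="\t", index=False
    )
    paths["truth_counts"] = str(Path(outdir) / "truth_counts.tsv")
    return paths


def compare_truth(truth_path, result: PipelineResult) -> dict:
    """Planted-truth recovery metrics for a completed run."""
    truth = pd.read_csv(truth_path, sep="\t")
    novel = truth[(truth["kind"] == "mirna_hairpin") & (truth["known"] == 0)]
    predicted_matures = {to_dna(c.mature_seq) for c in result.candidates}
    expressed = novel[(novel["base_tpm_plus"] > 0) | (novel["base_tpm_minus"] > 0)]
    recovered = sum(
        1 for _, row in expressed.iterrows()
        if row["tag_seqs"].split(",")[0] in predicted_matures
    )
    sirna_truth = truth[truth["kind"] == "sirna_locus"]
    found_loci = {(p.chromosome, p.minus_start, p.plus_end) for p in result.sirna_pairs}
    sirna_recovered = sum(
        1 for _, row in sirna_truth.iterrows()
        if (row["chrom"], int(row["start"]), int(row["end"])) in found_loci
    )
    return {
        "novel_mirna_planted": int(len(expressed)),
        "novel_mirna_recovered": int(recovered),
        "sirna_planted": int(len(sirna_truth)),
        "sirna_recovered": int(sirna_recovered),
    }
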
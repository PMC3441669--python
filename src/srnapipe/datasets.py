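"""Bundled reference tables from a two-condition sulfur-deprivation
small-RNA profiling experiment in *Chlamydomonas reinhardtii*.

These tables carry the printed accounting and differential-expression
numbers that the worked examples and acceptance checks recompute:

* ``load_cleaning_counts`` — per-library read-cleaning counters for the
  sulfur-replete (+S) and sulfur-deprived (-S) libraries;
* ``load_known_diffexp`` — the 24 known miRNAs responsive to sulfur
  deprivation (normalized expression, log2 fold change, p-value, label);
* ``load_novel_mirnas`` — 23 predicted miRNAs with mature sequence,
  precursor location, reported MFE and raw read counts per library.

Note: the -S cleaning counters as printed are internally inconsistent by
one read (removals sum to one less than high-quality minus clean); they
are kept verbatim, and consumers that need exact conservation should
rebuild reports from the removal counters.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cleaning import CleaningReport


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("srnapipe").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_cleaning_counts() -> pd.DataFrame:
    """Per-library cleaning counters, one row per library ('plus', 'minus')."""
    return _read("cleaning_counts.tsv").set_index("library")


def cleaning_report(library: str) -> CleaningReport:
    """Rebuild a CleaningReport from the reference removal counters.

    Clean reads follow from the conservation identity, so for the -S
    library this differs from the printed clean-read count by one.
    """
    row = load_cleaning_counts().loc[library]
    return CleaningReport.from_removals(
        high_quality=int(row["high_quality"]),
        adaptor3_null=int(row["adaptor3_null"]),
        insert_null=int(row["insert_null"]),
        adaptor5_contaminants=int(row["adaptor5_contaminants"]),
        smaller_than_18nt=int(row["smaller_than_18nt"]),
        polyA=int(row["polyA"]),
        total_reads=int(row["total_reads"]),
    )


def load_known_diffexp() -> pd.DataFrame:
    """Known miRNAs responsive to sulfur deprivation (24 rows)."""
    return _read("known_mirna_diffexp.tsv")


def load_novel_mirnas() -> pd.DataFrame:
    """Predicted miRNAs responsive to sulfur deprivation (23 rows)."""
    return _read("novel_mirna.tsv")


def library_totals() -> tuple[int, int]:
    """(N1, N2): clean-read totals of the +S and -S libraries."""
    df = load_cleaning_counts()
    return int(df.loc["plus", "clean_reads"]), int(df.loc["minus", "clean_reads"])
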
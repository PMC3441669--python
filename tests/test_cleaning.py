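"""Read cleaning: elimination order, exact accounting, histograms, overlap."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnapipe.cleaning import (
    CleaningReport,
    QualityConfig,
    ReadParseError,
    SmallRNATag,
    clean_reads,
    length_histogram,
    library_overlap,
    merge_libraries,
)
from srnapipe.simulate import (
    DEFAULT_ADAPTER3,
    DEFAULT_ADAPTER5,
    GenomeSpec,
    ReadSimSpec,
    hairpin_feature,
    make_genome,
    random_mature,
    simulate_reads,
)

A3 = DEFAULT_ADAPTER3
A5 = DEFAULT_ADAPTER5
HQ = "I" * 36


def _read(insert, a3=A3, n=36):
    return ((insert + a3 + a3)[:n], HQ[:n])


class TestCleanReads:
    def test_empty_input_gives_zeroed_report(self):
        tags, report = clean_reads([], A3, A5)
        assert tags == {}
        assert report == CleaningReport()

    def test_survivor_is_trimmed_and_collapsed(self):
        insert = "ACGTACGTACGTACGTACGTA"  # 21 nt
        tags, report = clean_reads([_read(insert)] * 3, A3, A5)
        assert tags == {insert: 3}
        assert report.clean_reads == 3 and report.high_quality == 3

    def test_each_elimination_step(self):
        reads = [
            _read("ACGTACGTACGTACGTACGTA"),              # clean
            ("ACGTACGTACGTACGTACGTACGTACGTACGTACGT", "#" * 36),  # low quality
            (A5[:20] + "ACGTACGTACGTACGT", HQ),          # 5' adapter contaminant
            ("ACGT" * 9, HQ),                            # no 3' adapter
            _read(""),                                   # empty insert
            _read("AAAAAAAAAAAAAAAAAAAA"),               # poly-A (20 nt, all A)
            _read("ACGTACGTACGT"),                       # 12 nt insert
        ]
        tags, r = clean_reads(reads, A3, A5)
        assert (r.total_reads, r.high_quality) == (7, 6)
        assert r.adaptor5_contaminants == 1
        assert r.adaptor3_null == 1
        assert r.insert_null == 1
        assert r.polyA == 1
        assert r.smaller_than_18nt == 1
        assert r.clean_reads == 1

    def test_over_30nt_insert_goes_to_its_own_counter(self):
        tags, r = clean_reads([_read("ACGT" * 8, n=60)], A3, A5)
        assert r.longer_than_30nt == 1 and r.clean_reads == 0
        assert tags == {}

    def test_first_failure_wins(self):
        # 5'-adapter-prefixed AND missing 3' adapter: attributed to step 2
        _, r = clean_reads([(A5[:6] + "ACGTACGTACGTACGTACGTACGTACGTAC", HQ)], A3, A5)
        assert r.adaptor5_contaminants == 1 and r.adaptor3_null == 0

    def test_unparseable_record_names_index(self):
        with pytest.raises(ReadParseError, match="record 1"):
            list(clean_reads([_read("ACGTACGTACGTACGTACGTA"), ("AC-GT", HQ)], A3, A5))

    def test_quality_threshold_configurable(self):
        qual = "I" * 18 + "#" * 18  # exactly half low: not removed at 0.5
        reads = [(("ACGTACGTACGTACGTACGTA" + A3)[:36], qual)]
        _, r = clean_reads(reads, A3, A5, QualityConfig(max_low_fraction=0.5))
        assert r.high_quality == 1
        _, r = clean_reads(reads, A3, A5, QualityConfig(max_low_fraction=0.4))
        assert r.high_quality == 0

    def test_simulated_contaminant_counts_reproduced_exactly(self, rng):
        """Generator truth and cleaning report agree per category."""
        feat = hairpin_feature(
            "chromosome_1", 2001, random_mature(rng),
            base_tpm_plus=50_000, base_tpm_minus=0, name="mir",
        )
        genome = make_genome(GenomeSpec(chromosome_lengths=(20_000,), seed=9), [feat])
        fractions = {
            "low_quality": 0.02,
            "adaptor3_null": 0.01,
            "insert_null": 0.01,
            "adaptor5_contaminants": 0.02,
            "smaller_than_18nt": 0.03,
            "polyA": 0.005,
        }
        sim = ReadSimSpec(
            total_reads_plus=10_000, total_reads_minus=0,
            contaminant_fractions=fractions, seed=21,
        )
        lib, _ = simulate_reads(genome, sim)
        _, report = clean_reads([(s, q) for _, s, q in lib.reads], A3, A5)
        truth = lib.contaminant_counts
        assert report.total_reads == 10_000
        assert report.high_quality == 10_000 - truth["low_quality"]
        for field in ("adaptor3_null", "insert_null", "adaptor5_contaminants",
                      "smaller_than_18nt", "polyA"):
            assert getattr(report, field) == truth[field], field
        report.validate()

    def test_zero_contaminants_gives_zero_removals(self, rng):
        feat = hairpin_feature("chromosome_1", 2001, random_mature(rng),
                               base_tpm_plus=100_000, name="mir")
        genome = make_genome(GenomeSpec(chromosome_lengths=(20_000,), seed=9), [feat])
        sim = ReadSimSpec(total_reads_plus=3000, total_reads_minus=0, seed=2)
        lib, _ = simulate_reads(genome, sim)
        _, r = clean_reads([(s, q) for _, s, q in lib.reads], A3, A5)
        assert (r.adaptor3_null, r.insert_null, r.adaptor5_contaminants,
                r.smaller_than_18nt, r.polyA) == (0, 0, 0, 0, 0)
        assert r.clean_reads == r.high_quality == 3000


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["clean", "noadapter", "empty", "polya", "short", "lowq"]),
            st.integers(0, 3),
        ),
        max_size=40,
    )
)
def test_conservation_identity_on_random_libraries(recipe):
    inserts = {
        "clean": "ACGTACGTACGTACGTACGTA",
        "empty": "",
        "polya": "A" * 20,
        "short": "ACGTACGTACGT",
    }
    reads = []
    for kind, mult in recipe:
        for _ in range(mult):
            if kind == "noadapter":
                reads.append(("ACGT" * 9, HQ))
            elif kind == "lowq":
                reads.append((("ACGTACGTACGTACGTACGTA" + A3)[:36], "#" * 36))
            else:
                reads.append(_read(inserts[kind]))
    tags, report = clean_reads(reads, A3, A5)
    report.validate()  # exact conservation, every time
    assert sum(tags.values()) == report.clean_reads
    assert report.total_reads == len(reads)


class TestReportArithmetic:
    def test_from_removals_applies_conservation(self):
        r = CleaningReport.from_removals(
            high_quality=1000, adaptor3_null=10, insert_null=5,
            adaptor5_contaminants=20, smaller_than_18nt=60, polyA=5,
        )
        assert r.clean_reads == 900
        assert r.percentage("clean_reads") == 90.0
        r.validate()

    def test_frame_uses_printed_row_labels(self):
        frame = CleaningReport.from_removals(high_quality=100).to_frame()
        assert list(frame["row"])[:3] == ["Total reads", "High quality", "Adaptor3 null"]


class TestHistogramAndOverlap:
    def test_single_tag_histogram(self):
        h = length_histogram({"A" * 20 + "C": 5})
        assert h.loc[21, "total"] == 5 and h.loc[21, "unique"] == 1
        assert h["total"].sum() == 5 and h["unique"].sum() == 1

    def test_empty_histogram(self):
        h = length_histogram({})
        assert (h == 0).all().all()

    def test_demo_library_mode_is_21nt(self, demo):
        genome, sim, lp, _ = demo
        tags, _ = clean_reads(
            [(s, q) for _, s, q in lp.reads], sim.adapter3, sim.adapter5
        )
        h = length_histogram(tags)
        assert h["total"].idxmax() == 21

    def test_identical_libraries_fully_common(self):
        tags = {"ACGTACGTACGTACGTAC": 5, "TGCATGCATGCATGCATG": 2}
        ov = library_overlap(tags, tags)
        assert ov.unique_percentages()["common"] == 100.0
        assert ov.total_percentages()["common"] == 100.0

    def test_disjoint_libraries_zero_common(self):
        ov = library_overlap({"ACGTACGTACGTACGTAC": 5}, {"TGCATGCATGCATGCATG": 2})
        assert ov.unique_common == 0 and ov.total_common == 0
        assert ov.total_percentages()["common"] == 0.0

    def test_constructed_mix_percentages(self):
        shared = "ACGTACGTACGTACGTAC"
        ov = library_overlap(
            {shared: 49, "TTTTGGGGCCCCAAAATT": 1},
            {shared: 49, "GGGGCCCCAAAATTTTGG": 1},
        )
        assert ov.total_percentages()["common"] == 98.0
        assert ov.unique_common == 1
        assert ov.unique_common / (ov.unique_common + ov.unique_plus_specific
                                   + ov.unique_minus_specific) == pytest.approx(1 / 3)

    def test_merge_preserves_total_reads(self):
        plus = {"ACGTACGTACGTACGTAC": 5, "TGCATGCATGCATGCATG": 2}
        minus = {"ACGTACGTACGTACGTAC": 3}
        merged = merge_libraries(plus, minus)
        assert sum(t.total for t in merged) == 10
        assert all(isinstance(t, SmallRNATag) for t in merged)
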
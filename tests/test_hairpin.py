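"""Hairpin prediction: window arithmetic, duplex criteria, recovery,
known-miRNA quantification."""

import pytest

from srnapipe._seq import to_dna
from srnapipe.folding import fold, structure_energy
from srnapipe.hairpin import (
    MireapParams,
    candidate_windows,
    evaluate_candidate,
    predict_novel,
    quantify_known,
)
from srnapipe.mapping import AlignmentHit, build_index, map_library
from srnapipe.simulate import plant_hairpin
from tests.conftest import random_seq

PARAMS = MireapParams()


class TestCandidateWindows:
    def test_window_arithmetic(self):
        hit = AlignmentHit("chromosome_1", 1000, 1020, "+")
        assert candidate_windows(hit, PARAMS, 100_000) == [(980, 1340), (680, 1040)]

    def test_left_clipping(self):
        hit = AlignmentHit("chromosome_1", 5, 25, "+")
        windows = candidate_windows(hit, PARAMS, 100_000)
        assert windows[0] == (1, 345)
        assert windows[1] == (1, 45)

    def test_window_contains_planted_precursor(self, demo_genome, demo_index):
        for f in demo_genome.features:
            if f.kind != "mirna_hairpin":
                continue
            hit = demo_index.map_tag(f.tag_seqs[0])[0]
            windows = candidate_windows(hit, PARAMS, 100_000)
            assert any(lo <= f.start and f.end <= hi for lo, hi in windows)


class TestEvaluateCandidate:
    def test_planted_hairpin_accepted(self):
        hp = plant_hairpin("GCGTACGTAGCTAGCATGGCA", loop_len=8)
        cand = evaluate_candidate(fold(hp.precursor), hp.mature_span, PARAMS)
        assert cand.accepted, cand.reasons
        assert cand.duplex_pairs == 19
        assert cand.max_bulge_found == 0 and cand.asymmetry_found == 0

    def test_weak_stem_rejected_for_mfe_only(self):
        # A G/U-only precursor can form at most 16 G:U pairs (one per U),
        # capping the energy at -16 kcal/mol: every criterion except the
        # -18 energy bound is met.
        precursor = "G" * 18 + "G" * 8 + "T" * 16 + "GG"
        cand = evaluate_candidate(fold(precursor), (0, 18), PARAMS)
        assert not cand.accepted
        assert cand.reasons == ["mfe"]
        assert cand.duplex_pairs == 16
        assert cand.fold.mfe == -16.0

    def test_boundary_mfe_is_inclusive(self):
        # 6 GC + 3 GU pairs inside the mature/star duplex is unrealistic,
        # so use an 18-nt mature pairing 16 times: 5 GC + 11 AU = -37;
        # with a custom engine pinning the energy at exactly -18, accept.
        hp = plant_hairpin("GCGTACGTAGCTAGCATG")
        base = fold(hp.precursor)
        pinned = lambda s: (base.structure, -18.0)  # noqa: E731
        cand = evaluate_candidate(
            fold(hp.precursor, engine=pinned), hp.mature_span, PARAMS
        )
        assert cand.accepted

    def test_mature_in_loop_has_no_star(self):
        seq = "G" * 8 + "A" * 21 + "C" * 8
        cand = evaluate_candidate(fold(seq), (8, 29), PARAMS)
        assert not cand.accepted and cand.reasons == ["no_star"]

    def test_mature_outside_window_rejected(self):
        with pytest.raises(ValueError, match="mature interval"):
            evaluate_candidate(fold("GGGAAACCC"), (5, 30), PARAMS)

    def test_reported_metrics_describe_reported_fold(self):
        hp = plant_hairpin("GCGTACGTAGCTAGCATGGCA")
        cand = evaluate_candidate(fold(hp.precursor), hp.mature_span, PARAMS)
        assert structure_energy(cand.fold.sequence, cand.fold.structure) == cand.fold.mfe


def _independent_recheck(cand, params):
    """Re-derive the six acceptance predicates from the reported fold."""
    pairs = dict(cand.fold.pairs())
    pairs.update({j: i for i, j in cand.fold.pairs()})
    m_lo, m_hi = cand.mature_span
    s_lo, s_hi = cand.star_span
    duplex = [i for i in range(m_lo, m_hi) if s_lo <= pairs.get(i, -1) < s_hi]
    assert len(duplex) >= params.min_duplex_pairs
    assert cand.fold.mfe <= params.max_precursor_mfe
    assert structure_energy(cand.fold.sequence, cand.fold.structure) == cand.fold.mfe
    # opposite arms: star strictly one side of the mature
    assert s_lo >= m_hi or s_hi <= m_lo
    gap = s_lo - m_hi if s_lo >= m_hi else m_lo - s_hi
    assert gap <= params.max_space
    assert cand.max_bulge_found <= params.max_bulge
    assert cand.asymmetry_found <= params.max_asymmetry


class TestPredictNovel:
    def test_all_planted_matures_recovered_on_clean_background(
        self, demo_genome, demo_index
    ):
        tags = {
            f.tag_seqs[0]: (10, 10)
            for f in demo_genome.features
            if f.kind == "mirna_hairpin"
        }
        result = map_library(demo_index, {s: 20 for s in tags})
        cands = predict_novel(tags, result.hits, demo_genome.chromosomes, PARAMS)
        assert len(cands) == len(tags)
        planted = {to_dna(f.tag_seqs[0]) for f in demo_genome.features
                   if f.kind == "mirna_hairpin"}
        assert {to_dna(c.mature_seq) for c in cands} == planted
        for c in cands:
            _independent_recheck(c, PARAMS)
        assert [c.name for c in cands] == [f"n{i + 1:03d}" for i in range(len(cands))]
        assert c.count_plus == 10

    def test_high_copy_tags_excluded(self, rng):
        hp = plant_hairpin(random_seq(rng, 21, gc=0.6))
        spacer = lambda: random_seq(rng, 150)  # noqa: E731
        genome = {"chromosome_1": spacer() + (hp.precursor + spacer()) * 25}
        tag = hp.precursor[:21]
        index = build_index(genome)
        hits = index.map_tag(tag)
        assert len(hits) >= 25
        cands = predict_novel(
            {tag: (1, 1)}, {tag: hits}, genome, PARAMS
        )
        assert cands == []

    def test_empty_input(self, demo_genome):
        assert predict_novel({}, {}, demo_genome.chromosomes, PARAMS) == []

    def test_relaxing_mfe_never_loses_candidates(self, demo_genome, demo_index):
        tags = {
            f.tag_seqs[0]: (5, 5)
            for f in demo_genome.features
            if f.kind == "mirna_hairpin"
        }
        result = map_library(demo_index, {s: 10 for s in tags})
        strict = predict_novel(tags, result.hits, demo_genome.chromosomes, PARAMS)
        relaxed_params = MireapParams(max_precursor_mfe=-10.0)
        relaxed = predict_novel(tags, result.hits, demo_genome.chromosomes, relaxed_params)
        assert len(relaxed) >= len(strict)


class TestQuantifyKnown:
    MATURE = {"mirA": "GCGTACGTAGCTAGCATGGCA", "mirB": "TTTTGGGGCCCCAAAATTGGC"}

    def test_exact_mature_match_counts(self):
        tags = {"GCGTACGTAGCTAGCATGGCA": (28, 68)}
        df = quantify_known(tags, self.MATURE)
        assert df.loc["mirA", "count_plus"] == 28
        assert df.loc["mirA", "count_minus"] == 68
        assert df.loc["mirB", "count_plus"] == 0

    def test_tag_within_precursor_counts(self):
        hp = plant_hairpin(self.MATURE["mirA"])
        star = hp.precursor[hp.star_span[0] : hp.star_span[1]]
        df = quantify_known({star: (3, 4)}, self.MATURE, {"mirA": hp.precursor})
        assert df.loc["mirA", "count_plus"] == 3
        assert not df.loc["mirA", "multi_assigned"]

    def test_tag_matching_two_precursors_flagged(self):
        shared = "GCGTACGTAGCTAGCATGGCA"
        precursors = {"mirA": "AAAA" + shared + "GGGG", "mirB": shared + "CCCC"}
        df = quantify_known({shared: (5, 0)}, {}, precursors)
        assert df.loc["mirA", "count_plus"] == 5
        assert df.loc["mirB", "count_plus"] == 5
        assert df["multi_assigned"].all()

    def test_rna_dna_alphabet_equivalence(self):
        df = quantify_known(
            {"GCGUACGUAGCUAGCAUGGCA": (2, 1)},
            {"mirA": self.MATURE["mirA"]},
        )
        assert df.loc["mirA", "count_plus"] == 2
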
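"""TPM normalization, fold change, and the Audic-Claverie test.

The log-space implementation is cross-checked against the equivalent
negative-binomial distribution from scipy (size x+1, success probability
1/(1 + N2/N1)), which serves as the independent oracle.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom

from srnapipe.diffexp import (
    LibraryTotals,
    ac_log_pmf,
    ac_pvalue,
    diff_table,
    expression_frame,
    log2_fc,
    sig_label,
    tpm,
)


def _nbinom_params(x, n1, n2):
    r = n2 / n1
    return x + 1, 1 / (1 + r)


class TestTpm:
    def test_zero_and_full_counts(self):
        assert tpm(0, 123) == 0.0
        assert tpm(123, 123) == 1e6

    def test_published_normalization_example(self):
        assert round(tpm(28, 10_029_992), 4) == 2.7916

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tpm(1, 0)
        with pytest.raises(ValueError):
            tpm(-1, 10)


class TestLog2Fc:
    def test_equal_expression_is_zero(self):
        assert log2_fc(7.5, 7.5) == 0.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.floats(1e-3, 1e6, allow_nan=False),
        st.floats(1e-3, 1e6, allow_nan=False),
    )
    def test_antisymmetry(self, a, b):
        assert log2_fc(a, b) == pytest.approx(-log2_fc(b, a), abs=1e-12)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            log2_fc(0.0, 1.0)


class TestAcPmf:
    def test_equal_libraries_zero_counts(self):
        assert math.exp(ac_log_pmf(0, 0, 1000, 1000)) == pytest.approx(0.5, abs=1e-12)

    def test_equal_library_closed_form(self):
        """N1 = N2: p(y|x) = C(x+y, y) * 2^-(x+y+1), exact in log space."""
        n = 500_000
        for x in range(0, 51, 10):
            for y in range(0, 51, 7):
                expected = (
                    math.lgamma(x + y + 1)
                    - math.lgamma(x + 1)
                    - math.lgamma(y + 1)
                    - (x + y + 1) * math.log(2)
                )
                assert ac_log_pmf(x, y, n, n) == pytest.approx(expected, abs=1e-12)

    def test_normalization_sums_to_one(self, rng):
        """Sum over y of p(y|x) = 1 +/- 1e-9 for x in 0..30, random totals."""
        for x in range(31):
            n1 = int(rng.integers(10**5, 10**8))
            n2 = int(rng.integers(10**5, 10**8))
            size, p = _nbinom_params(x, n1, n2)
            hi = int(nbinom.ppf(1 - 1e-13, size, p)) + 10
            total = np.exp(ac_log_pmf(x, np.arange(hi + 1), n1, n2)).sum()
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_negative_binomial(self):
        for x, n1, n2 in [(0, 10**6, 10**6), (17, 10_029_992, 9_918_931), (400, 3 * 10**6, 10**6)]:
            size, p = _nbinom_params(x, n1, n2)
            ys = np.arange(0, 200)
            np.testing.assert_allclose(
                ac_log_pmf(x, ys, n1, n2), nbinom.logpmf(ys, size, p), rtol=1e-10
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ac_log_pmf(-1, 0, 10, 10)


class TestAcPvalue:
    def test_observation_at_mode_is_not_significant(self):
        assert ac_pvalue(30, 30, 10**6, 10**6) > 0.39

    def test_upper_tail_decreasing_in_y(self):
        n1 = n2 = 10**6
        previous = 1.1
        for y in (10, 20, 40, 80, 160):
            p = ac_pvalue(10, y, n1, n2)
            assert p < previous
            previous = p

    def test_matches_scipy_tails(self):
        """Both tails agree with nbinom sf/cdf across count scales."""
        cases = [
            (28, 68, 10_029_992, 9_918_931),
            (5, 1, 10**6, 10**6),
            (2330, 9139, 10_029_992, 9_918_931),
            (28_390, 68_361, 10_029_992, 9_918_931),
            (0, 0, 10**6, 2 * 10**6),
        ]
        for x, y, n1, n2 in cases:
            size, p = _nbinom_params(x, n1, n2)
            if y / n2 >= x / n1:
                expected = nbinom.sf(y - 1, size, p)
            else:
                expected = nbinom.cdf(y, size, p)
            assert ac_pvalue(x, y, n1, n2) == pytest.approx(expected, rel=1e-9)

    def test_large_counts_do_not_overflow(self):
        # Counts at the 1e7 scale: the tail probability underflows toward
        # the printed "0" rather than raising or overflowing.
        p = ac_pvalue(10**7, 2 * 10**7, 10**8, 10**8)
        assert math.isfinite(p) and 0 <= p < 1e-100
        q = ac_pvalue(100_000, 101_000, 10**8, 10**8)
        assert 0 < q < 1


class TestSigLabel:
    @pytest.mark.parametrize(
        "p,label",
        [(0.0464712840858496, "*"), (0.00218223161858286, "**"),
         (0.05, ""), (0.01, "*"), (0.5, ""), (0.0, "**")],
    )
    def test_thresholds(self, p, label):
        assert sig_label(p) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            sig_label(1.5)


class TestDiffTable:
    TOTALS = LibraryTotals(n1=10**6, n2=10**6)

    def test_condition_specific_record(self):
        records = diff_table({"n197": 0}, {"n197": 321}, self.TOTALS)
        (r,) = records
        assert r.specificity == "minus_only"
        assert r.log2fc is None and r.pvalue is None
        assert r.significant  # 321 >= the 10-read floor

    def test_low_count_specific_not_significant(self):
        (r,) = diff_table({"m": 0}, {"m": 3}, self.TOTALS)
        assert r.specificity == "minus_only" and not r.significant

    def test_equal_counts_not_significant(self):
        records = diff_table(
            {f"m{i}": 50 for i in range(5)},
            {f"m{i}": 50 for i in range(5)},
            self.TOTALS,
        )
        assert all(not r.significant for r in records)
        assert all(r.log2fc == 0.0 for r in records)

    def test_missing_ids_are_zero_counts(self):
        records = diff_table({"a": 40}, {"b": 40}, self.TOTALS)
        by_name = {r.mirna: r for r in records}
        assert by_name["a"].specificity == "plus_only"
        assert by_name["b"].specificity == "minus_only"

    def test_significance_rule(self):
        records = diff_table({"up": 20, "flat": 20}, {"up": 90, "flat": 24}, self.TOTALS)
        by_name = {r.mirna: r for r in records}
        assert by_name["up"].significant
        assert abs(by_name["flat"].log2fc) < 1.0 and not by_name["flat"].significant

    def test_frame_has_published_headers_and_rounding(self):
        frame = expression_frame(diff_table({"m": 28}, {"m": 68},
                                            LibraryTotals(10_029_992, 9_918_931)))
        assert list(frame.columns) == [
            "miR-name", "+S-std", "-S-std", "fold-change (log2 -S/+S)",
            "p-value", "sig-lable",
        ]
        assert frame.loc[0, "+S-std"] == 2.7916
        assert frame.loc[0, "-S-std"] == 6.8556
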
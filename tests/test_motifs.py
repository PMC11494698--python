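"""Canonical scans, Fisher enrichment vs enumeration, Dunn vs hand ranks."""

import itertools
from math import comb, sqrt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from earkit import assay, motifs
from earkit.datatypes import ParameterError


def fisher_enumeration(table):
    """Independent oracle: full hypergeometric enumeration at fixed margins."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = {
        x: comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1) for x in support
    }
    p_obs = probs[a]
    one = sum(p for x, p in probs.items() if x >= a)
    two = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
    return one, two


class TestScanCanonical:
    @pytest.mark.parametrize("seq,lxlxl,dlnxxp", [
        ("LDLNLPP", True, True),   # natural EAR motif with both patterns
        ("AAAAA", False, False),
        ("LALAL", True, False),
        ("DLNAAP", False, True),
    ])
    def test_patterns(self, seq, lxlxl, dlnxxp):
        s = motifs.scan_canonical(seq)
        assert s.has_LxLxL is lxlxl
        assert s.has_DLNxxP is dlnxxp
        assert s.has_both is (lxlxl and dlnxxp)

    def test_rejects_non_amino_acids(self):
        with pytest.raises(ParameterError):
            motifs.scan_canonical("LXLZL1")

    @settings(derandomize=True, max_examples=50)
    @given(flank=st.text(alphabet="AGKRSTV", min_size=0, max_size=8))
    def test_invariant_to_nonmatching_flanks(self, flank):
        core = "LDLNLPP"
        flanked = motifs.scan_canonical(flank + core + flank)
        assert flanked.has_LxLxL and flanked.has_DLNxxP


class TestFisherExact:
    def test_no_association(self):
        assert motifs.fisher_exact_2x2([[1, 1], [1, 1]])["p_two_sided"] == \
            pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        # all six "both-motif" constructs in the stronger half of 84
        res = motifs.fisher_exact_2x2([[6, 0], [36, 42]])
        expected = comb(42, 6) / comb(84, 6)
        assert res["p_one_sided"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.0129, abs=5e-4)

    def test_degenerate_margin(self):
        assert motifs.fisher_exact_2x2([[0, 0], [5, 5]])["p_two_sided"] == \
            pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ParameterError):
            motifs.fisher_exact_2x2([[0, 0], [0, 0]])

    def test_matches_enumeration_small_margins(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            t = rng.integers(0, 16, size=(2, 2))
            if t.sum() == 0:
                continue
            res = motifs.fisher_exact_2x2(t.tolist())
            one, two = fisher_enumeration(t.tolist())
            assert res["p_one_sided"] == pytest.approx(one, abs=1e-9)
            assert res["p_two_sided"] == pytest.approx(two, abs=1e-7)

    def test_invariant_to_double_swap(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            swapped = t[::-1, ::-1]
            assert motifs.fisher_exact_2x2(t.tolist())["p_two_sided"] == \
                pytest.approx(
                    motifs.fisher_exact_2x2(swapped.tolist())["p_two_sided"])


def summaries_for(strengths):
    # relative gfp = 1 - strength with a Gal4 mean of 1000 AU
    return [assay.summarize(cid, [1000.0 * (1 - s)], 1000.0)
            for cid, s in strengths.items()]


class TestLengthStrength:
    def test_perfectly_monotone(self):
        seqs = {f"c{i}": "A" * (5 + i) for i in range(6)}
        summaries = summaries_for({f"c{i}": 0.05 + 0.1 * i for i in range(6)})
        res = motifs.length_strength(summaries, seqs)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_independent_lengths_near_zero(self):
        rng = np.random.default_rng(0)
        n = 300
        seqs = {f"c{i}": "A" * int(rng.integers(5, 20)) for i in range(n)}
        summaries = summaries_for(
            {f"c{i}": float(rng.uniform(-0.2, 0.8)) for i in range(n)})
        res = motifs.length_strength(summaries, seqs)
        assert abs(res.spearman_rho) < 0.12

    def test_excluding_driver_reduces_correlation(self):
        # mild trend plus one long, very strong construct (an SRDX analogue)
        seqs = {"a": "A" * 5, "b": "A" * 6, "c": "A" * 7, "d": "A" * 8,
                "e": "A" * 9, "srdx": "A" * 30}
        summaries = summaries_for(
            {"a": 0.30, "b": 0.1, "c": 0.35, "d": 0.2, "e": 0.4, "srdx": 0.95})
        full = motifs.length_strength(summaries, seqs)
        without = motifs.length_strength(summaries, seqs, exclude={"srdx"})
        assert abs(without.spearman_rho) < abs(full.spearman_rho)

    def test_box_stats_quartiles(self):
        seqs = {f"c{i}": "AAAAA" for i in range(4)}
        seqs.update({f"d{i}": "AAAAAAA" for i in range(4)})
        strengths = {f"c{i}": v for i, v in enumerate([0.1, 0.2, 0.3, 0.4])}
        strengths.update({f"d{i}": v for i, v in
                          enumerate([0.5, 0.6, 0.7, 0.8])})
        res = motifs.length_strength(summaries_for(strengths), seqs)
        row5 = res.table[res.table.length == 5].iloc[0]
        assert row5["median"] == pytest.approx(0.25)
        assert row5["q25"] == pytest.approx(0.175)
        assert row5["q75"] == pytest.approx(0.325)

    def test_equal_lengths_correlation_missing(self):
        seqs = {"a": "AAAAA", "b": "CCCCC", "c": "DDDDD"}
        res = motifs.length_strength(
            summaries_for({"a": 0.1, "b": 0.2, "c": 0.3}), seqs)
        assert res.spearman_rho is None


class TestStrongerHalf:
    def test_top_half_with_id_tiebreak(self):
        summaries = summaries_for({"a": 0.5, "b": 0.5, "c": 0.2, "d": 0.1,
                                   "e": 0.9})
        assert motifs.stronger_half(summaries) == {"a", "b", "e"}


class TestDunn:
    def test_hand_computed_oracle(self):
        """z statistics against directly hand-ranked data (no ties).

        Pooled sort: 1(A) 2(B) 3(C) 4(A) 5(C) 6(A) 7(B) 8(C) 9(B);
        mean ranks A=11/3, B=6, C=16/3; sigma = sqrt(9*10/12 * 2/3) = sqrt(5).
        """
        groups = {"A": [1, 4, 6], "B": [2, 7, 9], "C": [3, 5, 8]}
        out = motifs.dunn_test(groups).set_index(["group1", "group2"])
        s5 = sqrt(5.0)
        assert out.loc[("A", "B"), "z"] == pytest.approx((11 / 3 - 6) / s5)
        assert out.loc[("A", "C"), "z"] == pytest.approx((11 / 3 - 16 / 3) / s5)
        assert out.loc[("B", "C"), "z"] == pytest.approx((6 - 16 / 3) / s5)

    def test_bonferroni_triples_raw_p(self):
        groups = {"A": [1, 4, 6], "B": [2, 7, 9], "C": [3, 5, 8]}
        out = motifs.dunn_test(groups)
        assert np.allclose(out["p_adj"],
                           np.minimum(1.0, out["p_raw"] * 3))

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(size=6).tolist() for i in range(4)}
        out = motifs.dunn_test(groups)
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()
        assert (out["p_adj"] > 0.05).all()

    def test_single_comparison_unadjusted(self):
        out = motifs.dunn_test({"lo": [1, 2, 3], "hi": [10, 11, 12]})
        assert len(out) == 1
        assert out.loc[0, "p_adj"] == pytest.approx(out.loc[0, "p_raw"])

    def test_small_group_excluded(self):
        out = motifs.dunn_test({"a": [1, 2, 3], "b": [4, 5, 6], "tiny": [9]})
        assert set(out.group1) | set(out.group2) == {"a", "b"}

    def test_too_few_groups_error(self):
        with pytest.raises(ParameterError):
            motifs.dunn_test({"a": [1, 2], "tiny": [1]})
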
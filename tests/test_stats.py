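import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycopssm.seqio import ProteinRecord
from glycopssm.stats import (
    background_from_sequences,
    binomial_upper_tail,
    composition,
    compositional_bias,
    evaluate_predictions,
    format_confusion_report,
    pearson,
    positional_frequency,
)
from glycopssm.windows import LabeledPeptideSet, PeptideWindow


def _set(*windows: str, label="positive") -> LabeledPeptideSet:
    return LabeledPeptideSet(
        name="t", label=label,
        windows=[PeptideWindow(parent_id="p", center_position=1, window=w)
                 for w in windows],
    )


class TestPositionalFrequency:
    def test_one_hot_single_window(self):
        fm = positional_frequency(_set("AST"))
        assert fm.frequency("A", -1) == 1.0
        assert fm.frequency("S", 0) == 1.0
        assert fm.frequency("T", +1) == 1.0
        assert fm.frequency("G", -1) == 0.0

    def test_hand_count_two_windows(self):
        fm = positional_frequency(_set("AST", "GTV"))
        assert fm.frequency("A", -1) == 0.5
        assert fm.frequency("G", -1) == 0.5

    def test_center_column_all_st(self):
        fm = positional_frequency(_set("AST", "GTV", "PSP"))
        assert fm.frequency("S", 0) + fm.frequency("T", 0) == pytest.approx(1.0)

    def test_pad_and_x_excluded(self):
        fm = positional_frequency(_set("-SX"))
        assert fm.counts[0] == 0 and fm.counts[2] == 0
        assert fm.frequencies[:, 0].sum() == 0.0

    def test_columns_normalized(self):
        rng = np.random.default_rng(0)
        windows = []
        for _ in range(40):
            fl = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=8))
            windows.append(fl[:4] + "S" + fl[4:])
        fm = positional_frequency(_set(*windows))
        sums = fm.frequencies.sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_duplication_invariant(self):
        fm1 = positional_frequency(_set("AST", "GTV"))
        fm2 = positional_frequency(_set("AST", "GTV", "AST", "GTV"))
        np.testing.assert_allclose(fm1.frequencies, fm2.frequencies)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            positional_frequency(_set())


def brute_force_upper_tail(k: int, n: int, p: float) -> float:
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


class TestBinomialTail:
    def test_zero_count_gives_one(self):
        assert binomial_upper_tail(0, 100, 0.3) == (1.0, 0.0)

    def test_hand_case_vs_enumeration(self):
        p, log10p = binomial_upper_tail(5, 10, 0.1)
        expected = brute_force_upper_tail(5, 10, 0.1)
        assert p == pytest.approx(expected, rel=1e-10)
        assert log10p == pytest.approx(math.log10(expected), rel=1e-10)

    @given(st.integers(1, 40), st.integers(0, 45),
           st.floats(0.01, 0.99))
    def test_matches_direct_summation(self, n, k, p):
        k = min(k, n + 2)
        tail, _ = binomial_upper_tail(k, n, p)
        assert tail == pytest.approx(
            brute_force_upper_tail(k, n, p) if k <= n else 0.0,
            rel=1e-10, abs=1e-300,
        )

    @given(st.integers(5, 60), st.floats(0.05, 0.5))
    def test_monotone_nonincreasing_in_count(self, n, p):
        tails = [binomial_upper_tail(k, n, p)[0] for k in range(n + 1)]
        assert all(b <= a for a, b in zip(tails, tails[1:]))

    def test_extreme_magnitude_via_log(self):
        # far-tail magnitudes beyond double precision stay usable in log10
        _, log10p = binomial_upper_tail(900, 1000, 0.05)
        assert log10p < -700
        assert math.isfinite(log10p)


class TestBackgroundAndComposition:
    def test_single_residue(self):
        bg = background_from_sequences([ProteinRecord(id="a", sequence="AAAA")])
        assert bg["A"] == 1.0 and bg["G"] == 0.0

    def test_pooled_hand_count(self):
        bg = background_from_sequences(
            [ProteinRecord(id="a", sequence="AG"),
             ProteinRecord(id="b", sequence="GA")]
        )
        assert bg["A"] == 0.5 and bg["G"] == 0.5

    @given(st.lists(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
        min_size=1, max_size=5))
    def test_background_sums_to_one(self, seqs):
        recs = [ProteinRecord(id=f"r{i}", sequence=s)
                for i, s in enumerate(seqs)]
        assert sum(background_from_sequences(recs).values()) == pytest.approx(
            1.0, abs=1e-12)

    def test_composition_hand_count(self):
        frac = composition(ProteinRecord(id="p", sequence="GGS"))
        assert frac["G"] == pytest.approx(2 / 3)
        assert frac["S"] == pytest.approx(1 / 3)

    def test_composition_permutation_invariant(self):
        a = composition(ProteinRecord(id="p", sequence="GGSAT"))
        b = composition(ProteinRecord(id="p", sequence="TASGG"))
        assert a == b


class TestCompositionalBias:
    def test_unobserved_residue_has_p_one(self):
        bg = {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        results = compositional_bias(
            [ProteinRecord(id="a", sequence="AAAA")], bg)
        by_res = {r.residue: r for r in results}
        assert by_res["G"].observed_count == 0
        assert by_res["G"].p_bias == 1.0

    def test_enrichment_detected_against_uniform_background(self):
        bg = {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        seq = "G" * 50 + "AVLIPT" * 10
        results = compositional_bias([ProteinRecord(id="a", sequence=seq)], bg)
        by_res = {r.residue: r for r in results}
        assert by_res["G"].p_bias < 1e-10
        assert by_res["H"].p_bias == 1.0

    def test_matches_hand_binomial(self):
        bg = {aa: (0.1 if aa == "G" else 0.9 / 19)
              for aa in "ACDEFGHIKLMNPQRSTVWY"}
        seq = "GGGGGAVLIP"  # 5 G out of 10
        results = compositional_bias([ProteinRecord(id="a", sequence=seq)], bg)
        g = next(r for r in results if r.residue == "G")
        assert g.p_bias == pytest.approx(
            brute_force_upper_tail(5, 10, 0.1), rel=1e-10)

    def test_invalid_background_rejected(self):
        bg = {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        bg["A"] = 0.5
        with pytest.raises(ValueError, match="sum"):
            compositional_bias([ProteinRecord(id="a", sequence="AG")], bg)


class TestEvaluatePredictions:
    def test_perfect_prediction(self):
        s = evaluate_predictions({1, 2}, {1, 2}, {1, 2})
        assert (s.sensitivity, s.specificity, s.accuracy) == (1.0, None, 1.0)

    def test_hand_confusion_table(self):
        s = evaluate_predictions({2, 3}, {2}, {1, 2, 3, 4})
        assert (s.tp, s.fp, s.fn, s.tn) == (1, 1, 0, 2)
        assert s.sensitivity == 1.0
        assert s.specificity == pytest.approx(2 / 3)
        assert s.accuracy == 0.75
        assert s.precision == 0.5
        assert s.percent("specificity") == 67

    def test_subset_violation_listed(self):
        with pytest.raises(ValueError, match=r"\[9\]"):
            evaluate_predictions({9}, {1}, {1, 2})

    @given(st.sets(st.integers(1, 30)), st.data())
    def test_counts_partition_site_universe(self, all_sites, data):
        if not all_sites:
            all_sites = {1}
        known = data.draw(st.sets(st.sampled_from(sorted(all_sites))))
        pred = data.draw(st.sets(st.sampled_from(sorted(all_sites))))
        s = evaluate_predictions(pred, known, all_sites)
        assert s.tp + s.fp + s.tn + s.fn == len(all_sites)

    def test_report_layout(self):
        s = evaluate_predictions({2, 3}, {2}, {1, 2, 3, 4})
        report = format_confusion_report(s)
        assert "Positive sites found\t1" in report
        assert "Total sites found\t2" in report
        assert "Sensitivity\t100%" in report


class TestPearson:
    def test_perfect_correlation(self):
        r, _ = pearson([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        r, _ = pearson([1, 2, 3], [-1, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 4, 5, 4])
        r, p = pearson(x, y)
        # independent oracle: the raw product-moment formula plus the
        # t-distribution tail on n - 2 degrees of freedom
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(r_hand, rel=1e-12)
        from scipy.stats import t as tdist

        tstat = r_hand * math.sqrt((len(x) - 2) / (1 - r_hand**2))
        assert p == pytest.approx(2 * tdist.sf(abs(tstat), len(x) - 2),
                                  rel=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])
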
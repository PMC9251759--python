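"""FLR estimators: worked examples, filtering rules, q-values, thresholds."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flrkit as fk

from conftest import make_psm, make_table

CONFIG = fk.DecoyConfig(decoy_residue="A")


class TestModelFlr:
    def test_running_sum_of_local_flr(self):
        table = make_table([1.0, 0.9, 0.8], [False] * 3)
        assert fk.model_flr(table) == pytest.approx([0.0, 0.05, 0.10])

    def test_perfect_probabilities_give_zero(self):
        table = make_table([1.0] * 5, [False] * 5)
        assert fk.model_flr(table) == pytest.approx([0.0] * 5)

    def test_constant_probability_gives_constant_flr(self):
        table = make_table([0.7] * 4, [False] * 4)
        assert fk.model_flr(table) == pytest.approx([0.3] * 4)

    def test_missing_combined_probability_is_an_error(self):
        table = make_table([0.9], [False])
        table.sites[0].combined_probability = None
        with pytest.raises(ValueError, match="combined"):
            fk.model_flr(table)


class TestResidueCounting:
    def test_direct_count_on_one_peptide(self):
        counters = fk.count_residues([make_psm("ASTYAK", [2], [0.9])], CONFIG)
        assert (counters.target_count, counters.decoy_count) == (3, 2)

    def test_same_peptide_in_two_psms_counts_twice(self):
        psms = [
            make_psm("ASTYAK", [2], [0.9], spectrum_id="a"),
            make_psm("ASTYAK", [2], [0.9], spectrum_id="b"),
        ]
        counters = fk.count_residues(psms, CONFIG)
        assert (counters.target_count, counters.decoy_count) == (6, 4)
        unique = fk.count_residues(psms, CONFIG, unique_peptides=True)
        assert (unique.target_count, unique.decoy_count) == (3, 2)

    def test_absent_decoy_residue_is_an_error(self):
        with pytest.raises(ValueError, match="absent"):
            fk.count_residues([make_psm("STYK", [1], [0.9])], CONFIG)


class TestDecoyFlr:
    def test_no_decoy_sites_gives_zero(self):
        table = make_table([0.9] * 10, [False] * 10)
        counters = fk.FlrCounters(100, 100)
        assert fk.decoy_flr(table, counters) == pytest.approx([0.0] * 10)

    def test_parity_worked_example(self):
        # T_c = X_c, 5 decoy sites among the first 100 rows -> 2*1*5/100 = 0.10
        flags = [False] * 100
        for i in (10, 30, 50, 70, 90):
            flags[i] = True
        table = make_table([0.9] * 100, flags)
        flr = fk.decoy_flr(table, fk.FlrCounters(1000, 1000))
        assert flr[99] == pytest.approx(0.10)

    def test_ratio_three_worked_example(self):
        # T_c/X_c = 3, 2 decoy sites among 60 rows -> 2*3*2/60 = 0.20
        flags = [False] * 60
        flags[5] = flags[40] = True
        table = make_table([0.9] * 60, flags)
        flr = fk.decoy_flr(table, fk.FlrCounters(300, 100))
        assert flr[59] == pytest.approx(0.20)

    def test_estimate_is_capped_at_one(self):
        table = make_table([0.9] * 4, [True] * 4)
        flr = fk.decoy_flr(table, fk.FlrCounters(500, 10))
        assert np.all(flr <= 1.0) and flr[0] == 1.0


class TestAnswerKeyFlr:
    def test_all_matching_gives_zero(self):
        key = fk.AnswerKey.from_positions({"SA": [1]})
        table = make_table([0.9] * 3, [False] * 3)
        assert fk.answer_key_flr(table, key) == pytest.approx([0.0] * 3)

    def test_mismatch_at_top_then_matches(self):
        key = fk.AnswerKey.from_positions({"SA": [2], "AS": [1]})
        # decoy rows use peptide "AS" site 1 (matches), target rows "SA" site 1
        # (true position is 2 -> mismatch)
        table = make_table([0.9] * 3, [False, True, True])
        flr = fk.answer_key_flr(table, key)
        assert flr == pytest.approx([1.0, 1 / 2, 1 / 3])

    def test_missing_peptide_is_reported(self):
        key = fk.AnswerKey.from_positions({"WWW": [1]})
        table = make_table([0.9], [False])
        with pytest.raises(KeyError, match="SA"):
            fk.answer_key_flr(table, key)


class TestAnswerKeyFilter:
    def test_removal_reasons(self):
        key = fk.AnswerKey.from_positions({"ASTKY": [2]})
        keep = make_psm("ASTKY", [2], [0.9], spectrum_id="ok")
        count = make_psm("ASTKY", [2, 3], [0.9, 0.8], spectrum_id="count")
        partial = make_psm("STKY", [1], [0.9], spectrum_id="partial")
        unknown = make_psm("WWWW", [1], [0.9], spectrum_id="unknown")
        extra = make_psm("ASTKY", [2], [0.9], spectrum_id="extra",
                         other_modifications=("Oxidation",))
        kept, removed = fk.answer_key_filter([keep, count, partial, unknown, extra], key)
        assert [p.spectrum_id for p in kept] == ["ok"]
        reasons = {r.psm.spectrum_id: r.reason for r in removed}
        assert "count mismatch" in reasons["count"]
        assert reasons["partial"] == "partial peptide"
        assert reasons["unknown"] == "peptide not in key"
        assert reasons["extra"] == "additional modifications"


class TestQValues:
    def test_bottom_up_minimum(self):
        assert fk.to_q_values(np.array([0.0, 0.2, 0.1])) == pytest.approx([0.0, 0.1, 0.1])

    def test_monotone_input_is_a_fixed_point(self):
        raw = np.array([0.0, 0.05, 0.05, 0.2])
        assert fk.to_q_values(raw) == pytest.approx(raw)

    def test_out_of_range_raw_rejected(self):
        with pytest.raises(ValueError):
            fk.to_q_values(np.array([0.5, 1.2]))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_q_values_non_decreasing_and_below_raw(self, raw):
        raw = np.array(raw)
        q = fk.to_q_values(raw)
        assert np.all(np.diff(q) >= 0)
        assert np.all(q <= raw + 1e-12)


class TestThreshold:
    def test_direct_scan(self):
        table = make_table([0.9, 0.8, 0.7], [False, True, False])
        result = fk.threshold_at(table, np.array([0.001, 0.02, 0.06]), alpha=0.05)
        assert result.n_rows == 2
        assert result.target_site_count == 1
        assert result.decoy_site_count == 1

    def test_nothing_passes(self):
        table = make_table([0.9] * 3, [False] * 3)
        result = fk.threshold_at(table, np.array([0.2, 0.3, 0.4]), alpha=0.05)
        assert result.n_rows == 0 and not result.attained

    def test_alpha_one_accepts_all(self):
        table = make_table([0.9] * 3, [False] * 3)
        assert fk.threshold_at(table, np.array([0.2, 0.3, 0.4]), alpha=1.0).n_rows == 3

    def test_monotone_in_alpha(self):
        table = make_table([0.9] * 5, [False] * 5)
        q = np.array([0.01, 0.02, 0.04, 0.08, 0.2])
        counts = [fk.threshold_at(table, q, a).n_rows for a in (0.01, 0.03, 0.05, 0.1, 1.0)]
        assert counts == sorted(counts)

    def test_invalid_alpha(self):
        table = make_table([0.9], [False])
        with pytest.raises(ValueError, match="alpha"):
            fk.threshold_at(table, np.array([0.1]), alpha=0.0)


def brute_force_estimates(probs, decoy_flags, false_flags, counters):
    """Independent per-row recomputation with exact rational arithmetic."""
    model, decoy, key = [], [], []
    for n in range(1, len(probs) + 1):
        model.append(sum(Fraction(1) - p for p in probs[:n]) / n)
        raw = (
            2 * Fraction(counters.target_count, counters.decoy_count)
            * sum(decoy_flags[:n]) / n
        )
        decoy.append(min(Fraction(1), raw))
        key.append(Fraction(sum(false_flags[:n]), n))
    return model, decoy, key


class TestBruteForceEquivalence:
    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_estimators_match_exact_recomputation(self, data):
        n = data.draw(st.integers(min_value=1, max_value=30))
        # dyadic probabilities are exact in binary floating point
        probs = [
            Fraction(data.draw(st.integers(0, 256)), 256) for _ in range(n)
        ]
        decoy_flags = [data.draw(st.booleans()) for _ in range(n)]
        false_flags = [data.draw(st.booleans()) for _ in range(n)]
        counters = fk.FlrCounters(
            data.draw(st.integers(1, 50)), data.draw(st.integers(1, 50))
        )
        table = make_table([float(p) for p in probs], decoy_flags)
        key_entries = {}
        for site, false in zip(table.sites, false_flags):
            # register a per-row peptide so the answer key marks it as desired
            site.psm.peptide = site.psm.spectrum_id.replace("row", "S" * 1) + "SA"
            pep = site.psm.peptide
            site.site_position = 1 if not false else len(pep)
            site.psm.mod_positions = [site.site_position]
            key_entries[pep] = [1]
        key = fk.AnswerKey.from_positions(key_entries)
        model, decoy, keyflr = brute_force_estimates(probs, decoy_flags, false_flags, counters)
        assert fk.model_flr(table) == pytest.approx([float(x) for x in model], abs=1e-12)
        assert fk.decoy_flr(table, counters) == pytest.approx([float(x) for x in decoy], abs=1e-12)
        assert fk.answer_key_flr(table, key) == pytest.approx([float(x) for x in keyflr], abs=1e-12)
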
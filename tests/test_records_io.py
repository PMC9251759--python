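"""Domain types, validation, and interchange round-trips."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flrkit as fk
from flrkit import io
from flrkit.records import AMINO_ACIDS

from conftest import make_psm


class TestDecoyConfig:
    def test_decoy_must_not_be_a_target(self):
        with pytest.raises(ValueError, match="target"):
            fk.DecoyConfig(decoy_residue="S")

    def test_candidates_are_targets_plus_decoy(self):
        config = fk.DecoyConfig(decoy_residue="A")
        assert config.candidate_residues == frozenset("STYA")
        assert fk.DecoyConfig(decoy_residue=None).candidate_residues == frozenset("STY")


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs, expect_field",
        [
            (dict(peptide="ASK", positions=[2], ptm_probs=[0.9]), None),
            (dict(peptide="ASK", positions=[4], ptm_probs=[0.9]), "mod_positions"),
            (dict(peptide="ASK", positions=[2], ptm_probs=[0.9], psm_prob=1.3), "psm_probability"),
            (dict(peptide="ASK", positions=[2, 1], ptm_probs=[0.9, 0.8]), "mod_positions"),
            (dict(peptide="ASK", positions=[2], ptm_probs=[0.9, 0.8]), "ptm_probabilities"),
            (dict(peptide="ASK", positions=[2], ptm_probs=[0.9], psm_prob=None), "psm_probability"),
            (dict(peptide="aZk", positions=[2], ptm_probs=[0.9]), "peptide"),
        ],
    )
    def test_invariant_violations_are_located(self, kwargs, expect_field):
        issues = fk.validate_table([make_psm(**kwargs)])
        if expect_field is None:
            assert issues == []
        else:
            assert any(i.field == expect_field and i.row == 0 for i in issues)

    def test_validation_reports_all_rows_without_mutating(self):
        records = [
            make_psm("ASK", [2], [0.9]),
            make_psm("ASK", [9], [0.9], spectrum_id="s2"),
        ]
        before = [r.mod_positions[:] for r in records]
        issues = fk.validate_table(records)
        assert [i.row for i in issues] == [1]
        assert [r.mod_positions for r in records] == before


peptides = st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=25)
probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


@st.composite
def psm_records(draw, index=0):
    peptide = draw(peptides)
    n_mods = draw(st.integers(min_value=1, max_value=min(3, len(peptide))))
    positions = sorted(
        draw(
            st.lists(
                st.integers(min_value=1, max_value=len(peptide)),
                min_size=n_mods,
                max_size=n_mods,
                unique=True,
            )
        )
    )
    return fk.PsmRecord(
        spectrum_id=f"spec{draw(st.integers(min_value=0, max_value=10 ** 6))}",
        peptide=peptide,
        charge=draw(st.integers(min_value=1, max_value=5)),
        mod_positions=positions,
        ptm_probabilities=[draw(probs) for _ in positions],
        psm_probability=draw(probs),
        psm_score=draw(st.none() | st.floats(-100, 100, allow_nan=False)),
        protein_accessions=[f"P{draw(st.integers(0, 99))}"],
        is_decoy_protein=draw(st.booleans()),
        is_contaminant=draw(st.booleans()),
    )


class TestInterchangeTsv:
    @settings(max_examples=50, deadline=None)
    @given(records=st.lists(psm_records(), min_size=0, max_size=8))
    def test_round_trip_reproduces_field_values(self, tmp_path_factory, records):
        path = tmp_path_factory.mktemp("io") / "psms.tsv"
        io.write_psm_table(records, path)
        back = io.read_psm_table(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert (a.spectrum_id, a.peptide, a.charge) == (b.spectrum_id, b.peptide, b.charge)
            assert a.mod_positions == b.mod_positions
            assert a.ptm_probabilities == pytest.approx(b.ptm_probabilities)
            assert a.psm_probability == pytest.approx(b.psm_probability)
            assert (a.is_decoy_protein, a.is_contaminant) == (b.is_decoy_protein, b.is_contaminant)

    def test_header_only_file_parses_to_empty(self, tmp_path):
        path = tmp_path / "empty.tsv"
        io.write_psm_table([], path)
        assert io.read_psm_table(path) == []

    def test_malformed_row_is_located_not_dropped(self, tmp_path):
        path = tmp_path / "bad.tsv"
        io.write_psm_table([make_psm("ASK", [2], [0.9])], path)
        text = path.read_text().replace("\t2\t", "\ttwo\t")
        path.write_text(text)
        with pytest.raises(io.TableFormatError, match="row 2"):
            io.read_psm_table(path)

    def test_mixed_native_and_missing_probabilities_rejected(self, tmp_path):
        records = [
            make_psm("ASK", [2], [0.9], spectrum_id="a"),
            make_psm("ASK", [2], [0.9], psm_prob=None, spectrum_id="b"),
        ]
        records[1].psm_score = 12.0
        path = tmp_path / "mixed.tsv"
        io.write_psm_table(records, path)
        with pytest.raises(io.TableFormatError, match="mixed"):
            io.read_psm_table(path)


class TestAnswerKeyAndSites:
    def test_answer_key_round_trip_and_partial_detection(self, tmp_path):
        key = fk.AnswerKey.from_positions({"ASTKY": [2], "MSSR": [2, 3]})
        path = tmp_path / "key.tsv"
        io.write_answer_key(key, path)
        back = io.read_answer_key(path)
        assert back.true_positions("ASTKY") == frozenset({2})
        assert back.expected_mod_count("MSSR") == 2
        assert back.is_partial("SSR")
        assert not back.is_partial("ASTKY")
        assert not back.is_partial("WWWW")

    def test_answer_key_position_outside_peptide_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            fk.AnswerKey.from_positions({"ASK": [7]})

    def test_site_table_round_trip_shares_psm_per_spectrum(self, tmp_path):
        psm = make_psm("ASTK", [2, 3], [0.9, 0.8], psm_prob=0.95)
        sites = fk.expand_to_sites([psm], fk.DecoyConfig(decoy_residue="A"))
        path = tmp_path / "sites.tsv"
        io.write_site_table(sites, path)
        back = io.read_site_table(path)
        assert len(back) == 2
        assert back[0].psm is back[1].psm  # one PSM object per spectrum
        assert [s.site_position for s in back] == [2, 3]
        assert back[0].combined_probability == pytest.approx(0.95 * 0.9)
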
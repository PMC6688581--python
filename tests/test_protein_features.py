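"""Protein sequence/structure feature computations against hand oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaffinity.protein_features import (DsspParseError, DsspResidue,
                                         ResiduePropertyTable,
                                         SecondaryStructureRecord,
                                         compute_protein_features,
                                         hydrogen_bond_total, parse_dssp,
                                         protein_molecular_mass,
                                         residue_class_counts,
                                         secondary_structure_features,
                                         total_rasa)

seqs = st.text(alphabet="ARNDCEQGHILKMFPSTWYV", min_size=1, max_size=60)


def _ssr(ss_string, acc=None, chain="A", aa_seq=None):
    acc = acc if acc is not None else [10] * len(ss_string)
    aa_seq = aa_seq or "A" * len(ss_string)
    return SecondaryStructureRecord([
        DsspResidue(chain_id=chain, seq_number=i + 1, insertion_code="",
                    aa=aa, ss_code=c, accessibility=float(a))
        for i, (c, a, aa) in enumerate(zip(ss_string, acc, aa_seq))])


class TestPropertyTable:
    def test_default_table_complete(self, prop_table):
        assert set(prop_table.mass) == set("ARNDCEQGHILKMFPSTWYV")
        assert not (prop_table.classes["hydrophilic"]
                    & prop_table.classes["hydrophobic"])

    def test_glycine_mass(self, prop_table):
        assert prop_table.mass["G"] == pytest.approx(75.07)

    def test_overlapping_partition_rejected(self, prop_table):
        bad = {"mass": prop_table.mass, "hbond": prop_table.hbond,
               "classes": {**{k: list(v) for k, v
                              in prop_table.classes.items()},
                           "hydrophilic": ["A", "R"]}}
        with pytest.raises(ValueError, match="overlap"):
            ResiduePropertyTable.from_dict(bad)


class TestSequenceFeatures:
    def test_single_glycine(self, prop_table):
        assert protein_molecular_mass("G", prop_table) == \
            pytest.approx(prop_table.mass["G"])

    def test_mass_additivity(self, prop_table):
        assert protein_molecular_mass("GG", prop_table) == \
            pytest.approx(2 * prop_table.mass["G"])

    def test_unknown_residue_skipped(self, prop_table):
        assert protein_molecular_mass("GXG", prop_table) == \
            pytest.approx(2 * prop_table.mass["G"])

    def test_empty_sequence_is_error(self, prop_table):
        with pytest.raises(ValueError):
            protein_molecular_mass("", prop_table)
        with pytest.raises(ValueError):
            hydrogen_bond_total("", prop_table)
        with pytest.raises(ValueError):
            residue_class_counts("", prop_table)

    def test_hbond_additivity(self, prop_table):
        assert hydrogen_bond_total("GG", prop_table) == \
            2 * prop_table.hbond["G"]

    @settings(derandomize=True, max_examples=50)
    @given(seq=seqs)
    def test_hbond_matches_character_loop(self, seq, prop_table):
        expected = 0
        for ch in seq:
            expected += prop_table.hbond[ch]
        assert hydrogen_bond_total(seq, prop_table) == expected

    def test_saturated_class_is_100_percent(self, prop_table):
        counts = residue_class_counts("KKKK", prop_table)
        assert counts["n_charged"] == 4
        assert counts["pct_charged"] == pytest.approx(100.0)

    def test_charged_set(self, prop_table):
        assert residue_class_counts("KRDE", prop_table)["n_charged"] == 4

    @settings(derandomize=True, max_examples=50)
    @given(seq=seqs)
    def test_hydropathy_classes_are_exclusive(self, seq, prop_table):
        counts = residue_class_counts(seq, prop_table)
        assert counts["n_hydrophilic"] + counts["n_hydrophobic"] <= len(seq)
        for group in ("hydrophilic", "hydrophobic", "aromatic_positive",
                      "charged", "polar"):
            assert 0.0 <= counts[f"pct_{group}"] <= 100.0

    @settings(derandomize=True, max_examples=30)
    @given(seq=seqs)
    def test_percentages_invariant_under_duplication(self, seq, prop_table):
        once = residue_class_counts(seq, prop_table)
        twice = residue_class_counts(seq * 2, prop_table)
        for group in ("hydrophilic", "polar"):
            assert twice[f"pct_{group}"] == \
                pytest.approx(once[f"pct_{group}"])
            assert twice[f"n_{group}"] == 2 * once[f"n_{group}"]

    @settings(derandomize=True, max_examples=30)
    @given(seq=seqs)
    def test_counts_permutation_invariant(self, seq, prop_table):
        shuffled = "".join(sorted(seq))
        assert residue_class_counts(seq, prop_table) == \
            residue_class_counts(shuffled, prop_table)


class TestParseDssp:
    def test_fixture_residue_count(self, toy_files):
        ssr = parse_dssp(toy_files.dssp_text)
        assert len(ssr) == 35

    def test_chain_break_skipped(self, toy_files):
        lines = toy_files.dssp_text.splitlines()
        break_line = lines[10][:13] + "!" + lines[10][14:]
        text = "\n".join(lines[:10] + [break_line] + lines[10:])
        ssr = parse_dssp(text)
        assert len(ssr) == 35

    def test_empty_text_is_error(self):
        with pytest.raises(DsspParseError):
            parse_dssp("")

    def test_missing_header_is_error(self):
        with pytest.raises(DsspParseError, match="header"):
            parse_dssp("just some text\nwithout a ruler\n")


class TestSecondaryStructure:
    def test_all_coil_is_zero(self, prop_table):
        feats = secondary_structure_features(_ssr("CCCCC"), "AAAAA",
                                             prop_table)
        assert feats["helix_count"] == 0
        assert feats["sheet_mass"] == 0
        assert feats["helix_pct"] == 0

    def test_hand_counted_mixed_string(self, prop_table):
        feats = secondary_structure_features(_ssr("HHHHEEECCC"),
                                             "AAAAAAAAAA", prop_table)
        assert feats["helix_count"] == 4
        assert feats["sheet_count"] == 3
        assert feats["helix_pct"] == pytest.approx(40.0)
        assert feats["sheet_pct"] == pytest.approx(30.0)
        assert feats["helix_segments"] == 1
        assert feats["sheet_segments"] == 1

    def test_helix_mass_of_glycines(self, prop_table):
        feats = secondary_structure_features(_ssr("HHHCC", aa_seq="GGGGG"),
                                             "GGGGG", prop_table)
        assert feats["helix_mass"] == pytest.approx(3 * prop_table.mass["G"])

    def test_length_mismatch_is_error(self, prop_table):
        with pytest.raises(ValueError, match="join"):
            secondary_structure_features(_ssr("HH"), "AAA", prop_table)

    def test_g_and_i_codes_count_as_helix(self, prop_table):
        feats = secondary_structure_features(_ssr("GIHBE"), "AAAAA",
                                             prop_table)
        assert feats["helix_count"] == 3
        assert feats["sheet_count"] == 2


class TestTotalRasa:
    def test_forced_sum(self):
        assert total_rasa(_ssr("CCC", acc=[10, 20, 30])) == \
            pytest.approx(60.0)

    def test_all_zero(self):
        assert total_rasa(_ssr("CC", acc=[0, 0])) == 0.0

    def test_matches_loop_oracle(self, rng):
        acc = rng.integers(0, 250, size=40)
        expected = 0.0
        for a in acc:
            expected += float(a)
        assert total_rasa(_ssr("C" * 40, acc=acc)) == pytest.approx(expected)

    def test_negative_accessibility_is_error(self):
        record = _ssr("C", acc=[5])
        object.__setattr__(record.residues[0], "accessibility", -1.0)
        with pytest.raises(ValueError):
            total_rasa(record)


def test_feature_block_covers_both_families(prop_table, toy_files):
    ssr = parse_dssp(toy_files.dssp_text)
    block = compute_protein_features(toy_files.protein_seq, prop_table, ssr)
    assert set(block.structure) >= {"helix_count", "total_rasa"}
    assert block.sequence["protein_molecular_mass"] > 0
    assert np.isfinite(list(block.as_dict().values())).all()
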
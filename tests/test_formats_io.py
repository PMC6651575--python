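"""I/O contracts: parsing, validation, filtering, and round-trips."""

import numpy as np
import pytest

from memlig.formats_io import (
    FormatError,
    PredictionRecord,
    ProteinRecord,
    PSSMProfile,
    TopologyAnnotation,
    read_annotations,
    read_fasta,
    read_predictions,
    read_pssm,
    read_topology,
    write_annotations,
    write_fasta,
    write_predictions,
    write_pssm,
    write_topology,
)


def _write(path, text):
    path.write_text(text)
    return path


class TestReadFasta:
    def test_canonical_sequence_passes_filters(self, tmp_path):
        f = _write(tmp_path / "a.fasta", ">P1\n" + "ACDEFGHIKL" * 6 + "\n")
        kept, reports = read_fasta(f, min_length=50)
        assert len(kept) == 1 and not reports
        assert kept[0].length == 60

    def test_short_sequence_reported_not_silently_dropped(self, tmp_path):
        f = _write(tmp_path / "a.fasta", ">P1\n" + "ACDEFGHIKL" * 4 + "\n")
        kept, reports = read_fasta(f, min_length=50)
        assert kept == []
        assert len(reports) == 1 and "min_length" in reports[0].reason

    def test_ambiguous_residue_excluded_with_reason(self, tmp_path):
        f = _write(tmp_path / "a.fasta", ">P1\n" + "ACDEF" * 11 + "X\n")
        kept, reports = read_fasta(f, min_length=50, drop_ambiguous=True)
        assert kept == []
        assert "ambiguous" in reports[0].reason and "X" in reports[0].reason

    def test_kept_plus_excluded_equals_total(self, tmp_path):
        seqs = [
            ("OK1", "ACDEFGHIKL" * 6),
            ("SHORT", "ACDEF"),
            ("AMBIG", "ACDEFGHIKX" * 6),
            ("OK2", "MKLVW" * 12),
        ]
        f = _write(
            tmp_path / "a.fasta",
            "".join(f">{n}\n{s}\n" for n, s in seqs),
        )
        kept, reports = read_fasta(f, min_length=50)
        assert len(kept) + len(reports) == len(seqs)
        assert [p.id for p in kept] == ["OK1", "OK2"]

    def test_empty_file_is_explicit_error(self, tmp_path):
        f = _write(tmp_path / "a.fasta", "")
        with pytest.raises(FormatError, match="empty"):
            read_fasta(f)

    def test_fasta_round_trip(self, tmp_path):
        prot = ProteinRecord(id="P1", sequence="ACDEFGHIKLMNPQRSTVWY" * 4)
        write_fasta(tmp_path / "o.fasta", [prot])
        kept, _ = read_fasta(tmp_path / "o.fasta", min_length=50)
        assert kept[0].sequence == prot.sequence


PSSM_5ROW = """
Last position-specific scoring matrix computed, weighted

           A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 A   4  -1  -2  -2   0  -1  -1   0  -2  -1  -1  -1  -1  -2  -1   1   0  -3  -2   0
    2 C   0  -3  -3  -3   9  -3  -4  -3  -3  -1  -1  -3  -1  -2  -3  -1  -1  -2  -2  -1
    3 D  -2  -2   1   6  -3   0   2  -1  -1  -3  -4  -1  -3  -3  -1   0  -1  -4  -3  -3
    4 E  -1   0   0   2  -4   2   5  -2   0  -3  -3   1  -2  -3  -1   0  -1  -3  -2  -2
    5 F  -2  -3  -3  -3  -2  -3  -3  -3  -1   0   0  -3   0   6  -4  -2  -2   1   3  -1
"""


class TestReadPssm:
    def test_row_and_column_counts(self, tmp_path):
        f = _write(tmp_path / "p.pssm", PSSM_5ROW)
        prof = read_pssm(f)
        assert prof.scores.shape == (5, 20)
        assert prof.scores[1, 4] == 9  # C row, C column

    def test_sequence_mismatch_names_position(self, tmp_path):
        f = _write(tmp_path / "p.pssm", PSSM_5ROW)
        with pytest.raises(FormatError, match="position 3"):
            read_pssm(f, sequence="ACREF")

    def test_matching_sequence_accepted(self, tmp_path):
        f = _write(tmp_path / "p.pssm", PSSM_5ROW)
        prof = read_pssm(f, sequence="ACDEF")
        assert prof.length == 5

    def test_all_zero_matrix_is_legal(self, tmp_path):
        rows = "\n".join(
            f"    {i + 1} A " + "  0" * 20 for i in range(3)
        )
        f = _write(tmp_path / "p.pssm", "header\n\n" + rows + "\n")
        prof = read_pssm(f)
        assert np.all(prof.scores == 0)

    def test_short_row_raises_with_line_number(self, tmp_path):
        bad = "\n\n    1 A   1   2   3\n"
        f = _write(tmp_path / "p.pssm", bad)
        with pytest.raises(FormatError, match="expected at least 20"):
            read_pssm(f)

    def test_write_read_round_trip(self, tmp_path):
        seq = "ACDEF"
        scores = np.arange(100).reshape(5, 20).astype(float)
        prof = PSSMProfile("P1", scores)
        write_pssm(tmp_path / "p.pssm", prof, seq)
        back = read_pssm(tmp_path / "p.pssm", sequence=seq)
        assert np.array_equal(back.scores, scores)

    def test_trailing_columns_ignored(self, tmp_path):
        # PSI-BLAST files carry 40 score columns plus two trailing floats
        row = "    1 A " + " ".join(str(v) for v in range(1, 21))
        row += "  " + " ".join("50" for _ in range(20)) + "  0.36 0.12"
        f = _write(tmp_path / "p.pssm", "\n\n" + row + "\n")
        prof = read_pssm(f)
        assert prof.scores.shape == (1, 20)
        assert list(prof.scores[0]) == list(range(1, 21))


class TestTopology:
    def test_round_trip(self, tmp_path):
        t = TopologyAnnotation("P1", "IIIMMMOOO")
        write_topology(tmp_path / "t.txt", [t])
        back = read_topology(tmp_path / "t.txt")
        assert back["P1"].states == "IIIMMMOOO"

    def test_invalid_state_rejected(self):
        with pytest.raises(FormatError, match="invalid state"):
            TopologyAnnotation("P1", "IIZMO")

    def test_multi_record_file(self, tmp_path):
        f = _write(tmp_path / "t.txt", ">A\nIIII\n>B\nMMOU\nUU\n")
        back = read_topology(f)
        assert back["A"].states == "IIII"
        assert back["B"].states == "MMOUUU"


class TestAnnotations:
    def _protein(self, n=10):
        return ProteinRecord(id="P1", sequence="ACDEFGHIKL"[:n])

    def test_out_of_range_index_names_protein(self, tmp_path):
        f = _write(tmp_path / "ann.tsv",
                   "protein_id\tresidue_index\tligand_category\nP1\t11\tmetal\n")
        with pytest.raises(FormatError, match=r"11.*P1.*length 10"):
            read_annotations(f, [self._protein()])

    def test_unknown_category_lists_allowed(self, tmp_path):
        f = _write(tmp_path / "ann.tsv",
                   "protein_id\tresidue_index\tligand_category\nP1\t2\tsugar\n")
        with pytest.raises(FormatError, match="drug, metal, biomacromolecule"):
            read_annotations(f, [self._protein()])

    def test_multi_ligand_residue_accumulates_categories(self, tmp_path):
        f = _write(
            tmp_path / "ann.tsv",
            "protein_id\tresidue_index\tligand_category\n"
            "P1\t4\tmetal\nP1\t4\tdrug\n",
        )
        prot = self._protein()
        read_annotations(f, [prot])
        assert prot.binding_mask[3]
        assert prot.ligand_categories[3] == {"metal", "drug"}
        assert prot.binding_mask.sum() == 1

    def test_unknown_protein_is_hard_error(self, tmp_path):
        f = _write(tmp_path / "ann.tsv",
                   "protein_id\tresidue_index\tligand_category\nP9\t1\tmetal\n")
        with pytest.raises(FormatError, match="P9"):
            read_annotations(f, [self._protein()])

    def test_annotation_round_trip(self, tmp_path):
        prot = self._protein()
        prot.ligand_categories[2] = frozenset({"metal"})
        prot.ligand_categories[5] = frozenset({"drug", "biomacromolecule"})
        prot.binding_mask = np.array([len(c) > 0 for c in prot.ligand_categories])
        write_annotations(tmp_path / "ann.tsv", [prot])
        fresh = self._protein()
        read_annotations(tmp_path / "ann.tsv", [fresh])
        assert list(fresh.binding_mask) == list(prot.binding_mask)
        assert fresh.ligand_categories == prot.ligand_categories


def test_prediction_table_round_trip(tmp_path):
    records = [
        PredictionRecord("P1", 3, "H", 0.875, True, "metal"),
        PredictionRecord("P2", 1, "A", 0.125, False, "universal"),
    ]
    write_predictions(tmp_path / "pred.tsv", records)
    back = read_predictions(tmp_path / "pred.tsv")
    assert back == records


def test_protein_record_rejects_ambiguity_codes():
    with pytest.raises(FormatError, match="non-canonical"):
        ProteinRecord(id="P1", sequence="ACDXE")
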
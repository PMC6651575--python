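"""Encoder contracts: window geometry, segment contents, dimension invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memlig.encoders import (
    DEFAULT_PCP,
    GAP,
    N_PCP,
    PCPTable,
    encode_pcp,
    encode_protein,
    encode_pssm,
    encode_residue,
    encode_seqseg,
    encode_topo,
    extract_window,
    feature_names,
    pseudo_pssm,
    segment_slices,
    total_dim,
)
from memlig.formats_io import (
    PSSM_ALPHABET,
    FormatError,
    ProteinRecord,
    PSSMProfile,
    TopologyAnnotation,
)

SEQ9 = "ACDEFGHIK"


def _record(seq=SEQ9):
    return ProteinRecord(id="P", sequence=seq)


class TestExtractWindow:
    def test_interior_window_has_no_gaps(self):
        win = extract_window(_record(), 4)
        assert [aa for _, aa in win] == list("CDEFGHI")

    def test_n_terminus_pads_with_leading_gaps(self):
        win = extract_window(_record(), 0)
        assert [aa for _, aa in win] == [GAP, GAP, GAP, "A", "C", "D", "E"]

    def test_c_terminus_pads_with_trailing_gaps(self):
        win = extract_window(_record(), 8)
        # center 8 of a 9-residue sequence covers positions 5..11
        assert [aa for _, aa in win] == ["G", "H", "I", "K", GAP, GAP, GAP]

    def test_out_of_range_index_raises(self):
        with pytest.raises(IndexError):
            extract_window(_record(), 9)


class TestEncodePssm:
    def test_zero_profile_gives_zero_vector(self):
        prof = PSSMProfile("P", np.zeros((9, 20)))
        vec = encode_pssm(extract_window(_record(), 4), prof)
        assert vec.shape == (140,) and not vec.any()

    def test_terminus_gap_rows_are_zero(self):
        prof = PSSMProfile("P", np.ones((9, 20)))
        vec = encode_pssm(extract_window(_record(), 0), prof)
        assert not vec[:60].any()
        assert vec[60:].all()

    def test_row_constant_profile_lays_out_window_order(self):
        # row i holds the constant i; center 3 of a 7-residue protein
        rec = _record("ACDEFGH")
        prof = PSSMProfile("P", np.tile(np.arange(7)[:, None], (1, 20)))
        vec = encode_pssm(extract_window(rec, 3), prof)
        expected = np.repeat(np.arange(7), 20).astype(float)
        assert np.array_equal(vec, expected)


class TestEncodeTopo:
    def test_counts_in_fixed_iomu_order(self):
        topo = TopologyAnnotation("P", "IIIMMOOOO")
        win = extract_window(_record(), 3)  # covers positions 0..6
        counts = encode_topo(win, topo)
        assert list(counts) == [3, 2, 2, 0]

    def test_terminus_counts_only_in_bounds(self):
        topo = TopologyAnnotation("P", "M" * 9)
        counts = encode_topo(extract_window(_record(), 0), topo)
        assert list(counts) == [0, 0, 4, 0]

    def test_all_unknown_full_window(self):
        topo = TopologyAnnotation("P", "U" * 9)
        counts = encode_topo(extract_window(_record(), 4), topo)
        assert list(counts) == [0, 0, 0, 7]


class TestPCPTable:
    def test_exactly_15_properties_defined_for_all_residues(self):
        assert len(DEFAULT_PCP.property_names) == N_PCP
        for name in DEFAULT_PCP.property_names:
            assert set(DEFAULT_PCP.raw[name]) == set(PSSM_ALPHABET)

    def test_minmax_normalization_hits_zero_and_one(self):
        # brute force: per property, min maps to 0 and max to 1
        for name in DEFAULT_PCP.property_names:
            vals = [DEFAULT_PCP.normalized[name][aa] for aa in PSSM_ALPHABET]
            assert min(vals) == 0.0 and max(vals) == 1.0
            raw = DEFAULT_PCP.raw[name]
            lo_aa = min(raw, key=raw.get)
            assert DEFAULT_PCP.normalized[name][lo_aa] == 0.0

    def test_identical_residue_window_repeats_block(self):
        rec = _record("AAAAAAAAA")
        vec = encode_pcp(extract_window(rec, 4))
        block = vec[:N_PCP]
        assert np.array_equal(vec, np.tile(block, 7))

    def test_leading_gaps_zero_first_blocks(self):
        vec = encode_pcp(extract_window(_record(), 0))
        assert not vec[: 3 * N_PCP].any()

    def test_wrong_property_count_rejected(self):
        raw = {f"p{i}": dict.fromkeys(PSSM_ALPHABET, 0.0) for i in range(14)}
        with pytest.raises(ValueError, match="15"):
            PCPTable(raw=raw)


class TestEncodeSeqseg:
    def test_composition_counts(self):
        rec = _record("AAACDEG")
        counts = encode_seqseg(extract_window(rec, 3))
        by_aa = dict(zip(PSSM_ALPHABET, counts))
        assert by_aa["A"] == 3
        assert by_aa["C"] == by_aa["D"] == by_aa["E"] == by_aa["G"] == 1
        assert counts.sum() == 7

    def test_terminus_counts_sum_to_in_bounds_size(self):
        counts = encode_seqseg(extract_window(_record(), 0))
        assert counts.sum() == 4


class TestAssembly:
    def test_segment_sizes_and_total(self, sim_small):
        p = sim_small.proteins[0]
        v = encode_residue(p, 5, sim_small.profiles[p.id], sim_small.topologies[p.id])
        assert (len(v.pssm), len(v.topo), len(v.pcp), len(v.seqseg)) == (140, 4, 105, 20)
        assert len(v.full) == 269 == total_dim()

    def test_full_vector_slices_reproduce_segments(self, sim_small):
        p = sim_small.proteins[1]
        v = encode_residue(p, 0, sim_small.profiles[p.id], sim_small.topologies[p.id])
        sl = segment_slices()
        assert np.array_equal(v.full[sl["pssm"]], v.pssm)
        assert np.array_equal(v.full[sl["topo"]], v.topo)
        assert np.array_equal(v.full[sl["pcp"]], v.pcp)
        assert np.array_equal(v.full[sl["seqseg"]], v.seqseg)

    def test_encode_protein_matches_per_residue_path(self, sim_small):
        p = sim_small.proteins[2]
        X = encode_protein(p, sim_small.profiles[p.id], sim_small.topologies[p.id])
        assert X.shape == (p.length, 269)
        for i in (0, 1, p.length // 2, p.length - 1):
            v = encode_residue(p, i, sim_small.profiles[p.id], sim_small.topologies[p.id])
            assert np.allclose(X[i], v.full)

    def test_length_mismatch_raises(self):
        rec = _record()
        prof = PSSMProfile("P", np.zeros((8, 20)))
        topo = TopologyAnnotation("P", "I" * 9)
        with pytest.raises(FormatError, match="profile length"):
            encode_residue(rec, 0, prof, topo)

    def test_feature_names_align_with_dimension(self):
        names = feature_names()
        assert len(names) == 269
        assert names[0] == "pssm_0" and names[140] == "topo_I"
        assert names[144] == "pcp_0" and names[249] == "aa_A"


@st.composite
def random_protein(draw):
    seq = draw(st.text(alphabet=PSSM_ALPHABET, min_size=1, max_size=40))
    states = draw(st.text(alphabet="IOMU", min_size=len(seq), max_size=len(seq)))
    return seq, states


class TestProperties:
    @given(random_protein(), st.data())
    @settings(max_examples=40, deadline=None)
    def test_dimension_and_count_invariants(self, prot, data):
        seq, states = prot
        rec = ProteinRecord(id="P", sequence=seq)
        idx = data.draw(st.integers(min_value=0, max_value=len(seq) - 1))
        prof = pseudo_pssm(seq)
        topo = TopologyAnnotation("P", states)
        v = encode_residue(rec, idx, prof, topo)
        assert len(v.full) == 269
        in_bounds = sum(
            1 for p in range(idx - 3, idx + 4) if 0 <= p < len(seq)
        )
        assert v.topo.sum() == v.seqseg.sum() == in_bounds

    @given(random_protein())
    @settings(max_examples=20, deadline=None)
    def test_encoding_is_deterministic(self, prot):
        seq, states = prot
        rec = ProteinRecord(id="P", sequence=seq)
        prof = pseudo_pssm(seq)
        topo = TopologyAnnotation("P", states)
        a = encode_protein(rec, prof, topo)
        b = encode_protein(rec, prof, topo)
        assert np.array_equal(a, b)

    def test_shifting_center_shifts_pssm_blocks(self, sim_small):
        p = sim_small.proteins[0]
        prof, topo = sim_small.profiles[p.id], sim_small.topologies[p.id]
        i = 10
        a = encode_residue(p, i, prof, topo).pssm
        b = encode_residue(p, i + 1, prof, topo).pssm
        # slots 1..6 of window i equal slots 0..5 of window i+1
        assert np.array_equal(a[20:], b[:120])


class TestPseudoPssm:
    def test_deterministic_and_length_matched(self):
        a = pseudo_pssm("ACDEF")
        b = pseudo_pssm("ACDEF")
        assert np.array_equal(a.scores, b.scores)
        assert a.length == 5 and a.source == "pseudo"

    def test_rows_come_from_substitution_table(self):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        prof = pseudo_pssm("A")
        expected = [blosum["A", b] for b in PSSM_ALPHABET]
        assert list(prof.scores[0]) == expected
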
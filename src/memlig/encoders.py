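"""Residue feature encoders: the 269-dimensional hybrid vector.

Each residue is described through a sliding window of 7 residues (3
upstream, the target, 3 downstream) by four concatenated feature
segments, in this fixed order:

====== ===== =========================================================
segment  dim  content
====== ===== =========================================================
pssm    140  the 7 window rows of the L x 20 evolutionary profile
topo      4  counts of I, O, M, U topology states in the window
pcp     105  15 physicochemical property values for each window residue
seqseg   20  amino-acid composition counts of the window residues
====== ===== =========================================================

Total: 140 + 4 + 105 + 20 = 269.

Window positions falling outside the sequence contribute zero rows to
the pssm and pcp segments and are simply not counted in topo and seqseg
(so ``sum(topo) == sum(seqseg) ==`` number of in-bounds positions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from memlig.formats_io import (
    PSSM_ALPHABET,
    TOPOLOGY_STATES,
    FormatError,
    ProteinRecord,
    PSSMProfile,
    TopologyAnnotation,
)

GAP = None  # out-of-bounds window marker


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: ``half_width`` residues on each side."""

    half_width: int = 3

    def __post_init__(self):
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")

    @property
    def window_length(self) -> int:
        return 2 * self.half_width + 1


# ---------------------------------------------------------------------------
# Physicochemical property table
# ---------------------------------------------------------------------------
# Fifteen per-amino-acid scalar indices transcribed from the AAindex
# compendium; the accession realizing each named property is pinned below
# and the table is deliberately editable (pass your own dict to PCPTable).
# Values are keyed in the order A R N D C Q E G H I L K M F P S T W Y V.

_PCP_RAW: dict[str, tuple[str, tuple[float, ...]]] = {
    # name: (AAindex accession, 20 values in PSSM_ALPHABET order)
    "hydrophilicity": ("HOPT810101", (
        -0.5, 3.0, 0.2, 3.0, -1.0, 0.2, 3.0, 0.0, -0.5, -1.8,
        -1.8, 3.0, -1.3, -2.5, 0.0, 0.3, -0.4, -3.4, -2.3, -1.5)),
    "hydrophobicity": ("KYTJ820101", (
        1.8, -4.5, -3.5, -3.5, 2.5, -3.5, -3.5, -0.4, -3.2, 4.5,
        3.8, -3.9, 1.9, 2.8, -1.6, -0.8, -0.7, -0.9, -1.3, 4.2)),
    "net_charge": ("KLEP840101", (
        0.0, 1.0, 0.0, -1.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0,
        0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)),
    "polarity": ("GRAR740102", (
        8.1, 10.5, 11.6, 13.0, 5.5, 10.5, 12.3, 9.0, 10.4, 5.2,
        4.9, 11.3, 5.7, 5.2, 8.0, 9.2, 8.6, 5.4, 6.2, 5.9)),
    "size": ("DAWD720101", (
        2.5, 7.5, 5.0, 2.5, 3.0, 6.0, 5.0, 0.5, 6.0, 5.5,
        5.5, 7.0, 6.0, 6.5, 5.5, 3.0, 5.0, 7.0, 7.0, 5.0)),
    "residue_volume": ("BIGC670101", (
        52.6, 109.1, 75.7, 68.4, 68.3, 89.7, 84.7, 36.3, 91.9, 102.0,
        102.0, 105.1, 97.7, 113.9, 73.6, 54.9, 71.2, 135.4, 116.2, 85.1)),
    "molecular_weight": ("FASG760101", (
        89.09, 174.20, 132.12, 133.10, 121.15, 146.15, 147.13, 75.07, 155.16, 131.17,
        131.17, 146.19, 149.21, 165.19, 115.13, 105.09, 119.12, 204.24, 181.19, 117.15)),
    "diameter": ("FAUJ880103", (
        1.00, 6.13, 2.95, 2.78, 2.43, 3.95, 3.78, 0.00, 4.66, 4.00,
        4.00, 4.77, 4.43, 5.89, 2.72, 1.60, 2.60, 8.08, 6.47, 3.00)),
    "aa_composition": ("DAYM780101", (
        8.6, 4.9, 4.3, 5.5, 2.9, 3.9, 6.0, 8.4, 2.0, 4.5,
        7.4, 6.6, 1.7, 3.6, 5.2, 7.0, 6.1, 1.3, 3.4, 6.6)),
    "membrane_composition": ("CEDJ970105", (
        8.1, 4.6, 3.7, 4.0, 2.2, 3.7, 5.5, 6.8, 2.1, 6.0,
        11.0, 4.4, 2.8, 5.6, 4.6, 7.2, 5.7, 1.8, 3.3, 7.0)),
    "side_chain_interaction": ("KRIW790101", (
        9.25, 10.74, 9.77, 9.42, 9.77, 9.93, 9.62, 8.51, 10.33, 10.42,
        10.14, 10.80, 10.33, 10.88, 9.85, 9.08, 9.40, 11.41, 11.04, 9.94)),
    "solvation_free_energy": ("EISD860101", (
        0.67, -2.10, -0.60, -1.20, 0.38, -0.22, -0.76, 0.00, 0.64, 1.90,
        1.90, -0.57, 2.40, 2.30, 1.20, 0.01, 0.52, 2.60, 1.60, 1.50)),
    "transfer_free_energy": ("NOZY710101", (
        0.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.5, 1.8,
        1.8, 0.0, 1.3, 2.5, 0.0, 0.0, 0.4, 3.4, 2.3, 1.5)),
    "average_flexibility": ("BHAR880101", (
        0.357, 0.529, 0.463, 0.511, 0.346, 0.493, 0.497, 0.544, 0.323, 0.462,
        0.365, 0.466, 0.295, 0.314, 0.509, 0.507, 0.444, 0.305, 0.420, 0.386)),
    "accessible_surface_area": ("CHOC760101", (
        115.0, 225.0, 160.0, 150.0, 135.0, 180.0, 190.0, 75.0, 195.0, 175.0,
        170.0, 200.0, 185.0, 210.0, 145.0, 115.0, 140.0, 255.0, 230.0, 155.0)),
}

N_PCP = 15


class PCPTable:
    """Fifteen named physicochemical property vectors over the 20 amino acids.

    Values are kept both raw and min-max normalized to [0, 1] per property
    (tree ensembles are scale-invariant, but correlation diagnostics and
    any distance-based downstream use benefit from a common scale; the
    encoder emits the normalized values).
    """

    def __init__(self, raw: dict[str, dict[str, float]] | None = None,
                 accessions: dict[str, str] | None = None):
        if raw is None:
            raw = {
                name: dict(zip(PSSM_ALPHABET, vals))
                for name, (_, vals) in _PCP_RAW.items()
            }
            accessions = {name: acc for name, (acc, _) in _PCP_RAW.items()}
        if len(raw) != N_PCP:
            raise ValueError(f"expected exactly {N_PCP} properties, got {len(raw)}")
        for name, vec in raw.items():
            missing = set(PSSM_ALPHABET) - set(vec)
            if missing:
                raise ValueError(f"property {name!r} missing amino acids {sorted(missing)}")
        self.property_names: tuple[str, ...] = tuple(raw)
        self.accessions = dict(accessions or {})
        self.raw = {name: dict(vec) for name, vec in raw.items()}
        self.normalized: dict[str, dict[str, float]] = {}
        # rows: aa -> 15-vector of normalized values, in property order
        self._norm_rows: dict[str, np.ndarray] = {aa: np.empty(N_PCP) for aa in PSSM_ALPHABET}
        for j, name in enumerate(self.property_names):
            vals = np.array([raw[name][aa] for aa in PSSM_ALPHABET], dtype=float)
            lo, hi = vals.min(), vals.max()
            span = hi - lo
            norm = np.zeros_like(vals) if span == 0 else (vals - lo) / span
            self.normalized[name] = dict(zip(PSSM_ALPHABET, norm))
            for aa, v in zip(PSSM_ALPHABET, norm):
                self._norm_rows[aa][j] = v

    def normalized_row(self, aa: str) -> np.ndarray:
        """The 15 normalized property values of one amino acid, in property order."""
        try:
            return self._norm_rows[aa]
        except KeyError:
            raise KeyError(f"residue {aa!r} not in the property table") from None


DEFAULT_PCP = PCPTable()


# ---------------------------------------------------------------------------
# Segment geometry within the assembled vector
# ---------------------------------------------------------------------------

def segment_slices(spec: WindowSpec = WindowSpec()) -> dict[str, slice]:
    """Column slices of the four segments inside the assembled vector."""
    w = spec.window_length
    n_pssm = 20 * w
    n_pcp = N_PCP * w
    return {
        "pssm": slice(0, n_pssm),
        "topo": slice(n_pssm, n_pssm + 4),
        "pcp": slice(n_pssm + 4, n_pssm + 4 + n_pcp),
        "seqseg": slice(n_pssm + 4 + n_pcp, n_pssm + 4 + n_pcp + 20),
    }


def total_dim(spec: WindowSpec = WindowSpec()) -> int:
    return segment_slices(spec)["seqseg"].stop


def feature_names(spec: WindowSpec = WindowSpec()) -> list[str]:
    """Stable column names: pssm_0.., topo_I/O/M/U, pcp_0.., aa_A..aa_V."""
    w = spec.window_length
    names = [f"pssm_{i}" for i in range(20 * w)]
    names += [f"topo_{s}" for s in TOPOLOGY_STATES]
    names += [f"pcp_{i}" for i in range(N_PCP * w)]
    names += [f"aa_{a}" for a in PSSM_ALPHABET]
    return names


@dataclass
class ResidueFeatureVector:
    """The encoded residue: four named segments plus their concatenation."""

    protein_id: str
    residue_index: int  # 0-based
    pssm: np.ndarray
    topo: np.ndarray
    pcp: np.ndarray
    seqseg: np.ndarray

    @property
    def full(self) -> np.ndarray:
        return np.concatenate([self.pssm, self.topo, self.pcp, self.seqseg])


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

def extract_window(record: ProteinRecord, index: int, spec: WindowSpec = WindowSpec()):
    """The window around residue ``index`` as (position, residue-or-None) pairs.

    Positions outside ``[0, L)`` carry ``None`` in place of a residue.
    """
    L = record.length
    if not (0 <= index < L):
        raise IndexError(f"residue index {index} out of range for length {L}")
    out = []
    for pos in range(index - spec.half_width, index + spec.half_width + 1):
        if 0 <= pos < L:
            out.append((pos, record.sequence[pos]))
        else:
            out.append((pos, GAP))
    return out


def encode_pssm(window, profile: PSSMProfile) -> np.ndarray:
    """Concatenate the window's profile rows; gaps contribute zero rows."""
    out = np.zeros(20 * len(window))
    for k, (pos, aa) in enumerate(window):
        if aa is not GAP:
            out[20 * k : 20 * (k + 1)] = profile.scores[pos]
    return out


def encode_topo(window, topo: TopologyAnnotation) -> np.ndarray:
    """Counts of I, O, M, U states over the in-bounds window positions."""
    counts = np.zeros(4)
    for pos, aa in window:
        if aa is not GAP:
            counts[TOPOLOGY_STATES.index(topo.states[pos])] += 1
    return counts


def encode_pcp(window, table: PCPTable = DEFAULT_PCP) -> np.ndarray:
    """Per window position, the 15 normalized property values; gaps are zeros."""
    out = np.zeros(N_PCP * len(window))
    for k, (pos, aa) in enumerate(window):
        if aa is not GAP:
            out[N_PCP * k : N_PCP * (k + 1)] = table.normalized_row(aa)
    return out


def encode_seqseg(window) -> np.ndarray:
    """Amino-acid composition counts of the in-bounds window residues."""
    counts = np.zeros(20)
    for pos, aa in window:
        if aa is not GAP:
            counts[PSSM_ALPHABET.index(aa)] += 1
    return counts


def _check_lengths(record: ProteinRecord, profile: PSSMProfile, topo: TopologyAnnotation):
    if profile.length != record.length:
        raise FormatError(
            f"profile length {profile.length} != protein {record.id!r} "
            f"length {record.length}"
        )
    if topo.length != record.length:
        raise FormatError(
            f"topology length {topo.length} != protein {record.id!r} "
            f"length {record.length}"
        )


def encode_residue(
    record: ProteinRecord,
    index: int,
    profile: PSSMProfile,
    topo: TopologyAnnotation,
    table: PCPTable = DEFAULT_PCP,
    spec: WindowSpec = WindowSpec(),
) -> ResidueFeatureVector:
    """Encode one residue as the concatenation pssm || topo || pcp || seqseg."""
    _check_lengths(record, profile, topo)
    window = extract_window(record, index, spec)
    return ResidueFeatureVector(
        protein_id=record.id,
        residue_index=index,
        pssm=encode_pssm(window, profile),
        topo=encode_topo(window, topo),
        pcp=encode_pcp(window, table),
        seqseg=encode_seqseg(window),
    )


def encode_protein(
    record: ProteinRecord,
    profile: PSSMProfile,
    topo: TopologyAnnotation,
    table: PCPTable = DEFAULT_PCP,
    spec: WindowSpec = WindowSpec(),
) -> np.ndarray:
    """Encode every residue of a protein; returns an L x D feature matrix.

    Vectorized equivalent of calling :func:`encode_residue` for each
    residue (the per-residue path is retained as the readable reference
    and for spot checks in the tests).
    """
    _check_lengths(record, profile, topo)
    L = record.length
    w = spec.window_length
    h = spec.half_width
    D = total_dim(spec)
    sl = segment_slices(spec)
    out = np.zeros((L, D))

    aa_idx = np.array([PSSM_ALPHABET.index(a) for a in record.sequence])
    topo_idx = np.array([TOPOLOGY_STATES.index(s) for s in topo.states])
    pcp_rows = np.stack([table.normalized_row(a) for a in record.sequence])

    pssm_base = sl["pssm"].start
    pcp_base = sl["pcp"].start
    topo_base = sl["topo"].start
    seq_base = sl["seqseg"].start
    for k in range(w):  # window slot k covers residue i + (k - h)
        off = k - h
        src_lo, src_hi = max(0, -off), min(L, L - off)
        rows = np.arange(src_lo, src_hi)
        src = rows + off
        out[rows, pssm_base + 20 * k : pssm_base + 20 * (k + 1)] = profile.scores[src]
        out[rows, pcp_base + N_PCP * k : pcp_base + N_PCP * (k + 1)] = pcp_rows[src]
        out[rows, topo_base + topo_idx[src]] += 1
        out[rows, seq_base + aa_idx[src]] += 1
    return out


def pseudo_pssm(sequence: str, protein_id: str = "", matrix: str = "BLOSUM62") -> PSSMProfile:
    """A deterministic stand-in profile built from a substitution matrix.

    Row ``i`` is the BLOSUM row of residue ``i``, restricted to the 20
    canonical columns in PSI-BLAST order.  Useful when real PSI-BLAST
    profiles are unavailable; marked ``source="pseudo"``.
    """
    table = substitution_matrices.load(matrix)
    rows = np.empty((len(sequence), 20))
    for i, aa in enumerate(sequence):
        rows[i] = [table[aa, b] for b in PSSM_ALPHABET]
    return PSSMProfile(protein_id=protein_id or "pseudo", scores=rows, source="pseudo")
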
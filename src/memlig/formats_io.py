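"""Readers and writers for every external format the pipeline touches.

External files use 1-based residue indexing (UniProt convention); all
in-memory indices are 0-based.  The conversion happens exactly here, at
the I/O boundary.

Formats
-------
* FASTA protein sequences (via Bio.SeqIO).
* PSI-BLAST ASCII PSSM (``-out_ascii_pssm`` layout): only the first 20
  log-odds columns are consumed; trailing weighted-percentage and
  information-content columns are ignored.
* Topology text: FASTA-like, one record per protein — a ``>id`` header
  followed by a state string over {I, O, M, U} (inside / outside /
  membrane / unknown).  TOPCONS per-residue output converts to this
  layout by prepending a header and joining the per-line states.
* Binding annotations: TSV ``protein_id<TAB>residue_index<TAB>ligand_category``
  with a header row; residue_index is 1-based; category is one of
  {drug, metal, biomacromolecule}.
* Predictions: TSV ``protein_id<TAB>residue_index<TAB>residue<TAB>score<TAB>label<TAB>model``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: The 20 canonical amino acids in PSI-BLAST PSSM column order.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

CANONICAL_AA = frozenset(PSSM_ALPHABET)

LIGAND_CATEGORIES = ("drug", "metal", "biomacromolecule")

TOPOLOGY_STATES = "IOMU"


class FormatError(ValueError):
    """A file violated its format contract (parse or consistency failure)."""


@dataclass
class ProteinRecord:
    """A protein sequence with optional per-residue binding annotations.

    ``binding_mask[i]`` is True when residue ``i`` (0-based) contacts any
    ligand; ``ligand_categories[i]`` holds the categories of the ligands it
    contacts (empty set for non-binding residues).
    """

    id: str
    sequence: str
    binding_mask: np.ndarray = None  # bool, shape (L,)
    ligand_categories: list = None  # list of frozenset per residue

    def __post_init__(self):
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise FormatError(
                f"protein {self.id!r}: non-canonical residue(s) {sorted(bad)}"
            )
        L = len(self.sequence)
        if self.binding_mask is None:
            self.binding_mask = np.zeros(L, dtype=bool)
        else:
            self.binding_mask = np.asarray(self.binding_mask, dtype=bool)
        if self.ligand_categories is None:
            self.ligand_categories = [frozenset() for _ in range(L)]
        if len(self.binding_mask) != L or len(self.ligand_categories) != L:
            raise FormatError(
                f"protein {self.id!r}: annotation length differs from sequence length {L}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PSSMProfile:
    """An L x 20 evolutionary log-odds profile in PSI-BLAST column order."""

    protein_id: str
    scores: np.ndarray  # float, shape (L, 20)
    source: str = "psiblast"  # or "pseudo"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise FormatError(
                f"PSSM for {self.protein_id!r}: expected L x 20 matrix, "
                f"got shape {self.scores.shape}"
            )
        if self.source not in ("psiblast", "pseudo"):
            raise FormatError(f"unknown PSSM source {self.source!r}")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class TopologyAnnotation:
    """Per-residue membrane topology states over {I, O, M, U}."""

    protein_id: str
    states: str

    def __post_init__(self):
        bad = set(self.states) - set(TOPOLOGY_STATES)
        if bad:
            raise FormatError(
                f"topology for {self.protein_id!r}: invalid state(s) {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.states)


@dataclass
class PredictionRecord:
    """One residue's prediction from one model."""

    protein_id: str
    residue_index: int  # 1-based, as in all external files
    residue: str
    score: float
    predicted_label: bool
    model_name: str


@dataclass
class FilterReport:
    """Why a FASTA record was excluded by ``read_fasta``."""

    id: str
    reason: str


def read_fasta(
    path,
    min_length: int = 50,
    drop_ambiguous: bool = True,
) -> tuple[list[ProteinRecord], list[FilterReport]]:
    """Read protein sequences, applying the length and ambiguity filters.

    Returns ``(kept_records, filter_reports)``; a record failing a filter
    appears in the reports with its reason rather than being silently
    dropped.  ``kept + excluded == total`` always holds.

    Parameters
    ----------
    min_length : minimum sequence length to keep (default 50; proteins
        shorter than 50 residues are excluded from the benchmark data).
    drop_ambiguous : exclude sequences containing letters outside the 20
        canonical amino acids (X, B, Z, ...).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        seq_records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython raises rarely
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not seq_records:
        raise FormatError(f"empty or headerless FASTA file: {path}")

    kept: list[ProteinRecord] = []
    reports: list[FilterReport] = []
    seen: set[str] = set()
    for rec in seq_records:
        rid = rec.id
        if not rid:
            raise FormatError(f"malformed FASTA {path}: record with empty header")
        if rid in seen:
            raise FormatError(f"duplicate protein id {rid!r} in {path}")
        seen.add(rid)
        seq = str(rec.seq).upper()
        if not seq:
            reports.append(FilterReport(rid, "empty sequence"))
            continue
        bad = set(seq) - CANONICAL_AA
        if bad:
            if drop_ambiguous:
                reports.append(
                    FilterReport(rid, f"ambiguous residue: {','.join(sorted(bad))}")
                )
                continue
            raise FormatError(
                f"protein {rid!r} contains non-canonical residue(s) "
                f"{sorted(bad)} and drop_ambiguous is off"
            )
        if len(seq) < min_length:
            reports.append(
                FilterReport(rid, f"length {len(seq)} < min_length {min_length}")
            )
            continue
        kept.append(ProteinRecord(id=rid, sequence=seq))
    return kept, reports


def write_fasta(path, proteins: Iterable[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, p.length, 60):
                fh.write(p.sequence[i : i + 60] + "\n")


# A data row of the PSI-BLAST ascii PSSM: position, residue letter, >= 20 numbers.
_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Z])\s+(-?\d[\d\s.+-]*)$")


def read_pssm(path, sequence: str | None = None, protein_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into an L x 20 profile.

    Only the first 20 score columns (log-odds) are consumed; the trailing
    weighted-percentage and information-content columns, when present, are
    ignored.  When ``sequence`` is given, the residue letter of every row
    is cross-checked against it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[list[float]] = []
    letters: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            m = _PSSM_ROW.match(line.rstrip())
            if m is None:
                continue  # header / footer lines
            pos = int(m.group(1))
            fields = m.group(3).split()
            if len(fields) < 20:
                raise FormatError(
                    f"{path}:{lineno}: PSSM row {pos} has {len(fields)} score "
                    "fields, expected at least 20"
                )
            if pos != len(rows) + 1:
                raise FormatError(
                    f"{path}:{lineno}: position {pos} out of order "
                    f"(expected {len(rows) + 1})"
                )
            rows.append([float(x) for x in fields[:20]])
            letters.append(m.group(2))
    if not rows:
        raise FormatError(f"{path}: no PSSM data rows found")
    if sequence is not None:
        if len(sequence) != len(rows):
            raise FormatError(
                f"{path}: PSSM has {len(rows)} rows but sequence has "
                f"{len(sequence)} residues"
            )
        for i, (a, b) in enumerate(zip(letters, sequence)):
            if a != b:
                raise FormatError(
                    f"{path}: residue mismatch at position {i + 1}: "
                    f"PSSM has {a!r}, sequence has {b!r}"
                )
    return PSSMProfile(
        protein_id=protein_id or path.stem,
        scores=np.array(rows, dtype=float),
        source="psiblast",
    )


def write_pssm(path, profile: PSSMProfile, sequence: str) -> None:
    """Write a profile in the PSI-BLAST ascii layout (20 log-odds columns)."""
    if len(sequence) != profile.length:
        raise FormatError(
            f"sequence length {len(sequence)} != profile length {profile.length}"
        )
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(PSSM_ALPHABET) + "\n")
        for i, (aa, row) in enumerate(zip(sequence, profile.scores), start=1):
            cells = " ".join(f"{int(round(v)):3d}" for v in row)
            fh.write(f"{i:5d} {aa}  {cells}\n")


def read_topology(path) -> dict[str, TopologyAnnotation]:
    """Read a FASTA-like topology file: ``>id`` then a state string over IOMU."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, TopologyAnnotation] = {}
    current_id = None
    chunks: list[str] = []

    def _flush():
        if current_id is None:
            return
        states = "".join(chunks)
        if not states:
            raise FormatError(f"{path}: empty topology for {current_id!r}")
        out[current_id] = TopologyAnnotation(current_id, states)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current_id = line[1:].split()[0]
                if current_id in out:
                    raise FormatError(f"{path}:{lineno}: duplicate id {current_id!r}")
                chunks = []
            else:
                if current_id is None:
                    raise FormatError(f"{path}:{lineno}: state line before any header")
                chunks.append(line.upper())
    _flush()
    if not out:
        raise FormatError(f"{path}: no topology records")
    return out


def write_topology(path, topologies: Iterable[TopologyAnnotation]) -> None:
    with open(path, "w") as fh:
        for t in topologies:
            fh.write(f">{t.protein_id}\n{t.states}\n")


def read_annotations(path, proteins: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Populate binding masks and ligand categories from an annotation TSV.

    The file has a header row and columns ``protein_id``, ``residue_index``
    (1-based) and ``ligand_category``.  A protein named in the file but
    absent from ``proteins`` is a hard error: silent misjoins corrupt
    labels.  The input records are mutated in place and returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    by_id = {p.id: p for p in proteins}
    staged: dict[str, list[set]] = {
        p.id: [set(cats) for cats in p.ligand_categories] for p in proteins
    }
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty annotation file")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            pid, idx_s, category = fields
            if pid not in by_id:
                raise FormatError(
                    f"{path}:{lineno}: protein {pid!r} not present in the sequence set"
                )
            try:
                idx1 = int(idx_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad residue index {idx_s!r}") from None
            prot = by_id[pid]
            if not (1 <= idx1 <= prot.length):
                raise FormatError(
                    f"{path}:{lineno}: residue index {idx1} out of range for "
                    f"protein {pid!r} of length {prot.length}"
                )
            if category not in LIGAND_CATEGORIES:
                raise FormatError(
                    f"{path}:{lineno}: unknown ligand category {category!r}; "
                    f"allowed: {', '.join(LIGAND_CATEGORIES)}"
                )
            staged[pid][idx1 - 1].add(category)
    for pid, cats in staged.items():
        prot = by_id[pid]
        prot.ligand_categories = [frozenset(c) for c in cats]
        prot.binding_mask = np.array([len(c) > 0 for c in cats], dtype=bool)
    return list(proteins)


def write_annotations(path, proteins: Iterable[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tresidue_index\tligand_category\n")
        for p in proteins:
            for i, cats in enumerate(p.ligand_categories):
                for cat in sorted(cats):
                    fh.write(f"{p.id}\t{i + 1}\t{cat}\n")


PREDICTION_HEADER = ["protein_id", "residue_index", "residue", "score", "label", "model"]


def write_predictions(path, records: Iterable[PredictionRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_HEADER) + "\n")
        for r in records:
            fh.write(
                f"{r.protein_id}\t{r.residue_index}\t{r.residue}\t"
                f"{r.score:.6g}\t{int(r.predicted_label)}\t{r.model_name}\n"
            )


def read_predictions(path) -> list[PredictionRecord]:
    path = Path(path)
    out: list[PredictionRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PREDICTION_HEADER:
            raise FormatError(f"{path}: unexpected prediction header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 fields")
            out.append(
                PredictionRecord(
                    protein_id=fields[0],
                    residue_index=int(fields[1]),
                    residue=fields[2],
                    score=float(fields[3]),
                    predicted_label=bool(int(fields[4])),
                    model_name=fields[5],
                )
            )
    return out
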
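"""Glue between file inputs, encoders, and residue datasets."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from memlig.encoders import DEFAULT_PCP, PCPTable, WindowSpec, encode_protein
from memlig.formats_io import (
    FormatError,
    ProteinRecord,
    PSSMProfile,
    TopologyAnnotation,
    read_annotations,
    read_fasta,
    read_pssm,
    read_topology,
)
from memlig.encoders import pseudo_pssm
from memlig.sampling import ResidueDataset


def load_inputs(
    fasta_path,
    pssm_dir=None,
    topology_path=None,
    annotations_path=None,
    min_length: int = 50,
):
    """Load and cross-validate all pipeline inputs.

    Missing profiles fall back to deterministic pseudo-profiles; a missing
    topology file yields all-unknown (U) topologies.  Returns
    ``(proteins, profiles, topologies)``.
    """
    proteins, _reports = read_fasta(fasta_path, min_length=min_length)
    profiles: dict[str, PSSMProfile] = {}
    if pssm_dir is not None:
        pssm_dir = Path(pssm_dir)
        for p in proteins:
            f = pssm_dir / f"{p.id}.pssm"
            if f.exists():
                profiles[p.id] = read_pssm(f, sequence=p.sequence, protein_id=p.id)
    for p in proteins:
        if p.id not in profiles:
            profiles[p.id] = pseudo_pssm(p.sequence, protein_id=p.id)

    topologies: dict[str, TopologyAnnotation] = {}
    if topology_path is not None:
        topologies = read_topology(topology_path)
        for p in proteins:
            if p.id not in topologies:
                raise FormatError(f"no topology record for protein {p.id!r}")
            if topologies[p.id].length != p.length:
                raise FormatError(
                    f"topology length {topologies[p.id].length} != protein "
                    f"{p.id!r} length {p.length}"
                )
    else:
        topologies = {p.id: TopologyAnnotation(p.id, "U" * p.length) for p in proteins}

    if annotations_path is not None:
        read_annotations(annotations_path, proteins)
    return proteins, profiles, topologies


def encode_features(
    proteins: Sequence[ProteinRecord],
    profiles: Mapping[str, PSSMProfile],
    topologies: Mapping[str, TopologyAnnotation],
    table: PCPTable = DEFAULT_PCP,
    spec: WindowSpec = WindowSpec(),
) -> dict[str, np.ndarray]:
    """Per-protein L x 269 feature matrices, keyed by protein id."""
    return {
        p.id: encode_protein(p, profiles[p.id], topologies[p.id], table, spec)
        for p in proteins
    }


def build_dataset(
    proteins: Sequence[ProteinRecord],
    features_by_protein: Mapping[str, np.ndarray],
    category: str | None = None,
) -> ResidueDataset:
    """Stack per-protein features into one residue dataset.

    With ``category`` set, labels follow that ligand category and the
    dataset is restricted to proteins having at least one such residue.
    """
    feats, labels, pids, ridx = [], [], [], []
    for p in proteins:
        if category is None:
            y = p.binding_mask
        else:
            y = np.array([category in c for c in p.ligand_categories], dtype=bool)
            if not y.any():
                continue
        feats.append(features_by_protein[p.id])
        labels.append(y)
        pids.append(np.full(p.length, p.id, dtype=object))
        ridx.append(np.arange(p.length))
    if not feats:
        raise ValueError(f"no proteins with category {category!r}")
    return ResidueDataset(
        features=np.vstack(feats),
        labels=np.concatenate(labels),
        protein_ids=np.concatenate(pids),
        residue_indices=np.concatenate(ridx),
        ligand_filter=category,
    )


def split_proteins(
    proteins: Sequence[ProteinRecord], test_fraction: float = 0.2, seed: int = 0
):
    """Protein-level train/test split (no residue of a protein crosses sides)."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(proteins))
    n_test = max(1, int(round(test_fraction * len(proteins))))
    test_set = set(idx[:n_test])
    train = [p for i, p in enumerate(proteins) if i not in test_set]
    test = [p for i, p in enumerate(proteins) if i in test_set]
    return train, test
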
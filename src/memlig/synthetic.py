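"""Self-contained synthetic fixtures with planted binding-site signal.

The generator emulates the structure of a curated membrane-protein
binding-site benchmark: proteins of 50-400 residues, binding residues at
roughly 1:150 prevalence, drawn preferentially from the polar
hydrophilic residues C, H and D, placed preferentially outside the
membrane-spanning segments, and marked by elevated conservation in their
pseudo evolutionary profiles.  Each signal channel (conservation,
composition, topology placement) has an independent strength knob, so a
null dataset (no signal anywhere) is one configuration away.

Everything is reproducible from the seed, and all outputs are written in
the package's external formats, so the full pipeline is testable with no
downloads.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from memlig.formats_io import (
    LIGAND_CATEGORIES,
    PSSM_ALPHABET,
    ProteinRecord,
    PSSMProfile,
    TopologyAnnotation,
    write_annotations,
    write_fasta,
    write_pssm,
    write_topology,
)

# Background amino-acid usage (Dayhoff-style composition, normalized).
_BACKGROUND = np.array(
    [8.6, 4.9, 4.3, 5.5, 2.9, 3.9, 6.0, 8.4, 2.0, 4.5,
     7.4, 6.6, 1.7, 3.6, 5.2, 7.0, 6.1, 1.3, 3.4, 6.6]
)
_BACKGROUND = _BACKGROUND / _BACKGROUND.sum()

#: Residues favoured at binding positions (polar hydrophilic).
BINDING_FAVOURED = "CHD"


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate the benchmark's structure.

    ``composition_bias`` is the probability that a binding residue is
    rewritten to one of C/H/D; ``conservation_boost`` is added to the
    own-residue column of the pseudo-profile at binding positions;
    ``membrane_weight`` scales the chance that a binding site lands on a
    membrane-spanning (M) residue (1.0 = no avoidance).  Setting all
    three to their null values (0, 0, 1) removes every label-feature
    association.
    """

    n_proteins: int = 120
    min_length: int = 50
    max_length: int = 400
    prevalence: float = 1.0 / 150.0
    category_weights: tuple[float, float, float] = (0.20, 0.55, 0.25)  # drug, metal, biomacromolecule
    multi_category_prob: float = 0.03
    composition_bias: float = 0.7
    conservation_boost: float = 8.0
    pssm_noise: float = 2.0
    membrane_weight: float = 0.05
    soluble_fraction: float = 0.15  # proteins with all-U (unknown) topology
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if abs(sum(self.category_weights) - 1.0) > 1e-9:
            raise ValueError("category_weights must sum to 1")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("invalid length range")
        if self.n_proteins * self.max_length * self.prevalence < 1:
            raise ValueError("infeasible config: expected zero binding residues")

    @staticmethod
    def null(**overrides) -> "SimConfig":
        """A signal-free configuration: binding labels independent of features."""
        base = dict(composition_bias=0.0, conservation_boost=0.0, membrane_weight=1.0)
        base.update(overrides)
        return SimConfig(**base)


@dataclass
class SimResult:
    """Generated proteins plus their profiles, topologies, and provenance."""

    proteins: list[ProteinRecord]
    profiles: dict[str, PSSMProfile]
    topologies: dict[str, TopologyAnnotation]
    config: SimConfig
    manifest: dict = field(default_factory=dict)


def _simulate_topology(rng: np.random.Generator, L: int, cfg: SimConfig) -> str:
    if rng.random() < cfg.soluble_fraction:
        return "U" * L
    states = []
    side = "I" if rng.random() < 0.5 else "O"
    while len(states) < L:
        run = int(rng.integers(5, 40))
        states.extend(side * run)
        if len(states) >= L:
            break
        tm = int(np.clip(round(rng.normal(21, 3)), 15, 28))
        states.extend("M" * tm)
        side = "O" if side == "I" else "I"
    return "".join(states[:L])


def _simulate_protein(rng: np.random.Generator, pid: str, cfg: SimConfig, blosum):
    L = int(rng.integers(cfg.min_length, cfg.max_length + 1))
    seq = list(rng.choice(list(PSSM_ALPHABET), size=L, p=_BACKGROUND))
    topo = _simulate_topology(rng, L, cfg)

    n_pos = rng.binomial(L, cfg.prevalence)
    weights = np.array([cfg.membrane_weight if s == "M" else 1.0 for s in topo])
    weights = weights / weights.sum()
    pos_idx = rng.choice(L, size=n_pos, replace=False, p=weights) if n_pos else np.array([], dtype=int)

    cats: list[set] = [set() for _ in range(L)]
    for i in pos_idx:
        if rng.random() < cfg.composition_bias:
            seq[i] = BINDING_FAVOURED[rng.integers(len(BINDING_FAVOURED))]
        primary = LIGAND_CATEGORIES[
            rng.choice(3, p=np.asarray(cfg.category_weights))
        ]
        cats[i].add(primary)
        if rng.random() < cfg.multi_category_prob:
            others = [c for c in LIGAND_CATEGORIES if c != primary]
            cats[i].add(others[rng.integers(2)])

    sequence = "".join(seq)
    mask = np.zeros(L, dtype=bool)
    mask[pos_idx] = True
    record = ProteinRecord(
        id=pid,
        sequence=sequence,
        binding_mask=mask,
        ligand_categories=[frozenset(c) for c in cats],
    )

    # pseudo-profile: BLOSUM row of the observed residue plus integer noise,
    # with extra conservation on the own-residue column at binding positions
    scores = np.empty((L, 20))
    for i, aa in enumerate(sequence):
        scores[i] = [blosum[aa, b] for b in PSSM_ALPHABET]
    scores += rng.normal(0.0, cfg.pssm_noise, size=scores.shape)
    own_col = np.array([PSSM_ALPHABET.index(a) for a in sequence])
    scores[np.arange(L), own_col] += cfg.conservation_boost * mask
    scores = np.round(scores)
    profile = PSSMProfile(protein_id=pid, scores=scores, source="pseudo")

    return record, profile, TopologyAnnotation(pid, topo)


def simulate(config: SimConfig = SimConfig(), outdir=None) -> SimResult:
    """Generate a complete synthetic dataset; optionally write it to disk.

    With ``outdir`` set, writes ``proteins.fasta``, ``pssm/<id>.pssm``,
    ``topology.txt``, ``annotations.tsv`` and ``manifest.json`` there.
    Byte-identical output for identical config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    blosum = substitution_matrices.load("BLOSUM62")
    proteins, profiles, topologies = [], {}, {}
    for i in range(config.n_proteins):
        pid = f"SYN{i + 1:04d}"
        rec, prof, topo = _simulate_protein(rng, pid, config, blosum)
        proteins.append(rec)
        profiles[pid] = prof
        topologies[pid] = topo

    n_res = sum(p.length for p in proteins)
    n_bind = int(sum(p.binding_mask.sum() for p in proteins))
    manifest = {
        "config": dataclasses.asdict(config),
        "n_proteins": len(proteins),
        "n_residues": n_res,
        "n_binding": n_bind,
        "binding_per_category": {
            cat: int(
                sum(
                    sum(cat in c for c in p.ligand_categories) for p in proteins
                )
            )
            for cat in LIGAND_CATEGORIES
        },
    }
    result = SimResult(
        proteins=proteins, profiles=profiles, topologies=topologies,
        config=config, manifest=manifest,
    )
    if outdir is not None:
        write_fixture(result, outdir)
    return result


def write_fixture(result: SimResult, outdir) -> None:
    """Write every generated file in the pipeline's external formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "proteins.fasta", result.proteins)
    pssm_dir = outdir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for p in result.proteins:
        write_pssm(pssm_dir / f"{p.id}.pssm", result.profiles[p.id], p.sequence)
    write_topology(outdir / "topology.txt", (result.topologies[p.id] for p in result.proteins))
    write_annotations(outdir / "annotations.tsv", result.proteins)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
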
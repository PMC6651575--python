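"""Random under-sampling (RUS) of non-binding residues.

Binding residues are 140-220 times rarer than non-binding ones, so the
training set keeps every positive and a uniform random subset of the
negatives at a configurable negative:positive ratio (default 30).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class ResidueDataset:
    """A residue-level feature matrix with labels and protein provenance.

    ``protein_ids`` keeps the protein of origin of every row so that
    grouped splitting (all residues of a protein in one fold) is possible.
    """

    features: np.ndarray  # (N, D)
    labels: np.ndarray  # (N,) bool
    protein_ids: np.ndarray  # (N,) str
    residue_indices: np.ndarray | None = None  # (N,) 0-based within protein
    ligand_filter: str | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features)
        self.labels = np.asarray(self.labels, dtype=bool)
        self.protein_ids = np.asarray(self.protein_ids)
        n = len(self.labels)
        if self.features.shape[0] != n or len(self.protein_ids) != n:
            raise ValueError("features, labels and protein_ids must have equal row counts")
        if self.residue_indices is not None:
            self.residue_indices = np.asarray(self.residue_indices)
            if len(self.residue_indices) != n:
                raise ValueError("residue_indices length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.labels).sum())

    def subset(self, idx: np.ndarray) -> "ResidueDataset":
        return ResidueDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            protein_ids=self.protein_ids[idx],
            residue_indices=None if self.residue_indices is None else self.residue_indices[idx],
            ligand_filter=self.ligand_filter,
        )


@dataclass(frozen=True)
class RUSConfig:
    """Under-sampling parameters: keep ``ratio`` negatives per positive."""

    ratio: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


def rus_indices(labels: np.ndarray, config: RUSConfig) -> np.ndarray:
    """Row indices of the under-sampled set: all positives plus a uniform
    random subset of ``min(round(ratio * P), N)`` negatives, without
    replacement, in ascending order."""
    labels = np.asarray(labels, dtype=bool)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    if len(pos) == 0:
        raise ValueError("cannot under-sample a dataset with zero positive residues")
    target = int(round(config.ratio * len(pos)))
    if target > len(neg):
        warnings.warn(
            f"requested {target} negatives but only {len(neg)} available; keeping all",
            stacklevel=2,
        )
        chosen = neg
    else:
        rng = np.random.default_rng(config.seed)
        chosen = rng.choice(neg, size=target, replace=False)
    return np.sort(np.concatenate([pos, chosen]))


def rus_sample(dataset: ResidueDataset, config: RUSConfig = RUSConfig()) -> ResidueDataset:
    """Under-sample the negatives of a dataset; positives are never dropped."""
    return dataset.subset(rus_indices(dataset.labels, config))


def ratio_sweep(dataset: ResidueDataset, ratios, eval_protocol):
    """Evaluate the pipeline at each negative:positive ratio.

    ``eval_protocol(dataset, ratio)`` performs resampling at that ratio
    plus training and evaluation (typically a cross-validation closure)
    and returns a metrics object.  Duplicated ratios are evaluated again,
    not deduplicated.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("ratio list must not be empty")
    return [(r, eval_protocol(dataset, r)) for r in ratios]
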
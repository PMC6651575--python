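"""Random-forest training, prediction, and the ligand-specific model registry.

The forest follows the published configuration: 140 CART trees, 20
candidate features examined per split, bootstrap resampling of the
(under-sampled) training set, trees grown to purity.  The prediction
score of a residue is the fraction of trees voting for the binding
class; a score exactly at the decision threshold is classified binding
(the use case is recall-oriented: users want candidate binding residues).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from memlig.formats_io import LIGAND_CATEGORIES, PredictionRecord, ProteinRecord
from memlig.sampling import ResidueDataset, RUSConfig, rus_sample

MODEL_NAMES = ("universal",) + LIGAND_CATEGORIES


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters (defaults are the published configuration)."""

    n_trees: int = 140
    split_candidates: int = 20
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.split_candidates < 1:
            raise ValueError("split_candidates must be >= 1")
        if not (0.0 <= self.decision_threshold <= 1.0):
            raise ValueError("decision_threshold must be in [0, 1]")


def schema_fingerprint(n_features: int, feature_names: Sequence[str] | None = None) -> str:
    """A short digest identifying the feature layout a model was trained on."""
    h = hashlib.sha256()
    h.update(str(n_features).encode())
    if feature_names is not None:
        h.update("\n".join(feature_names).encode())
    return h.hexdigest()[:16]


@dataclass
class ModelBundle:
    """A fitted forest plus everything needed to apply it safely later."""

    model_name: str
    forest: RandomForestClassifier
    config: RFConfig
    n_features: int
    fingerprint: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model_name not in MODEL_NAMES:
            raise ValueError(
                f"model_name must be one of {MODEL_NAMES}, got {self.model_name!r}"
            )

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, ModelBundle):
            raise TypeError(f"{path} does not contain a model bundle")
        return bundle


def train(
    dataset: ResidueDataset,
    rf: RFConfig = RFConfig(),
    rus: RUSConfig | None = None,
    model_name: str = "universal",
    feature_names: Sequence[str] | None = None,
) -> ModelBundle:
    """Fit a random forest on a residue dataset.

    When ``rus`` is given, the dataset is under-sampled first (all
    positives, ``ratio`` negatives per positive).  Training on a
    single-class set is an error.  Deterministic under fixed seeds.
    """
    if rus is not None:
        dataset = rus_sample(dataset, rus)
    y = dataset.labels
    if y.all() or not y.any():
        raise ValueError("training set must contain both classes")
    n_features = dataset.features.shape[1]
    forest = RandomForestClassifier(
        n_estimators=rf.n_trees,
        criterion="gini",
        max_features=min(rf.split_candidates, n_features),
        bootstrap=True,
        max_depth=None,  # trees grown to purity
        random_state=rf.seed,
        n_jobs=1,
    )
    forest.fit(dataset.features, y.astype(int))
    return ModelBundle(
        model_name=model_name,
        forest=forest,
        config=rf,
        n_features=n_features,
        fingerprint=schema_fingerprint(n_features, feature_names),
        metadata={
            "n_train_positive": dataset.n_positive,
            "n_train_negative": dataset.n_negative,
            "rus_ratio": None if rus is None else rus.ratio,
            "rus_seed": None if rus is None else rus.seed,
            "rf_seed": rf.seed,
            "ligand_filter": dataset.ligand_filter,
        },
    )


def predict_scores(bundle: ModelBundle, features: np.ndarray) -> np.ndarray:
    """Fraction of tree votes for the binding class, in [0, 1]."""
    features = np.asarray(features)
    if features.ndim != 2 or features.shape[1] != bundle.n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {bundle.n_features}, "
            f"got {features.shape[1] if features.ndim == 2 else features.shape}"
        )
    proba = bundle.forest.predict_proba(features)
    pos_col = list(bundle.forest.classes_).index(1)
    return proba[:, pos_col]


def predict_labels(bundle: ModelBundle, features: np.ndarray) -> np.ndarray:
    """Binding-class calls; a score equal to the threshold counts as binding."""
    return predict_scores(bundle, features) >= bundle.config.decision_threshold


def predict(
    bundle: ModelBundle,
    features: np.ndarray,
    protein_ids: Sequence[str] | None = None,
    residue_indices: Sequence[int] | None = None,
    residues: Sequence[str] | None = None,
) -> list[PredictionRecord]:
    """Score residues and assemble prediction records.

    ``residue_indices`` are 0-based (internal convention) and emitted
    1-based in the records, matching the external file convention.
    """
    scores = predict_scores(bundle, features)
    n = len(scores)
    protein_ids = ["?"] * n if protein_ids is None else list(protein_ids)
    residue_indices = list(range(n)) if residue_indices is None else list(residue_indices)
    residues = ["?"] * n if residues is None else list(residues)
    thr = bundle.config.decision_threshold
    return [
        PredictionRecord(
            protein_id=pid,
            residue_index=int(ri) + 1,
            residue=aa,
            score=float(s),
            predicted_label=bool(s >= thr),
            model_name=bundle.model_name,
        )
        for pid, ri, aa, s in zip(protein_ids, residue_indices, residues, scores)
    ]


def build_ligand_datasets(
    proteins: Sequence[ProteinRecord],
    features_by_protein: Mapping[str, np.ndarray],
    ) -> dict[str, ResidueDataset]:
    """Assemble the universal and per-ligand-category residue datasets.

    * universal: every protein; positives are residues binding any ligand.
    * drug / metal / biomacromolecule: only proteins with at least one
      residue of that category; positives are that category's residues,
      negatives all remaining residues of those proteins.  A residue with
      two categories is a positive in both category datasets (the protein
      subsets overlap).
    """
    out: dict[str, ResidueDataset] = {}
    for name in MODEL_NAMES:
        feats, labels, pids, ridx = [], [], [], []
        for p in proteins:
            if name == "universal":
                y = p.binding_mask
            else:
                y = np.array([name in cats for cats in p.ligand_categories], dtype=bool)
                if not y.any():
                    continue  # protein outside this category's subset
            X = features_by_protein[p.id]
            if X.shape[0] != p.length:
                raise ValueError(
                    f"feature matrix for {p.id!r} has {X.shape[0]} rows, "
                    f"protein has {p.length} residues"
                )
            feats.append(X)
            labels.append(y)
            pids.append(np.full(p.length, p.id, dtype=object))
            ridx.append(np.arange(p.length))
        if not feats:
            continue
        out[name] = ResidueDataset(
            features=np.vstack(feats),
            labels=np.concatenate(labels),
            protein_ids=np.concatenate(pids),
            residue_indices=np.concatenate(ridx),
            ligand_filter=None if name == "universal" else name,
        )
    return out
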
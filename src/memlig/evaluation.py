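"""Confusion-matrix metrics and the cross-validation / independent-test protocols.

Metrics are the four standard binary-classification quantities computed
from the confusion counts:

    Spe = TN / (TN + FP)
    Sen = TP / (TP + FN)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is the headline number throughout: with binding residues 140-200
times rarer than non-binding ones, accuracy alone is uninformative.
A metric whose denominator is zero is reported as ``None`` with a
reason, never silently as 0 — silent zeros corrupt ratio sweeps at
extreme under-sampling ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from memlig.classifier import ModelBundle, RFConfig, predict_labels, train
from memlig.encoders import PCPTable, DEFAULT_PCP, WindowSpec, encode_protein, segment_slices
from memlig.sampling import ResidueDataset, RUSConfig, rus_sample

FEATURE_GROUPS = ("PSSM", "TOPO", "PCP", "SeqSeg")
_GROUP_TO_SEGMENT = {"PSSM": "pssm", "TOPO": "topo", "PCP": "pcp", "SEQSEG": "seqseg"}


@dataclass
class EvalMetrics:
    """Confusion counts plus the four derived metrics.

    Derived values are ``None`` when their denominator is zero; the
    ``undefined`` mapping then records the reason.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    spe: float | None = field(init=False)
    sen: float | None = field(init=False)
    acc: float | None = field(init=False)
    mcc: float | None = field(init=False)
    undefined: dict = field(init=False, default_factory=dict)

    def __post_init__(self):
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        if min(tp, fp, tn, fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        total = tp + fp + tn + fn
        if total == 0:
            raise ValueError("empty confusion matrix")

        self.spe = tn / (tn + fp) if (tn + fp) else None
        if self.spe is None:
            self.undefined["spe"] = "no true negatives or false positives (TN+FP=0)"
        self.sen = tp / (tp + fn) if (tp + fn) else None
        if self.sen is None:
            self.undefined["sen"] = "no positive ground-truth labels (TP+FN=0)"
        self.acc = (tp + tn) / total

        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom == 0:
            self.mcc = None
            zero = [
                name
                for name, v in [
                    ("TP+FP", tp + fp), ("TP+FN", tp + fn),
                    ("TN+FP", tn + fp), ("TN+FN", tn + fn),
                ]
                if v == 0
            ]
            self.undefined["mcc"] = f"zero factor(s) in denominator: {', '.join(zero)}"
        else:
            self.mcc = (tp * tn - fp * fn) / math.sqrt(denom)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "spe": self.spe, "sen": self.sen, "acc": self.acc, "mcc": self.mcc,
            "undefined": dict(self.undefined),
        }


def compute_metrics(true_labels, predicted_labels) -> EvalMetrics:
    """Confusion counts and metrics from two equal-length boolean vectors."""
    y = np.asarray(true_labels, dtype=bool)
    p = np.asarray(predicted_labels, dtype=bool)
    if y.shape != p.shape:
        raise ValueError(f"label length mismatch: {y.shape} vs {p.shape}")
    tp = int(np.sum(y & p))
    fp = int(np.sum(~y & p))
    tn = int(np.sum(~y & ~p))
    fn = int(np.sum(y & ~p))
    return EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class CVResult:
    """Per-fold metrics plus their arithmetic mean.

    The summary follows the average-of-sub-predictors convention: each
    metric's mean is taken over the folds where it is defined
    (``n_defined`` records how many).  ``pooled`` aggregates the
    confusion counts of all folds instead, for the alternative reading.
    """

    folds: list[EvalMetrics]
    mean: dict = field(init=False)
    pooled: EvalMetrics = field(init=False)

    def __post_init__(self):
        self.mean = {}
        for name in ("spe", "sen", "acc", "mcc"):
            vals = [getattr(f, name) for f in self.folds if getattr(f, name) is not None]
            self.mean[name] = float(np.mean(vals)) if vals else None
            self.mean[f"n_defined_{name}"] = len(vals)
        self.pooled = EvalMetrics(
            tp=sum(f.tp for f in self.folds),
            fp=sum(f.fp for f in self.folds),
            tn=sum(f.tn for f in self.folds),
            fn=sum(f.fn for f in self.folds),
        )


def cross_validate(
    dataset: ResidueDataset,
    k: int = 10,
    rf: RFConfig = RFConfig(),
    rus: RUSConfig | None = RUSConfig(),
    seed: int = 0,
    grouped: bool = False,
    sample_first: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of the under-sample-then-forest pipeline.

    Positives and negatives are each divided into k equal parts; every
    fold's model is trained on the other k-1 parts.  By default RUS is
    applied inside each training fold only, so validation folds keep the
    natural class imbalance; ``sample_first=True`` instead under-samples
    the whole dataset once before splitting (the alternative reading of
    the protocol).  ``grouped=True`` keeps all residues of a protein in
    one fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2 (no held-out data otherwise)")
    if sample_first and rus is not None:
        dataset = rus_sample(dataset, rus)
        rus = None
    y = dataset.labels.astype(int)
    if y.sum() < k or (len(y) - y.sum()) < k:
        raise ValueError(
            f"need at least {k} samples of each class for {k}-fold stratified CV "
            f"(have {int(y.sum())} positives, {int(len(y) - y.sum())} negatives)"
        )
    if grouped:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(dataset.features, y, groups=dataset.protein_ids)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(dataset.features, y)

    folds: list[EvalMetrics] = []
    for fold_i, (train_idx, val_idx) in enumerate(splits):
        train_ds = dataset.subset(train_idx)
        fold_rus = None
        if rus is not None:
            # derive a distinct, reproducible per-fold sampling seed
            fold_rus = RUSConfig(ratio=rus.ratio, seed=(rus.seed * 1000 + fold_i) % (2**31))
        bundle = train(train_ds, rf=rf, rus=fold_rus)
        pred = predict_labels(bundle, dataset.features[val_idx])
        folds.append(compute_metrics(dataset.labels[val_idx], pred))
    return CVResult(folds=folds)


def evaluate_independent(
    bundle: ModelBundle,
    test_proteins,
    profiles,
    topologies,
    table: PCPTable = DEFAULT_PCP,
    spec: WindowSpec = WindowSpec(),
) -> EvalMetrics:
    """Encode and score every residue of the held-out proteins.

    No resampling on the test side; metrics are pooled over all residues
    of all proteins, not averaged per protein.  ``profiles`` and
    ``topologies`` are mappings keyed by protein id.
    """
    test_proteins = list(test_proteins)
    if not test_proteins:
        raise ValueError("empty test set")
    y_parts, p_parts = [], []
    for prot in test_proteins:
        X = encode_protein(prot, profiles[prot.id], topologies[prot.id], table, spec)
        p_parts.append(predict_labels(bundle, X))
        y_parts.append(prot.binding_mask)
    return compute_metrics(np.concatenate(y_parts), np.concatenate(p_parts))


def feature_group_columns(
    groups: Sequence[str], spec: WindowSpec = WindowSpec()
) -> np.ndarray:
    """Column indices of the selected feature groups within the full vector."""
    if not groups:
        raise ValueError("at least one feature group required")
    sl = segment_slices(spec)
    cols: list[np.ndarray] = []
    seen = set()
    for g in groups:
        key = _GROUP_TO_SEGMENT.get(g.upper())
        if key is None:
            raise ValueError(f"unknown feature group {g!r}; allowed: {FEATURE_GROUPS}")
        if key in seen:
            continue
        seen.add(key)
        cols.append(np.arange(sl[key].start, sl[key].stop))
    # preserve canonical segment order regardless of request order
    return np.sort(np.concatenate(cols))


def ablation(
    dataset: ResidueDataset,
    feature_groups: Sequence[str],
    protocol: Callable[[ResidueDataset], EvalMetrics | CVResult],
    spec: WindowSpec = WindowSpec(),
):
    """Evaluate the pipeline on a subset of the four feature groups.

    ``protocol`` receives the column-sliced dataset and runs training plus
    evaluation (e.g. a cross-validation or held-out closure).
    """
    cols = feature_group_columns(feature_groups, spec)
    sliced = ResidueDataset(
        features=dataset.features[:, cols],
        labels=dataset.labels,
        protein_ids=dataset.protein_ids,
        residue_indices=dataset.residue_indices,
        ligand_filter=dataset.ligand_filter,
    )
    return protocol(sliced)


def all_group_combinations() -> list[tuple[str, ...]]:
    """The 15 non-empty subsets of the four feature groups, smallest first."""
    from itertools import combinations

    out = []
    for r in range(1, 5):
        out.extend(combinations(FEATURE_GROUPS, r))
    return out
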
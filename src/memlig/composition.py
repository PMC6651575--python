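"""Descriptive statistics of binding residues.

Four analyses characterize what distinguishes ligand-binding residues:

* relative residue composition — how enriched each amino acid is among
  binding residues relative to the all-residue background of the same
  dataset (polar hydrophilic residues C, H, D are typically enriched,
  especially for metal ions);
* a two-sample logo — position-wise enrichment/depletion of residues in
  windows around binding residues versus non-binding windows;
* per-feature Pearson correlation between encoded features and the
  binding label;
* the membrane-topology distribution of binding residues (binding sites
  overwhelmingly sit outside the membrane region).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from memlig.encoders import WindowSpec, feature_names
from memlig.formats_io import PSSM_ALPHABET, ProteinRecord, TopologyAnnotation
from memlig.sampling import ResidueDataset

WINDOW_GAP = "-"


@dataclass
class CompositionProfile:
    """Per-amino-acid binding vs background frequencies and their ratio.

    ``relative[aa]`` is binding frequency / background frequency; ``None``
    when the background frequency is zero (flagged, never silently 0).
    """

    binding_freq: dict[str, float]
    background_freq: dict[str, float]
    relative: dict[str, float | None]
    n_binding: int
    n_background: int
    category: str | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "aa": list(PSSM_ALPHABET),
                "binding_freq": [self.binding_freq[a] for a in PSSM_ALPHABET],
                "background_freq": [self.background_freq[a] for a in PSSM_ALPHABET],
                "relative": [self.relative[a] for a in PSSM_ALPHABET],
            }
        )


def relative_composition(
    proteins: Sequence[ProteinRecord], category: str | None = None
) -> CompositionProfile:
    """Relative composition of binding residues against the dataset background.

    With ``category`` set, positives are residues binding that ligand
    category and the background is restricted to proteins that have at
    least one such residue (the category's own dataset).
    """
    bind_counts = dict.fromkeys(PSSM_ALPHABET, 0)
    back_counts = dict.fromkeys(PSSM_ALPHABET, 0)
    for p in proteins:
        if category is None:
            pos_mask = p.binding_mask
        else:
            pos_mask = np.array([category in c for c in p.ligand_categories], dtype=bool)
            if not pos_mask.any():
                continue
        for aa in p.sequence:
            back_counts[aa] += 1
        for i in np.flatnonzero(pos_mask):
            bind_counts[p.sequence[i]] += 1
    n_bind = sum(bind_counts.values())
    n_back = sum(back_counts.values())
    if n_bind == 0:
        raise ValueError("no binding residues in the requested dataset")
    bind_f = {a: bind_counts[a] / n_bind for a in PSSM_ALPHABET}
    back_f = {a: back_counts[a] / n_back for a in PSSM_ALPHABET}
    rel = {
        a: (bind_f[a] / back_f[a]) if back_f[a] > 0 else None for a in PSSM_ALPHABET
    }
    return CompositionProfile(
        binding_freq=bind_f,
        background_freq=back_f,
        relative=rel,
        n_binding=n_bind,
        n_background=n_back,
        category=category,
    )


def residue_windows(
    proteins: Sequence[ProteinRecord],
    positive: bool,
    spec: WindowSpec = WindowSpec(),
    category: str | None = None,
) -> list[str]:
    """Sequence windows (strings, ``-`` for out-of-bounds) around binding
    (``positive=True``) or non-binding residues."""
    h = spec.half_width
    out = []
    for p in proteins:
        if category is None:
            mask = p.binding_mask
        else:
            mask = np.array([category in c for c in p.ligand_categories], dtype=bool)
        padded = WINDOW_GAP * h + p.sequence + WINDOW_GAP * h
        for i in range(p.length):
            if bool(mask[i]) == positive:
                out.append(padded[i : i + 2 * h + 1])
    return out


def _two_proportion_p(x1: int, n1: int, x2: int, n2: int) -> float:
    """Pooled two-proportion z-test (two-sided p-value)."""
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return float(2 * stats.norm.sf(abs(z)))


def two_sample_logo(
    pos_windows: Sequence[str],
    neg_windows: Sequence[str],
    alpha: float = 0.05,
    bonferroni: bool = False,
    spec: WindowSpec = WindowSpec(),
) -> pd.DataFrame:
    """Position-wise residue enrichment of one window set over another.

    For every (window offset, amino acid) cell, the occurrence frequency
    in the positive set is compared against the negative set with a
    pooled two-proportion z-test.  Cells with p < alpha are flagged
    enriched (positive frequency difference) or depleted (negative).
    ``bonferroni=True`` divides alpha by the number of cells.

    Returns a long-format frame with columns
    ``position`` (offset, -half_width..+half_width), ``aa``, ``pos_freq``,
    ``neg_freq``, ``diff``, ``p_value``, ``significant``, ``direction``.
    """
    if not pos_windows or not neg_windows:
        raise ValueError("both window sets must be non-empty")
    w = spec.window_length
    for name, ws in (("positive", pos_windows), ("negative", neg_windows)):
        bad = {len(x) for x in ws} - {w}
        if bad:
            raise ValueError(f"{name} windows with length(s) {sorted(bad)}; expected {w}")

    n1, n2 = len(pos_windows), len(neg_windows)
    threshold = alpha / (w * 20) if bonferroni else alpha
    rows = []
    for k in range(w):
        pos_col = [x[k] for x in pos_windows]
        neg_col = [x[k] for x in neg_windows]
        # gaps at termini are excluded from the per-position denominators
        n1k = sum(c != WINDOW_GAP for c in pos_col)
        n2k = sum(c != WINDOW_GAP for c in neg_col)
        for aa in PSSM_ALPHABET:
            x1 = sum(c == aa for c in pos_col)
            x2 = sum(c == aa for c in neg_col)
            if n1k == 0 or n2k == 0:
                p = 1.0
                diff = 0.0
            else:
                diff = x1 / n1k - x2 / n2k
                p = _two_proportion_p(x1, n1k, x2, n2k)
            sig = p < threshold
            rows.append(
                {
                    "position": k - spec.half_width,
                    "aa": aa,
                    "pos_freq": x1 / n1k if n1k else np.nan,
                    "neg_freq": x2 / n2k if n2k else np.nan,
                    "diff": diff,
                    "p_value": p,
                    "significant": sig,
                    "direction": "+" if diff > 0 else ("-" if diff < 0 else "0"),
                }
            )
    return pd.DataFrame(rows)


def feature_label_correlation(
    dataset: ResidueDataset, spec: WindowSpec = WindowSpec()
) -> pd.DataFrame:
    """Pearson r of every feature column against the binding label.

    Constant columns get ``r = NaN`` with ``constant = True`` — a zero
    would misstate "no linear association" as "measured zero".  The
    ``group`` column maps features to their family (PSSM/TOPO/PCP/SeqSeg)
    for grouped summaries.
    """
    X = np.asarray(dataset.features, dtype=float)
    y = dataset.labels.astype(float)
    yc = y - y.mean()
    sy = yc.std()
    if sy == 0:
        raise ValueError("labels are constant; correlation undefined")
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).mean(axis=0) / (sx * sy)
    constant = sx == 0
    r[constant] = np.nan

    names = feature_names(spec)
    if len(names) != X.shape[1]:
        names = [f"f_{i}" for i in range(X.shape[1])]

    def group_of(name: str) -> str:
        if name.startswith("pssm_"):
            return "PSSM"
        if name.startswith("topo_"):
            return "TOPO"
        if name.startswith("pcp_"):
            return "PCP"
        if name.startswith("aa_"):
            return "SeqSeg"
        return "other"

    return pd.DataFrame(
        {
            "feature": names,
            "group": [group_of(n) for n in names],
            "r": r,
            "constant": constant,
        }
    )


TOPOLOGY_NAMES = {"I": "inside", "O": "outside", "M": "membrane", "U": "unknown"}


def topology_distribution(
    proteins: Sequence[ProteinRecord],
    topologies: Mapping[str, TopologyAnnotation],
) -> pd.DataFrame:
    """Counts and fractions of binding residues per topology state."""
    counts = dict.fromkeys("IOMU", 0)
    for p in proteins:
        states = topologies[p.id].states
        if len(states) != p.length:
            raise ValueError(f"topology length mismatch for {p.id!r}")
        for i in np.flatnonzero(p.binding_mask):
            counts[states[i]] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no binding residues")
    return pd.DataFrame(
        {
            "state": list("IOMU"),
            "location": [TOPOLOGY_NAMES[s] for s in "IOMU"],
            "count": [counts[s] for s in "IOMU"],
            "fraction": [counts[s] / total for s in "IOMU"],
        }
    )
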
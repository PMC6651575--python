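"""memlig: sequence-based prediction of membrane protein-ligand binding residues.

The pipeline encodes each residue of a membrane protein with a hybrid
269-dimensional feature vector built over a 7-residue sliding window
(evolutionary profile, membrane topology, physicochemical properties,
and window amino-acid composition), tames the extreme binding/non-binding
class imbalance with random under-sampling, and classifies residues with
a random forest.  Ligand-specific sub-models (drug-like compound, metal
ion, biomacromolecule) refine the universal predictor.
"""

from memlig.formats_io import (
    ProteinRecord,
    PSSMProfile,
    TopologyAnnotation,
    PredictionRecord,
    read_fasta,
    read_pssm,
    read_topology,
    read_annotations,
)
from memlig.encoders import (
    WindowSpec,
    PCPTable,
    ResidueFeatureVector,
    encode_protein,
    encode_residue,
    pseudo_pssm,
)
from memlig.sampling import ResidueDataset, RUSConfig, rus_sample, ratio_sweep
from memlig.classifier import RFConfig, ModelBundle, train, predict, build_ligand_datasets
from memlig.evaluation import EvalMetrics, compute_metrics, cross_validate, evaluate_independent, ablation
from memlig.composition import (
    relative_composition,
    two_sample_logo,
    feature_label_correlation,
    topology_distribution,
)
from memlig.synthetic import SimConfig, simulate

__version__ = "0.1.0"

__all__ = [
    "ProteinRecord", "PSSMProfile", "TopologyAnnotation", "PredictionRecord",
    "read_fasta", "read_pssm", "read_topology", "read_annotations",
    "WindowSpec", "PCPTable", "ResidueFeatureVector",
    "encode_protein", "encode_residue", "pseudo_pssm",
    "ResidueDataset", "RUSConfig", "rus_sample", "ratio_sweep",
    "RFConfig", "ModelBundle", "train", "predict", "build_ligand_datasets",
    "EvalMetrics", "compute_metrics", "cross_validate", "evaluate_independent", "ablation",
    "relative_composition", "two_sample_logo", "feature_label_correlation", "topology_distribution",
    "SimConfig", "simulate",
]
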
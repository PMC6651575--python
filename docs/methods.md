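# Methods

## The prediction problem

Given a membrane protein's amino-acid sequence, an evolutionary profile,
and a predicted membrane topology, classify every residue as
ligand-binding or not.  The problem is extremely imbalanced: in curated
benchmark data non-binding residues outnumber binding ones by roughly
140–220 to 1, which shapes every design choice below (under-sampling,
MCC as the headline metric, recall-friendly tie-breaking).

## Feature encoding

Every residue is encoded over a sliding window of 7 residues — the
target plus 3 upstream and 3 downstream.  The four segments, always
concatenated in the order PSSM ‖ TOPO ‖ PCP ‖ SeqSeg:

* **PSSM (140)** — the 7 window rows of the protein's L×20 log-odds
  profile, in PSI-BLAST column order (A R N D C Q E G H I L K M F P S T
  W Y V).  Values are used as raw log-odds with no sigmoid squashing:
  tree ensembles are invariant to monotone rescaling, and raw scores
  keep the diagnostics interpretable.
* **TOPO (4)** — counts of the topology states I (inside), O (outside),
  M (membrane-spanning), U (unknown/non-membrane) over the in-bounds
  window positions.  The U state is counted as a fourth dimension rather
  than ignored: dropping it would discard the distinction between "a
  short window at a terminus" and "a window in an unannotated region",
  and the 269 total dimension fixes the segment at 4.
* **PCP (105)** — for each window position, 15 physicochemical property
  values of its residue, min–max normalized to [0,1] per property over
  the 20 amino acids.  Raw AAindex properties span four orders of
  magnitude (net charge ±1 vs molecular weight ~200); normalization does
  not change the forest but makes correlation heat maps comparable
  across properties.  The 15 properties and the AAindex accession chosen
  to realize each are pinned in `encoders.PCPTable` (hydrophilicity
  HOPT810101, hydrophobicity KYTJ820101, net charge KLEP840101, polarity
  GRAR740102, size DAWD720101, residue volume BIGC670101, molecular
  weight FASG760101, diameter FAUJ880103, amino-acid composition
  DAYM780101, membrane-protein composition CEDJ970105, side-chain
  interaction KRIW790101, solvation free energy EISD860101, transfer
  free energy NOZY710101, average flexibility BHAR880101, accessible
  surface area CHOC760101); the table is a plain dict and deliberately
  swappable.
* **SeqSeg (20)** — amino-acid composition counts of the in-bounds
  window residues in PSSM column order.

Window positions outside the sequence contribute zero rows to PSSM and
PCP (keeping the dimension fixed at 269, the dominant convention in
window-based residue predictors) and are simply not counted in TOPO and
SeqSeg, so `sum(topo) == sum(seqseg) ==` the number of in-bounds
positions — an invariant the property tests enforce.

When a real PSI-BLAST profile is unavailable, `pseudo_pssm` substitutes
the BLOSUM62 row of each residue (marked `source="pseudo"`).  This keeps
the pipeline runnable and deterministic but carries no alignment-depth
information; conclusions about PSSM feature importance on pseudo
profiles reflect residue identity plus whatever signal a generator
plants, not real conservation.

## Imbalance handling

Random under-sampling keeps every binding residue and draws
`ratio × P` non-binding residues uniformly without replacement
(default ratio 30).  In cross-validation, RUS is applied **inside each
training fold only**, so validation folds retain the natural imbalance;
resampling before splitting would let the validation distribution leak
into training and inflate metrics.  A `sample_first` flag restores the
sample-then-split protocol for comparison.  Requesting more negatives
than exist keeps all negatives and warns rather than failing.

## Classifier

A random forest of 140 CART (Gini) trees, 20 candidate features per
split, bootstrap resampling of the under-sampled training set, trees
grown to purity (no depth cap), via scikit-learn's
`RandomForestClassifier`.  The prediction score is the fraction of tree
votes for the binding class; `score >= 0.5` is classified binding —
ties break toward the positive class because users of a binding-site
predictor want candidate residues, not certainty.  Model bundles record
the feature-schema fingerprint, training counts, the RUS ratio and all
seeds, and refuse to score feature matrices of the wrong dimension.

Ligand-specific models decompose the task: the drug, metal and
biomacromolecule datasets each contain only proteins with at least one
residue binding that category; positives are that category's residues
and negatives the remaining residues of those proteins.  A residue
binding two categories is a positive in both datasets, so the datasets
overlap by construction.

## Evaluation

`compute_metrics` derives Spe, Sen, ACC and MCC directly from the
confusion counts.  Any metric with a zero denominator is reported as
`None` with a reason string, never silently as 0 — at extreme
under-sampling ratios a model can make no positive calls at all, and a
silent zero would corrupt ratio sweeps.  Cross-validation is
class-stratified (each class divided into k equal parts); the summary is
the arithmetic mean of per-fold metric values over the folds where each
is defined (pooled confusion counts are also reported).  Independent
testing encodes and scores every residue of held-out proteins with no
test-side resampling and pools residues across proteins.  Ablation
slices the feature matrix by segment columns and re-runs any evaluation
protocol; all 15 non-empty group combinations are enumerable.

## Descriptive statistics

* Relative composition: binding-residue amino-acid frequencies divided
  by the all-residue frequencies of the same dataset (not a uniform
  background); zero-background ratios are flagged null.
* Two-sample logo: per (window position, amino acid), a pooled
  two-proportion z-test between binding-centered and
  non-binding-centered windows at α = 0.05, without multiple-testing
  correction by default (matching standard two-sample-logo practice);
  a Bonferroni option divides α by the 140 cells.  Under the null the
  significant-cell rate measures ~0.048 at 250 windows per class.
* Feature–label correlation: Pearson r per feature column against the
  binary label, constant columns flagged rather than zeroed, grouped by
  feature family.
* Topology distribution: counts and fractions of binding residues per
  topology state.

## Synthetic data generator

The generator emulates the *structure* of a curated membrane-protein
binding-site benchmark, not its biological detail.  Defaults, chosen
once: 120 proteins, lengths uniform on [50, 400], binding prevalence
1/150 per residue (binomial per protein), ligand-category mixture
drug 0.20 / metal 0.55 / biomacromolecule 0.25 (matching the rough
proportions of curated positive counts), 3% of binding residues
assigned a second category.  Topology alternates inside/outside loops
(5–40 residues) with membrane runs of ~21 ± 3 residues; 15% of proteins
are all-U.

Signal is planted in three independent channels:

* composition — with probability 0.7 a binding residue is rewritten to
  one of C/H/D, the polar hydrophilic residues enriched at real binding
  sites;
* conservation — the pseudo-profile (BLOSUM62 row + N(0, 2) noise,
  rounded) gets +8 on the residue's own column at binding positions;
* topology placement — binding positions are drawn with weight 0.05 on
  membrane-spanning residues, reproducing the observation that very few
  binding residues are transmembrane.

The conservation boost and composition bias were fixed so that the
default generator satisfies the module's contract that the full
pipeline (RUS 30, 140-tree forest) recovers the planted signal with
held-out MCC ≥ 0.5 with margin (measured 0.74–0.82 across seeds);
`SimConfig.null()` zeroes all three channels, and the same pipeline then
shows no association (typically zero positive calls).  What passing
these tests shows: the encoders, sampler, forest and protocols are wired
correctly and can extract a multi-channel planted signal at realistic
imbalance.  What it does not show: performance on real proteins, where
conservation is position-dependent, binding sites cluster spatially, and
PSSMs derive from actual alignments.

## Problem sizes and numerics

The test suite and the acceptance script run on desk-scale data chosen
to exercise every code path with stable statistics: 120-protein
simulations (~27k residues) for pipeline recovery and ablation, a
100/1000-sample dataset for fold-size checks, 200 null trials of 250
windows per class for logo calibration, 100 seeds for the RUS uniformity
chi-square.  The headline benchmark results reported for the original
curated datasets (universal independent-test MCC ≈ 0.63, metal ≈ 0.7)
require ~2,700 UniProt-derived proteins with PSI-BLAST profiles against
nr and TOPCONS runs, and are out of scope here.

Determinism: every stochastic stage (generator, RUS, fold shuffling,
forest) takes an explicit seed; per-fold RUS seeds are derived as
`seed·1000 + fold` to be distinct but reproducible.  The chi-square
uniformity statistic is conservative because without-replacement draws
fix each seed's total, slightly underdispersing per-negative counts.

## Known limitations

* The embedded AAindex property values are transcribed constants; users
  wanting exact published index values for a different property set
  should supply their own table to `PCPTable`.
* The topology file format is FASTA-like by design; raw TOPCONS
  per-residue output must be joined into a single state string per
  protein (one-line transformation) before reading.
* Grouped (protein-level) fold assignment is available but not the
  default; with residue-level folds, residues of one protein can span
  folds, which matches the stated CV protocol but can flatter metrics
  when windows overlap.
* The two-sample-logo z-test is asymptotic; with very few windows per
  class (tens) its calibration degrades and the Bonferroni option or an
  exact test on exported counts is advisable.
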
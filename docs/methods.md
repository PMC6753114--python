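# Methods

This note documents the models, conventions and design choices behind
`guidehf`, and what the synthetic-data tests do and do not establish.

## Coordinates and sequence conventions

Internally all coordinates are 0-based, half-open. Positions reported to
users are 1..20 along the 20-nt spacer, 5'→3', so position 20 is the base
immediately adjacent to the NGG PAM (`G_20` means a G there; `GG_19` a GG
dimer starting at position 19). The manifest stores each target context in
the orientation where spacer+PAM read left to right. The sgRNA scaffold is
the 81-nt constant used as the parsing anchor; it is configurable on the
`LibraryManifest`.

## Indel quantification

Per read: bases with Phred quality < 10 are masked to N; the read must then
contain the scaffold exactly (a masked base inside the scaffold window
breaks the match, so the anchor is N-free by construction); reads with ≥ 4
masked bases are dropped; the 20-nt barcode (5' of the scaffold) and the
target region (3' of it) must be entirely N-free. Demultiplexing is by
exact spacer match — for a synthesized amplicon design this is equivalent to
aligning against an index of the designed guides, and it is deterministic
with no external aligner. The scaffold-match test is applied before the
N-count budget; the pipeline order matters only for which rejection status a
doomed read receives.

Target sequences observed in the *unedited plasmid* library that differ from
the design are catalogued as synthesis/PCR errors. In the edited library
those sequences are removed first; of the remainder, reads differing from
the design count as edited, and

    indel frequency = edited / total  (total = post-removal count),

with a guide valid only when total > 100 (`min_reads`). The denominator is
the post-removal count because removal precedes classification. Rejected and
unmatched reads are tallied in the QC report, never silently dropped. Guides
with zero post-removal reads report frequency 0.0 and valid=False rather
than NaN.

## Guide design rules

Candidate guides are all N20-NGG sites on both strands. Library filters: the
spacer must start with A or G (a mouse U6 promoter can initiate either
base, and high-fidelity nucleases do not tolerate a 5' mismatch introduced
by forcing a G) and must not contain TTTT (Pol III terminator). The TTTT
scan covers the spacer only, not the PAM. Ranking is caller-supplied
(`rank_key`); by default input order is kept, and a trained activity model
can serve as the ranker. Up to four guides per feature are retained.

## Feature engineering

* **Indicators**: 20×4 position-dependent mononucleotide indicators, 19×16
  overlapping dinucleotide indicators, 4 + 16 composition counts (dimer
  counts are overlapping, so `n_TT` of a poly-T 20-mer is 19), and the
  longest homopolymer run.
* **Thermodynamics**: duplex melting temperatures from the unified
  nearest-neighbor parameter set (Biopython `Tm_NN`), at 50 mM Na+, 250 nM
  strand (25 nM complement), entropy salt correction. Besides the global Tm,
  segment Tms cover positions 1–5 (PAM-distal), 6–13 (middle) and 14–20
  (PAM-proximal), the segmentation long used by on-target feature sets.
* **Secondary structure**: the default backend is a base-pair-maximization
  dynamic program (Nussinov-style) over Watson–Crick + G-U pairs with
  minimum hairpin loop 3. Its score is the negated pair count (lower = more
  folded, matching the sign of a free energy); it also yields a pairing
  vector, per-position accessibility (1 = unpaired) and the hairpin-loop
  count. It is deterministic, dependency-free, numba-accelerated, and equals
  an exhaustive-search oracle on all sequences up to length 12 in the test
  suite. Traceback ties prefer leaving 5' bases unpaired. An `external`
  backend shells out to ViennaRNA `RNAfold` for true MFE energies and is an
  explicit error when the binary is absent — never a silent fallback.
* **Registry**: the fusion model's biofeature vector h_bio is assembled from
  named groups. The default registry is `gc` (2), `tm` (4), `self_fold` (2)
  and `scaffold_fold` (2 + 20 per-position accessibilities within
  spacer+scaffold), so p = 30. The composition is fingerprinted
  (SHA-256 of the group and feature names) and stored with every trained
  model; prediction refuses to run on a mismatch. A `minimal` registry
  (p = 8, no full-length fold) exists for contexts where features must be
  recomputed for many hybrid sequences. The full published inventories of
  screen-scale feature sets run to ~1,000 columns; the `feature_table` here
  covers every family (indicators, counts, Tm, GC, folding, accessibility;
  435 columns) without reproducing any specific inventory verbatim.

## Sequence encoding and the network

A spacer is encoded as 21 tokens — a START symbol plus the 20 bases — over
the vocabulary (START, A, C, G, T); the length-21 input is interpreted as
START + spacer, isolated behind `encode_sequence` so the alternative
(spacer + first PAM base) would be a one-function change. One-hot rows are
embedded by a 5×m lookup matrix (equivalently a matrix product, tested both
ways). The recurrence is the standard LSTM gate system; the bidirectional
pass runs 5'→3' and 3'→5' with separate parameters and concatenates per-step
hidden states to 2n. The fusion head input is
`concat(h_bio, flatten(H_bi))` of dimension 21·2n + p, asserted at build
time, followed by ReLU dense layers (dropout optional) and a sigmoid output
unit so predictions respect the [0, 1] activity range. A sigmoid (rather
than an unconstrained linear output) is a deliberate choice: the target is a
frequency, and bounding the output stabilizes small-sample training.

Training: minibatch Adam on mean squared error, early stopping on
validation Spearman with configurable patience, parameters restored to the
best epoch. Everything is seeded; the same seed and config reproduce the
same fit bit-for-bit. Gradients come from a ~200-line reverse-mode autodiff
engine over numpy (matmul, broadcasting add, elementwise ops, concat,
1-D convolution); every op and an LSTM-like recurrence are checked against
central-difference gradients in the tests. Divergent (non-finite) loss
raises with the offending configuration attached.

Baselines: linear/ridge/MLP (scikit-learn pipelines with standardization),
gradient-boosted trees (xgboost), and a 1-D CNN over the one-hot sequence
(width-5 filters by default; fully configured, not hard-coded). Conventional
kinds train on train+validation (85 %) since they have no early-stopping
use for a validation set; neural kinds use the 76.5/8.5/15 partition. The
split is a seeded shuffle with floor(0.765 N)/floor(0.085 N)/remainder
sizes — the rule that reproduces a 42,537/4,726/8,341 partition of 55,604
guides exactly.

Hyperparameter search evaluates candidate configurations by validation
Spearman; random search is the deterministic default, and a Bayesian
strategy (Gaussian process + expected improvement over the numeric encoding
of the space) is available. `kfold_validation` is *shuffled* validation —
k independent reshuffles of the three-way split, not a k-way partition —
reporting mean ± sd. Transfer learning (`fine_tune`) updates only the
parameters in scope; `last_hidden_layer` means the final dense hidden layer
plus the output transform, leaving embedding and recurrent weights
bit-identical.

## Interpretation

Shapley attributions come from three explainers. For linear models the
closed form w_i(x_i − E[x_i]) is exact. For gradient-boosted trees the
exact polynomial-time Tree SHAP implemented inside xgboost is used
(`pred_contribs`). For everything else — including the recurrent fusion
model — a model-agnostic permutation-sampling estimator walks from a
background sample to the explained input one feature at a time and averages
marginal changes over permutations. Permutations are drawn in antithetic
(forward, reversed) pairs bound to a common background row, which cancels
the sampling error contributed by pairwise feature interactions; because
marginal changes telescope, attributions sum exactly to
prediction − base at any budget (local accuracy by construction). The
estimator is checked against exhaustive coalition enumeration at ≤ 8
features. This model-agnostic route was chosen over a DeepLIFT-style
backpropagation approximation because the quantity of interest is defined by
the Shapley semantics, not by any particular approximation; a
backprop-based explainer could be slotted in behind the same interface.

For sequence models the attribution features are the 20 spacer positions;
hybrids are re-featurized in full, so effects that flow through derived
biofeatures (Tm, folding) are attributed back to the positions causing
them. Position profiles average attributions over the *carriers* of each
nucleotide at each position — the only well-defined reading of a
per-(position, nucleotide) average — then Z-standardize jointly over all 80
cells (a single global standardization matches the use of one |Z| > 1
threshold; cells with no carriers are excluded and flagged). Between-model
contrasts use ΔZ with |ΔZ| > 1. Repetitive 4-mer contributions sum
attributions over the motif window per start position, starts 1..17 on the
spacer (a flag relabels them in the coordinates of the length-21 encoded
input). Log-odds composition contrasts the top and bottom activity
quantiles (default 25 %) per (position, nucleotide) with Laplace
pseudocounts: ln((c_top+0.5)/(N_top+2)) − ln((c_bot+0.5)/(N_bot+2)); natural
log and the +0.5/+2 smoothing are configurable. The statistic depends only
on activity ranks.

## Synthetic data: what it emulates, what it does not

`simulate_activity_dataset` draws A/G-start spacers uniformly (motifs such
as TTTT are additionally planted in ~15 % of spacers so motif effects are
identifiable) and produces activities through a logit-linear planted rule —
position-nucleotide weights, motif penalties, scaled biofeature
coefficients — plus Gaussian logit noise (sd 0.25 by default) and a
logistic link. The default rule combines a strong G_20 bonus (+0.9), a C_20
penalty, PAM-proximal T penalties, a TTTT penalty (−1.2) and a Tm
coefficient (+0.6 per 10 °C), i.e. the effect families consistently
reported for SpCas9 guides; a Tm-dominated variant isolates the value of
feeding hand-crafted features to the network.

`simulate_screen_reads` emits barcode+scaffold+target reads for both
libraries: per-guide true frequencies are Beta(2,2); synthesis/PCR error
variants (same-length substitutions, so never confusable with indel
alleles) are injected at the same planted rates into both libraries; edited
reads carry 1–10 bp insertions/deletions at the canonical cut site (between
protospacer positions 17 and 18, 3 bp 5' of the PAM); 5 % of reads carry a
single Q5 base to exercise the masking path.

These generators validate the *mechanics* — estimator recovery within
binomial error, error-subtraction correctness, learnability and attribution
recovery of a planted rule. They do not emulate realistic Illumina error
spectra, PCR duplicates, lentiviral integration effects, or the true
sequence-activity landscape, so passing tests demonstrate correctness of
the pipeline, not expected predictive performance on real screens. Training
full-scale models on real data (tens of thousands of guides, hundreds of
epochs) is out of scope for the test suite; the shipped configurations are
CPU-sized (n = 3,000 guides, ≤ 40 epochs, hidden size 16–24), chosen as the
smallest sizes at which the planted rule is comfortably recovered.

## Numerical choices and degenerate inputs

* Spearman uses average ranks for ties; constant prediction vectors yield an
  explicit undefined flag rather than NaN propagation.
* Feature selection keeps the ceil(fraction·k) largest mean |SHAP| features,
  ties at the cut broken lexicographically for determinism.
* Z-standardization with zero variance (e.g. all-zero attributions) sets a
  degenerate flag; nothing is called significant.
* Quantification with zero post-removal reads reports frequency 0.0,
  valid=False.
* All stochastic components take explicit seeds; derived seeds stay below
  2^31.

## Known limitations

* The internal fold backend maximizes base pairs; it is a topological, not
  thermodynamic, model. Energies require the external ViennaRNA backend.
* The sampling explainer's per-guide cost grows linearly in permutations ×
  sequence length; profiles over thousands of guides are better served by
  the tree explainer on the indicator feature table.
* `fine_tune` re-splits the new data internally when it is large enough;
  for very small transfer sets it trains on everything without early
  stopping.
* The CNN baseline is a deliberately simple convolution + dense head, a
  reference point rather than a tuned architecture.
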
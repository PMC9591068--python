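# Methods

## The model

`crossdti` predicts binary drug–target interactions (DTIs) from a drug's
SMILES string and a protein's amino-acid sequence with a cross-attention
encoder and a convolutional decoder.

Both sequences are tokenized, mapped to integer labels, right-padded to
fixed position caps (50 drug tokens, 545 protein tokens by default), and
embedded. With the learned ("nn.Embedding"-style) schemes each position
receives the sum of a token-table row and a position-table row, giving
50×384 and 545×384 embedding matrices at the defaults; with the one-hot
schemes a position receives the indicator row of its label.

The attention layer computes, per head *i* of *h* = 4 heads,

    Q_i^P = Y^P W_i^Q     K_i^D = Y^D W_i^K     V_i^D = Y^D W_i^V
    AttentionWeight_i^P = softmax(Q_i^P (K_i^D)^T / √d)
    head_i^P = AttentionWeight_i^P · V_i^D

with *d* = 384/*h* = 96 the per-head width, and assembles the protein
context matrix

    C^P = concat(Q_1^P … Q_h^P) + concat(head_1^P … head_h^P) · W_0 ,

i.e. a residual of the concatenated per-head queries plus the projected
multi-head attention output. The drug context C^D swaps the roles of the
two sequences. Self-attention variants use one sequence for queries,
keys and values alike. Architectures are named by their mechanism,
depth, context selection and head: CA_DP, CA2_DP, CA3_DP, CA_DP_FCL,
SA_DP, CA_D, and the default CA_P (one cross-attention layer, protein
context only, CNN decoder).

The CNN decoder applies two blocks of (1-D convolution along the
sequence axis with features as channels, ReLU, max-pool, dropout) and a
final linear layer; training optimizes binary cross-entropy on the
logit with Adam (learning rate 0.001, batch 128, up to 50 epochs), and
the parameters of the epoch with the best validation PRAUC are kept.
The alternative FCL decoder is two (linear, ReLU, dropout) blocks on
the flattened context plus a final linear layer.

Formal residual notation: the residual adds the feature-axis
concatenation of the per-head query matrices so that its width (h·d =
384) matches the multi-head output; W_0 is square (h·d × h·d). The
softmax denominator is √d (standard scaled dot-product); a plain-d
variant is exposed as `scale_mode="d"`.

## Tokenization

Five encoding schemes are provided. SMILES "characters" are strictly
single characters (a letter or a symbol), so `Cl` splits into `C`, `l`;
protein tokens are the 20 standard amino-acid letters, with anything
else mapped to UNK. SELFIES words come from a built-in encoder/decoder
covering the common organic subset (B/C/N/O/S/P/halogens, single,
double and triple bonds, branches, rings; aromatics are kekulized
first); every encoding is verified in tests by decoding back and
comparing RDKit canonical forms. Frequent-consecutive-subsequence (FCS)
mining is BPE-style: the most frequent adjacent token pair across the
training corpus is fused repeatedly until the best pair's frequency
falls below `min_freq` (default 5) or the vocabulary reaches
`max_vocab` (defaults 2,000 drug / 10,000 protein). Frequency ties
break by the lexicographic order of the fused token, making mining
deterministic. Segmentation replays merges by mining rank; this is
equivalent to ordered replay and is tested against it.

Vocabularies are mined on the training split only. Padding uses label
0; PAD key positions are excluded from the attention softmax by an
additive mask (a mask-free fidelity mode exists), and PAD query rows
are zeroed in the context so the decoder is invariant to padding
content.

## Dataset handling

Positive pairs are split 7:1:2 into train/validation/test (validation
and test counts floored, remainder to train). Training negatives are
downsampled without replacement to equal the training positives;
remaining negatives are divided between validation and test in their
1:2 ratio, so the test set keeps the source skew. Samples whose SMILES
RDKit cannot parse are dropped with a logged count. Splitting is by DTI
pair; cold-start (unseen drug/protein) splitting is out of scope.

## Evaluation

SN, SP, PR and F1 come from the 0.5-threshold confusion table (scores
exactly at the threshold count as positive); ROCAUC and PRAUC are
threshold-free, with PRAUC computed as step-wise average precision
(trapezoidal integration available), the robust choice for
negative-skewed test sets. `multi_run` averages all six metrics over
independently re-seeded trainings (5 by default) with fixed splits.

## Attention-site analysis

For interpretability the protein-query/drug-key attention weights of
the final layer are averaged over heads, cropped to true lengths, and
expanded to residue × atom resolution by broadcasting each token-level
weight over the residues/atoms its token pair covers. The k largest
cells (k = 30) are the attention sites; the consistency number of one
DTI counts sites whose residue coordinate is an annotated binding
residue. The null model redraws each protein's binding residues
uniformly at random (same count b, without replacement), keeps the
observed sites fixed, and records the mean consistency over DTIs;
10,000 iterations give a null profile whose mean and SD yield
z = (observed − mean)/SD. Under this null the single-DTI expectation is
k·b/L, which the tests verify against both the simulation and exact
enumeration for small L. Sensitivity analyses rerun everything for a
range of k and for site coordinates shifted by −2…+2 residues (shifted
coordinates outside [1, L] are dropped).

Ambiguities resolved as package choices: heads are averaged rather
than analysed singly; a "site" is a cell of the
expanded matrix and corresponds via its residue coordinate (a
per-residue max-over-atoms aggregation is provided as an alternative);
ties sort by ascending (residue, atom); coordinates are 1-based in all
reports.

## Synthetic data

The generator emulates curated DTI benchmarks at desk scale. Drugs are
concatenations of chain-safe SMILES fragments from a curated list (any
concatenation parses in RDKit); proteins are uniform random strings
over the 20 amino acids, 80–160 residues. A pair interacts iff the drug
contains a fixed SMILES motif (`CC(=O)NCC`) and the protein a fixed
8-residue motif (`HWYKRFDE`); labels are then flipped with probability
ρ (default 0.05). Proteins carrying the motif are annotated with its
residue positions as binding sites, giving the interpretability
analysis a known ground truth. The positive:negative ratio is
configurable (balanced by default; real benchmark test sets range from
balanced to >20-fold negative-skewed). Negative pairs lack the drug
motif, the protein motif, or both, with the type drawn uniformly, so a
model must learn the conjunction rather than either motif alone.

What the generator does **not** emulate: chemistry of binding, homology
structure among proteins, shared scaffolds among drugs, or realistic
sequence composition. Passing the signal-recovery test therefore shows
that the architecture, optimization and interpretability machinery can
extract a planted cross-sequence interaction — not that the model
reaches benchmark accuracy on real DTI data.

## Desk-scale study configuration

The packaged end-to-end study (tests and `scripts/acceptance.py`) uses
2,000 pairs, ρ = 0.05, the default CA_P architecture, and 10 training
epochs. Sizes were set to the data: FCS vocabulary caps 200 (drug) and
400 (protein) and a 96-token protein cap (an 80–160-residue protein
segments to roughly 60 FCS tokens). All other knobs are the defaults
above. The attention-site analysis uses the annotated positive test
pairs (capped at 160 DTIs), k = 30, 10,000 iterations.

## Numerical and design choices

* The network runs on a compact reverse-mode automatic-differentiation
  engine over float32 NumPy arrays written for this package; every
  operation is finite-difference tested, and the attention forward pass
  is additionally checked against an independent per-head loop.
* Projection weights initialize uniformly in ±1/√fan_in; token tables
  initialize N(0, 1); positional tables initialize N(0, 0.1). The small
  positional scale matters: position offsets comparable in magnitude to
  token vectors degrade the weight-shared convolution's ability to
  recognize token patterns regardless of position.
* CNN defaults: conv 384→64 then 64→32, kernels 3, max-pool width 4,
  dropout 0.1. The pool width is deliberately coarse so the flattened
  readout tolerates translation of localized sequence features; with
  pool 2 the planted protein motif is under-learned at desk scale.
* Truncation keeps the sequence prefix. Overlong proteins have binding
  annotations beyond the encoded prefix excluded from analysis.
* Score ties at the 0.5 threshold count as positive predictions.
* Model selection uses the best-validation-PRAUC epoch; validation
  PRAUC degenerates to negative training loss if the validation split
  is single-class.
* The five evaluation runs re-seed initialization/batching only; splits
  stay fixed.

## Known limitations

* The SELFIES codec covers the neutral organic subset only; charged,
  stereo-annotated or isotopic SMILES are skipped (with a logged
  error), matching the upstream filtering contract.
* Training is single-process CPU; the engine is adequate for
  desk-scale studies, not for the full public DTI benchmarks.
* FCS mining defaults suit large corpora; small corpora should cap the
  vocabulary (the estimator exposes `max_vocab_drug/protein`).
* No calibration of output probabilities is attempted; threshold-based
  metrics inherit the 0.5 convention.
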
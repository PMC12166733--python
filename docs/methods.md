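# Methods

## Data model

Proteins are plain amino-acid strings over the 20-letter alphabet; the
letter X is tolerated on input but masked out of training and evaluation,
since nothing meaningful can be learned or scored at an unknown residue.
Feature annotations use 1-based inclusive start/end coordinates at every
file boundary (the convention of curated protein databases); all internal
vectors are 0-based NumPy arrays of length equal to the protein, and the
conversion happens exactly once, in `build_label_track`.

Twenty controlled feature names are supported, organised into five groups
(functional; sub-cellular location; PTM & processing; structure; family &
domain). Two deliberate interpretation rules:

- **Disulfide bonds** are annotated as residue pairs, so only the two
  bonded cysteines are labelled — labelling the span between them would
  mark arbitrary interior residues with a property they do not have.
- **Absence of annotation is not a negative label.** A protein with no
  information for a feature receives an all-zero *mask*, making it a
  prediction-only target; it never contributes "absent" labels to training.

## Classifier

Backbone → per-residue embedding → head (linear to hidden 32 → ReLU →
dropout 0.2 → linear to 2 classes → softmax). The head depth and
nonlinearity are this package's choice (one hidden rectified layer); hidden
size and dropout follow the standard token-classification configuration.
Training uses Adam at learning rate 3·10⁻⁴ for 10 epochs with per-residue
cross-entropy; the epoch with the lowest pooled validation loss is the
checkpoint kept (first epoch wins ties). Batches accumulate gradients one
sequence at a time before each optimiser step — with masked losses this is
mathematically identical to padding to the longest sequence in a batch and
masking the padding, and it avoids any padding bookkeeping. The default
batch size is 1 (one optimiser step per sequence), which at desk scale
(tens of training proteins) gives the optimiser enough steps to converge
within the fixed 10 epochs.

Two modes:

- `frozen_embedding`: embeddings are computed once per sequence and cached;
  only the head receives gradients.
- `fine_tune`: LoRA adapters are attached at the query/key/value/output
  projections of every attention block (rank 4, α = 1, A ~ N(0, 0.01²),
  B = 0). Base backbone weights are never updated; the adapted forward pass
  is bit-identical to the frozen one until the first optimiser step, and the
  trainable backbone parameter count is exactly r·(d_in + d_out) per site.

**Class weighting** (off by default): inverse-frequency weights on the two
classes in the loss. Rare features (a few percent of residues) train to
well-ranked but under-confident probabilities under plain cross-entropy at
the fixed epoch budget; that is fine for AUROC-style evaluation but starves
the gain/loss-calling workflow, which needs the positive class to cross the
0.5 decision threshold. Workflows that call label flips should enable the
flag (the CLI exposes `--class-weighting`); headline evaluation is
threshold-free either way.

**Backbones.** `onehot_window(w)` encodes each residue as the one-hot
identities of the residues in a ±w window (dimension 20·(2w+1), X rows are
zero); it is deterministic and parameter-free, and any locally-determined
feature is exactly representable on top of it. `tiny_transformer` is a
single-head transformer encoder (default 1 layer, width 32, sinusoidal
positions, frozen random base weights seeded for reproducibility) whose
genuine q/k/v/o projections exercise the LoRA path end to end. The widths
were chosen once so the fixture task is learnable within the fixed training
budget; both backbones are stand-ins for large pretrained encoders in
scale, not in contract — any encoder mapping an L-residue sequence to an
L × d matrix with exposed attention projections can be slotted in.

**Long sequences** are processed in windows of the configured maximum
length (default 1024). At inference, windows overlap by 64 residues
(capped at half the window) and probabilities in overlaps are averaged; in
training, sequences are simply chunked, accepting truncated context at
chunk borders.

**Numerics.** The NN core is a small NumPy reverse-mode autodiff (float64
throughout). Gradients are verified against central finite differences in
the test suite. Softmax is computed with max-shift; inference never applies
dropout, so repeated predictions are bit-identical.

## Splitting

Cluster-level 70/15/15 splits. External MMseqs2 cluster TSVs
(`representative<TAB>member`) are read directly. The bundled fallback is a
greedy clusterer: proteins visited longest-first each join the first
representative whose k-mer-seeded best-diagonal match reaches the identity
threshold (default 0.2) at coverage ≥ 0.2, else found a new cluster.
Identity is normalised by the shorter sequence rather than by the seeded
overlap — per-overlap identity systematically overestimates similarity
between unrelated sequences when the overlap is short. The fallback is a
deterministic stand-in with the same interface, not a reimplementation of
MMseqs2's alignment.

Cluster-to-split assignment: shuffle clusters with the seed, order
largest-first (stable, so equal sizes keep shuffled order), and give each
cluster to the split with the largest remaining protein-count deficit
(ties to the earlier of train/validation/test). Fractions are measured in
proteins, matching the stated percentages; achieved fractions are
guaranteed within ±(largest cluster)/(total proteins) of the targets. A
single all-containing cluster cannot be split and goes to train with a
warning. Per-feature datasets are subsets of one global split, not
re-splits.

## Evaluation

Metrics are pooled over all masked-in residues (micro over residues) and
macro-averaged over the two classes for F1/precision/recall; AUROC, MCC and
accuracy complete the report. Single-class truth yields AUROC = NaN with a
warning — not 0.5, which would fabricate information. The fine-tune vs
frozen comparison across features uses the two-sided paired Wilcoxon
signed-rank test with zero differences dropped. Labeled-vs-predicted score
distributions (e.g. conservation or pathogenicity tracks) are compared with
the two-sample Kolmogorov–Smirnov test; the effect size is taken to be the
KS statistic itself (the maximum empirical CDF gap) since no other
definition is canonical, and a comparison is significant at p ≤ 0.05 with
effect ≥ 0.2. Both cutoffs are arguments.

## Variant interpretation

For each feature checkpoint, the reference and the single-substitution
alternate sequence are predicted and the positionwise delta
p_alt − p_ref is recorded along the *whole* protein — substitutions perturb
predictions at distant positions, and restricting to the variant site would
hide that. A call requires a predicted label flip AND |delta| ≥ threshold;
the default threshold 0 reproduces pure label-flip calling, and the
0.1–0.9 sensitivity sweep reports how call counts shrink (necessarily
monotonically) as the threshold rises. Cohort summaries count calls per
feature × direction × variant class; all three aggregations (positionwise
calls, per-variant counts, per-variant maxima) can be derived from the
long-format call table.

## Enrichment and reclassification

Per feature: a = pathogenic inside, b = benign inside, c = pathogenic
outside, d = benign outside; OR = a·d/(b·c); two-sided Fisher's exact test.
A zero b·c reports OR = ∞ with a flag (the formula has no correction); an
optional Haldane–Anscombe +0.5 correction is available. Across the 20
features, p-values are Benjamini–Hochberg adjusted at FDR 0.05 by default
(20 simultaneous tests warrant it; raw-p mode is available), and a feature
is pathogenic-enriched when the adjusted p passes and OR > 1.

The probability-of-pathogenicity combiner is the Bayesian point framework:
supporting/moderate/strong/very-strong criteria contribute 1/2/4/8 points
(benign evidence negative), combined odds O = O_vs^(points/8) with
O_vs = 350, prior 0.1, PoP = O·prior/((O−1)·prior + 1). These constants
follow the established calibration of the ACMG/AMP Bayesian framework and
every one of them is exposed in `FrameworkParams`. Classes: pathogenic at
PoP ≥ 0.9, benign at PoP ≤ 0.1, VUS between. Reclassification recomputes
PoP with the moderate criterion PM1 added for baseline-VUS variants lying
inside at least one pathogenic-enriched feature; since PM1 is pathogenic
evidence, reclassification can only move variants upward.

## Synthetic fixtures

The generator emulates the statistical shape of the real inputs, not their
biology. Families are founder sequences (uniform over the 20 letters,
lengths 80–160) plus copies mutated at 5% per residue; the default dataset
is 60 proteins in 12 families, which a 70/15/15 split partitions into
roughly 40/10/10. A feature ("motif") is defined as the exact occurrences
of planted trigrams, so the per-residue label is a deterministic function
of a 3-residue window — learnable by construction, which is precisely what
makes the fixture a test of the machinery rather than of biology. Ground
truth (pre-noise tracks, family map, design odds ratio) is retained in a
manifest; optional label noise corrupts only the emitted annotations.
Variant cohorts place pathogenic variants inside feature residues with
probability 0.8 and benign with 0.2 (design OR
(0.8/0.2)/(0.2/0.8) = 16), with any non-reference alternate amino acid —
which necessarily destroys an exact-match motif, giving the cohort its
designed loss-call asymmetry. One spec-level seed fans out to
per-component seeds by fixed offsets, so regenerating one artifact never
perturbs the others.

What passing these fixtures does *not* show: real features are not local
sequence grammars; real annotations are incomplete and biased; real
backbones are pretrained at scale. Results here certify contracts —
oracle-exact statistics, the LoRA identity, split integrity, direction of
designed effects — not expected performance on the human proteome.

## Problem sizes

Default tests and the acceptance script train on the 60-protein fixture
(seconds per fit on one CPU), sweep all ~1.4·10⁵ contingency tables with
total ≤ 40 against the enumeration oracle, and use 2,000 variants per class
for enrichment recovery with 100 null replicates for type-I control. These
sizes were chosen to make every check exact or tightly bounded while the
whole suite stays interactive.

## Known limitations

- The bundled greedy clusterer approximates, not reproduces, MMseqs2; with
  real data, supply an MMseqs2 cluster TSV.
- No loader for large pretrained encoders is included; the backbone
  contract is where one would attach.
- The evidence inputs to the PoP combiner are consumed, not derived:
  automated assignment of non-PM1 criteria from annotation sources is out
  of scope.
- Training is single-feature by design; a multi-task variant sharing signal
  across features would need denser annotations than the data model
  assumes.
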
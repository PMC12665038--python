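# Methods

## Problem and model

`etnet` predicts whether two enhancers physically interact (an
enhancer–enhancer interaction, EEI) from their DNA sequences alone. The
classifier maps a pair of one-hot encoded windows — each `L×4`, columns
A/C/G/T, ambiguous bases as all-zero rows — to an interaction probability.

The architecture has three stages per 2000 bp input window:

1. **Local features.** A single convolutional layer with 128 kernels of
   length 9 over the 4 base channels (motif-scale receptive field), ReLU,
   then non-overlapping max pooling with factor 4, reducing 2000 positions
   to 500 tokens. A single-layer MLP (one linear map + ReLU, width 512)
   projects the pooled features into the token space. Deeper convolutional
   stacks are deliberately avoided: at these data scales extra depth
   amplifies noise rather than extracting additional structure.
2. **Global integration.** Tokens from both windows are concatenated along
   the position axis (1000 tokens) and passed through a Transformer encoder:
   multi-head self-attention (8 heads; total query/key width 1000, value
   width 1024), a learned relative-position bias added to the attention
   logits, residual connections with post-layer-norm, and a position-wise
   feed-forward network. One encoder layer is the default; the count is
   configurable.
3. **Two prediction heads.** Head 1 mean-pools the left-window tokens,
   head 2 the right-window tokens; each is a small MLP producing a scalar.
   The two scalars are averaged and passed through a sigmoid.

Design choices the architecture text leaves open, and how they were fixed
here:

- The "9 × 9" kernel is realized as a 1-D convolution of length 9 over the
  4-channel input: a true 9×9 2-D kernel is dimensionally impossible on an
  `L×4` input at the stated channel count.
- The two branches share convolution weights (siamese) by default
  (`tied_conv=False` gives independent branches). Sharing halves the
  parameter count and matches the intuition that motif detection is the
  same task on both sides.
- Pair fusion: token concatenation before the encoder, with one pooled head
  per branch, averaged. The fusion is isolated in `forward_logits` so
  alternatives are drop-in.
- The relative positional encoding is a learned per-head bias table indexed
  by token offset `i−j`, added to the attention logits.
- Note that 2000 input positions pooled by factor 4 give 500 tokens of 4 bp
  granularity each (each token's *receptive field* is wider because the
  convolution precedes pooling); the pooled length 500 is taken as
  authoritative for the architecture.

## Implementation substrate

The network, its training loop (Adam), and the input gradients used by the
attribution analysis run on a small reverse-mode automatic-differentiation
module (`etnet._autodiff`) over NumPy float64 arrays. It implements exactly
the operators the model needs (matmul, unfold-based convolution, max
pooling, softmax, layer norm, gather for the relative-position bias).
Gradients are verified against central finite differences in the test
suite. Evaluation-mode forward passes are bitwise deterministic; dropout
(default rate 0.1) is active only when a training RNG is supplied.

## Dataset construction

- **Positives.** For each chromatin loop (BEDPE, two anchors; cross-
  chromosome records are rejected on load), every enhancer *fully
  contained* in the left anchor is paired with every enhancer fully
  contained in the right anchor. Partial anchor overlap does not count; no
  overlap-fraction threshold is introduced. Duplicate unordered pairs are
  removed. Pairs are unordered samples; the stored orientation is by
  genomic coordinate.
- **Windows.** All enhancers are standardized to a fixed window (default
  2000 bp) centered on the native midpoint; windows overhanging chromosome
  ends are N-padded rather than shifted, keeping the midpoint anchored.
- **Negatives** (balanced 1:1 with positives by default), three strategies:
  *random* re-pairing of enhancers seen on left/right anchor sides,
  excluding the positive set; *distance-matched*, where the positive
  midpoint-distance distribution is split into decile bins and
  same-chromosome candidates are sampled per bin proportionally (bins short
  of candidates redistribute their quota to neighbors with a warning); and
  *fixed-end*, keeping one enhancer of a positive pair (side chosen
  uniformly) while the partner is re-drawn.
- **Splits.** Stratified 8:1:1 ratio split; 10-fold random CV; and a
  dual-constraint enhancer-level split in which (i) no enhancer occurs in
  both train and test and (ii) each enhancer occurs at most once in test.
  The test set is built greedily from a random pair order until the quota
  is reached; pairs sharing an enhancer with the test set are dropped from
  training. The same exclusion rule is applied to the optional validation
  carve-out.
- **Super-enhancer categories.** Each enhancer maps to the super-enhancer
  with the largest overlap (ties: leftmost). A pair is `SE_intra` when both
  enhancers map to the same SE, `SE_inter` when to different SEs, `SE_out`
  otherwise.

## Training and evaluation

Training minimizes binary cross-entropy (numerically stable logit form)
with Adam. Full-scale defaults are learning rate 1e-5, 50 epochs, batch
size 100; the checkpoint with the best validation AUC is kept. Early
stopping (patience on validation AUC) is available and is the default for
fine-tuning. The desk-scale experiments in the tests and the acceptance
script use a reduced configuration (window 320 bp, 16–24 channels, token
width 32, 2 heads) and learning rate 1e-3, sized so the full pipeline
trains in minutes on one CPU; these sizes are the package's own study
conditions, not statements about full-scale behavior.

Metrics follow the standard confusion-matrix formulas (ACC, Precision,
Recall, F1 at threshold 0.5) plus AUC and AUPR. AUC is the normalized
Mann–Whitney statistic with ties credited 1/2 — chosen to coincide exactly
with the DeLong kernel, so the AUC reported by `metrics` and by
`delong_paired` agree to machine precision. AUPR is the step-wise integral
of precision over recall (identical to average precision). Curves are
returned as explicit (FPR, TPR) and (Recall, Precision) points.

`delong_paired` implements the correlated-AUC form of the DeLong test:
per-positive and per-negative structural components with the 1/2-tie
kernel, 2×2 sample covariance matrices `S10`, `S01`, variance
`[1,−1](S10/m + S01/n)[1,−1]ᵀ`, normal two-sided p. Degenerate variance
with equal AUCs yields p = 1; with unequal AUCs, p is reported as <1e-300
with a warning.

**Selective fine-tuning** adapts the convolutional, input-projection and
output-head parameter groups at learning rate 1e-4 (30 epochs, patience 5)
while every Transformer-encoder parameter is excluded from the optimizer
and therefore stays bitwise unchanged.

## Interpretability suite

- **Dinucleotide shuffle.** Altschul–Erickson Eulerian-walk construction:
  conservation of the dinucleotide count multiset is exact, and the first
  and last base of every ACGT run are preserved; N positions are fixed and
  split the sequence into independently shuffled runs.
- **Attribution.** The per-base contribution is
  `(input − reference) × gradient`, with the gradient averaged over
  interpolation points along the reference→input contrast (8 points by
  default — an integrated-gradients path from each reference) and the whole
  estimate averaged over several dinucleotide-shuffled references (default
  10). Several path points are essential here: motif detectors are
  ReLU-gated, so their gradient appears only part-way between the shuffled
  reference (motif absent) and the input (motif present); a two-point
  endpoint estimate systematically underweights motif positions. The
  estimator is isolated behind `attribute` so alternatives are drop-in.
  Per-position importance is the contribution at the observed base.
- **Greedy region search.** Both windows are tiled into non-overlapping
  regions (default 100 bp). Each iteration shuffles every remaining region
  `n_shuffles` times *on top of the already-perturbed sequences*, fixes the
  region with the largest (or smallest) mean prediction change, and removes
  it from the pool. Ties break to the leftmost region, left side before
  right. The permanently retained perturbation is the replicate whose
  prediction is closest to the replicate mean. On additive scorers the
  greedy order provably equals exhaustive subset search; this is exercised
  against a full-enumeration oracle in the tests.
- **Super-additivity.** For one region per side,
  `S = Δ_joint − (Δ_left + Δ_right)` where each Δ is baseline minus the
  mean over shuffle replicates, and the joint perturbation reuses the same
  replicate shuffles as the single-sided ones so that additive scorers give
  S = 0 exactly. A pair is super-additive when `S > τ` (default τ = 0, with
  a 1e-12 float guard). The population survey takes the top-1 region per
  side (largest single-region drop), reports the super-additive fraction,
  and correlates S with pairwise sequence similarity, defined here as the
  cosine similarity of 4-mer count vectors (the similarity notion is a
  package choice; whole-enhancer perturbation is available through explicit
  region arguments).
- **Surrogate scorers** provide closed-form oracles: `additive` returns
  Σ wᵢ·[region i intact]; `and_gate` models redundancy — the prediction is
  1.0 unless *both* designated regions are disrupted (an AND over
  disruptions), the minimal scorer whose joint effect exceeds its summed
  single effects; `constant` ignores its input (all deltas 0).
- **Motif recovery.** Attribution tracks are scanned with a sliding window
  whose size equals the mean database motif width; windows whose summed
  positive importance is strictly above a per-track quantile (default 0.95)
  become PWMs. Each PWM row carries the position's positive importance at
  the *observed* base, normalized (uniform where importance ≤ 0): on
  one-hot inputs the observed base is where the real sequence's attribution
  lives, whereas raw per-base attribution mass would also encode the
  shuffled reference bases and scramble the consensus. Queries match the
  database motif with the highest cosine similarity over alignment offsets
  (overhangs up to 3 positions allowed, cosine over the overlapping
  columns) and are retained at similarity ≥ 0.8. Forward orientation only
  by default (`both_orientations=True` adds reverse complements). Matches
  are written in MEME minimal format with `nsites` carrying occurrence
  counts.
- **SNP deltas.** anchor1 is the 150 bp immediately upstream of the variant
  plus the variant base, standardized to the model window; each candidate
  partner enhancer forms anchor2. Δ = p_alt − p_ref per partner; the
  summary is the mean |Δ| in percentage points. The genome base must equal
  the stated reference allele.

## Synthetic study system

The fixture generates a 2×200 kb genome with 120 enhancers (300–600 bp,
echoing the 541 bp 95th-percentile of native enhancer length), of which 20%
carry planted motif A, 20% motif B (widths 10), inside the central 240 bp
of the enhancer. Loop candidates are all same-chromosome A–B co-occurring
enhancer pairs plus an equal-sized random sample of non-co-occurring pairs;
a candidate becomes a loop with probability 0.9 (co-occurrence) or 0.05
(otherwise), so labels are recoverable from sequence with ~5–10% planted
label noise. Anchors extend 200–700 bp beyond each enhancer, so containment
and straddle cases are both exercised. Random negatives for the fixture are
drawn same-chromosome: with a single global motif pair, cross-chromosome
co-occurring pairs would be mislabeled by construction (loops are
intra-chromosomal), which no sequence model could resolve. Super-enhancers
cover clusters of consecutive enhancers; variants hit planted motif centers
(effect) or enhancer background 60 bp away from the motif (null).

A second, genome-free fixture emits sequence pairs directly: positives
carry motif A in the left and motif B in the right sequence; two thirds of
the negatives carry exactly one of the motifs (single-motif decoys), so
one-sided motif detection cannot separate the classes, and every pair's
background is freshly drawn. The SNP fixture places motif-A sites and
motif-B partner enhancers on a toy chromosome; effect variants hit motif
centers, null variants sit 25 bp downstream of the motif start — inside the
scoring window but outside the motif.

**Enhancer identity as a leakage channel.** Under the random 8:1:1 split of
the genome fixture, train and test pairs recombine the *same* enhancers. A
model can then generalize to unseen pairs by memorizing each enhancer's
arbitrary background fingerprint together with its effective class, without
using the planted motifs at all — the package's own ablation probe
(hard-replacing the planted motifs and re-scoring; see
`scripts/acceptance.py`, `pipeline_motif_ablation_auc_drop`) shows the
genome-fixture model's AUC barely moves under motif ablation, whereas the
sequence-pair model's collapses (`motif_model_motif_ablation_auc_drop`).
This is precisely the leakage the dual-constraint enhancer-level split is
designed to control, reproduced in miniature. Consequently the
attribution, motif-recovery, synergy-survey and SNP analyses are run on the
sequence-pair model, whose unique per-pair backgrounds make motif detection
the only generalizing strategy; the genome-fixture model is used for the
pipeline-level learnability check, where generalization to unseen pairs is
the quantity of interest regardless of mechanism.

Because the planted interaction rule is a strict AND of the two motifs, a
well-trained model's prediction already collapses when either motif alone
is shuffled, so the joint drop cannot exceed the summed single drops and
the super-additive fraction computed on the fixture is near zero.
Super-additivity in the sense of S > 0 arises from *redundant* region
dependence — the prediction only falls when both regions are disrupted —
which the `and_gate` surrogate realizes exactly; the fixture's biology is
not of that kind, and no fixture-level value of this fraction should be
read as a statement about real enhancer pairs.

What the fixtures do *not* emulate: genomic distance decay of contact
frequency, GC/repeat structure, multi-motif grammars, cell-type-specific
activity, or assay noise. Passing tests therefore demonstrate that the
machinery is correct and that the architecture can learn a planted
co-occurrence rule at desk scale — not that real-data performance levels
are reproduced.

## Numerical choices and degenerate inputs

- float64 throughout the network; parameter init is He-scaled normal from a
  seeded generator, so same-seed builds are bitwise identical.
- BCE is computed in the logit domain (`max(x,0) − xy + log(1+e^{−|x|})`).
- AUC/AUPR are undefined for single-class label vectors and raise.
- Classification threshold 0.5 for ACC/Precision/Recall/F1.
- Greedy ties break leftmost/left-first; `max_iters` beyond the region
  count is clipped with a warning.
- The super-additivity comparison `S > τ` uses a 1e-12 guard so exact
  additivity under float arithmetic is not misclassified.
- Windows overhanging chromosome ends one-hot encode as all-zero rows; a
  model fed all-N windows still returns a finite probability.

## Known limitations

- Desk-scale training uses windows of a few hundred bp and small token
  widths; the full 2000 bp/128-channel configuration is expressible but
  slow on one CPU.
- The attribution estimator is a gradient-based realization of
  reference-based attribution, not the layerwise backpropagation rules of
  the original method; on near-linear models the two coincide.
- The enhancer-level split is greedy and seed-dependent; it guarantees the
  two leakage constraints but not a maximum-size admissible test set.
- Motif matching scans forward orientation by default; palindromic or
  reverse-strand motifs require the orientation flag.
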
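# Methods

## Scope and model of the data

`bescreen` works with self-targeting base-editor screens: pooled libraries in
which each construct carries a 20-nt protospacer target (plus NGG PAM)
between two 6-nt barcodes, so that sequencing the target locus reads out the
editing outcome produced by the guide on the same molecule. Two editor
classes are supported — ABE (A→G) and CBE (C→T) — and only these *canonical
transitions* are quantified; reads with any other difference from the
designed protospacer are excluded from both numerator and denominator and
tallied separately.

Protospacer positions are 1-based and counted from the PAM-distal end
everywhere: position 1 is the 5′-most base, position 20 abuts the PAM. All
emitted tables state this convention in a leading comment line.

## Screen quantification

For one target with total read count *N*:

- per-position editing percentage at substrate position *i*:
  100 · (#reads carrying the canonical transition at *i*) / *N*;
- overall editing percentage: 100 · (#non-wild-type reads) / *N*.

A read edited at any position is a non-wild-type read, so the per-position
percentage can never exceed the overall percentage; this invariant is
asserted in the tests on every simulated table. Replicates are pooled by
summing outcome counts before efficiencies are computed; pooling maximizes
depth and is recorded in table provenance. Loci are filtered for read depth
≥ 100 and optionally for overall efficiency strictly above the library mean
(the mean is computed after the depth filter and recorded). Dichotomization
labels a substrate base *edited* when its per-position efficiency is greater
than **or equal to** the library mean editing percentage — ties go to
edited.

Read assignment replaces alignment with exact matching, which is
sufficient because library barcode pairs are unique and the simulator
produces error-free reads: a 35-bp read is parsed by the designed geometry
barcode5(6) + target(20) + PAM(3) + barcode3(6); reads with wrong length,
unknown barcode pairs, or non-canonical target differences are dropped and
counted per class.

## Synthetic screens

The generator is the package's study-condition definition, not a
convenience: its defaults fix the conditions every downstream result is
measured under.

- **Library**: random 20-mers at 1:1:1:1 base composition, uniform 1-nt
  flanks, sampled NGG PAM, unique barcode pairs.
- **Editing truth**: per-position window probability × trinucleotide-context
  multiplier, capped at a ceiling (default 1). Each read edits each
  substrate position independently given its context; co-editing beyond
  what the shared window/context induces is deliberately absent (an
  optional per-read latent "dose" knob exists, off by default), because the
  screen literature gives no co-editing law — this is exactly why the joint
  distribution of the trained bystander model should factorize into its
  marginals on simulated data, which the tests check (KL ≤ 0.05).
- **Packaged profiles**: four editor emulations. Window maxima sit at
  position 6 (ABEmax-, CBE4max-, ABE8e-like) and position 3
  (Target-AID-like); the ABE8e-like window is broader at half maximum; the
  context multipliers encode preceding-T preference (ABEmax-, CBE4max-like),
  preceding-A aversion and following-C preference (ABEmax-like), a weak
  preceding-A aversion (ABE8e-like) and following-C aversion
  (Target-AID-like). The numeric window values are fixture definitions
  calibrated so mean overall editing lands in the 3–4.5% range
  (measured ≈ 3.6–3.9% across the four profiles at default scale).
- **Coverage and replicates**: depth is negative-binomial per
  target/replicate (mean 1,000, dispersion 10 by default) so the ≥100-read
  filter has something to reject. Replicate noise is a single
  N(0, sd) offset applied on the logit of every per-position probability of
  a (replicate, target) pair; the logit scale keeps probabilities in (0,1)
  without clipping. The default sd = 0.10 was calibrated once so that
  replicate overall-efficiency r² on default screens falls in the
  0.86–0.92 band typical of real self-targeting screens (measured 0.78–0.88
  across the four profiles; the ABE8e-like profile sits lowest because its
  diffuse window leaves more binomial noise per position).
- **Randomness**: one master seed expands into named substreams (library,
  depths, edits, noise, fastq), so stages are independently reproducible.

What the generator does *not* emulate: indels, non-canonical conversions,
sequencing error, barcode synthesis errors, lentiviral coverage/MOI
structure, chromatin or cell-state effects. Tests passing on these screens
therefore demonstrate correctness of the quantification and learnability of
window/context structure — not real-data performance.

## Per-base model

The classifier embeds nucleotide identity (4 × d) and position (20 × d),
sums the two, and passes the 20-slot sequence through a stack of
Transformer encoder layers (multi-head scaled-dot-product self-attention,
residual connections, layer normalization, position-wise feed-forward). The
output block computes, for each queried position *t*, a single-head
attention distribution over the 20 contextual vectors with the query built
from the positional embedding of *t*; the resulting context vector, plus a
residual connection from the queried slot's own contextual vector, feeds a
logistic classifier. The residual gives the optimizer a direct path from
the queried position to the logit and removed an init-seed sensitivity we
observed in early experiments (some seeds collapsed to the all-negative
basin without it). The attention distribution retained per queried position
is what the interpretation layer aggregates.

Training: binary cross-entropy at substrate (labelled) positions only —
labels are defined only for target nucleotides — with Adam, early stopping
on validation AUPR. Defaults: embedding 64, 8 heads, 2 encoder layers,
feed-forward 128, dropout 0.1, batch 256, lr 1e-3, patience 10; the tests
use a smaller stack (dim 16–32, 1–2 layers) that solves the separable
fixtures in seconds on one CPU. Dataset construction follows the screen
design: every depth-passing target with ≥1 edited base, plus unedited
targets at 1:4 (unedited:edited; the direction is configurable since the
phrase "a ratio of 1:4" is ambiguous), ~80% train and a 1:1 test/validation
split of the remainder, stratified on per-target edit status, repeated over
independent runs (default 5).

The reference baseline is the per-position Bernoulli maximum-likelihood
predictor: p̂(pos) = edited fraction at that position in training data,
predicted class edited iff p̂ > 0.5 (the p̂ = 0.5 tie predicts non-edited —
the conservative choice, documented in output). Per-position
accuracy comparisons are restricted to positions whose pooled test examples
have a minority class ≥ 20% (the "balanced" positions; the threshold is
configurable because only the concept, not a value, is standard). ROC
curves are averaged across runs by interpolating TPR on a fixed 101-point
FPR grid.

## Bystander (outcome-distribution) model

An encoder identical in structure to the per-base model encodes the
protospacer; a decoder with masked (causal) self-attention and
cross-attention to the encoder walks the outcome sequence left-to-right
(PAM-distal first, same order as the encoder — decode order is a design
choice) and emits a two-way conditional at each substrate slot: substrate
retained vs converted, given the preceding outcome symbols and the encoded
protospacer. Non-substrate slots are forced identity. Because every slot
conditional is a proper two-way softmax, the chain product defines a
normalized distribution over all 2^k canonical outcomes; the two-way
formulation (rather than a 4-letter output alphabet) reflects that screen
data contain only canonical transitions.

Enumeration is exact up to a cap (default 2^12 outcomes); beyond it a
model-guided beam over substrate positions (default width 256) retains the
most probable outcomes and the emitted distribution is renormalized over
the retained set with an explicit truncation flag. Edited-only mode drops
the wild type before renormalizing, i.e. conditions on a non-wild-type
read.

Training minimizes the cross-entropy between predicted chain probabilities
and empirical outcome frequencies of filter-passing edited targets,
partitioned 8:1:1 at the target level. Rows are weighted by frequency ×
log10(depth) by default (damping shallow-target noise; the weighting is a
design choice with an off switch). Early stopping monitors weighted
validation NLL.

## Attention interpretation

For each queried substrate position, the output block's position-attention
rows of test sequences *predicted to be edited* there (score ≥ 0.5,
configurable) are averaged; each aggregated row remains a probability
distribution. The layer choice (output-block attention rather than encoder
self-attention) is a design decision: it yields exactly one distribution
per queried target position, which is what a per-position attention map
needs; encoder-layer maps are additionally dumpable. The flank-focus
summary is the mean total weight on {t−1, t, t+1} (clipped at boundaries);
a uniform-attention model scores 3/20 at interior positions.

## Numerical choices

- All model arithmetic is float64 on a small reverse-mode autodiff engine
  (`bescreen.nn`) written for this package; gradients are verified against
  central finite differences in the tests.
- Softmax is computed with max-subtraction; BCE uses the stable
  logit formulation; attention masks are additive (−1e9).
- Attention rows are asserted to sum to 1 within 1e-5; distribution masses
  within 1e-6; chain factorization makes full enumerations sum to 1 up to
  float error before the final renormalization.
- Degenerate inputs: zero-read targets error in efficiency computations and
  are dropped (and counted) by table construction; an empty filtered table
  warns rather than raises; targets without substrate bases predict an
  empty per-base score set and a pure wild-type outcome distribution.

## Problem sizes used by the test suite and acceptance script

Recovery and round-trip checks run on screens of 800–2,400 targets at mean
depths 1,000–2,500; the acceptance script simulates 2,000 targets at mean
depth 1,000 × 2 replicates per editor profile and reports the argmax of the
filtered mean-efficiency profile. Model-quality checks train compact
configurations (embedding 16–32, 1–2 layers) on ~1,000–2,000 sequences.
These sizes are the package's chosen desk-scale study conditions; the
defaults in the library remain the larger documented values.

## Known limitations

- Exact-match assignment tolerates no sequencing error by construction.
- The simulator's independence assumption means co-occurrence structure in
  real screens (if any) is unrepresented; the bystander model's advantage
  over per-base marginals on such data cannot be demonstrated here.
- Real-data headline metrics (AUC/AUPR, endogenous-locus and cross-dataset
  correlations) require the original screens and are out of scope.
- Beam-restricted distributions are normalized over the retained set and
  therefore overstate each retained outcome's probability slightly when
  truncation discards mass.
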
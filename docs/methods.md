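# Methods

This note documents the modelling choices, the synthetic data the
package is validated on, and the numerical conventions — in the spirit
of a model-description appendix.

## Signal conventions

All tracks are fixed-bin vectors per chromosome (0-based half-open
coordinates throughout; 1-based inputs such as variant TSVs are
converted at the reader). Three scales are distinguished and carried as
a tag on every track: `neglog10p` (MACS2-style −log10 adjusted
p-values, ≥ 0), `arcsinh` (sinh⁻¹x = ln(x + √(1+x²)), the training
scale), and `delta` (signed difference of two arcsinh tracks).
Rebinning to a coarser resolution uses exact base-pair-overlap
weighting (needed because 128 is not a multiple of 25); trailing
partial bins average over covered bases only, a convention chosen here
since upstream pipelines do not document theirs. Positions absent from
a bedGraph are zero, matching the "no evidence of binding" semantics.

## Window geometry

A training example is a predictive window of `window_len` bp centred
in an input window of `input_len` bp; the local accessibility window is
wider still (`local_atac_len`). The full-scale profile is
196,608 / 114,688 / 199,936 bp at 128-bp bins (896 output bins, 1,562
local accessibility positions, and 1,216 marker genes × 12 global bins
= 14,592 global positions); the desk-scale default used by all
benchmarks is 4,096 / 2,048 / 4,352 bp with 8 marker genes. Candidate
windows tile each chromosome, are dropped if the input window (plus the
shift-augmentation margin) leaves the chromosome or the predictive
window overlaps the blacklist, and are admitted per mark when the
fraction of window bins at or above −log10 p = 2 strictly exceeds
12.5% in at least one training cell; marks are then balanced by
seeded downsampling to the least-represented mark.

Augmentation shifts are drawn at bin granularity (default ±3 bins =
384 bp). This keeps shifted windows aligned with the binned targets
and, because one shift is drawn per (region, strand), keeps the set of
unique backbone inputs small enough to cache. Validation holds out both
chromosomes and a seeded 20% of cells; held-out cells are excluded from
every average and distribution target.

## Targets

Per window, bin and mark: the **average** of the arcsinh signal across
training cells; the **distribution** — the fraction of training cells
falling in each of K = 10 signal bins ([0,0.5), …, [4.5,∞)) — and the
cell-minus-average **delta**. The distribution is binned on raw −log10
p values (recovered exactly through sinh); binning the arcsinh values
instead is a config flag, and the two agree on the documented 104-cell
worked example (first component 0.98, last 0.019). K is configurable
because the worked example can also be read as an 11-bin vector; the
first and last components are identical under either reading.

## Model

The backbone contract: one-hot (L × 4) → latent (T × C) with frozen
weights, bitwise-deterministic forwards, and an analytically declared
receptive field. Internally the model keeps the full input-resolution
grid (L/bin positions) through every stage and crops to the predictive
window only at the end; the contract-level `backbone(onehot)` call
returns the cropped grid. Keeping the full grid makes the fully
convolutional configuration exactly translation-equivariant for any
output bin whose dependency interval stays inside both inputs, which is
what the off-centre consistency analysis exploits.

Two backbone constructors are provided:

* `make_toy_backbone` — a random stem + log2(bin) stages of
  (same-padded conv, activation, width-2 max pool). Dependency
  intervals are computed by exact interval propagation (invert the pool,
  then the conv, per stage), and the declared receptive field equals the
  field measured by exhaustive single-base flips — this is asserted in
  the tests. Random weights are sufficient for every geometry,
  determinism and receptive-field contract.
* `make_matched_backbone` — a synthetic stand-in for a *pre-trained*
  backbone. A randomly initialised frozen stack carries no motif
  information once pooled to 128 bp (its features reduce to base
  composition; measured site-detection AUC ≈ 0.5), so nothing trained
  on top of it can recover sequence-driven signal. A backbone chopped
  from a trained model, by contrast, carries motif detectors. The
  matched constructor emulates that artifact directly: one stem channel
  per motif of the genome's (planted) vocabulary and per reverse
  complement, set to an exact-match filter with a threshold bias, with
  identity convolutions propagating detections under max pooling and
  the remaining channels left as random texture features. It is
  deterministic, frozen, and satisfies the same contract.

Heads: the DNA branch applies a trainable conv trunk over the latent,
then per-position dense heads — soft-plus for the average (strictly
positive Poisson rates; exponential link is a config alternative) and a
softmax K-simplex for the distribution. The celltyping branch embeds
the local delta (1-D conv) and the global vector (conv + pooling +
dense; constant per cell regardless of position) and by default
flattens and concatenates them through two dense layers into per-mark
heads; a fully convolutional per-bin variant
(`position_dependent_celltyping=False`) exists for equivariance
analyses. The combined head concatenates [avg ∥ dist (as probabilities)
∥ delta] channelwise per bin, applies a conv block and per-mark
soft-plus heads, and crops. Exact embedding widths and depths are
config with the defaults above; no reference for them exists, so they
were chosen as the smallest sizes that train stably at desk scale.

The whole network runs on a minimal tape-based reverse-mode autodiff
engine (`epitype.nn`) written on numpy: broadcast arithmetic, matmul,
same-padded 1-D convolution, average/max pooling, tanh/relu/soft-plus,
log-softmax, reductions, slicing, concatenation, and Adam. Gradients
are float64 and are verified against central finite differences in the
test suite; with a fixed seed, forward, backward and the training loss
trace are reproducible bit-for-bit.

## Training

Stage 1 fits the DNA heads (Poisson NLL for the average; cross-entropy
against the *soft* target simplex for the distribution, since targets
are proportions, not classes) and the celltyping branch (MSE, as deltas
are signed), each with its own Adam optimiser. Stage 2 trains all
non-backbone parameters with Poisson NLL on the arcsinh cell-specific
signal, evaluating a fixed validation subset periodically, stopping
after 3 evaluations without improvement, and restoring the best
checkpoint. Frozen-backbone latents are computed once per unique
(region, strand, shift) input and cached on disk keyed by the
backbone's weight hash; a hash mismatch invalidates the cache.

Stored step profiles: the full-scale profile keeps the reference
constants (1,000 pre-training steps, 6,940 full steps, batch 128,
learning rates 0.0002 / 0.005); the toy profile is 200 / 500 steps at
batch 8. At toy scale both stages use learning rate 2 × 10⁻³: the
full-scale rates are tuned to batch-128 training and under-train (or,
for 5 × 10⁻³ at batch 8, destabilise) the much smaller toy model.

## Variant scoring

The three input placements (centred, ±(input−window)/2, snapped to bin
alignment) give prediction windows whose union tiles the input span;
the centre window is appended whole and each slid window contributes
only its non-overlapping outer margin, so every position in the
variant's receptive field is counted exactly once. Per placement and
augmentation ({forward, reverse-complement} × {no shift, one seeded
random shift derived from the variant id}), the (alt − ref) prediction
difference is summed over appended bins per mark — on the arcsinh
training scale by default (raw-scale summation is a flag) — and
averaged over augmentations: 2 × 3 × 4 = 24 forward passes per SNP.
Accessibility features are deliberately *not* modified for the
alternative allele, mirroring the method's stated limitation. hQTL
munging drops trans records, records whose SNP-to-nearest-peak-edge
distance exceeds the receptive field (the boundary is retained), and
SNPs outside a whitelist; per-SNP aggregation is
α̂ₘ = |Gₘ|^(−1/2) Σₖ α̂ₘ⁽ᵏ⁾. Concordance reports the sign-agreement
fraction, an exact two-sided binomial test against 0.5, and a Spearman
rank correlation; the sumstats export (SNP, A1, A2, Z) is the input to
external signed-LD-profile regression, which is out of scope here.

## Probing

Receptive-field scans measure the mean |Δ prediction| over the centre
512 bp (four output bins) averaged over all mark channels on the
arcsinh scale, for single random base variants (DNA) or for replacing a
640-bp block of the cell's local accessibility with the training
average, i.e. zeroing the delta (ATAC). For convolutional backbones the
DNA effect is *exactly* zero outside the declared dependency interval —
asserted bitwise in the tests. Peak calling for attribution uses
non-overlapping 1,024-bp windows with mean predicted −log10 p > 2
(mean was chosen over max for scale robustness); per peak, attribution
is the summed absolute gradient of the mean peak output with respect to
the global input vector, the top 10% (ceiling) by absolute attribution
are selected, and their DNA is exported to FASTA as the hand-off to
external motif-enrichment tooling.

## Synthetic data

The generator plants a regulatory grammar: 8-bp consensus motifs, each
with a per-mark affinity in [0.6, 1] and a per-cell usage in [0, 1];
by default each cell owns one private motif (usage 1 for it alone) and
two motifs are shared by all cells, so cell-specific peaks exist by
construction. Sites are placed at roughly exponential spacings (mean
640 bp plus a 256-bp separation floor), snapped to bin centres so that
a zero-noise peak maximum equals the planted amplitude exactly; 25% of
instances are planted *broken* (central base mutated — they contribute
no signal and are the substrate for restoring variants). A site
contributes a truncated-Gaussian bump (half-width 256 bp at half
maximum, cut at 3σ) of height 5 × usage × affinity on the −log10 p
scale — typical of strong MACS2 peaks — over half-normal background
noise of scale 0.2. ATAC for a cell is its total site activity times
the same amplitude plus noise (a monotone function of regulatory
usage). The default study has 3 chromosomes × 65,536 bp, 8 cell types
(2 held out), 3 marks, and 8 marker genes anchored at private sites;
marker separation is checked at generation against a zero-usage
(noise-only) null. hQTL variants flip the central base of motif
instances — breaking intact ones (negative true effect on overlapping
peaks) or restoring broken ones (positive) — with β = effect +
N(0, 0.15) and a one-sided normal p-value; trans and beyond-receptive-
field decoys are appended for the munging path.

What this emulates: sparse non-negative peak tracks with shared and
cell-specific structure, accessibility that predicts activity, markers
that encode cell identity, and variants with known signed local
effects. What it does not: realistic nucleotide composition, linkage
disequilibrium, indirect/distal regulatory logic (all planted effects
are local motif disruptions), peak-shape variability, or replicate
noise structure. Passing the benchmarks therefore demonstrates that
the pipeline recovers planted signal through the intended mechanisms —
not that the model would reach any particular accuracy on real
ChIP-seq data.

## Benchmarks and problem sizes

The end-to-end benchmark trains the toy profile (~30 s per seed on one
CPU) and reports (1) held-out-cell recovery — Pearson correlation with
truth inside each held-out cell's planted cell-specific peak regions,
per (cell, chromosome), against the training-average baseline; pooled
over seeds 1–3 the model wins ≥ 70% of comparisons — and (2) hQTL sign
concordance in a held-out study cell over 40 variants, significant
(binomial p < 0.05) in a majority of the three seeds. Within
cell-specific regions the average baseline is uninformative by
construction, which is exactly the regime where accessibility-driven
generalisation must carry the prediction.

## Known limitations

* The matched-filter backbone knows the planted motif vocabulary; it
  models a backbone pre-trained on the same genome, not transfer from
  an unrelated corpus.
* The autodiff engine is single-threaded float64 numpy: fine at desk
  scale, not a route to the full-scale profile.
* bigWig support requires pyBigWig and is read-only; bedGraph is the
  canonical format.
* The off-centre correlation equals 1 only for the fully convolutional
  configuration; the default flatten-dense celltyping branch is not
  translation-equivariant, and its off-centre correlations are merely
  high, not exact.
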
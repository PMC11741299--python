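# Methods

## The model

`cleavenet` models base-resolution chromatin-accessibility cleavage profiles
(ATAC-seq Tn5 insertions or DNase-seq DNase-I cuts) as a function of local DNA
sequence, explicitly factorizing the enzyme's intrinsic sequence preference
away from the regulatory signal.

Each submodel is a fully convolutional sequence-to-profile network: a wide
first convolution (21 bp), a stack of width-3 dilated convolutions with
residual skip connections whose dilation rate doubles per layer starting at 2,
and two heads — a wide (75 bp) convolutional **profile head** producing one
logit per output base, and a global-average-pool + dense **count head**
predicting `log(1 + total counts)` over the output window. The effective
receptive field is `21 + Σ_l 2·2·2^(l-1)`: 1041 bp for the 8-layer residual
configuration and 81 bp for the 4-layer bias configuration.

The factorized model combines a **frozen, background-trained bias submodel**
with a trainable **residual (TF) submodel**:

* profile: `p_pred ∝ p_tf · p_bias`, realized as logit addition followed by
  softmax (the product of probabilities is unnormalized as written; softmax of
  summed logits is its normalized form);
* counts: `n_pred = n_tf + γ·n_bias` on the log-count-head scale (the printed
  rule; a physically motivated log-sum-exp alternative on the count scale is
  available via `count_combine="logsumexp"`), with
  `γ = exp(mean[log(n_bias+1) − log(n_obs+1)])` estimated over the training and
  validation regions before residual training (the "fit and scale" stage).

The **bias-corrected prediction** is the residual submodel alone, with the
bias submodel disconnected.

### Loss

Training minimizes `MNLL(k_obs; p_pred) + λ·(log(1+n_obs) − log(1+n_pred))²`,
where MNLL is the multinomial negative log-likelihood of the observed per-base
counts under the predicted positional probabilities (natural log, including
the multinomial coefficient when reported as a loss value; the coefficient is
constant and does not affect gradients). λ defaults to the median total count
of the validation regions divided by 10. The bias model reuses the same λ rule
computed over its background validation regions, since no separate rule is
specified for it.

### Numpy implementation

No deep-learning framework is used: the convolutions, backpropagation, Adam,
and the DeepLIFT rescale rule are implemented directly in numpy
(`cleavenet.nn`). Each convolution is a single BLAS GEMM (tap gathering on the
input side, or a one-shot projection onto (tap, channel) pairs for the wide
single-channel profile head). Gradients are verified against central
differences in the test suite; forward passes are deterministic given weights,
and training is deterministic given the seed on a fixed platform.

## Training procedure

**Stage 1 — bias submodel.** Trained only on GC-matched background regions
whose 1 kb totals fall at or below `quantile(peak totals, 0.01) × fraction`.
The fraction is tuned iteratively (0.8, 0.6, 0.4, 0.2, 0.1): after each
candidate fit, a contamination check computes count- and profile-head
attributions over the training background, extracts each region's top
attribution seqlet, and scans those seqlets against a library of known TF
PWMs (at 70% of each PWM's maximum log-odds). Any appreciable number of
matches (≥ max(2, 5% of seqlets)) fails the candidate and the fraction is
lowered. This is a deterministic, desk-scale stand-in for a visual motif
audit with a de novo motif discovery tool, which is out of scope here.

**Stage 2 — residual submodel.** Trained on peaks plus a background subset
capped at a 1:10 non-peak:peak ratio, with the bias submodel frozen (asserted
by checksum before/after). Peaks are re-jittered each epoch by a uniform
offset of up to ±500 bp around the summit, capped at half the output window
so the summit always stays inside it (the full ±500 bp applies to a 1000 bp
output window; the desk-scale 500 bp output admits ±250 bp). Adam (lr 0.001),
early stopping on validation combined loss with patience 5 and best-weights
restore, epoch cap 100 as a safety bound. Chromosome-level folds keep
train/validation/test disjoint; fold bookkeeping asserts that test
chromosomes are never read during training.

**Desk-scale optimization scheme.** With a few hundred training regions and a
few hundred optimizer steps — orders of magnitude less than a production
training run — three measures make the optimization well-conditioned without
changing the architecture's function class:

* *Closed-form count readout.* Pooled trunk features vary ~100× less than
  log-count targets, so the final dense layer would need weights far beyond
  the reach of a short gradient run; until it has them, the trunk receives no
  usable count gradient. The count readout is therefore refit exactly (ridge
  regression on the pooled features, intercept warm-started at the mean
  training log total) at the start of every epoch, and gradient steps refine
  it in between. For factorized training the refit targets have the scaled
  bias count-head contribution removed.
* *Summit-enriched k-mer filter seeding.* Random first-layer filters do not
  develop motif detectors against multinomial gradient noise at this scale
  (parameter displacement from initialization stays at a few gradient steps'
  worth). Before training, k-mers overrepresented within ±25 bp of training
  summits relative to the full windows are written into the first-layer
  filters (with reverse complements) as thresholded match detectors — a
  negative bias keeps the ReLU silent below ~one mismatch. This prior is
  computed from the training sequences only.
* *Dropout.* Inverted dropout (p = 0.25) on the residual trunk's ReLU
  outputs; without it, long desk-scale training overfits the peak set and
  held-out motif responses degrade and can invert sign. The bias submodel
  (lower capacity, more training regions) trains without dropout.

Peak-set hygiene before training: peaks above the 0.99 linear-interpolation
quantile of 1 kb totals, peaks whose full input window cannot be constructed,
and blacklist-overlapping peaks are removed.

## The synthetic-data generator

The simulator produces a random genome (default 4 × 500 kb chromosomes at
GC 0.41) with evenly spaced accessible peaks (800 bp wide, ~3 kb apart —
dense on purpose: the 2 Mb desk genome then carries ~650 peaks, a few hundred
per training fold, the smallest regime in which the two-stage training is
well-posed; production peak sets are hundreds of thousands). The
per-base expected cut rate is a deterministic function of the sequence:

    rate(x) = accessibility(x) · exp(bias(x)) · protection(x)

* **accessibility**: a small constant background (0.02) plus, per peak, a
  Gaussian bump (σ = width/6) whose amplitude is 1 plus the summed
  accessibility gains of PWM matches actually present in the peak sequence;
* **bias**: a hand-set, roughly palindromic 6-mer preference (additive per
  position, zero-mean over all 4096 6-mers for identifiability) strong enough
  to dominate base-resolution profile shape while leaving regional totals
  essentially unchanged;
* **protection**: multiplicative cut suppression across each matched motif
  span — three planted motifs with deep (0.15), moderate (0.45) and shallow
  (0.80) protection and accessibility gains 6/4/3.

Reads are multinomially sampled at the configured depth (default 2×10⁶) and
assigned strands so that the assay's read shift (+4/−4 ATAC, 0/+1 DNase)
re-aligns both strands onto the cut centre. A quarter of peaks carry a
deliberately broken motif instance (one high-information column), leaving
room for motif-creating variants; variant ground truth (the exact log fold
change of 1 kb window totals) is recomputed by rebuilding the rate field with
the alternate base.

Because the rate field is sequence-deterministic, observed totals are almost
perfectly predictable in principle (oracle log-count correlation ≈ 0.999 at
the default depth), so model shortfalls reflect the model, not irreducible
noise. What the simulator does **not** emulate: fragment-length structure,
nucleosome positioning, mappability artifacts, GC amplification bias beyond
composition, or single-cell sparsity. Passing tests therefore demonstrate
that the method recovers planted structure under its own assumptions, not
performance on real chromatin.

## Interpretation

Attributions use the DeepLIFT rescale rule against 20 dinucleotide-shuffled
references (exact Euler-path shuffles; dinucleotide counts preserved
exactly). For this package's ReLU/linear architecture the rescale rule
satisfies summation-to-delta exactly, so the completeness contract — the sum
of per-base scores equals the mean output difference against references — is
the normative property, asserted at 5% in tests. Profile-head attributions
aggregate per-output-position contributions weighted by the predicted
probabilities (held fixed).

Marginal footprints insert a motif at the centre of GC-matched background
sequences (replacement, not insertion; even-length motifs sit 1 bp left),
predict response profiles `softmax(f)·exp(S)` for each sequence and its
reverse complement (flipped), and average over strands and the library.
Controls are the uninserted backgrounds. The reported footprint M is the
probability-normalized inserted profile scaled by `exp(logFC vs control)` and
smoothed with a width-5 moving average (the stated intent of the width-5
"identity filter" is smoothing; an identity kernel would be a no-op; the
probability × fold-change product is formed before smoothing). Valley
boundaries are the positions of maximum second-difference magnitude on either
side of the centre (ties toward the centre); height is
`max(M[:rs], M[ls:]) − min(M[rs:ls])` and width is `ls − rs`; flat profiles
are flagged degenerate.

The bias audit measures corrected vs uncorrected footprint heights for bias
k-mers and TF motifs; it passes when bias k-mer ratios fall below 0.2 (the
audit's own QC bar; deconvolution on the simulator typically reaches well
below 0.1) and TF ratios stay within [0.8, 1.2].

## Variant scoring

Per fold: `logFC = log f(S2) − log f(S1)` from the count head (counts scale,
`f = expm1(head)`); Jensen-Shannon divergence between the two predicted
probability profiles with **natural** logs (no square root; range [0, ln 2]),
signed by `sign(logFC)`; AAQ is the larger allele's empirical percentile
(fraction ≤) of predicted log counts within the fold's peak distribution.
Across folds, `IES = mean(logFC)·mean(signed JSD)` and
`IPS = mean(|logFC|)·mean(|JSD|)·mean(AAQ)` — the unsigned JSD magnitude is
used in IPS so it is non-negative by construction, the sign being a direction
annotation only. Scores use bias-corrected predictions by default
(`corrected=False` for ablations). Empirical p-values compare the observed
IPS against IPS of dinucleotide-shuffled windows with alleles reintroduced,
with an add-one pseudocount (desk default 10,000 nulls; the full-scale
procedure would use 10⁶). Evaluation-module JSD independently uses base-2
logs (range [0, 1]); the two conventions are deliberate and kept separate.

Fine-mapped-overlap enrichment is `Observed/Expected` with
`Observed(t,p) = #{PIP > p and score > t}` and
`Expected(t,p) = (rate of score > t among PIP≈0 controls) × #{PIP > p}`;
the printed form of the Expected term is typographically garbled in the
source description, and this background-rate reading is the package's
documented interpretation.

## Genome-wide evaluation

Bins of 100 bp are labeled positive when fully covered by IDR summit ±100 bp
regions; ambiguous when partially covered, overlapping a relaxed
("overlap") peak without being positive, overlapping the blacklist at all, or
<50% uniquely mappable (rule skipped with a warning when no mappability
intervals are supplied); negative otherwise. Ambiguous bins are excluded from
AUROC/AUPRC. Per-bin scores aggregate the predicted log counts of covering
1 kb windows (250 bp stride) with max by default (mean by flag).

## Numerical and design choices

* Coordinates are 0-based half-open throughout; summits are offsets.
* GC matching uses 0.01-wide GC bins over the full interval; N bases count as
  neither G nor C and intervals with >5% N are excluded; empty bins borrow
  from the nearest non-empty bin (logged); largest-remainder rounding hits
  the target size exactly.
* The 0.99/0.01 count quantiles use numpy's linear-interpolation convention.
* N bases one-hot encode as all-zero columns; attribution refuses sequences
  with >20% N.
* Dilation rates are 2, 4, …, 2^n — the only geometric schedule consistent
  with both published receptive fields (1041 and 81 bp).
* Candidate-negative generation (2× the peak count) and the 1:10 training
  ratio are independent parameters, not reconciled.
* Desk-scale defaults: residual net 64 filters / 4 dilated layers /
  1114 bp in / 500 bp out; bias net 32 filters / 4 dilated layers. The
  published full-scale configuration (512 filters, 8 layers, 2114/1000) is
  constructed explicitly where needed. Default simulation: 2 Mb genome,
  2×10⁶ reads, as above.

## Known limitations

* Desk-scale models under-learn TF protection-valley depth. With a few
  hundred training peaks the learned valley reaches roughly a quarter of the
  generative truth for a deep footprint and less for shallow ones, so
  corrected-vs-uncorrected footprint-height ratios for TF motifs sit well
  below 1 even though bias-k-mer footprints deconvolve cleanly (ratios
  ≲ 0.01) and held-out count correlation is high (~0.9). Two causes: the
  uncorrected footprint of an inserted TF motif is partly the enzyme's
  response to the motif's own k-mer content (for shallow footprints that
  response dominates, so a near-unity ratio is unreachable even for a perfect
  model), and short training runs cannot drive the profile head's valley
  coefficients to full depth without overfitting. Production-scale peak sets
  remove the second cause.
* The count head saturates below the oracle at desk scale: a few hundred
  training peaks cannot support the count-prediction accuracy reachable with
  ENCODE-scale peak sets; the profile head and footprint/variant directions
  are much less data-hungry.
* Indels are not scored (window re-centering rules are future work).
* The bias submodel's architecture is fixed at 4 dilated layers (81 bp
  receptive field); one published prose mention of "~100 bp" conflicts with
  that architecture's arithmetic and is not reproducible from it.
* bedGraph is the canonical on-disk track format; bigWig IO is provided via
  pyBigWig for interoperability.
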
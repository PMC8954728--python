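# Methods

## Signature-image encoding

The encoder maps a character sequence to an m×m matrix through k-mer
counting and max-normalization (see README for the formulas). Points where
the procedure requires a concrete choice:

- **Alphabets.** The molecule alphabet is the fixed 36-character SMILES set
  `B C H N O S P F I b c l n o s p r 0-9 ( ) [ ] = . + - #`; the protein
  alphabet is the 20 standard amino acids plus the ambiguity code `X`
  (21 symbols). Tokenization is strictly character-level: two-letter element
  symbols such as `Cl` and `Br` decompose into `C`,`l` and `B`,`r`, which is
  what the inclusion of lowercase `l` and `r` in the alphabet implies.
- **Out-of-alphabet characters.** Real SMILES contain characters the
  alphabet cannot represent (`@`, `/`, `\`, `%`, …), and protein sequences
  may contain `U`, `B`, `Z`. The tokenizer's policy is configurable:
  `drop` (default) removes them and records `dropped_count` on every record
  so the loss is auditable; `error` aborts naming the character and its
  position. Windows are slid over the *cleaned* sequence, so
  l = c − k + 1 holds for the kept characters; dropped characters do not
  create gaps.
- **k-mer ordering.** A k-mer's index is its rank in lexicographic order by
  alphabet position (a base-n positional value). Any fixed bijection gives
  an equivalent model; this is the only canonical one the alphabet order
  defines.
- **Reshape and padding.** The normalized profile is padded with
  e = m² − n^k trailing zeros and reshaped row-major. The padding cells are
  always exactly zero and sit at the end of the flattened image.
- **Degenerate inputs.** Sequences shorter than k are rejected (the count
  vector would be all-zero and the max-normalization undefined), as are
  sequences that are empty after cleaning.
- **Precision.** Images are float64 in memory; the optional PNG export
  quantizes to 8-bit grayscale and is labelled lossy, for inspection only.

A documented quirk: the worked 215-residue protein example in the source
literature states l = 215 − 2 + 1 = 214 alongside k = 3; with k = 3 the
count is 213. The implementation uses l = c − k + 1 throughout.

## Metrics

- **Concordance index.** N is the number of *comparable* pairs — ordered
  pairs (i, j) with yᵢ > yⱼ; ties in the true affinity contribute no pair.
  Each comparable pair contributes 1 if the predictions are in the same
  order, 0.5 if they are tied, 0 otherwise. Reading N as "pairs in the
  correct order" would force CI ≡ 1, so the standard comparable-pairs
  definition is used. The implementation is a vectorized all-pairs
  computation; tests check it against a literal pairwise loop and against
  `lifelines`' independent implementation.
- **rm².** rm² = r²·(1 − √(r² − r₀²)) with r² the squared Pearson
  correlation and r₀² the coefficient of determination of the through-origin
  regression with slope k = Σ(y·ŷ)/Σŷ². Because that k is the least-squares
  through-origin slope, r₀² ≤ r² holds mathematically; the square-root
  argument is still clamped at zero (with a warning) to guard against
  floating-point noise. Values above 0.5 are conventionally read as an
  acceptable model.
- **Binarization.** pKd-scaled affinities are positive (binding) at ≥ 7,
  i.e. Kd ≤ 100 nM, boundary included; KIBA scores are positive strictly
  below 12.1. Synthetic affinities live on a pKd-like scale and use the
  pKd rule.
- **AUC-PR.** Step-wise (non-interpolated) summation of precision over
  recall increments — the average-precision convention; tied scores enter
  the curve as one group. Trapezoidal interpolation is deliberately avoided
  as optimistic. For KIBA, where *lower* scores mean stronger binding,
  continuous predictions are negated before ranking so that larger oriented
  score means the positive class.
- **Degenerate folds.** A fold whose true affinities are constant has no
  comparable pairs and a single class after thresholding; CI and AUC-PR are
  reported as NaN rather than silently averaged.

## Architecture

Each branch is Input → (Conv2D+ReLU → MaxPool2D) ×3 → Flatten; the branch
outputs are concatenated and passed through Dropout(0.4) → Dense(512, ReLU)
→ Dropout(0.4) → Dense(1, linear). Kernel sizes, strides, padding and
filter counts are free hyperparameters of the design; the defaults —
3×3 kernels, stride 1, valid (no-padding) convolutions, 2×2 pools,
(32, 32, 32) filters per branch — are the minimal conventional setting whose
flatten widths reproduce the reference concatenation width exactly:
36→34→17→15→7→5→2 gives 2·2·32 = 128 and 97→95→47→45→22→20→10 gives
10·10·32 = 3200, summing to 3328. All of these are configurable;
`ArchitectureSpec(strict_concat=True)` rejects any configuration whose
computed concatenation width differs from 3328.

## The NumPy network engine

The model runs on a compact NumPy engine (`kmersig.nn`): convolutions are
computed as a single wide GEMM over an im2col buffer in float32, pooling is
2×2/stride-2 with floor semantics (a trailing odd row/column is cropped,
matching the shape chain above), dropout is inverted, and the optimizer is
Adam with bias correction. Two numerical notes:

- **Max-pool ties.** The backward pass routes the gradient through *every*
  cell equal to the window maximum (a valid subgradient). Ties occur mainly
  in all-zero windows after ReLU, where the gradient is zero anyway.
- **Entity-deduplicated batches.** An affinity batch typically repeats the
  same drugs and targets many times. `forward_indexed`/`backward_indexed`
  push each *unique* image through its branch once and gather/scatter-add
  per-pair features and gradients. This is algebraically identical to the
  naive expanded batch (verified by an exactness test) and reduces the
  convolution cost by roughly the duplication factor.

All randomness (weight initialization, shuffling, dropout masks) flows from
seeded `numpy` Generators, so a run is exactly reproducible for a given
seed on a given platform.

## Training protocol

Per fold the procedure is two-phase: (1) train on the fold's four training
parts with the fifth as validation, recording per-epoch train/validation
MSE, and persist the weights; (2) evaluate the persisted model on the
held-out sixth part with the full metric suite. `cross_validate` repeats
this for all five folds and reports per-fold metrics with mean and std.

The reference schedule is 1000 epochs at batch size 256
(`--paper-protocol` on the CLI); the CLI's default profile is 20 epochs,
a desk-scale setting under which the synthetic benchmark below already
shows clear ranking signal. The final dense layer's bias is initialized to
the training-target mean — a standard regression-head initialization that
removes the many epochs a zero-initialized bias would spend drifting to the
affinity scale's center (~7 on the pKd scale).

## Synthetic data

The generator emulates the *structure* of the public kinase benchmarks, not
their chemistry: uniform-random sequences over the two alphabets with
lognormal lengths (molecule mean 64, range 20–590; protein mean 728, range
215–4128, matching the benchmarks' summary statistics), and an interaction
matrix of configurable density with missing cells excluded everywhere.
Affinities are constructed in exactly the feature space the encoder
produces:

y(d,t) = a·g(d) + b·h(t) + c·g(d)·h(t) + ε,  g = ⟨u, f_mol⟩, h = ⟨v, f_prot⟩,

with u, v standard-normal latent weights, g and h standardized across the
sampled entities, the combined signal rescaled to center 7 / SD 1 (a
pKd-like scale), and ε Gaussian with SD expressed as a fraction of the
signal SD (default 0.2). Defaults are 200 drugs × 50 targets at density 0.2
(2,000 interactions). The ground truth (u, v, a, b, c, projections,
realized noise) is returned so tests can verify recovery independently
through the encoder.

What passing tests on these data show: the encoder is information-
preserving enough, and the network trainable enough, to recover a signal
that is linear-plus-interaction in k-mer content. What they do not show:
performance on real binding data, where affinity is not a linear functional
of k-mer frequencies, sequences are not uniform-random, and assay noise is
not Gaussian. The generator is a test harness, not a biological simulator.

## Problem sizes used by the test suite

The acceptance-level tests run the full default architecture at desk scale:
the learnability check trains one fold for 20 epochs on the default
2,000-interaction dataset (noise SD 0.2; held-out CI > 0.70 and rm² > 0.5,
validation MSE decreasing), and the idempotence check runs the complete
synth → prepare → crossval → evaluate pipeline twice at 180 interactions ×
2 epochs and requires byte-identical reports. Counting and CI oracles are
exercised on 1,000 random sequences and 100 random instances up to n = 500
respectively.

## Known limitations

- The encoding discards all positional information beyond k-mer adjacency;
  two sequences with equal k-mer multisets are indistinguishable by design.
- Max-normalization makes pixel intensities relative; absolute k-mer
  frequency scale (sequence length) is not represented.
- The published-benchmark reader expects the affinity matrix as delimited
  text; binary pickles from other toolchains must be exported to text first.
- Training is CPU-bound NumPy: ample for the desk-scale protocol and for
  method development, not tuned for the full 1000-epoch benchmark runs.
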
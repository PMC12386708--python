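# Methods

This note documents the models, the parameters that matter, the synthetic
data the package is validated on, and the numerical and design choices made
where the design was genuinely open.

## The selection problem

Breed (class) membership leaves a population-genetic fingerprint: allele
frequencies drift apart between reproductively separated populations. With
millions of SNPs and only thousands of individuals, fitting one joint
classifier is statistically hopeless (p ≫ n) and computationally wasteful,
because the informative signal is carried by a small subset of strongly
differentiated variants embedded in a sea of weakly drifting background. All
three selectors in this package are ways of finding that subset.

## LD tagging

Linkage disequilibrium makes neighbouring SNPs redundant. `LDTagger` scans
each chromosome in position order and retains a SNP iff its squared Pearson
correlation of dosages (composite r², so unphased genotypes work) with every
already-retained tag within `window_bp` (default 100,000) is at most
`r2_max` (default 0.5). The scan is deterministic and order-stable, and
every pruned SNP is certified in the output manifest by the tag and r² that
pruned it. The greedy-scan formulation was chosen over a moving-window
variant because it is fully specified and reproducible; `step_bp` is kept as
a configuration knob for exploration. Monomorphic SNPs (r² undefined) are
assigned r² = 0 and retained; QC normally removes them first.

## Supervised rank aggregation

Both SRA routes start the same way: shuffle the P SNP indices with a seeded
RNG, cut them into K blocks of S (default 250; the incomplete tail block is
kept by default so every SNP is scored — `drop_remainder` reproduces the
strict K = ⌊P/S⌋ behaviour), and fit a reference-class multinomial logistic
regression per block on allele dosages (0/1/2). Each SNP's *feature
performance* (FP) is the largest-magnitude coefficient across the B−1 class
rows; each model's quality is its training cross-entropy CE_k. Model fit,
not held-out prediction, is deliberately the ranking signal.

Two defaults deserve explanation because both were changed after their naive
versions demonstrably broke the method on synthetic data:

- **Ridge strength.** With S features, B−1 coefficient rows and N ≲ 6S
  observations, an (almost) unpenalised fit interpolates: every CE_k
  collapses toward 0, the weights 1/CE_k explode, and the aggregation step
  amplifies pure overfitting noise. The default penalty is 0.01·½‖β‖² on the
  mean-log-likelihood scale (about the classic unit-C penalty of standard
  logistic solvers at N ≈ 300), which keeps the CE spread informative: across
  blocks, 1/CE correlates ≈ 0.5 with the number of planted discriminative
  SNPs in the block. The near-zero setting remains available via `ridge`.
- **Signed vs absolute maximum.** Taking the signed maximum over class rows
  silently discards any SNP whose allele frequency peaks in the reference
  class — all its coefficients are negative, which is ≈ 1/B of the
  discriminative SNPs. The default is therefore the absolute maximum
  (`fp_mode="abs_max"`); the signed variant is available as
  `fp_mode="signed_max"`.

**1D route.** The K values y_k = 1/CE_k are regressed on the sparse K×P FP
design Z with the mixed model y = μ1 + Za + ε, a ~ N(0, Iσ²_a),
ε ~ N(0, Iσ²_ε). The variances are treated as known (defaults 6.5·10⁻⁵ and
1.5·10⁻⁴; solutions depend on them only through λ = σ²_ε/σ²_a ≈ 2.31, which
is verified by a test). The mixed model equations are solved by conjugate
gradients with a Jacobi (diagonal) preconditioner — the natural 1+P diagonal
of the intercept/SNP split — using only sparse Z·v and Zᵀ·v products;
convergence is declared at relative residual ‖r‖/‖rhs‖ ≤ `tol` (default
10⁻¹⁰; tighter settings are often below float64 attainability). 1D 2-means
(n_init = 10, seeded) on the solutions â defines the relevant cluster as the
one with the larger |centroid|; ties go to the smaller cluster.

Because the blocks are disjoint, Z'Z is block rank-one and the solution is
essentially â_j ∝ FP_j · (y_k − μ̂) within block k: a SNP is relevant when
its own coefficient is large *and* its model fits better than average. This
makes the 1D route a single-shot estimator — each SNP is scored by exactly
one model — with the consequences discussed under *Limitations*.

**MD route.** The reduced-model stage is repeated W times (default 5) on
independent seeded partitions. Each repeat collapses to one dense P-vector
(every SNP occurs once per repeat) with entries FP·(1/CE of its model);
2-means on the resulting P×W matrix, with the cluster of larger centroid
L2-norm taken as relevant, replaces the linear-system solve. Columns are not
standardized (the weighting is part of the method); a `standardize` flag
exists for exploration. Zero rows of never-sampled SNPs (remainder-dropping
mode) are included in the clustering and noted in diagnostics.

## The classifier

`FocalCNNClassifier` is a sequential 1D-CNN over the selected dosage panel:
`n_conv_blocks` × [conv(`kernels_per_conv`=10 filters, width
`kernel_size`=150, auto-capped so the conv output still admits one pooling
window) → ReLU → batch-norm → max-pool(5)] → flatten → dense 128/64/32 with
ReLU → softmax. Training uses Adam (default learning rate 5·10⁻⁵) on the
class-balanced focal loss α_b(1−p)²·CE with α_b = N/(B·g_b), which
down-weights easy examples and rebalances unequal class sizes. All forward
and backward passes are explicit NumPy; this keeps the dependency footprint
minimal and gives exact input gradients, which the attribution module uses
for gradient×input scores aggregated per SNP as the mean over individuals of
the class-wise maximum. The attribution backend is pluggable; gradient×input
is the default.

Defaults not determined by the architecture description (two conv blocks,
dense widths 128/64/32, 50 epochs, batch 32, no early stopping) are
configurable and logged in the run manifest. For the few-hundred-SNP panels
of the synthetic benchmarks the package uses a scaled profile — one conv
block, kernel 21, Adam at 10⁻³, 40–60 epochs (`sraselect.benchmarks.
scaled_cnn`) — because a 150-wide kernel followed by two pools reduces a
300-SNP panel to a near-empty representation, and the small-rate schedule
appropriate for millions-of-SNP inputs undertrains badly in a few hundred
optimizer steps.

Evaluation: stratified k-fold cross-validation; macro F1 is the harmonic
mean of macro-averaged precision and recall (classes with zero predicted or
actual counts contribute 0 to the respective average); macro AUC averages
one-vs-rest AUCs computed by the rank-sum formulation, so ties earn half
credit and classes without both positives and negatives are skipped with a
warning. "Averaging AUCs" is interpreted as macro averaging over classes —
the per-individual reading has no standard meaning.

## Synthetic data

`simulate_frequencies` draws an ancestral frequency per SNP uniform on
[0.1, 0.9] and class frequencies from the Balding–Nichols distribution
Beta(p(1−F)/F, (1−p)(1−F)/F): F is the fixation index, and the between-class
frequency variance is p(1−p)F. A planted subset of `n_signal` SNPs uses
`fst_signal` (class-discriminative); the rest use `fst_background`.

LD is induced by finite haplotype pools: per class and block,
`haplotypes_per_block` haplotypes are drawn site-wise Bernoulli(class
frequency) and each individual draws two with replacement. Two consequences
matter:

- within-block r² scales like 1/H — a pool of 2 forces r² ≈ 1, a pool of 2N
  gives none;
- the pool's empirical frequency is itself a Binomial(H, f)/H draw, so a
  finite pool adds ≈ 1/H of *spurious* between-class differentiation to
  every SNP. The default H = 100 keeps this artifact at the scale of the
  background Fst (0.01); tests that need strong LD pass small pools
  explicitly. The two-stage sampling is also why frequency-consistency
  checks use SE = sqrt(f(1−f)(1/H + 1/2N)).

What the simulator does *not* emulate: recombination-gradient LD decay,
allele-frequency spectra shaped by selection, relatedness/pedigree
structure, genotyping error, and imputation artifacts. Passing tests on this
generator therefore demonstrate algorithmic correctness and statistical
behaviour under clean drift-only differentiation, not performance on real
whole-genome data.

## Benchmark problem sizes and what they show

The standing recovery benchmark (`sraselect.benchmarks`) uses three classes
of 100 individuals, 3,000 SNPs, 30 planted SNPs at Fst 0.25 over a 0.01
background, reduced models of S = 50, W = 5 repeats, five simulation seeds;
downstream classification uses the scaled CNN with 3-fold CV. A full
five-seed run takes about five minutes on one CPU. Results reproduced by
`scripts/acceptance.py`:

- MD-SRA recovers ≈ 0.88 of the planted SNPs; 1D-SRA ≈ 0.60; both selected
  panels beat a size-matched random panel in downstream macro F1 on every
  seed (≈ 98 / 89 / 73% respectively).

## Limitations

- **The 1D route is noisier than the MD route at desk scale.** With K = 60
  reduced models, each SNP's score comes from a single model; a planted SNP
  in a block whose model fits below average receives a negative solution and
  cannot join the (positive) relevant cluster — about 80% of its misses are
  of this kind, and most of the rest are intrinsically weak Balding–Nichols
  draws whose between-class spread sits near the background noise floor. The
  W-repeat MD route averages that partition noise away, which is why it
  *outperforms* the 1D route here, in both recall and downstream F1. The
  opposite ordering (1D best) belongs to the K ≈ 47,660 regime of full
  whole-genome panels, where single-model noise is small relative to the
  aggregate and the LMM's shrinkage pays off.
- Relatedly, MD-SRA's runtime advantage over 1D-SRA only materialises at
  scales where the P-dimensional linear solve dominates; at P ≈ 3,000 the MD
  route simply fits W times more models.
- Training cross-entropy (model fit) is the ranking signal by design;
  features that help fit need not help predict.
- The CNN treats the SNP panel as an ordered sequence; on shuffled synthetic
  panels convolution width is an arbitrary smoothing choice, which is
  another reason the scaled profile uses small kernels.
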
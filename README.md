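# sraselect

Feature selection for ultra-high-dimensional SNP panels, with a downstream
CNN classifier. The package addresses the p ≫ n problem that arises when a
few thousand individuals are to be classified (e.g. cattle into breeds) from
millions of whole-genome-sequence SNPs: before any classifier can be trained,
the SNP panel must be reduced to the variants that actually carry
class-discriminative information.

Three selection routes are implemented as scikit-learn estimators:

- **`LDTagger`** — the mechanistic baseline: pairwise genotype
  R² within bounded genomic windows (default 100 kbp, R² ≤ 0.5), retaining
  one tagSNP per linkage-disequilibrium neighbourhood.
- **`SRA1DSelector`** — one-dimensional supervised rank aggregation. The P
  SNPs are shuffled into K disjoint blocks of S (default 250); a reference-
  class multinomial logistic regression `log(P_b/P_B) = α_b + β_b·x` is
  fitted per block; each SNP's feature performance FP (max |β̂| over class
  rows) and each model's training cross-entropy CE_k fill a sparse K×(P+1)
  performance matrix C. The aggregation step fits the mixed linear model

      y = μ1 + Za + ε,   y_k = 1/CE_k,   a ~ N(0, Iσ²_a),  ε ~ N(0, Iσ²_ε)

  with known variances (σ²_a = 6.5·10⁻⁵, σ²_ε = 1.5·10⁻⁴, so the shrinkage
  ratio λ = σ²_ε/σ²_a ≈ 2.31), where Z is the sparse FP design (the first P
  columns of C). The mixed model equations are solved matrix-free by
  Jacobi-preconditioned conjugate gradients; 1D 2-means on the BLUP solutions
  â splits SNPs into *relevant* / *irrelevant* without an arbitrary cutoff.
- **`MDSRASelector`** — multidimensional supervised rank aggregation: the
  reduced-model stage is repeated W times (default 5) on independent
  partitions, each repeat collapsed to a dense P-vector of FPs weighted by
  1/CE of their model; 2-means on the P×W score matrix with the centroid
  L2-norm rule gives the relevant cluster. Same statistical idea, no large
  linear system.

Classification uses **`FocalCNNClassifier`**, a NumPy 1D-CNN
(conv → ReLU → batch-norm → max-pool blocks, three ReLU dense layers,
softmax) trained with Adam on the class-balanced focal loss
`FL_i = α_b (1−p_ib)² CE_i` with `α_b = N/(B·g_b)`, evaluated by stratified
k-fold cross-validation with macro F1 (harmonic mean of macro precision and
macro recall) and one-vs-rest macro AUC, and explained by gradient×input
attributions aggregated per SNP as `mean_i max_b attr_ibp`.

A Balding–Nichols simulator (`sraselect.simulate`) generates breed-structured
genotypes with haplotype-block LD and a planted set of class-discriminative
SNPs, so the whole pipeline is testable without external data.

## Worked example

```python
import numpy as np
from sraselect import (SimConfig, simulate_dataset, apply_qc,
                       MDSRASelector, FocalCNNClassifier, train_cv)

ds, truth = simulate_dataset(SimConfig(
    n_per_class=[100, 100, 100], p_snps=3000, n_signal=30,
    fst_signal=0.25, fst_background=0.01, seed=2))
ds = apply_qc(ds)

sel = MDSRASelector(w=5, s=50, random_state=2).fit(ds, ds.labels)
sig = np.isin(ds.snp_ids, truth.signal_snp_ids)
print(f"selected {sel.support_.sum()} of {ds.n_snps} SNPs, "
      f"planted-SNP recall {sig[sel.support_].sum() / sig.sum():.2f}")

clf = FocalCNNClassifier(n_conv_blocks=1, kernel_size=21,
                         learning_rate=1e-3, epochs=40, random_state=2)
report = train_cv(ds.dosages[:, sel.support_], ds.labels,
                  classifier=clf, n_folds=3, seed=2)
print(report.summary())
```

Output:

```
selected 791 of 2993 SNPs, planted-SNP recall 0.89
validation macro F1 99.02% +/- 0.00, macro AUC 0.9997 +/- 0.0004 (3 folds)
```

The selector kept about a quarter of the panel while recovering 89% of the
planted discriminative SNPs; the CNN trained on that panel separates the
three simulated breeds almost perfectly, whereas a size-matched random panel
typically lands 10–25 F1 points lower (see `sraselect.benchmarks`).

The same pipeline is available from the shell:

```bash
sra-select simulate --p-snps 3000 --n-signal 30 --seed 2 --out-dir run/
sra-select sramd --vcf run/genotypes.vcf --labels run/labels.tsv \
    --s 50 --w 5 --seed 2 --out-dir run/selection/
sra-select train --vcf run/genotypes.vcf --labels run/labels.tsv \
    --features run/selection/relevant_snps.txt --folds 3 \
    --conv-blocks 1 --kernel-size 21 --learning-rate 1e-3 \
    --out-dir run/metrics/
```

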
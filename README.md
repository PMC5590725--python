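# ggmhet — network-level molecular heterogeneity

Molecular networks — the patterns of interplay between proteins, transcripts
or metabolites — can themselves differ between biological contexts such as
tissue, disease type or subtype.  `ggmhet` provides two complementary tools
for studying such heterogeneity in continuous molecular data, both built on
sparse Gaussian graphical models (GGMs), where the zeros of the precision
matrix Ω encode conditional independencies and the scaled negative
off-diagonals are partial correlations:

1. **Two-sample network testing** (`diffnet`): a formal test of
   H₀: Ω₁ = Ω₂ between two known groups.  The classical likelihood-ratio
   test breaks down when the p(p+1)/2 precision parameters are many relative
   to n; the split-based test stays valid there by estimating sparsity
   patterns with the graphical lasso on one random half of the data and
   computing a restricted likelihood-ratio P-value — a weighted-χ²₁ mixture
   null — on the held-out half.  Single-split (SS) and 50-split (MS)
   variants are provided, the latter combining per-split P-values with a
   quantile aggregation rule.  Baselines: asymptotic LRT, permutation LRT,
   and a multiplicity-corrected Fisher-Z test on partial correlations.
   All pairs of K groups can be tested with Benjamini–Hochberg FDR control.

2. **Network-based clustering** (`mixglasso`): a penalized mixture of GGMs
   for finding sample subgroups that differ in their networks, not just
   their means.  It maximizes

       ℓ(Θ; X) − λ Σₖ πₖ^{1/2} Σ_{j≠j'} |Ω_{k;jj'}| / √(Ω_{k;jj} Ω_{k;j'j'})

   by EM, with λ fixed at the universal value λ_uni = √(2 n log p)/2 — no
   cross-validation.  The πₖ^{1/2} factor adapts regularization to cluster
   size, the partial-correlation scaling to cluster scale.  The number of
   clusters K* minimizes the BIC score
   −ℓ + ½log(n)(K−1) + ½log(n)Σₖ Df(k), with Df(k) = p plus the nonzero
   upper-triangle entries of Ω̂ₖ.  Stability is assessed by refitting on
   random 75% subsamples and scoring assignment concordance with the
   adjusted Rand index (ARI).

A simulation module generates data from sparse-precision Gaussian (or
heavy-tailed t) mixtures and reproduces the two study designs: type-I
error / power / AUROC of the tests versus sample size, and clustering ARI
versus sample size against k-means, Ward hierarchical clustering and
(penalized) Gaussian-mixture baselines.

## Worked example

```python
import numpy as np
from ggmhet import (two_group_scenario, diffnet_multi_split,
                    default_scenario, sample_scenario, select_K,
                    adjusted_rand_index)

# --- testing: two groups whose networks differ in 10 edges -------------
X1, X2 = two_group_scenario(p=10, n_per_group=500, n_edges_changed=10, seed=3)
res = diffnet_multi_split(X1, X2, seed=0)
print(f"multi-split P-value: {res.pvalue:.4f}")
# multi-split P-value: 0.0000

X1, X2 = two_group_scenario(p=10, n_per_group=500, n_edges_changed=0, seed=3)
print(f"null P-value: {diffnet_multi_split(X1, X2, seed=0).pvalue:.3f}")
# null P-value: 1.000

# --- clustering: recover a 9-component network mixture -----------------
scen = default_scenario(K=9, p=30, n_total=1800, seed=2)
data, truth = sample_scenario(scen)
K_star, fits, bic = select_K(data, range(5, 13), seed=0)
print(f"selected K* = {K_star}, ARI vs truth = "
      f"{adjusted_rand_index(truth, fits[K_star].labels):.2f}")
# selected K* = 9, ARI vs truth = 0.96
```

The multi-split P-value below 10^-4 rejects network equality decisively for
the perturbed pair while the same pipeline leaves the null pair at 1.0; BIC
recovers the generating number of clusters and the fitted assignments agree
almost perfectly with the ground truth.

The command-line interface mirrors the library:

```bash
ggmhet diffnet --data matrix.tsv --groups type --method ms --seed 1 --out result.json
ggmhet mixglasso --data matrix.tsv --k-min 5 --k-max 12 --seed 1 \
       --out fit.json --networks-dir nets/
ggmhet simulate-study --study mixglasso --seed 1 --out table.tsv
ggmhet export-network --data matrix.tsv --lambda 0.1 --threshold 0.25 --out net.tsv
```

Exported networks keep edges with |partial correlation| above the threshold
(default 0.25) as TSV edge lists or GraphML.

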
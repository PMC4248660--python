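# nmlsa — network-based modular latent structure analysis

Gene expression programs are modular: groups of genes (modules) are driven
by a small number of shared, unobserved activity profiles (latent
factors), and a single module can be governed by several *interacting*
factors at once — cell-cycle genes peaking at different phases are the
classic example. Global decompositions (PCA, ICA, plain factor analysis)
mix modules together; hard clustering splits genes that share factors but
differ in phase or sign. `nmlsa` decomposes a genes-by-samples matrix
G<sub>p×n</sub> into quasi-independent modules and recovers each module's
factors, yielding the sparse global model

&nbsp;&nbsp;&nbsp;&nbsp;**G** = **L** **B** + **E**,

with **B** (K×n) the stacked factor activities, **L** (p×K) a sparse
loading matrix and **E** the residual. It is aimed at anyone analysing
moderate-size expression compendia (hundreds to a few thousand features,
dozens to hundreds of samples) who wants interpretable module/factor
structure rather than a monolithic embedding.

## Method

1. **Co-expression network.** Pearson correlations r<sub>ij</sub> for all
   feature pairs are mapped to t<sub>ij</sub> = r<sub>ij</sub>
   √((n−2)/(1−r<sub>ij</sub>²)), approximately normal under independence.
   An Efron-style two-group mixture is fitted to the pooled statistics
   (Poisson-regression spline density, empirical null by central
   matching), and a pair becomes an edge when its local false discovery
   rate lfdr(t) = π₀ f₀(t)/f(t) falls below a threshold (default 0.2).
   The empirical null adapts to pervasive baseline correlation instead of
   flooding the graph with edges.
2. **Module detection.** Walktrap random-walk communities (walk length 4)
   on the edge graph, followed by a merge pass: for communities i, j the
   statistic δ<sub>ij</sub> = [k<sub>ij</sub>/(m<sub>i</sub>m<sub>j</sub>)] /
   [(k<sub>i</sub>+k<sub>j</sub>)/(m<sub>i</sub>²+m<sub>j</sub>²)] compares
   the observed between-community edge density with the density expected
   were the pair one community; outliers of the pooled δ distribution
   (above median + 4·(Q75−median)) are merged, iterating to a fixed
   point. Communities below a minimum size are dropped.
3. **Latent factors per module.** Eigendecomposition of the module's
   (row-centered) covariance structure; sample-space eigenvectors
   explaining ≥5% of variance are candidates. Two candidates are
   *interactive* when features' projection lengths onto them correlate
   significantly — the footprint of genes co-driven by both. A greedy
   sequential rule keeps the leading eigenvector and extends the set
   while each next candidate interacts with it, then quartimin (oblique)
   rotation produces interpretable, possibly correlated factors.
4. **Global model.** Factor scores are stacked into **B**; **L** is
   filled either by per-gene OLS on the gene's own module factors
   (default) or by lasso over all factors with BIC model selection and a
   debiased OLS refit.

A benchmark generator reproduces the method's evaluation protocol:
planted modules (10 × 100 genes, 1–3 factors each, Gaussian or mixed
sine/square/sawtooth/Gaussian signals, configurable loading sparsity and
SNR, 1000 noise genes), and a two-stage multiple-R² score of how well any
method's factors recover the hidden ones.

## Worked example

```python
import numpy as np
from nmlsa import NMLSA, SimulationConfig, simulate_dataset, evaluate_recovery

cfg = SimulationConfig(n_modules=3, genes_per_module=60, noise_genes=300,
                       n_samples=80, signal_mode="gaussian", sparsity=0.0,
                       snr=2.0, seed=7)
values, feature_ids, sample_ids, truth = simulate_dataset(cfg)

est = NMLSA(random_state=0).fit(values.T)   # sklearn orientation: samples x features
print([F.shape[0] for F in truth.true_factors])        # [3, 2, 1]
print(est.n_modules_)                                  # 3
print([m.n_factors for m in est.module_models_])       # [1, 2, 3]
print(est.factor_scores_.shape)                        # (80, 6)

report = evaluate_recovery(est.factor_scores_.T, truth)
print(np.round(report.r2_per_hidden_factor, 3))
# [0.99  0.982 0.982 0.989 0.991 0.996]
```

All three planted modules are found, with the correct number of factors
per module (the pipeline orders modules by detection, not by planting).
Each hidden factor is regressed on the recovered factors assigned to its
module; R² ≈ 0.98–1.0 means the factors were recovered essentially
perfectly despite noise at SNR 2. Fitted attributes follow scikit-learn
decomposition conventions: `components_` is Lᵀ (K×p), `factor_scores_` is
Bᵀ (n×K), `labels_` gives each feature's module (−1 = unassigned), and
`transform(X)` projects new samples onto the factors.

The same pipeline is available from the shell:

```bash
nmlsa run --input expr.tsv --outdir out/ --lfdr 0.2 --min-module-size 10 \
          --loading-mode lasso_bic --seed 1
nmlsa simulate --mode mixed4 --sparsity 0.3 --snr 2 --reps 10 --seed 7 --outdir bench/
```

`nmlsa run` writes the module membership table, factor scores **B**,
loadings **L** and a JSON run summary.

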
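# deepsubtype

Molecular subtype discovery from multi-omics cancer data with a denoising
autoencoder, plus a sparse mRNA classifier that transfers the subtypes to
expression-only cohorts.

## The problem

Bulk tumour cohorts (the motivating case is ovarian cancer profiled by
TCGA) carry several omics layers per patient — mRNA expression, miRNA
expression, gene-level copy number — each noisy and high-dimensional.
Clustering patients directly on tens of thousands of concatenated features
works poorly; linear reductions (PCA, kernel PCA) help but miss nonlinear
structure. This package implements a deep-learning subtyping framework:

1. **Integration / reduction.** The per-omics matrices are cleaned
   (features and samples with > 20 % missingness removed, the rest
   median-imputed), min–max scaled to [−1, 1], concatenated, and compressed
   through a **denoising autoencoder (DAE)**: a symmetric 7-layer tanh
   network (hidden sizes 200–50–2–50–200) trained with Adam
   (learning rate 0.001, batch size 256, 100 epochs) to reconstruct the
   clean input *x* from a corrupted version *x̃* ~ q(x̃|x), minimising

   ‖x − f_d(f_e(x̃))‖²₂.

   The 2-unit bottleneck z = f_e(x) is the integrated representation; with
   no corruption the objective reduces exactly to the plain autoencoder.
2. **Clustering.** k-means on z, with k ∈ [2, 8] chosen by the mean
   silhouette width; cluster quality is reported as silhouette and
   Davies–Bouldin index, with PCA/KPCA/AE/raw-feature baselines available
   for comparison.
3. **Survival evaluation.** The cluster with the shorter Kaplan–Meier
   median survival is named High risk; the Low/High split is tested with
   the two-group log-rank test (χ², 1 df).
4. **Light-weight classifier.** An L1-penalised logistic regression
   p(y=1|x) = exp(β₀+βx)/(1+exp(β₀+βx)) is fitted on the mRNA block
   against the cluster-derived risk labels, maximising
   l(β) − λ‖β‖₁ (intercept unpenalised). The surviving non-zero
   coefficients form a small gene signature usable on cohorts where only
   expression is measured.

A seeded synthetic-cohort generator (`deepsubtype.simdata`) emulates the
assumed structure — omics blocks sharing one two-subtype latent signal,
Gaussian noise, MCAR missingness, subtype-dependent exponential survival —
so the whole framework is testable without any data download.

## Worked example

```python
import deepsubtype as ds

data, truth = ds.simulate_multiomics(ds.SimConfig(seed=0))
dataset, _ = ds.io_prep.preprocess_blocks(data.blocks, data.clinical)

results = ds.MultiOmicsSubtyper(dataset, dae_config=ds.DaeConfig(seed=0)).fit()
print(results.summary())
```

prints

```
Multi-omics DAE-kmeans subtyping results
==============================================
samples: 298
blocks: mRNA (200 features), miRNA (60 features), cnv (120 features)
bottleneck dimension: 2
final training loss: 40.7530 (epoch 1: 50.1865)
selected k: 2 (silhouette-maximizing over [2, 8])
silhouette: 0.8267
Davies-Bouldin index: 0.2578
cluster sizes: 0: 148, 1: 150
risk groups: Low = 148, High = 150 (cluster→risk map: {1: 1, 0: 0})
log-rank: chi2(1) = 71.769, p = 2.42e-17
```

Reading this: 300 simulated patients (two dropped/filtered during
preprocessing) were compressed to two coordinates, the silhouette scan
picked k = 2, and the two clusters separate survival decisively
(p ≈ 10⁻¹⁷ under the simulated hazard ratio of 3). Against the generator's
ground truth the clustering is exact (adjusted Rand index 1.0), and

```python
clf = results.fit_classifier(lambda_grid=(0.01, 0.1, 1.0), seed=0)
len(clf.selected_features)   # -> 21 of 200 mRNA features retained
```

distils the subtypes into a 21-gene signature.

The same pipeline is scriptable from the shell:

```bash
deepsubtype run-all --seed 0 --outdir results/demo        # synthetic demo
deepsubtype benchmark --seed 0 --outdir results/demo      # method comparison
```

Each stage writes its artifacts (embedding, per-k metrics, labels, KM step
tables and plot, classifier table) plus a JSON manifest; real cohorts are
supplied as CSV/TSV matrices via a YAML config (`blocks:`, `clinical:`).

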
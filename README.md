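# scGES

Batch-effect correction, reference mapping and denoising for single-cell
RNA-seq **across the entire gene expression space** — not just the
highly variable genes.

## Why

Integration methods usually embed a few thousand highly variable genes
(HVGs) and stop there. The other ~90% of the transcriptome — lowly
variable genes (LVGs) whose batch effects are typically *stronger*
relative to their biological signal — stays uncorrected, which hurts
gene-level downstream work (differential expression, co-expression,
trajectories). This package trains two coupled conditional
negative-binomial autoencoders, one per gene class, so the
well-conditioned HVG geometry anchors batch correction of the noisy LVG
majority, and returns harmonized, denoised expression for every gene.

## The model

For cell i with batch one-hot s_i, each block (HVG / LVG) learns

    z_i   = f_E(x_i, s_i)                     # encoder, scaled expression
    μ_i, θ_i = f_D(z_i [, z_i,H], s_i)        # decoder, NB parameters
    x_ij  ~ NB(mean = l_i μ_ij, dispersion = θ_ij)

with l_i the cell's library size over the block's genes and μ a softmax
mean fraction. The HVG block minimizes

    L = β1·L_triplet + β2·L_classification + L_NB-reconstruction

where the triplet loss pulls same-identity cells from different batches
together (anchors from shared labels, or mutual nearest neighbors), by
at least margin α against a same-batch negative. The LVG block trains
afterwards with z_H frozen, alternating reconstruction and
classification steps. Defaults: α = 1, β1 = 1, β2 = 5, β3 = 1.

A trained reference can be **extended for a query batch** (one
zero-initialized batch-input column; everything else frozen), so query
mapping can never move a reference cell — the invariance is bit-exact —
and query cells inherit labels through a two-step KNN vote in the HVG
latent.

Everything runs on plain numpy (a small built-in reverse-mode autodiff
engine); runs are deterministic for a fixed seed.

## Worked example

```python
import numpy as np
from sklearn.cluster import KMeans
from scges import (simulate, simulate_query, prepare_dataset,
                   SCGESIntegrator, SCGESMapper, align_query,
                   propagate_labels, adjusted_rand_index,
                   batch_mixing_entropy)

# 3 batches x 5 cell types x 60 cells, 2000 genes, known ground truth
raw, truth = simulate(seed=0)
data = prepare_dataset(raw, n_top=300)

est = SCGESIntegrator(seed=0).fit(data)          # ~1.5 min on one CPU
ari = adjusted_rand_index(
    truth.cell_types,
    KMeans(5, n_init=10, random_state=0).fit_predict(est.z_hvg_))
ent = batch_mixing_entropy(est.z_hvg_, data.batch_ids, k=30)
print(f"type recovery ARI {ari:.3f}, batch mixing {ent:.3f}")

res = est.denoise(data, target_batch="per-cell")
idx = np.flatnonzero(truth.gene_class == "lvg-like")
corr = np.corrcoef(res.denoised_counts_mean[:, idx].ravel(),
                   truth.true_mean[:, idx].ravel())[0, 1]
print(f"LVG denoised-vs-truth correlation {corr:.3f}")

# map a fresh query batch onto the frozen reference
raw_q, q_truth = simulate_query(truth, n_cells=300, seed=1)
query = align_query(raw_q, data)
mapper = SCGESMapper(integrator=est, seed=0).fit(query, data)
labels = propagate_labels(est.z_hvg_, data.labels, mapper.z_hvg_, k=15)
print(f"query label accuracy {(labels.labels == q_truth.cell_types).mean():.3f}")
```

Output:

```
type recovery ARI 1.000, batch mixing 0.980
LVG denoised-vs-truth correlation 0.982
query label accuracy 1.000
```

The integrated embedding recovers the planted cell types exactly, mixes
the three batches almost perfectly (entropy 1.0 = ideal), the denoised
LVG expression tracks the generating NB means better than the raw
counts do (0.982 vs 0.938 on this run), and label transfer annotates
the held-out query batch correctly.

## Command line

```bash
scges simulate  --preset default --seed 0 --out sim.h5ad
scges integrate --input sim.h5ad --batch-key batch --label-key cell_type \
                --n-hvg 300 --out result.h5ad
scges map      --reference result.h5ad --reference-checkpoint result.ckpt.npz \
               --query query.h5ad --out mapped.h5ad
scges annotate --reference result.h5ad --mapped mapped.h5ad --out labels.tsv
scges evaluate --input result.h5ad --out report.json
```

Inputs: H5AD (counts in `.X` or a named layer), MTX + barcodes/features
TSVs, or dense CSV. Outputs carry embeddings (`obsm["X_scges_hvg"]`,
`obsm["X_scges_lvg"]`), denoised layers, class probabilities, and the
resolved configuration.

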
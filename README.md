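# scfuse

Variational integration of single-cell multi-omics data, plus a
Gaussian-process test for spatially variable genes — in one small, fully
deterministic Python library with a matching command line.

`scfuse` is aimed at analysts who need to place cells from several datasets
(different technologies, batches, or modalities) into one shared
low-dimensional space, and at spatial-transcriptomics users who want a
calibrated per-gene test for spatial expression structure. It provides four
models behind one uniform interface:

| model | data | idea |
|---|---|---|
| VIPCCA (`fit_vipcca`) | unpaired batches | conditional VAE: decoder sees the latent `z` **and** a one-hot batch code `b`, so batch effects are absorbed by the condition |
| DAVAE (`fit_davae`) | unpaired batches | domain-adversarial VAE: a classifier on `z` predicts the batch and its **reversed** gradient pushes the encoder toward batch-invariant `z` |
| VIMCCA (`fit_vimcca`) | paired modalities | multi-view shared-latent VAE: one posterior per cell drives two view-specific decoders (e.g. RNA + protein, RNA + ATAC) |
| VISGP (`run_visgp`) | spatial spots | per-gene GP likelihood-ratio test `y ~ N(mu*1, s^2*K(l) + n^2*I)` with a squared-exponential kernel, profiled lengthscale, mixture-chi-square or permutation p-values, and BH correction |

All three integration models maximize an evidence lower bound

```
ELBO = E_q[log p(x | z, ...)] - beta * KL(q(z|x) || N(0, I))
```

with a Gaussian likelihood on log-normalized expression and a closed-form KL
term. A kNN label-transfer utility moves annotations from a reference
embedding (e.g. scRNA-seq) to a query embedding (e.g. scATAC-seq) by majority
vote with distance-then-lexicographic tie-breaking.

Because real multi-omics downloads are large, the package ships synthetic
generators with planted ground truth (cell types, batch offsets, spatially
variable genes) and the metrics to score against it (batch-mixing entropy,
k-means adjusted Rand index), so every model is testable at desk scale.

## Worked example

```python
import scfuse as sf

# two batches of one latent population: 2 x 500 cells x 200 genes, 3 types
datasets, truth = sf.simulate_batches(seed=0)
lognorm = [sf.normalize_log(d) for d in datasets]

res = sf.fit_davae(lognorm, sf.TrainingConfig(seed=0))
labels = truth.cell_types.reindex(res.obs_names).to_numpy()
print("ARI      ", round(sf.clustering_ari(res.latent, labels, 3), 3))
print("mixing   ", round(sf.batch_mixing_entropy(res.latent, res.batch), 3))

spatial, struth = sf.simulate_spatial(seed=0)   # 10x10 spots, 20 SV genes
hits = [r for r in sf.run_visgp(spatial, seed=0) if r.q < 0.05]
print("SV genes ", len(hits))
```

prints

```
ARI       0.991
mixing    0.901
SV genes  12
```

meaning: k-means on the 16-dimensional latent space recovers the three
planted cell types almost perfectly (adjusted Rand index 0.991, where 1 is
exact and 0 is chance); local neighborhoods contain both batches at 90% of
the maximal mixing entropy (0 would mean completely separated batches); and
the spatial scan flags 12 genes at FDR 0.05 (11 of the 20 planted patterns
plus one false positive — the weakest planted hotspots sit below the
detection limit at these count depths; see `docs/methods.md`).

The same workflow from a shell:

```bash
scfuse simulate batches --seed 0 --out sim/
scfuse integrate --model davae --input sim/batch0.h5ad --input sim/batch1.h5ad \
    --seed 0 --out fit/
scfuse evaluate --latent fit/latent.csv --truth sim/truth.json --out eval/
scfuse svg --input spatial.h5ad --seed 0 --out svg/
```

Every run writes a `config.yaml` echo and a timestamped `run.log` so results
can be reproduced exactly; exit codes are stable (0 ok, 2 usage, 3
validation, 4 numeric).

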
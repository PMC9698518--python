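# velodirect

RNA velocity direction classification for single-cell transcriptomics.

Single-cell RNA-seq captures, for every gene in every cell, both mature
(spliced) and nascent (unspliced, intron-containing) transcripts. Their
balance carries dynamic information: under the splicing kinetics

```
dU/dt = α(t) − βU        dS/dt = βU − γS
```

(α transcription, β splicing, γ degradation rate) a cell with more unspliced
mRNA than its equilibrium share is up-regulating the gene, and vice versa.
The deviation from equilibrium — the **RNA velocity** `v_i = u_i − γ̃·s_i`,
with `γ̃ = γ/β = uᵀs/‖s‖²` the steady-state ratio — points toward the cell's
future expression state.

`velodirect` turns velocity estimation into a supervised learning problem:
the per-cell velocity vector is projected into a 2D expression embedding, the
displacement angle is discretized into `d` equal circular segments
(`class = ⌊d·θ/2π⌋`, default `d = 4`), and a classifier learns to predict that
direction class from the cell's gene expression alone. The classifier is a
**cascade forest**: a stack of levels, each an ensemble of four heterogeneous
tree learners (random forest, extremely randomized trees, XGBoost, LightGBM)
whose out-of-fold class-probability vectors — produced by stratified 5-fold
cross-validation — are concatenated to the original features and passed to
the next level. Depth is chosen automatically: growth stops when the level's
out-of-fold accuracy stops improving. Performance is measured with accuracy,
macro-F1 (the harmonic mean of macro-averaged precision and recall) and
Cohen's kappa.

The package contains the full pipeline, usable on any paired
spliced/unspliced count matrices (MatrixMarket + TSV bundles), plus a kinetic
simulator that generates such data with known parameters and ground-truth
direction classes, so every stage is testable without downloads:

- `sim_kinetics` — exact closed-form splicing kinetics, clustered population
  simulator, directional benchmark generator
- `preprocess` — gene filtering, depth normalization + log1p, tiered
  highly-variable-gene selection (2000 / 2500 / 3000 genes for <3000,
  3000–6000, >6000 cells), kNN moment smoothing
- `velocity_models` — steady-state ratio fit and a dynamic one-switch
  trajectory model fit by EM with latent cell times
- `direction_labeling` — PCA projection of velocity and d-way angular labels
- `feature_selection` — top-k velocity genes per cluster (default k = 20),
  expression feature matrix
- `resampling` — SMOTE oversampling + Tomek-link cleaning of the training
  split
- `cascade_forest`, `eval_metrics`, `pipeline` / `cli`

## Worked example

```python
import json
import velodirect as vd

# 1000 cells, 4 direction classes, moderate noise, known ground truth
ds = vd.make_directional_benchmark(
    n_cells=1000, d=4, separation=3.0, noise_sd=0.12, seed=1
).to_count_dataset()

report = vd.run_experiment(vd.ExperimentConfig(seed=1), ds)
print(json.dumps(report.metrics["cascade"], indent=1))
```

prints

```json
{
 "accuracy": 0.98,
 "macro_precision": 0.9790764790764791,
 "macro_recall": 0.9810466649427978,
 "macro_f1": 0.9800605821425873,
 "kappa": 0.9732309746328437
}
```

meaning the cascade assigns 98% of held-out cells (20% of the data, never
seen in training or resampling) to the correct direction class, with
chance-corrected agreement κ = 0.973. The four standalone base ensembles on
the same split reach 0.97–0.98 accuracy; on noisier benchmarks (e.g.
`separation=1.5, noise_sd=0.25`) the cascade's margin over its base learners
widens. The same experiment is available from the shell:

```bash
velodirect simulate --benchmark --out data/ --seed 1
velodirect run --in data/ --out report.json
```

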
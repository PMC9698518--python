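# Methods

## Kinetic model and closed form

Per gene, unspliced (U) and spliced (S) mRNA follow the linear ODE system
`dU/dt = α(t) − βU`, `dS/dt = βU − γS`, with constant transcription rate α up
to a switch time `t_switch` and α = 0 afterwards (one induction/repression
cycle). `solve_kinetics` evaluates the exact piecewise solution

```
U(t) = α/β + (u₀ − α/β)·e^{−βt}
S(t) = α/γ + (s₀ − α/γ)·e^{−γt} + β(u₀ − α/β)/(γ − β)·(e^{−βt} − e^{−γt})
```

with the analytic limit `β(u₀ − α/β)·t·e^{−βt}` substituted when β = γ
(the degenerate case is handled by the limit expression, not by perturbing
γ, so it is exact). The repression phase restarts the same form with α = 0
from the state at `t_switch`; the solution is continuous there. Tests verify
the closed form against an independent fixed-step RK4 integration to 1e-6.

## Synthetic data

Two generators exist; their defaults are fixed study conditions, not tuning
knobs.

**`simulate_population`** emulates a small clustered scRNA-seq experiment:
per-gene rates drawn uniformly (α ∈ [5, 20], β ∈ [0.8, 2], γ ∈ [0.2, 0.6],
switch at 40–70% of an 8-time-unit cycle), clusters occupying disjoint
latent-time windows of the cycle (so clusters correlate with kinetic phase,
as in differentiation data), and Poisson sampling of the expected counts
(log-normal multiplicative noise available for continuous-valued tests;
noise off returns the exact trajectory). The dataset-wide unspliced fraction
is kept inside the 10–25% band typical of real single-cell protocols by
rescaling the unspliced layer toward 0.175 when the noiseless expectation
falls outside it. All randomness flows from one integer seed.

**`make_directional_benchmark`** constructs ground-truth direction classes,
which real datasets do not have: the "true class" is a construct of the
generator, not an observed biological quantity. `d` equal populations sit on
an ellipse in two high-variance driver genes; population `c` gets a velocity
offset of magnitude `separation` (default 8 count units ≈ 4× the driver
genes' γ̃·s scale; "high separation") pointing at the center angle of
angular segment `c`. Three constructions make the pipeline's estimate of the
truth unbiased rather than accidental: (i) population centers are placed in
quadrature with the offsets, so per gene the offset is uncorrelated with
spliced abundance and the steady-state ratio fit is not biased by the
direction signal; (ii) a filler gene tops every cell up to equal totals in
both layers, so depth normalization is exactly the identity; (iii)
populations are tight, separated blobs, so kNN moment smoothing averages
within populations. What passing the benchmark shows is that the pipeline's
mechanics (moments, ratio fit, projection, labeling, classification) are
correct and leak-free; it does not show that direction classes of real
tissues are equally learnable — real data have no equal totals, no planted
low-rank structure, and no known truth.

## Preprocessing

Gene filtering keeps genes whose summed spliced AND summed unspliced counts
each reach `min_shared_counts` (default 20, a conventional choice). Depth
normalization scales each layer by its own size factors (cell total /
median total); a log1p copy of the normalized spliced layer feeds HVG
selection and embeddings, while velocity estimation uses the
normalized-but-unlogged layers. Normalization is recorded in a provenance
flag and a second application is rejected rather than silently compounded.

HVG selection ranks genes by dispersion (variance/mean of normalized spliced
expression) z-scored within 20 equal-width mean bins — the standard
single-cell dispersion flavor — with deterministic tie-breaking; a test
cross-checks the ranking against scanpy's implementation. The number of HVGs
follows a tiered rule by dataset size: 2000 below 3000 cells, 2500 from 3000
to 6000, 3000 above. The boundary counts (exactly 3000 or 6000 cells) are
assigned to the middle tier; the tiers' interior is fixed by the published
dataset sizes (2930→2000, 3696→2500, 5780→2500, 7202→3000).

Moment smoothing builds a kNN graph (Euclidean distance in the top 30 PCs of
the log layer, 30 neighbors by default — conventional values, configurable)
and replaces each layer by neighborhood means; each cell's neighborhood
includes itself, which makes `k_neighbors=1` the identity — a clean testable
limit.

## Velocity estimation

**Steady state.** Per gene, `γ̃ = (u·s)/(s·s)` — the least-squares slope of
unspliced on spliced through the origin — computed on moment-smoothed layers
(smoothing denoises the ratio; an unsmoothed option exists). Velocity is the
residual `v = u − γ̃·s`. No extreme-quantile restriction is applied to the
regression by default. Genes with an all-zero spliced signal are flagged
invalid and carry zero velocity.

**Dynamic.** Per gene, a one-switch trajectory with latent cell times is fit
by EM against the Gaussian likelihood
`L(θ) = (1/√(2π)σ)·exp(−(1/2n)·Σᵢ‖xᵢ − x_{tᵢ}(θ)‖²/σ²)` with a single
per-gene σ shared across the u and s dimensions. Because only the
phase-space curve is observed and times are latent, (α, β, γ, t_switch) are
identifiable only up to a common time scaling; fitting fixes α = 1 and the
recovered quantities are β/α, γ/α and α·t_switch. E-step: each cell is
assigned the time minimizing squared distance to the trajectory over a
200-point grid spanning `[0, t_switch]` and four repression time constants
beyond it; the cell's previous assignment is always included among the
candidates, which makes the likelihood trace rigorously non-decreasing even
though the grid moves with θ. M-step: bounded trust-region least squares
over (β, γ, t_switch) at fixed times; σ² is the mean squared residual (its
ML profile). Initialization is deterministic: β₀ from the 98th percentile of
u, γ₀ from the steady-state ratio, and the best of three t_switch starts.
Non-convergence at `max_iter` flags the gene instead of raising. Dynamic
velocity is `v = βu − γs`, the spliced ODE right-hand side at the
observation; its per-gene scale is 1/α of the physical ds/dt, which leaves
direction classes unchanged.

## Direction labels

Velocity is pushed through the top-2 PCA of the log layer as an exact linear
map (`displacement = v · loadings`) rather than a transition-probability
embedding: it is deterministic and exactly testable (a finite-difference
test confirms the pushforward), and alternative projectors can be swapped
in. PCA signs are fixed by making each component's largest-magnitude loading
positive, so runs are bit-identical. The angle is measured counterclockwise
from +x and discretized into half-open segments `[2πc/d, 2π(c+1)/d)`;
values of `d·θ/2π` within 1e-9 of an integer are snapped to it before
flooring, so displacements exactly on a boundary go to the higher class
instead of being lost to float rounding. Cells with zero displacement have
no direction: they are flagged and excluded from training rather than
assigned an arbitrary class; their count is reported.

## Features, split, resampling

Genes are ranked per cluster by the Welch t-statistic of their velocity
values (cluster vs. rest; tie-break by gene id; an absolute-mean-velocity
ranker is available, and is also the fallback when only one cluster exists).
The classifier's features are the log-normalized spliced expression of the
union of the top-k genes per cluster (k = 20 by default) — expression, not
velocity, because the task is to predict a cell's velocity direction from
its expression alone.

The labeled cells are split 8:2 per class (seeded). SMOTE brings every
minority class up to the majority count by interpolating between a class
member and one of its k = 5 nearest same-class neighbors (fewer if the class
is smaller); Tomek cleaning then removes non-minority members of mutual
nearest-neighbor pairs with different labels, where "minority" is the
globally least frequent label (ties to the lowest). Resampling is applied to
the training split only — resampling before the split would leak synthetic
copies of test cells into training; published pipelines are often ambiguous
on this ordering, and scores obtained with pre-split resampling are inflated
accordingly.

## Cascade forest

Base roster: sklearn RandomForest and ExtraTrees (bagging with two
randomization schemes) and XGBoost and LightGBM (two boosting variants), 100
trees/rounds each, single-threaded, all seeded from one generator. The
roster is an adapter contract (`EstimatorSpec`), so any classifier with
`fit`/`predict_proba` can be plugged in. Per level, each estimator's
class-probability vectors are produced out-of-fold by stratified 5-fold CV
(fold models are retained); the 4·d probabilities are concatenated to the
original features — only the immediately preceding level's vectors, not all
history — as the next level's input. The level score is the accuracy of the
argmax of the four averaged OOF probability matrices. Growth stops when the
score fails to improve by more than `tol = 1e-4` for `patience = 1`
consecutive level (defaults `max_levels = 8`); the stopping rule's
"significant improvement" needs concrete numbers, and these are they.
Inference propagates through the best level, averaging each estimator's five
fold models (retraining on the full data is a config option); ties in the
final argmax go to the lowest class index. Models serialize to a versioned
joblib archive with a magic header; foreign or corrupt files are rejected.

## Metrics

Accuracy is trace/n of the confusion matrix (the multiclass form of
correct/total). Macro-F1 is `2·P_macro·R_macro/(P_macro + R_macro)` where
P_macro and R_macro are the plain means of per-class precision and recall —
note this is the harmonic mean of the macro averages, not the mean of
per-class F1 scores; the two conventions differ and are easy to conflate.
Undefined per-class precision (class never predicted) is treated as 0 with a
warning. Kappa is `(p0 − pe)/(1 − pe)` with `pe = Σ aᵢbᵢ/n²` from the
marginals; the degenerate pe = 1 case returns 0 with a warning.

## Experiment protocol and problem sizes

`run_experiment` reports, per configured classifier, all metrics on the
untouched test split. Unsupervised stages (normalization, HVG, kinetic fits,
feature ranking) use all cells; a strict mode that refits features on the
training split only is a documented alternative. Reference behavior is
asserted on the benchmark at n = 1000 cells, d = 4, high separation, with
the cascade's mean test accuracy over 5 seeded runs required to reach 0.9
and to be within 0.02 of every standalone base ensemble; the mean over seeds
(rather than per-seed assertion) is the package's protocol for comparing
stochastic classifiers. Test problem sizes throughout (hundreds to a
thousand cells, tens of genes, 50-seed EM checks at 60 cells/gene) are
chosen as the smallest scales at which the asserted properties are
statistically unambiguous.

## Known limitations

- The dynamic model fits one induction/repression cycle with shared rates;
  bursting, multiple switches, and cell-specific rates are out of scope.
- The 2D projection is linear PCA; nonlinear embeddings (UMAP/t-SNE) with
  velocity-graph projection are deliberately not implemented, and direction
  classes depend on the chosen projection.
- Direction "ground truth" exists only in the simulator; on real data the
  labels are themselves estimates, so classification scores measure
  consistency with the velocity pipeline, not biological truth.
- SMOTE/Tomek operates in the full feature space with Euclidean distance;
  no borderline/ADASYN variants.
- Metrics follow the printed macro-F1 convention above; comparisons against
  tools reporting mean-of-per-class-F1 need care.
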
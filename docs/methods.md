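# Methods

`kronsurv` implements an interpretable trimodal survival-modelling pipeline:
sparsely coded (capsule) neural encoders for gene expression and DNA
methylation, a graph-convolutional encoder over whole-slide patch graphs,
and a gated Kronecker trilinear fusion of the three modality embeddings,
all trained under the Cox partial likelihood. This note records the model,
its assumptions, the defaults that matter, and the design choices made where
the design was genuinely open.

## Survival model and losses

All outcomes are right-censored times in days with event indicators. The
training loss for every hazard-emitting network is the negative mean log Cox
partial likelihood over events,

    L(h) = -(1/d) * sum_{i: delta_i = 1} [ h_i - log sum_{j: T_j >= T_i} exp(h_j) ],

with **Breslow** handling of tied event times. Breslow is used consistently
in the loss, the Newton–Raphson `fit_coxph`, and the partial likelihood
ratio test, so nested log-likelihoods are directly comparable. The
alternative (Efron) weights tied events slightly differently; consistency
across the three uses mattered more here than the small efficiency gain.

Concordance is Harrell's C: a pair (i, j) is comparable iff T_i < T_j and
patient i had the event; tied predictions earn 0.5; pairs tied on event time
are not comparable. Confidence intervals are percentile bootstrap over
patients (default 1000 resamples, 95%); resamples without comparable pairs
are redrawn and counted. Hazard dichotomisation scans all midpoints between
sorted unique predictions, requires at least `minprop = 0.1` of the cohort
on each side, and maximises the standardised log-rank statistic
|O − E| / sqrt(V); ties resolve to the lower threshold, so the cut is
invariant to rank-preserving transformations of the predictions.

`fit_coxph` standardises covariates internally, runs Newton–Raphson with
step-halving to gradient norm < 1e-8 (max 100 iterations), and reports the
inverse observed information as the covariance. Coefficients diverging past
50 on the standardised scale are reported as separation rather than
returned. The implementation agrees with scikit-survival's Breslow fit to
machine precision on tie-free data (tested).

## Omics capsule encoders

Each omics input passes through a connectivity-masked linear layer: feature
f connects to capsule c only when the annotation maps it there (CpG→gene,
gene→pathway). The mask multiplies the weights, so a disconnected feature
can never influence a capsule — the locality contract is property-tested by
perturbation fuzzing. Capsule activations (tanh) feed a ReLU stack to a
latent vector (default width 128; the reference experiments in the test
suite use 16 to fit desk hardware).

Two pretraining heads exist:

* **Self-supervised (VAE)**: mu/log-variance heads over the latent, a
  mirrored decoder, loss = feature-mean squared reconstruction error plus
  KL(q ‖ N(0, I)) summed over latent dimensions. Defaults: 500 epochs,
  Adam, learning rate 0.008, checkpoints every 100 epochs; the checkpoint
  grid is resolved by survival finetuning performance on the validation
  fold.
* **Crossmodal + survival**: from a shared latent, one branch emits the
  scalar log-hazard (Cox loss) and a second predicts features of the
  complementary modality (MSE, weight `w_cm = 1.0`). Predicting *all*
  complementary features is wasteful; the target is the K most variable
  complementary features computed on the training fold (default K = 256;
  scaled runs use 32).

Survival-stage defaults: up to 40 epochs, Adam, learning rate 2e-4, batch
size 32, weight decay 1e-4. The coefficient 1e-4 is implemented as constant
L2 weight decay; a linear learning-rate decay variant is available behind
`decay_mode="linear_lr"` because the intended scheduler is ambiguous.

## Whole-slide graphs and the GCN encoder

A slide is a set of patches on a grid with precomputed embedding vectors
(the synthetic generator emulates these; real embeddings would come from a
CNN patch encoder, which is out of scope). Patches become nodes; edges
connect pairs within Euclidean radius 1.5 patch units — i.e. 8-connectivity
on a regular grid; only the largest connected component is kept (size ties
break to the component containing the lowest node index).

The encoder stacks `n_blocks` (default 3; scaled runs use 2) of:

1. **SAGE convolution**: h'_v = ReLU(W_self h_v + W_nbr mean_{u∈N(v)} h_u);
   isolated nodes get a zero neighbour term.
2. **Self-attention pooling**: a single-output graph convolution scores each
   node; the top ceil(r·n) nodes survive (r = 0.5; score ties keep the lower
   index), their features scaled by tanh(score); edges are induced.

Per-block global mean readouts are concatenated (jumping-knowledge) into the
graph embedding feeding hazard and crossmodal heads. The forward pass is
invariant to node relabelling when scores are untied (tested).

**Contrastive pretraining** is Deep Graph Infomax: corruption = row-shuffled
node features on the same topology, summary s = sigmoid(mean node
embedding), bilinear discriminator sigmoid(hᵀBs), mean binary cross-entropy
with real nodes labelled 1. Chance level is ln 2; training must drop below
it (tested). 15 epochs by default, transferring the epoch with the lowest
validation loss. Survival GCN training uses batch 4 with gradient
accumulation every 4 steps (effective 16) and a coarse learning-rate grid
{1e-4, 2e-4, 4e-4} resolved on validation.

## Gated Kronecker fusion

Penultimate features of the three trained unimodal networks are the
modality embeddings. Each is projected to a common fusion width (default 32;
scaled runs 4) and gated on the other two:

    g = sigmoid(W_g · concat(proj(ctx_1), proj(ctx_2))),  e = g ⊙ (W_t · h).

Each gated vector is augmented with a trailing 1 and fused by a triple outer
product, vectorised in row-major order, giving length (d+1)³; the appended
ones guarantee all unimodal and bimodal interaction terms appear. A
feed-forward head maps the fused vector to the log-hazard. Missing
modalities are a hard error — imputation is explicitly out of scope.

Fusion training: Adam, up to 40 epochs, batch 3 with accumulation every 8
steps (effective 24), weight decay 1e-4, encoders frozen for the first 10
epochs. Two implementation notes:

* While encoders are frozen their embeddings are constant, so the frozen
  phase trains the gates/head on precomputed embeddings — numerically
  identical to the naive forward pass and much cheaper.
* Cox risk sets are formed over each accumulation group (12–24 patients),
  not the raw mini-batch of 3–4, whose risk sets would be degenerate. One
  optimiser step is taken per group.
* The incoming parameter state competes with every epoch for checkpoint
  selection, so finetuning never returns a model worse on validation than
  its initialisation.
* An optional coarse learning-rate grid for the fusion stage (resolved by
  validation Cox loss) mirrors the grids used for the graph branch; the
  scaled reference experiments train the fusion stage at 2e-4.

## Training regimes

* `uni_self` — omics VAE pretraining → survival finetune; GCN survival from
  random initialisation.
* `uni_cross` — joint crossmodal + survival training (GCN additionally gets
  DGI pretraining first).
* `multi_self` / `multi_cross` — fusion model initialised from the
  corresponding unimodal weights.
* `transfer` — unimodal crossmodal pretraining and a 10-epoch multimodal
  pretrain on the pooled sub-cohorts, then per-sub-cohort finetuning for 40
  epochs at learning rate 1e-3.

Splits are 80/10/10, stratified by event status, and accepted only when all
pairwise log-rank tests between partitions have p ≥ 0.05 (up to 25 redraws
with incremented seeds, logged). All randomness flows from a single integer
seed; identical seed and config reproduce checkpoints bit-for-bit.

## Interpretation

* **Integrated Gradients** (right-Riemann, default 64 steps) attribute the
  hazard to the capsule layer: the reference input is the mean capsule
  activation of the low-risk group (zero baseline available), attributions
  are averaged over high-risk patients, and capsules are ranked by absolute
  mean score (top 10 reported). Completeness |Σ attr − Δf| is recorded;
  attributions are exact for linear heads at any step count.
* **Patch importance**: the nodes surviving the final attention pool, mapped
  back to grid coordinates with their scores.
* **TIL agreement**: a multivariate two-sample runs test (Friedman–Rafsky).
  The Euclidean minimal spanning tree of the pooled important-patch and TIL
  coordinates is built once; the statistic is the number of cross-label
  edges; the p-value comes from label permutations (default 1000) with
  mid-p handling of ties — the cross-edge count is a small integer, and
  mid-p keeps the null distribution of the p-value uniform (verified by
  simulation; a moment-based normal approximation is available). Duplicate
  coordinates receive an infinitesimal seeded jitter. High p = the two sets
  mix = the model localises TILs.
* **Fisher association**: slides are called TIL-localising when their runs
  p ≥ 0.05; the 2×2 table against dichotomised hazard is tested with the
  exact hypergeometric two-sided p, odds ratio Haldane-corrected when a
  cell is zero.

## Synthetic cohorts

The generator emulates matched TCGA-style trimodal data with planted
structure. Per patient: latent z ∈ R^k ~ N(0, I); pathway p's activity is
z_{p mod k}; gene g in pathway p(g) has expression loading·activity + N(0,
noise_sd²) with loadings ~ U(0.6, 1.4); CpG c mapped to gene g(c) has beta
value logistic(−expression + noise), so methylation is anti-correlated with
its gene and each omics modality predicts the other. Slides are grid_size²
patch grids; TILs are 3×3 blobs placed uniformly (Poisson count calibrated
to the target fraction); embeddings carry a +2.0 TIL channel and a channel
shifted by 0.5·(beta·z). The linear predictor eta = beta·z + gamma·burden
feeds exponential event times with baseline hazard ln(2)/730 per day
(median survival two years at eta = 0) and independent exponential censoring
(5e-4 per day, ≈ 50% censoring under the reference conditions), so proportional hazards holds exactly
and the censoring fraction has the closed form c/(c + λ₀e^eta).

Reference conditions: 300 patients, 200 genes, 500 CpGs, 20 pathways of 10
genes, k = 4 with beta = (1.0, 0.8, 0, 0) — so 10 of 20 pathways are causal
— 12×12 slides, embedding dimension 32, TIL fraction 0.15 with gamma = −5
(TILs protective). Under these conditions the concordance of the true
predictor is 0.788 (computed by direct simulation at n = 100 000). A config
flag adds a detached satellite patch block to exercise largest-component
selection. One slide per patient; Weibull times, copy-number/mutation
simulation and richer clinical covariates are out of scope.

What the generator does *not* emulate: real pathway overlap structure
(pathways here partition genes), probe-level methylation noise models,
heterogeneous slide sizes, batch effects, or informative censoring. Passing
tests therefore demonstrate that the machinery recovers planted structure
under the stated model, not performance on real cohorts.

## Problem sizes in the shipped experiments

The test suite and `scripts/acceptance.py` run everything on a single CPU,
so the reference experiments use scaled architectures (latent 16, GCN width
16/2 blocks, fusion width 4, K = 32) and schedules (omics 40 epochs, GCN 8
epochs + 2 DGI epochs, fusion 30 epochs with 10 frozen); the regime
comparison uses three sub-cohorts of 100 patients with 5×5 slides and
correspondingly smaller networks. Statistical checks use 2000 null
simulations for the likelihood-ratio test's type-I error and 500 for
runs-test calibration.

## Known limitations

* The autodiff engine is tape-based over float64 numpy; it is adequate for
  these model sizes but makes no attempt at GPU execution or kernel fusion.
* Graph batching is per-slide; very large slides would need neighbour
  sampling.
* The runs-test permutation p is Monte-Carlo; exact enumeration is only
  used in tests on tiny instances.
* `partial_lrt` assumes the supplied fits are genuinely nested on identical
  samples; it can only check parameter counts and sample counts.
* Bootstrap CIs are percentile, not BCa; with very few comparable pairs the
  redraw rule can bias intervals slightly upward.
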
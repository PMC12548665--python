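# Methods

## Model

The generative model is an encoder–decoder GAN over structural
connectivity (SC) matrices. An SC matrix x is n×n, symmetric, non-negative
with zero diagonal; only the strict lower triangle (n(n−1)/2 edges, fixed
row-major order: (1,0), (2,0), (2,1), …) is modelled, and decoder outputs
are matricized back symmetrically, which makes symmetry and zero diagonal
structural rather than learned.

* **Encoder D** — BrainNetCNN stack E2E → E2E → E2N → N2G (four
  convolutions) followed by two fully connected layers to the latent code.
  The E2E operator applies a cross-shaped filter,
  out(i,j) = Σ_k r_k·x(i,k) + Σ_k c_k·x(k,j) + b; E2N reduces each region's
  incident edges to a node value; N2G pools node values to graph-level
  units. Leaky-rectifier activations (slope 0.2) throughout; no activation
  on the latent code.
* **Decoder G** — five fully connected layers from the latent code to the
  edge vector; final softplus keeps edges non-negative.
* **Critic C** — the same four-convolution stack with a linear scalar head
  and *no* output nonlinearity (a Wasserstein critic must be unbounded).
* **Regressor R** (task-guided mode) — four convolutions + four fully
  connected layers from the synthesized matrix to a scalar score estimate.

The critic maximises E[C(x)] − E[C(x̃)] − λ·E[(‖∇_x̂C(x̂)‖−1)²] with
x̃ = G(D(x)) and x̂ = u·x + (1−u)·x̃, u ~ Uniform(0,1) per sample; the
generator minimises −E[C(x̃)] plus, in task-guided mode, α times the RMSE
between observed scores and R(x̃) (a sum-of-squares variant is available
via `sum_squares=True`). Scores are z-scored with training-set statistics
inside `train()` so the two loss terms share a scale.

The gradient penalty requires differentiating the critic's input-gradient
norm with respect to the critic parameters. The package therefore includes
a small reverse-mode autodiff core on numpy arrays (`tggan._tensor`) whose
vector-Jacobian products are themselves composed of differentiable tensor
operations, so second-order gradients are exact (verified against finite
differences to ~1e-10 in the tests). The piecewise-linear leaky rectifier
has zero curvature almost everywhere, so mask-based backward passes are
exact off the kink.

## Training

Adam (β1 = 0.9, β2 = 0.999) with a constant learning rate; alternating
updates with `critic_steps_per_gen` critic steps per generator step; the
generated batch is recomputed after every generator update and treated as
constant during critic steps. In task-guided mode training early-stops when
the validation regressor loss has not improved for `patience` (default 50)
consecutive epochs once `warmup_epochs` (default 500) have been reached,
and the returned model is the checkpoint with the best validation regressor
loss; in plain WGAN-GP mode (α = 0, no regressor) training runs the full
epoch budget and returns the final model. A NaN in any loss stops training
and returns the best previous checkpoint with a `diverged` flag. Runs are
bit-reproducible from `TrainConfig.seed`: weight init, dropout masks, batch
order and penalty interpolation each draw from named substreams of one
seed sequence.

Canonical defaults follow common practice for this model family
(learning rate 1e-4, batch size 2, 2000 epochs, λ = 10, 5 critic steps per
generator step). Hyperparameter selection is an exhaustive dropout × α grid
(defaults p ∈ {0.1..0.5}, α ∈ {0.1..1.0}) keyed on the training +
validation regressor loss at the stopping checkpoint, ties going to smaller
dropout then smaller α; a plain WGAN-GP baseline inherits the selected
dropout.

**Desk-scale protocol.** The reference demonstration
(`tggan.experiment.desk_scale_protocol`, also run by
`scripts/acceptance.py`) uses problem sizes chosen for a single CPU:
113 synthetic subjects with 30 regions (giving a 75-subject discovery set
and 38-subject test set under the every-third-rank split), the small
network spec (E2E channels 4/8, E2N 16, N2G 32, latent 16), batch size 2,
one critic step per generator step, learning rate 5e-4, α = 1.0, 120
epochs. The raised learning rate and reduced critic schedule compensate
for the much smaller networks and sample count: with them the
task-guided coupling (latent PC1 tracking the score, score information in
decoded matrices) develops within ~100 epochs instead of the thousands a
full-size configuration uses.

## Augmentation

New samples interpolate score-adjacent subjects: sort by score (stable
ties by subject id), take the N−1 consecutive pairs, combine latent codes
convexly with ε and the scores with the same ε. The ε grid for k samples
per pair is t/(k+1), t = 1..k — the unique symmetric interior grid;
endpoints are excluded because they would duplicate real samples. Arbitrary
target sizes distribute the extra samples round-robin across pairs in
sorted order. Synthesized samples carry a `synthetic` flag; the prediction
stage adds them to training folds only, never to validation folds or the
test set, and `evaluate_test` refuses test sets containing them.

## Fidelity evaluation

Averaged-matrix pipeline: average acquired and synthesized matrices,
binarize at edge densities 5–25% (keep the ⌊d·E⌋ strongest edges; ties
broken by weight desc, then row, then column — deterministic and
scale-invariant), compute nodal strength (degree), betweenness centrality
and clustering coefficient, then the KL divergence between Gaussian kernel
density estimates of the two distributions (Silverman bandwidth, 512-point
common grid spanning both samples, 1e-12 floor, discrete-sum KL; a
zero-variance sample falls back to a narrow fixed-bandwidth kernel).
Per-matrix pipeline: binarize every subject's matrix, compute betweenness,
clustering, modularity (greedy modularity maximisation, resolution 1),
global efficiency and local efficiency (nodal values averaged across
regions), and summarise acquired-vs-synthesized differences with paired
Cohen's d (mean difference over SD of differences; sign = synthesized −
acquired). Unreachable node pairs contribute zero efficiency; betweenness
is normalised by 2/((n−1)(n−2)) by default. Graph measures are computed
through networkx; the test suite verifies them against python-igraph and
closed forms on K5, stars and disjoint triangles to 1e-9.

## Prediction benchmark

Subjects are sorted by score and every third rank is held out (stride and
offset configurable), which matches the score distributions of the
discovery and test sets. On the discovery set: 20 repeats of an outer
5-fold CV; within each outer training fold an inner 5-fold CV tunes Ridge
α over {2^n, n = −10..5} (or Elastic-Net α ∈ {2^(2n), n = −5..4} ×
l1-ratio ∈ {0.2..1.0}), scoring each grid point by the z-scored fold-mean
Pearson r plus the z-scored inverse fold-mean MAE and breaking ties toward
weaker regularisation. Edge features are standardized per edge with
training-fold statistics. The resulting 100 models are evaluated on the
fixed test set (Pearson r, RMSE); a constant prediction's r is reported as
0 with a degeneracy flag so summaries stay computable. Model populations
are compared by Welch's t test after a single-pass removal of values more
than 3 SD from their group mean, Bonferroni-corrected by the number of
augmentation levels; edge-weight reliability is the per-edge mean and
95% percentile interval across the 100 models. Latent-space analysis
encodes a subset (dropout off), fits a PCA on that subset only, and
reports the PC1–score Pearson correlation with PC1's sign canonicalised
(largest-|loading| component positive).

## Synthetic data

The generator emulates the statistical shape of volume-normalised
streamline-count connectomes with a continuous cognitive composite score:

* score ~ Normal(419.2, 40.9²) by default — the scale of a summed
  cognition-battery fluid composite;
* a fixed sparse two-block community backbone (within-block edges ~4×
  likelier, weights Uniform(0.3, 1)), density 0.35, so modularity,
  clustering and efficiency are non-degenerate after thresholding;
* 40 signal edges within the backbone whose weights move linearly with the
  z-scored score (total strength 0.25 weight units per score SD, split
  evenly with alternating sign);
* half-normal subject noise (SD 0.08) on backbone edges, clipped at zero.

Defaults were fixed once so that the planted linear read-out is strongly
recoverable (oracle r ≈ 0.98 at n = 113; Ridge on standardized edges
reaches ≥ 0.8 of the oracle at n = 200), giving downstream stages a clear
signal to preserve. What the generator does *not* emulate: heavy-tailed
streamline-weight distributions, distance-dependent connection probability,
hub/rich-club organisation, site effects, or nonlinear edge–score
relations. Passing tests therefore show that the machinery preserves and
exploits a linear planted signal under realistic sparsity and symmetry
constraints — not that augmentation gains transfer to any particular
empirical cohort.

## Numerical and design notes

* Matrices are validated with symmetry tolerance 1e-8 (then symmetrized)
  and diagonal tolerance 1e-8 (then zeroed); negatives and non-finite
  values are rejected with the offending entry named.
* The rank-interleaved rule with stride 3 on N subjects holds out
  ⌈N/3⌉; 113 subjects give the 75/38 discovery/test split used by the
  desk-scale protocol.
* Welch comparisons of two zero-variance groups report t = 0, p = 1 when
  the means agree (no effect) and |t| = ∞, p = 0 otherwise.
* All multi-stage runs derive per-stage RNG streams from one root seed via
  CRC-tagged substreams (`derive_seed`), so every artifact is reproducible
  from the config alone; outputs carry the package version, a config hash
  and the seed.

## Known limitations

* The numpy autodiff core is single-threaded and eager; full-size
  configurations (100+ regions, thousands of epochs) are out of its
  practical range.
* Adversarial-only reconstruction (no pairwise reconstruction loss) means
  G(D(x)) matches the data distribution but is only loosely tied to x at
  desk scale; the decoded score signal is attenuated accordingly, and
  augmentation gains over the baseline are correspondingly modest in the
  scaled protocol.
* Elastic-Net fits use coordinate descent with a 5000-iteration cap; very
  small α values on ill-conditioned folds may stop early (sklearn warns).
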
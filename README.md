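# tggan — task-guided GAN augmentation for connectome-based prediction

Predicting a cognitive trait from a structural connectome is chronically
data-starved: a typical single-site cohort has on the order of 100 subjects,
while the feature space (the ~n(n−1)/2 edge weights of an n-region
connectivity matrix) has thousands of dimensions. `tggan` implements a
data-augmentation strategy for this setting: a Wasserstein GAN with gradient
penalty whose generator is an encoder–decoder over connectivity matrices,
*task-guided* by an auxiliary regressor so that the learned latent space
captures score-relevant variation, plus the full evaluation protocol needed
to judge whether the synthesized data helps — graph-theoretic fidelity
measures, latent-space analysis, and a repeated nested cross-validation
prediction benchmark.

## The model

A structural connectivity matrix x is square, symmetric, non-negative, with
zero diagonal. The encoder D (a BrainNetCNN: two edge-to-edge convolutions,
an edge-to-node convolution, node-to-graph pooling, then two fully connected
layers) maps x to a latent code z; the decoder G (a five-layer MLP with a
softplus output) maps z to the lower-triangle edge vector of a synthesized
matrix x̃ = G(D(x)). A critic C (BrainNetCNN with a linear scalar head)
estimates the Wasserstein-1 distance between real and synthesized matrices:

    L_{G,C} = E[C(x)] − E[C(x̃)] − λ·E[(‖∇_x̂ C(x̂)‖₂ − 1)²]

with x̂ sampled uniformly on segments between real and synthesized samples
(gradient penalty, λ = 10). In task-guided mode a regressor R predicts the
cognitive score from x̃ and its RMSE loss L_R joins the objective:

    min_{G,R} max_C  L_{G,C} + α·L_R .

New (matrix, score) pairs are synthesized by latent interpolation between
subjects adjacent in score rank:

    x_s = G(ε·D(X_i) + (1−ε)·D(X_j)),   y_s = ε·y_i + (1−ε)·y_j,  ε ∈ (0,1).

Doubling a 75-subject discovery set this way yields 75 + 74 = 149 training
samples; quintupling yields 371.

Because the networks require differentiating the critic's input-gradient
norm with respect to the critic parameters (double backprop), the package
ships a compact numpy reverse-mode autodiff core (`tggan._tensor`) whose
backward passes build differentiable graphs.

## Worked example

```python
from tggan import SyntheticConfig, generate_dataset, TaskGuidedGAN, augment
from tggan.brainnet import NetworkSpec
from tggan.gan import TrainConfig
from tggan.prediction import (rank_interleaved_split, split_dataset,
                              repeated_nested_cv, evaluate_test,
                              summarize_test, latent_pca, CVConfig)

# 113 synthetic subjects, 30 regions, a planted score-linked edge signal
dataset, truth = generate_dataset(SyntheticConfig(n_subjects=113, seed=11))
discovery, test = split_dataset(dataset, rank_interleaved_split(dataset))

model = TaskGuidedGAN(
    discovery,
    spec=NetworkSpec.small(30),
    config=TrainConfig(learning_rate=5e-4, batch_size=2, max_epochs=120,
                       critic_steps_per_gen=1, warmup_epochs=120,
                       task_alpha=1.0, seed=101),
).fit()
print(model.summary())

augmented = augment(discovery, model, per_pair_count=1)   # 75 -> 149
cv = repeated_nested_cv(augmented, CVConfig(seed=7))       # 20 x 5 folds
print(summarize_test(evaluate_test(cv, test)))
```

A run of this example printed:

```
task-guided (TG GAN II): 30 nodes, latent dim 16
epochs run: 120, checkpoint epoch: 54
final critic loss -0.3077, generator adv loss 0.5039
validation regressor loss at checkpoint: 0.9963
reconstruction error: 25.0087 -> 9.1203
{'r_mean': 0.9677, 'r_sd': 0.0062, 'rmse_mean': 12.16, 'rmse_sd': 1.25, 'n_models': 100}
```

The training summary shows the checkpoint returned (best validation
regressor loss, epoch 54) and that the mean distance between each input
matrix and its reconstruction G(D(x)) fell from 25.0 to 9.1 over training.
The final line is the test-set performance of the 100 nested-CV models
(20 repeats × 5 outer folds) trained on the augmented discovery set:
mean ± SD Pearson correlation 0.968 ± 0.006 and RMSE 12.2 ± 1.2 score
points between observed and predicted scores on the 38 held-out subjects
(the planted-signal generator makes this an easy prediction problem; the
oracle read-out reaches r ≈ 0.98).

There is also a CLI covering each stage:

```bash
tggan synth --n-subjects 113 --n-nodes 30 --seed 11 --out data/
tggan train --mode tg-gan2 --data data/ --epochs 120 --out model.npz
tggan augment --model model.npz --data data/ --factor 1 --out augmented/
tggan evaluate --acquired data/ --synthesized augmented/ --out report.json
tggan predict --data augmented/ --test test/ --out results/
tggan run-experiment --seed 11 --out results/
```

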
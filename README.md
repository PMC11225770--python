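# paddypest

Identification of insect pests in paddy-field photographs, built around
a from-scratch **Lion Optimization Algorithm (LOA)** used as a binary
wrapper feature selector over deep image features.

The workflow: field images are denoised (Gaussian / average / median
filters) and optionally augmented (seven standard operators), encoded
as fixed-length feature vectors by a pretrained-CNN-style backbone,
reduced by a feature selector (PCA, LDA, RFE, or the lion wrapper), and
classified as *pest present* / *pest absent* by a bank of seven
classical learners under a stratified 80/20 holdout and 5-fold
cross-validation protocol. A deterministic mock backbone and seeded
synthetic generators make every stage runnable and testable offline,
with no pretrained weights or image downloads.

## The optimizer in brief

The LOA minimizes `f(x)` over a box by evolving `Npop` candidate
solutions ("lions") organized into prides and a nomad pool. Prides keep
an elitist *territory* of personal bests; per iteration, females hunt a
dummy prey at their centroid (jumping between `2·PREY − Hunter` and
`PREY`), non-hunters move toward tournament-selected territory points
(`new = old + 2D·u·R₁ + U(−1,1)·tan θ·D·R₂` with `R₂ ⊥ R₁`), males roam
(`x ~ U(0, 2d)` toward territory points), mating produces
linear-combination cubs `β·F + (1−β)·mean(males)` with per-gene
mutation, and defense / migration / equilibrium restore the fixed
census. Tournament size follows `T = max(2, ⌈K/2⌉)` where `K` counts
last iteration's improved members.

For feature selection the optimizer searches `[0,1]^d`; coordinates
above 0.5 decode to the retained feature set, and a mask's fitness is
the stratified 5-fold error of a wrapped classifier on the masked
features. Defaults follow the published tuning (`Npop = 500`, 20 %
nomads, 5 prides, 80 % females, roaming 0.2, mating 0.3, mutation 0.2,
immigration 0.4). See `docs/methods.md` for the full model.

## Worked example

Generate a two-class Gaussian feature table (200 samples, 30 features,
8 informative at 1.2 SD separation), run lion-wrapper selection, and
evaluate the classifier bank on the selected features:

```bash
paddypest simulate --out table.tsv --n-per-class 100 --d 30 \
    --n-informative 8 --separation 1.2 --seed 42
paddypest select --features table.tsv --out mask.tsv --method loa \
    --population 24 --iterations 8 --seed 42
paddypest classify --features table.tsv --mask mask.tsv --out run \
    --protocol both --seed 42
```

which prints:

```
wrote 200x30 table to table.tsv (informative columns: [2, 11, 16, 18, 20, 24, 26, 28])
LOA kept 19/30 features (wrapper CV error 0.0300)
                              accuracy  precision  recall      f1
logistic_regression[holdout]     100.0     100.00   100.0  100.00
svm[holdout]                      97.5     100.00    95.0   97.44
knn[holdout]                      92.5      90.48    95.0   92.68
naive_bayes[holdout]              97.5     100.00    95.0   97.44
logistic_regression[cv5]          96.0      95.39    97.0   96.07
svm[cv5]                          96.0      96.67    96.0   96.05
knn[cv5]                          92.0      89.69    95.0   92.24
naive_bayes[cv5]                  96.5      97.23    96.0   96.48
```

The selector kept 19 of 30 features at a 3 % internal wrapper error;
the grid reports accuracy / precision / recall / F1 (0-100 scale, pest
= positive class) for each classifier under the 80/20 holdout and
5-fold cross-validation. `paddypest run --config run.yaml` executes the
full image pipeline (simulate or load an image tree, filter, extract,
select, classify) from one YAML file, and `paddypest simulate --kind
images` materializes a toy pest / no-pest image tree.

Library use mirrors the CLI:

```python
import numpy as np
from paddypest.loa import LOAConfig, optimize

config = LOAConfig(lower_bounds=np.full(5, -5.0), upper_bounds=np.full(5, 5.0),
                   population_size=50, max_iterations=200, patience=0, seed=0)
result = optimize(lambda x: float(np.sum(x * x)), config)
print(result.best_fitness)   # ~1e-6 on the 5-D sphere
```

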
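# Methods

`paddypest` implements a pest-identification workflow for paddy-field
photographs: images are denoised and augmented, encoded as fixed-length
deep-feature vectors, reduced by a feature selector, and classified as
"pest present" / "pest absent" by a bank of classical learners. Its
core is a from-scratch Lion Optimization Algorithm (LOA) used as a
binary wrapper feature selector. This note records the models, the
parameter choices, the numerical decisions, and what the synthetic
benchmarks do and do not demonstrate.

## The lion optimizer

The LOA is a population metaheuristic that minimizes an objective
`f : R^Nvar -> R` over a box. Each candidate ("lion") carries a
position, its fitness, and its personal best. The population splits
into `P` prides (sub-populations with an elitist *territory*, the set
of members' personal bests) and a nomad pool.

Per iteration, in a fixed order:

1. **Hunting.** A fraction of each pride's females encircles a dummy
   prey placed at the hunters' centroid. Hunters are split at random
   into left/center/right wings; a wing hunter jumps elementwise
   uniformly between the opposite position `2*PREY - Hunter` and
   `PREY`, a center hunter between `Hunter` and `PREY`. When an attack
   improves the hunter's fitness, the prey flees:
   `PREY' = PREY + u * PI * (PREY - Hunter)` with `u ~ U(0,1)` and `PI`
   the fractional improvement `(f_old - f_new)/max(|f_old|, 1e-12)`
   clamped to `[0,1]` (the clamp and the `f_old = 0` guard are ours;
   only "percentage of improvement" is prescribed).
2. **Safe-place moves.** Each non-hunting female picks a territory
   point by tournament — `T = max(2, ceil(K/2))` entries, `K` the count
   of pride members whose personal best improved last iteration — and
   moves `new = old + 2*D*u*R1 + U(-1,1)*tan(theta)*D*R2`, where `D` is
   the distance to the point, `R1` the unit direction toward it, `R2` a
   random unit vector orthogonal to `R1` and `theta ~ U(-pi/2, pi/2)`.
   `D = 0` leaves the female in place; in one dimension `R2` is zero.
3. **Roaming.** Each resident male visits `ceil(%R * |territory|)`
   random territory points, stepping `x ~ U(0, 2d)` toward each
   (`d` = current distance) with an angular jitter
   `theta ~ U(-pi/6, pi/6)` toward a random orthogonal direction, so
   the local search is not purely collinear. The jitter half-width is a
   configuration field and can be set to 0.
4. **Mating.** `%Ma` of each pride's females breed with a random
   nonempty subset of the pride's males (each male included with
   probability 1/2); nomad females breed with exactly one random nomad
   male. The two cubs are the linear combinations
   `beta*F + (1-beta)*mean(selected males)` and the `beta <-> 1-beta`
   mirror, `beta ~ N(0.5, 0.1)`. One randomly chosen cub has each gene
   replaced by a fresh uniform in-bounds draw with probability `%Mu`.
   Cubs get one gender each and join the mother's group.
5. **Defense.** Pride males are ranked by fitness; the best up to the
   pride's male quota stay, the rest become nomads. Each nomad male
   then challenges each pride with probability 1/2 and swaps roles with
   the weakest resident male if fitter. Fights are reduced to fitness
   comparison — fitness is the only strength measure available.
6. **Migration.** From each pride, surplus females beyond quota plus
   `round(%I * quota)` random females become nomads; vacancies are then
   refilled by the fittest nomad females.
7. **Equilibrium.** The worst nomads of each gender are culled back to
   the per-gender maxima fixed at initialization, returning the census
   exactly to `Npop`.

**Defaults** follow the tuning of the original pest study:
`Npop = 500`, nomad share 0.2, 5 prides, female share 0.8 per pride
(0.2 among nomads), roaming fraction 0.2, mating fraction 0.3, mutation
rate 0.2, immigration fraction 0.4. The hunting share per iteration is
not specified anywhere; we use 0.5, with the remaining females doing
the safe-place move. Stopping is `max_iterations` or `patience`
iterations without global-best improvement (default 20); wall-clock
stopping is deliberately not offered (non-deterministic).

**Quotas and the census.** Each pride's female quota is its initial
female count `round(%S * pride size)` and its male quota the
complement, so the per-pride quotas sum to the pride size and the
census returns exactly to `Npop` after equilibrium on every iteration.
(A `ceil((1-%S) * size)` male quota differs from the complement only at
rare rounding edges and would let the census drift.)

**Determinism.** A run owns a single seeded generator; operators draw
from it in the order listed above, prides in index order, lions in id
order, and all rank ties break by lion id. Two runs with identical
configuration and seed produce bit-identical traces.

## Wrapper feature selection

`loa_select` searches `[0,1]^d`; a position decodes to the mask of
coordinates strictly above 0.5 (an all-zero decode falls back to the
argmax coordinate). The fitness of a mask is the stratified 5-fold
cross-validation error of a wrapped classifier on the masked features,
plus an optional sparsity term `lambda * selected/d` with
`lambda = 0` by default. Fold assignment is fixed per run, making the
fitness a pure function of the mask; repeated masks are memoized, which
cuts the evaluation count severalfold.

A practical caveat the benchmarks exposed: when the class structure is
strongly separable, many masks reach *exactly* zero cross-validation
error and the accuracy-based fitness loses its gradient — the search
then keeps the first perfect mask it finds rather than the most
parsimonious or most complete one. For this reason the recovery
benchmarks wrap a k-nearest-neighbor classifier (k = 5, Manhattan
metric), the classical wrapper-selection evaluator, whose accuracy
degrades measurably with irrelevant dimensions; a regularized linear
model saturates at zero error far earlier. With `lambda > 0` the
selector additionally prefers smaller masks among equally accurate
ones.

## Classical reducers

- **PCA** diagonalizes the *population* covariance
  `sigma_jk = (1/n) * sum_i (x_j - mu_j)(x_k - mu_k)` — the `1/n`
  normalization, not the `1/(n-1)` sample version — and projects
  centered data onto the top-k eigenvectors.
- **LDA** follows the textbook five steps: class means, within- and
  between-class scatter, eigen-decomposition of `Sw^-1 Sb`, sort by
  eigenvalue, project `Y = X W`. `Sw` is ridge-regularized by
  `1e-6 * trace(Sw)/d` since deep-feature tables have `d >> n` and a
  singular scatter. Binary problems yield one informative direction.
- **RFE** removes one lowest-importance feature per round under a
  wrapped estimator (squared coefficients for linear models),
  delegating the loop to scikit-learn's implementation behind the same
  mask interface.

## Classifiers, metrics, protocol

The seven-learner bank (SVM, logistic regression, decision tree, KNN,
random forest, gradient-boosted trees, Gaussian naive Bayes) delegates
to scikit-learn/XGBoost with fixed seeds; KNN uses the Manhattan
metric. No study hyperparameters were reported, so the wrapped
learners' published defaults stand, all overridable per spec.

Metrics are computed from confusion counts with "pest present" as the
positive class, on a 0-100 scale: `A = (TP+TN)/total`,
`P = TP/(TP+FP)`, `R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`. Zero
denominators yield 0 with a warning rather than an error so that grid
reports never abort. The protocol offers a stratified 80/20 holdout
and stratified 5-fold cross-validation; cross-validation runs on the
full table by default (the overfitting-check reading), configurable.

## Preprocessing

Gaussian (kernel sampled from
`G(x) = exp(-x^2/(2 sigma^2))/(2 pi sigma^2)` on integer offsets,
renormalized to sum 1, applied separably), average and median filters,
all with reflective borders (an unstated choice; reflection avoids
dark halos that would perturb downstream features) and the odd
kernel-size schedule `a = 2A - 1`. Augmentation applies up to seven
operators: horizontal/vertical flip, rotation (default 15 degrees),
shear (0.1), a fixed 20 % contrast increase about the channel mean,
reflection (a vertical-axis mirror, hence a duplicate of the
horizontal flip — kept so the operator count matches the seven-step
expansion), and brightness (+25). Rotation/shear magnitudes and the
brightness delta are unstated upstream; the defaults are configurable.
All outputs are clipped to `[0, 255]` and preserve shape.

## Deep features and the mock backbone

Real convolutional backbones are optional plug-ins behind
`BackboneSpec`; requesting one without its framework raises an error
naming the extra. Their published pooled widths are exposed (VGG16/19:
4096; ResNet50, InceptionV3, Xception: 2048 — ResNet50's width follows
the published architecture). The `mock` backbone resizes to
224 x 224 x 3, standardizes each channel, pools per-patch mean,
standard deviation and 5th-percentile over an 8 x 8 grid, and applies
a fixed seeded random projection with a tanh squashing. It is a pure
function of the pixels and its internal seed — bit-reproducible and
batch-independent — and keeps dark localized structure (pest bodies)
linearly decodable. It is *not* a stand-in for pretrained
representations of real photographs; results on the toy images
validate the plumbing and the selector/classifier contracts, not
field-level accuracy.

## Synthetic data

`generate_feature_table` draws class-conditional Gaussians: both
classes `N(0, sd)` on noise dimensions, class 1 shifted by
`separation * sd` on a known informative subset. Gaussian structure is
the simplest under which wrapper selection is provably solvable, so
recovery thresholds are interpretable. `generate_toy_images` renders
bright textured backgrounds with an illumination gradient, plus 1-3
dark elliptical blobs with jittered pose for the pest class, at
64 x 64 by default so the full image-to-report path runs in seconds.
Benchmark objectives (sphere, Rastrigin, Rosenbrock) come with their
known minima and standard boxes.

## Benchmark sizes

The optimizer convergence check uses the 5-D sphere with population
50 and 200 iterations over 10 seeds, against a random-search baseline
given the optimizer's own evaluation count. Wrapper recovery uses
200 samples/class, 50 features, 10 informative at separation 2 SD,
with population 36 and 18 iterations (memoized fitness; roughly 900
distinct mask evaluations). The end-to-end pipeline check uses 20 toy
images/class. These sizes were chosen so the whole battery runs on a
laptop in under a minute; the library defaults remain the full-scale
tuning above.

## Known limitations

- The optimizer handles box constraints only, one objective at a time,
  serially; maximization is the caller's negation.
- Wrapper fitness plateaus at zero error on strongly separable data
  (see above); recovery counts then depend on the search trajectory,
  and ranged 7-10 of 10 across seeds under the benchmark conditions.
- The mating, defense and migration operators assume at least one male
  quota per pride; degenerate configurations (single-lion prides) are
  valid but reduce several operators to no-ops.
- Real-backbone extraction, feature fusion across backbones, and any
  CNN training are out of scope.
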
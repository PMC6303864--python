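# Methods

## Model and procedure

`gwpnet` fits a fully connected feed-forward regression network to one-hot
encoded SNP dosages.  An architecture is an ordered list of layer widths
ending in 1, with one activation (`linear`, `tanh` or `relu`) applied at
every layer; the one-layer, one-unit, linear configuration is exactly a
multiple regression `y_hat = Xw + b` and is the only configuration whose
weights are interpreted genetically.  Deeper variants ((2,1), (3,2,1)) are
supported for prediction comparisons only.

Training minimizes the half mean squared error `(1/2n) sum (y - y_hat)^2`
with one of three optimizers: full-batch gradient descent, single-sample
SGD, or mini-batch Adam.  Two l2-regularization routes exist and are **not**
interchangeable:

* **coupled** — `lambda1 ||W1||^2 + lambda2 ||W_deep||^2 + lambda3 ||b||^2`
  added to the cost and differentiated in backprop; used with plain GD,
  where the linear one-unit fit has the closed ridge form
  `(X'X + 2n*lambda1 I)^{-1} X'y` (the `2n` reflects the `1/(2n)` loss
  normalization);
* **decoupled** — each Adam update multiplies the parameter group by
  `(1 - lr*lambda_g/b)` before the moment step.  This is the canonical
  path.  Per-group coefficients: `lambda1` for input-layer weights,
  `lambda2` (default: equal to `lambda1`) for deeper weights, `lambda3`
  (default 0) for biases, so the intercept freely absorbs the phenotype mean.

The approximate-posterior chain runs T iterations.  Each iteration samples
Bernoulli dropout masks (retention `p1` on input features, `p2` on each
hidden layer's outputs; biases never masked), holds them fixed through one
optimization pass over the shuffled training data (warm-starting from the
current parameters — a single continuing chain, not T restarts), then
records the masked-and-rescaled parameter snapshot, its test predictions,
and their MSE/MAE.  Masking is implemented by row-scaling the weight
matrices with `z/p` (inverted dropout), which is elementwise-identical to
masking the layer inputs but cheaper.  After discarding a burn-in prefix
`t_s`, the summary reports elementwise snapshot means and variances (the
variance uses the `1/(T - t_s)` normalization, i.e. the biased sample
variance), the model-averaged `MSE_M` (the arithmetic mean of the retained
per-iteration MSEs), its SD over retained iterations, the analogous MAE, and
the mean prediction with its own MSE.  By construction
`MSE_M >= MSE(mean prediction)` (Jensen); the gap is the per-draw mask
noise and is itself informative about posterior spread.

## Effect extraction and its calibration

For the linear one-unit model the three first-layer weights of marker j
attach to its Hom0/Het1/Hom2 indicators, giving

    a_j = -E[w_Hom0] + E[w_Hom2],      d_j = E[w_Het1],

with posterior variances `var_a = var(w_Hom0) + var(w_Hom2)` and
`var_d = var(w_Het1)` (weight covariances are not tracked).  Requesting
effects from a deeper or nonlinear model raises an error: those weights mix
through subsequent layers and do not map to per-marker effects.

These are *regularized* estimates and their calibration follows from the
dropout itself.  With inverted dropout at retention p, the expected masked
loss adds a penalty `((1-p)/p) * f_c * w_c^2` per indicator column (`f_c` =
column frequency), whose optimum for a marker with genotype-class
contributions `(c_0, c_1, c_2)` is `w_g = p (c_g - cbar)`, with `cbar` the
frequency-weighted class mean absorbed by the intercept.  Consequences at
the default `p = 0.5`:

* the additive estimator is **exactly calibrated**:
  `a_hat -> (c_2 - c_0)/2`, the textbook additive effect, regardless of
  allele frequency (at n=2000 with LD r^2 ~ 0.1, replicate medians land
  ~0.2-0.4 below the generating value from linkage leakage);
* the dominance estimator is **attenuated and frequency-dependent**:
  `d_hat -> (c_1 - cbar)/2`, at most half the heterozygote deviation and
  shrinking further as the locus becomes common.  A full-dominance locus
  with class values (0, 5, 5.01) therefore reads d_hat of roughly 0.5-2
  rather than its classical deviation 2.495.  Dominance-class loci are
  still *detected* — they dominate the |d| ranking — but their magnitudes
  must not be read as unbiased effect sizes.  Shrinkage is deliberately not
  undone.

The acceptance suite asserts the recovery bands on replicate medians; the
dominance-magnitude band fails for the reason above and is retained as a
documented, expected failure rather than loosened.

## Regularization for prediction

Decoupled decay acts per optimizer step, so its effective total shrinkage
scales like `exp(-lr * lambda * n_steps / b)`: a decay value tuned for one
sample size, batch size and chain length does not transfer to another.  The
intended workflow (followed by `tune_weight_decay`) is to scan a broad
decade grid (0.1 ... 1000) on a calibration dataset, select by model-averaged
test MSE, and only then evaluate.  At the default simulated scale (n=2000,
train 1600, b=128, T~1000-2000) the grid typically selects lambda1 ~ 100,
where the tuned chain beats the mean predictor in 20/20 replicates.  The
near-zero decay used for effect extraction is the opposite regime: it keeps
the causal-weight shrinkage negligible at the price of noisier prediction
draws.

## Synthetic data

The simulator provides desk-scale datasets with known truth.  Haplotypes are
drawn from a Gaussian-copula Markov process: a latent AR(1) series
(coefficient `rho`, default 0.59) thresholded at each marker's allele
frequency (drawn uniformly on 0.05-0.95), two independent haplotypes summing
to the dosage.  The default `rho` was calibrated by simulation so the mean
adjacent-marker r^2 among common markers is ~0.10, a realistic SNP-panel
value; `calibrate_rho` re-runs that bisection for other targets.  Genotypes
are exactly Hardy-Weinberg by construction.

The trait combines QTL classes with fixed conventions: controlled additive
loci (effect +3, defined as half the homozygote-mean difference, contribution
`a*(g-1)`, placed at highly polymorphic markers), random additive loci
(N(0, 10) truncated by rejection to |a| < 2), additive-by-additive epistatic
pairs among controlled loci (+4 when both members are homozygous for the
lower allele; a per-locus variant is available), and dominance /
over-dominance / under-dominance loci with class values (0, 5, 5.01),
(-0.01, 5, 0.01) and (-0.01, -5, 0.01).  Gaussian residuals are scaled to a
target heritability (default 0.4; realized h2 is recorded and lands within
~0.01 at n=2000).  Samples carry a generation-like group label (five equal
groups; the last is the holdout test set).

What the simulator does **not** emulate: pedigree structure and family
relatedness, coalescent allele-frequency spectra, long-range LD, selection,
imprinting, or genotyping error.  Passing recovery tests therefore show the
estimator works on unrelated individuals with short-range LD — they do not
certify behavior under strong population or family structure.

## Numerical choices

* Weight init uniform on +-1/sqrt(fan_in), biases zero, all from the run's
  seeded generator; every source of randomness (simulation, masks, batch
  shuffles, splits) flows from explicit seeds and reruns are bitwise equal.
* Batches are sampled without replacement and reshuffled per epoch; a ragged
  final batch uses the configured batch size in the decay factor so the
  per-step shrinkage rate is constant.  `batch_size > n` is clamped to n.
* relu derivative at exactly 0 is taken as 0; gradient tests avoid kinks.
* `adam_step` rejects `lr*lambda/b >= 1` (sign-flipping decay).
* Missing dosages impute to the rounded per-marker mean (counts logged,
  >10% missingness per marker warns); any non-0/1/2 token is an error naming
  the offending cell.
* MAF = min(f, 1-f) with f = mean(dosage)/2; the filter keeps MAF >= threshold
  and errors if nothing survives.
* Effect ranking sorts by |effect| with a stable sort, so ties keep marker
  order.
* The plateau helper flags the first iteration whose trailing-window mean
  changes by less than a tolerance; it is advisory — burn-in is a config
  parameter (defaults 6000 iterations / 1000 burn-in in the CLI) and should
  be confirmed on the trace plot.
* Chains abort with the partial trace attached if the loss goes nonfinite.

## Problem sizes used by the test suite and acceptance script

Unit tests run on toy instances (n <= 100).  The study-scale checks use
n = 2000 individuals, 500 markers, h2 = 0.4, chains of 1200-2000 iterations
with burn-in 400-500, and 20 seeded replicates per scenario; the acceptance
script runs two such 20-replicate batches (~8 minutes on one CPU).  These
sizes are the package's chosen desk-scale study conditions; estimates at the
causal markers are aggregated as replicate medians.

## Known limitations

* Dominance magnitudes are attenuated estimates (see calibration above).
* The GBLUP baseline is a deterministic kernel ridge with inner-CV shrinkage,
  not a Bayesian mixed model; treat cross-method comparisons as approximate.
* No learning-rate schedules, momentum-SGD, l1 penalties, convolutional or
  recurrent layers; classification losses are out of scope.
* Genotype files are read fully into memory; the tool targets panels up to
  ~10^4-10^5 markers, not sequence-scale data.
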
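# Methods

## Problem and model

`nncopula` generates synthetic dichotomous item-response matrices that can
stand in for a real assessment dataset in psychometric work: the synthetic
data should reproduce the real data's item difficulty hierarchy, inter-item
dependence, 2PL parameter estimates, test information profile, and the
sampling variability of those estimates — without containing any real
examinee's record.

The generative model is a copula construction for binary margins:

1. **Randomized probability integral transform.** A binary response has no
   unique copula representation, so each cell `Y_ik` is spread uniformly over
   the sub-interval of (0, 1) its outcome occupies under the item's marginal
   probability `p_k`: `U ~ Uniform(1 - p_k, 1)` if `Y = 1`, else
   `U ~ Uniform(0, 1 - p_k)`. Marginally `U` is exactly Uniform(0, 1); rank
   dependence between items is preserved. `p_k` is always the
   training-partition proportion, reused for validation-row transforms and
   for generation thresholds. The pseudo-uniform matrix is drawn once per
   fit (a fixed draw keeps the training objective stationary); the intervals
   exclude their endpoints by one machine epsilon so the inverse threshold
   (strict `U > 1 - p_k`) inverts every cell exactly.

2. **Autoencoder dependence model.** An encoder
   `K -> 256 -> 128 -> 64 -> d` (affine, batch norm, ReLU, dropout 0.2 per
   hidden block; linear final layer so the latent space spans R^d) and a
   mirrored decoder `d -> 64 -> 128 -> 256 -> K` (affine, batch norm, ReLU;
   sigmoid output so reconstructions stay in (0, 1)). The loss is
   `L = L_recon + lambda * L_marginal` with `L_recon` the mean squared cell
   error and `L_marginal` the mean squared deviation of reconstructed column
   means from 0.5 (the Uniform(0,1) expectation), `lambda = 0.1`. Training:
   Adam at 1e-3, mini-batches of 64 reshuffled each epoch from the run seed,
   learning rate halved after 10 epochs without validation improvement
   (improvement = decrease of the best validation loss by more than 1e-6),
   early stopping after 20 such epochs with best-epoch weight restoration,
   cap 500 epochs.

3. **Latent density and generation.** Training latent codes are modelled by
   a Gaussian-kernel density with a single scalar bandwidth `h` in raw
   latent coordinates (default `h = 0.2`, latent dimension default
   `d = 20`). Generation samples codes exactly from that mixture (uniform
   code choice plus `h`·normal noise), decodes them in evaluation mode, and
   thresholds at `1 - p_k`. The threshold guarantees `E[Y_syn] = p_k`
   whenever the decoded column is uniform; decoder-induced deviation from
   uniformity is measured by the validation suite rather than corrected.

## Design choices that were genuinely open

* **Dropout placement.** Regularising both stacks with dropout 0.2 makes
  the decoder shrink decoded values toward their column means, which
  distorts the thresholded marginals and flattens inter-item dependence
  (on our simulated benchmark study: marginal MAD 0.036 and correlation
  RMSR 0.092, versus 0.010 and 0.022 with the adopted design). Dropout is
  therefore applied in the encoder only; batch normalisation stays in both
  stacks. The encoder is where over-memorisation of individual response
  patterns must be prevented; the decoder is the generative map and needs
  full capacity.
* **Batch-norm ordering** is affine → normalisation → ReLU; evaluation mode
  uses running statistics (momentum 0.1), so encoding/decoding is
  deterministic and batch-size independent.
* **Weight initialisation** is variance-scaled normal (He) for the
  rectified layers, drawn from the seeded run generator; the whole fit is
  bitwise reproducible given (data, config, seed).
* **Seed management.** Child seeds are spawned from a master seed with
  `numpy.random.SeedSequence`, a counter-based scheme that is stable across
  platforms; replication r of a Monte Carlo run always receives the same
  child seed.
* **Bandwidth reference.** The Silverman rule-of-thumb
  `(4/(d+2))^(1/(d+4)) n^(-1/(d+4)) * mean per-dimension SD` is computed and
  reported for context only; the operating bandwidth is the configured one.
* **Stratified partitioning** computes score deciles on the pooled sample
  before splitting; boundary ties go to the lower stratum; rows are
  apportioned by largest remainder within each decile (counts match the
  fractions to ±1). Strata smaller than the number of subsets degrade to a
  simple random split with a log message.

## 2PL estimation

The psychometric reference model is the two-parameter logistic IRT model,
estimated by marginal maximum likelihood with an EM algorithm. The latent
ability is integrated against a fixed N(0, 1) prior using 61 Gauss–Hermite
nodes (61 makes EAP scores agree with a 10,001-point dense-grid integration
to better than 1e-5; 41 nodes leave ~3e-4 errors). The E-step computes
posterior node weights per examinee; the M-step runs damped per-item Newton
updates in the slope/intercept parametrisation (better conditioned than
(a, b)). Convergence: max absolute parameter change below 1e-4, cap 500
cycles; the marginal log-likelihood is monotone non-decreasing across
cycles. Starting values: `a = 1`, `b = -logit(p_k)`.

Asymptotic standard errors use the per-item 2×2 expected Fisher information
with empirical posterior weighting,
`I(a_k, b_k) = sum_q n_q P(1-P) [[(t_q-b)^2, -a(t_q-b)], [., a^2]]`,
ignoring cross-item covariance (block-diagonal). Infit/Outfit mean squares
use plug-in probabilities at the EAP abilities, with probabilities clamped
to [1e-10, 1 - 1e-10] for the residuals. Note that plug-in EAP residuals
make both statistics sit below 1 even for perfectly model-consistent data
— at K = 20 with discriminations near 3, infit around 0.86–0.90 is the
expected value, not misfit; the acceptable band used for flagging is
[0.7, 1.3], with values below 0.5 flagged as severe under-dispersion.

## Validation facets

* **Data level:** total-score moments (SD with n−1; population-moment
  skewness and excess kurtosis), per-item marginal MAD / relative error /
  Pearson r with percentile bootstrap 95% CIs (1000 row resamples, seeded),
  and the RMSR over the K(K−1)/2 inter-item correlation pairs.
* **Psychometric:** MAD, RMSD (MAD ≤ RMSD by Jensen, asserted) and Pearson r
  separately for a and b; correlations of the test-information and CSEM
  profiles on a 100-point grid over [−4, 4]; Infit/Outfit comparison.
* **Precision:** Monte Carlo SE = sample SD (ddof 1) of each parameter across
  M regenerated-and-refit datasets, compared with the asymptotic SEs of the
  reference fit. The headline ratio is the ratio of the item-averaged MCSE
  to the item-averaged ASE (per-item ratios are also reported). Values near
  1 mean the synthetic data reproduce real sampling variability; above 1,
  conservative; below 1, over-smoothed. Non-convergent replications are
  excluded and counted; >10% exclusions flag the report.
* **Stability:** the full pipeline retrains under independent seeds; the
  mean and SD (n−1) of r_a, r_b and marginal MAD across seeds summarise
  sensitivity to initialisation.
* **Sensitivity:** a driver evaluates latent dimensions d ∈ {10, 20, 30, 50}
  and bandwidths h ∈ {0.1, 0.2, 0.3, 0.5}, averaging the four headline
  metrics over M replications per configuration. One model is trained per d;
  the bandwidth axis reuses the default-d model since h only affects latent
  sampling.

## Synthetic-data generator (test harness)

Because operational assessment data cannot be redistributed, every test
input is simulated from the unidimensional 2PL: abilities `theta ~ N(0,1)`,
responses Bernoulli with `P = logistic(a_k (theta - b_k))`. The default item
bank draws `a ~ log-normal(0, 0.5^2)` truncated to [0.5, 3.5] and
`b ~ N(0,1)` truncated to [−2.5, 2.5]; the end-to-end benchmark study
instead uses the bundled published 20-item parameter estimates as ground
truth (discriminations 0.85–3.03, difficulties −1.24–0.93) with n = 5069
examinees partitioned 64/16/20 by score decile, matching the published
study's scale. An optional testlet device adds a shared examinee-cluster
effect `gamma * u_ic` to the ability, inducing within-cluster local
dependence (`gamma = 0` recovers local independence); this is a harness
extension for exercising the dependence machinery, not part of the
benchmark conditions.

What the simulator does *not* emulate: real response processes with
guessing, speededness, differential item functioning, multidimensionality,
or missingness. Passing tests therefore demonstrate that the pipeline
reproduces 2PL-consistent structure at realistic scale, not that it handles
arbitrary operational data.

## Problem sizes used in the checks

The end-to-end checks train once on the simulated benchmark study
(n_train ≈ 3244, K = 20, ≈200 epochs), run the precision facet at M = 100
replications of n_train rows each, and the stability facet over 3 seeds on
a shortened (60-epoch) schedule. These sizes reproduce the published
fidelity regime while keeping a full run in the minutes range on one CPU.

## Known limitations

* High-discrimination items are amplified: dense latent clusters of
  near-deterministic response patterns are over-sampled by the
  fixed-bandwidth KDE, inflating synthetic discriminations and pushing
  Outfit below 0.5 for the steepest items. Adaptive bandwidths would be the
  natural remedy; not implemented.
* Fixed-bandwidth KDE under-represents the extreme total scores (boundary
  bias), visible as slight under-coverage of perfect scores.
* Binary responses and a unidimensional 2PL reference model only; no
  polytomous, multidimensional or guessing extensions.
* The marginal guarantee `E[Y_syn] = p_k` is exact only when decoded
  pseudo-uniform columns are exactly uniform; residual decoder distortion
  shows up in the marginal MAD metric.
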
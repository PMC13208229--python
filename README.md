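# nncopula

Synthetic dichotomous item-response data that preserves psychometric
properties, generated by a **neural-network copula**, with a complete
**2PL item-response-theory validation framework**.

## Who this is for

Psychometricians and measurement researchers who need to share, benchmark or
re-analyse binary assessment data (examinees × items, 0/1) that cannot be
released: the package learns a generative model of a response matrix and
emits synthetic matrices whose item difficulties, inter-item dependence,
2PL parameter estimates, information functions and sampling variability
match the source — then *quantifies* that match with a four-facet
validation suite.

## The model

Responses `Y ∈ {0,1}^{n×K}` are lifted into copula space by a randomized
probability integral transform with the training marginals `p̂_k`:

    U_ik ~ Uniform(1 − p̂_k, 1)  if Y_ik = 1,
    U_ik ~ Uniform(0, 1 − p̂_k)  if Y_ik = 0,

so each column is exactly Uniform(0,1) while inter-item rank dependence is
preserved. A deep autoencoder (encoder `K→256→128→64→d`, mirrored decoder
ending in a sigmoid) learns the dependence structure by minimising

    L(Θ) = (1/nK) Σ (U_ik − Û_ik)² + λ · (1/K) Σ_k (mean_i Û_ik − 0.5)²,

the second term preventing marginal collapse (λ = 0.1). New examinees are
sampled from a Gaussian-kernel density over the training latent codes
(bandwidth h = 0.2 by default), decoded, and thresholded:

    Y_syn = 1{ U_syn > 1 − p̂_k },

which pins the synthetic marginals to the training data by construction.

Validation runs against the two-parameter logistic IRT model
`P(Y=1|θ) = 1/(1+exp(−a(θ−b)))`, estimated by marginal maximum likelihood
(EM with Gauss–Hermite quadrature, N(0,1) ability prior), with EAP ability
scores, Fisher-information standard errors, test information / CSEM
profiles and Infit/Outfit statistics.

## Worked example

```python
from nncopula import (NeuralCopula, RunConfig, SimulationDesign, TwoPL,
                      simulate_2pl, stratified_partition)
from nncopula.validation import (marginal_facet, dependence_facet,
                                 psychometric_facet)

# simulate a 20-item assessment with known 2PL ground truth
Y, truth, theta = simulate_2pl(SimulationDesign(n=5069, K=20, seed=7))
Y_train, Y_val, Y_test = stratified_partition(Y, (0.64, 0.16, 0.20), seed=1)

# fit the generator and produce one synthetic dataset
results = NeuralCopula(Y_train, Y_val, RunConfig()).fit(seed=42)
print(results.summary())
synth = results.generate(len(Y_train), seed=42)

# four-facet style validation against the training partition
fit_real, fit_syn = TwoPL(Y_train).fit(), TwoPL(synth).fit()
marg = marginal_facet(Y_train.to_numpy(), synth.to_numpy(), seed=0)
psych = psychometric_facet(fit_real.params, fit_syn.params)
```

Output:

```
Neural copula generator
items: 20   latent dim: 20   KDE bandwidth: 0.2 (Silverman ref 1.0074)
epochs run: 207   best epoch: 186   best val loss: 0.005736
final learning rate: 3.13e-05   fit seed: 42
marginal MAD          0.017
dependence RMSR       0.021
r (difficulty b)      0.987
r (discrimination a)  0.962
TIF correlation       0.999
```

Reading the numbers: the synthetic item proportions differ from the real
ones by 0.017 on average (marginal MAD); the root-mean-square discrepancy
between the two inter-item correlation matrices is 0.021 (values below 0.05
indicate good dependence fit); difficulty and discrimination estimates from
the synthetic data correlate 0.987 / 0.962 with the real-data estimates;
and the test information profiles are nearly indistinguishable (r = 0.999).

## Command line

A thin CLI wraps the library:

```sh
nncopula simulate --n 5069 --k 20 --seed 7 --out matrix.csv --truth truth.json
nncopula train --in train.csv --val val.csv --out model.npz
nncopula generate --model model.npz --n 3244 --seed 42 --out synth.csv
nncopula fit-irt --in synth.csv --out params.json
nncopula validate --real train.csv --synth synth.csv --out report.json
nncopula stability --in matrix.csv --out stability.csv
nncopula sensitivity --in matrix.csv --reps 50 --out sensitivity.csv
```

## Layout

- `src/nncopula/` — library (`model`, `network`, `copula`, `kde`,
  `estimation`, `irt`, `simulate`, `validation`, `io`, `config`,
  `datasets`, `cli`)
- `docs/methods.md` — model, assumptions, numerical choices, limitations
- `tests/` — unit, property and end-to-end acceptance tests
- `scripts/acceptance.py` — headline-quantity recomputation
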
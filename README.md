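# glmmscore

Bayesian model evaluation for longitudinal count GLMMs.

When a clinical trial's primary endpoint is a repeatedly measured count
— attacks per month, seizures per quarter, exacerbations per season —
the statistical analysis plan must commit in advance to a mixed-model
family.  `glmmscore` is a toolbox for making that choice an *informed*
one from pilot or pre-study data: it fits a menu of rival generalized
linear mixed models and ranks them by leave-one-out predictive
performance, so the model written into the plan is the one that best
forecasts the data-generating process rather than the conventional
default.

## Models and criteria

Every candidate shares the linear predictor

```
eta_ij = (beta0 + b0_i) + (beta1 + b1_i) t_ij + beta2 x_i + beta3 x_i t_ij
```

with subject-level random intercepts (structure `I`) or correlated
intercepts and slopes (`IS`, Wishart hyperprior on the precision
matrix), and conditional families Poisson, negative binomial
(mean mu, variance mu + mu^2/k), zero-inflated Poisson/NB, or a normal
mixed model for the variance-stabilizing arcsinh transform of the
counts.  Fits come from an adaptive Metropolis-within-Gibbs sampler
that retains the per-draw per-observation log-likelihood matrix.

Model criticism is prediction-oriented:

* **CPO / logarithmic score** — the leave-one-out predictive density at
  each observation, CPO_ij = f(y_ij | y_-ij), estimated from a single
  full-data fit by the "ghost" mixed estimator (subject effect
  integrated by quadrature per draw, Pareto-smoothed importance
  combination across draws), with an exact-refit fallback for flagged
  observations.  Models are ranked by the mean of LS_ij = -log CPO_ij;
  the arcsinh model's mean score is back-calculated to the count scale
  so all candidates are comparable.
* **DIC** — D-bar + p_D at observation-level likelihood focus.
* **Adjusted PIT** — leave-one-out calibration histograms for count
  predictives (uniform under a correctly specified model).
* **Paired permutation tests** — sign-flip Monte Carlo tests (9999
  permutations) of mean-score differences against the best model.
* **AUC discrimination** — a simulation study measuring how reliably
  the mean log score separates each wrong model from the true one
  across replicate datasets.

See `docs/methods.md` for the full model, prior and estimator account.

## Worked example

The repository is organized as an analysis project; the numbered
scripts under `analysis/` run the two studies end to end and write
their tables under `results/`.

```
python analysis/01_simulate_trial_data.py --seed 1
python analysis/02_case_study.py --seed 1
```

The first script generates a vertigo-trial-like dataset (112 subjects
in dose groups of 50 and 62, five visits at months 0–12, Poisson counts
with correlated subject intercepts and slopes) and prints its
structure:

```
wrote results/vertigo_like_trial.csv: 112 subjects, 560 rows
zero counts: 37.5%
group 0: mean attacks per visit  6.8 -> 3.9 -> 3.0 -> 3.0 -> 2.7
group 1: mean attacks per visit  6.6 -> 2.4 -> 0.6 -> 0.4 -> 0.2
```

The second fits the eight-model menu (four families x {I, IS}) and
ranks it:

```
      model    D_bar    D_hat     p_D      DIC  mean_LS p_vs_best
Poisson(IS) 1518.814 1362.509 156.305 1675.119    1.537      ref.
    ZIP(IS) 1522.165 1366.394 155.771 1677.936    1.540    0.0002
     NB(IS) 1534.734 1375.106 159.628 1694.361    1.542    0.0002
      NB(I) 1775.759 1683.417  92.342 1868.101    1.670    0.0002
arcsinh(IS)  971.652  787.050 184.602 1156.253    1.808      n.a.
 arcsinh(I) 1109.358 1017.631  91.727 1201.085    1.826      n.a.
     ZIP(I) 1851.648 1756.079  95.569 1947.218    1.838    0.0002
 Poisson(I) 1852.104 1757.452  94.652 1946.755    1.844    0.0002
```

Reading the table: the data were generated from a Poisson process with
heterogeneous subject slopes, and the workflow recovers exactly that —
`Poisson(IS)` attains the lowest mean log score, every intercept-only
model scores significantly worse (the effective parameter count p_D
jumps from ~93 to ~156 when subject slopes enter), there is no support
for zero-inflation or extra overdispersion, and the arcsinh rows show
"n.a." because observation-level scores on a transformed outcome cannot
be permutation-tested against count-scale scores (their DIC is likewise
not comparable; only the back-calculated mean score is).  The fitted
fixed effects for the winning model (posterior mean, 95% interval)
are intercept 1.63 [1.46, 1.79], time -0.18 [-0.24, -0.13] and
dose-by-time -0.22 [-0.30, -0.15].

The third script runs the discriminatory-power simulation over a
configurable (k, n) grid:

```
python analysis/03_simulation_study.py --seed 1 --r 30 --k 0.5,50 --n 20,100
```

writing an AUC matrix (rows k x wrong model, columns n) where values
near 1 mean the mean log score reliably rejects that misspecification
and values near 0.5 mean the wrong model predicts as well as the truth.

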
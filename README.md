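# prognomod

Combined clinical + genomic prognostic modelling for breast-cancer
expression cohorts.

Node-negative breast-cancer patients face an adjuvant-therapy decision that
hinges on prognosis. Dozens of gene-expression signatures claim prognostic
value; this package implements the analysis pattern that evaluates them
*jointly*: summarise each signature as a per-sample **module score**,
combine the scores with classical clinical variables (ER, HER2, tumor size,
grade), fit sparse multivariate survival models, and ask — over repeated
train/test resampling — which variables keep getting selected and whether
the combined model predicts held-out outcomes better than clinical or
genomic variables alone. A parallel design predicts pathological complete
response (pCR) to neoadjuvant chemotherapy with penalized logistic models.

## The model

For samples with relapse-free survival time `T` (administratively censored
at 7 years) and covariates `x` — module scores plus encoded clinical
variables, standardized — the hazard is Cox proportional:

    h(t | x) = h0(t) · exp(βᵀx)

with β estimated by LASSO (L1-penalized partial likelihood),

    β̂ = argmax  ℓ_partial(β) − λ‖β‖₁ ,

λ chosen by seeded 10-fold cross-validated partial-likelihood deviance.
The **risk score** of a patient is `βᵀ(x − x̄_train)`, the log hazard ratio
relative to the training-average patient; the threshold 0 splits high- from
low-risk groups. A model counts as a **success** only when its Cox p-value
is below 0.05 on *both* the training and the testing set. Repeating the
stratified 2/3–1/3 split build N times yields per-variable **selection
frequencies** among successful models, per-family mean test-set
**Harrell's C-index**, and a pairwise **superiority matrix** (how often one
family's C-index beats another's). pCR prediction swaps the Cox likelihood
for a logistic one and the C-index for ROC AUC.

Supporting machinery: four module-scoring routes (median,
first-principal-component, centroid correlation, published linear models),
Distance Weighted Discrimination (DWD) batch integration, a HER2 mRNA
surrogate (top-20% expressers positive), nearest-centroid intrinsic-subtype
assignment, clinical subgroup analyses (ER+, Luminal, ...), and a synthetic
cohort generator with planted ground truth so the whole pipeline is
testable without external data. See `docs/methods.md` for conventions and
assumptions.

## Worked example

```python
import prognomod as pm
from prognomod.cohort import apply_followup_cutpoint
from prognomod.resample import run_resampling

cfg = pm.SimulationConfig(
    n_samples=300, n_genes=400, n_modules=30, genes_per_module=10,
    true_coefficients={"MOD_001": 0.8, "MOD_002": -0.6, "grade": 0.4},
    seed=1,
)
expr, cohort, scores, truth = pm.simulate_cohort(cfg)
cohort = apply_followup_cutpoint(cohort, 7.0)

results = pm.LassoCox.from_cohort(cohort, scores, family="combined").fit(
    cv_folds=10, seed=1)
print(results.summary())
```

```
L1-penalized Cox proportional hazards
  n train = 300, p = 34
  lambda = 0.0335909 (min rule, seed 1)
  nonzero coefficients: 10

  variable                         coef (std)
  MOD_001                              0.4606
  MOD_002                             -0.2751
  MOD_019                              0.1606
  ...
```

The two planted prognostic modules (`MOD_001`, adverse; `MOD_002`,
protective) top the coefficient table; the remaining small coefficients are
the usual noise admitted by the CV-minimum rule. Resampling separates them
cleanly:

```python
summary = run_resampling(cohort, scores, families=("clinical", "combined"),
                         n_target=20, max_attempts=30, base_seed=1)
print(summary.mean_test_cindex)
print(summary.selection_frequency().head(3))
```

```
mean test C-index: {'clinical': 0.5345, 'combined': 0.6544}
variable  count  frequency direction
 MOD_001     20       1.00      poor
 MOD_002     19       0.95      good
 MOD_019     16       0.80      poor
```

The combined model concordance (0.65 on held-out thirds) beats the
clinical-only model (0.53, barely above chance, as the simulated signal
lives in the modules), and the planted modules are selected in 95–100% of
successful models with the correct direction of association.

The same workflow is scriptable from the shell:

```bash
prognomod simulate --seed 1 --out data/
prognomod resample --cohort data/cohort.tsv --expression data/expression.tsv \
    --gmt data/modules.gmt --sidecar data/modules.json \
    --families clinical,genomic,combined --n-target 200 --seed 1 --out run/
```

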
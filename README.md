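# netpoisson

Group elastic net Poisson regression for predicting a count-valued
attention-problem score (a CBCL-style subscale, integers 0–14) from
resting-state functional-connectivity features and demographic risk
factors, with a synthetic-cohort generator so the whole pipeline can be
exercised and validated without access to restricted cohort data.

**Who it is for.** Researchers modelling right-skewed behavioral counts
from large developmental-imaging cohorts who want variable selection at
the level of whole predictors (a brain-network pair, a demographic
factor) rather than individual dummy or basis columns, with nonlinear
effects and honest cross-validated tuning.

## The model

For subject i with expected count mu_i,

    log mu_i = f0 + sum_j f_j(x_ij),        y_i ~ Poisson(mu_i).

Each predictor's effect f_j expands into a column block — all-level
indicators for unordered factors (site, sex, race, parental alcohol and
drug history), polynomial contrasts for ordered factors (income,
education), a spectral cubic-spline basis for numeric predictors (age
and the 78 within/between-network averaged Fisher-z correlations of the
12 cortical networks). The blocks are penalized as groups:

    min  (1/n) NLL + sum_g [ alpha * rho(||beta_g||; lambda w_g, gamma)
                             + (1-alpha) * (lambda w_g / 2) ||beta_g||^2 ]

with rho the LASSO, MCP (gamma > 2) or SCAD (gamma > 3) penalty,
w_g = sqrt(group size), and alpha the elastic-net mixing weight.
Hyperparameters are tuned by 10-fold cross-validation on mean absolute
error over a 100-value lambda path, with both the `min` and the sparser
`1se` selection rules. Interpretation follows the multiplicative form
mu = exp(f0) * prod_j exp(f_j): baseline rate, per-level effect tables,
nonlinear effect curves, deviance R² and a variable-importance
decomposition that sums to exactly 100.

See `docs/methods.md` for the solver (monotone accelerated proximal
gradient with exact group prox operators, strong-rule screening, KKT
verification), basis construction and generator details.

## Worked example

```python
from netpoisson import GeneratorSpec, generate_dataset, build_design
from netpoisson.cv import cv_fit, select
from netpoisson.interpret import baseline, deviance_r2, effect_table, importance
from netpoisson.synthetic import full_term_list

spec = GeneratorSpec(n_subjects=4000, seed=1)       # synthetic cohort
table = generate_dataset(spec)
design = build_design(table, full_term_list())      # 86 groups, 438 columns
y = table["attention"].to_numpy(float)

cv = cv_fit(design.X, y, design.group_index, family="mcp",
            alpha_grid=[1.0], gamma_grid=[3.0], k=10, seed=2,
            group_weights=design.group_weights())
pspec, path, sol = select(cv, rule="1se")

print("active terms:", sol.active_groups)
print("baseline exp(f0):", round(baseline(sol), 3))
print("deviance R2 (%):", round(deviance_r2(sol, design.X, y), 3))
print(importance(sol, design.X).round(3).to_string())
print(dict(effect_table(sol, design, "sex").round(3)))
```

prints

```
active terms: ['sex', 'income', 'drugs', 'DLA_DT']
baseline exp(f0): 1.442
deviance R2 (%): 19.095
DLA_DT    74.378
sex       17.577
drugs      8.043
income     0.002
{'Male': 1.18, 'Female': 0.844}
```

The MCP fit at the 1se rule recovers the generator's structure: the
single informative connectivity feature (`DLA_DT`, the default-mode /
dorsal-attention pair) plus the sex, drugs and income factors; the
baseline of 1.44 expected problems matches the generative exp(f0) =
1.452, and males are predicted about 1.18/0.844 ≈ 1.4 times the
female rate, matching the generative 1.17/0.85. The importance
indices apportion the model's explained variation and sum to 100.

The same pipeline runs from a config file:

```
netpoisson all --config demo.yaml --seed 1 --out runs/demo
```

writing the cohort CSV, cross-validation surfaces, fitted paths,
importance tables, effect tables/curves and a run manifest.

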
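# siode — single-index ODE models for dynamic gene regulatory networks

Time-course expression experiments (e.g. yeast cell-cycle microarrays:
~300 genes over 18 timepoints spanning two cycles) record how
transcription evolves, but the regulatory question — *which modules
drive which* — needs a dynamic model. Linear ODE network models,
dX_k/dt = X(t)ᵀβ, are easy to fit but miss saturating, oscillatory and
exponential regulation. `siode` implements the semiparametric
generalization

    dX_k(t)/dt = η_k( X(t)ᵀ β[k] ) + ε,     ‖β[k]‖ = 1,

a **single-index ODE**: the regulation shape η_k is an unknown smooth
function estimated by local-linear kernel regression, and the index
vector β[k] — whose nonzero entries name the regulators of module k —
is estimated by **SCAD-penalized profile least squares** with a
BIC-selected penalty, so module selection and coefficient estimation
happen in one step. Estimation is by gradient matching (regress
estimated derivatives on estimated state curves), so no differential
equation is solved during fitting and no initial conditions are needed.

The package is aimed at computational biologists and statisticians
working with time-course expression data, and provides:

- clustering of gene curves into functional modules (EM mixture of
  smooth curves, BIC for the number of modules), or ingestion of a
  precomputed gene→module table;
- penalized-spline mixed-effects (NPME) estimation of module state
  curves and spline estimation of their derivatives;
- `SingleIndexODE` and `LinearODE` model classes with statsmodels-style
  `fit()` / `fit_path()` returning results objects (estimates, active
  set, λ path with BIC, RSS, link diagnostics, `summary()`);
- directed-network assembly and export (edge-list TSV, GraphML, DOT);
- a self-contained seven-equation benchmark simulator with replicated
  support-recovery experiments (C/U/O classification, MSE/ARE tables).

## Worked example

Simulate one benchmark replicate, estimate derivatives, and recover the
regulators of module 1 (truth: modules 1 and 2 with coefficients
(0.707, 0.707)):

```python
from siode import (BenchmarkParams, generate_replicates,
                   states_from_trajectory, SingleIndexODE)

params = BenchmarkParams(n_points=180, n_reps=1, seed=11)
traj = generate_replicates(params)[0]      # integrate the 7-ODE system
states = states_from_trajectory(traj)      # spline derivative estimation
res = SingleIndexODE.from_states(states, 0).fit_path(n_lambdas=15, seed=3)
print(res.summary())
```

```
Single-index ODE (SCAD-penalized profile least squares)
========================================================
module index:      1
n observations:    180
lambda:            0.13895  (BIC-selected from a 15-point path)
kernel / h:        gaussian / 0.174486
RSS (profile):     3.24083e-12
BIC:               -31.5905
converged:         True

coef        estimate   active
beta_1       0.707107   *
beta_2       0.707107   *
beta_3       0.000000
beta_4       0.000000
beta_5       0.000000
beta_6       0.000000
beta_7       0.000000
```

The BIC-selected penalty (λ = 0.139) zeroes the five irrelevant
modules; the surviving unit-norm index (0.707, 0.707) matches the true
direction to six decimals, and the profile RSS ~3e-12 says the
local-linear link reproduces the derivative curve essentially exactly.
`res.active_set`, `res.lambda_path`, `res.link` and `res.plot_link()`
expose the selection path and the estimated regulation shape.

The same objects drive the command line:

```bash
siode simulate --seed 1 --n-points 180 --n-reps 1 --out traj/
siode cluster  --expr expr.tsv --k-min 2 --k-max 15 --seed 1 --out modules.tsv
siode smooth   --expr expr.tsv --modules modules.tsv --n-grid 300 --out states.tsv
siode fit      --states states.tsv --module 1 --family single-index --out fit_1.json
siode network  --states states.tsv --out network/
siode benchmark --reps 100 --n-points 180 --seed 1 --out report.tsv
```

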
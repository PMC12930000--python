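# hpr — horseshoe process regression

Bayesian nonparametric regression for outcomes that change abruptly:
biomarker series that jump after an intervention, basal body temperature
spiking at ovulation, dose-response curves with thresholds.  Classical
smoothers (splines, Gaussian process regression) either blur sharp jumps or
chase measurement noise; `hpr` models the latent trajectory as a **horseshoe
process**, whose increments carry a horseshoe (local-global shrinkage)
prior, so the fit favors long flat stretches punctuated by data-supported
jumps at locations that need not be known in advance.

On a grid t_1 < ... < t_m of unique predictor values (plus optional
interpolation points), with x_i = t_j:

    g(E[y_i]) = f_j = α + Σ_{k≤j} h_k,      h_1 = 0
    h_k | τ, λ_k ~ N(0, τ² λ_k² (t_k − t_{k−1}))
    τ ~ C⁺(0, c),   λ_k ~ iid C⁺(0, 1),   α ~ N(a, b²)

with identity/logit/log links for Gaussian, Bernoulli and Poisson outcomes.
The global scale τ shrinks all increments; the local scales λ_k let
individual increments escape shrinkage, which is what produces clean steps.
Extensions: interpolation/extrapolation at augmentation points (each gets
its own λ and increment), partial-linear covariates (g(E[y_i]) = f_j + β'z_i),
and monotone-increasing/decreasing constraints (f_j = α ± Σ|h_k|).

Posterior sampling is dynamic Hamiltonian Monte Carlo (a No-U-Turn sampler
with dual-averaging step size and diagonal mass adaptation) over a fully
non-centered parameterization with analytic gradients; the hot path is
numba-compiled.  See `docs/methods.md` for the full model, defaults and
numerical choices.

## Worked example

```python
from hpr import (SamplerConfig, ScenarioSpec, compute_metrics, diagnostics_report,
                 fit_hpr, simulate_dataset, summarize_posterior, true_function)

data = simulate_dataset(ScenarioSpec("bigstep", n=100), seed=42)   # 5-level step + N(0, 0.5²) noise
fit = fit_hpr(data, sampler=SamplerConfig(seed=1))   # 4 chains × (1000 + 2000)
summary = summarize_posterior(fit)                   # per-gridpoint mean + 95% band
truth = true_function("bigstep", summary["t"].to_numpy())
print(compute_metrics(truth, summary))
print(diagnostics_report(fit).verdict)
```

Running `python examples/fit_step_function.py` (this example plus printing,
about 1.5 minutes) gives

```
 gridpoint        t  is_observed     point     lower    upper
         1 0.000000         True -0.048589 -0.382752 0.329099
         2 0.101010         True -0.062325 -0.371690 0.252582
...
MAD      0.092   (best constant fit would give 3.100)
Width    0.604
Coverage 0.960  (0.95 is nominal)
sampler: 2.1% divergent draws, worst R-hat 1.005, verdict ok
```

MAD is the mean absolute error of the posterior-mean fit against the true
step function at the 100 observed points — a 30-fold improvement over the
best constant fit; Coverage is the share of those points whose 95% credible
band contains the truth (0.95 is nominal).  Sporadic divergences below 5%
of draws are expected for horseshoe-type posteriors and are flagged only
above that threshold.

Other narrative examples: `examples/interpolate_uneven_design.py`
(augmentation grids on uneven designs), `examples/covariates_and_monotonicity.py`,
`examples/replicate_study.py`.

## Command line

```bash
hpr simulate --scenario bigstep --n 100 --seed 1 --output data.csv
hpr fit --input data.csv --outcome y --predictor x --family gaussian \
        --augment-step 0.5 --chains 4 --warmup 1000 --samples 2000 \
        --seed 1 --outdir results/
hpr study --config study.yaml --output study.csv
```

`hpr fit` writes a per-gridpoint summary CSV, a coefficient table when
covariates are present (scaled and original units), a diagnostics JSON and a
reproducibility log.

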
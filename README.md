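# dceident

Structural and practical identifiability analysis of the nested
contrast-transport models used for dynamic contrast-enhanced MRI
(DCE-MRI): Patlak (PM), Tofts–Kety (TK), extended Tofts–Kety (eTK), and
Leaky Tofts–Kety (LTK).

DCE-MRI tracks a gadolinium contrast agent through tissue; compartment
models turn the tissue concentration time course `C_t(t)` and the plasma
input `C_p(t)` (the vascular input function, VIF) into kinetic parameters
— the transfer constant `K^trans`, fractional volumes `v_e` and `v_p`,
and the leakage rate `λ` — that carry diagnostic weight in oncology.
Whether those parameters are *uniquely determined* is a property of both
the model (structural identifiability) and the data quality (practical
identifiability). This package implements the full analysis pipeline for
researchers working with tracer-kinetic models:

* forward solutions of all four nested models driven by the analytic
  Parker population VIF or a measured VIF series, cross-checked against
  an independent ODE integrator;
* the closed-form observable-ODE coefficient map and its inversion — the
  structural-identifiability result, testable as an exact round trip;
* global maximum-likelihood fitting (particle swarm + trust-region
  polish) of the objective `MLE(θ) = σ⁻² Σ (y_i^D − y_i^M(θ))²`;
* profile likelihoods `PL(θ_i) = min_{θ_j≠i} MLE(θ)`, chi-squared
  (1 df) confidence intervals
  `CI = {θ_i : PL(θ_i) ≤ MLE(θ̂) + Δ_α}` at the 68/80/95% levels,
  identifiability verdicts, and compensating co-parameter traces;
* a synthetic-data generator for the three study conditions
  (artificial/artificial, real-artificial-like, real-real-like) covering
  the persistent, plateau, and wash-out enhancement-curve types;
* the two perturbation studies: a graded VIF-noise ladder and a
  moving-average data-smoothing ladder, run over multiple noise seeds
  with majority verdicts.

See `docs/methods.md` for the model equations, numerical choices, and
the σ conventions behind every confidence statement.

## Worked example

```python
from dceident import (
    FitConfig, ModelKind, ScenarioSpec, classify, confidence_interval,
    fit_global, generate_scenario, profile_likelihood,
)

# noise-free persistent-enhancement curve, analytic VIF, 35-frame grid
vif, ca, truth = generate_scenario(ScenarioSpec(curve_type="I", case="AA"))
cfg = FitConfig(seed=1)

fit = fit_global(ca, vif, ModelKind.LTK, cfg)
print({k: round(v, 6) for k, v in fit.theta.items()})

prof = profile_likelihood(ca, vif, ModelKind.LTK, fit, "ktrans", config=cfg)
ci = confidence_interval(prof, 0.95)
print(round(ci.lower, 6), round(ci.upper, 6), classify(prof, 0.95).status)
```

prints

```
{'ktrans': 0.0025, 've': 0.9, 'vp': 0.05, 'lam': 0.01}
0.000347 0.003611 identifiable
```

— the fit recovers the generating parameters
(`K^trans` = 0.0025 s⁻¹, `v_e` = 0.9, `v_p` = 0.05, `λ` = 0.01 s⁻¹)
essentially exactly on noise-free data, and the `K^trans` profile
likelihood crosses the 95% chi-squared threshold on both sides, i.e. the
parameter is practically identifiable with a finite interval
[0.00035, 0.0036] s⁻¹. Adding 5% noise to the VIF typically demotes the
verdict to the 80% level, and 10–15% noise destroys it — run
`dceident noise-ladder` to reproduce that ladder.

## Command line

```
dceident fixtures            # materialize all 9 synthetic scenarios (CSV/JSON)
dceident fit                 # fit-study table over models x curve types
dceident profile --model LTK --curve-type I --case AA --target ktrans
dceident noise-ladder        # VIF-noise ladder with majority verdicts
dceident smooth-ladder       # smoothing ladder on the noisy surrogate
dceident report              # profile + compensating-trace figure panels
```

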
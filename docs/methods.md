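# Methods

## The model family

Dynamic contrast-enhanced MRI (DCE-MRI) follows a gadolinium tracer through
tissue. The tissue concentration `C_t(t)` (mM) is modeled from the plasma
concentration `C_p(t)` — the vascular input function (VIF) — by a nested
family of linear compartment models:

| model | tissue curve | active parameters |
|---|---|---|
| Patlak (PM) | `v_p C_p + K^trans ∫ C_p` | `K^trans, v_p` |
| Tofts–Kety (TK) | `K^trans ∫ C_p e^{-K_ep(t-τ)} dτ` | `K^trans, v_e` |
| extended TK (eTK) | TK + `v_p C_p` | `K^trans, v_e, v_p` |
| Leaky TK (LTK) | eTK + `λ ∫ C_p` | `K^trans, v_e, v_p, λ` |

`K^trans` (1/s) is the plasma→EES transfer constant, `v_e` and `v_p` the
fractional extravascular-extracellular and plasma volumes,
`K_ep = K^trans/v_e` the reflux rate, and `λ` (1/s) the unidirectional
transfer into a non-refluxing leakage compartment. Compartments start
empty; the VIF is an empirical forcing function. `v_e + v_p ≤ 1` is *not*
enforced: the standard synthetic parameter rows violate it, and only
per-parameter box bounds are used.

The VIF is the population model of Parker et al. — two Gaussians plus a
sigmoid-gated exponential washout — with constants expressed in
seconds/mM. On the default acquisition grid (3 pre-contrast frames plus
32 dynamic frames at 6.03 s; bolus clock starting at the first
post-baseline frame) it peaks at ≈ 6.05 mM near t = 10.35 s after
arrival. Note the value at the arrival instant is ≈ 0.079 mM, not zero:
the Gaussian centers sit only ~3σ from t = 0.

## Numerics of the forward solutions

The exponential-kernel convolution treats the sampled VIF as piecewise
linear and integrates each panel exactly through the stable recursion
`I_i = e^{-K_ep h} I_{i-1} + panel`, with a series branch for
`K_ep·h < 1e-4`. This stays accurate at arbitrarily large `K_ep·h`; the
synthetic row with `v_e = 10⁻³` (i.e. `K_ep ≈ 8 s⁻¹`, `K_ep·Δt ≈ 48`)
would be ~2% wrong under plain trapezoid quadrature of the sampled
integrand, which is retained only as `method="trapezoid"` (its O(Δt²)
error makes grid-refinement convergence visible). The leakage and Patlak
integrals use cumulative trapezoid, exact for piecewise-linear inputs.
An independent oracle integrates the compartment ODEs (LSODA, rtol 1e-9)
with the same linearly interpolated VIF; convolution and oracle agree to
~1e-9 relative L2 on the default grid.

## Structural identifiability

Eliminating the compartment states reduces the LTK system to one ODE in
the observable, `ẏ + a₁y + a₂u + a₃u̇ + a₄v = 0` with `v = ∫u`. The
package ships two coefficient maps: the one conventional in the DCE
identifiability literature
(`a₁ = K^trans/v_e²`, `a₂ = −K^trans − K^trans/v_e² − λ`, `a₃ = −v_p`,
`a₄ = −(K^trans/v_e²)λ`) together with its exact closed-form inverse —
the round-trip is the structural-identifiability statement — and a map
derived from the same dynamics that generate the convolution solutions
(`a₁ = K_ep`, `a₂ = −(K^trans + λ + K_ep v_p)`, `a₄ = −K_ep λ`), which is
the one that annihilates simulated curves in the observable-residual
check. The literature map descends from a nonstandard writing of the EES
equation and drops `v_p` from the `a₂` cross-term; both maps are
closed-form invertible, so the identifiability conclusion is identical.
The nested submodels inherit structural identifiability as constrained
special cases of the inversion.

## Fitting

The objective is `MLE(θ) = σ⁻² Σ (y_i^D − y_i^M(θ))²`, a Gaussian
measurement model with constant variance. Minimization: global-best
particle swarm (50 particles, ≤500 iterations with a 75-iteration
no-improvement stop, constriction coefficients w = 0.7298,
c₁ = c₂ = 1.49618, velocity clamp at half the box, 3 independent
restarts), followed by a bounded trust-region least-squares polish.
Default bounds: `K^trans ∈ [10⁻⁶, 1] s⁻¹`, `v_e ∈ [10⁻³, 1]`,
`v_p ∈ [0, 1]`, `λ ∈ [0, 0.1] s⁻¹`. On noise-free synthetic curves the
fit recovers all four LTK parameters to machine precision in well under a
second.

One genuine degeneracy deserves mention: at the `v_e` floor with
`K_ep·Δt ≫ 1` the convolution term collapses to `v_e·C_p`, i.e. a second
vascular term indistinguishable from `v_p·C_p` and independent of
`K^trans`. Fits to vascular-dominated data may split the vascular
fraction across this ridge; the recoverable quantities there are the
total vascular fraction and the curve itself.

## The noise scale σ

σ only rescales the objective — the optimum location is σ-free — but it
directly scales the profile-likelihood confidence thresholds, so every
identifiability verdict depends on it. The package uses, per study:

* **measured/noisy data**: σ estimated from the data. The inverse-SNR
  estimator (baseline SD over peak enhancement) is appropriate for
  peak-normalized curves; when the objective consumes curves in mM the
  absolute baseline SD is the consistent choice
  (`estimate_sigma(..., relative=False)`).
* **noise-free synthetic curves**: no SD is estimable; the default
  σ = 0.035 mM was calibrated once so that the noise-free Type I baseline
  shows a finite 95% interval inside the standard profile window (any
  σ < 0.039 does; 0.035 ≈ 1/SNR at SNR 65 of the ~2.3 mM Type-I peak)
  and then frozen.
* **VIF-noise ladder**: injected noise of fractional amplitude `level`
  means a known SNR of `1/level`, so σ = `level` per rung — the
  inverse-SNR rule applied to the known noise.
* **smoothing ladder**: the absolute baseline SD of the unsmoothed
  surrogate divided by `√w` for window `w`, the exact variance reduction
  of a w-point average of white noise. The smoothed series' own 3-frame
  baseline is unusable: windows of ≥5 samples leak post-bolus signal into
  the pre-contrast frames.

## Profiles, intervals, verdicts

`PL(θ_i)` re-optimizes the remaining active parameters at each grid value
of the target, sweeping outward from the optimum with warm starts plus
two random restarts per point (suppressing spurious bumps that would fake
non-identifiability). The default grid is 41 log-spaced points over
`[θ̂/10, 10θ̂]` clipped to the fit bounds, plus the optimum itself;
openness of an interval side is judged within the profiled window, which
is configurable. Confidence intervals collect
`{θ_i : PL ≤ MLE(θ̂) + Δ_α}` with `Δ_α` the 1-df chi-squared quantile
(0.989 / 1.642 / 3.841 at 68/80/95%), crossings located by linear
interpolation. A parameter is *identifiable* at a level when both sides
cross; *flat* when the profile's total variation is below 0.05·Δ_α (an
explicit package convention, recorded in profile metadata); otherwise
*practically non-identifiable*. Open sides always carry the window edge
plus an explicit open flag.

Compensating profiles perturb the target ±50% (configurable) and track
the re-optimized co-parameters. They default to warm-start continuation
*without* random restarts: they are a local sensitivity analysis, and
restarts can hop to the `v_e`-floor ridge and destroy the
interpretation. Even so, continuation legitimately collapses to that
ridge once the perturbation exceeds what the remaining parameters can
physically absorb (for λ, beyond about +20%); within a moderate span the
expected pattern holds — `v_e` and λ compensate a `K^trans`
perturbation while `v_p`, which shares no observable coefficient with
the rates, stays near its optimum.

## Synthetic scenarios

`generate_scenario` reproduces the three study conditions:

* **AA** — analytic VIF, noise-free LTK curve from the Type I/II/III
  parameter rows (`K^trans` = 0.0025/0.009/0.03 s⁻¹ with
  v_e = 0.9/0.5/0.5, v_p = 0.05/0.1/0.1, λ = 0.01/0.001/0.001 s⁻¹).
* **RA_like** — the measured VIF is emulated by adding per-element
  Gaussian noise (default 10% amplitude) to the analytic VIF; its
  dedicated parameter rows include a deliberately near-singular
  `v_e = 10⁻³` row that stresses the fitter.
* **RR_like** — RA_like plus additive Gaussian noise on the tissue curve
  (default SNR 20), sharing the AA parameter rows (it surrogates the same
  tissue observed through degraded measurements).

In the noisy cases the tissue curve is always simulated with the *true*
noise-free VIF while the returned "measured" VIF carries the noise. This
is deliberate and load-bearing: if the curve is simulated with the same
noisy VIF used for fitting, the inverse problem is exactly consistent and
identifiability is empirically unimpaired at any noise level; the
input-measurement mismatch is what degrades it, and is also the
physically faithful picture (tissue responds to the true plasma input;
noise lives in the vessel-ROI readout).

What the generator does *not* emulate: MR signal formation (flip angles,
T1 mapping, relaxivity), Rician noise statistics, temporally correlated
or structured VIF errors (delay, dispersion, shape bias of a real
vessel-ROI measurement), or patient motion. Passing tests therefore show
that the pipeline behaves correctly under idealized white-noise
perturbations of the stated sizes, not that real acquisitions will
reproduce the same confidence levels; the white-noise surrogate's
smoothing study in particular recovers identifiability faster than real
data (the recovery appears already at window 3, and large windows also
bias the sharp vascular peak on the 6.03-s grid).

## The perturbation studies

The VIF-noise ladder holds the noise-free Type I curve fixed and adds
5/10/15% per-element Gaussian noise to the VIF used for fitting and
profiling, 10 noise replicates per rung (a single
realization would be realization-dependent; the package reports per-replicate
detail, the fraction of finite intervals per level, and two summary
statistics — the headline *majority-finite level*, the highest level at
which a strict majority of replicates keeps a finite interval, and the
noisier mode of per-replicate verdicts). Typical outcome: 95% at zero
noise, 80% at 5%, no finite interval at 10–15%.

The smoothing ladder applies a centered moving average (window
`max(3, nearest odd to γN)`, shrinking symmetrically at the ends) with
γ ∈ {0, 0.05, 0.10, 0.15} to the RR-like surrogate before refitting.
At γ = 0 the Ktrans profile is non-identifiable at 95% for the majority
of replicates; smoothing (with its σ reduction) recovers identifiability.

## Problem sizes and determinism

All studies run on the 35-frame grid; a full four-rung ladder with 10
replicates completes in a few minutes on one core. Every random draw
descends from a single master seed through named `SeedSequence` streams,
so identical configurations reproduce bit-identical tables.

## Known limitations

* Verdicts near a chi-squared threshold are realization-dependent; at 10
  replicates the 5%-noise rung occasionally reports 68% instead of 80%.
* σ for noise-free data is a convention (see above), not an estimate;
  all AA-case confidence statements are conditional on it.
* The profile window (one decade around the optimum by default) bounds
  the search for interval ends; a parameter can be declared open-sided
  within the window yet cross far outside it.
* The two observable-ODE coefficient conventions disagree in one
  cross-term; both maps are provided and separately inverted (see
  Structural identifiability above).
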
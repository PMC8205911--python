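# frapkit

Inverse modelling of two-species reaction–diffusion FRAP
(fluorescence recovery after photobleaching) experiments.

FRAP bleaches the fluorophores inside a small disk of radius r_n and
records the return of fluorescence as unbleached molecules redistribute.
When the tagged protein both diffuses (diffusivity D_u) and binds
reversibly to a partner (pseudo-first-order association rate k_on,
dissociation rate k_off, bound-state diffusivity D_v), fitting a model to
the recovery yields binding kinetics — *when the experiment can determine
them at all*.  Whether it can is governed by three dimensionless groups:

- η = D_u/(k_on r_n²) — diffusion vs binding rate across the bleach spot,
- κ = k_off/k_on — the equilibrium constant ratio,
- δ = D_v/D_u — bound-state mobility.

For η ≫ 1 (rapid equilibration) all four parameters θ = (D_u, D_v, k_on,
k_off) are estimable, D_u only if the frame interval resolves r_n²/D_u.
For η ≪ 1 (slow equilibration) the recovery is indistinguishable from
single-species diffusion with the effective diffusivity
D_eff = (k_on D_v + k_off D_u)/(k_on + k_off), and only that combination
is estimable.  For κ ≫ 1 or κ ≪ 1 only D_u or D_v, respectively, is
measurable.  frapkit packages the whole workflow around this structure:

- `frapkit.simulate` — radial two-species reaction–diffusion solver on a
  zero-flux disk (exact-in-time eigensolver by default, stiff LSODA
  backend as cross-check), plus the synthetic-experiment protocol
  (parameter sampling, noise, initial guesses);
- `frapkit.analytic` — the closed-form recovery curves of every
  asymptotic regime, built on the Soumpasis function
  F_S(z) = e^{−z}(I₀(z) + I₁(z));
- `frapkit.inference` — recovery-curve and spatio-temporal objectives,
  Nelder–Mead fitting in log-parameter space, estimation-error metrics;
- `frapkit.identifiability` — Fisher information matrix, sloppiness
  spectrum, and the tractability conditions on (κ, δ, r_n, Δt, Δr, L);
- `frapkit.regimes` — AIC-scored constrained fits that identify the
  dynamical regime of arbitrary data, with boundary rejection and
  diffusive-regime disambiguation;
- `frapkit.batch` — Monte-Carlo benchmarks (sample → simulate → fit →
  score) at configurable scale;
- `frap` CLI — `simulate`, `curve`, `fit`, `fim`, `tractability`,
  `identify`, `study`, `fixtures`.

See `docs/methods.md` for the model, numerics and design choices.

## Worked example

Simulate a rapid-equilibration experiment (η = 40) and fit all four
parameters from a recovery curve:

```python
from frapkit import (ExperimentDesign, PhysicalParams, simulate_recovery,
                     initial_guess)
from frapkit.inference import FitProblem, fit, estimation_error

design = ExperimentDesign()              # r_n = 0.5 um, 1024 frames / 15 s
truth = PhysicalParams(D_u=20.0, D_v=0.05, k_on=2.0, k_off=1.0)
curve = simulate_recovery(truth, design)
print(f"F(t_1)  = {curve.values[0]:.4f}")
print(f"F(15 s) = {curve.values[-1]:.4f}")

guess = initial_guess(truth, "precise", rng=1)   # within 50% of the truth
result = fit(FitProblem(datasets=[(curve, design)]), guess)
err = estimation_error(result.theta_hat, truth)
print(f"phi = {result.objective:.3e}, converged = {result.converged}")
for name in ("D_u", "D_v", "k_on", "k_off"):
    print(f"  {name:5s} true {getattr(truth, name):6.3f}   "
          f"fit {getattr(result.theta_hat, name):8.4f}   "
          f"rel.err {err[name]:.1e}")
```

prints

```
F(t_1)  = 0.3221
F(15 s) = 0.9975
phi = 4.844e-16, converged = True
  D_u   true 20.000   fit  20.0000   rel.err 7.6e-07
  D_v   true  0.050   fit   0.0500   rel.err 5.6e-07
  k_on  true  2.000   fit   2.0000   rel.err 1.8e-08
  k_off true  1.000   fit   1.0000   rel.err 2.3e-07
```

The first frame sits near u_eq = k_off/(k_on + k_off) = 1/3 — the free
pool has already re-equilibrated by diffusion — and the rest of the
recovery is dominated by dissociation at rate k_off.  The fit recovers
all four parameters to ~10⁻⁶ because this regime (η = 40, κ = 0.5,
δ = 0.0025) is tractable.  The tractability report for the same setting,

```python
from frapkit.identifiability import tractability
rep = tractability(truth, design, mode="recovery")
print(f"tractable (recovery mode): {rep.tractable}")
print("ratios:", {k: round(v, 3) for k, v in rep.ratios.items()})
```

```
tractable (recovery mode): False
ratios: {'kappa': 0.5, 'delta': 0.003, 'eta_roi': 40.0, 'dt_diffusion': 1.172, 'eta_pixel': 16000.0, 'eta_fov': 0.1}
```

flags the experimental conditions (`dt_diffusion` = Δt·D_u/r_n² ≈ 1.2,
i.e. the frame interval does *not* resolve the diffusion phase), a
warning that D_u rests on information-poor early frames — the verdicts
are order-of-magnitude sufficient conditions and should be read together
with the ratios.

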
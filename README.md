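# dsdesign

Statistical efficiency and survey design for **conventional distance sampling
(CDS)** — single-observer line-transect estimation of animal (or plant, or
object) abundance.

In a line-transect survey, observers record perpendicular distances of
detected objects out to a truncation distance *w*. Detection is modelled by a
curve *g(d; θ)* with *g(0) = 1*, non-increasing in distance; the abundance
estimator scales the *n* detections by the estimated mean detectability:

    N̂_CDS = n / (P · ḡ(θ̂)),     ḡ(θ) = w⁻¹ ∫₀ʷ g(u; θ) du,

where *P* is the fraction of the study area covered by the surveyed strips
and *θ̂* maximizes the likelihood of the distances conditional on *n*.
Having to estimate *θ* carries a hidden cost. Under the uniform-distance
model, the limiting variance of N̂_CDS equals the known-*θ* variance
*N P⁻¹ ḡ⁻¹ (1 − Pḡ)* inflated by the penalty factor

    F = 1 + h̄ᵀ Δ⁻¹ h̄ · ḡ⁻² (1 − Pḡ)⁻¹  ≥ 1,

with *h = ∂g/∂θ*, *h̄* its mean over [0, w], and *Δ = var_D[h(D)/g(D)]* for a
distance *D* drawn from the detection-conditional density. The required
sample size for a target coefficient of variation follows directly:
*E[n] = F / CV²* (or *(N⁻¹ + CV² F⁻¹)⁻¹* for finite populations).

The package provides:

- **Detection families** (`dsdesign.families`): half-normal
  `exp(−d²/2θ²)` and hazard-rate `1 − exp(−(d/θ₁)^(−θ₂))` curves with
  analytic gradients, means ḡ and h̄ by quadrature (with closed-form fast
  paths), and numerical calibration of the scale to a target ḡ.
- **Asymptotics** (`dsdesign.asymptotics`): Δ by quadrature, Fisher
  information of (N, θ) and its blockwise inverse, the penalty *F*, CV and
  sample-size formulas, and full penalty tables over coverage × mean
  detection × shape grids.
- **Estimation** (`dsdesign.estimation`): conditional maximum likelihood
  (Brent for one parameter, Nelder–Mead for two, on log parameters), the
  CDS, known-θ, and strip-transect estimators, and strip-width curves.
- **Simulation** (`dsdesign.simulate`): a replicate harness with a
  Dirichlet-process-style overdispersed distance generator (interval counts
  inflated by a factor *c*), detection thinning, and summaries: bias, MSE,
  relative RMSE, empirical penalty, MSE-optimal strip width, and the width
  range where strip transects beat CDS.
- **CLI** (`dsdesign`): `penalty`, `table`, `samplesize`, `simulate`, `fit`.

## Worked example

How much does estimating a two-parameter hazard-rate detection function cost,
and what sample size does a 15% CV require?

```sh
$ dsdesign penalty --family hazard_rate --shape 2 --gbar 0.6 --P 0.1
F = 2.586
gbar = 0.6
hbar = [0.9326, -0.04237]
Delta condition number = 113.9

$ dsdesign samplesize --cv 0.15 --family hazard_rate --shape 2 --gbar 0.6 --P 0.1
F = 2.586
required E[n] = 115
```

The variance of the abundance estimate is 2.59× what it would be if the
detection parameters were known, so ~115 expected detections are needed for a
15% CV (a known-θ survey would need only 1/CV² ≈ 44).

Small-sample behaviour, with overdispersed object locations (*c* = 2):

```python
from dsdesign import (SimulationConfig, run_simulation, optimal_strip_width,
                      empirical_penalty, crossing_range)

cfg = SimulationConfig(family="hazard_rate", theta_true=(0.448, 2.0), E_n=100,
                       c=2.0, reps=500, fit_families=("hazard_rate",), master_seed=1)
res = run_simulation(cfg)
print("N =", res.N)
print("empirical penalty =", round(empirical_penalty(res), 2))
print("optimal strip width =", optimal_strip_width(res))
print("strip beats CDS over =", crossing_range(res))
```

```
N = 1667
empirical penalty = 4.16
optimal strip width = 0.42
strip beats CDS over = (0.17, 0.7)
```

With only ~100 detections and realistic overdispersion, the empirical
variance penalty (4.16) exceeds its asymptote (2.59), and a simple strip
transect of half-width ≈ 0.42·w would actually beat CDS on mean squared
error — provided the ecologist can guess the right strip width within the
(0.17, 0.7) window.

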
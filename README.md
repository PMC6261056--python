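# cargodyn

Stochastic simulation and trajectory statistics for motor-driven
intracellular cargo transport with **non-Markovian detachment kinetics**
and **fractional-Gaussian-noise sub-diffusion**.

Organelles tracked at high speed inside living cells show a hallmark
transition: sub-diffusive wiggling at short times (time-averaged variance
TAVAR ~ Δ^0.7) crossing over to *super-diffusive* transport at long times
(TAVAR ~ Δ^1.6) — behaviour a constant-rate (Markovian) attachment /
detachment model cannot produce, since it relaxes to normal diffusion
(TAVAR ~ Δ). `cargodyn` implements the model that can: a cargo hauled by
an effective motor whose detachment hazard *decreases with the time τ
since it last attached*,

    T_d(τ) = μ/(τ_d + τ) · e^{F/F_d},      1 < μ < 2,

giving power-law run lengths (survival (τ_d/(τ_d+τ))^μ) and
Lévy-walk-like runs interrupted by rests, with long-lag

    TAVAR(Δ) ∼ Δ^{3−μ}.

Short-time sub-diffusion enters through an external fractional Gaussian
noise ξ_H (Hurst exponent H < ½) in the overdamped cargo equation
β dr/dt = F + D\*ξ_H. The package is aimed at biophysicists modelling
single-particle-tracking data of active transport: it provides the
simulator, exact fGn generators, the time-average statistics used on
real tracks (TAMSD / TAMD / TAVAR, anomalous exponents, MFPT, pooled
window-velocity distributions), microscopic justifications of the
non-Markovian rate (heterogeneous motor populations, gamma rate
mixtures, cooperative Klumpp–Lipowsky teams), and two in-silico
experiments probing why the kinetics are biologically useful (overcoming
a blocking filament; reaching a neighbouring filament).

See `docs/methods.md` for the full model description, parameter table
and numerical choices.

## Worked example

```python
import numpy as np
from cargodyn import (NonMarkovRate, SimConfig, simulate,
                      make_lag_grid, tavar, anomalous_exponent)

# 100 trajectories, 128 s each, with the dynein-like defaults
curves = []
for seed in range(100):
    cfg = SimConfig(duration=128.0, dt=1e-4, noise_amplitude=0.0,
                    detachment=NonMarkovRate(mu=1.4, tau_d=1.0), seed=seed)
    tr = simulate(cfg)
    grid = make_lag_grid(tr, 1.0, 7.0)
    curves.append(tavar(tr, grid).values)

mean_curve = np.mean(curves, axis=0)
alpha = np.polyfit(np.log(grid.lags), np.log(mean_curve), 1)[0]
print(f"long-lag TAVAR exponent: {alpha:.2f}")
```

```
long-lag TAVAR exponent: 1.47
```

The fitted exponent sits in the super-diffusive band predicted by
3 − μ = 1.6 for μ = 1.4 (the measured value is pulled slightly below the
ideal by the tether-load factor e^{F/F_d} on the hazard and residual
finite-duration bias; swapping in `MarkovRate(epsilon=0.25)` yields
1.0 — normal diffusion — under the same analysis). With
`noise_amplitude=0.002, hurst=0.35` the same statistic fitted over lags
10⁻³–10⁻² s gives ≈ 0.71, the fGn sub-diffusion exponent 2H.

A command-line interface covers the same ground for shell use:

```bash
cargodyn simulate --config cfg.toml --out traj.csv
cargodyn analyze --traj traj.csv --stat tavar --fit-window 1 7
cargodyn scenario-reach --n-traj 3000 --out reach.csv
cargodyn fixture --kind run_rest --duration 30 --out fx.csv
```

Every stage writes a JSON manifest (config, seeds, outputs) sufficient
to re-run it bit-identically.

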
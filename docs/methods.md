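# Methods

## The model

`cargodyn` simulates a single organelle-scale cargo hauled along a
microtubule by an *effective motor* — a mean-field stand-in for the
(possibly heterogeneous or cooperative) team of dyneins engaged on one
cargo. The filament is the x-axis; motion is toward +x; positions are
continuous 2D coordinates in μm.

While **attached**, the motor makes discrete 8-nm steps at the
load-dependent rate

    κ(F) = v0/d · (1 − √(F/F_s)),   F < F_s;   κ = 0 at or past stall,

with a fixed probability (default 0.25) of stepping backward. The motor
and cargo are joined by a Hookean tether of natural length l and
stiffness k that pulls only when stretched: |F| = k(d(t) − l) for
d(t) > l, zero otherwise. The cargo obeys the overdamped Langevin
equation

    β dr/dt = F + D* ξ_H(t),

integrated by explicit Euler at resolution dt, where ξ_H is fractional
Gaussian noise (fGn) with Hurst exponent H. The noise models the
non-equilibrium, viscoelastic cytoplasm as an *external* forcing; no
fluctuation–dissipation relation is imposed, so β and D* are independent
parameters.

**Detachment** is where the model departs from standard treatments. The
hazard of unbinding is run-length dependent:

    T_d(τ) = μ/(τ_d + τ) · exp(F/F_d),   1 < μ < 2,

where τ is the time since the last attachment. Force-free, this hazard
integrates to the Lomax (shifted-Pareto) survival law
Ψ(τ) = (τ_d/(τ_d + τ))^μ — power-law run times with tail exponent μ.
Long runs are self-reinforcing: the longer a cargo has run, the less
likely it is to let go. The Markovian reference model replaces this with
a constant Arrhenius rate T_d = ε·exp(F/F_d).

**Attachment** occurs at a constant rate T_a. The cytoskeletal mesh is
dense, so a parallel filament is assumed available wherever the cargo
happens to be when it rebinds: reattachment engages a fresh filament
through the cargo's current position (the engaged filament's transverse
offset is reset to the cargo's y, the motor starts at the cargo's x,
tether unstretched, run clock zeroed). Pinning reattachment to the
original line y = 0 instead would make the tether start stretched by the
cargo's accumulated transverse fBm excursion (rms ~60–160 nm per rest
against a 100-nm tether), producing tens of pN of instantaneous load and
immediate re-detachment — an artifact that destroys the run–rest
phenomenology the model exists to study.

### Why the non-Markovian rate: three microscopic scenarios

The `kinetics` module implements three origins of an effective
decreasing hazard, all exposed through one interface (ψ, Ψ, ψ/Ψ):

1. **Discrete heterogeneous population** — each run engages one motor
   drawn from N types with rates λ_i and weights p_i; ψ is a finite
   mixture of exponentials and ψ/Ψ decreases from Σp_iλ_i to min λ_i.
2. **Gamma-distributed rate continuum** — λ ~ Gamma(μ, τ_d) reproduces
   the Lomax survival *exactly*: ψ/Ψ = μ/(τ_d + τ). This identity is
   tested to machine precision.
3. **Cooperative (Klumpp–Lipowsky) transport** — n of up to N motors
   bound, unbinding n·ε₁, binding (N−n)·π; the run ends at first
   passage to n = 0. ψ comes from the eigen-decomposition of the
   transient birth–death generator. Its mixture weights are signed and
   its tail is exponential, so the effective rate flattens to a positive
   constant: cooperativity mimics the decreasing hazard only over a
   window and cannot produce asymptotic super-diffusion.

## Trajectory statistics

For a path sampled at interval δ with lag Δ = nδ:

* TAMSD(Δ) — sliding-window mean of the squared 2D displacement.
* TAMD(Δ) — sliding-window mean displacement vector.
* TAVAR(Δ) = TAMSD − |TAMD|² — the variance of the window displacement.
  Directed motion makes TAMSD trivially ballistic; TAVAR removes the
  drift and is the discriminating statistic: long-lag TAVAR ~ Δ^(3−μ)
  for the non-Markovian model (super-diffusion, 1.6 for μ = 1.4) versus
  ~ Δ for the Markovian one, with short-lag sub-diffusion ~ Δ^(2H) from
  the fGn in both.
* Anomalous exponents are least-squares log–log slopes over explicit lag
  windows, recorded with every fit. Exponents are measured on the
  trajectory-averaged TAVAR curve (lower variance than averaging
  per-trajectory slopes; the heavy-tailed run lengths make single-curve
  fits extremely noisy).
* MFPT(L) — mean over start samples of the first lag at which the
  displacement modulus reaches L (first grid crossing, R(Δ) ≥ L).
  Starts that never reach L are excluded; their count is reported.
* Window velocities — speeds |r(t'+Δ) − r(t')|/Δ pooled over all start
  points and a geometric lag grid (20 points/decade) from δ up to a
  tenth of the duration, binned in an unweighted histogram. The pooled
  histogram carries a monotone falling background (a superposition of
  Rayleigh-like noise bumps at every lag scale); the cargo's run
  velocity appears as a *local* peak on top of it, so the dominant-peak
  estimator looks for the strongest smoothed interior local maximum
  above a speed floor rather than a global arg-max.

A note on an equivalence: TAVAR equals the TAMSD with the mean window
displacement removed *at each lag* — an exact identity (tested at 1e-10
relative). The often-quoted variant "subtract the global mean increment
so the path starts and ends together, then take TAMSD" agrees only up to
O((Δ/T)²) boundary terms and is checked loosely.

## Fractional Gaussian noise

Unit-variance fGn has autocovariance
γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}). Two exact samplers are
provided and validated against this closed form: the Hosking
(Durbin–Levinson) recursion, quadratic in n and used up to 2^14 steps,
and Davies–Harte circulant embedding (O(n log n)) beyond. x and y noise
are independent streams with seeds derived from one base seed via
`numpy` SeedSequence spawning.

Amplitude convention (the model text leaves the prefactor open): the
package fixes the free-cargo per-axis MSD to (D*/β²)·Δ^{2H} μm², i.e.
per-step displacements √D*/β·dt^H·ξ, with β taken numerically in
pN·s/μm. With the defaults this gives free-cargo excursions of ~90 nm
per second — the scale on which organelles are observed to hover near
their filament — and TAVAR magnitudes of order 10⁻³ μm² at 0.1 s lags,
matching single-particle-tracking scales. Only the exponent, never this
prefactor, is asserted in tests.

One consequence worth knowing: with D* = 0.002 the noise frequently
slackens the tether, and since κ(F) is convex and maximal at F = 0, the
motor rectifies these episodes into extra forward progress. The
attached-run cargo speed is ~0.95 μm/s in the continuum force-balance
limit, ~1.05 with 8-nm stepping discreteness, and ~1.2 with the default
noise. The pooled velocity-histogram peak for v0 = 4 μm/s therefore
sits near 1.2 μm/s, at the upper edge of (and slightly above) the
0.8–1.1 μm/s band quoted for the original parameterization, whose noise
prefactor convention is not recoverable from the text.

## Scenario experiments

**Blocked filament.** A perpendicular microtubule of 24-nm diameter at
x = l₁ excludes the motor (stepping and reattachment) from
|x − l₁| < 12 nm; the cargo itself passes freely, so overtaking the
blocker requires detaching, diffusing past, and reattaching beyond. The
observable is the mean sliding-window distance ⟨L⟩(Δ) normalized by the
blocker-free mean; the non-Markovian model, which detaches readily early
in a run (T_d(0) = 1.4/s vs ε = 0.25/s), clears near-origin blockers
faster. To compare models fairly, `match_free_run_distance` bisects one
parameter (default: the attachment rate of the designated model, on a
log scale, with common random numbers) until blocker-free mean distances
at a 2-s horizon agree within 2%.

**Neighbouring-filament reach.** Force-free 2D fGn walkers take discrete
steps of duration δt = 1 s with the single-step MSD equalized across H
at fixed D* ("equal energy per step"): per-axis single-step
MSD = D*·δt, so the step rms (~45 nm at D* = 0.002) deliberately
exceeds the 24-nm target filament at x = l₂. A Brownian walker
frequently jumps clean across the thin filament without landing on it; an
anti-correlated (H < ½) walker recrosses the neighbourhood repeatedly
and samples it finely. Sub-diffusion therefore *raises* the hit
probability for filaments within its explored range, at the cost of a
smaller range — far beyond it the wider Brownian excursions win by
default. The ordering tests are accordingly run at in-range targets
(l₂ ≈ 0.03–0.05 μm for ΔT = 16.4 s); a per-time-step hit rule with
steps much finer than the filament would abolish the effect entirely, as
every crossing would then register.

**Run-and-rest ensembles.** Case-1/2 style 1D trajectories: run
durations drawn from a mixture residence law (inverse-transform
τ = τ_d(U^{−1/μ} − 1) for the gamma/Lomax family), displacement v·τ at
constant speed (default 1 μm/s, a typical cargo speed), rests
exponential with rate T_a. These reproduce the Δ^{3−μ} TAVAR without
any motor mechanics and are the fastest route to the super-diffusion
exponent.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| l | tether natural length | 100 | nm |
| k | tether stiffness | 0.32 | pN/nm |
| β | cargo drag | 0.72 | pN·s/μm |
| v0 | unloaded motor speed | 4 | μm/s |
| d | step size | 8 | nm |
| F_s | stall force | 2.5 | pN |
| F_d | detachment force scale | 3 | pN |
| μ, τ_d | non-Markovian hazard | 1.4, 1 | –, s |
| ε | Markovian load-free rate | 0.25 | 1/s |
| T_a | attachment rate | 1 | 1/s |
| H | Hurst exponent | 0.35 | – |
| D* | fGn intensity | 0.002 | μm²/s^{2H} |
| dt | integration step | 1e-4 | s |
| backstep_prob | backward-step fraction | 0.25 | – |
| measurement_sigma | localization error | 0 (off) | nm |

The stability guard requires every zero-load hazard × dt < 0.1; all
hazards are realized per step as Bernoulli events with probability
1 − e^{−h·dt}, which stays well-defined even during transient force
spikes. dt = 1e-4 s (the tracking experiment's frame interval) satisfies
the guard with the default stepping rate v0/d = 500/s; a 1-ms step would
not.

## Numerical and design choices

* **Problem sizes.** Exponent measurements average TAVAR over
  trajectories before fitting. The super-diffusion exponent converges
  slowly from below in the trajectory length (lag/duration ≲ 1/20 is
  needed for the fit window's upper end): 128-s trajectories are used
  for the [1, 7] s window. With the force coupling active, the
  sustained ~0.7 pN tether load multiplies the hazard by
  e^{F/F_d} ≈ 1.26, which *raises* the effective tail exponent toward
  μ·1.26 ≈ 1.77; the measured long-lag exponent ~1.47 (vs the
  force-free 3 − μ = 1.6) reflects that genuine coupling plus residual
  finite-time bias, and sits within the 1.6 ± 0.15 band.
* **Cargo radius** is carried as metadata only; it plays no dynamical
  role.
* **Hill tail fits** estimate the survival exponent μ (density exponent
  minus one) by maximum likelihood on the upper tail fraction (default
  0.1). Estimates on Lomax samples are threshold-biased low unless the
  tail is deep (threshold ≫ τ_d); parameter-recovery tests therefore use
  a 1–2% tail. Stability is probed by halving the tail: a >10% shift
  flags a non-power-law (e.g. exponential) tail.
* **Degenerate inputs.** ψ/Ψ is evaluated in log space (nonnegative
  mixtures) or with the slowest exponential factored out (signed
  cooperative weights), so effective rates at τ ~ 10⁵ s neither under-
  nor overflow. Zero-length steps, zero noise, and zero measurement
  noise are all exact no-ops.
* **Seeds.** One base seed per run; per-trajectory, per-axis and
  per-stage streams derive from it by SeedSequence spawning. Identical
  seeds give bit-identical trajectories.

## What the synthetic data does and does not show

Generated trajectories emulate the recordings' sampling interval
(10⁻⁴ s), durations (seconds to ~a minute), run–rest alternation and
optional Gaussian localization error (20 nm in fixtures). They do not
emulate 3D-to-2D projection artifacts, filament curvature or network
geometry, multi-motor tug-of-war, step-size mixtures (5/8/18 nm), or
spatially varying cytoplasm. Passing tests therefore demonstrate
internal consistency of the model and estimators at realistic scales,
not that the model fits any particular recording.

## Known limitations

* The effective motor is strictly mean-field; only the cooperative
  *residence law* (not cooperative force sharing) is modelled.
* The force-coupled non-Markovian hazard has no closed-form sampler;
  inside the dynamics it is realized as a per-step hazard, exact only to
  O(dt).
* The catch-bond regime (detachment rate decreasing with load) is out of
  scope.
* TAVAR exponent estimates on heavy-tailed run-length processes are
  biased downward at finite duration; quoted exponents always name their
  fit window and trajectory length.
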
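"""Coupled motor-cargo dynamics on a microtubule.

A point-like effective motor walks along the filament (the x-axis, plus
end at the origin, motion toward +x) in discrete 8-nm steps at the
load-dependent rate kappa(F) = v0/d (1 - sqrt(F/F_s)).  It is tethered to
the cargo by a Hookean spring of natural length l and stiffness k that
only pulls when stretched.  The cargo obeys the overdamped Langevin
equation

    beta dr/dt = F + D* xi_H(t),

integrated by explicit Euler at resolution dt; xi_H is fractional
Gaussian noise from :mod:`cargodyn.noise`.  The motor detaches with the
configured hazard (Markovian or run-length dependent, force-amplified by
e^{F/F_d}) and, while detached, reattaches at constant rate T_a.  The
cytoskeletal mesh is dense, so a parallel filament is always available
where the cargo happens to be: reattachment engages a filament passing
through the cargo's current position (the engaged filament's y-offset is
reset to the cargo's y), placing the motor at the nearest point, with an
unstretched tether.  All hazards are realized as per-step
Bernoulli events with probability 1 - e^{-hazard*dt}; a guard rejects
configurations with hazard*dt >= 0.1 at zero load.

An optional perpendicular blocking filament of 24 nm diameter at x = l1
excludes the motor (stepping and reattachment) from |x - l1| < 12 nm; the
cargo itself is unconstrained, so passage requires detaching, diffusing
past the blocker and reattaching beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .errors import ConfigError
from .kinetics import (
    CooperativeModel,
    DetachmentModel,
    DiscreteMixture,
    GammaMixture,
    MarkovRate,
    NonMarkovRate,
    effective_rate,
)
from .noise import FgnSpec, displacement_increments, generate_fgn

__all__ = [
    "SimConfig",
    "Geometry",
    "MotorState",
    "Trajectory",
    "spring_force",
    "stepping_rate",
    "simulate",
    "add_measurement_noise",
]

BLOCKER_RADIUS_UM = 0.012  # half of the 24-nm filament diameter


@dataclass(frozen=True)
class Geometry:
    """Filament layout: main filament along y=0 from x=0 toward +x.

    blocker_x : position l1 (um) of a perpendicular blocking filament, or None
    target_x  : position l2 (um) of a neighbouring target filament, or None
    """

    blocker_x: Optional[float] = None
    target_x: Optional[float] = None

    def __post_init__(self) -> None:
        if self.blocker_x is not None and self.blocker_x <= 0:
            raise ValueError("blocker_x must be positive")
        if self.target_x is not None and self.target_x <= 0:
            raise ValueError("target_x must be positive")


@dataclass(frozen=True)
class SimConfig:
    """All physical and numerical parameters of one simulation.

    Units: lengths in the field's natural mix (tether/steps/noise-sigma in
    nm, positions in um), forces pN, times s, rates 1/s.  Defaults are the
    dynein-like parameter set used throughout: l=100 nm, k=0.32 pN/nm,
    beta=0.72 pN s/um, v0=4 um/s, d=8 nm, F_s=2.5 pN, F_d=3 pN, T_a=1/s,
    dt=1e-4 s, backstep probability 0.25, H=0.35, D*=0.002 um^2/s^{2H}.
    """

    duration: float = 32.0
    dt: float = 1e-4
    tether_length: float = 100.0      # nm
    stiffness: float = 0.32           # pN/nm
    drag: float = 0.72                # pN s/um
    noise_amplitude: float = 0.002    # D*, um^2/s^{2H}
    hurst: float = 0.35
    unloaded_speed: float = 4.0       # v0, um/s
    step_size: float = 8.0            # nm
    stall_force: float = 2.5          # pN
    detach_force: float = 3.0         # pN (used when the model carries no F_d)
    detachment: Optional[DetachmentModel] = field(
        default_factory=lambda: NonMarkovRate(mu=1.4, tau_d=1.0)
    )
    attachment_rate: float = 1.0      # T_a, 1/s
    backstep_prob: float = 0.25
    cargo_radius: float = 250.0       # nm, metadata only (no dynamical role)
    measurement_sigma: float = 0.0    # nm, 0 = off
    start_attached: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        pos = {
            "duration": self.duration, "dt": self.dt,
            "tether_length": self.tether_length, "stiffness": self.stiffness,
            "drag": self.drag, "unloaded_speed": self.unloaded_speed,
            "step_size": self.step_size, "stall_force": self.stall_force,
            "detach_force": self.detach_force,
        }
        for name, val in pos.items():
            if val <= 0:
                raise ConfigError(f"{name} must be positive, got {val}")
        if self.noise_amplitude < 0 or self.measurement_sigma < 0:
            raise ConfigError("noise_amplitude and measurement_sigma must be >= 0")
        if not 0.0 <= self.backstep_prob <= 1.0:
            raise ConfigError("backstep_prob must lie in [0,1]")
        if self.noise_amplitude > 0 and not 0.0 < self.hurst < 1.0:
            raise ConfigError("hurst must lie in (0,1)")
        if self.attachment_rate < 0:
            raise ConfigError("attachment_rate must be >= 0")
        # stability guard: zero-load hazards must be well resolved by dt
        step_hazard = self.unloaded_speed / (self.step_size * 1e-3)
        hazards = {"stepping": step_hazard, "attachment": self.attachment_rate}
        if self.detachment is not None:
            hazards["detachment"] = float(effective_rate(self.detachment, 0.0))
        for name, h in hazards.items():
            if h * self.dt >= 0.1:
                raise ConfigError(
                    f"{name} hazard * dt = {h * self.dt:.3g} >= 0.1: "
                    "reduce dt for a stable Bernoulli-thinned integration"
                )

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class MotorState:
    """Instantaneous motor state: attachment flag, filament position, run clock."""

    attached: bool
    motor_x: float = np.nan  # um; defined only while attached
    run_clock: float = 0.0   # s since last attachment


@dataclass
class Trajectory:
    """Time-indexed 2D cargo path on a uniform grid, with attachment flags."""

    times: np.ndarray        # s
    x: np.ndarray            # um
    y: np.ndarray            # um
    attached: Optional[np.ndarray] = None
    motor_x: Optional[np.ndarray] = None
    extras: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.times.size
        if self.x.size != n or self.y.size != n:
            raise ValueError("times, x, y must have equal length")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("attached", "motor_x"):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col)
                if col.size != n:
                    raise ValueError(f"{name} must have length {n}")
                setattr(self, name, col)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)

    def positions(self) -> np.ndarray:
        """(n, 2) array of cargo positions."""
        return np.column_stack([self.x, self.y])


def spring_force(
    motor_x: float, cargo: tuple, tether_length: float, stiffness: float
) -> np.ndarray:
    """Elastic tether force (pN, 2-vector) on the cargo.

    Zero when the motor-cargo distance is at most the natural length
    (compressed tethers exert nothing); otherwise magnitude
    k (d - l) directed from the cargo toward the motor at (motor_x, 0).
    Lengths in um except tether_length in nm and stiffness in pN/nm.
    """
    l_um = tether_length * 1e-3
    k_um = stiffness * 1e3  # pN/um
    dx = motor_x - cargo[0]
    dy = -cargo[1]
    d = np.hypot(dx, dy)
    if d <= l_um or d == 0.0:
        return np.zeros(2)
    mag = k_um * (d - l_um)
    return mag * np.array([dx, dy]) / d


def stepping_rate(F: float, v0: float, step_size: float, stall_force: float) -> float:
    """Load-dependent stepping rate kappa(F) = v0/d (1 - sqrt(F/F_s)), 0 past stall.

    F in pN, v0 in um/s, step_size in nm, stall_force in pN; rate in 1/s.
    """
    if F < 0:
        raise ValueError("F must be >= 0")
    if F >= stall_force:
        return 0.0
    return v0 / (step_size * 1e-3) * (1.0 - np.sqrt(F / stall_force))


# --- detachment-model encoding for the compiled kernel ---------------------
# kind 0: constant rate a          (MarkovRate)
# kind 1: a/(b+tau)                (NonMarkovRate, GammaMixture)
# kind 2: sum w e^{-z tau} / sum (w/z) e^{-z tau}  (Discrete/Cooperative)
# kind -1: detachment disabled


def _encode_detachment(model, default_Fd: float):
    empty = np.zeros(1)
    if model is None:
        return -1, 0.0, 0.0, empty, empty, np.inf
    if isinstance(model, MarkovRate):
        return 0, model.epsilon, 0.0, empty, empty, model.F_d
    if isinstance(model, NonMarkovRate):
        return 1, model.mu, model.tau_d, empty, empty, model.F_d
    if isinstance(model, GammaMixture):
        return 1, model.mu, model.tau_d, empty, empty, default_Fd
    if isinstance(model, DiscreteMixture):
        lam = np.asarray(model.lam, dtype=float)
        w = np.asarray(model.p, dtype=float) * lam
        return 2, 0.0, 0.0, w, lam, default_Fd
    if isinstance(model, CooperativeModel):
        z, w = model.exponential_decomposition()
        return 2, 0.0, 0.0, w, z, default_Fd
    raise TypeError(f"unsupported detachment model {type(model).__name__}")


@njit(cache=True)
def _det_hazard(kind, a, b, w, z, tau):  # pragma: no cover
    if kind == -1:
        return 0.0
    if kind == 0:
        return a
    if kind == 1:
        return a / (b + tau)
    zmin = z[0]
    for i in range(z.size):
        if z[i] < zmin:
            zmin = z[i]
    num = 0.0
    den = 0.0
    for i in range(z.size):
        e = np.exp(-(z[i] - zmin) * tau)
        num += w[i] * e
        den += w[i] / z[i] * e
    if den <= 0.0:
        return num / 1e-300
    return num / den


@njit(cache=True)
def _simulate_core(  # pragma: no cover
    n_steps, dt, l_um, k_um, beta, v0, d_um, Fs, Ta, backstep_p,
    det_kind, det_a, det_b, det_w, det_z, det_Fd,
    noise_x, noise_y, u,
    blocker_x, blocker_r, start_attached,
):
    x = np.empty(n_steps + 1)
    y = np.empty(n_steps + 1)
    att = np.zeros(n_steps + 1, dtype=np.uint8)
    mx = np.full(n_steps + 1, np.nan)
    x[0] = 0.0
    y[0] = 0.0
    attached = start_attached
    motor_x = 0.0
    fil_y = 0.0  # y-offset of the filament currently engaged
    tau = 0.0
    if attached:
        att[0] = 1
        mx[0] = 0.0
    kappa0 = v0 / d_um
    for i in range(n_steps):
        fx = 0.0
        fy = 0.0
        F = 0.0
        if attached:
            dx = motor_x - x[i]
            dy = fil_y - y[i]
            dist = np.sqrt(dx * dx + dy * dy)
            if dist > l_um:
                F = k_um * (dist - l_um)
                fx = F * dx / dist
                fy = F * dy / dist
        # cargo explicit Euler update
        x[i + 1] = x[i] + fx / beta * dt + noise_x[i]
        y[i + 1] = y[i] + fy / beta * dt + noise_y[i]
        if not np.isfinite(x[i + 1]) or not np.isfinite(y[i + 1]):
            return x, y, att, mx, i  # caller raises with step index
        # motor events
        if attached:
            if F < Fs:
                kappa = kappa0 * (1.0 - np.sqrt(F / Fs))
            else:
                kappa = 0.0
            if u[i, 0] < -np.expm1(-kappa * dt):
                if u[i, 1] < backstep_p:
                    new_mx = motor_x - d_um
                else:
                    new_mx = motor_x + d_um
                blocked = False
                if blocker_x > 0.0 and np.abs(new_mx - blocker_x) < blocker_r:
                    blocked = True
                if not blocked:
                    motor_x = new_mx
            h = _det_hazard(det_kind, det_a, det_b, det_w, det_z, tau)
            h *= np.exp(F / det_Fd)
            if u[i, 2] < -np.expm1(-h * dt):
                attached = False
                tau = 0.0
            else:
                tau += dt
        else:
            if u[i, 3] < -np.expm1(-Ta * dt):
                ax = x[i + 1]
                if blocker_x > 0.0 and np.abs(ax - blocker_x) < blocker_r:
                    if ax < blocker_x:
                        ax = blocker_x - blocker_r
                    else:
                        ax = blocker_x + blocker_r
                motor_x = ax
                fil_y = y[i + 1]  # fresh filament through the cargo's position
                attached = True
                tau = 0.0
        if attached:
            att[i + 1] = 1
            mx[i + 1] = motor_x
    return x, y, att, mx, -1


def simulate(config: SimConfig, geometry: Optional[Geometry] = None) -> Trajectory:
    """Run the motor-cargo simulation; reproducible for a fixed seed.

    Per dt step: the tether force is evaluated, the cargo moves by
    (F/beta) dt plus its fGn increment, and the motor steps / detaches /
    reattaches by Bernoulli-thinned hazards as described in the module
    docstring.  Returns a Trajectory sampled on the full dt grid
    (n_steps + 1 points including t = 0).
    """
    geometry = geometry or Geometry()
    n = config.n_steps
    ss = config.seed
    if not isinstance(ss, np.random.SeedSequence):
        ss = np.random.SeedSequence(ss)
    ss_x, ss_y, ss_events, ss_meas = ss.spawn(4)

    if config.noise_amplitude > 0:
        inc = []
        for sub in (ss_x, ss_y):
            spec = FgnSpec(
                hurst=config.hurst, n_steps=n, dt=config.dt,
                amplitude=config.noise_amplitude, seed=sub,
            )
            seq = generate_fgn(spec)
            inc.append(
                displacement_increments(seq, config.noise_amplitude, config.drag, config.dt)
            )
        noise_x, noise_y = inc
    else:
        noise_x = np.zeros(n)
        noise_y = np.zeros(n)

    u = np.random.default_rng(ss_events).uniform(size=(n, 4))
    det = _encode_detachment(config.detachment, config.detach_force)
    blocker = geometry.blocker_x if geometry.blocker_x is not None else -1.0

    x, y, att, mx, bad = _simulate_core(
        n, config.dt,
        config.tether_length * 1e-3, config.stiffness * 1e3,
        config.drag, config.unloaded_speed, config.step_size * 1e-3,
        config.stall_force, config.attachment_rate, config.backstep_prob,
        det[0], det[1], det[2], det[3], det[4], det[5],
        noise_x, noise_y, u,
        blocker, BLOCKER_RADIUS_UM, config.start_attached,
    )
    if bad >= 0:
        raise RuntimeError(f"non-finite cargo state at step {bad}")

    traj = Trajectory(
        times=np.arange(n + 1) * config.dt,
        x=x, y=y, attached=att.astype(bool), motor_x=mx,
        meta={"config": config, "geometry": geometry},
    )
    if config.measurement_sigma > 0:
        traj = add_measurement_noise(traj, config.measurement_sigma, seed=ss_meas)
    return traj


def add_measurement_noise(traj: Trajectory, sigma: float, seed=0) -> Trajectory:
    """Return a copy with iid Gaussian localization error (sigma in nm) added.

    The original trajectory is left unmodified; sigma = 0 is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return traj
    rng = np.random.default_rng(seed)
    s_um = sigma * 1e-3
    return Trajectory(
        times=traj.times.copy(),
        x=traj.x + rng.normal(0.0, s_um, traj.x.size),
        y=traj.y + rng.normal(0.0, s_um, traj.y.size),
        attached=None if traj.attached is None else traj.attached.copy(),
        motor_x=None if traj.motor_x is None else traj.motor_x.copy(),
        extras=dict(traj.extras),
        meta={**traj.meta, "measurement_sigma_nm": sigma},
    )
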
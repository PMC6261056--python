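"""Exact stationary fractional Gaussian noise (fGn) and its calibration.

fGn is the increment process of fractional Brownian motion.  For Hurst
exponent ``H`` the unit-variance autocovariance is

    gamma(k) = 1/2 (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}),

which decays as ``2H(2H-1) k^{2H-2}`` for large lags.  ``H < 1/2`` gives
anti-correlated increments and sub-diffusion, ``H = 1/2`` white noise,
``H > 1/2`` persistent increments.

Two exact samplers are provided: the Hosking/Durbin-Levinson recursion
(O(n^2), used up to ``EXACT_METHOD_MAX`` steps) and circulant embedding
(Davies-Harte, O(n log n)) for longer sequences.  Both draw from the exact
finite-dimensional Gaussian law; they are validated against the same
closed-form covariance.

Amplitude convention
--------------------
The cargo Langevin equation reads  beta dr/dt = F + D* xi_H(t).  The
amplitude prefactor is fixed package-wide so that a force-free cargo has
per-axis MSD

    MSD(Delta) = (D*/beta^2) Delta^{2H}     [um^2, Delta in s]

i.e. per-step displacement increments are sqrt(D*)/beta * dt^H * xi with
unit-variance fGn xi (beta taken numerically in pN s/um).  Only the
exponent, not this prefactor, is constrained by observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import CapabilityError

__all__ = [
    "EXACT_METHOD_MAX",
    "FgnSpec",
    "NoiseSeq",
    "fgn_autocovariance",
    "generate_fgn",
    "displacement_increments",
    "step_msd_calibration",
]

#: largest sequence length handled by the quadratic exact recursion
EXACT_METHOD_MAX = 2**14


@dataclass(frozen=True)
class FgnSpec:
    """Parameters of one fGn stream.

    hurst      : Hurst exponent H, 0 < H < 1 (dimensionless)
    n_steps    : number of noise samples
    dt         : time step (s)
    amplitude  : noise intensity D* (um^2 / s^{2H})
    seed       : integer seed (any object accepted by numpy SeedSequence)
    """

    hurst: float
    n_steps: int
    dt: float
    amplitude: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError(f"hurst must lie in (0,1), got {self.hurst}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude D* must be >= 0")


@dataclass
class NoiseSeq:
    """A generated unit-variance fGn sequence together with its spec."""

    values: np.ndarray
    spec: FgnSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_steps,):
            raise ValueError("values length must equal spec.n_steps")


def fgn_autocovariance(hurst: float, lag) -> float | np.ndarray:
    """Closed-form autocovariance gamma(lag) of unit-variance fGn.

    Accepts a scalar lag or an array of lags (integers >= 0).
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in (0,1)")
    lag_arr = np.asarray(lag)
    if np.any(lag_arr < 0):
        raise ValueError("lag must be >= 0")
    h2 = 2.0 * hurst
    g = 0.5 * (
        np.abs(lag_arr + 1.0) ** h2
        - 2.0 * np.abs(lag_arr) ** h2
        + np.abs(lag_arr - 1.0) ** h2
    )
    if np.isscalar(lag):
        return float(g)
    return g


@njit(cache=True)
def _hosking_filter(gamma: np.ndarray, z: np.ndarray) -> np.ndarray:  # pragma: no cover
    """Durbin-Levinson recursion turning iid N(0,1) draws z into exact fGn."""
    n = z.shape[0]
    x = np.empty(n)
    x[0] = z[0]
    if n == 1:
        return x
    phi = np.zeros(n)
    phi_prev = np.zeros(n)
    v = 1.0
    for i in range(1, n):
        # partial correlation phi_ii
        acc = gamma[i]
        for j in range(1, i):
            acc -= phi_prev[j - 1] * gamma[i - j]
        phi_ii = acc / v
        for j in range(1, i):
            phi[j - 1] = phi_prev[j - 1] - phi_ii * phi_prev[i - 1 - j]
        phi[i - 1] = phi_ii
        v *= 1.0 - phi_ii * phi_ii
        mean = 0.0
        for j in range(i):
            mean += phi[j] * x[i - 1 - j]
        x[i] = mean + np.sqrt(v) * z[i]
        for j in range(i):
            phi_prev[j] = phi[j]
    return x


def _fgn_exact(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray:
    gamma = np.asarray(fgn_autocovariance(hurst, np.arange(n)))
    z = rng.standard_normal(n)
    return _hosking_filter(gamma, z)


def _fgn_circulant(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Davies-Harte circulant embedding; exact for fGn (eigenvalues >= 0)."""
    m = 1
    while m < n:
        m *= 2
    gamma = np.asarray(fgn_autocovariance(hurst, np.arange(m + 1)))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2m
    eigs = np.fft.fft(row).real
    # guaranteed nonnegative for fGn covariance; clip fp dust
    eigs = np.clip(eigs, 0.0, None)
    big = 2 * m
    z = rng.standard_normal(big) + 1j * rng.standard_normal(big)
    x = np.fft.fft(np.sqrt(eigs / big) * z)
    return x.real[:n]


def generate_fgn(spec: FgnSpec, method: str = "auto") -> NoiseSeq:
    """Generate a unit-variance stationary fGn sequence.

    method : 'auto' (exact recursion up to EXACT_METHOD_MAX, circulant
             embedding beyond), 'exact', or 'circulant'.  'exact' raises
             CapabilityError for sequences past the quadratic method's
             practical limit.
    """
    seed = spec.seed
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed)
    n = spec.n_steps
    if method == "auto":
        method = "exact" if n <= EXACT_METHOD_MAX else "circulant"
    if method == "exact":
        if n > EXACT_METHOD_MAX:
            raise CapabilityError(
                f"exact recursion limited to n <= {EXACT_METHOD_MAX}; "
                "use method='circulant' (or 'auto') for longer sequences"
            )
        values = _fgn_exact(spec.hurst, n, rng)
    elif method == "circulant":
        values = _fgn_circulant(spec.hurst, n, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    return NoiseSeq(values=values, spec=spec)


def displacement_increments(
    noise: NoiseSeq, amplitude: float, beta: float, dt: float
) -> np.ndarray:
    """Per-step cargo displacements (um) from a unit fGn stream.

    Scaled so a force-free cargo has per-axis MSD(Delta) =
    (amplitude/beta^2) * Delta^{2H}; amplitude enters the displacement
    linearly through sqrt(amplitude).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    scale = np.sqrt(amplitude) / beta * dt**noise.spec.hurst
    return scale * noise.values


def step_msd_calibration(amplitude: float, hurst: float, dt: float) -> float:
    """Per-step displacement scale equalizing the single-step MSD across H.

    Returns sigma such that increments sigma*xi_H have per-axis single-step
    MSD = amplitude*dt for *every* Hurst exponent (equal energy per step);
    the cumulative per-axis MSD is then amplitude*dt*n^{2H}.  For H = 1/2
    this is plain Brownian scaling with per-axis MSD = amplitude*t.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in (0,1)")
    if amplitude < 0 or dt <= 0:
        raise ValueError("amplitude must be >= 0 and dt > 0")
    return float(np.sqrt(amplitude * dt))
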
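"""Detachment/attachment kinetics of the effective motor.

The central object is the run-length dependent (non-Markovian) detachment
rate

    T_d(tau) = mu / (tau_d + tau) * exp(F / F_d),        1 < mu < 2,

whose force-free survival function is the Lomax law
Psi(tau) = (tau_d / (tau_d + tau))^mu, i.e. power-law distributed run
times with tail exponent mu.  The module also implements the microscopic
scenarios that give rise to such an effective rate:

* a discrete heterogeneous motor population (finite mixture of
  exponentials),
* a gamma-distributed continuum of single-motor rates (which reproduces
  the Lomax survival exactly), and
* cooperative transport by up to N motors (Klumpp-Lipowsky birth-death
  chain; mixture of exponentials with signed weights, hence an eventually
  constant effective rate and no long-time memory).

Every family exposes its residence-time density psi, survival Psi, and the
effective hazard T_d = psi/Psi, together with exact samplers where a
closed form exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import scipy.linalg
from scipy.special import logsumexp

from .errors import EstimationError

__all__ = [
    "NonMarkovRate",
    "MarkovRate",
    "AttachRate",
    "DiscreteMixture",
    "GammaMixture",
    "CooperativeModel",
    "DetachmentModel",
    "nonmarkov_rate",
    "markov_rate",
    "survival",
    "residence_pdf",
    "effective_rate",
    "sample_run_time",
    "fit_tail_exponent",
    "TailExponentFit",
]


# ---------------------------------------------------------------------------
# model families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NonMarkovRate:
    """Run-length dependent detachment: T_d(tau,F) = mu/(tau_d+tau) e^{F/F_d}."""

    mu: float
    tau_d: float
    F_d: float = 3.0

    def __post_init__(self) -> None:
        if not 1.0 < self.mu < 2.0:
            raise ValueError("mu must lie in (1,2)")
        if self.tau_d <= 0 or self.F_d <= 0:
            raise ValueError("tau_d and F_d must be positive")


@dataclass(frozen=True)
class MarkovRate:
    """Constant-rate (Arrhenius) detachment: T_d(F) = epsilon e^{F/F_d}."""

    epsilon: float
    F_d: float = 3.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.F_d <= 0:
            raise ValueError("epsilon and F_d must be positive")


@dataclass(frozen=True)
class AttachRate:
    """Constant attachment rate (1/s) of the detached motor."""

    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("attachment rate must be positive")


@dataclass(frozen=True)
class DiscreteMixture:
    """Heterogeneous motor population: psi(tau) = sum_i p_i lam_i e^{-lam_i tau}."""

    p: tuple
    lam: tuple

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        lam = np.asarray(self.lam, dtype=float)
        object.__setattr__(self, "p", tuple(p))
        object.__setattr__(self, "lam", tuple(lam))
        if p.shape != lam.shape or p.ndim != 1 or p.size == 0:
            raise ValueError("p and lam must be 1d sequences of equal length")
        if np.any(p < 0) or np.any(lam <= 0):
            raise ValueError("probabilities must be >= 0 and rates > 0")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("mixture probabilities must sum to 1 within 1e-12")


@dataclass(frozen=True)
class GammaMixture:
    """Gamma-distributed single-motor rates, p(lam) ~ lam^{mu-1} e^{-tau_d lam}.

    Marginalizing gives the Lomax residence law: psi(tau) =
    mu/(tau_d+tau) (tau_d/(tau_d+tau))^mu, exactly the non-Markovian rate.
    """

    mu: float
    tau_d: float

    def __post_init__(self) -> None:
        if self.mu <= 1.0:
            raise ValueError("mu must be > 1")
        if self.tau_d <= 0:
            raise ValueError("tau_d must be positive")


@dataclass(frozen=True)
class CooperativeModel:
    """Klumpp-Lipowsky cooperative transport by up to N_max motors.

    Bound-motor count n follows a birth-death chain: unbinding n*unbind_1,
    binding (N_max-n)*bind; the cargo run ends at first passage to n = 0.
    initial_bound defaults to 1 (cargo just attached).
    """

    N_max: int
    unbind_1: float
    bind: float
    initial_bound: int = 1

    def __post_init__(self) -> None:
        if self.N_max < 1:
            raise ValueError("N_max must be >= 1")
        if not 1 <= self.initial_bound <= self.N_max:
            raise ValueError("initial_bound must lie in [1, N_max]")
        if self.unbind_1 <= 0 or self.bind <= 0:
            raise ValueError("rates must be positive")

    def exponential_decomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Rates z_i > 0 and signed weights w_i with psi(tau) = sum w_i e^{-z_i tau}.

        Obtained by eigen-decomposition of the transient generator of the
        bound-motor chain (states 1..N_max, absorption at 0).
        """
        n = self.N_max
        T = np.zeros((n, n))
        for s in range(1, n + 1):
            i = s - 1
            T[i, i] = -(s * self.unbind_1 + (n - s) * self.bind)
            if s < n:
                T[i, i + 1] = (n - s) * self.bind
            if s > 1:
                T[i, i - 1] = s * self.unbind_1
        exit_rates = -T.sum(axis=1)  # only state 1 exits, at rate unbind_1
        vals, vecs = scipy.linalg.eig(T)
        vals = vals.real
        vecs = vecs.real
        e0 = np.zeros(n)
        e0[self.initial_bound - 1] = 1.0
        left = np.linalg.solve(vecs, exit_rates)
        w = (e0 @ vecs) * left
        z = -vals
        order = np.argsort(z)
        return z[order], w[order]


DetachmentModel = Union[
    NonMarkovRate, MarkovRate, DiscreteMixture, GammaMixture, CooperativeModel
]


# ---------------------------------------------------------------------------
# rates, densities, survival
# ---------------------------------------------------------------------------


def nonmarkov_rate(model: NonMarkovRate, tau, F=0.0):
    """Non-Markovian detachment rate mu/(tau_d+tau) e^{F/F_d} (1/s)."""
    tau = np.asarray(tau, dtype=float)
    F = np.asarray(F, dtype=float)
    if np.any(tau < 0) or np.any(F < 0):
        raise ValueError("tau and F must be >= 0")
    out = model.mu / (model.tau_d + tau) * np.exp(F / model.F_d)
    return float(out) if out.ndim == 0 else out


def markov_rate(model: MarkovRate, F=0.0):
    """Markovian detachment rate epsilon e^{F/F_d} (1/s), independent of run time."""
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("F must be >= 0")
    out = model.epsilon * np.exp(F / model.F_d)
    return float(out) if out.ndim == 0 else out


def _as_mixture(model) -> tuple[np.ndarray, np.ndarray]:
    """(z, w) with psi(tau) = sum w e^{-z tau}, Psi(tau) = sum (w/z) e^{-z tau}."""
    if isinstance(model, DiscreteMixture):
        lam = np.asarray(model.lam)
        return lam, np.asarray(model.p) * lam
    if isinstance(model, CooperativeModel):
        return model.exponential_decomposition()
    raise TypeError(f"not an exponential-mixture family: {type(model).__name__}")


def survival(model, tau):
    """Force-free survival probability Psi(tau) of a run.

    NonMarkovRate / GammaMixture: (tau_d/(tau_d+tau))^mu;
    DiscreteMixture / CooperativeModel: mixture of exponentials.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    if isinstance(model, (NonMarkovRate, GammaMixture)):
        out = (model.tau_d / (model.tau_d + tau)) ** model.mu
    elif isinstance(model, MarkovRate):
        out = np.exp(-model.epsilon * tau)
    else:
        z, w = _as_mixture(model)
        out = np.sum((w / z)[..., :] * np.exp(-np.multiply.outer(tau, z)), axis=-1)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def residence_pdf(model, tau):
    """Residence-time (run-duration) density psi(tau) (1/s), force-free."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    if isinstance(model, GammaMixture):
        out = model.mu / (model.tau_d + tau) * (model.tau_d / (model.tau_d + tau)) ** model.mu
    elif isinstance(model, NonMarkovRate):
        out = model.mu / (model.tau_d + tau) * (model.tau_d / (model.tau_d + tau)) ** model.mu
    elif isinstance(model, MarkovRate):
        out = model.epsilon * np.exp(-model.epsilon * tau)
    else:
        z, w = _as_mixture(model)
        out = np.sum(w * np.exp(-np.multiply.outer(tau, z)), axis=-1)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def effective_rate(model, tau):
    """Effective detachment hazard T_d(tau) = psi(tau)/Psi(tau) (1/s).

    Evaluated in log space (nonnegative mixtures) or with the slowest
    exponential factored out (signed mixtures) so large tau never
    underflows.  For GammaMixture this equals mu/(tau_d+tau) exactly.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    if isinstance(model, (NonMarkovRate, GammaMixture)):
        out = model.mu / (model.tau_d + tau)
    elif isinstance(model, MarkovRate):
        out = np.full_like(tau, model.epsilon)
    elif isinstance(model, DiscreteMixture):
        lam = np.asarray(model.lam)
        logp = np.log(np.asarray(model.p) + 1e-300)
        expo = logp - np.multiply.outer(tau, lam)
        log_psi = logsumexp(expo + np.log(lam), axis=-1)
        log_Psi = logsumexp(expo, axis=-1)
        out = np.exp(log_psi - log_Psi)
    else:
        z, w = _as_mixture(model)
        zmin = z.min()
        damp = np.exp(-np.multiply.outer(tau, z - zmin))
        psi_s = np.sum(w * damp, axis=-1)
        Psi_s = np.sum((w / z) * damp, axis=-1)
        out = psi_s / Psi_s
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def sample_run_time(model, rng: np.random.Generator, size=None):
    """Draw force-free run durations whose survival matches ``survival(model)``.

    NonMarkovRate / GammaMixture use the exact inverse transform
    tau = tau_d (U^{-1/mu} - 1); MarkovRate and DiscreteMixture are
    exponential (mixtures).  Force-coupled detachment is handled per step
    inside the dynamics, not here.
    """
    if isinstance(model, (NonMarkovRate, GammaMixture)):
        u = rng.uniform(size=size)
        return model.tau_d * (u ** (-1.0 / model.mu) - 1.0)
    if isinstance(model, MarkovRate):
        return rng.exponential(1.0 / model.epsilon, size=size)
    if isinstance(model, DiscreteMixture):
        p = np.asarray(model.p)
        lam = np.asarray(model.lam)
        idx = rng.choice(p.size, size=size, p=p)
        return rng.exponential(1.0, size=size) / lam[idx]
    raise TypeError(f"no exact sampler for {type(model).__name__}")


# ---------------------------------------------------------------------------
# tail-exponent estimation
# ---------------------------------------------------------------------------


@dataclass
class TailExponentFit:
    """Hill-type maximum-likelihood fit of a survival tail exponent.

    Convention: for a residence density psi(tau) ~ A tau^{-mu-1} the
    survival decays as tau^{-mu}; ``mu`` below is that survival exponent
    (density exponent minus one).
    """

    mu: float
    stderr: float
    n_tail: int
    stable: bool
    message: str = ""


def _hill(samples_sorted_desc: np.ndarray, k: int) -> float:
    top = samples_sorted_desc[:k]
    threshold = samples_sorted_desc[k]
    return k / np.sum(np.log(top / threshold))


def fit_tail_exponent(samples, tail_fraction: float = 0.1) -> TailExponentFit:
    """Estimate the power-law tail exponent mu of run-time samples.

    Hill maximum-likelihood estimator on the upper ``tail_fraction`` of the
    sample.  Stability is probed by re-estimating on half the tail: a
    threshold-dependent estimate (as for an exponential, which has no
    power tail) is flagged ``stable=False``.
    """
    x = np.sort(np.asarray(samples, dtype=float))[::-1]
    n = x.size
    if n < 1000:
        raise EstimationError("need at least 1000 samples for a tail fit")
    k = int(tail_fraction * n)
    if k < 20 or k >= n:
        raise EstimationError("tail_fraction leaves too few (or all) samples in the tail")
    if x[k] <= 0:
        raise EstimationError("tail samples must be positive")
    mu = _hill(x, k)
    mu_half = _hill(x, max(k // 2, 10))
    rel = abs(mu - mu_half) / mu
    stable = rel < 0.1
    msg = "" if stable else (
        f"threshold-dependent estimate (changes {rel:.0%} when the tail is halved): "
        "the tail is likely not a power law"
    )
    return TailExponentFit(
        mu=float(mu), stderr=float(mu / np.sqrt(k)), n_tail=k, stable=stable, message=msg
    )
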
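"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cargodyn.analysis import make_lag_grid, tavar

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20180711)


def mean_tavar_slope(trajs, lag_lo, lag_hi, points_per_decade=8):
    """Log-log slope of the trajectory-averaged TAVAR over [lag_lo, lag_hi]."""
    curves = []
    for tr in trajs:
        grid = make_lag_grid(tr, lag_lo, lag_hi, points_per_decade)
        curves.append(tavar(tr, grid).values)
        lags = grid.lags
    mean_curve = np.mean(curves, axis=0)
    return float(np.polyfit(np.log(lags), np.log(mean_curve), 1)[0])


def gillespie_first_passage(n_max, unbind_1, bind, initial_bound, n_samples, rng):
    """Independent stochastic oracle for the cooperative bound-motor chain.

    Direct Gillespie simulation of the birth-death chain until absorption
    at zero bound motors; returns first-passage times.
    """
    out = np.empty(n_samples)
    for i in range(n_samples):
        n = initial_bound
        t = 0.0
        while n > 0:
            r_un = n * unbind_1
            r_b = (n_max - n) * bind
            total = r_un + r_b
            t += rng.exponential(1.0 / total)
            if rng.uniform() < r_un / total:
                n -= 1
            else:
                n += 1
        out[i] = t
    return out
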
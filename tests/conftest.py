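"""Shared fixtures: small synthetic cases and analytic field stubs."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import settings

from migflow.synth import FlowSpec, generate_case

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

T0 = datetime(2013, 4, 5, 18, 0, tzinfo=timezone.utc)


class AnalyticField:
    """Field stub with a closed-form velocity, for integrator tests.

    ``fn(xy_km, t) -> (u, v) m/s``. Mimics the VectorField surface used by
    the integrators and the streamlet engine (velocity/density/at, t0,
    interval, t_end).
    """

    def __init__(self, fn, t0=T0, interval_minutes=20, n_intervals=10**6, density=100.0):
        self.fn = fn
        self.t0 = t0
        self.interval = timedelta(minutes=interval_minutes)
        self.n_intervals = n_intervals
        self._density = density

    @property
    def t_end(self):
        return self.t0 + self.interval * self.n_intervals

    def velocity(self, point, t, band=0):
        return np.asarray(self.fn(np.asarray(point, dtype=float), t), dtype=float)

    def density(self, point, t, band=0):
        return self._density

    def at(self, t, band=0):
        return SimpleNamespace(
            velocity=lambda p: self.velocity(p, t, band),
            density=lambda p: self.density(p, t, band),
        )


@pytest.fixture(scope="session")
def t0():
    return T0


@pytest.fixture(scope="session")
def uniform_case():
    """Zero-noise EU5 case: broad-front flow toward 41 deg at 10 m/s, 4 h."""
    return generate_case(
        layout="eu5",
        flow=FlowSpec(kind="uniform", speed=10.0, bearing_deg=41.0),
        start=T0,
        hours=4.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noisy_case():
    """Same flow with realistic measurement jitter."""
    return generate_case(
        layout="eu5",
        flow=FlowSpec(kind="uniform", speed=10.0, bearing_deg=41.0, noise_v=0.5, noise_density=0.1),
        start=T0,
        hours=2.0,
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
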
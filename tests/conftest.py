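"""Shared fixtures: tiny hand-built streams and reduced simulator configs."""

from __future__ import annotations

import numpy as np
import pytest

from ethoclock.core import BehaviorCatalog, EthogramStream, PhaseSchedule
from ethoclock.simulate import (
    DurationModel,
    PhaseParams,
    SimulatorConfig,
    default_calibration,
    simulate_stream,
)


@pytest.fixture
def catalog3() -> BehaviorCatalog:
    return BehaviorCatalog(("A", "B", "C"))


def make_stream(catalog, rows, total_s=None) -> EthogramStream:
    """Build a stream from (behavior, start_s, dur_s) rows."""
    beh, start, dur = (np.array(c, dtype=float) for c in zip(*rows))
    return EthogramStream(catalog, beh.astype(int), start, dur, total_s)


def alternating_stream(catalog, total_s, bout_s=1.5, behaviors=(0, 1)):
    """Day-only test stream cycling through the given behaviors."""
    n = int(np.ceil(total_s / bout_s))
    beh = np.array([behaviors[i % len(behaviors)] for i in range(n)])
    dur = np.full(n, bout_s)
    start = np.arange(n) * bout_s
    dur[-1] = total_s - start[-1]
    return EthogramStream(catalog, beh, start, dur, total_s)


def noise_injection_config(seed: int, n_inform: int = 4, contrast: float = 2.0,
                           noise_weight: float = 2.0, n_days: int = 1) -> SimulatorConfig:
    """Reduced strong-effect config with one pure-noise behavior appended.

    Informative behaviors alternate the direction of their day/night
    bout-frequency contrast.  Their count must be even so that the summed
    weights match across phases: only then is the ``noise`` behavior's
    relative frequency — and hence its composition share — truly identical
    in both phases (compositional closure would otherwise leak phase
    information into it).  The noise behavior is given a higher bout weight
    so its columns contribute visible variance without any signal.
    """
    if n_inform % 2:
        raise ValueError("n_inform must be even to keep the noise share phase-free")
    names = tuple(f"beh.{i}" for i in range(n_inform)) + ("noise",)
    k = len(names)
    w_day = np.ones(k)
    w_night = np.ones(k)
    w_day[-1] = w_night[-1] = noise_weight
    for i in range(n_inform):
        if i % 2 == 0:
            w_night[i] *= contrast
        else:
            w_day[i] *= contrast

    def params(w):
        P = np.tile(w / w.sum(), (k, 1))
        np.fill_diagonal(P, 0.0)
        P /= P.sum(axis=1, keepdims=True)
        dur = [DurationModel("lognormal", mu=float(np.log(1.2)), sigma=0.6,
                             min_s=0.03, max_s=60.0)] * k
        return PhaseParams(P, list(dur))

    return SimulatorConfig(
        BehaviorCatalog(names), params(w_day), params(w_night),
        PhaseSchedule(), n_days=n_days, fps=100.0 / 3.0, seed=seed,
    )


@pytest.fixture(scope="session")
def day1_calibrated_stream():
    """One simulated day under the default calibration (reused, seed 11)."""
    cfg = default_calibration(seed=11)
    return cfg, simulate_stream(cfg)
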
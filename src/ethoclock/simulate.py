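"""Circadian semi-Markov simulator of home-cage behavior streams.

The generator emulates the statistical structure of round-the-clock mouse
ethograms: behavior bouts with explicit (semi-Markov) durations, Markov
transitions between distinct behaviors, and phase-dependent parameters under
a 10-h day / 14-h night light cycle.  The default calibration reproduces the
headline summary statistics of real recordings: roughly 225 bouts per
fully-day 5-min window versus 263 per fully-night window, daytime-only long
sleep (bouts above 300 s about 2–3 times per day, capped at 460 s), a
0.03-s minimum bout duration, and an elevated exploratory repertoire (Dig,
Forage, Walk.Left, Turn, ...) at night.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import (
    DAY,
    NIGHT,
    SECONDS_PER_DAY,
    BehaviorCatalog,
    EthogramStream,
    PhaseSchedule,
)

__all__ = [
    "DurationModel",
    "PhaseParams",
    "SimulatorConfig",
    "simulate_stream",
    "make_null_config",
    "make_order_only_config",
    "default_calibration",
    "stationary_distribution",
]

_FAMILIES = ("lognormal", "gamma", "fixed")


@dataclass(frozen=True)
class DurationModel:
    """Clamped bout-duration distribution for one behavior in one phase.

    ``lognormal`` uses (mu, sigma) on the log scale; ``gamma`` uses
    (shape, scale); ``fixed`` emits ``value`` every time.  Samples are
    clamped into [min_s, max_s]; clamping rather than resampling keeps the
    bounds deterministic.
    """

    family: str = "lognormal"
    mu: float = 0.0
    sigma: float = 0.7
    shape: float = 1.0
    scale: float = 1.0
    value: float = 1.0
    min_s: float = 0.03
    max_s: float = 120.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown duration family {self.family!r}")
        if self.min_s <= 0:
            raise ValueError("min_s must be positive")
        if self.max_s < self.min_s:
            raise ValueError("max_s must be >= min_s")

    def mean(self) -> float:
        """Exact mean of the clamped distribution."""
        a, b = self.min_s, self.max_s
        if self.family == "fixed":
            return float(np.clip(self.value, a, b))
        if self.family == "lognormal":
            mu, s = self.mu, self.sigma
            if s == 0:
                return float(np.clip(np.exp(mu), a, b))
            za = (np.log(a) - mu) / s
            zb = (np.log(b) - mu) / s
            body = np.exp(mu + s * s / 2.0) * (
                stats.norm.cdf(zb - s) - stats.norm.cdf(za - s)
            )
            return float(a * stats.norm.cdf(za) + b * stats.norm.sf(zb) + body)
        # gamma: E[clip(X,a,b)] via the shape+1 identity
        k, th = self.shape, self.scale
        Fa = stats.gamma.cdf(a, k, scale=th)
        Fb = stats.gamma.cdf(b, k, scale=th)
        body = k * th * (stats.gamma.cdf(b, k + 1, scale=th) - stats.gamma.cdf(a, k + 1, scale=th))
        return float(a * Fa + b * (1.0 - Fb) + body)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed":
            out = np.full(n, self.value)
        elif self.family == "lognormal":
            out = np.exp(self.mu + self.sigma * rng.standard_normal(n))
        else:
            out = rng.gamma(self.shape, self.scale, n)
        return np.clip(out, self.min_s, self.max_s)


@dataclass
class PhaseParams:
    """Per-phase semi-Markov parameters over one behavior catalog."""

    transition: np.ndarray
    durations: list[DurationModel]

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=np.float64)
        self.validate()

    @property
    def size(self) -> int:
        return self.transition.shape[0]

    def validate(self) -> "PhaseParams":
        P = self.transition
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("transition must be a square matrix")
        if len(self.durations) != P.shape[0]:
            raise ValueError("need one DurationModel per behavior")
        if np.any(P < 0):
            raise ValueError("transition entries must be nonnegative")
        if np.any(np.diagonal(P) != 0.0):
            raise ValueError("transition diagonal must be exactly zero")
        rows = P.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(rows - 1.0)))
            raise ValueError(f"transition row {bad} sums to {rows[bad]}, expected 1")
        return self


@dataclass
class SimulatorConfig:
    """Everything needed to generate a stream reproducibly."""

    catalog: BehaviorCatalog
    day: PhaseParams
    night: PhaseParams
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    n_days: int = 1
    fps: float = 100.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.day.size != self.catalog.size or self.night.size != self.catalog.size:
            raise ValueError("phase params must match the catalog size")


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible row-stochastic matrix."""
    k = P.shape[0]
    A = np.vstack([P.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def simulate_stream(config: SimulatorConfig) -> EthogramStream:
    """Generate one ethogram stream from a simulator configuration.

    The process starts in a behavior drawn from the stationary composition
    of the starting phase.  Each bout's duration and the transition row used
    to pick the next behavior are governed by the phase at the *bout start*
    (a bout begun in the day keeps day parameters even if it crosses into
    night — which is how long daytime sleep can spill over).  The final bout
    is truncated (or minimally extended) so the stream ends exactly at
    ``n_days * 86400`` s.  Fully reproducible from ``config.seed``.
    """
    config.day.validate()
    config.night.validate()
    rng = np.random.default_rng(config.seed)
    total_s = config.n_days * SECONDS_PER_DAY
    sched = config.schedule
    k = config.catalog.size

    params = (config.day, config.night)  # indexed by DAY / NIGHT
    cum = tuple(np.cumsum(p.transition, axis=1) for p in params)
    # Flatten duration models into per-phase arrays for a cheap inner loop.
    fam = np.zeros((2, k), dtype=np.int8)  # 0 lognormal, 1 gamma, 2 fixed
    mu = np.zeros((2, k)); sg = np.zeros((2, k))
    gsh = np.ones((2, k)); gsc = np.ones((2, k))
    fxv = np.ones((2, k))
    lo = np.zeros((2, k)); hi = np.zeros((2, k))
    for p in (DAY, NIGHT):
        for b, dm in enumerate(params[p].durations):
            fam[p, b] = _FAMILIES.index(dm.family)
            mu[p, b], sg[p, b] = dm.mu, dm.sigma
            gsh[p, b], gsc[p, b] = dm.shape, dm.scale
            fxv[p, b] = dm.value
            lo[p, b], hi[p, b] = dm.min_s, dm.max_s

    day_len, period, day0 = sched.day_len_s, sched.period_s, sched.day_start_s

    BUF = 1 << 16
    zbuf = rng.standard_normal(BUF)
    ubuf = rng.random(BUF)
    zi = ui = 0

    est = int(total_s / max(0.2, np.exp(mu).min())) + 1000
    beh = np.empty(max(est, 1024), dtype=np.int64)
    dur = np.empty_like(beh, dtype=np.float64)

    t = 0.0
    phase = DAY if (0.0 - day0) % period < day_len else NIGHT
    cur = int(rng.choice(k, p=stationary_distribution(params[phase].transition)))
    i = 0
    min_overall = lo.min()
    while t < total_s:
        phase = DAY if (t - day0) % period < day_len else NIGHT
        f = fam[phase, cur]
        if f == 0:
            if zi >= BUF:
                zbuf = rng.standard_normal(BUF); zi = 0
            d = np.exp(mu[phase, cur] + sg[phase, cur] * zbuf[zi]); zi += 1
        elif f == 1:
            d = rng.gamma(gsh[phase, cur]) * gsc[phase, cur]
        else:
            d = fxv[phase, cur]
        if d < lo[phase, cur]:
            d = lo[phase, cur]
        elif d > hi[phase, cur]:
            d = hi[phase, cur]
        remaining = total_s - t
        if d >= remaining or remaining - d < min_overall:
            d = remaining  # truncate/extend the final bout to the exact end
        if i >= beh.size:
            beh = np.resize(beh, beh.size * 2)
            dur = np.resize(dur, dur.size * 2)
        beh[i] = cur
        dur[i] = d
        i += 1
        t += d
        if ui >= BUF:
            ubuf = rng.random(BUF); ui = 0
        cur = int(np.searchsorted(cum[phase][cur], ubuf[ui], side="right")); ui += 1
        if cur >= k:  # guard against u landing on the last cumulative edge
            cur = k - 1

    beh = beh[:i]
    dur = dur[:i]
    start = np.concatenate(([0.0], np.cumsum(dur)[:-1]))
    return EthogramStream(
        config.catalog, beh, start, dur, total_s, merge=True, validate=True
    )


def make_null_config(base: SimulatorConfig) -> SimulatorConfig:
    """Negative control: night parameters replaced by day parameters.

    Day/night labels then carry no behavioral signal; any classifier should
    sit at chance.  Idempotent.
    """
    return dataclasses.replace(base, night=copy.deepcopy(base.day))


def make_order_only_config(
    k: int,
    bout_s: float = 3.0,
    *,
    jitter_sigma: float = 0.75,
    n_days: int = 1,
    fps: float = 100.0 / 3.0,
    schedule: PhaseSchedule | None = None,
    seed: int = 0,
) -> SimulatorConfig:
    """Phases that differ *only* in the order of behaviors.

    Both phases cycle deterministically through ``k`` behaviors — the day
    phase in one cyclic order, the night phase in the reversed order — with
    identically distributed bout durations (lognormal around ``bout_s`` with
    log-scale spread ``jitter_sigma``, the same law in both phases for every
    behavior).  Single-position sample compositions are therefore identically
    distributed across phases, while the adjacent-pair (order) structure
    differs; only an order-aware model can tell the phases apart.

    Duration jitter is essential: with exactly fixed durations the windows
    collapse onto a handful of rotation patterns of the cycle whose
    positional phase a linear model can exploit.  ``jitter_sigma=0`` gives
    the fixed-duration variant.
    """
    if k < 3:
        raise ValueError("need at least 3 behaviors for distinguishable orders")
    catalog = BehaviorCatalog(tuple(f"state.{i:02d}" for i in range(k)))
    fwd = np.zeros((k, k))
    bwd = np.zeros((k, k))
    for i in range(k):
        fwd[i, (i + 1) % k] = 1.0
        bwd[i, (i - 1) % k] = 1.0
    if jitter_sigma > 0:
        mu = float(np.log(bout_s) - jitter_sigma**2 / 2.0)  # mean == bout_s
        dm = DurationModel("lognormal", mu=mu, sigma=jitter_sigma,
                           min_s=0.03, max_s=20.0 * bout_s)
    else:
        dm = DurationModel("fixed", value=bout_s, min_s=0.03, max_s=max(bout_s, 0.03))
    durations = [dm] * k
    return SimulatorConfig(
        catalog=catalog,
        day=PhaseParams(fwd, list(durations)),
        night=PhaseParams(bwd, list(durations)),
        schedule=schedule or PhaseSchedule(),
        n_days=n_days,
        fps=fps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Default calibration: the shipped 37-behavior day/night parameter set.

# Bout-frequency multipliers (relative to 1.0) applied on top of a uniform
# base weight.  Day: rest-phase repertoire.  Night: exploratory repertoire.
_DAY_WEIGHT = {
    "Twitch": 2.2, "Groom": 1.8, "Pause": 1.8, "Stationary": 1.8,
    "Remain.Low": 1.6, "Stretch": 1.3, "Stretch.Body": 1.3,
    "Hang.Cuddled": 1.4, "remain.Hang.Cuddled": 1.6, "Awaken": 1.3,
}
_NIGHT_WEIGHT = {
    "Dig": 2.6, "Forage": 2.6, "Walk.Left": 2.2, "Walk.Right": 2.0,
    "Walk.Slow": 1.6, "Turn": 2.2, "Circle": 1.5, "Sniff": 1.7,
    "Sniff.Object": 1.6, "Eat": 1.9, "Drink": 1.7, "Chew": 1.6,
    "Rear.Up": 1.7, "Run": 1.9, "Jump": 1.4, "Repeated.Jumping": 1.3,
    "Hang.Vertical": 1.3, "Remain.Hang.Vertical": 1.2, "Come.Down": 1.5,
    "Land.Vertical": 1.3,
}

# Nominal (median s, log-sigma) per behavior, before per-phase scaling.
_BASE_DUR = {
    "Twitch": (0.25, 0.6), "Awaken": (0.2, 0.6), "Groom": (2.5, 0.8),
    "Eat": (2.0, 0.8), "Drink": (1.2, 0.7), "Forage": (1.0, 0.8),
    "Dig": (0.5, 0.9), "Walk.Left": (0.8, 0.7), "Walk.Right": (0.8, 0.7),
    "Walk.Slow": (1.0, 0.7), "Turn": (0.4, 0.7), "Circle": (0.8, 0.7),
    "Sniff": (0.6, 0.7), "Chew": (1.2, 0.7), "Jump": (0.3, 0.5),
    "Repeated.Jumping": (0.8, 0.6), "Rear.Up": (0.5, 0.6),
    "Remain.Rear.Up": (1.0, 0.7), "Come.Down": (0.4, 0.5),
    "Land.Vertical": (0.2, 0.5), "Hang.Cuddled": (1.5, 0.8),
    "remain.Hang.Cuddled": (2.5, 0.9), "Hang.Vertical": (1.0, 0.7),
    "Remain.Hang.Vertical": (1.5, 0.8), "Stretch": (0.5, 0.5),
    "Stretch.Body": (0.6, 0.5), "Pause": (1.0, 0.8), "Remain.Low": (1.5, 0.8),
    "Stationary": (2.0, 0.9), "Urinate": (0.8, 0.5),
    "Come.Down.To.Partially.Reared": (0.5, 0.6),
    "Rear.Up.From.Partially.Reared": (0.5, 0.6),
    "Remain.Partially.Reared": (0.8, 0.7), "Unknown.Behavior": (0.5, 0.8),
    "Sniff.Object": (0.7, 0.7), "Run": (0.6, 0.6),
}

# Night-phase duration factor per behavior (before the global per-phase
# scale).  Values != 1 for most behaviors so that per-window durations of
# well over 20 activities separate day from night.
_NIGHT_DUR_FACTOR = {
    "Twitch": 0.7, "Awaken": 0.8, "Groom": 0.75, "Eat": 1.35, "Drink": 1.3,
    "Forage": 1.4, "Dig": 1.45, "Walk.Left": 1.35, "Walk.Right": 1.3,
    "Walk.Slow": 1.25, "Turn": 1.3, "Circle": 1.25, "Sniff": 1.3,
    "Chew": 1.25, "Jump": 1.2, "Repeated.Jumping": 1.25, "Rear.Up": 1.3,
    "Remain.Rear.Up": 1.25, "Come.Down": 1.2, "Land.Vertical": 1.2,
    "Hang.Cuddled": 0.75, "remain.Hang.Cuddled": 0.7, "Hang.Vertical": 1.2,
    "Remain.Hang.Vertical": 1.2, "Stretch": 0.8, "Stretch.Body": 0.8,
    "Pause": 0.75, "Remain.Low": 0.75, "Stationary": 0.7, "Urinate": 1.1,
    "Come.Down.To.Partially.Reared": 1.2, "Rear.Up.From.Partially.Reared": 1.2,
    "Remain.Partially.Reared": 1.2, "Unknown.Behavior": 1.0,
    "Sniff.Object": 1.25, "Run": 1.3,
}

# Target mean bout counts per fully-day / fully-night 5-min window.
_TARGET_DAY_BOUTS = 225.0
_TARGET_NIGHT_BOUTS = 263.0
_WINDOW_S = 300.0

#: Sleep bout-duration models.  Day sleep is heavy-tailed (log-normal,
#: median 12 s, sigma 1.25, capped at 460 s) so that bouts above 300 s occur
#: about 2–3 times per 10-h day; night sleep is lighter-tailed and capped at
#: 300 s, so sleep beyond 5 min happens only in the daytime.
_SLEEP_DAY = DurationModel("lognormal", mu=float(np.log(12.0)), sigma=1.25,
                           min_s=0.03, max_s=460.0)
_SLEEP_NIGHT = DurationModel("lognormal", mu=float(np.log(8.0)), sigma=0.9,
                             min_s=0.03, max_s=300.0)
_SLEEP_SHARE = {DAY: 0.020, NIGHT: 0.008}  # bout-frequency share of Sleep


def _weights(catalog: BehaviorCatalog, mult: dict, sleep_share: float) -> np.ndarray:
    w = np.ones(catalog.size)
    for name, m in mult.items():
        w[catalog.index(name)] = m
    si = catalog.index("Sleep")
    w[si] = 0.0
    w *= (1.0 - sleep_share) / w.sum()
    w[si] = sleep_share
    return w


def _transition_from_weights(w: np.ndarray) -> np.ndarray:
    k = w.size
    P = np.tile(w, (k, 1))
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _phase_params(
    catalog: BehaviorCatalog,
    weights: np.ndarray,
    sleep_model: DurationModel,
    dur_factor: dict,
    target_mean_bouts: float,
) -> PhaseParams:
    """Build phase params whose expected bout rate hits the target.

    Non-sleep log-normal medians are scaled by a common factor solved so
    that the stationary mean bout duration equals 300 s / target bouts.
    """
    P = _transition_from_weights(weights)
    pi = stationary_distribution(P)
    si = catalog.index("Sleep")
    target_mean_dur = _WINDOW_S / target_mean_bouts

    base = []
    for b, name in enumerate(catalog.names):
        if b == si:
            base.append(sleep_model)
            continue
        med, sig = _BASE_DUR.get(name, (0.8, 0.7))
        med = med * dur_factor.get(name, 1.0)
        base.append(DurationModel("lognormal", mu=float(np.log(med)), sigma=sig,
                                  min_s=0.03, max_s=120.0))

    def mean_dur(log_scale: float) -> float:
        tot = pi[si] * sleep_model.mean()
        for b, dm in enumerate(base):
            if b != si:
                tot += pi[b] * dataclasses.replace(dm, mu=dm.mu + log_scale).mean()
        return tot

    f = lambda ls: mean_dur(ls) - target_mean_dur
    log_scale = optimize.brentq(f, np.log(1e-3), np.log(1e3), xtol=1e-10)
    durations = [
        sleep_model if b == si else dataclasses.replace(dm, mu=dm.mu + log_scale)
        for b, dm in enumerate(base)
    ]
    return PhaseParams(P, durations)


def default_calibration(
    catalog: BehaviorCatalog | None = None,
    *,
    n_days: int = 1,
    fps: float = 100.0 / 3.0,
    seed: int = 0,
) -> SimulatorConfig:
    """The shipped day/night parameter set over the default 37-activity catalog.

    Day: frequent Sleep (heavy-tailed, occasionally >300 s), Twitch, Groom
    and quiescent postures.  Night: elevated exploratory repertoire and a
    higher bout rate.  Expected bouts per fully-day / fully-night 5-min
    window are solved analytically to 225 and 263 respectively.
    """
    catalog = catalog or BehaviorCatalog()
    if "Sleep" not in catalog.names:
        raise ValueError("default calibration requires a catalog containing 'Sleep'")
    day = _phase_params(
        catalog,
        _weights(catalog, _DAY_WEIGHT, _SLEEP_SHARE[DAY]),
        _SLEEP_DAY,
        {name: 1.0 for name in catalog.names},
        _TARGET_DAY_BOUTS,
    )
    night = _phase_params(
        catalog,
        _weights(catalog, _NIGHT_WEIGHT, _SLEEP_SHARE[NIGHT]),
        _SLEEP_NIGHT,
        _NIGHT_DUR_FACTOR,
        _TARGET_NIGHT_BOUTS,
    )
    return SimulatorConfig(
        catalog=catalog, day=day, night=night,
        schedule=PhaseSchedule(), n_days=n_days, fps=fps, seed=seed,
    )
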
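"""Closed-form solution of the master equation for deterministic rates.

For known (deterministic) schedules k_b(t), k_d(t) and zero initial mRNA the
chemical master equation of the birth-death process has the exact solution

    P(m, t) = exp(-mu(t)) * mu(t)**m / m!,

a Poisson law whose parameter solves  d(mu)/dt = k_b(t) - k_d(t) * mu  with
mu(0) = 0.  For piecewise-constant rates mu is advanced exactly segment by
segment; when a rate is itself random, the marginal output law is the mixture
of Poisson laws over rate-path draws.

This module also integrates the truncated master equation directly (matrix
exponentials per constant-rate segment) as an independent numerical oracle
for the stochastic simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .errors import InvalidParameterError, SignalRangeError
from .signal_gen import PulseSignal
from .simulate import ModelConfig, combined_schedule

__all__ = [
    "MuPath",
    "MixtureDistribution",
    "mu_path",
    "mu_time_average",
    "analytic_pmf",
    "mixture_pmf",
    "cycle_mean",
    "integrate_master_equation",
]


def _schedule(birth, death, t_max: float):
    config = ModelConfig(birth=birth, death=death, t_max=t_max, sample_dt=t_max)
    return combined_schedule(config)


def _advance_mu(mu0: float, kb: float, kd: float, dt: float) -> float:
    """Exact segment update of d(mu)/dt = kb - kd*mu over a span dt."""
    if kd > 0:
        target = kb / kd
        return target + (mu0 - target) * np.exp(-kd * dt)
    return mu0 + kb * dt


def _segment_mu_integral(mu0: float, kb: float, kd: float, dt: float) -> float:
    """Exact integral of mu(t) over one constant-rate segment of length dt."""
    if kd > 0:
        target = kb / kd
        return target * dt + (mu0 - target) * (1.0 - np.exp(-kd * dt)) / kd
    return mu0 * dt + 0.5 * kb * dt**2


@dataclass(frozen=True)
class MuPath:
    """Mean-count path mu(t) evaluated on a time grid."""

    times: np.ndarray
    mu: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t)
        if idx >= self.times.size or self.times[idx] != t:
            raise SignalRangeError(f"t={t!r} not on the evaluated grid")
        return float(self.mu[idx])


def mu_path(birth, death, times, mu0: float = 0.0) -> MuPath:
    """Solve d(mu)/dt = k_b(t) - k_d(t)*mu, mu(0)=mu0, exactly per segment.

    ``birth``/``death`` are constants or :class:`PulseSignal` schedules that
    must cover ``[0, max(times)]``; evaluation inside a segment uses the
    closed form mu(t) = kb/kd + (mu_seg - kb/kd) * exp(-kd (t - t_seg)).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return MuPath(times=times, mu=times.copy())
    if times.min() < 0:
        raise SignalRangeError("times must be >= 0")
    if np.any(np.diff(times) < 0):
        raise InvalidParameterError("times must be sorted ascending")
    t_max = float(times.max())
    if t_max == 0.0:
        return MuPath(times=times, mu=np.full(times.shape, mu0))
    for src in (birth, death):
        if isinstance(src, PulseSignal) and src.total_time < t_max:
            raise SignalRangeError("schedule does not cover the requested times")
    bounds, kb, kd = _schedule(birth, death, t_max)

    out = np.empty_like(times)
    mu_seg = float(mu0)
    ti = 0
    for i in range(kb.size):
        t0, t1 = bounds[i], bounds[i + 1]
        while ti < times.size and times[ti] <= t1:
            out[ti] = _advance_mu(mu_seg, kb[i], kd[i], times[ti] - t0)
            ti += 1
        mu_seg = _advance_mu(mu_seg, kb[i], kd[i], t1 - t0)
    while ti < times.size:  # times exactly at t_max fall out of the loop
        out[ti] = mu_seg
        ti += 1
    return MuPath(times=times, mu=out)


def mu_time_average(birth, death, t0: float, t1: float, mu0: float = 0.0) -> float:
    """Exact time average of mu(t) over the window [t0, t1], given mu(0)=mu0."""
    if not 0 <= t0 < t1:
        raise InvalidParameterError("need 0 <= t0 < t1")
    bounds, kb, kd = _schedule(birth, death, t1)
    mu = float(mu0)
    acc = 0.0
    for i in range(kb.size):
        a, b = bounds[i], bounds[i + 1]
        lo, hi = max(a, t0), min(b, t1)
        if lo < hi:
            mu_lo = _advance_mu(mu, kb[i], kd[i], lo - a)
            acc += _segment_mu_integral(mu_lo, kb[i], kd[i], hi - lo)
        mu = _advance_mu(mu, kb[i], kd[i], b - a)
    return acc / (t1 - t0)


def default_m_max(mu: float, tail_mass: float = 1e-12) -> int:
    """Smallest support bound with Poisson tail mass below ``tail_mass``."""
    if mu <= 0:
        return 0
    return int(stats.poisson.ppf(1.0 - tail_mass, mu)) + 1


def analytic_pmf(mu: float, m_max: int | None = None) -> np.ndarray:
    """Poisson(mu) pmf on 0..m_max — the exact law P(m, t) given mu(t)."""
    if mu < 0:
        raise InvalidParameterError(f"mu must be >= 0, got {mu!r}")
    if m_max is None:
        m_max = default_m_max(mu)
    return stats.poisson.pmf(np.arange(m_max + 1), mu)


@dataclass(frozen=True)
class MixtureDistribution:
    """Poisson mixture over random-rate draws: the marginal output law."""

    support: np.ndarray
    pmf: np.ndarray
    n_rate_draws: int

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))


def mixture_pmf(mu_draws, m_max: int | None = None) -> MixtureDistribution:
    """Average of Poisson pmfs over draws of mu(t) under a random input.

    ``mu_draws`` are values of mu at a common time under independent signal
    realizations; the returned mixture is the marginal P(m, t).
    """
    mu_draws = np.asarray(mu_draws, dtype=float)
    if mu_draws.size == 0:
        raise InvalidParameterError("need at least one rate-path draw")
    if np.any(mu_draws < 0):
        raise InvalidParameterError("mu draws must be >= 0")
    if m_max is None:
        m_max = default_m_max(float(mu_draws.max()))
    support = np.arange(m_max + 1)
    pmf = stats.poisson.pmf(support[None, :], mu_draws[:, None]).mean(axis=0)
    return MixtureDistribution(
        support=support, pmf=pmf, n_rate_draws=int(mu_draws.size)
    )


def cycle_mean(birth, death, period: float | None = None) -> float:
    """Time-averaged mu over one period at the periodic steady state.

    Propagates the affine per-period map mu(T) = A*mu(0) + B through the
    segments of one period, solves the fixed point mu* = B/(1-A), and
    integrates mu exactly over the period.  For periodic k_b with constant
    k_d this equals <k_b>/k_d.
    """
    if period is None:
        for src in (birth, death):
            if isinstance(src, PulseSignal) and src.params is not None:
                period = src.params.period
                break
    if period is None or period <= 0:
        raise InvalidParameterError("periodic schedules require a positive period")
    bounds, kb, kd = _schedule(birth, death, float(period))

    A, B = 1.0, 0.0  # mu_end = A*mu_start + B across processed segments
    for i in range(kb.size):
        dt = bounds[i + 1] - bounds[i]
        if kd[i] > 0:
            decay = np.exp(-kd[i] * dt)
            target = kb[i] / kd[i]
            A, B = A * decay, B * decay + target * (1.0 - decay)
        else:
            B = B + kb[i] * dt
    if A >= 1.0:
        raise InvalidParameterError(
            "death rate vanishes over the whole period; no periodic steady state"
        )
    mu_star = B / (1.0 - A)

    mu = mu_star
    acc = 0.0
    for i in range(kb.size):
        dt = bounds[i + 1] - bounds[i]
        acc += _segment_mu_integral(mu, kb[i], kd[i], dt)
        mu = _advance_mu(mu, kb[i], kd[i], dt)
    return acc / period


def _generator(kb: float, kd: float, m_max: int) -> np.ndarray:
    """Truncated birth-death generator on states 0..m_max (births off at top)."""
    n = m_max + 1
    Q = np.zeros((n, n))
    m = np.arange(n)
    Q[m[:-1], m[:-1] + 1] = kb
    Q[m[1:], m[1:] - 1] = kd * m[1:]
    Q[m, m] -= Q.sum(axis=1)
    return Q


def integrate_master_equation(
    config: ModelConfig, times, m_max: int = 60
) -> np.ndarray:
    """Direct numerical integration of the master equation, truncated at m_max.

    Uses a matrix exponential per constant-rate span (exact for the truncated
    system); returns pmf rows aligned with ``times``.  Serves as the
    independent oracle for :func:`pulsedecode.simulate.simulate_ensemble`.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0) or (times.size and times.min() < 0):
        raise InvalidParameterError("times must be sorted and >= 0")
    if times.size and times.max() > config.t_max:
        raise SignalRangeError("times beyond config.t_max")
    bounds, kb, kd = combined_schedule(config)

    p = np.zeros(m_max + 1)
    if config.m0 > m_max:
        raise InvalidParameterError("m0 exceeds the truncation bound")
    p[config.m0] = 1.0

    cache: dict[tuple, np.ndarray] = {}

    def propagate(vec, b, d, dt):
        if dt <= 0:
            return vec
        key = (round(b, 12), round(d, 12), round(dt, 12))
        if key not in cache:
            cache[key] = linalg.expm(_generator(b, d, m_max) * dt)
        return vec @ cache[key]

    out = np.empty((times.size, m_max + 1))
    ti = 0
    t_cur = 0.0
    for i in range(kb.size):
        seg_end = bounds[i + 1]
        while ti < times.size and times[ti] <= seg_end:
            p_q = propagate(p, kb[i], kd[i], times[ti] - t_cur)
            out[ti] = p_q
            p, t_cur = p_q, times[ti]
            ti += 1
        p = propagate(p, kb[i], kd[i], seg_end - t_cur)
        t_cur = seg_end
    while ti < times.size:
        out[ti] = p
        ti += 1
    return out
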
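"""Pulsatile, noisy input-signal generation.

The input to the gene model is a two-level square wave: a transcription rate
``k_b(t)`` or an mRNA degradation rate ``k_d(t)`` that alternates between an
upper and a lower branch.  Noise enters in one of two ways:

* **AM (amplitude modulation)** — branch widths are fixed, but within each
  branch the level is re-sampled every ``duration`` seconds from a
  moment-matched log-normal (or gamma) distribution with the branch mean and
  variance ``amplitude_variance``.
* **FM (frequency modulation)** — levels are fixed at the branch means, but
  successive branch widths are drawn from a moment-matched distribution whose
  squared coefficient of variation is ``frequency_noise``.

Signals are piecewise-constant rate schedules (left-closed, right-open
segments) so the downstream stochastic simulation stays exact.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, SignalRangeError

__all__ = [
    "SignalParams",
    "PulseSignal",
    "SignalSummary",
    "lognormal_from_moments",
    "moment_matched_sampler",
    "make_am_signal",
    "make_fm_signal",
    "make_signal",
    "deterministic_skeleton",
    "signal_value_at",
    "summarize_signal",
]

UPPER, LOWER = 0, 1
_BRANCH_NAMES = {UPPER: "upper", LOWER: "lower"}


@dataclass(frozen=True)
class SignalParams:
    """Parameters of a pulsatile input signal.

    ``on_time_mean`` / ``off_time_mean`` follow the regulatory convention:
    the ON state is the branch that produces *high mRNA*.  For transcription
    regulation that is the upper branch of ``k_b``; for degradation
    regulation it is the *lower* branch of ``k_d`` (a small decay rate means
    abundant mRNA).
    """

    upper_mean: float
    lower_mean: float
    on_time_mean: float
    off_time_mean: float
    total_time: float
    regulation_target: str = "transcription"
    modulation: str = "am"
    amplitude_variance: float = 0.0  # "Var": absolute variance of AM levels
    frequency_noise: float = 0.0  # "Noise": CV^2 of FM branch widths
    duration: float = 3.0  # "D": refresh interval of AM amplitude noise
    noise_family: str = "lognormal"

    def __post_init__(self):
        problems = []
        if not (self.upper_mean > self.lower_mean > 0):
            problems.append(
                f"need upper_mean > lower_mean > 0, got "
                f"{self.upper_mean!r} and {self.lower_mean!r}"
            )
        for name in ("on_time_mean", "off_time_mean", "duration", "total_time"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be > 0")
        if self.amplitude_variance < 0:
            problems.append("amplitude_variance must be >= 0")
        if self.frequency_noise < 0:
            problems.append("frequency_noise must be >= 0")
        if self.regulation_target not in ("transcription", "degradation"):
            problems.append(f"unknown regulation_target {self.regulation_target!r}")
        if self.modulation not in ("am", "fm"):
            problems.append(f"unknown modulation {self.modulation!r}")
        if self.noise_family not in ("lognormal", "gamma"):
            problems.append(f"unknown noise_family {self.noise_family!r}")
        if problems:
            raise InvalidParameterError("; ".join(problems))

    @property
    def period(self) -> float:
        """Nominal period T = ON-time mean + OFF-time mean."""
        return self.on_time_mean + self.off_time_mean

    @property
    def upper_width_mean(self) -> float:
        """Mean dwell time in the upper branch."""
        if self.regulation_target == "transcription":
            return self.on_time_mean
        return self.off_time_mean

    @property
    def lower_width_mean(self) -> float:
        """Mean dwell time in the lower branch."""
        if self.regulation_target == "transcription":
            return self.off_time_mean
        return self.on_time_mean

    def branch_for_state(self, state: str) -> int:
        """Map the physiological ON/OFF state onto the upper/lower branch."""
        on_branch = UPPER if self.regulation_target == "transcription" else LOWER
        if state == "on":
            return on_branch
        if state == "off":
            return 1 - on_branch
        raise InvalidParameterError(f"unknown state {state!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def lognormal_from_moments(mean: float, variance: float):
    """Sampler over positive rates with exact first two moments.

    Returns ``f(rng, size=None)`` drawing log-normal variates whose arithmetic
    mean is ``mean`` and whose variance is ``variance`` (log-scale shape
    ``sigma^2 = ln(1 + variance/mean^2)``).  ``variance == 0`` degenerates to
    the constant ``mean``.
    """
    return moment_matched_sampler(mean, variance, family="lognormal")


def moment_matched_sampler(mean: float, variance: float, family: str = "lognormal"):
    """Positive-valued sampler matching the requested mean and variance.

    ``family`` may be ``lognormal`` or ``gamma``; both are parameterized on
    the natural scale so swapping families preserves the first two moments.
    """
    if not mean > 0:
        raise InvalidParameterError(f"mean must be > 0, got {mean!r}")
    if variance < 0:
        raise InvalidParameterError(f"variance must be >= 0, got {variance!r}")

    if variance == 0:

        def constant(rng, size=None):
            if size is None:
                return mean
            return np.full(size, mean)

        return constant

    if family == "lognormal":
        sigma2 = np.log1p(variance / mean**2)
        sigma = np.sqrt(sigma2)
        mu = np.log(mean) - 0.5 * sigma2

        def sample_lognormal(rng, size=None):
            return rng.lognormal(mean=mu, sigma=sigma, size=size)

        return sample_lognormal

    if family == "gamma":
        shape = mean**2 / variance
        scale = variance / mean

        def sample_gamma(rng, size=None):
            return rng.gamma(shape=shape, scale=scale, size=size)

        return sample_gamma

    raise InvalidParameterError(f"unknown noise_family {family!r}")


@dataclass(frozen=True)
class PulseSignal:
    """Piecewise-constant rate schedule realizing k_b(t) or k_d(t).

    Segments are left-closed, right-open: segment ``i`` covers
    ``[start_times[i], start_times[i+1])`` and the last one runs to
    ``total_time``.
    """

    start_times: np.ndarray
    levels: np.ndarray
    branch_labels: np.ndarray  # 0 = upper branch, 1 = lower branch
    total_time: float
    params: SignalParams | None = None

    def __post_init__(self):
        st = np.asarray(self.start_times, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        lb = np.asarray(self.branch_labels, dtype=np.int8)
        object.__setattr__(self, "start_times", st)
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "branch_labels", lb)
        if st.size == 0 or st[0] != 0.0:
            raise InvalidParameterError("segments must start at time 0")
        if not (st.size == lv.size == lb.size):
            raise InvalidParameterError("segment arrays must have equal length")
        if np.any(np.diff(st) <= 0):
            raise InvalidParameterError("start_times must be strictly increasing")
        if st[-1] >= self.total_time:
            raise InvalidParameterError("last segment must start before total_time")
        if np.any(lv <= 0):
            raise InvalidParameterError("all levels must be > 0")

    @property
    def n_segments(self) -> int:
        return self.start_times.size

    @property
    def end_times(self) -> np.ndarray:
        return np.append(self.start_times[1:], self.total_time)

    @property
    def widths(self) -> np.ndarray:
        return self.end_times - self.start_times

    def value_at(self, t: float) -> float:
        """Rate level of the segment containing ``t`` (half-open segments)."""
        if not (0 <= t < self.total_time):
            raise SignalRangeError(
                f"t={t!r} outside signal domain [0, {self.total_time!r})"
            )
        idx = np.searchsorted(self.start_times, t, side="right") - 1
        return float(self.levels[idx])

    def values_at(self, times: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`value_at`."""
        times = np.asarray(times, dtype=float)
        if times.size and (times.min() < 0 or times.max() >= self.total_time):
            raise SignalRangeError("query times outside signal domain")
        idx = np.searchsorted(self.start_times, times, side="right") - 1
        return self.levels[idx]

    def branches_at(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if times.size and (times.min() < 0 or times.max() >= self.total_time):
            raise SignalRangeError("query times outside signal domain")
        idx = np.searchsorted(self.start_times, times, side="right") - 1
        return self.branch_labels[idx]

    # -- serialization -----------------------------------------------------

    def to_text(self) -> str:
        """Two-column table (start_time, level) with params in a header comment."""
        buf = io.StringIO()
        meta = {
            "total_time": self.total_time,
            "params": self.params.to_dict() if self.params is not None else None,
            "branch_labels": [int(b) for b in self.branch_labels],
        }
        buf.write("# pulsedecode signal v1 " + json.dumps(meta) + "\n")
        buf.write("start_time\tlevel\n")
        for t, lv in zip(self.start_times, self.levels):
            buf.write(f"{float(t)!r}\t{float(lv)!r}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "PulseSignal":
        lines = text.strip().splitlines()
        header = lines[0]
        prefix = "# pulsedecode signal v1 "
        if not header.startswith(prefix):
            raise InvalidParameterError("not a pulsedecode signal table")
        meta = json.loads(header[len(prefix):])
        rows = [ln.split("\t") for ln in lines[2:]]
        start_times = np.array([float(r[0]) for r in rows])
        levels = np.array([float(r[1]) for r in rows])
        params = (
            SignalParams(**meta["params"]) if meta["params"] is not None else None
        )
        return cls(
            start_times=start_times,
            levels=levels,
            branch_labels=np.array(meta["branch_labels"], dtype=np.int8),
            total_time=float(meta["total_time"]),
            params=params,
        )


def signal_value_at(signal: PulseSignal, t: float) -> float:
    """Module-level alias for :meth:`PulseSignal.value_at`."""
    return signal.value_at(t)


def _branch_means(params: SignalParams):
    return {UPPER: params.upper_mean, LOWER: params.lower_mean}


def _branch_widths(params: SignalParams):
    return {UPPER: params.upper_width_mean, LOWER: params.lower_width_mean}


def deterministic_skeleton(
    params: SignalParams, total_time: float | None = None
) -> PulseSignal:
    """Noise-free square wave with the branch means and mean widths."""
    zero = dataclasses.replace(
        params,
        amplitude_variance=0.0,
        frequency_noise=0.0,
        total_time=total_time if total_time is not None else params.total_time,
    )
    if zero.modulation == "am":
        return make_am_signal(zero, rng=0)
    return make_fm_signal(zero, rng=0)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def make_am_signal(params: SignalParams, rng) -> PulseSignal:
    """Amplitude-modulated pulse train.

    The square-wave skeleton has fixed branch widths; within each branch the
    level is re-sampled every ``params.duration`` seconds ("D") from the
    moment-matched noise family (mean = branch mean, variance = Var).  With
    Var = 0 the exact square wave is returned, one segment per branch,
    regardless of the seed.
    """
    if params.modulation != "am":
        raise InvalidParameterError("make_am_signal requires modulation='am'")
    rng = _as_rng(rng)
    means = _branch_means(params)
    widths = _branch_widths(params)
    var = params.amplitude_variance
    samplers = {
        b: moment_matched_sampler(means[b], var, params.noise_family)
        for b in (UPPER, LOWER)
    }

    starts, levels, labels = [], [], []
    t = 0.0
    branch = UPPER
    eps = 1e-12 * params.total_time
    while t < params.total_time - eps:
        branch_end = min(t + widths[branch], params.total_time)
        if var == 0:
            starts.append(t)
            levels.append(means[branch])
            labels.append(branch)
        else:
            s = t
            while s < branch_end - eps:
                starts.append(s)
                levels.append(float(samplers[branch](rng)))
                labels.append(branch)
                s += params.duration
        t += widths[branch]
        branch = 1 - branch

    return PulseSignal(
        start_times=np.array(starts),
        levels=np.array(levels),
        branch_labels=np.array(labels, dtype=np.int8),
        total_time=params.total_time,
        params=params,
    )


def make_fm_signal(params: SignalParams, rng) -> PulseSignal:
    """Frequency-modulated pulse train.

    Levels alternate exactly between the branch means; branch widths are drawn
    from the moment-matched noise family with mean = branch width mean and
    CV^2 = ``frequency_noise``.  Noise = 0 reduces to the deterministic square
    wave regardless of the seed.
    """
    if params.modulation != "fm":
        raise InvalidParameterError("make_fm_signal requires modulation='fm'")
    rng = _as_rng(rng)
    means = _branch_means(params)
    width_means = _branch_widths(params)
    cv2 = params.frequency_noise
    samplers = {
        b: moment_matched_sampler(
            width_means[b], cv2 * width_means[b] ** 2, params.noise_family
        )
        for b in (UPPER, LOWER)
    }

    starts, levels, labels = [], [], []
    t = 0.0
    branch = UPPER
    eps = 1e-12 * params.total_time
    while t < params.total_time - eps:
        starts.append(t)
        levels.append(means[branch])
        labels.append(branch)
        t += float(samplers[branch](rng)) if cv2 > 0 else width_means[branch]
        branch = 1 - branch

    return PulseSignal(
        start_times=np.array(starts),
        levels=np.array(levels),
        branch_labels=np.array(labels, dtype=np.int8),
        total_time=params.total_time,
        params=params,
    )


def make_signal(params: SignalParams, rng) -> PulseSignal:
    """Dispatch on ``params.modulation``."""
    if params.modulation == "am":
        return make_am_signal(params, rng)
    return make_fm_signal(params, rng)


@dataclass(frozen=True)
class SignalSummary:
    on_time_mean: float
    off_time_mean: float
    level_mean: float
    level_variance: float
    frequency_noise: float
    n_branches: int = 0


def _branch_runs(signal: PulseSignal):
    """Consecutive same-branch segments merged into (label, width) runs.

    The trailing, possibly truncated branch is dropped from width statistics.
    """
    labels = signal.branch_labels
    change = np.flatnonzero(np.diff(labels)) + 1
    run_starts = np.concatenate(([0], change))
    run_start_times = signal.start_times[run_starts]
    run_end_times = np.append(run_start_times[1:], signal.total_time)
    run_labels = labels[run_starts]
    widths = run_end_times - run_start_times
    # drop the final run: it is truncated at total_time
    return run_labels[:-1], widths[:-1]


def summarize_signal(signal: PulseSignal) -> SignalSummary:
    """Observed ON/OFF-time means, level moments and width noise of a signal.

    ON/OFF labelling follows ``params.regulation_target``: for transcription
    regulation ON is the upper branch, for degradation regulation ON is the
    lower branch (the one yielding high mRNA).  The level variance is the
    within-branch variance of segment levels, pooled over the two branches
    (i.e. an estimate of the AM "Var"); frequency noise is the pooled CV^2 of
    complete branch widths (the FM "Noise").
    """
    params = signal.params
    if params is None:
        raise InvalidParameterError("summarize_signal needs signal.params")
    run_labels, run_widths = _branch_runs(signal)
    if run_labels.size < 2:
        raise InvalidParameterError("signal must span at least one full cycle")

    on_branch = params.branch_for_state("on")
    on_widths = run_widths[run_labels == on_branch]
    off_widths = run_widths[run_labels != on_branch]

    seg_w = signal.widths
    level_mean = float(np.average(signal.levels, weights=seg_w))

    var_parts, cv2_parts = [], []
    for b in (UPPER, LOWER):
        lv = signal.levels[signal.branch_labels == b]
        if lv.size > 1:
            var_parts.append(float(np.var(lv, ddof=1)))
        w = run_widths[run_labels == b]
        if w.size > 1 and w.mean() > 0:
            cv2_parts.append(float(np.var(w, ddof=1) / w.mean() ** 2))

    return SignalSummary(
        on_time_mean=float(on_widths.mean()) if on_widths.size else float("nan"),
        off_time_mean=float(off_widths.mean()) if off_widths.size else float("nan"),
        level_mean=level_mean,
        level_variance=float(np.mean(var_parts)) if var_parts else 0.0,
        frequency_noise=float(np.mean(cv2_parts)) if cv2_parts else 0.0,
        n_branches=int(run_labels.size),
    )
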
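import numpy as np
import pytest
from scipy import stats

from conftest import tv_distance
from pulsedecode.analytic import analytic_pmf, integrate_master_equation, mu_path
from pulsedecode.errors import InvalidParameterError, SignalRangeError
from pulsedecode.signal_gen import SignalParams, make_am_signal
from pulsedecode.simulate import (
    ModelConfig,
    Trajectory,
    combined_schedule,
    sample_states,
    simulate_ensemble,
    simulate_trajectory,
)


def test_constant_rate_trajectory_reaches_stationary_mean():
    """Time-averaged count approaches k_b/k_d = 10 for constant rates."""
    config = ModelConfig(birth=0.5, death=0.05, t_max=20_000.0)
    traj = simulate_trajectory(config, rng_seed=4)
    counts = sample_states(traj, np.arange(500.0, 20_000.0, 5.0))
    assert counts.mean() == pytest.approx(10.0, abs=0.8)


def test_pure_death_is_monotone_and_absorbs_at_zero():
    config = ModelConfig(birth=0.0, death=0.5, t_max=200.0, m0=5)
    traj = simulate_trajectory(config, rng_seed=0)
    assert np.all(traj.event_signs == -1)
    assert traj.event_times.size == 5
    assert traj.final_count() == 0


def test_stationary_distribution_is_poisson():
    """Pooled stationary samples match Poisson(10), TV < 0.02 at ~1e5 samples."""
    config = ModelConfig(birth=0.5, death=0.05, t_max=200.0, m0=10, sample_dt=2.0)
    ens = simulate_ensemble(config, 2000, rng_seed=8)
    pooled = ens.counts[:, ens.times >= 100.0].ravel()
    m_max = max(int(pooled.max()), 30)
    pmf = np.bincount(pooled, minlength=m_max + 1) / pooled.size
    assert pooled.size >= 100_000
    assert tv_distance(pmf, analytic_pmf(10.0, m_max)) < 0.02


def test_sample_states_matches_event_replay():
    """Grid sampling equals a brute-force replay of the event list."""
    config = ModelConfig(birth=0.5, death=0.05, t_max=500.0, m0=3)
    traj = simulate_trajectory(config, rng_seed=17)
    times = np.sort(np.random.default_rng(0).uniform(0, 500.0, size=200))
    fast = sample_states(traj, times)
    for t, got in zip(times, fast):
        m = traj.m0
        for et, sign in zip(traj.event_times, traj.event_signs):
            if et <= t:
                m += int(sign)
            else:
                break
        assert got == m


def test_sample_states_right_continuous():
    traj = Trajectory(
        event_times=np.array([1.0]),
        event_signs=np.array([1], dtype=np.int8),
        m0=2,
        t_max=5.0,
    )
    assert sample_states(traj, [0.5])[0] == 2
    assert sample_states(traj, [1.0])[0] == 3  # value *after* the event
    with pytest.raises(SignalRangeError):
        sample_states(traj, [6.0])


def test_ensemble_matches_analytic_poisson_along_cycle(square_signal):
    """Conditional law is Poisson(mu(t)) exactly; simulation agrees in TV."""
    config = ModelConfig(birth=square_signal, death=0.05, t_max=200.0)
    ens = simulate_ensemble(config, 2000, rng_seed=2)
    check_times = np.array([50.0, 100.0, 150.0, 200.0])
    mus = mu_path(square_signal, 0.05, check_times).mu
    for t, mu in zip(check_times, mus):
        j = int(np.flatnonzero(ens.times == t)[0])
        m_max = max(int(ens.counts[:, j].max()), int(mu + 10))
        assert tv_distance(ens.pmf_at(j, m_max), analytic_pmf(mu, m_max)) < 0.05


def test_ensemble_matches_master_equation_everywhere(square_signal):
    """Simulated pmfs track direct master-equation integration at all grid times."""
    config = ModelConfig(birth=square_signal, death=0.05, t_max=200.0, sample_dt=10.0)
    ens = simulate_ensemble(config, 2000, rng_seed=3)
    exact = integrate_master_equation(config, ens.times, m_max=60)
    worst = max(
        tv_distance(ens.pmf_at(j, 60), exact[j]) for j in range(ens.times.size)
    )
    # MC tolerance: TV of a 2000-sample histogram vs Poisson(mu<=16) is
    # ~0.04 on average, <0.07 at the 99.9th percentile
    assert worst < 0.07


def test_first_event_time_follows_inhomogeneous_exponential_law():
    """Breakpoint-horizon redraws give the exact two-segment first-event law."""
    # rate jumps from a1 to a2 at t=1: survival S(t) = exp(-a1 t) then
    # exp(-a1 - a2 (t-1)); pure-birth process so the propensity is k_b only
    a1, a2, t_switch = 2.0, 0.3, 1.0
    sig = make_am_signal(
        SignalParams(a1, a2, t_switch, 50.0, 51.0), rng=0
    )
    config = ModelConfig(birth=sig, death=0.0, t_max=51.0)
    rng = np.random.default_rng(99)
    draws = np.array(
        [simulate_trajectory(config, rng).event_times[0] for _ in range(20_000)]
    )

    def cdf(t):
        t = np.asarray(t)
        return np.where(
            t < t_switch,
            1.0 - np.exp(-a1 * t),
            1.0 - np.exp(-a1 * t_switch - a2 * (t - t_switch)),
        )

    ks = stats.kstest(draws, cdf)
    assert ks.pvalue > 1e-3


def test_counts_non_negative_with_unit_jumps():
    sig = make_am_signal(
        SignalParams(0.8, 0.1, 50.0, 50.0, 500.0, amplitude_variance=0.01), rng=1
    )
    config = ModelConfig(birth=sig, death=0.05, t_max=400.0)
    traj = simulate_trajectory(config, rng_seed=23)
    counts = np.concatenate(([traj.m0], traj.counts_after_events))
    assert counts.min() >= 0
    assert set(np.unique(traj.event_signs)) <= {-1, 1}


def test_combined_schedule_merges_breakpoints(square_signal):
    config = ModelConfig(birth=square_signal, death=0.05, t_max=350.0)
    bounds, kb, kd = combined_schedule(config)
    assert bounds[0] == 0.0 and bounds[-1] == 350.0
    np.testing.assert_allclose(kb, [0.8, 0.1, 0.8, 0.1])
    np.testing.assert_allclose(kd, 0.05)


def test_config_validation():
    sig = make_am_signal(SignalParams(0.8, 0.1, 50.0, 50.0, 100.0), rng=0)
    with pytest.raises(InvalidParameterError):
        ModelConfig(birth=sig, death=sig, t_max=50.0)
    with pytest.raises(InvalidParameterError):
        ModelConfig(birth=sig, death=0.05, t_max=500.0)  # signal too short
    with pytest.raises(InvalidParameterError):
        ModelConfig(birth=0.5, death=0.05, t_max=100.0, m0=-1)
    with pytest.raises(InvalidParameterError):
        simulate_ensemble(ModelConfig(birth=0.5, death=0.05, t_max=10.0), 1, 0)


def test_ensemble_pmfs_normalized_and_deterministic():
    config = ModelConfig(birth=0.5, death=0.05, t_max=50.0, sample_dt=5.0)
    a = simulate_ensemble(config, 100, rng_seed=5)
    b = simulate_ensemble(config, 100, rng_seed=5)
    np.testing.assert_array_equal(a.counts, b.counts)
    pmf = a.pmf_matrix()
    np.testing.assert_allclose(pmf.sum(axis=1), 1.0, atol=1e-12)
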
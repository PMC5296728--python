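import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulsedecode.errors import InvalidParameterError, SignalRangeError
from pulsedecode.signal_gen import (
    PulseSignal,
    SignalParams,
    deterministic_skeleton,
    lognormal_from_moments,
    make_am_signal,
    make_fm_signal,
    moment_matched_sampler,
    signal_value_at,
    summarize_signal,
)


@pytest.mark.parametrize("family", ["lognormal", "gamma"])
@pytest.mark.parametrize("mean,variance", [(0.8, 0.01), (1.0, 1.0), (0.1, 0.001)])
def test_sampler_matches_requested_moments(family, mean, variance):
    """Moment-matched samplers reproduce the requested mean/variance (4 SE)."""
    sampler = moment_matched_sampler(mean, variance, family=family)
    rng = np.random.default_rng(1234)
    draws = sampler(rng, size=1_000_000)
    n = draws.size
    se_mean = draws.std(ddof=1) / np.sqrt(n)
    assert abs(draws.mean() - mean) < 4 * se_mean
    centered = (draws - draws.mean()) ** 2
    se_var = centered.std(ddof=1) / np.sqrt(n)
    assert abs(draws.var(ddof=1) - variance) < 4 * se_var
    assert np.all(draws > 0)


def test_lognormal_log_scale_shape():
    """mean = variance = 1 implies a log-scale variance of ln 2."""
    sampler = lognormal_from_moments(1.0, 1.0)
    rng = np.random.default_rng(7)
    draws = sampler(rng, size=1_000_000)
    log_var = np.log(draws).var(ddof=1)
    assert abs(log_var - np.log(2.0)) < 4 * np.log(2.0) / np.sqrt(draws.size / 2)


def test_zero_variance_sampler_is_constant():
    sampler = lognormal_from_moments(0.8, 0.0)
    rng = np.random.default_rng(0)
    assert sampler(rng) == 0.8
    assert np.all(sampler(rng, size=5) == 0.8)


@pytest.mark.parametrize("mean,variance", [(0.0, 0.1), (-1.0, 0.1), (1.0, -0.1)])
def test_sampler_rejects_bad_moments(mean, variance):
    with pytest.raises(InvalidParameterError):
        moment_matched_sampler(mean, variance)


def test_zero_noise_am_is_exact_square_wave(square_params):
    """Var = 0 gives the deterministic square wave: 0.8/0.1 alternating."""
    sig = make_am_signal(square_params, rng=0)
    assert sig.n_segments == 5  # 410 s cover: 4 full branches + a truncated one
    np.testing.assert_allclose(sig.levels[:4], [0.8, 0.1, 0.8, 0.1])
    np.testing.assert_allclose(sig.start_times[:4], [0.0, 100.0, 200.0, 300.0])


def test_zero_noise_signals_identical_across_seeds(square_params):
    a = make_am_signal(square_params, rng=1)
    b = make_am_signal(square_params, rng=999)
    np.testing.assert_array_equal(a.levels, b.levels)
    np.testing.assert_array_equal(a.start_times, b.start_times)
    fm_params = SignalParams(
        0.8, 0.1, 100.0, 100.0, 410.0, modulation="fm", frequency_noise=0.0
    )
    c = make_fm_signal(fm_params, rng=1)
    d = make_fm_signal(fm_params, rng=999)
    np.testing.assert_array_equal(c.levels, d.levels)
    np.testing.assert_array_equal(c.start_times, d.start_times)


def test_am_refresh_segment_count():
    """Var > 0 re-samples the level every D seconds: ceil(100/3) per branch."""
    params = SignalParams(
        0.8, 0.1, 100.0, 100.0, 200.0, amplitude_variance=0.01, duration=3.0
    )
    sig = make_am_signal(params, rng=5)
    upper = sig.branch_labels == 0
    assert upper.sum() == int(np.ceil(100 / 3))
    assert (~upper).sum() == int(np.ceil(100 / 3))
    assert np.all(sig.levels > 0)


def test_am_duration_longer_than_branch_gives_one_draw():
    params = SignalParams(
        0.8, 0.1, 50.0, 50.0, 200.0, amplitude_variance=0.01, duration=80.0
    )
    sig = make_am_signal(params, rng=5)
    # one segment per branch over 4 branches
    assert sig.n_segments == 4


def test_am_branch_levels_converge_to_branch_means():
    params = SignalParams(
        0.8, 0.1, 100.0, 100.0, 100_000.0, amplitude_variance=0.01, duration=3.0
    )
    sig = make_am_signal(params, rng=11)
    for branch, mean in ((0, 0.8), (1, 0.1)):
        levels = sig.levels[sig.branch_labels == branch]
        se = levels.std(ddof=1) / np.sqrt(levels.size)
        assert abs(levels.mean() - mean) < 4 * se


def test_fm_levels_take_only_branch_means():
    params = SignalParams(
        0.8, 0.1, 100.0, 100.0, 50_000.0, modulation="fm", frequency_noise=1.0
    )
    sig = make_fm_signal(params, rng=3)
    assert set(np.unique(sig.levels)) == {0.8, 0.1}


def test_fm_width_cv2_matches_noise():
    """Empirical CV^2 of sampled widths matches the requested Noise = 1."""
    sampler = moment_matched_sampler(100.0, 1.0 * 100.0**2)
    rng = np.random.default_rng(21)
    widths = sampler(rng, size=100_000)
    cv2 = widths.var(ddof=1) / widths.mean() ** 2
    # CV^2 of a lognormal with CV^2=1 has heavy sampling error; allow 10%
    assert abs(cv2 - 1.0) < 0.1


def test_signal_value_half_open_convention(square_signal):
    assert signal_value_at(square_signal, 50.0) == 0.8
    assert signal_value_at(square_signal, 100.0) == 0.1  # boundary -> next segment
    assert signal_value_at(square_signal, 0.0) == 0.8
    with pytest.raises(SignalRangeError):
        signal_value_at(square_signal, square_signal.total_time)
    with pytest.raises(SignalRangeError):
        signal_value_at(square_signal, -1.0)


@given(
    on=st.floats(10.0, 300.0),
    off=st.floats(10.0, 300.0),
    var=st.sampled_from([0.0, 0.001, 0.01]),
    noise=st.sampled_from([0.0, 0.1, 1.0]),
    modulation=st.sampled_from(["am", "fm"]),
    seed=st.integers(0, 2**31 - 1),
)
def test_segments_cover_total_time_exactly(on, off, var, noise, modulation, seed):
    """Concatenated segment widths always sum to total_time, gap-free."""
    params = SignalParams(
        0.8,
        0.1,
        on,
        off,
        3.3 * (on + off),
        modulation=modulation,
        amplitude_variance=var if modulation == "am" else 0.0,
        frequency_noise=noise if modulation == "fm" else 0.0,
        duration=3.0,
    )
    sig = make_am_signal(params, seed) if modulation == "am" else make_fm_signal(params, seed)
    assert sig.start_times[0] == 0.0
    assert np.all(np.diff(sig.start_times) > 0)
    assert sig.widths.sum() == pytest.approx(sig.total_time, rel=1e-12)
    assert np.all(sig.levels > 0)


def test_gamma_family_keeps_signal_moments():
    """Switching the noise family preserves the first two level moments."""
    base = dict(
        upper_mean=0.8,
        lower_mean=0.1,
        on_time_mean=100.0,
        off_time_mean=100.0,
        total_time=60_000.0,
        amplitude_variance=0.01,
        duration=3.0,
    )
    out = {}
    for family in ("lognormal", "gamma"):
        sig = make_am_signal(SignalParams(**base, noise_family=family), rng=2)
        upper = sig.levels[sig.branch_labels == 0]
        out[family] = (upper.mean(), upper.var(ddof=1))
    assert out["lognormal"][0] == pytest.approx(out["gamma"][0], abs=0.01)
    assert out["lognormal"][1] == pytest.approx(out["gamma"][1], abs=0.005)


def test_summary_square_wave(square_params):
    sig = make_am_signal(square_params, rng=0)
    summary = summarize_signal(sig)
    assert summary.on_time_mean == pytest.approx(100.0)
    assert summary.off_time_mean == pytest.approx(100.0)
    assert summary.level_variance == pytest.approx(0.0, abs=1e-12)
    assert summary.frequency_noise == 0.0


def test_summary_swaps_on_off_for_degradation_regulation():
    """Under degradation regulation the ON state is the *lower* branch."""
    params = SignalParams(
        0.1,
        0.025,
        on_time_mean=150.0,
        off_time_mean=50.0,
        total_time=650.0,
        regulation_target="degradation",
    )
    sig = make_am_signal(params, rng=0)
    # upper branch (high k_d) is the OFF state and has the off_time width
    assert sig.widths[0] == pytest.approx(50.0)
    summary = summarize_signal(sig)
    assert summary.on_time_mean == pytest.approx(150.0)
    assert summary.off_time_mean == pytest.approx(50.0)


def test_summary_fm_noise_estimate():
    params = SignalParams(
        0.8, 0.1, 100.0, 100.0, 200_000.0, modulation="fm", frequency_noise=1.0
    )
    sig = make_fm_signal(params, rng=9)
    summary = summarize_signal(sig)
    assert summary.frequency_noise == pytest.approx(1.0, abs=0.25)
    assert summary.on_time_mean == pytest.approx(100.0, rel=0.1)


def test_serialization_round_trip():
    params = SignalParams(
        0.8, 0.1, 100.0, 100.0, 600.0, amplitude_variance=0.01, duration=3.0
    )
    sig = make_am_signal(params, rng=13)
    clone = PulseSignal.from_text(sig.to_text())
    np.testing.assert_array_equal(sig.start_times, clone.start_times)
    np.testing.assert_array_equal(sig.levels, clone.levels)
    np.testing.assert_array_equal(sig.branch_labels, clone.branch_labels)
    assert sig.total_time == clone.total_time
    assert sig.params == clone.params


def test_invalid_params_rejected():
    with pytest.raises(InvalidParameterError):
        SignalParams(0.1, 0.8, 100.0, 100.0, 400.0)  # upper < lower
    with pytest.raises(InvalidParameterError):
        SignalParams(0.8, 0.1, -1.0, 100.0, 400.0)
    with pytest.raises(InvalidParameterError):
        SignalParams(0.8, 0.1, 100.0, 100.0, 400.0, amplitude_variance=-0.1)
    with pytest.raises(InvalidParameterError):
        SignalParams(0.8, 0.1, 100.0, 100.0, 400.0, noise_family="cauchy")


def test_skeleton_matches_zero_noise_signal():
    params = SignalParams(
        0.8, 0.1, 80.0, 120.0, 600.0, amplitude_variance=0.01, duration=3.0
    )
    skel = deterministic_skeleton(params)
    assert np.all(np.isin(skel.levels, [0.8, 0.1]))
    assert skel.widths[0] == pytest.approx(80.0)
    assert skel.widths[1] == pytest.approx(120.0)
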
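"""The dwell-time generator must reproduce the statistics the fits assume."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from smkinetics import (
    MixtureModel,
    ObservationWindow,
    SimulationConfig,
    fit_mixture,
    simulate_decay,
    simulate_dwells,
    simulate_traces,
)
from smkinetics.simulate import EmptyDatasetError

from conftest import truncated_mixture_cdf


class TestSimulateDwells:
    def test_single_exponential_mean(self):
        """The sample mean recovers the lifetime (up to the exact memoryless
        shift: left-truncation at t_min adds t_min to the mean, and round-up
        frame quantization adds about half a frame)."""
        data = simulate_dwells(
            MixtureModel([1.0], [5.0]),
            ObservationWindow(0.1, 10_000.0),
            SimulationConfig(n_events=20_000, seed=1),
        )
        assert data.durations.mean() - 0.1 - 0.05 == pytest.approx(5.0, rel=0.02)
        continuous = simulate_dwells(
            MixtureModel([1.0], [5.0]),
            ObservationWindow(0.1, 10_000.0),
            SimulationConfig(n_events=20_000, seed=1, frame_interval=None),
        )
        assert continuous.durations.mean() - 0.1 == pytest.approx(5.0, rel=0.02)

    def test_degenerate_weight_equals_single_component(self):
        """A zero-weight component must not change the distribution."""
        win = ObservationWindow(0.1, 180.0)
        cfg = SimulationConfig(n_events=5000, seed=3)
        two = simulate_dwells(MixtureModel([1.0, 0.0], [2.0, 60.0]), win, cfg)
        one = simulate_dwells(MixtureModel([1.0], [2.0]), win, cfg)
        ks = stats.ks_2samp(two.durations, one.durations)
        assert ks.pvalue > 0.01

    def test_empirical_cdf_matches_analytic_truncated_mixture(self):
        """Continuous-time draws agree with the closed-form truncated CDF (KS, α=0.01)."""
        data = simulate_dwells(
            MixtureModel([0.56, 0.44], [2.0, 60.0]),
            ObservationWindow(0.1, 180.0),
            SimulationConfig(n_events=10_000, seed=42, frame_interval=None),
        )
        ks = stats.kstest(
            data.durations,
            lambda t: truncated_mixture_cdf(t, [0.56, 0.44], [2.0, 60.0], 0.1, 180.0),
        )
        critical = 1.628 / math.sqrt(data.n)  # two-sided alpha = 0.01
        assert ks.statistic < critical

    def test_bleaching_adds_rates(self):
        """Competing photobleaching: observed rate = 1/tau + 1/tau_bleach."""
        data = simulate_dwells(
            MixtureModel([1.0], [60.0]),
            ObservationWindow(0.1, 1000.0),
            SimulationConfig(n_events=10_000, seed=5, bleach_lifetime=173.0),
        )
        fit = fit_mixture(data, 1, seed=5)
        expected = 1.0 / (1.0 / 60.0 + 1.0 / 173.0)  # ~44.5 s
        assert fit.model.lifetimes[0] == pytest.approx(expected, rel=0.05)

    def test_discard_fraction_matches_survival(self):
        """Losses below t_min match 1 - S(t_min) of the mixture (binomial error)."""
        w, tau = [0.8, 0.2], [0.3, 60.0]
        n = 20_000
        data = simulate_dwells(
            MixtureModel(w, tau),
            ObservationWindow(0.1, 180.0),
            SimulationConfig(n_events=n, seed=17),
        )
        p = 1.0 - sum(a * math.exp(-0.1 / t) for a, t in zip(w, tau))
        observed = data.n_discarded_short / n
        assert abs(observed - p) < 4.0 * math.sqrt(p * (1 - p) / n)

    def test_same_seed_bit_identical(self, model_no_crc, window):
        cfg = SimulationConfig(n_events=2000, seed=99)
        a = simulate_dwells(model_no_crc, window, cfg)
        b = simulate_dwells(model_no_crc, window, cfg)
        assert np.array_equal(a.durations, b.durations)
        assert np.array_equal(a.molecule_id, b.molecule_id)
        assert np.array_equal(a.start_s, b.start_s)

    def test_zero_survivors_names_filter(self):
        with pytest.raises(EmptyDatasetError, match="t_min"):
            simulate_dwells(
                MixtureModel([1.0], [0.001]),
                ObservationWindow(0.1, 180.0),
                SimulationConfig(n_events=50, seed=0),
            )

    def test_censoring_policies(self, model_no_crc):
        win = ObservationWindow(0.1, 30.0)  # short movie: many long events censored
        dropped = simulate_dwells(
            model_no_crc, win, SimulationConfig(n_events=5000, seed=2)
        )
        capped = simulate_dwells(
            model_no_crc, win,
            SimulationConfig(n_events=5000, seed=2, censoring_policy="cap_at_window"),
        )
        assert dropped.n_discarded_long > 0
        assert dropped.n < capped.n
        assert capped.durations.max() <= 30.0
        assert np.sum(capped.durations == 30.0) >= dropped.n_discarded_long

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 2**16),
        tau=st.floats(0.5, 100.0),
        frac=st.floats(0.05, 0.95),
    )
    def test_durations_in_window_and_frame_quantized(self, seed, tau, frac):
        win = ObservationWindow(0.1, 180.0)
        data = simulate_dwells(
            MixtureModel([frac, 1 - frac], [tau, 2 * tau]),
            win,
            SimulationConfig(n_events=300, seed=seed),
        )
        assert np.all(data.durations >= win.t_min)
        assert np.all(data.durations <= win.t_max)
        frames = data.durations / 0.1
        assert np.allclose(frames, np.round(frames), atol=1e-9)


class TestSimulateTraces:
    def test_single_event_renders_one_run(self):
        cfg = SimulationConfig(n_events=1, frame_interval=0.1, seed=0)
        traces = simulate_traces({"m0": [(1.0, 2.0)]}, cfg, snr=100.0, recording_s=5.0)
        arr = traces.traces["m0"]
        above = arr > 150.0  # halfway between baseline and bound level
        runs = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        assert above.sum() == 10
        assert len(runs) == 2  # exactly one contiguous run

    def test_empty_schedule_is_all_noise(self):
        cfg = SimulationConfig(n_events=1, frame_interval=0.1, seed=1)
        traces = simulate_traces({"m0": []}, cfg, snr=10.0, recording_s=10.0)
        arr = traces.traces["m0"]
        # baseline 100, noise sd 10: staying below the bound level (200) is ~10 sigma
        assert np.all(arr < 200.0)

    def test_overlapping_events_rejected(self):
        cfg = SimulationConfig(n_events=1, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            simulate_traces({"m0": [(1.0, 3.0), (2.0, 4.0)]}, cfg)

    def test_event_outside_recording_rejected(self):
        cfg = SimulationConfig(n_events=1, seed=0)
        with pytest.raises(ValueError, match="outside"):
            simulate_traces({"m0": [(170.0, 200.0)]}, cfg, recording_s=180.0)


class TestSimulateDecay:
    @pytest.mark.parametrize(
        "half_life, t, shape, expected",
        [
            (1.0, 1.0, "first_order", 50.0),
            (10.0, 10.0, "linear", 50.0),
            (1.7, 5.1, "first_order", 12.5),  # three half-lives
        ],
    )
    def test_noiseless_percent(self, half_life, t, shape, expected):
        series = simulate_decay(half_life, [0.0, t], shape=shape)
        from smkinetics import normalize_to_reference

        norm = normalize_to_reference(series)
        assert norm.percent_remaining[1] == pytest.approx(expected, rel=1e-9)

    def test_times_must_start_at_zero(self):
        with pytest.raises(ValueError, match="start at 0"):
            simulate_decay(1.0, [1.0, 2.0])

    def test_noise_is_seeded(self):
        a = simulate_decay(1.7, list(range(9)), noise_sd=5.0, seed=4)
        b = simulate_decay(1.7, list(range(9)), noise_sd=5.0, seed=4)
        assert np.array_equal(a.target_signal, b.target_signal)
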
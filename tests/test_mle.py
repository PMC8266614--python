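"""Truncated-mixture likelihood and its maximizer, checked against closed forms,
naive summation, and brute-force grid search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from smkinetics import (
    DwellDataset,
    MixtureModel,
    ObservationWindow,
    SimulationConfig,
    fit_mixture,
    neg_log_likelihood,
    select_K,
    simulate_dwells,
    truncated_cdf,
    truncated_pdf,
)
from smkinetics.mle import FitError


class TestTruncatedPdf:
    def test_single_component_closed_form(self):
        """K=1, tau=2, near-infinite window: (1/2) e^-1 / e^-0.05."""
        value = truncated_pdf(
            2.0, MixtureModel([1.0], [2.0]), ObservationWindow(0.1, 1e9)
        )
        assert value == pytest.approx(0.5 * math.exp(-1.0) / math.exp(-0.05), rel=1e-12)

    def test_two_component_against_direct_formula(self):
        """Frozen value from an independent evaluation of the truncated density."""
        # sum_k (w_k/tau_k) e^(-1/tau_k) / sum_k w_k (e^(-0.1/tau_k) - e^(-180/tau_k))
        value = truncated_pdf(
            1.0, MixtureModel([0.56, 0.44], [2.0, 60.0]), ObservationWindow(0.1, 180.0)
        )
        assert value == pytest.approx(0.186348941765, abs=1e-11)

    def test_normalizes_over_window(self):
        model = MixtureModel([0.56, 0.44], [2.0, 60.0])
        win = ObservationWindow(0.1, 180.0)
        integral, _ = quad(lambda t: truncated_pdf(t, model, win), 0.1, 180.0,
                           limit=200)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_outside_window_is_domain_error(self):
        model = MixtureModel([1.0], [2.0])
        win = ObservationWindow(0.1, 180.0)
        for t in (0.05, 181.0):
            with pytest.raises(ValueError, match="window"):
                truncated_pdf(t, model, win)
            with pytest.raises(ValueError, match="window"):
                truncated_cdf(t, model, win)

    @settings(max_examples=40, deadline=None)
    @given(
        w1=st.floats(0.01, 0.99),
        tau1=st.floats(0.2, 20.0),
        ratio=st.floats(1.5, 100.0),
    )
    def test_normalization_property(self, w1, tau1, ratio):
        """The truncated density integrates to 1 for any valid two-component model."""
        model = MixtureModel([w1, 1 - w1], [tau1, tau1 * ratio])
        win = ObservationWindow(0.1, 180.0)
        integral, _ = quad(lambda t: truncated_pdf(t, model, win), 0.1, 180.0,
                           limit=200)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_cdf_endpoints(self):
        model = MixtureModel([0.3, 0.7], [1.0, 30.0])
        win = ObservationWindow(0.1, 180.0)
        assert truncated_cdf(0.1, model, win) == pytest.approx(0.0, abs=1e-12)
        assert truncated_cdf(180.0, model, win) == pytest.approx(1.0, abs=1e-12)


class TestNegLogLikelihood:
    def test_single_event(self):
        win = ObservationWindow(0.1, 180.0)
        model = MixtureModel([1.0], [5.0])
        data = DwellDataset(np.array([3.0]), "x", win)
        assert neg_log_likelihood(data, model) == pytest.approx(
            -math.log(truncated_pdf(3.0, model, win)), rel=1e-12
        )

    def test_additivity_under_duplication(self, dwells_no_crc, model_no_crc):
        doubled = DwellDataset(
            np.concatenate([dwells_no_crc.durations, dwells_no_crc.durations]),
            "x",
            dwells_no_crc.window,
        )
        single = neg_log_likelihood(dwells_no_crc, model_no_crc)
        assert neg_log_likelihood(doubled, model_no_crc) == pytest.approx(
            2 * single, rel=1e-12
        )

    def test_against_naive_summation(self, window):
        """Vectorized nll equals an event-by-event python-float summation."""
        data = simulate_dwells(
            MixtureModel([0.5, 0.5], [2.0, 60.0]),
            window,
            SimulationConfig(n_events=100, seed=21),
        )
        model = MixtureModel([0.5, 0.5], [2.0, 60.0])
        e = math.exp
        Z = sum(
            w * (e(-0.1 / tau) - e(-180.0 / tau))
            for w, tau in zip(model.weights, model.lifetimes)
        )
        naive = -sum(
            math.log(
                sum(w / tau * e(-t / tau) for w, tau in zip(model.weights, model.lifetimes))
                / Z
            )
            for t in data.durations
        )
        assert neg_log_likelihood(data, model) == pytest.approx(naive, rel=1e-9)

    def test_out_of_window_rows_reported(self, window):
        data = DwellDataset(np.array([1.0, 500.0, 2.0]), "x", window)
        with pytest.raises(ValueError, match="1"):
            neg_log_likelihood(data, MixtureModel([1.0], [5.0]))


class TestFitMixture:
    def test_matches_grid_search_oracle(self):
        """K=1 numeric MLE agrees with a dense brute-force grid over tau."""
        win = ObservationWindow(0.1, 1e6)
        data = simulate_dwells(
            MixtureModel([1.0], [5.0]), win, SimulationConfig(n_events=5000, seed=4)
        )
        fit = fit_mixture(data, 1, seed=4)
        # grid oracle via the K=1 sufficient statistics (n, sum t)
        taus = 0.1 * 1.001 ** np.arange(int(math.log(1000.0) / math.log(1.001)) + 1)
        z = np.exp(-0.1 / taus) - np.exp(-1e6 / taus)
        nll = data.n * np.log(taus) + data.durations.sum() / taus + data.n * np.log(z)
        tau_grid = taus[np.argmin(nll)]
        assert fit.model.lifetimes[0] == pytest.approx(tau_grid, rel=0.03)

    def test_two_state_recovery(self, model_no_crc, window):
        """The ~2 s / ~60 s two-state regime is recovered from 5000 events."""
        data = simulate_dwells(
            model_no_crc, window, SimulationConfig(n_events=5000, seed=0)
        )
        fit = fit_mixture(data, 2, seed=0)
        assert fit.converged
        assert fit.model.lifetimes[0] == pytest.approx(2.0, rel=0.15)
        assert fit.model.lifetimes[1] == pytest.approx(60.0, rel=0.15)
        assert fit.model.weights[0] == pytest.approx(0.56, abs=0.05)

    def test_three_state_long_weight(self, model_mutant, window):
        """The mutant-like three-state model: long-lived weight recovered."""
        data = simulate_dwells(
            model_mutant, window, SimulationConfig(n_events=8000, seed=11)
        )
        fit = fit_mixture(data, 3, seed=11)
        assert fit.model.weights[2] == pytest.approx(0.14, abs=0.05)

    def test_lifetimes_sorted_ascending(self, dwells_no_crc):
        fit = fit_mixture(dwells_no_crc, 2, seed=5)
        assert list(fit.model.lifetimes) == sorted(fit.model.lifetimes)

    def test_optimum_beats_truth(self, window):
        """Fitted likelihood >= likelihood at the generating parameters."""
        for seed in range(3):
            truth = MixtureModel([0.56, 0.44], [2.0, 60.0])
            data = simulate_dwells(
                truth, window, SimulationConfig(n_events=2000, seed=seed)
            )
            fit = fit_mixture(data, 2, seed=seed)
            assert fit.log_likelihood >= -neg_log_likelihood(data, truth) - 1e-6

    def test_quantization_bias_at_two_frames(self):
        """Continuous likelihood on 0.1-s-quantized data overestimates a 0.2 s
        lifetime by roughly a quarter — the documented cost of fitting
        frame-quantized dwells with a continuous density."""
        data = simulate_dwells(
            MixtureModel([1.0], [0.2]),
            ObservationWindow(0.1, 180.0),
            SimulationConfig(n_events=20_000, seed=9),
        )
        fit = fit_mixture(data, 1, seed=9)
        bias = fit.model.lifetimes[0] - 0.2
        assert 0.0 < bias < 0.08  # positive, bounded; ~+28% at tau = 2 frames

    def test_too_few_events_guard(self, window):
        data = DwellDataset(np.linspace(0.2, 5.0, 15), "x", window)
        with pytest.raises(ValueError, match="too few"):
            fit_mixture(data, 2)

    def test_all_starts_failing_carries_diagnostics(self, dwells_no_crc):
        with pytest.raises(FitError) as err:
            fit_mixture(dwells_no_crc, 2, seed=0, max_iter=0)
        assert len(err.value.diagnostics) >= 1
        assert all("nll" in d for d in err.value.diagnostics)

    def test_deterministic_given_seed(self, dwells_no_crc):
        a = fit_mixture(dwells_no_crc, 2, seed=7)
        b = fit_mixture(dwells_no_crc, 2, seed=7)
        assert a.model.as_dict() == b.model.as_dict()
        assert a.log_likelihood == b.log_likelihood


class TestSelectK:
    def test_pure_exponential_selects_one(self, window):
        data = simulate_dwells(
            MixtureModel([1.0], [5.0]), window, SimulationConfig(n_events=5000, seed=2)
        )
        assert select_K(data, (1, 2, 3), seed=2).K == 1

    def test_two_state_selects_two(self, dwells_no_crc):
        fit = select_K(dwells_no_crc, (1, 2, 3), seed=0)
        assert fit.K == 2
        assert len(fit.k_table) == 3
        # BIC ordering is the implementation's own table; sanity-check against a
        # likelihood-ratio oracle: K=2 must beat K=1 by far more than the 2-dof
        # penalty difference.
        by_k = {row["K"]: row for row in fit.k_table}
        lr = 2 * (by_k[2]["log_likelihood"] - by_k[1]["log_likelihood"])
        assert lr > 2 * math.log(dwells_no_crc.n)

    def test_three_state_selects_three(self, window):
        data = simulate_dwells(
            MixtureModel([0.5, 0.3, 0.2], [0.2, 2.0, 60.0]),
            window,
            SimulationConfig(n_events=10_000, seed=6),
        )
        assert select_K(data, (1, 2, 3), seed=6).K == 3

    def test_rejects_unsupported_k(self, dwells_no_crc):
        with pytest.raises(ValueError, match="candidate"):
            select_K(dwells_no_crc, (1, 5))


def test_rmse_shrinks_with_sample_size():
    """RMSE of the short-component weight shrinks from n=500 to n=5000."""
    win = ObservationWindow(0.1, 180.0)
    truth = MixtureModel([0.56, 0.44], [2.0, 60.0])
    rmse = {}
    for n in (500, 5000):
        errs = []
        for seed in range(10):
            data = simulate_dwells(truth, win, SimulationConfig(n_events=n, seed=seed))
            fit = fit_mixture(data, 2, n_starts=8, seed=seed)
            errs.append((fit.model.weights[0] - 0.56) ** 2)
        rmse[n] = math.sqrt(np.mean(errs))
    assert rmse[5000] < rmse[500]
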
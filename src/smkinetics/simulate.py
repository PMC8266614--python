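"""Synthetic single-molecule binding data and mRNA decay time courses.

The generator emulates the statistical structure of a TIRF co-localization
binding assay: dwell times drawn from an exponential mixture, a competing
photobleaching exponential, quantization to the camera frame clock, loss of
sub-resolution events, and an observation window that ends with the movie.
It also produces rifampicin-chase decay curves (first-order or linear) as
target/reference signal pairs so the normalization step can be exercised.
"""

from __future__ import annotations

import math

import numpy as np

from .models import (
    DecaySeries,
    DwellDataset,
    MixtureModel,
    ObservationWindow,
    SimulationConfig,
    TraceSet,
)

__all__ = ["simulate_dwells", "simulate_traces", "simulate_decay"]

# Linear percent-remaining curves are floored here so a log transform of the
# series stays defined; well below any real signal.
_LINEAR_FLOOR_PERCENT = 1e-3


class EmptyDatasetError(RuntimeError):
    """All simulated events were removed by a filter."""


def simulate_dwells(
    model: MixtureModel,
    window: ObservationWindow,
    config: SimulationConfig,
    condition: str = "synthetic",
) -> DwellDataset:
    """Draw dwell times from an exponential mixture through an observation window.

    Each of ``config.n_events`` raw events picks component ``k`` with probability
    ``weights[k]`` and draws a duration from ``Exponential(lifetimes[k])``.  When
    photobleaching is enabled the observed duration is the minimum of the binding
    duration and an independent ``Exponential(bleach_lifetime)`` draw.  Events
    shorter than ``window.t_min`` are discarded (they fall below the resolution
    of the recording), then survivors are rounded *up* to the next full frame —
    an event must occupy a frame to be seen.  Events outlasting ``window.t_max``
    are discarded (``drop_incomplete``, the default) or truncated to ``t_max``
    (``cap_at_window``).

    Returns a :class:`DwellDataset` whose ``n_discarded_short`` / ``n_discarded_long``
    record the losses; raises :class:`EmptyDatasetError` if nothing survives.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_events

    comps = rng.choice(model.K, size=n, p=np.asarray(model.weights))
    durations = rng.exponential(np.asarray(model.lifetimes)[comps])
    if config.bleach_lifetime is not None:
        bleach = rng.exponential(config.bleach_lifetime, size=n)
        durations = np.minimum(durations, bleach)

    # Sub-resolution loss happens on the true (continuous) duration, before the
    # camera clock rounds anything: the discard fraction then matches the
    # mixture's 1 - S(t_min) exactly.
    visible = durations >= window.t_min
    n_short = int(n - visible.sum())
    durations = durations[visible]

    if config.frame_interval is not None:
        dt = config.frame_interval
        durations = np.ceil(durations / dt - 1e-12) * dt

    over = durations > window.t_max
    if config.censoring_policy == "drop_incomplete":
        n_long = int(over.sum())
        durations = durations[~over]
    else:  # cap_at_window
        n_long = 0
        durations = np.minimum(durations, window.t_max)

    if durations.size == 0:
        raise EmptyDatasetError(
            f"no events survived: {n_short} below t_min={window.t_min}, "
            f"{n_long} beyond t_max={window.t_max} "
            f"(policy={config.censoring_policy})"
        )

    # Rastergram plumbing: spread events over molecules with uniform starts.
    n_mol = config.n_molecules or max(1, durations.size // 10)
    molecule_id = rng.integers(0, n_mol, size=durations.size)
    slack = np.maximum(window.t_max - durations, 0.0)
    start_s = rng.uniform(0.0, 1.0, size=durations.size) * slack

    return DwellDataset(
        durations=durations,
        condition=condition,
        window=window,
        molecule_id=molecule_id,
        start_s=start_s,
        n_discarded_short=n_short,
        n_discarded_long=n_long,
    )


def simulate_traces(
    schedule: dict[str, list[tuple[float, float]]],
    config: SimulationConfig,
    snr: float = 10.0,
    recording_s: float = 180.0,
    baseline: float = 100.0,
    amplitude: float = 100.0,
) -> TraceSet:
    """Render ground-truth event schedules into noisy per-frame intensity traces.

    ``schedule`` maps trace id -> list of (start_s, end_s) bound intervals.
    Per-frame intensity is ``baseline + amplitude`` while bound, ``baseline``
    otherwise, plus Gaussian noise of standard deviation ``amplitude / snr``.
    A frame counts as bound when the event covers its midpoint.  Overlapping
    events on one molecule are rejected; the schedule is retained as ground
    truth for validating the event caller.
    """
    if snr <= 0:
        raise ValueError(f"snr must be positive, got {snr}")
    dt = config.frame_interval
    if dt is None:
        raise ValueError("trace synthesis needs a frame_interval")
    n_frames = int(round(recording_s / dt))
    rng = np.random.default_rng(config.seed)
    noise_sd = amplitude / snr

    traces: dict[str, np.ndarray] = {}
    truth: dict[str, list[tuple[float, float]]] = {}
    mid = (np.arange(n_frames) + 0.5) * dt
    for trace_id, events in schedule.items():
        events = sorted(events)
        for (s0, e0), (s1, e1) in zip(events, events[1:]):
            if s1 < e0:
                raise ValueError(
                    f"trace {trace_id!r}: overlapping events ({s0}, {e0}) and ({s1}, {e1})"
                )
        for s, e in events:
            if not (0.0 <= s < e <= recording_s):
                raise ValueError(
                    f"trace {trace_id!r}: event ({s}, {e}) outside recording [0, {recording_s}]"
                )
        bound = np.zeros(n_frames, dtype=bool)
        for s, e in events:
            bound |= (mid >= s) & (mid < e)
        intensity = baseline + amplitude * bound + rng.normal(0.0, noise_sd, n_frames)
        traces[trace_id] = intensity
        truth[trace_id] = list(events)

    return TraceSet(traces=traces, frame_interval=dt, ground_truth_events=truth)


def simulate_decay(
    half_life: float,
    times: "np.ndarray | list[float]",
    shape: str = "first_order",
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_level: float = 1000.0,
    target_level: float = 1000.0,
    label: str = "",
) -> DecaySeries:
    """Generate a rifampicin-chase series with a known half-life.

    ``first_order`` gives ``percent(t) = 100 exp(-(ln 2 / t_half) t)``; ``linear``
    gives ``percent(t) = 100 - (50 / t_half) t`` floored at a small positive
    value.  ``noise_sd`` (percent of signal) applies independent multiplicative
    Gaussian noise to target and reference signals, emulating gel-band
    quantification error.  The target/reference pair is constructed so that
    reference-normalization recovers ``percent`` (exactly, when noiseless).
    """
    if half_life <= 0:
        raise ValueError(f"half_life must be positive, got {half_life}")
    times = np.asarray(times, dtype=float)
    if times.size < 2 or times[0] != 0.0:
        raise ValueError("times must start at 0 and contain at least two points")

    if shape == "first_order":
        percent = 100.0 * np.exp(-(math.log(2.0) / half_life) * times)
    elif shape == "linear":
        percent = np.maximum(100.0 - (50.0 / half_life) * times, _LINEAR_FLOOR_PERCENT)
    else:
        raise ValueError(f"unknown decay shape {shape!r}")

    rng = np.random.default_rng(seed)
    reference = np.full_like(times, float(reference_level))
    target = target_level * percent / 100.0
    if noise_sd > 0:
        target = target * (1.0 + rng.normal(0.0, noise_sd / 100.0, times.size))
        reference = reference * (1.0 + rng.normal(0.0, noise_sd / 100.0, times.size))
        target = np.maximum(target, 1e-9 * target_level)
        reference = np.maximum(reference, 1e-9 * reference_level)

    return DecaySeries(
        times=times,
        target_signal=target,
        reference_signal=reference,
        label=label or f"{shape}_t12={half_life}",
    )
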
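"""Core domain types for single-molecule dwell-time kinetics.

The central objects are a :class:`MixtureModel` (the weights and characteristic
lifetimes of a K-exponential dwell-time process), an :class:`ObservationWindow`
(the minimum resolvable interval ``t_min`` and the maximum observable duration
``t_max`` of a recording), and a :class:`DwellDataset` (the observed bound-interval
durations for one condition — the unit of fitting).  Dwell-time densities are
always normalized over ``[t_min, t_max]``: an event shorter than one frame is
invisible and an event still bound when the movie ends cannot be timed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "MixtureModel",
    "ObservationWindow",
    "SimulationConfig",
    "DwellDataset",
    "TraceSet",
    "DecaySeries",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class MixtureModel:
    """Weights and lifetimes of a K-component exponential mixture.

    Parameters
    ----------
    weights
        Mixture amplitudes, one per component.  Must lie in [0, 1] and sum
        to 1 (within 1e-9).  Interpreted as the fraction of binding events
        that dissociate with rate ``1/lifetimes[k]``.
    lifetimes
        Characteristic lifetimes in seconds, strictly positive.

    Models with more than three components are permitted but flagged via
    :attr:`nonstandard`, since dwell-time data rarely support them.
    """

    weights: tuple[float, ...]
    lifetimes: tuple[float, ...]

    def __init__(self, weights: Sequence[float], lifetimes: Sequence[float]):
        w = tuple(float(x) for x in weights)
        tau = tuple(float(x) for x in lifetimes)
        if len(w) != len(tau):
            raise ValueError(
                f"weights (len {len(w)}) and lifetimes (len {len(tau)}) must match"
            )
        if len(w) == 0:
            raise ValueError("mixture needs at least one component")
        if any(not (0.0 <= x <= 1.0) for x in w):
            raise ValueError(f"weights must lie in [0, 1], got {w}")
        if abs(sum(w) - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights must sum to 1 within {_WEIGHT_TOL}, got sum {sum(w)!r}")
        if any(t <= 0.0 or not np.isfinite(t) for t in tau):
            raise ValueError(f"lifetimes must be strictly positive and finite, got {tau}")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "lifetimes", tau)

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def nonstandard(self) -> bool:
        """True when K exceeds the 1-3 components dwell-time data usually support."""
        return self.K > 3

    def sorted(self) -> "MixtureModel":
        """Return an equivalent model with lifetimes ascending (weights permuted along)."""
        order = np.argsort(self.lifetimes, kind="stable")
        return MixtureModel(
            [self.weights[i] for i in order], [self.lifetimes[i] for i in order]
        )

    def as_dict(self) -> dict:
        return {"weights": list(self.weights), "lifetimes": list(self.lifetimes)}


@dataclass(frozen=True)
class ObservationWindow:
    """Observable dwell-time range: ``0 < t_min < t_max`` (seconds).

    ``t_min`` is the minimum resolvable interval (one camera frame by default);
    ``t_max`` is the longest duration the recording can contain.
    """

    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not (0.0 < self.t_min < self.t_max):
            raise ValueError(
                f"require 0 < t_min < t_max, got t_min={self.t_min}, t_max={self.t_max}"
            )

    def contains(self, t: np.ndarray | float) -> np.ndarray | bool:
        return (np.asarray(t) >= self.t_min) & (np.asarray(t) <= self.t_max)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic binding-event generator.

    ``frame_interval`` is the camera exposure (0.1 s in the emulated assay);
    set it to ``None`` for idealized continuous-time sampling.  ``bleach_lifetime``
    is the fluorophore photobleaching lifetime (173 s for Cy5 under the emulated
    conditions); bleaching competes with dissociation so the observed duration is
    the minimum of the two draws.  ``censoring_policy`` controls events still
    bound at ``t_max``: ``drop_incomplete`` discards them (matching a density
    normalized over the window), ``cap_at_window`` truncates them to ``t_max``.
    """

    n_events: int = 5000
    frame_interval: float | None = 0.1
    bleach_lifetime: float | None = None
    seed: int = 0
    censoring_policy: Literal["drop_incomplete", "cap_at_window"] = "drop_incomplete"
    n_molecules: int | None = None

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError(f"n_events must be positive, got {self.n_events}")
        if self.frame_interval is not None and self.frame_interval <= 0:
            raise ValueError(f"frame_interval must be positive, got {self.frame_interval}")
        if self.bleach_lifetime is not None and self.bleach_lifetime <= 0:
            raise ValueError(f"bleach_lifetime must be positive, got {self.bleach_lifetime}")
        if self.censoring_policy not in ("drop_incomplete", "cap_at_window"):
            raise ValueError(f"unknown censoring_policy {self.censoring_policy!r}")
        if self.n_molecules is not None and self.n_molecules <= 0:
            raise ValueError(f"n_molecules must be positive, got {self.n_molecules}")


@dataclass
class DwellDataset:
    """Observed dwell durations (seconds) for one condition.

    ``molecule_id`` and ``start_s`` are optional per-event annotations used for
    rastergrams and per-molecule block bootstrap; fitting uses ``durations`` only.
    ``n_discarded_short``/``n_discarded_long`` record how many raw draws the
    simulator or event caller dropped below ``t_min`` / at the window end.
    """

    durations: np.ndarray
    condition: str
    window: ObservationWindow
    molecule_id: np.ndarray | None = None
    start_s: np.ndarray | None = None
    n_discarded_short: int = 0
    n_discarded_long: int = 0

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if self.durations.ndim != 1:
            raise ValueError("durations must be one-dimensional")
        if self.molecule_id is not None:
            self.molecule_id = np.asarray(self.molecule_id)
            if self.molecule_id.shape != self.durations.shape:
                raise ValueError("molecule_id must align with durations")
        if self.start_s is not None:
            self.start_s = np.asarray(self.start_s, dtype=float)
            if self.start_s.shape != self.durations.shape:
                raise ValueError("start_s must align with durations")

    @property
    def n(self) -> int:
        return int(self.durations.size)

    def validate_in_window(self) -> None:
        """Raise if any duration falls outside the observation window."""
        bad = np.flatnonzero(~self.window.contains(self.durations))
        if bad.size:
            raise ValueError(
                f"{bad.size} duration(s) outside window "
                f"[{self.window.t_min}, {self.window.t_max}]; first offending rows: "
                f"{bad[:10].tolist()} (values {self.durations[bad[:10]].tolist()})"
            )

    def subset(self, idx: np.ndarray) -> "DwellDataset":
        return DwellDataset(
            durations=self.durations[idx],
            condition=self.condition,
            window=self.window,
            molecule_id=None if self.molecule_id is None else self.molecule_id[idx],
            start_s=None if self.start_s is None else self.start_s[idx],
        )


@dataclass
class TraceSet:
    """Per-molecule fluorescence intensity traces on a common frame clock.

    ``traces`` maps trace id -> 1-D intensity array (a.u., frame 0 first).
    ``ground_truth_events`` optionally retains the planted (start_s, end_s)
    intervals per trace for caller validation.
    """

    traces: dict[str, np.ndarray]
    frame_interval: float
    ground_truth_events: dict[str, list[tuple[float, float]]] | None = None

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        clean: dict[str, np.ndarray] = {}
        for key, arr in self.traces.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"trace {key!r} must be one-dimensional")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"trace {key!r} contains non-finite intensities")
            clean[key] = arr
        self.traces = clean

    @property
    def n_traces(self) -> int:
        return len(self.traces)


@dataclass
class DecaySeries:
    """A rifampicin-chase time course: target and reference signal over time.

    ``percent_remaining`` is derived by :func:`smkinetics.halflife.normalize_to_reference`
    (target/reference, scaled so time 0 is 100%).  Times are minutes and must
    start at 0 (the transcription shut-off sample).
    """

    times: np.ndarray
    target_signal: np.ndarray
    reference_signal: np.ndarray
    percent_remaining: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.target_signal = np.asarray(self.target_signal, dtype=float)
        self.reference_signal = np.asarray(self.reference_signal, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need at least two time points")
        if self.times[0] != 0.0:
            raise ValueError(f"times must start at 0 (shut-off sample), got {self.times[0]}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, arr in (("target_signal", self.target_signal),
                          ("reference_signal", self.reference_signal)):
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must align with times")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.percent_remaining is not None:
            self.percent_remaining = np.asarray(self.percent_remaining, dtype=float)
            if self.percent_remaining.shape != self.times.shape:
                raise ValueError("percent_remaining must align with times")

    @property
    def n_points(self) -> int:
        return int(self.times.size)
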
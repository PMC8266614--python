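"""Figure-style outputs: rastergrams, dwell-time survival curves, decay curves.

Uses the object-oriented matplotlib API (no pyplot state), so figures render
identically headless.
"""

from __future__ import annotations

import warnings

import numpy as np
from matplotlib.figure import Figure

from .halflife import HalfLifeResult, normalize_to_reference
from .mle import truncated_cdf
from .models import DecaySeries, DwellDataset

__all__ = ["render_rastergram", "plot_survival", "plot_decay"]


def render_rastergram(
    data: DwellDataset,
    path=None,
    selection_size: int = 50,
    seed: int = 0,
):
    """Horizontal-bar plot of binding events per molecule over the recording.

    ``selection_size`` molecules are chosen at random (deterministically for a
    given seed); if fewer are available, all are shown with a warning.  Returns
    the Figure; also saves to ``path`` when given.
    """
    if data.n == 0 or data.molecule_id is None or data.start_s is None:
        raise ValueError("rastergram needs a non-empty dataset with molecule/start annotations")
    molecules = np.unique(data.molecule_id)
    rng = np.random.default_rng(seed)
    if molecules.size >= selection_size:
        chosen = rng.choice(molecules, size=selection_size, replace=False)
    else:
        warnings.warn(
            f"only {molecules.size} molecules available for a "
            f"{selection_size}-trace rastergram; showing all"
        )
        chosen = molecules

    fig = Figure(figsize=(6, 0.12 * max(len(chosen), 10) + 1))
    ax = fig.add_subplot(111)
    for row, mol in enumerate(chosen):
        mask = data.molecule_id == mol
        for start, dur in zip(data.start_s[mask], data.durations[mask]):
            ax.plot([start, start + dur], [row, row], lw=2.0, color="k",
                    solid_capstyle="butt")
    ax.set_xlim(0, data.window.t_max)
    ax.set_ylim(-1, len(chosen))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("molecule")
    ax.set_title(f"{data.condition}: {len(chosen)} traces")
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_survival(data: DwellDataset, fit=None, path=None):
    """Empirical dwell-time survival curve, optionally with a fitted model overlay."""
    if data.n == 0:
        raise ValueError("empty dataset")
    t = np.sort(data.durations)
    surv = 1.0 - np.arange(1, t.size + 1) / t.size

    fig = Figure(figsize=(5, 4))
    ax = fig.add_subplot(111)
    ax.step(t, surv, where="post", label=f"{data.condition} (n={data.n})")
    if fit is not None:
        grid = np.linspace(data.window.t_min, min(data.window.t_max, t[-1]), 400)
        ax.plot(grid, 1.0 - truncated_cdf(grid, fit.model, fit.window),
                "r-", lw=1.2, label=f"K={fit.K} fit")
    ax.set_yscale("log")
    ax.set_xlabel("dwell time (s)")
    ax.set_ylabel("fraction surviving")
    ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_decay(series: DecaySeries, result: HalfLifeResult | None = None, path=None):
    """Percent-remaining decay curve with the fitted trendline."""
    if series.percent_remaining is None:
        series = normalize_to_reference(series)
    fig = Figure(figsize=(5, 4))
    ax = fig.add_subplot(111)
    ax.plot(series.times, series.percent_remaining, "o", label=series.label or "data")
    if result is not None and not result.no_decay:
        grid = np.linspace(series.times[0], series.times[-1], 200)
        if result.method == "first_order":
            ax.plot(grid, 100.0 * np.exp(-result.rate * grid), "r-",
                    label=f"first order, t½={result.half_life:.2f} min")
        else:
            ax.plot(grid, 100.0 - result.rate * grid, "r-",
                    label=f"linear, t½={result.half_life:.2f} min")
    ax.set_xlabel("time after rifampicin (min)")
    ax.set_ylabel("% remaining (target / 16S, t=0 = 100%)")
    ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
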
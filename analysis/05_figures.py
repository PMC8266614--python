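#!/usr/bin/env python
"""Render the figure-style outputs: rastergrams, survival curves, decay curves.

Figures are written under scratch/figures/ (binary artifacts, regenerable from
the tables produced by the earlier scripts).
"""

from pathlib import Path

import numpy as np

from smkinetics import (
    MixtureModel,
    ObservationWindow,
    SimulationConfig,
    choose_method,
    fit_mixture,
    normalize_to_reference,
    simulate_decay,
    simulate_dwells,
)
from smkinetics.plots import plot_decay, plot_survival, render_rastergram

ROOT = Path(__file__).resolve().parents[1]
FIGDIR = ROOT / "scratch" / "figures"
WINDOW = ObservationWindow(0.1, 180.0)


def main() -> None:
    FIGDIR.mkdir(parents=True, exist_ok=True)
    for name, weights in (("no_crc", [0.56, 0.44]), ("with_crc", [0.30, 0.70])):
        data = simulate_dwells(
            MixtureModel(weights, [2.0, 60.0]),
            WINDOW,
            SimulationConfig(n_events=5000, seed=1, n_molecules=400),
            condition=name,
        )
        render_rastergram(data, FIGDIR / f"rastergram_{name}.png",
                          selection_size=50, seed=0)
        fit = fit_mixture(data, 2, seed=1)
        plot_survival(data, fit, FIGDIR / f"survival_{name}.png")
        print(f"{name}: rastergram + survival curve")

    for name, times, spec in (
        ("fast", np.arange(0.0, 9.0), dict(half_life=1.7, shape="first_order")),
        ("slow", np.arange(0.0, 21.0, 2.0), dict(half_life=10.4, shape="linear")),
    ):
        series = normalize_to_reference(
            simulate_decay(times=times, seed=5, noise_sd=3.0, label=name, **spec)
        )
        plot_decay(series, choose_method(series), FIGDIR / f"decay_{name}.png")
        print(f"{name}: decay curve")
    print(f"\nfigures -> {FIGDIR}")


if __name__ == "__main__":
    main()
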
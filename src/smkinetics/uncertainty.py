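"""Bootstrap standard errors and between-condition significance tests.

Parameter uncertainties come from a nonparametric bootstrap: resample the
observed dwell times with replacement, refit, and take the standard deviation
of the replicate estimates (equivalently, the sigma of a normal fit to them).
The residual amplitude of a three-component model, ``a3 = 1 - a1 - a2``, gets
its sigma by quadrature propagation ``sqrt(sigma_a1^2 + sigma_a2^2)`` — exact
only when the a1/a2 resamples are uncorrelated, so the direct bootstrap sigma
of a3 is reported alongside.  Conditions are compared with a two-tailed
unpaired test on the (estimate, sigma) pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mle import FitError, FitResult, fit_mixture
from .models import DwellDataset

__all__ = [
    "BootstrapSummary",
    "ComparisonResult",
    "bootstrap_fit",
    "propagate_residual_sigma",
    "histogram_bar_sigma",
    "compare_conditions",
]


@dataclass
class BootstrapSummary:
    """Point estimates with bootstrap sigmas for every mixture parameter.

    ``estimates``/``sigmas`` are keyed ``w1..wK`` and ``tau1..tauK`` after
    ascending-lifetime sorting, so component labels line up across replicates.
    A summary is ``valid`` only when at least 90% of replicates converged.
    For K >= 3, ``residual_sigma_propagated`` carries the quadrature-propagated
    sigma of the last weight and ``sigmas['wK']`` the direct bootstrap sigma.
    """

    n_boot: int
    failures: int
    estimates: dict[str, float]
    sigmas: dict[str, float]
    samples: dict[str, np.ndarray] | None = None
    residual_sigma_propagated: float | None = None
    base_fit: FitResult | None = None

    @property
    def n_effective(self) -> int:
        return self.n_boot - self.failures

    @property
    def valid(self) -> bool:
        return self.n_effective >= 0.9 * self.n_boot

    def as_dict(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "failures": self.failures,
            "valid": self.valid,
            "estimates": dict(self.estimates),
            "sigmas": dict(self.sigmas),
            "residual_sigma_propagated": self.residual_sigma_propagated,
        }


@dataclass
class ComparisonResult:
    """Two-tailed unpaired comparison of one parameter across two conditions."""

    parameter: str
    condition_a: str
    condition_b: str
    difference: float
    statistic: float
    p_value: float
    df_policy: str = "normal"
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "difference": self.difference,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df_policy": self.df_policy,
            "significant": self.significant,
            "degenerate": self.degenerate,
        }


def _param_names(K: int) -> list[str]:
    return [f"w{k + 1}" for k in range(K)] + [f"tau{k + 1}" for k in range(K)]


def _param_vector(fit: FitResult) -> np.ndarray:
    return np.concatenate([fit.model.weights, fit.model.lifetimes])


def bootstrap_fit(
    data: DwellDataset,
    K: int,
    n_boot: int = 1000,
    seed: int = 0,
    base_fit: FitResult | None = None,
    n_restarts: int = 3,
    keep_samples: bool = False,
    by_molecule: bool = False,
    **fit_kwargs,
) -> BootstrapSummary:
    """Bootstrap standard errors for a K-component truncated-mixture fit.

    Each of ``n_boot`` replicates resamples the events with replacement
    (or whole molecules when ``by_molecule`` — a block bootstrap respecting
    within-molecule dependence), refits warm-started from the base optimum plus
    ``n_restarts`` random restarts, and records the ascending-lifetime-sorted
    parameters.  Non-converged replicates are dropped and counted; more than
    10% of them marks the summary invalid.
    """
    if base_fit is None:
        base_fit = fit_mixture(data, K, seed=seed, **fit_kwargs)
    if by_molecule and data.molecule_id is None:
        raise ValueError("by_molecule bootstrap needs molecule_id annotations")

    rng = np.random.default_rng(seed)
    names = _param_names(K)
    draws = np.full((n_boot, len(names)), np.nan)
    failures = 0
    if by_molecule:
        mols = np.unique(data.molecule_id)
        by_mol = {m: np.flatnonzero(data.molecule_id == m) for m in mols}
    for b in range(n_boot):
        if by_molecule:
            picked = rng.choice(mols, size=mols.size, replace=True)
            idx = np.concatenate([by_mol[m] for m in picked])
        else:
            idx = rng.integers(0, data.n, size=data.n)
        resample = data.subset(idx)
        try:
            fit = fit_mixture(
                resample,
                K,
                n_starts=n_restarts,
                seed=int(rng.integers(0, 2**31 - 1)),
                init=base_fit.model,
                **fit_kwargs,
            )
        except (FitError, ValueError):
            failures += 1
            continue
        if not fit.converged:
            failures += 1
            continue
        draws[b] = _param_vector(fit)

    ok = ~np.isnan(draws[:, 0])
    est = dict(zip(names, _param_vector(base_fit)))
    if ok.sum() >= 2:
        sig = dict(zip(names, np.std(draws[ok], axis=0, ddof=1)))
    else:
        sig = {name: math.nan for name in names}

    residual = None
    if K >= 3 and ok.sum() >= 2:
        # quadrature-propagated sigma for the residual amplitude
        residual = propagate_residual_sigma(sig["w1"], sig["w2"]) if K == 3 else None

    return BootstrapSummary(
        n_boot=n_boot,
        failures=failures,
        estimates=est,
        sigmas=sig,
        samples={n: draws[ok][:, i] for i, n in enumerate(names)} if keep_samples else None,
        residual_sigma_propagated=residual,
        base_fit=base_fit,
    )


def propagate_residual_sigma(sigma_a1: float, sigma_a2: float) -> float:
    """Quadrature-propagated sigma of a residual amplitude ``a3 = 1 - a1 - a2``.

    Returns ``sqrt(sigma_a1**2 + sigma_a2**2)``; exact when the two amplitude
    estimates are uncorrelated (constrained mixture weights generally are not,
    which is why the direct bootstrap sigma is also reported).
    """
    if sigma_a1 < 0 or sigma_a2 < 0:
        raise ValueError(f"sigmas must be non-negative, got ({sigma_a1}, {sigma_a2})")
    return math.hypot(sigma_a1, sigma_a2)


def histogram_bar_sigma(N: int, P: float) -> float:
    """Binomial standard deviation ``sqrt(N P (1 - P))`` of a histogram bar.

    ``N`` is the number of events and ``P`` the per-event probability of
    landing in the bar.
    """
    if N < 0:
        raise ValueError(f"N must be non-negative, got {N}")
    if not (0.0 <= P <= 1.0):
        raise ValueError(f"P must lie in [0, 1], got {P}")
    return math.sqrt(N * P * (1.0 - P))


def compare_conditions(
    estimate_a: float,
    sigma_a: float,
    estimate_b: float,
    sigma_b: float,
    parameter: str = "",
    condition_a: str = "A",
    condition_b: str = "B",
    df_policy: str = "normal",
    df: float | None = None,
) -> ComparisonResult:
    """Two-tailed unpaired test of ``estimate_a`` vs ``estimate_b``.

    The statistic is ``(A - B) / sqrt(sigma_a^2 + sigma_b^2)``.  Under the
    default ``normal`` policy (bootstrap sigmas treated as the estimators'
    standard errors) the p-value uses the standard normal; the ``welch``
    policy uses a t reference with user-supplied ``df``.
    """
    if sigma_a < 0 or sigma_b < 0:
        raise ValueError("sigmas must be non-negative")
    diff = estimate_a - estimate_b
    pooled = math.hypot(sigma_a, sigma_b)
    if pooled == 0.0:
        if diff == 0.0:
            return ComparisonResult(parameter, condition_a, condition_b,
                                    0.0, 0.0, 1.0, df_policy, degenerate=True)
        return ComparisonResult(parameter, condition_a, condition_b,
                                diff, math.copysign(math.inf, diff), 0.0,
                                df_policy, degenerate=True)
    z = diff / pooled
    if diff == 0.0:
        p = 1.0
    elif df_policy == "normal":
        p = 2.0 * stats.norm.sf(abs(z))
    elif df_policy == "welch":
        if df is None or df <= 0:
            raise ValueError("welch policy needs a positive df")
        p = 2.0 * stats.t.sf(abs(z), df)
    else:
        raise ValueError(f"unknown df_policy {df_policy!r}")
    return ComparisonResult(parameter, condition_a, condition_b, diff, z, float(p), df_policy)
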
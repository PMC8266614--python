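"""Maximum-likelihood fitting of truncated exponential-mixture dwell-time models.

A recording only shows dwell times inside ``[t_min, t_max]``, so the density of
an observed dwell ``t`` under a K-component exponential mixture with weights
``w_k`` and lifetimes ``tau_k`` is

    f(t) = [ sum_k (w_k / tau_k) exp(-t / tau_k) ]
           / [ sum_k w_k (exp(-t_min / tau_k) - exp(-t_max / tau_k)) ]

i.e. the mixture density renormalized over the window.  Un-binned dwell times
are fit by maximizing the product of these densities; weights live on the
simplex (softmax reparameterization) and lifetimes on the log scale, optimized
with L-BFGS-B from multiple deterministic random starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .models import DwellDataset, MixtureModel, ObservationWindow

__all__ = [
    "FitResult",
    "FitError",
    "truncated_pdf",
    "truncated_cdf",
    "neg_log_likelihood",
    "fit_mixture",
    "select_K",
]

# Two lifetimes closer than this ratio are flagged as unresolvable.
_RESOLVE_RATIO = 1.05


class FitError(RuntimeError):
    """No optimization start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list[dict] | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class FitResult:
    """A fitted truncated mixture: point estimates plus fit provenance.

    ``model`` always carries lifetimes sorted ascending with weights permuted
    along, so component labels are comparable across fits and bootstrap
    replicates.  ``k_table`` is populated by :func:`select_K` with one row per
    candidate K (log-likelihood, BIC, convergence).
    """

    model: MixtureModel
    window: ObservationWindow
    log_likelihood: float
    n_events: int
    converged: bool
    n_starts_used: int
    best_start: int
    warnings: list[str] = field(default_factory=list)
    k_table: list[dict] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.model.K

    @property
    def n_parameters(self) -> int:
        # K lifetimes + (K - 1) free weights
        return 2 * self.K - 1

    @property
    def bic(self) -> float:
        return self.n_parameters * np.log(self.n_events) - 2.0 * self.log_likelihood

    def as_dict(self) -> dict:
        return {
            "model": self.model.as_dict(),
            "window": {"t_min": self.window.t_min, "t_max": self.window.t_max},
            "log_likelihood": self.log_likelihood,
            "K": self.K,
            "n_events": self.n_events,
            "bic": self.bic,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "best_start": self.best_start,
            "warnings": list(self.warnings),
            "k_table": list(self.k_table),
        }


def _norm_constants(model: MixtureModel, window: ObservationWindow) -> tuple[np.ndarray, float]:
    tau = np.asarray(model.lifetimes)
    w = np.asarray(model.weights)
    z = np.exp(-window.t_min / tau) - np.exp(-window.t_max / tau)
    return z, float(np.dot(w, z))


def truncated_pdf(t, model: MixtureModel, window: ObservationWindow):
    """Density of an observed dwell time under the window-truncated mixture.

    Raises ``ValueError`` for any ``t`` outside ``[t_min, t_max]`` — the model
    assigns such durations probability zero by construction.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(~window.contains(t_arr)):
        raise ValueError(
            f"dwell time outside observation window [{window.t_min}, {window.t_max}]"
        )
    tau = np.asarray(model.lifetimes)
    w = np.asarray(model.weights)
    _, Z = _norm_constants(model, window)
    dens = np.sum((w / tau) * np.exp(-t_arr[..., None] / tau), axis=-1) / Z
    return dens if t_arr.ndim else float(dens)


def truncated_cdf(t, model: MixtureModel, window: ObservationWindow):
    """CDF of the window-truncated mixture (0 at ``t_min``, 1 at ``t_max``)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(~window.contains(t_arr)):
        raise ValueError(
            f"dwell time outside observation window [{window.t_min}, {window.t_max}]"
        )
    tau = np.asarray(model.lifetimes)
    w = np.asarray(model.weights)
    _, Z = _norm_constants(model, window)
    mass = np.sum(
        w * (np.exp(-window.t_min / tau) - np.exp(-t_arr[..., None] / tau)), axis=-1
    ) / Z
    return mass if t_arr.ndim else float(mass)


def neg_log_likelihood(data: DwellDataset, model: MixtureModel) -> float:
    """Negative log-likelihood (nats) of the truncated mixture on a dwell dataset."""
    data.validate_in_window()
    w = np.asarray(model.weights)
    tau = np.asarray(model.lifetimes)
    keep = w > 0  # zero-weight components contribute nothing and break the log
    log_c = (
        np.log(w[keep]) - np.log(tau[keep]) - data.durations[:, None] / tau[keep]
    )
    _, Z = _norm_constants(model, window=data.window)
    return float(-np.sum(logsumexp(log_c, axis=1)) + data.n * np.log(Z))


# ---------------------------------------------------------------------------
# optimization internals


def _unpack(theta: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    logits = np.concatenate([theta[: K - 1], [0.0]])
    logits = logits - logits.max()
    w = np.exp(logits)
    w /= w.sum()
    tau = np.exp(theta[K - 1 :])
    return w, tau


def _nll_and_grad(
    theta: np.ndarray, t: np.ndarray, K: int, t_min: float, t_max: float
) -> tuple[float, np.ndarray]:
    """Value and analytic gradient of the nll in (logit, log-lifetime) coordinates."""
    w, tau = _unpack(theta, K)
    n = t.size

    with np.errstate(all="ignore"):
        log_c = np.log(w) - np.log(tau) - t[:, None] / tau  # (n, K)
        log_S = logsumexp(log_c, axis=1)
        r = np.exp(log_c - log_S[:, None])  # responsibilities

        z = np.exp(-t_min / tau) - np.exp(-t_max / tau)
        Z = float(np.dot(w, z))
        nll = -float(np.sum(log_S)) + n * np.log(Z)

        # d nll / d w_k (unconstrained), then project through the softmax
        dw = -r.sum(axis=0) / w + n * z / Z
        g_logits_full = w * (dw - float(np.dot(w, dw)))

        # d z_k / d tau_k, then chain d/d log tau = tau * d/d tau
        dz = (t_min / tau**2) * np.exp(-t_min / tau) \
            - (t_max / tau**2) * np.exp(-t_max / tau)
        g_logtau = -np.sum(r * (t[:, None] - tau) / tau, axis=0) + n * w * tau * dz / Z

        grad = np.concatenate([g_logits_full[: K - 1], g_logtau])
    if not np.isfinite(nll) or not np.all(np.isfinite(grad)):
        return np.inf, np.zeros_like(theta)
    return nll, grad


def _initial_points(
    K: int,
    n_starts: int,
    window: ObservationWindow,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Deterministic multi-start inits: log-uniform lifetimes, uniform simplex weights."""
    points = []
    lo, hi = np.log(window.t_min), np.log(window.t_max)
    for _ in range(n_starts):
        log_tau = np.sort(rng.uniform(lo, hi, size=K))
        w = rng.dirichlet(np.ones(K))
        logits = np.log(w[:-1]) - np.log(w[-1])
        points.append(np.concatenate([logits, log_tau]))
    return points


def fit_mixture(
    data: DwellDataset,
    K: int,
    n_starts: int = 20,
    seed: int = 0,
    min_events_per_component: int = 10,
    ftol: float = 1e-12,
    gtol: float = 1e-8,
    init: MixtureModel | None = None,
    max_iter: int = 2000,
) -> FitResult:
    """Maximum-likelihood fit of a K-component truncated mixture to dwell times.

    The likelihood is maximized over mixture weights (simplex-constrained via a
    softmax reparameterization) and log-lifetimes with L-BFGS-B, from
    ``n_starts`` seed-derived random initializations (plus ``init`` as a warm
    start when given).  The best local optimum wins; among starts of equal
    likelihood the lowest start index wins, so fits are deterministic.  The
    returned lifetimes are sorted ascending with weights permuted along.

    Raises :class:`FitError` (with per-start diagnostics) if no start converges,
    and ``ValueError`` when the dataset is too small (fewer than
    ``min_events_per_component * K`` events).
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    data.validate_in_window()
    if data.n < min_events_per_component * K:
        raise ValueError(
            f"{data.n} events is too few to fit K={K} components "
            f"(need at least {min_events_per_component * K})"
        )

    rng = np.random.default_rng(seed)
    starts = _initial_points(K, n_starts, data.window, rng)
    if init is not None:
        if init.K != K:
            raise ValueError(f"warm start has K={init.K}, expected {K}")
        m = init.sorted()
        w = np.clip(np.asarray(m.weights), 1e-12, None)
        logits = np.log(w[:-1]) - np.log(w[-1])
        starts.insert(0, np.concatenate([logits, np.log(m.lifetimes)]))

    t = data.durations
    t_min, t_max = data.window.t_min, data.window.t_max
    args = (t, K, t_min, t_max)
    # keep exp() in range: weights stay on the open simplex, lifetimes within a
    # generous margin around the window
    bounds = [(-35.0, 35.0)] * (K - 1) + [
        (np.log(t_min) - 7.0, np.log(t_max) + 7.0)
    ] * K

    best = None
    best_nll = np.inf
    best_idx = -1
    any_converged = False
    diagnostics: list[dict] = []
    for idx, x0 in enumerate(starts):
        res = minimize(
            _nll_and_grad,
            x0,
            args=args,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": ftol, "gtol": gtol, "maxiter": max_iter},
        )
        diagnostics.append(
            {"start": idx, "nll": float(res.fun), "converged": bool(res.success),
             "message": str(res.message)}
        )
        if not np.isfinite(res.fun):
            continue
        any_converged = any_converged or res.success
        # strict improvement only: equal-likelihood ties keep the earliest start
        if res.fun < best_nll - 1e-9 * max(1.0, abs(best_nll) if np.isfinite(best_nll) else 1.0):
            best, best_nll, best_idx = res, float(res.fun), idx

    if best is None:
        raise FitError(
            f"all {len(starts)} starts produced non-finite likelihoods for K={K}",
            diagnostics,
        )
    if not any_converged:
        raise FitError(
            f"no start converged for K={K} (best nll {best_nll:.6g})", diagnostics
        )

    w, tau = _unpack(best.x, K)
    model = MixtureModel(w, tau).sorted()
    warnings: list[str] = []
    taus = np.asarray(model.lifetimes)
    if K > 1 and np.any(taus[1:] / taus[:-1] < _RESOLVE_RATIO):
        warnings.append(
            f"two fitted lifetimes within {100 * (_RESOLVE_RATIO - 1):.0f}%: "
            f"K={K} may exceed the resolvable number of components"
        )
    if model.nonstandard:
        warnings.append("K > 3 exceeds the component count dwell-time data usually support")

    return FitResult(
        model=model,
        window=data.window,
        log_likelihood=-best_nll,
        n_events=data.n,
        converged=bool(best.success),
        n_starts_used=len(starts),
        best_start=best_idx,
        warnings=warnings,
    )


def select_K(
    data: DwellDataset,
    candidate_Ks: list[int] | tuple[int, ...] = (1, 2, 3),
    n_starts: int = 20,
    seed: int = 0,
    **fit_kwargs,
) -> FitResult:
    """Fit every candidate K and return the BIC-minimizing result.

    The full K-versus-BIC table (including per-K failures) is attached to the
    winning result as ``k_table``.  Fit failures for one K do not abort the
    others; if every K fails, the last error is re-raised.
    """
    if any(k not in (1, 2, 3, 4) for k in candidate_Ks):
        raise ValueError(f"candidate Ks must be within {{1, 2, 3, 4}}, got {candidate_Ks}")
    fits: dict[int, FitResult] = {}
    table: list[dict] = []
    last_err: Exception | None = None
    for K in candidate_Ks:
        try:
            fit = fit_mixture(data, K, n_starts=n_starts, seed=seed, **fit_kwargs)
        except (FitError, ValueError) as err:
            table.append({"K": K, "error": str(err)})
            last_err = err
            continue
        fits[K] = fit
        table.append(
            {"K": K, "log_likelihood": fit.log_likelihood, "bic": fit.bic,
             "converged": fit.converged}
        )
    if not fits:
        assert last_err is not None
        raise last_err
    best = min(fits.values(), key=lambda f: f.bic)
    best.k_table = table
    return best
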
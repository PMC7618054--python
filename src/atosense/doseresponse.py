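"""Dose-response sweeps of the AtoSC model and Hill-function characterisation.

The biosensor's transfer function is summarised by a four-parameter Hill
curve with basal expression,

    GFP(d) = fmin + (fmax - fmin) * d^n / (K^n + d^n),

where ``d`` is the dose (the HK autophosphorylation rate ``k_ap`` for model
sweeps, or the inducer concentration in uM for cytometry data), ``K`` is the
half-maximal dose (K1/2) and ``n`` the Hill coefficient.  Two derived
amplitude metrics characterise switching performance:

    dynamic range = (fmax - fmin) / fmin        fold change = fmax / fmin
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .model import TCSParameters, TCSState, simulate_to_steady_state

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "hill_eval",
    "default_kap_grid",
    "sweep_dose_response",
    "fit_hill",
    "SweepError",
]


class SweepError(RuntimeError):
    """A steady-state solve in a dose sweep failed to converge."""


def hill_eval(dose, fmin: float, fmax: float, K: float, n: float):
    """Hill curve with basal expression; accepts scalar or array dose >= 0."""
    if K <= 0 or n <= 0:
        raise ValueError("hill_eval requires K > 0 and n > 0")
    d = np.asarray(dose, dtype=float)
    dn = np.power(d, n)
    out = fmin + (fmax - fmin) * dn / (K**n + dn)
    return float(out) if np.isscalar(dose) or out.ndim == 0 else out


@dataclass(frozen=True)
class DoseResponseCurve:
    """Steady-state (or measured) response over a strictly increasing dose grid."""

    dose: np.ndarray
    response: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "dose", np.asarray(self.dose, dtype=float))
        object.__setattr__(self, "response", np.asarray(self.response, dtype=float))
        if self.replicate_sd is not None:
            object.__setattr__(self, "replicate_sd", np.asarray(self.replicate_sd, dtype=float))
        if self.dose.ndim != 1 or self.dose.shape != self.response.shape:
            raise ValueError("dose and response must be 1-D and the same length")
        if len(self.dose) < 5:
            raise ValueError("need at least 5 points to fit 4 Hill parameters")
        if np.any(np.diff(self.dose) <= 0):
            raise ValueError("dose grid must be strictly increasing")
        if np.any(self.dose < 0):
            raise ValueError("doses must be >= 0")
        if not np.all(np.isfinite(self.response)) or np.any(self.response < 0):
            raise ValueError("responses must be finite and >= 0")
        if self.replicate_sd is not None and self.replicate_sd.shape != self.dose.shape:
            raise ValueError("replicate_sd must match dose length")

    def to_frame(self) -> pd.DataFrame:
        d = {"dose": self.dose, "response": self.response}
        if self.replicate_sd is not None:
            d["sd"] = self.replicate_sd
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DoseResponseCurve":
        df = pd.read_csv(path)
        sd = df["sd"].to_numpy() if "sd" in df.columns else None
        return cls(df["dose"].to_numpy(), df["response"].to_numpy(), sd)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with asymptotic standard errors.

    ``dynamic_range`` and ``fold_change`` are derived from the fitted
    plateaus; by construction fold_change - dynamic_range == 1 exactly.
    """

    fmin: float
    fmax: float
    K: float
    n: float
    se_fmin: float = math.nan
    se_fmax: float = math.nan
    se_K: float = math.nan
    se_n: float = math.nan
    converged: bool = True
    sse: float = math.nan
    n_points: int = 0

    def __post_init__(self):
        if self.converged:
            if not (self.fmax >= self.fmin >= 0):
                raise ValueError("require fmax >= fmin >= 0")
            if self.K <= 0 or self.n <= 0:
                raise ValueError("require K > 0 and n > 0")

    @property
    def fold_change(self) -> float:
        return self.fmax / self.fmin if self.fmin > 0 else math.inf

    @property
    def dynamic_range(self) -> float:
        return self.fold_change - 1.0

    def predict(self, dose):
        return hill_eval(dose, self.fmin, self.fmax, self.K, self.n)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dynamic_range"] = self.dynamic_range
        d["fold_change"] = self.fold_change
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def default_kap_grid(lo: float = 1e-3, hi: float = 10.0, n_log: int = 12) -> np.ndarray:
    """Default dose grid: explicit zero plus ``n_log`` log-spaced points.

    Spans four decades of k_ap by default; dose 0 anchors the basal level
    (the Hill curve is defined there).
    """
    return np.concatenate([[0.0], np.logspace(math.log10(lo), math.log10(hi), n_log)])


def sweep_dose_response(
    params: TCSParameters,
    kap_grid=None,
    rel_tol: float = 1e-6,
    t_max: float = 1e6,
) -> DoseResponseCurve:
    """One steady-state solve per k_ap value; response is mature GFP.

    Successive solves are warm-started from the previous steady state
    (totals are shared across the sweep, so conservation is preserved),
    which roughly halves the sweep cost.
    """
    grid = default_kap_grid() if kap_grid is None else np.asarray(kap_grid, dtype=float)
    if len(grid) < 5:
        raise ValueError("kap_grid must have at least 5 points")
    if np.any(np.diff(grid) <= 0) or np.any(grid < 0):
        raise ValueError("kap_grid must be strictly increasing and non-negative")
    responses = np.empty(len(grid))
    state = TCSState.initial(params)
    for i, kap in enumerate(grid):
        res = simulate_to_steady_state(
            params.replace(k_ap=float(kap)), init=state, rel_tol=rel_tol, t_max=t_max
        )
        if not res.converged:
            raise SweepError(f"steady state not reached at k_ap={kap:g}")
        state = res.state
        responses[i] = res.state.Gm
    return DoseResponseCurve(grid, responses)


def _hill_model_factory(n_fixed):
    if n_fixed is None:
        def f(d, fmin, fmax, K, n):
            return hill_eval(d, fmin, fmax, K, n)
        return f, 4
    def f(d, fmin, fmax, K):
        return hill_eval(d, fmin, fmax, K, n_fixed)
    return f, 3


def fit_hill(curve: DoseResponseCurve, n_fixed: float | None = None) -> HillFit:
    """Weighted nonlinear least-squares Hill fit.

    Multi-start initialisation: fmin0 = min(response), fmax0 = max(response),
    K0 = dose whose response is closest to the midpoint, Hill slope started
    from each of {0.5, 1, 2, 4}; the lowest-SSE converged fit wins.
    Inverse-variance weights are applied when per-dose replicate
    dispersions are available (and all positive); otherwise unweighted.
    Raw per-dose SDs from a handful of replicates are too noisy to weight
    by directly (occasional tiny SDs blow up their weights and the
    covariance underestimates), so the dispersions are pooled under a
    constant-CV error model: sigma_i = pooled_cv * response_i.  Standard
    errors come from the local covariance at the optimum.
    """
    d, y = curve.dose, curve.response
    sigma = None
    if curve.replicate_sd is not None and np.all(curve.replicate_sd > 0):
        if np.all(y > 0):
            pooled_cv = float(np.sqrt(np.mean((curve.replicate_sd / y) ** 2)))
            sigma = pooled_cv * y
        else:
            sigma = curve.replicate_sd

    fmin0 = float(np.min(y))
    fmax0 = float(np.max(y))
    mid = 0.5 * (fmin0 + fmax0)
    positive = d > 0
    K0 = float(d[positive][np.argmin(np.abs(y[positive] - mid))]) if positive.any() else 1.0
    span = fmax0 - fmin0

    model, n_free = _hill_model_factory(n_fixed)
    eps = 1e-12
    if n_fixed is None:
        lower = [0.0, 0.0, eps, eps]
        upper = [np.inf, np.inf, np.inf, 10.0]
    else:
        if n_fixed <= 0:
            raise ValueError("n_fixed must be > 0")
        lower = [0.0, 0.0, eps]
        upper = [np.inf, np.inf, np.inf]

    best = None
    for n0 in (0.5, 1.0, 2.0, 4.0):
        p0 = [fmin0, max(fmax0, fmin0 + max(span, eps)), max(K0, eps)]
        if n_fixed is None:
            p0.append(n0)
        try:
            popt, pcov = curve_fit(
                model, d, y, p0=p0, sigma=sigma, absolute_sigma=False,
                bounds=(lower, upper), maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - model(d, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
        if n_fixed is not None:
            break  # the start only varies n; one pass suffices when n is clamped

    if best is None:
        return HillFit(
            fmin=fmin0, fmax=fmax0, K=K0, n=n_fixed or 1.0,
            converged=False, n_points=len(d),
        )

    popt, pcov, sse = best
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    if n_fixed is None:
        fmin, fmax, K, n = popt
        se_fmin, se_fmax, se_K, se_n = se
    else:
        fmin, fmax, K = popt
        n = float(n_fixed)
        se_fmin, se_fmax, se_K = se
        se_n = 0.0
    # degenerate flat data can invert the plateaus within noise; repair order
    if fmax < fmin:
        fmin, fmax = fmax, fmin
        se_fmin, se_fmax = se_fmax, se_fmin
    return HillFit(
        fmin=float(fmin), fmax=float(fmax), K=float(K), n=float(n),
        se_fmin=float(se_fmin), se_fmax=float(se_fmax),
        se_K=float(se_K), se_n=float(se_n),
        converged=True, sse=sse, n_points=len(d),
    )
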
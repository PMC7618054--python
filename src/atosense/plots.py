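"""Minimal plotting helpers: dose-response curves and the mu* heatmap."""

from __future__ import annotations

import numpy as np

from .doseresponse import DoseResponseCurve, HillFit
from .morris import MorrisResult


def plot_dose_response(curve: DoseResponseCurve, fit: HillFit | None = None, ax=None):
    """Log-x dose-response scatter with an optional fitted Hill curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.dose, curve.response, "o", label="steady-state response")
    if curve.replicate_sd is not None:
        ax.errorbar(curve.dose, curve.response, yerr=curve.replicate_sd,
                    fmt="none", alpha=0.5)
    if fit is not None and fit.converged:
        lo = max(curve.dose[curve.dose > 0].min() / 3, 1e-12)
        grid = np.logspace(np.log10(lo), np.log10(curve.dose.max() * 3), 200)
        ax.plot(grid, fit.predict(grid), "-",
                label=f"Hill fit (K={fit.K:.3g}, n={fit.n:.2g})")
        ax.axvline(fit.K, ls="--", lw=0.8, color="grey")
    ax.set_xscale("log")
    ax.set_xlabel("dose")
    ax.set_ylabel("response")
    ax.legend()
    return ax


def plot_mu_star_heatmap(result: MorrisResult, ax=None):
    """Normalised mu* heatmap: rows parameters, columns response features."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 7))
    frame = result.heatmap_frame()
    im = ax.imshow(frame.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(frame.columns)), frame.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(frame.index)), frame.index)
    ax.figure.colorbar(im, ax=ax, label="normalised $\\mu^*$")
    return ax
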
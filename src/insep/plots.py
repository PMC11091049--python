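"""Diagnostic and result plots (matplotlib)."""

from __future__ import annotations

import numpy as np

from .deconvolution import FitDiagnostics
from .metrics import DecompositionResult


def plot_fit_diagnostics(diag: FitDiagnostics, times=None):
    """Studentized residuals vs standardized predictions and vs time."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    stud = np.asarray(diag.studentized_residuals)
    pred = diag.extras.get("predicted")
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    if pred is not None:
        z = (pred - np.mean(pred)) / (np.std(pred) or 1.0)
        axes[0].plot(z, stud, "ko")
    axes[0].axhline(0, color="0.6", lw=0.8)
    axes[0].set_xlabel("standardized prediction")
    axes[0].set_ylabel("Studentized residual")
    x = times if times is not None else np.arange(stud.size)
    axes[1].plot(x, stud, "ko")
    axes[1].axhline(0, color="0.6", lw=0.8)
    axes[1].set_xlabel("time (min)" if times is not None else "sample index")
    axes[1].set_ylabel("Studentized residual")
    fig.tight_layout()
    return fig


def plot_decomposition(result: DecompositionResult):
    """Measured total, predicted endogenous and derived exogenous insulin."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.times, result.i_total, "k.-", label="total (measured)")
    ax.plot(result.times, result.i_endo, "-", color="0.5", label="endogenous (predicted)")
    ax.plot(result.times, result.i_exo, "k--", label="exogenous (derived)")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("plasma insulin (pmol/L)")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig
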
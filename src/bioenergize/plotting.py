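"""Small plotting helpers for consumption distributions and sensitivity bars."""

from __future__ import annotations

import numpy as np

from .uncertainty import ConsumptionDraws, SensitivityReport

__all__ = ["plot_consumption_distributions", "plot_sensitivity"]


def plot_consumption_distributions(draws_list: list[ConsumptionDraws],
                                   path=None, ax=None):
    """Overlay the fitted log-normal consumption curves of several models."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy import stats

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    hi = max(np.quantile(d.draws, 0.99) for d in draws_list)
    grid = np.linspace(1.0, hi, 400)
    for d in draws_list:
        pdf = stats.lognorm.pdf(grid, s=d.lognormal_sigma,
                                scale=np.exp(d.lognormal_mu))
        ax.plot(grid, pdf / pdf.max(),
                label=f"{d.model} (median {d.median:.0f}, σ {d.lognormal_sigma:.2f})")
    ax.set_xlabel("consumption (J g$^{-1}$ day$^{-1}$)")
    ax.set_ylabel("relative probability")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_sensitivity(report: SensitivityReport, path=None, ax=None):
    """Bar chart of standardized regression coefficients for one model."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    items = report.ranked()
    names = [k for k, _ in items]
    values = [v for _, v in items]
    ax.bar(range(len(items)), values)
    ax.set_xticks(range(len(items)), names, rotation=45, ha="right")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("standardized coefficient")
    ax.set_title(f"{report.model} model (R² = {report.r_squared:.3f})")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
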
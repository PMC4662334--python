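"""Generic diagnostic plots for simulation studies and fitted surfaces."""

from __future__ import annotations

import numpy as np

from .density import DensityModel
from .evaluation import StudyResult


def plot_density_profiles(
    result: StudyResult, estimator: str = "singlecatch", ax=None
):
    """East-west density profiles: truth, per-replicate fits, and their mean."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    region = result.geometry.full_report
    xs = np.unique(region.points[:, 0])
    pts = np.column_stack([xs, np.zeros_like(xs)])
    recs = result.usable_records(estimator)
    fits = np.array(
        [DensityModel(r.fit.density_form, r.fit.phi_hat).intensity(pts) for r in recs]
    )
    for row in fits:
        ax.plot(xs, row, color="0.7", lw=0.5)
    ax.plot(xs, fits.mean(axis=0), "k--", label="mean estimate")
    ax.plot(xs, result.geometry.model.intensity(pts), "k-", label="truth")
    tx = result.geometry.design.traps.x
    for edge in (tx.min(), tx.max()):
        ax.axvline(edge, color="r", ls=":", lw=0.8)
    ax.set_xlabel("east-west coordinate (m)")
    ax.set_ylabel("density (per ha)")
    ax.legend()
    return ax


def plot_slope_distribution(result: StudyResult, ax=None):
    """Sampling distributions of the density-slope estimates per estimator."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for est, recs in result.records.items():
        vals = [r.estimates["slope"] for r in recs if r.usable and "slope" in r.estimates]
        if vals:
            ax.hist(vals, bins=30, alpha=0.5, label=est)
    truth = result.geometry.truths.get("slope")
    if truth is not None:
        ax.axvline(truth, color="r", label="truth")
    ax.set_xlabel("slope estimate (per m)")
    ax.legend()
    return ax


def plot_surface_metrics(summaries: list[dict], metric: str = "rmspe", ax=None):
    """Bar chart of RMSPE or RMSB across study cells, full vs reduced area."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = []
    width = 0.35
    for i, summ in enumerate(summaries):
        labels.append(summ["scenario"])
        for j, est in enumerate(sorted(summ["estimators"])):
            entry = summ["estimators"][est]
            if "surface_metrics" not in entry:
                continue
            val, se = entry["surface_metrics"]["full"][metric]
            ax.bar(
                i + (j - 0.5) * width,
                val,
                width=width,
                yerr=2 * se,
                color=f"C{j}",
                label=est if i == 0 else None,
            )
    ax.set_xticks(range(len(labels)), labels)
    ax.set_ylabel(metric.upper())
    ax.legend()
    return ax
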
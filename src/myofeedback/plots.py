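"""Plotting hooks: hold-phase ER distributions and session trend lines."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .stats import SessionSummary, longitudinal_trend  # noqa: E402


def plot_er_distributions(er_by_label: dict[str, np.ndarray], ax=None):
    """Violin plot of pointwise hold-phase ER per device/condition.

    A well-matched pair of sensors during co-activated grips produces
    distributions centered near 0.5.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 + 1.2 * len(er_by_label), 4))
    labels = list(er_by_label)
    data = [np.concatenate([np.ravel(v)]) for v in er_by_label.values()]
    ax.violinplot(data, showmedians=True)
    ax.axhline(0.5, color="gray", ls="--", lw=0.8)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel("extensor ratio")
    ax.set_ylim(0, 1)
    return ax.figure


def plot_session_trend(summaries: list[SessionSummary], field: str = "er_mean", ax=None):
    """Scatter of a per-session field against session number with its OLS line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    usable = [s for s in summaries if not s.excluded]
    x = np.array([s.session_index for s in usable], dtype=float)
    y = np.array([getattr(s, field) for s in usable], dtype=float)
    ax.plot(x, y, "o", ms=4)
    if len(usable) >= 3 and np.ptp(y) > 0:
        trend = longitudinal_trend(summaries, field)
        coef = np.polyfit(x, y, 1)
        xs = np.array([x.min(), x.max()])
        ax.plot(xs, np.polyval(coef, xs), "-", lw=1.5,
                label=f"rho={trend.rho:.2f}, p={trend.p:.3g}")
        ax.legend(frameon=False)
    ax.set_xlabel("session")
    ax.set_ylabel(field)
    return ax.figure
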
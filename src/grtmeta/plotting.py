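"""Static figures: the decision space and the SvM curve with its band."""

from __future__ import annotations

import numpy as np

from .model import StimulusCondition
from .svm import aggregate_reference_criteria

__all__ = ["plot_decision_space", "plot_svm_curve"]

_COLORS = {
    StimulusCondition.CORRECT_NAME: "tab:red",
    StimulusCondition.INCORRECT_NAME: "tab:blue",
    StimulusCondition.CATCH: "tab:gray",
}


def _ellipse_points(mean, rho, n=200):
    # 1-SD contour of a unit-variance bivariate normal with correlation rho
    t = np.linspace(0, 2 * np.pi, n)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    pts = chol @ np.vstack([np.cos(t), np.sin(t)])
    return mean[0] + pts[0], mean[1] + pts[1]


def plot_decision_space(fitted, ax=None):
    """Group-level stimulus ellipses plus the aggregated criteria."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for stim in StimulusCondition:
        x, y = _ellipse_points(
            fitted.group.mean(stim), fitted.group.correlation(stim)
        )
        ax.plot(x, y, color=_COLORS[stim], label=stim.name.lower())
        ax.plot(*fitted.group.mean(stim), "o", color=_COLORS[stim], ms=4)
    c1, c2 = aggregate_reference_criteria(fitted.participants)
    for c in (c1, c2):
        ax.axvline(c, color="green", ls=":", lw=1)
    cy = np.mean(
        [p.c_y * np.sqrt(p.kappa * (1 - p.lam)) for p in fitted.participants]
    )
    ax.axhline(cy, color="green", ls=":", lw=1)
    ax.set_xlabel("recognition / confidence evidence (x)")
    ax.set_ylabel(f"{fitted.judgment} evidence (y)")
    ax.legend(loc="best", fontsize=8)
    ax.set_title("fitted decision space")
    return ax


def plot_svm_curve(curve, band=None, ax=None):
    """meta-d' against relative likelihood, with the objective criterion
    (blue), participant criteria (green) and optional bootstrap band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if band is not None:
        ax.fill_between(
            band.L_grid,
            band.lower,
            band.upper,
            color="red",
            alpha=0.2,
            label=f"{band.level:.0%} bootstrap band",
        )
    ax.plot(curve.rel_likelihood, curve.meta_d, color="red", label="SvM curve")
    ax.axvline(1.0, color="blue", lw=1.2, label="objective criterion (L=1)")
    for i, pos in enumerate(curve.participant_positions):
        ax.axvline(
            pos,
            color="green",
            lw=0.6,
            alpha=0.6,
            label="participant criteria" if i == 0 else None,
        )
    ax.axhline(0.0, color="black", lw=0.6)
    ax.set_xlabel(f"relative likelihood of {curve.judgment}")
    ax.set_ylabel("conditional meta-d'")
    ax.set_xlim(left=0)
    ax.legend(loc="best", fontsize=8)
    return ax
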
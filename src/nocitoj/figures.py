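"""Summary figures: fitted logistic curves and bar panels with
within-subject CIs, in the layout used for crossmodal TOJ results."""

from __future__ import annotations

import numpy as np

from .analysis import cousineau_ci
from .psychometric import PsychometricParams, response_probability

__all__ = ["plot_results"]


def plot_results(results: dict, path) -> None:
    """Write a two-panel PNG: group psychometric curves (cue frame for
    unilateral cells) with dashed PSS verticals, and PSS bars with
    Cousineau 95% CIs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pss_mat = results["pss_matrix"]  # (n, 2, 2)
    slope_mat = results["slope_matrix"]
    labels = _cell_labels(results)
    fig, (ax_curve, ax_bar) = plt.subplots(1, 2, figsize=(10, 4))

    x = np.linspace(-200, 200, 401)
    colors = ["tab:blue", "tab:red", "tab:cyan", "tab:orange"]
    for idx, label in enumerate(labels):
        i, j = divmod(idx, 2)
        pss = pss_mat[:, i, j].mean()
        beta = slope_mat[:, i, j].mean()
        curve = response_probability(x, PsychometricParams(pss, beta))
        ax_curve.plot(x, curve, color=colors[idx], label=label)
        ax_curve.axvline(pss, color=colors[idx], linestyle="--", linewidth=0.8)
    ax_curve.axhline(0.5, color="gray", linewidth=0.5)
    ax_curve.set_xlabel("SOA (ms)")
    ax_curve.set_ylabel("P(reference first)")
    ax_curve.legend(fontsize=7)

    ci = cousineau_ci(pss_mat.reshape(pss_mat.shape[0], 4))
    ax_bar.bar(range(4), ci["mean"], yerr=ci["half_width"], capsize=4,
               color=colors[:4])
    ax_bar.set_xticks(range(4), labels, rotation=20, fontsize=7)
    ax_bar.set_ylabel("PSS (ms)")
    ax_bar.axhline(0, color="black", linewidth=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _cell_labels(results: dict) -> list[str]:
    tab = results["anova_pss"]
    if tab.factor_a == "cue_condition":
        return ["unilateral near", "unilateral far", "bilateral near", "bilateral far"]
    return ["near congruent", "near incongruent", "far congruent", "far incongruent"]
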
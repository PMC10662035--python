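"""Diagnostic figures: growth-rate map and reflection curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_growth_rates(scan: pd.DataFrame):
    """Growth rate of the 2*kappa mode versus normalized forcing amplitude."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.plot(scan["a_rel"], scan["r_n1"], "o-", color="seagreen")
    ax.set_xlabel(r"$a/a^*$")
    ax.set_ylabel(r"$r_{n1}$ at $2\kappa$  [1/period]")
    ax.set_title("Modulation growth rate of the seagrass perturbation")
    fig.tight_layout()
    return fig


def plot_reflection_curves(curves):
    """K_R versus 2*kappa/kappa_n1* for each pattern-amplitude multiplier."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    styles = {0.5: ("--", "yellowgreen"), 1.0: ("-", "seagreen"),
              2.0: ("-.", "darkgreen")}
    for c in curves:
        ls, color = styles.get(c.amplitude_multiplier, ("-", "gray"))
        ax.plot(c.kappa_ratio, c.K_R, ls, color=color,
                label=f"amplitude x{c.amplitude_multiplier:g}")
    ax.axvline(1.0, color="0.6", lw=0.8)
    ax.set_xlabel(r"$2\kappa/\kappa_{n1}^*$")
    ax.set_ylabel(r"$K_R$")
    ax.set_title("Bragg reflection over the frozen seagrass topography")
    ax.legend()
    fig.tight_layout()
    return fig
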
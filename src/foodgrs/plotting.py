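"""Forest plot of stratified food effects (low vs high genetic risk)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .interaction_screen import StratifiedEffects  # noqa: E402


def forest_plot(
    results: Sequence[StratifiedEffects], path: str | Path
) -> None:
    """b-coefficients with 95% CI for each food, per risk stratum."""
    fig, ax = plt.subplots(figsize=(7, 1.2 * max(len(results), 1) + 1))
    ys, labels = [], []
    y = 0.0
    for res in results:
        for grp, color in (("low", "tab:blue"), ("high", "tab:red")):
            d = res.per_group[grp]
            ax.errorbar(
                d["b"], y,
                xerr=[[d["b"] - d["ci_low"]], [d["ci_high"] - d["b"]]],
                fmt="o", color=color, capsize=3,
            )
            ys.append(y)
            labels.append(f"{res.food} ({grp})")
            y += 1.0
        y += 0.5
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels(labels)
    ax.set_xlabel("food effect on BMIz, b (95% CI)")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
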
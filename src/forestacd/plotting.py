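"""Best-effort figures: ACD distribution panels per equation and arm."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .plot_acd import AcdSampleSet


def plot_acd_distributions(
    samples: AcdSampleSet, path: str | Path, title: str = "ACD distributions"
) -> None:
    """One violin panel per error scenario, one violin per equation plus the
    pooled distribution, ACD on the y axis in Mg C ha^-1."""
    df = samples.samples
    scenarios = list(df["scenario"].unique())
    fig, axes = plt.subplots(
        1, len(scenarios), figsize=(4.5 * len(scenarios), 4.0), squeeze=False, sharey=True
    )
    for ax, scen in zip(axes[0], scenarios):
        sub = df[df["scenario"] == scen]
        groups = [g["acd_mg_c_ha"].to_numpy() for _, g in sub.groupby("equation")]
        labels = [str(eid) for eid, _ in sub.groupby("equation")]
        groups.append(sub["acd_mg_c_ha"].to_numpy())
        labels.append("pooled")
        ax.violinplot(groups, showmedians=True)
        ax.set_xticks(range(1, len(labels) + 1), labels, rotation=45, ha="right")
        ax.set_title(scen)
        ax.set_ylabel("ACD (Mg C ha$^{-1}$)")
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
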
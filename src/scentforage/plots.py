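"""Quick-look figures for sweep tables.

One panel grid summarises a competition sweep: per-capita nectar collected,
the scent/no-scent collected ratio, nectar per visit, CV of remaining
nectar, visits per flower and pollen carryover, each against pollinator
abundance with one line per refill coefficient and strategy.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_PANELS = [
    ("mean_nectar_collected", "nectar collected / pollinator"),
    ("mean_nectar_per_visit", "nectar / accepted visit"),
    ("cv_nectar_remaining", "CV of remaining nectar"),
    ("mean_visits_per_flower", "visits / flower"),
    ("mean_pollen_transfer", "pollen carryover"),
]


def plot_competition_sweep(table: pd.DataFrame, out_path: str | Path) -> Path:
    """Render the standard panel grid from a tidy competition-sweep table.

    Expects the columns produced by
    :func:`scentforage.experiments.run_sweep` on a design with
    ``pollinator_ratio``, ``refill_coef`` and ``use_scent`` axes.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = table.groupby(["refill_coef", "pollinator_ratio", "use_scent"]).mean(
        numeric_only=True
    )
    refills = sorted(table["refill_coef"].unique())

    fig, axes = plt.subplots(2, 3, figsize=(13, 7), sharex=True)
    axes = axes.ravel()
    for ax, (column, label) in zip(axes, _PANELS):
        for refill in refills:
            for scent, style in ((True, "-o"), (False, "--s")):
                sub = cells.xs((refill, scent), level=("refill_coef", "use_scent"))
                ax.plot(sub.index, sub[column], style, ms=3,
                        label=f"c={refill} {'scent' if scent else 'no scent'}")
        ax.set_ylabel(label)
        ax.set_xlabel("pollinators per flower")

    # last panel: the collected-nectar ratio with its break-even line
    ax = axes[-1]
    for refill in refills:
        s = cells.xs((refill, True), level=("refill_coef", "use_scent"))["mean_nectar_collected"]
        ns = cells.xs((refill, False), level=("refill_coef", "use_scent"))["mean_nectar_collected"]
        ax.plot(s.index, s / ns, "-o", ms=3, label=f"c={refill}")
    ax.axhline(1.0, color="red", ls=":")
    ax.set_ylabel("collected: scent / no scent")
    ax.set_xlabel("pollinators per flower")
    axes[0].legend(fontsize=6)
    ax.legend(fontsize=6)
    fig.tight_layout()

    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
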
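"""Diagnostic seasonal boxplots of the analysis responses."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SEASON_COLORS = {"summer": "#e08214", "winter": "#2166ac"}


def seasonal_boxplots(records: pd.DataFrame, out_dir) -> list[Path]:
    """One boxplot per response kind, split by season; returns written paths.

    ``records`` is the long analysis-record table (kind, season, value).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for kind, sub in records.groupby("kind"):
        seasons = [s for s in ("summer", "winter") if (sub["season"] == s).any()]
        fig, ax = plt.subplots(figsize=(4, 3.2))
        box = ax.boxplot(
            [sub.loc[sub["season"] == s, "value"] for s in seasons],
            tick_labels=seasons,
            patch_artist=True,
        )
        for patch, s in zip(box["boxes"], seasons):
            patch.set_facecolor(SEASON_COLORS[s])
        ax.set_ylabel(kind)
        fig.tight_layout()
        path = out_dir / f"{kind}_by_season.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
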
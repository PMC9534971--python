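"""Summary figures for pipeline output: coverage, proliferation, layering,
and radial profiles, in the layout conventions of the coculture readouts
(islands purple, networks green, total EC yellow; profiles on a 0-255
scale with the Fn/SMC ratio overlaid)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

CLASS_COLORS = {"island": "#9628b4", "network": "#28b43c", "gap": "#444444"}


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def render_report(result_dir: Path, out_png: Path | None = None) -> Path:
    """Render a 2x2 summary figure from ``run_pipeline`` output tables."""
    region = _read_table(result_dir / "region_table.csv")
    profiles = _read_table(result_dir / "profile_table.csv")
    out_png = out_png or result_dir / "report.png"

    fig, axes = plt.subplots(2, 2, figsize=(11, 8))

    ax = axes[0, 0]
    for i, cname in enumerate(("island", "network", "gap")):
        sub = region[region["region_class"] == cname]
        ax.bar(
            np.arange(len(sub)) + i * 0.28,
            100 * sub["area_fraction"],
            width=0.26,
            color=CLASS_COLORS[cname],
            label=cname,
        )
        ax.set_xticks(np.arange(len(sub)) + 0.28, sub["zone"])
    ax.set_ylabel("area covered (%)")
    ax.set_title("EC coverage by region class")
    ax.legend()

    ax = axes[0, 1]
    sub = region.dropna(subset=["smc_prolif_pct"])
    colors = [CLASS_COLORS[c] for c in sub["region_class"]]
    ax.bar(
        [f"{z}\n{c}" for z, c in zip(sub["zone"], sub["region_class"])],
        sub["smc_prolif_pct"],
        color=colors,
    )
    ax.set_ylabel("proliferative SMCs (%)")
    ax.set_title("SMC proliferation by region")

    ax = axes[1, 0]
    sub = region.dropna(subset=["smc_intensity_norm"])
    ax.bar(
        [f"{z}\n{c}" for z, c in zip(sub["zone"], sub["region_class"])],
        sub["smc_intensity_norm"],
        color=[CLASS_COLORS[c] for c in sub["region_class"]],
    )
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_ylabel("cell-tracker intensity (island = 1)")
    ax.set_title("SMC layering index")

    ax = axes[1, 1]
    x = profiles["bin_index"]
    if profiles["smc_0_255"].notna().any():
        ax.plot(x, profiles["smc_0_255"], color="#c03030", label="SMC (0-255)")
    if profiles["fn_0_255"].notna().any():
        ax.plot(x, profiles["fn_0_255"], color="#808080", label="Fn (0-255)")
    ax.set_xlabel("radial bin (rim -> center)")
    ax.set_ylabel("intensity (0-255)")
    if profiles["fn_over_smc"].notna().any():
        ax2 = ax.twinx()
        ax2.plot(x, profiles["fn_over_smc"], color="#3060c0", label="Fn / SMC")
        ax2.set_ylabel("Fn / SMC")
    ax.set_title("radial profiles")
    ax.legend(loc="upper right")

    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return out_png
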
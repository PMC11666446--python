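"""Optional figure outputs (written to file, never displayed)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .evaluation import CalibrationReport  # noqa: E402

__all__ = ["plot_independence", "plot_calibration_radar"]


def plot_independence(table: pd.DataFrame, path: str | Path) -> Path:
    """Heat-table of within-bin correlations for one scaler."""
    path = Path(path)
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), constrained_layout=True)
    for ax, sex in zip(axes, ("male", "female")):
        sub = table[table["sex"] == sex]
        vals = sub["r"].to_numpy()[:, None]
        ax.imshow(vals, vmin=-0.5, vmax=0.5, cmap="RdBu", aspect="auto")
        ax.set_yticks(range(len(sub)), sub["wl_bin"])
        ax.set_xticks([])
        for i, (r, sig) in enumerate(zip(sub["r"], sub["significant"])):
            text = "n/a" if not np.isfinite(r) else f"{r:.2f}" + ("*" if sig else "")
            ax.text(0, i, text, ha="center", va="center", fontsize=8)
        ax.set_title(sex)
    fig.suptitle(f"Within-bin r of VO2peak/{table.attrs.get('scaler', '?')} vs scaler")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_calibration_radar(report: CalibrationReport, path: str | Path) -> Path:
    """Radar chart of subgroup calibration slopes around the unit circle."""
    path = Path(path)
    fig, axes = plt.subplots(
        1, 2, figsize=(9, 4.5), subplot_kw={"projection": "polar"}, constrained_layout=True
    )
    for ax, sex in zip(axes, ("male", "female")):
        sub = report.table[report.table["sex"] == sex]
        if sub.empty:
            continue
        labels = (sub["age_band"] + "y\n" + sub["bmi_band"]).tolist()
        angles = np.linspace(0, 2 * np.pi, len(sub), endpoint=False)
        slopes = sub["slope"].to_numpy()
        ax.plot(np.r_[angles, angles[:1]], np.r_[slopes, slopes[:1]], "o-")
        ax.fill_between(np.linspace(0, 2 * np.pi, 100), 0.95, 1.05, alpha=0.2, color="gray")
        ax.set_xticks(angles, labels, fontsize=7)
        ax.set_ylim(0.5, 1.5)
        ax.set_title(sex)
    fig.suptitle(f"Calibration slopes ({report.model})")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
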
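"""Report renderers: radar charts of dependency profiles and ∆ Annexin V heatmaps.

Every renderer also writes its plotted numbers as a CSV sidecar, and is a
pure function of its inputs: with the style pinned here, re-rendering the
same table produces byte-identical SVG.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ValidationError
from .scoring import SCORE_AXES, DependencyProfile

_SAVEFIG_KW = {"metadata": {"Date": None}}


def _deterministic_style() -> None:
    plt.rcParams["svg.hashsalt"] = "bh3kit"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".csv")


def render_radar(
    profiles: DependencyProfile | list[DependencyProfile] | dict[str, dict[str, float]],
    path,
    reference_score: float = 100.0,
    title: str | None = None,
) -> Path:
    """Radar chart of one or more three-axis profiles, reference polygon at 100.

    ``profiles`` may be a single profile, a list (e.g. vehicle vs pre-treated
    arms of a dynamic experiment), or a mapping label → {axis: score}.
    """
    if isinstance(profiles, DependencyProfile):
        series = {profiles.sample_id: profiles.scores}
    elif isinstance(profiles, list):
        series = {p.sample_id: p.scores for p in profiles}
    else:
        series = {str(k): dict(v) for k, v in profiles.items()}
    for label, scores in series.items():
        missing = [a for a in SCORE_AXES if a not in scores]
        if missing:
            raise ValidationError(f"profile {label!r} missing axis/axes {missing}")

    path = Path(path)
    _deterministic_style()
    angles = np.linspace(0, 2 * np.pi, len(SCORE_AXES), endpoint=False).tolist()
    angles_closed = angles + angles[:1]

    fig, ax = plt.subplots(figsize=(5, 5), subplot_kw={"polar": True})
    ref = [reference_score] * (len(SCORE_AXES) + 1)
    ax.plot(angles_closed, ref, linestyle=":", color="0.4", label=f"control ({reference_score:g})")
    for label in sorted(series):
        vals = [series[label][a] for a in SCORE_AXES]
        ax.plot(angles_closed, vals + vals[:1], label=label)
        ax.fill(angles_closed, vals + vals[:1], alpha=0.15)
    ax.set_xticks(angles)
    ax.set_xticklabels(SCORE_AXES)
    ax.set_title(title or "Anti-apoptotic dependency profile")
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.savefig(path, **_SAVEFIG_KW)
    plt.close(fig)

    rows = [{"label": label, **{a: series[label][a] for a in SCORE_AXES}} for label in sorted(series)]
    pd.DataFrame(rows).to_csv(_sidecar(path), index=False)
    return path


def render_heatmap(
    delta_table: pd.DataFrame,
    path,
    value_col: str = "delta_pct",
    vmin: float = 0.0,
    vmax: float = 100.0,
) -> Path:
    """Heatmap of ∆ Annexin V over the drug × dose grid (one block per sample).

    Fixed color scale [0, 100]; missing grid cells render blank with a warning.
    """
    required = {"sample_id", "drug", "dose_nM", value_col}
    missing = required - set(delta_table.columns)
    if missing:
        raise ValidationError(f"delta table missing columns {sorted(missing)}")
    path = Path(path)
    _deterministic_style()

    pivot = delta_table.pivot_table(
        index=["sample_id", "drug"], columns="dose_nM", values=value_col, aggfunc="mean"
    ).sort_index()
    if pivot.isna().any().any():
        warnings.warn("incomplete drug × dose grid: blank cells in heatmap", stacklevel=2)

    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * pivot.shape[1], 0.8 + 0.4 * pivot.shape[0]))
    masked = np.ma.masked_invalid(pivot.to_numpy(dtype=float))
    im = ax.imshow(masked, aspect="auto", cmap="viridis", vmin=vmin, vmax=vmax)
    ax.set_xticks(range(pivot.shape[1]))
    ax.set_xticklabels([f"{d:g} nM" for d in pivot.columns])
    ax.set_yticks(range(pivot.shape[0]))
    ax.set_yticklabels([f"{s} / {d}" for s, d in pivot.index])
    fig.colorbar(im, ax=ax, label="∆ Annexin V (pp)")
    fig.tight_layout()
    fig.savefig(path, **_SAVEFIG_KW)
    plt.close(fig)

    pivot.reset_index().to_csv(_sidecar(path), index=False)
    return path
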
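"""Fold-change graphics: the diverging blue/red heat map and per-contrast bar graphs.

The heat map shows the "most active" genes × contrasts for a probe set:
activity is mean absolute log2 fold change (genes scored over all
contrasts, then contrasts scored over the chosen genes).  Red means
upregulated, blue downregulated, white no change; the scale is symmetric
about 0 and clipped so single outliers do not wash it out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless, deterministic rendering

import matplotlib.pyplot as plt
import numpy as np

from .core import ContrastDatabase, EmptyResultError, ValidationError

#: diverging palette: pure blue at -limit, white at 0, pure red at +limit
CMAP = "bwr"

_SAVEFIG = dict(dpi=100, metadata={"Software": "exprsearch"})


@dataclass
class HeatmapPanel:
    """The selected fold-change submatrix behind one heat map."""

    gene_rows: list[str]
    contrast_cols: list[str]
    values: np.ndarray
    color_limit: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_rows), len(self.contrast_cols)):
            raise ValidationError(
                f"panel shape {self.values.shape} does not match "
                f"{len(self.gene_rows)} rows x {len(self.contrast_cols)} cols"
            )
        if self.color_limit <= 0:
            finite = np.abs(self.values[np.isfinite(self.values)])
            # 98th percentile keeps one extreme cell from flattening the scale
            self.color_limit = float(np.percentile(finite, 98)) if finite.size else 1.0
            if self.color_limit <= 0:
                self.color_limit = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _rank_by_activity(scores: dict[str, float], limit: int) -> list[str]:
    usable = [(k, v) for k, v in scores.items() if np.isfinite(v)]
    usable.sort(key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in usable[:limit]]


def select_active(
    probes,
    db: ContrastDatabase,
    max_genes: int = 10,
    max_contrasts: int = 30,
    color_limit: float = 0.0,
) -> HeatmapPanel:
    """Pick the most active genes and contrasts for a probe set.

    Gene activity = mean |fold| across all contrasts (missing skipped);
    the top ``max_genes`` genes are kept, then contrast activity = mean
    |fold| over those genes picks the top ``max_contrasts`` contrasts.
    Ties break by id ascending.  Never pads: a small database yields a
    small panel.
    """
    universe = set(db.probe_universe)
    present = sorted({str(p) for p in probes} & universe)
    if not present:
        raise EmptyResultError("none of the requested probes are in the database")
    sub = db.fold_table.loc[present].abs()
    gene_scores = dict(sub.mean(axis=1, skipna=True))
    genes = _rank_by_activity(gene_scores, max_genes)
    if not genes:
        raise EmptyResultError("requested probes have no fold-change values in any contrast")
    contrast_scores = dict(sub.loc[genes].mean(axis=0, skipna=True))
    contrasts = _rank_by_activity(contrast_scores, max_contrasts)
    values = db.fold_table.loc[genes, contrasts].to_numpy()
    return HeatmapPanel(
        gene_rows=genes, contrast_cols=contrasts, values=values, color_limit=color_limit
    )


def render_heatmap(panel: HeatmapPanel, path: str | Path) -> Path:
    """Write the panel as a PNG heat map (blue = down, red = up)."""
    if panel.values.size == 0:
        raise ValidationError("cannot render an empty panel")
    n_rows, n_cols = panel.shape
    fig, ax = plt.subplots(figsize=(max(4.0, 0.32 * n_cols + 2.2), max(2.5, 0.3 * n_rows + 1.8)))
    cmap = plt.get_cmap(CMAP).copy()
    cmap.set_bad("#d9d9d9")
    im = ax.imshow(
        np.ma.masked_invalid(panel.values),
        cmap=cmap,
        vmin=-panel.color_limit,
        vmax=panel.color_limit,
        aspect="auto",
        interpolation="nearest",
    )
    ax.set_yticks(range(n_rows), labels=panel.gene_rows, fontsize=7)
    ax.set_xticks(range(n_cols), labels=panel.contrast_cols, fontsize=6, rotation=90)
    cbar = fig.colorbar(im, ax=ax, shrink=0.8)
    cbar.set_label("log2 fold change")
    fig.tight_layout()
    out = Path(path)
    fig.savefig(out, **_SAVEFIG)
    plt.close(fig)
    return out


def render_bargraph(
    probes: list[str],
    db: ContrastDatabase,
    path: str | Path,
    max_panels: int = 5,
    max_probes: int = 10,
    contrast_ids: list[str] | None = None,
) -> list[Path]:
    """Grouped bars of fold change per probe, one panel per contrast.

    Up to ``max_panels`` contrast panels per image; further contrasts are
    paginated into ``<stem>_p2.png``, ``<stem>_p3.png``, ...  Returns the
    written paths.  Gene sets larger than ``max_probes`` are rejected (a
    heat map is the right display for those).
    """
    universe = set(db.probe_universe)
    present = [str(p) for p in probes if str(p) in universe]
    if not present:
        raise EmptyResultError("none of the requested probes are in the database")
    if len(present) > max_probes:
        raise ValidationError(
            f"{len(present)} probes exceed the bar-graph cap of {max_probes}; "
            "use the heat map output instead"
        )
    cids = contrast_ids if contrast_ids is not None else list(db.fold_table.columns)
    if not cids:
        raise EmptyResultError("database holds no contrasts to plot")
    out = Path(path)
    pages = [cids[i : i + max_panels] for i in range(0, len(cids), max_panels)]
    written: list[Path] = []
    width = 0.8 / len(present)
    colors = plt.get_cmap("tab10").colors
    for page_no, page in enumerate(pages, 1):
        fig, axes = plt.subplots(
            1, len(page), figsize=(2.2 * len(page) + 1.5, 3.2), sharey=True, squeeze=False
        )
        for ax, cid in zip(axes[0], page):
            folds = db.fold_table.loc[present, cid].to_numpy()
            xs = np.arange(len(present)) * width
            ax.bar(
                xs,
                np.nan_to_num(folds, nan=0.0),
                width=width * 0.9,
                color=[colors[i % len(colors)] for i in range(len(present))],
            )
            ax.axhline(0.0, color="black", linewidth=0.8)
            ax.set_xticks(xs, labels=present, rotation=90, fontsize=6)
            ax.set_title(cid, fontsize=7)
        axes[0][0].set_ylabel("log2 fold change")
        fig.tight_layout()
        target = out if page_no == 1 else out.with_name(f"{out.stem}_p{page_no}{out.suffix}")
        fig.savefig(target, **_SAVEFIG)
        plt.close(fig)
        written.append(target)
    return written
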
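"""Outer merge of per-gene-set summary tables and the figure families.

The merged matrix unions categories across gene sets (missing cells are
zero) and keeps one column per input table in input order.  Figures:
pie charts (one per gene set), a grouped bar plot, raw and
log10(x+1)-transformed heatmaps, and a bubble graph whose marker areas
scale with each cell's share of its column total.

Figure tests assert the data fed to the plotting layer (fractions,
matrix values), never pixels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .formats_io import FormatError, SlimCountTable

__all__ = [
    "MergedTable",
    "merge_tables",
    "log_transform",
    "pie_fractions",
    "bubble_sizes",
    "render",
    "write_merged_table",
    "read_merged_table",
    "PLOT_KINDS",
]

PLOT_KINDS = ("pie", "bar", "heatmap", "heatmap_log", "bubble")


@dataclass
class MergedTable:
    """Category x gene-set matrix assembled from several summary tables."""

    categories: list[str]
    samples: list[str]
    matrix: np.ndarray  # shape (n_categories, n_samples)
    kind: str
    level: str = "gene"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.categories,
                            columns=self.samples)

    def column_sums(self) -> dict[str, float]:
        return dict(zip(self.samples, self.matrix.sum(axis=0)))


def merge_tables(tables: Sequence[SlimCountTable]) -> MergedTable:
    """Outer-merge >= 1 summary tables sharing level and kind.

    Categories become the sorted union; columns keep the input order;
    cells absent from a source table are 0, so each column sum equals
    its source table's total.
    """
    if not tables:
        raise ValueError("need at least one table to merge")
    kinds = {t.kind for t in tables}
    levels = {t.level for t in tables}
    if len(kinds) > 1 or len(levels) > 1:
        raise ValueError(
            f"cannot merge tables of mixed kind {sorted(kinds)} or "
            f"level {sorted(levels)}")
    categories = sorted(set().union(*(t.values.keys() for t in tables)))
    samples = [t.label for t in tables]
    matrix = np.zeros((len(categories), len(tables)), dtype=float)
    for j, t in enumerate(tables):
        for i, cat in enumerate(categories):
            matrix[i, j] = t.values.get(cat, 0)
    return MergedTable(categories, samples, matrix,
                       kind=tables[0].kind, level=tables[0].level)


def log_transform(m: MergedTable) -> MergedTable:
    """Elementwise log10(x + 1); zeros stay zero.  Raw counts only."""
    if m.kind != "raw":
        raise ValueError("log transform applies to raw count tables")
    if (m.matrix < 0).any():
        raise ValueError("negative cell in raw count matrix")
    return replace(m, matrix=np.log10(m.matrix + 1.0), kind="raw")


def pie_fractions(values: Sequence[float]) -> np.ndarray:
    """Wedge fractions for one gene set's column (sums to 1)."""
    arr = np.asarray(values, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("pie chart needs a positive column total")
    return arr / total


def bubble_sizes(m: MergedTable) -> np.ndarray:
    """Per-cell share of its column total — the bubble scaling matrix."""
    totals = m.matrix.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(totals > 0, m.matrix / totals, 0.0)
    return shares


def write_merged_table(m: MergedTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("GO_slim_category\t" + "\t".join(m.samples) + "\n")
        for i, cat in enumerate(m.categories):
            cells = [
                str(int(v)) if m.kind == "raw" and float(v).is_integer()
                else repr(float(v))
                for v in m.matrix[i]
            ]
            fh.write(cat + "\t" + "\t".join(cells) + "\n")


def read_merged_table(path: str | os.PathLike, kind: str = "raw",
                      level: str = "gene") -> MergedTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "GO_slim_category":
        raise FormatError("missing 'GO_slim_category' header column", path)
    return MergedTable(
        categories=list(df.index), samples=list(df.columns),
        matrix=df.to_numpy(dtype=float), kind=kind, level=level)


# ---------------------------------------------------------------------------
# rendering

def _save(fig, outdir: str, stem: str, formats: Iterable[str]) -> list[str]:
    paths = []
    for ext in formats:
        path = os.path.join(outdir, f"{stem}.{ext}")
        fig.savefig(path)
        paths.append(path)
    plt.close(fig)
    return paths


def render(m: MergedTable, kinds: Iterable[str] = PLOT_KINDS,
           outdir: str | os.PathLike = ".",
           formats: Iterable[str] = ("png", "svg")) -> list[str]:
    """Render the requested figure families; returns the files written.

    One file per format per kind, except pies which are one per gene set.
    """
    kinds = list(kinds)
    unknown = set(kinds) - set(PLOT_KINDS)
    if unknown:
        raise ValueError(f"unknown plot kind(s) {sorted(unknown)}")
    if m.matrix.size == 0:
        raise ValueError("cannot render an empty merged table")
    os.makedirs(outdir, exist_ok=True)
    outdir = str(outdir)
    formats = list(formats)
    written: list[str] = []

    if "pie" in kinds:
        for j, sample in enumerate(m.samples):
            col = m.matrix[:, j]
            keep = col > 0
            fractions = pie_fractions(col[keep])
            labels = [c for c, k in zip(m.categories, keep) if k]
            fig, ax = plt.subplots(figsize=(7, 7))
            ax.pie(fractions, labels=labels, startangle=90,
                   textprops={"fontsize": 7})
            ax.set_title(sample)
            written += _save(fig, outdir, f"pie_{sample}", formats)

    if "bar" in kinds:
        df = m.to_frame()
        fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(m.categories) * max(1, len(m.samples))), 5))
        df.plot.bar(ax=ax, width=0.8)
        ax.set_ylabel("frequency" if m.kind == "frequency" else "count")
        ax.set_xlabel("GO slim category")
        ax.tick_params(axis="x", labelsize=6, rotation=90)
        fig.tight_layout()
        written += _save(fig, outdir, "bar", formats)

    for kind, transform, stem in (
            ("heatmap", lambda x: x, "heatmap"),
            ("heatmap_log", log_transform, "heatmap_log")):
        if kind not in kinds:
            continue
        data = transform(m) if kind == "heatmap_log" else m
        fig, ax = plt.subplots(
            figsize=(max(4, 0.8 * len(m.samples) + 3),
                     max(4, 0.25 * len(m.categories))))
        sns.heatmap(data.to_frame(), ax=ax, cmap="viridis",
                    cbar_kws={"label": "log10(count + 1)"
                              if kind == "heatmap_log" else m.kind})
        ax.tick_params(labelsize=6)
        fig.tight_layout()
        written += _save(fig, outdir, stem, formats)

    if "bubble" in kinds:
        shares = bubble_sizes(m)
        fig, ax = plt.subplots(
            figsize=(max(4, 0.8 * len(m.samples) + 2),
                     max(4, 0.25 * len(m.categories))))
        for j in range(len(m.samples)):
            ax.scatter([j] * len(m.categories), range(len(m.categories)),
                       s=2000 * shares[:, j], alpha=0.7, edgecolors="k",
                       linewidths=0.3)
        ax.set_xticks(range(len(m.samples)), m.samples, rotation=45,
                      ha="right", fontsize=7)
        ax.set_yticks(range(len(m.categories)), m.categories, fontsize=6)
        ax.set_xlim(-0.5, len(m.samples) - 0.5)
        fig.tight_layout()
        written += _save(fig, outdir, "bubble", formats)

    return written
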
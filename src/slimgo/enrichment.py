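"""Chi-square comparison of GO slim composition between two gene sets.

A focal gene set (e.g., retained paralogs) is compared to a reference
set (e.g., the full transcriptome) in a 2 x C contingency table.  Pearson
residuals of the focal-row cells, (O - E) / sqrt(E), flag categories as
over-represented (residual > threshold, default 2) or under-represented
(residual < -threshold); both inequalities are strict.  An adjusted
(standardized) residual variant is available behind a flag.

No multiple-testing correction is applied across categories.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import TwoSlopeNorm
from scipy import stats

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "build_contingency",
    "chi_square",
    "residual_calls",
    "enrichment_heatmap",
    "write_enrichment_tsv",
]

DEFAULT_THRESHOLD = 2.0


@dataclass
class ContingencyTable:
    """2 x C observed counts: row 0 = focal gene set, row 1 = reference."""

    categories: list[str]
    observed: np.ndarray  # shape (2, C), non-negative integers

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.shape != (2, len(self.categories)):
            raise ValueError("observed matrix shape does not match categories")
        if (self.observed < 0).any():
            raise ValueError("negative observed count")
        if self.grand_total <= 0:
            raise ValueError("empty contingency table")
        if len(self.categories) < 2:
            raise ValueError("need at least two categories")

    @property
    def row_totals(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.observed.sum())

    def expected(self) -> np.ndarray:
        return np.outer(self.row_totals, self.col_totals) / self.grand_total


@dataclass
class EnrichmentResult:
    chi2: float
    df: int
    p_value: float
    categories: list[str]
    residuals: dict[str, float]
    calls: dict[str, str]  # over | under | ns
    threshold: float = DEFAULT_THRESHOLD
    observed_focal: dict[str, float] = field(default_factory=dict)
    observed_reference: dict[str, float] = field(default_factory=dict)
    expected_focal: dict[str, float] = field(default_factory=dict)


def build_contingency(focal: Mapping[str, int], reference: Mapping[str, int],
                      drop_empty: bool = False) -> ContingencyTable:
    """Assemble the 2 x C table over the union of categories.

    Missing cells are 0.  With ``drop_empty``, categories whose column
    total is 0 are removed (a zero column otherwise makes the expected
    counts degenerate and :func:`chi_square` will refuse it).
    """
    categories = sorted(set(focal) | set(reference))
    observed = np.array([
        [float(focal.get(c, 0)) for c in categories],
        [float(reference.get(c, 0)) for c in categories],
    ])
    if drop_empty:
        keep = observed.sum(axis=0) > 0
        categories = [c for c, k in zip(categories, keep) if k]
        observed = observed[:, keep]
    if len(categories) < 2:
        raise ValueError(
            "fewer than two usable categories in the contingency table")
    return ContingencyTable(categories, observed)


def chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square: E = row x col / N, chi2 = sum (O-E)^2 / E.

    df = (rows - 1)(cols - 1) = C - 1 for a 2 x C table; p from the
    upper tail of the chi-square distribution (no continuity correction).
    """
    expected = table.expected()
    if (expected == 0).any():
        raise ValueError(
            "a cell has expected count 0 (empty row or column); rebuild "
            "the table with drop_empty=True")
    chi2 = float(((table.observed - expected) ** 2 / expected).sum())
    df = (table.observed.shape[0] - 1) * (table.observed.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def residual_calls(table: ContingencyTable,
                   threshold: float = DEFAULT_THRESHOLD,
                   adjusted: bool = False) -> EnrichmentResult:
    """Per-category residuals of the focal row and over/under/ns calls.

    Default residual is the Pearson residual (O - E) / sqrt(E) of the
    focal cell; with ``adjusted=True`` it is divided by
    sqrt((1 - row/N)(1 - col/N)) (standardized residual).
    """
    chi2, df, p = chi_square(table)
    expected = table.expected()
    resid = (table.observed - expected) / np.sqrt(expected)
    if adjusted:
        n = table.grand_total
        adj = np.sqrt(np.outer(1 - table.row_totals / n,
                               1 - table.col_totals / n))
        resid = resid / adj
    focal = resid[0]
    calls = {}
    residuals = {}
    for cat, r in zip(table.categories, focal):
        residuals[cat] = float(r)
        if r > threshold:
            calls[cat] = "over"
        elif r < -threshold:
            calls[cat] = "under"
        else:
            calls[cat] = "ns"
    return EnrichmentResult(
        chi2=chi2, df=df, p_value=p,
        categories=list(table.categories),
        residuals=residuals, calls=calls, threshold=threshold,
        observed_focal=dict(zip(table.categories, table.observed[0])),
        observed_reference=dict(zip(table.categories, table.observed[1])),
        expected_focal=dict(zip(table.categories, expected[0])),
    )


def write_enrichment_tsv(result: EnrichmentResult,
                         path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# chi2={result.chi2!r}\n")
        fh.write(f"# df={result.df}\n")
        fh.write(f"# p_value={result.p_value!r}\n")
        fh.write(f"# threshold={result.threshold!r}\n")
        fh.write("category\tobserved_focal\tobserved_reference\t"
                 "expected_focal\tresidual\tcall\n")
        for cat in result.categories:
            fh.write("\t".join([
                cat,
                str(int(result.observed_focal[cat])),
                str(int(result.observed_reference[cat])),
                repr(result.expected_focal[cat]),
                repr(result.residuals[cat]),
                result.calls[cat],
            ]) + "\n")


def enrichment_heatmap(results: Mapping[str, EnrichmentResult],
                       outpath: str | os.PathLike) -> list[str]:
    """Category x gene-set grid colored by residual for over/under calls.

    Non-significant (and absent) cells are gray.  A TSV of the residual
    matrix is written alongside the figure.
    """
    if not results:
        raise ValueError("no enrichment results to plot")
    samples = list(results)
    categories = sorted(set().union(*(r.residuals.keys()
                                      for r in results.values())))
    grid = np.full((len(categories), len(samples)), np.nan)
    for j, s in enumerate(samples):
        res = results[s]
        for i, c in enumerate(categories):
            if res.calls.get(c) in ("over", "under"):
                grid[i, j] = res.residuals[c]

    fig, ax = plt.subplots(
        figsize=(max(4, 0.8 * len(samples) + 2),
                 max(4, 0.25 * len(categories))))
    vmax = max(2.0, np.nanmax(np.abs(grid))) if not np.isnan(grid).all() else 2.0
    cmap = plt.get_cmap("bwr").copy()
    cmap.set_bad("lightgray")
    im = ax.imshow(grid, aspect="auto", cmap=cmap,
                   norm=TwoSlopeNorm(vcenter=0.0, vmin=-vmax, vmax=vmax))
    ax.set_xticks(range(len(samples)), samples, rotation=45, ha="right",
                  fontsize=7)
    ax.set_yticks(range(len(categories)), categories, fontsize=6)
    fig.colorbar(im, ax=ax, label="focal-cell residual")
    fig.tight_layout()
    fig.savefig(outpath)
    plt.close(fig)

    base, _ = os.path.splitext(str(outpath))
    tsv_path = base + "_residuals.tsv"
    with open(tsv_path, "w") as fh:
        fh.write("category\t" + "\t".join(samples) + "\n")
        for i, cat in enumerate(categories):
            cells = []
            for j, s in enumerate(samples):
                r = results[s].residuals.get(cat)
                cells.append("NA" if r is None else repr(r))
            fh.write(cat + "\t" + "\t".join(cells) + "\n")
    return [str(outpath), tsv_path]
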
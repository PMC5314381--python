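"""Category decomposition of selected feature sets.

After feature selection, the selected features are broken down by entity
(HLA protein vs peptide) and category (AAC plus the five property scales)
and reported as *relative ratios* — the fraction of each category's features
that made the selection. A ratio of 1.0 means the whole block was selected;
comparing ratios across categories shows which kinds of sequence information
survive de-redundancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import FeatureCatalogue
from .selection import RankedFeatureList

ENTITIES = ("protein", "peptide")
CATEGORIES = ("AAC", "CD", "EC", "MV", "2nd_stru", "polarity")


@dataclass
class CategoryBreakdown:
    """Selected / total counts and relative ratios per (entity, category)."""

    table: pd.DataFrame  # columns: entity, category, selected, total, ratio

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    def ratio(self, entity: str, category: str) -> float:
        row = self.table[
            (self.table["entity"] == entity) & (self.table["category"] == category)
        ]
        if row.empty:
            raise KeyError(f"no cell ({entity}, {category})")
        return float(row["ratio"].iloc[0])


def category_breakdown(
    top_indices, catalogue: FeatureCatalogue
) -> CategoryBreakdown:
    """Decompose a selected feature-index set by entity and category.

    Parameters
    ----------
    top_indices : iterable of int
        Selected feature indices (e.g. the top of a ranked list).
    catalogue : FeatureCatalogue
        Descriptors defining each index's entity and category.
    """
    idx = np.asarray(list(top_indices), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= len(catalogue)):
        raise IndexError(
            f"feature index out of range for a {len(catalogue)}-feature catalogue"
        )
    if len(np.unique(idx)) != idx.size:
        raise ValueError("selected feature indices must be unique")
    totals = catalogue.block_sizes()
    selected: dict[tuple[str, str], int] = {k: 0 for k in totals}
    for i in idx:
        d = catalogue[int(i)]
        selected[(d.entity, d.category)] += 1
    rows = []
    for entity in ENTITIES:
        for category in CATEGORIES:
            key = (entity, category)
            if key not in totals:
                continue
            tot = totals[key]
            sel = selected[key]
            rows.append((entity, category, sel, tot, sel / tot))
    return CategoryBreakdown(
        pd.DataFrame(rows, columns=["entity", "category", "selected", "total", "ratio"])
    )


def top_fraction(ranked: RankedFeatureList, fraction: float) -> np.ndarray:
    """First ``ceil(fraction * n_features)`` indices of a ranked list.

    Ceiling rounding makes the top 10 percent of 340 features exactly 34.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = math.ceil(fraction * ranked.n_features)
    return ranked.top(k)


def plot_breakdown(breakdown: CategoryBreakdown, path) -> None:
    """Bar chart of relative ratios, one panel per entity."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entities = breakdown.table["entity"].unique()
    fig, axes = plt.subplots(1, len(entities), figsize=(5 * len(entities), 4), squeeze=False)
    for ax, entity in zip(axes[0], entities):
        sub = breakdown.table[breakdown.table["entity"] == entity]
        ax.bar(sub["category"], sub["ratio"], color="#4878d0")
        ax.set_ylim(0, 1.05)
        ax.set_ylabel("relative ratio (selected / total)")
        ax.set_title(f"{entity} features")
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ifs_curve(curve: pd.DataFrame, path, optimal_size: int | None = None) -> None:
    """MCC-vs-feature-count curve with the optimum highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["size"], curve["MCC"], lw=1)
    if optimal_size is not None:
        row = curve[curve["size"] == optimal_size]
        ax.plot(row["size"], row["MCC"], "ro", label=f"optimum (size {optimal_size})")
        ax.legend()
    ax.set_xlabel("number of features")
    ax.set_ylabel("MCC (10-fold CV, pooled)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
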
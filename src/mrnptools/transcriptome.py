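"""Dye-swap microarray replicate analysis and binding-category stratification.

Two-color comparisons run in duplicate with a dye swap: the swapped
replicate's log2 ratio is sign-flipped before averaging so both replicates
share the mutant/wild-type orientation.  The between-replicate standard
deviation (n-1 denominator; for two replicates |difference| / sqrt(2)) feeds
a consistency filter that removes genes with SD strictly greater than the
threshold (default 0.5).  Retained genes are stratified by RBP-binding
category and each category's log2-ratio distribution is compared to the
weakest-binding category with the Mann-Whitney-Wilcoxon test (Welch's t-test
available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interactome import Category, SCORED_CATEGORIES

__all__ = [
    "ExpressionComparison",
    "CategoryStratification",
    "combine_dye_swap_replicates",
    "combine_replicate_table",
    "filter_by_replicate_sd",
    "stratify_by_binding_category",
]

DEFAULT_SD_THRESHOLD = 0.5


@dataclass
class ExpressionComparison:
    gene: str
    replicate_log2_ratios: list  # (value, dye_swapped) as measured
    mean_log2: float
    sd: Optional[float]  # None when < 2 oriented replicates
    single_replicate: bool = False
    mean_intensity: Optional[float] = None


@dataclass
class CategoryStratification:
    categories: dict  # category name -> list of genes
    summaries: pd.DataFrame  # per-category median / quartiles / n
    p_values: dict  # category name -> p vs baseline category
    baseline: str
    test: str


def combine_dye_swap_replicates(
    gene: str,
    replicates: Sequence[tuple[float, bool]],
    mean_intensity: Optional[float] = None,
) -> ExpressionComparison:
    """Orient (sign-flip swapped) replicates, then average.

    A single replicate yields its own value with undefined SD and a flag.
    """
    if not replicates:
        raise ValueError(f"no replicates for gene {gene!r}")
    oriented = np.array([-v if swapped else v for v, swapped in replicates], dtype=float)
    mean = float(oriented.mean())
    if len(oriented) >= 2:
        sd = float(oriented.std(ddof=1))
        single = False
    else:
        sd = None
        single = True
    return ExpressionComparison(
        gene=gene,
        replicate_log2_ratios=[(float(v), bool(s)) for v, s in replicates],
        mean_log2=mean,
        sd=sd,
        single_replicate=single,
        mean_intensity=mean_intensity,
    )


def combine_replicate_table(ratios: pd.DataFrame) -> list[ExpressionComparison]:
    """Combine a long table (gene, log2_ratio, dye_swapped[, intensity])."""
    required = {"gene", "log2_ratio", "dye_swapped"}
    if not required.issubset(ratios.columns):
        raise ValueError(f"ratio table needs columns {sorted(required)}")
    out = []
    for gene, grp in ratios.groupby("gene", sort=True):
        reps = list(zip(grp["log2_ratio"].astype(float), grp["dye_swapped"].astype(bool)))
        intensity = (
            float(grp["intensity"].mean()) if "intensity" in grp.columns else None
        )
        out.append(combine_dye_swap_replicates(str(gene), reps, mean_intensity=intensity))
    return out


def filter_by_replicate_sd(
    comparisons: Sequence[ExpressionComparison],
    threshold: float = DEFAULT_SD_THRESHOLD,
) -> tuple[list[ExpressionComparison], list[ExpressionComparison]]:
    """Remove genes whose between-replicate SD exceeds the threshold.

    The inequality is strict (SD exactly at the threshold is retained);
    genes with undefined SD (single replicate) are removed and stay flagged.
    Returns (kept, removed).
    """
    kept, removed = [], []
    for comp in comparisons:
        if comp.sd is None or comp.sd > threshold:
            removed.append(comp)
        else:
            kept.append(comp)
    return kept, removed


def stratify_by_binding_category(
    comparisons: Sequence[ExpressionComparison],
    categories: Mapping[str, Category],
    baseline: Category = Category.VERY_LOW_NONE,
    test: str = "mww",
) -> CategoryStratification:
    """Group mean log2 ratios by binding category and test each vs baseline.

    ``test`` is "mww" (two-sided Mann-Whitney-Wilcoxon, the default) or
    "welch" (two-sided Welch's t-test).  Every analyzed gene must appear in
    the category map and every scored category must be non-empty.
    """
    if test not in ("mww", "welch"):
        raise ValueError(f"unknown test {test!r}")
    baseline = Category(baseline)
    values: dict[Category, list[float]] = {c: [] for c in SCORED_CATEGORIES}
    genes: dict[Category, list[str]] = {c: [] for c in SCORED_CATEGORIES}
    for comp in comparisons:
        if comp.gene not in categories:
            raise ValueError(f"gene {comp.gene!r} absent from the category map")
        cat = Category(categories[comp.gene])
        values[cat].append(comp.mean_log2)
        genes[cat].append(comp.gene)
    for cat in SCORED_CATEGORIES:
        if not values[cat]:
            raise ValueError(f"empty category {cat.value}")
    rows = []
    for cat in SCORED_CATEGORIES:
        arr = np.array(values[cat])
        rows.append(
            {
                "category": cat.value,
                "n": len(arr),
                "median": float(np.median(arr)),
                "q1": float(np.percentile(arr, 25)),
                "q3": float(np.percentile(arr, 75)),
                "mean": float(arr.mean()),
            }
        )
    base = np.array(values[baseline])
    p_values: dict[str, float] = {}
    for cat in SCORED_CATEGORIES:
        if cat is baseline:
            continue
        arr = np.array(values[cat])
        if np.array_equal(np.sort(arr), np.sort(base)) and len(set(arr)) == 1:
            # identical constant samples: no evidence of a shift
            p = 1.0
        elif test == "mww":
            p = float(stats.mannwhitneyu(arr, base, alternative="two-sided").pvalue)
        else:
            p = float(stats.ttest_ind(arr, base, equal_var=False).pvalue)
        p_values[cat.value] = p
    return CategoryStratification(
        categories={c.value: genes[c] for c in SCORED_CATEGORIES},
        summaries=pd.DataFrame(rows),
        p_values=p_values,
        baseline=baseline.value,
        test=test,
    )
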
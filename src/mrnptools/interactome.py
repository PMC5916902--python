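"""Harmonization of heterogeneous RBP-binding datasets into a common binding matrix.

Three assay families measure RBP–RNA association at different resolutions and
on different scales: CRAC yields per-transcript crosslink read counts, RIP
(followed by microarray) yields continuous binding scores, and CLIP peak
calling yields binary bound/unbound calls.  To compare them side by side, CRAC
counts are (1) depth-normalized to hits per million within each library,
(2) unit-normalized per transcript across libraries (the per-transcript vector
of hpm values is scaled to Euclidean norm 1) so that transcript abundance,
common to all libraries, cancels, and (3) min–max rescaled to [0, 1] within
each experiment.  Scored experiments (CRAC after normalization, RIP scores)
are then cut into four equally sized binding categories; CLIP calls map
directly onto BOUND/UNBOUND.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Assay",
    "Category",
    "BindingExperiment",
    "BindingMatrix",
    "hits_per_million",
    "unit_norm_per_transcript",
    "rescale_unit_interval",
    "categorize_quartiles",
    "assemble_binding_matrix",
]


class Assay(str, enum.Enum):
    CRAC_COUNT = "CRAC_COUNT"
    RIP_SCORE = "RIP_SCORE"
    CLIP_CALL = "CLIP_CALL"


class Category(str, enum.Enum):
    HIGH = "HIGH"
    MEDIUM = "MEDIUM"
    LOW = "LOW"
    VERY_LOW_NONE = "VERY_LOW_NONE"
    BOUND = "BOUND"
    UNBOUND = "UNBOUND"


#: Scored categories ordered from strongest to weakest binding.
SCORED_CATEGORIES = (
    Category.HIGH,
    Category.MEDIUM,
    Category.LOW,
    Category.VERY_LOW_NONE,
)


@dataclass
class BindingExperiment:
    """One RBP-binding dataset: raw counts, scores or calls per transcript."""

    rbp_id: str
    assay: Assay
    replicate: int
    values: pd.Series

    def __post_init__(self) -> None:
        self.assay = Assay(self.assay)
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if not isinstance(self.values, pd.Series):
            self.values = pd.Series(self.values, dtype=float)
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise ValueError("transcript ids must be unique within an experiment")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite values in experiment")
        if self.assay is Assay.CRAC_COUNT:
            if np.any(vals < 0) or np.any(vals != np.round(vals)):
                raise ValueError("CRAC counts must be non-negative integers")
        if self.assay is Assay.CLIP_CALL and not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("CLIP calls must be 0 or 1")

    @property
    def label(self) -> str:
        return f"{self.rbp_id}.{self.assay.value}.{self.replicate}"

    def with_values(self, values: pd.Series) -> "BindingExperiment":
        out = object.__new__(BindingExperiment)
        out.rbp_id = self.rbp_id
        out.assay = self.assay
        out.replicate = self.replicate
        out.values = values
        return out


@dataclass
class BindingMatrix:
    """Harmonized 0–1 scores and binding categories for a set of experiments."""

    transcripts: list
    experiments: list  # (rbp_id, assay, replicate) tuples, column order
    score: pd.DataFrame  # NaN for CLIP columns
    category: pd.DataFrame  # Category values as strings
    normalization_log: list = field(default_factory=list)


def hits_per_million(experiment: BindingExperiment) -> BindingExperiment:
    """Depth-normalize a CRAC count library so its values sum to 1e6."""
    if experiment.assay is not Assay.CRAC_COUNT:
        raise ValueError("hits_per_million applies to CRAC count experiments")
    total = float(experiment.values.sum())
    if total <= 0:
        raise ValueError("empty library")
    return experiment.with_values(experiment.values * 1e6 / total)


def unit_norm_per_transcript(
    experiments: Sequence[BindingExperiment],
) -> tuple[list[BindingExperiment], list[str]]:
    """Scale each transcript's cross-experiment vector to Euclidean norm 1.

    The hpm value of a transcript is the product of its abundance and its
    affinity for the assayed RBP; abundance is shared across all libraries,
    so dividing the per-transcript vector by its norm removes it.  Returns
    the normalized experiments and the list of transcripts whose vector was
    all-zero (left at zero, flagged rather than failed).
    """
    if not experiments:
        raise ValueError("no experiments supplied")
    universe = experiments[0].values.index
    for exp in experiments[1:]:
        if not exp.values.index.equals(universe):
            raise ValueError("experiments have mismatched transcript universes")
    mat = np.column_stack([exp.values.to_numpy() for exp in experiments])
    norms = np.linalg.norm(mat, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    normed = mat / safe[:, None]
    flagged = list(universe[zero])
    out = [
        exp.with_values(pd.Series(normed[:, j], index=universe))
        for j, exp in enumerate(experiments)
    ]
    return out, flagged


def rescale_unit_interval(
    experiment: BindingExperiment,
) -> tuple[BindingExperiment, list[str]]:
    """Min–max rescale an experiment's values onto [0, 1].

    A constant experiment (max == min) degenerates to all zeros and is
    reported through the returned warning list instead of raising.
    """
    vals = experiment.values.to_numpy()
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values")
    lo, hi = float(vals.min()), float(vals.max())
    warnings: list[str] = []
    if hi == lo:
        warnings.append(f"{experiment.label}: constant values, rescaled to all zeros")
        scaled = np.zeros_like(vals)
    else:
        scaled = (vals - lo) / (hi - lo)
    return experiment.with_values(pd.Series(scaled, index=experiment.values.index)), warnings


def quartile_sizes(n: int) -> list[int]:
    """Four group sizes differing by at most one; remainders go to the
    strongest-binding groups first (sizes non-increasing from HIGH down)."""
    q, r = divmod(n, 4)
    return [q + (1 if i < r else 0) for i in range(4)]


def categorize_quartiles(
    experiment: BindingExperiment,
    zero_flagged: Sequence[str] = (),
) -> tuple[pd.Series, list[str]]:
    """Rank transcripts by descending score and cut into four equal groups.

    Ties are broken by a stable sort with transcript id as the final key.
    Transcripts in ``zero_flagged`` (all-zero before normalization) are
    forced to VERY_LOW_NONE regardless of their rank.
    """
    values = experiment.values
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 transcripts to form quartile categories")
    warnings: list[str] = []
    vals = values.to_numpy()
    if np.all(vals == vals[0]):
        warnings.append(f"{experiment.label}: all scores tied; categories follow transcript-id order")
    ids = values.index.to_numpy()
    # lexsort: last key is primary -> descending score, then ascending id
    order = np.lexsort((ids, -vals))
    sizes = quartile_sizes(n)
    cats = np.empty(n, dtype=object)
    start = 0
    for cat, size in zip(SCORED_CATEGORIES, sizes):
        cats[order[start : start + size]] = cat
        start += size
    result = pd.Series(cats, index=values.index)
    if len(zero_flagged) > 0:
        present = [t for t in zero_flagged if t in result.index]
        result.loc[present] = Category.VERY_LOW_NONE
    return result, warnings


def assemble_binding_matrix(
    experiments: Sequence[BindingExperiment],
    gene_order: Optional[Sequence[str]] = None,
    unit_norm_scope: str = "all",
    rescale_scope: str = "per_experiment",
) -> BindingMatrix:
    """Run the full harmonization and return scores plus categories.

    CRAC experiments flow through hits-per-million -> per-transcript unit
    norm -> [0, 1] rescaling -> quartile categories.  RIP scores are
    quartile-categorized as published.  CLIP calls pass through to
    BOUND/UNBOUND.  ``unit_norm_scope`` is "all" (one joint normalization
    across every CRAC experiment, the default, since transcript abundance is
    common to all libraries) or "per_rbp" (each RBP's replicates normalized
    separately).  ``rescale_scope`` is "per_experiment" or "global" (one
    min/max over all CRAC experiments).
    """
    if not experiments:
        raise ValueError("no experiments supplied")
    universe = experiments[0].values.index
    for exp in experiments[1:]:
        if not exp.values.index.equals(universe):
            raise ValueError("experiments have mismatched transcript universes")
    log: list[dict] = []

    crac = [e for e in experiments if e.assay is Assay.CRAC_COUNT]
    processed: dict[str, BindingExperiment] = {}
    categories: dict[str, pd.Series] = {}
    zero_flagged: list[str] = []

    if crac:
        hpm = [hits_per_million(e) for e in crac]
        log.append({"step": "hits_per_million", "experiments": [e.label for e in crac]})
        if unit_norm_scope == "all":
            groups = [hpm]
        elif unit_norm_scope == "per_rbp":
            keys = sorted({e.rbp_id for e in hpm})
            groups = [[e for e in hpm if e.rbp_id == k] for k in keys]
        else:
            raise ValueError(f"unknown unit_norm_scope {unit_norm_scope!r}")
        normed: list[BindingExperiment] = []
        for group in groups:
            unit, flagged = unit_norm_per_transcript(group)
            normed.extend(unit)
            zero_flagged.extend(t for t in flagged if t not in zero_flagged)
        log.append(
            {
                "step": "unit_norm_per_transcript",
                "scope": unit_norm_scope,
                "all_zero_transcripts": list(zero_flagged),
            }
        )
        if rescale_scope == "global":
            allvals = np.concatenate([e.values.to_numpy() for e in normed])
            lo, hi = float(allvals.min()), float(allvals.max())
            if hi == lo:
                rescaled = [e.with_values(e.values * 0.0) for e in normed]
                log.append({"step": "rescale_unit_interval", "scope": "global", "warning": "constant"})
            else:
                rescaled = [e.with_values((e.values - lo) / (hi - lo)) for e in normed]
                log.append({"step": "rescale_unit_interval", "scope": "global"})
        elif rescale_scope == "per_experiment":
            rescaled = []
            warns: list[str] = []
            for e in normed:
                r, w = rescale_unit_interval(e)
                rescaled.append(r)
                warns.extend(w)
            log.append({"step": "rescale_unit_interval", "scope": "per_experiment", "warnings": warns})
        else:
            raise ValueError(f"unknown rescale_scope {rescale_scope!r}")
        for e in rescaled:
            processed[e.label] = e
            cat, warns = categorize_quartiles(e, zero_flagged=zero_flagged)
            categories[e.label] = cat
            if warns:
                log.append({"step": "categorize_quartiles", "warnings": warns})

    for e in experiments:
        if e.assay is Assay.RIP_SCORE:
            cat, warns = categorize_quartiles(e)
            categories[e.label] = cat
            if warns:
                log.append({"step": "categorize_quartiles", "warnings": warns})
            log.append({"step": "categorize_quartiles", "experiment": e.label})
        elif e.assay is Assay.CLIP_CALL:
            categories[e.label] = e.values.map(
                lambda v: Category.BOUND if v > 0 else Category.UNBOUND
            )
            log.append({"step": "clip_passthrough", "experiment": e.label})

    order = list(gene_order) if gene_order is not None else list(universe)
    missing = set(order) - set(universe)
    if missing:
        raise ValueError(f"gene_order contains unknown transcripts: {sorted(missing)[:5]}")
    columns = [e.label for e in experiments]
    score = pd.DataFrame(index=order, columns=columns, dtype=float)
    category = pd.DataFrame(index=order, columns=columns, dtype=object)
    for e in experiments:
        if e.label in processed:
            # only CRAC-derived columns carry a harmonized 0-1 score;
            # RIP and CLIP columns are category-only
            score[e.label] = processed[e.label].values.reindex(order)
        category[e.label] = categories[e.label].reindex(order).map(
            lambda c: c.value if isinstance(c, Category) else c
        )
    meta = [(e.rbp_id, e.assay.value, e.replicate) for e in experiments]
    return BindingMatrix(
        transcripts=order,
        experiments=meta,
        score=score,
        category=category,
        normalization_log=log,
    )
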
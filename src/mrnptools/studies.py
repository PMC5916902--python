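"""Seeded simulation studies that exercise the pipeline against ground truth.

Each study generates synthetic data with the generator's default conditions,
runs the corresponding analysis stage, and measures how well the planted
parameters are recovered.  They are the package's own validation battery and
are reused by the test suite, the acceptance script and the analysis drivers.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .enrichment import GeneSet, permutation_p_value
from .interactome import assemble_binding_matrix, hits_per_million
from .polysome import summarize_profile
from .qpcr import quantify_rip
from .simulate import (
    SimulationConfig,
    simulate_binding_experiments,
    simulate_chase_series,
    simulate_dye_swap_ratios,
    simulate_polysome_profiles,
    simulate_rip_qpcr,
    stage_rng,
)
from .transcriptome import (
    combine_replicate_table,
    filter_by_replicate_sd,
    stratify_by_binding_category,
)
from .turnover import fit_exponential_decay

__all__ = [
    "confound_removal_study",
    "enrichment_null_calibration",
    "enrichment_power_study",
    "polysome_recovery_study",
    "qpcr_roundtrip_study",
    "half_life_recovery_study",
    "transcriptome_power_study",
    "transcriptome_exact_recovery",
]


def confound_removal_study(seed: int, n_transcripts: int = 2000) -> dict:
    """Does harmonization recover affinity and cancel expression?

    Simulates the default panel (one specific binder, two generic factors,
    two replicates each; expression sdlog 1.5, dispersion 0.2), harmonizes,
    and reports Spearman correlations of the final 0-1 score with the planted
    affinity and expression for the specific RBP's experiments, plus the
    per-experiment gain of the final score over raw hits-per-million.
    """
    config = SimulationConfig(n_transcripts=n_transcripts, seed=seed)
    experiments, truth = simulate_binding_experiments(config)
    matrix = assemble_binding_matrix(experiments)
    transcripts = matrix.transcripts
    expression = np.array([truth.expression[t] for t in transcripts])
    focal_aff_corr, focal_expr_corr, gains = [], [], []
    for exp in experiments:
        aff = np.array([truth.affinity[(t, exp.rbp_id)] for t in transcripts])
        final = matrix.score[exp.label].to_numpy()
        hpm = hits_per_million(exp).values.reindex(transcripts).to_numpy()
        r_final = spearmanr(final, aff).statistic
        r_raw = spearmanr(hpm, aff).statistic
        gains.append(r_final - r_raw)
        if exp.rbp_id == config.rbp_specs[0].rbp_id:
            focal_aff_corr.append(r_final)
            focal_expr_corr.append(spearmanr(final, expression).statistic)
    return {
        "spearman_score_affinity": float(min(focal_aff_corr)),
        "spearman_score_expression_abs": float(max(abs(r) for r in focal_expr_corr)),
        "min_gain_over_raw": float(min(gains)),
        "n_experiments": len(experiments),
    }


def _random_ranking(rng: np.random.Generator, n: int) -> pd.Series:
    ids = [f"G{i:04d}" for i in range(n)]
    return pd.Series(rng.normal(0.0, 1.0, n), index=ids)


def enrichment_null_calibration(
    seed: int,
    n_sims: int = 1000,
    universe: int = 500,
    set_size: int = 7,
    n_perm: int = 199,
    alpha: float = 0.05,
) -> dict:
    """Type-I rate of the permutation test on null rankings."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(101,)))
    hits = 0
    for i in range(n_sims):
        ranking = _random_ranking(rng, universe)
        members = rng.choice(ranking.index.to_numpy(), size=set_size, replace=False)
        result = permutation_p_value(
            ranking,
            GeneSet("null", members),
            n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        hits += result.p_value <= alpha
    return {"type_i_rate": hits / n_sims, "n_sims": n_sims, "alpha": alpha}


def enrichment_power_study(
    seed: int,
    n_runs: int = 200,
    universe: int = 500,
    set_size: int = 7,
    shift_sd: float = 1.5,
    n_perm: int = 199,
    alpha: float = 0.05,
) -> dict:
    """Detection rate for a set whose scores are shifted up by ``shift_sd``
    pooled standard deviations."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(102,)))
    hits = 0
    for i in range(n_runs):
        ranking = _random_ranking(rng, universe)
        members = rng.choice(ranking.index.to_numpy(), size=set_size, replace=False)
        ranking.loc[members] += shift_sd  # scores are unit-SD by construction
        result = permutation_p_value(
            ranking,
            GeneSet("planted", members),
            n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        hits += result.p_value <= alpha
    return {"power": hits / n_runs, "n_runs": n_runs, "shift_sd": shift_sd}


def polysome_recovery_study(
    seed: int,
    thetas: tuple = (0.2, 0.5, 0.8),
    n_targets: int = 8,
) -> dict:
    """Recovery of planted translated proportions under noise and spike skew.

    Generates ``n_targets`` transcripts per planted theta under the default
    10% CV noise and +-30% spike recovery perturbation, runs spike
    correction -> normalization -> translated proportion, and reports the
    mean recovered value and worst per-theta deviation of the mean.
    """
    config = SimulationConfig(seed=seed)
    theta_map = {}
    for k, theta in enumerate(thetas):
        for j in range(n_targets):
            theta_map[f"tgt_{k}_{j}"] = theta
    profiles, truth = simulate_polysome_profiles(config, {"wt": theta_map})
    summaries = summarize_profile(profiles[0])
    by_target = {s.target: s.translated_proportion for s in summaries}
    out = {"n_targets_per_theta": n_targets}
    worst = 0.0
    for k, theta in enumerate(thetas):
        rec = np.mean([by_target[f"tgt_{k}_{j}"] for j in range(n_targets)])
        out[f"recovered_theta_{theta}"] = float(rec)
        worst = max(worst, abs(rec - theta))
    out["max_abs_error"] = float(worst)
    return out


def qpcr_roundtrip_study(seed: int, folds: tuple = (10.0, 6.0, 2.0, 1.0)) -> dict:
    """Exactness of the zero-noise Ct roundtrip through RIP quantification."""
    config = SimulationConfig(seed=seed)
    config.qpcr_specs.ct_noise_sd = 0.0
    fold_map = {f"tgt{i}": f for i, f in enumerate(folds)}
    wells, sample_map, truth = simulate_rip_qpcr(config, fold_map)
    result = quantify_rip(wells, sample_map)
    tagged = result[result["sample"] == "ip_tag"].set_index("target")
    rel_errors = []
    for target, fold in fold_map.items():
        rec = float(tagged.loc[target, "fold_over_no_tag"])
        rel_errors.append(abs(rec - fold) / fold)
    no_tag = result[result["sample"] == "ip_notag"]["fold_over_no_tag"]
    return {
        "max_rel_error": float(max(rel_errors)),
        "no_tag_fold": float(no_tag.iloc[0]),
        "n_targets": len(fold_map),
    }


def half_life_recovery_study(
    seed: int,
    n_series: int = 100,
    true_half_life: float = 30.0,
    noise_cv: float = 0.05,
) -> dict:
    """Median relative half-life error over seeded noisy chase series."""
    config = SimulationConfig(seed=seed)
    config.chase_specs.noise_cv = noise_cv
    rng = stage_rng(seed, "chase")
    rel_errors = []
    for i in range(n_series):
        series = simulate_chase_series(
            config, true_half_life, protein=f"p{i}", condition="wt", rng=rng
        )
        fit = fit_exponential_decay(series)
        rel_errors.append(abs(fit.half_life - true_half_life) / true_half_life)
    return {
        "median_rel_error": float(np.median(rel_errors)),
        "n_series": n_series,
        "true_half_life": true_half_life,
    }


def _category_map(genes: list, rng: np.random.Generator) -> dict:
    """Random four-way equal split of genes into binding categories."""
    from .interactome import SCORED_CATEGORIES, quartile_sizes

    order = list(genes)
    rng.shuffle(order)
    sizes = quartile_sizes(len(order))
    cats = {}
    start = 0
    for cat, size in zip(SCORED_CATEGORIES, sizes):
        for g in order[start : start + size]:
            cats[g] = cat
        start += size
    return cats


def transcriptome_power_study(
    seed: int,
    n_runs: int = 200,
    n_genes: int = 200,
    downshift: float = -0.5,
    alpha: float = 0.05,
) -> dict:
    """Detection rate of a planted downshift in the strongest-binding category
    by the Mann-Whitney-Wilcoxon category-vs-baseline comparison."""
    from .interactome import Category

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(103,)))
    hits = 0
    for run in range(n_runs):
        config = SimulationConfig(
            n_transcripts=max(n_genes, 2), seed=int(rng.integers(0, 2**31 - 1))
        )
        genes = config.transcript_ids()[:n_genes]
        categories = _category_map(genes, rng)
        log2_fold = {
            g: (downshift if categories[g] is Category.HIGH else 0.0) for g in genes
        }
        ratios, _ = simulate_dye_swap_ratios(config, log2_fold)
        comparisons = combine_replicate_table(ratios)
        kept, _ = filter_by_replicate_sd(comparisons)
        strat = stratify_by_binding_category(kept, categories)
        hits += strat.p_values[Category.HIGH.value] <= alpha
    return {"power": hits / n_runs, "n_runs": n_runs, "downshift": downshift}


def transcriptome_exact_recovery(seed: int, n_genes: int = 120) -> dict:
    """Zero-noise checks: mean log2 equals the planted fold exactly and the
    SD > 0.5 filter removes exactly the genes with planted inconsistency > 0.5."""
    config = SimulationConfig(n_transcripts=max(n_genes, 2), seed=seed)
    config.microarray_specs.noise_sd = 0.0
    genes = config.transcript_ids()[:n_genes]
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(104,)))
    log2_fold = {g: float(rng.normal(0.0, 0.5)) for g in genes}
    planted_sd = {g: float(sd) for g, sd in zip(genes, rng.uniform(0.0, 1.0, n_genes))}
    ratios, truth = simulate_dye_swap_ratios(config, log2_fold, planted_sd)
    comparisons = combine_replicate_table(ratios)
    kept, removed = filter_by_replicate_sd(comparisons)
    removed_genes = {c.gene for c in removed}
    expected_removed = {g for g, sd in planted_sd.items() if sd > 0.5}
    max_fold_err = max(
        abs(c.mean_log2 - log2_fold[c.gene]) for c in comparisons
    )
    return {
        "max_abs_fold_error": float(max_fold_err),
        "filter_exact": removed_genes == expected_removed,
        "n_removed": len(removed_genes),
        "n_genes": n_genes,
    }
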
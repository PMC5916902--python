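"""End-to-end orchestration of the analysis stages from one configuration.

Stages run in dependency order (simulate -> interactome -> enrich; rip;
polysome; turnover; transcriptome; scan); a stage failure aborts everything
downstream and is recorded in the run report.  All randomness flows from the
single global seed via the generator's documented child-seed derivation, so
identical (config, seed) produces identical outputs and checksums.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as mio
from .enrichment import permutation_p_value
from .interactome import assemble_binding_matrix
from .motifs import MotifSpec, scan_motif
from .polysome import compare_conditions, summarize_profile
from .qpcr import quantify_rip
from .simulate import (
    SimulationConfig,
    simulate_binding_experiments,
    simulate_chase_series,
    simulate_dye_swap_ratios,
    simulate_polysome_profiles,
    simulate_rip_qpcr,
    simulate_sequences,
    stage_rng,
)
from .transcriptome import (
    combine_replicate_table,
    filter_by_replicate_sd,
    stratify_by_binding_category,
)
from .turnover import fit_exponential_decay

STAGE_ORDER = [
    "simulate",
    "interactome",
    "enrich",
    "rip",
    "polysome",
    "turnover",
    "transcriptome",
    "scan",
]

@dataclass
class RunConfig:
    stages: list
    seed: int = 0
    outdir: Path = Path("pipeline_out")
    params: dict = field(default_factory=dict)  # per-stage blocks

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        self.stages = [s for s in STAGE_ORDER if s in self.stages]
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path, seed: Optional[int] = None, outdir: Optional[Path] = None):
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            stages=raw.get("stages", STAGE_ORDER),
            seed=seed if seed is not None else int(raw.get("seed", 0)),
            outdir=Path(outdir or raw.get("outdir", "pipeline_out")),
            params={k: v for k, v in raw.items() if k not in ("stages", "seed", "outdir")},
        )


@dataclass
class RunReport:
    seed: int
    stages: list = field(default_factory=list)  # per-stage records

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "stages": self.stages}, indent=2)

    @property
    def checksums(self) -> dict:
        out = {}
        for record in self.stages:
            out.update(record.get("outputs", {}))
        return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record_outputs(paths) -> dict:
    return {str(p): _checksum(Path(p)) for p in paths}


def _sim_config(config: RunConfig) -> SimulationConfig:
    block = dict(config.params.get("simulate", {}))
    block.pop("geneset_size", None)
    block.pop("geneset_shift_sd", None)
    block.setdefault("n_transcripts", 500)
    return SimulationConfig(seed=config.seed, **block)


def _stage_simulate(config: RunConfig, outdir: Path) -> dict:
    block = dict(config.params.get("simulate", {}))
    geneset_size = int(block.get("geneset_size", 40))
    geneset_shift_sd = float(block.get("geneset_shift_sd", 1.5))
    sim = _sim_config(config)
    experiments, truth = simulate_binding_experiments(
        sim, geneset_size=geneset_size, geneset_shift_sd=geneset_shift_sd
    )
    mio.write_binding_experiments(
        experiments, outdir / "binding_counts.tsv", outdir / "binding_meta.yaml"
    )
    members = truth.member_sets["planted_targets"]["members"]
    mio.write_gene_set(members, outdir / "planted_set.txt")

    targets = sim.transcript_ids()[:4]
    thetas = {
        "wt": {t: 0.3 for t in targets},
        "mutant": {t: 0.7 for t in targets},
    }
    profiles, poly_truth = simulate_polysome_profiles(sim, thetas)
    mio.write_polysome_profiles(profiles, outdir / "polysome_quant.tsv")
    truth.translated_proportion = poly_truth.translated_proportion

    rng = stage_rng(sim.seed, "chase")
    half_lives = {("nup_a", "wt"): 120.0, ("nup_a", "mutant"): 45.0, ("control", "wt"): 90.0}
    series = [
        simulate_chase_series(sim, hl, protein=p, condition=c, rng=rng)
        for (p, c), hl in half_lives.items()
    ]
    mio.write_chase_table(series, outdir / "chase.tsv")
    truth.half_life = {k: v for k, v in half_lives.items()}

    folds = {t: f for t, f in zip(targets, (10.0, 6.0, 1.0, 1.0))}
    wells, sample_map, rip_truth = simulate_rip_qpcr(sim, folds)
    mio.write_qpcr_wells(wells, outdir / "qpcr_wells.tsv")
    mio.write_sample_map(sample_map, outdir / "qpcr_samples.yaml")
    truth.true_fold_enrichment = rip_truth.true_fold_enrichment

    # expression change upon loss of the repressor: transcripts strongly
    # bound by the specific RBP (top affinity quartile) shift down
    ids = sim.transcript_ids()
    focal = sim.rbp_specs[0].rbp_id
    focal_aff = pd.Series({t: truth.affinity[(t, focal)] for t in ids})
    cutoff = focal_aff.quantile(0.75)
    log2_fold = {t: (-0.5 if focal_aff[t] >= cutoff else 0.0) for t in ids}
    inconsistent = {t: 0.8 for t in ids[: max(2, len(ids) // 50)]}
    ratios, micro_truth = simulate_dye_swap_ratios(sim, log2_fold, inconsistent)
    mio.write_ratio_table(ratios, outdir / "ratios.tsv")
    truth.inconsistent_genes = micro_truth.inconsistent_genes
    truth.log2_fold = micro_truth.log2_fold

    seqs, seq_truth = simulate_sequences(sim)
    mio.write_fasta(seqs, outdir / "transcripts.fasta")
    truth.motif_sites = seq_truth.motif_sites
    mio.write_motifs(
        [MotifSpec("consensus_ca", "FIXED_IUPAC", "CAUCAUCA")], outdir / "motifs.yaml"
    )
    mio.write_ground_truth(truth, outdir / "ground_truth.json")
    outputs = [
        outdir / name
        for name in (
            "binding_counts.tsv",
            "binding_meta.yaml",
            "planted_set.txt",
            "polysome_quant.tsv",
            "chase.tsv",
            "qpcr_wells.tsv",
            "qpcr_samples.yaml",
            "ratios.tsv",
            "transcripts.fasta",
            "motifs.yaml",
            "ground_truth.json",
        )
    ]
    return {"outputs": _record_outputs(outputs), "records": len(ids)}


def _require(path: Path) -> Path:
    if not Path(path).exists():
        raise FileNotFoundError(f"missing input: {path}")
    return Path(path)


def _stage_interactome(config: RunConfig, outdir: Path) -> dict:
    block = config.params.get("interactome", {})
    counts = _require(Path(block.get("counts", outdir / "binding_counts.tsv")))
    meta = _require(Path(block.get("meta", outdir / "binding_meta.yaml")))
    experiments = mio.read_binding_experiments(counts, meta)
    matrix = assemble_binding_matrix(
        experiments,
        unit_norm_scope=block.get("unit_norm_scope", "all"),
        rescale_scope=block.get("rescale_scope", "per_experiment"),
    )
    paths = mio.write_binding_matrix(matrix, outdir)
    focal = matrix.score.columns[0]
    mio.write_ranking(matrix.score[focal], outdir / "ranking.tsv")
    paths["ranking"] = str(outdir / "ranking.tsv")
    return {"outputs": _record_outputs(paths.values()), "records": len(matrix.transcripts)}


def _stage_enrich(config: RunConfig, outdir: Path) -> dict:
    block = config.params.get("enrich", {})
    ranking = mio.read_ranking(_require(Path(block.get("ranking", outdir / "ranking.tsv"))))
    gene_set = mio.read_gene_set(_require(Path(block.get("set", outdir / "planted_set.txt"))))
    result = permutation_p_value(
        ranking,
        gene_set,
        n_perm=int(block.get("n_perm", 2000)),
        seed=config.seed,
        weighting_exponent=float(block.get("weighting_exponent", 0.0)),
        alternative=block.get("alternative", "greater"),
    )
    out = outdir / "enrichment.json"
    out.write_text(json.dumps(result.__dict__, indent=2))
    return {"outputs": _record_outputs([out]), "records": 1}


def _stage_rip(config: RunConfig, outdir: Path) -> dict:
    block = config.params.get("rip", {})
    wells = mio.read_qpcr_wells(_require(Path(block.get("wells", outdir / "qpcr_wells.tsv"))))
    sample_map = mio.read_sample_map(
        _require(Path(block.get("samples", outdir / "qpcr_samples.yaml")))
    )
    result = quantify_rip(wells, sample_map)
    out = outdir / "rip_quantification.tsv"
    result.to_csv(out, sep="\t", index=False)
    return {"outputs": _record_outputs([out]), "records": len(result)}


def _stage_polysome(config: RunConfig, outdir: Path) -> dict:
    block = config.params.get("polysome", {})
    profiles = mio.read_polysome_profiles(
        _require(Path(block.get("quant", outdir / "polysome_quant.tsv")))
    )
    summaries = {p.condition: summarize_profile(p) for p in profiles}
    rows = []
    for condition, summary_list in summaries.items():
        for s in summary_list:
            rows.append(
                {
                    "condition": condition,
                    "target": s.target,
                    "translated_proportion": s.translated_proportion,
                    "heavy_polysome_proportion": s.heavy_polysome_proportion,
                }
            )
    out = outdir / "translation_summary.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    outputs = [out]
    compare = block.get("compare")
    if compare is None and len(summaries) == 2:
        compare = sorted(summaries)
    if compare:
        cond_a, cond_b = compare
        shift = {}
        by_target_a = {s.target: s for s in summaries[cond_a]}
        by_target_b = {s.target: s for s in summaries[cond_b]}
        for target in by_target_a:
            if target in by_target_b:
                rep = compare_conditions(by_target_a[target], by_target_b[target])
                shift[target] = {
                    "delta_translated_proportion": rep.delta_translated_proportion,
                    "delta_heavy_polysome_proportion": rep.delta_heavy_polysome_proportion,
                }
        shift_path = outdir / "translation_shift.json"
        shift_path.write_text(json.dumps({"a": cond_a, "b": cond_b, "targets": shift}, indent=2))
        outputs.append(shift_path)
    return {"outputs": _record_outputs(outputs), "records": sum(len(v) for v in summaries.values())}


def _stage_turnover(config: RunConfig, outdir: Path) -> dict:
    block = config.params.get("turnover", {})
    series_list = mio.read_chase_table(_require(Path(block.get("chase", outdir / "chase.tsv"))))
    rows = []
    for series in series_list:
        fit = fit_exponential_decay(series)
        rows.append(
            {
                "protein": fit.protein,
                "condition": fit.condition,
                "k_per_min": fit.k,
                "half_life_min": fit.half_life if math.isfinite(fit.half_life) else "inf",
                "residual_sd": fit.residual_sd,
            }
        )
    out = outdir / "decay_fits.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return {"outputs": _record_outputs([out]), "records": len(rows)}


def _stage_transcriptome(config: RunConfig, outdir: Path) -> dict:
    block = config.params.get("transcriptome", {})
    ratios = mio.read_ratio_table(_require(Path(block.get("ratios", outdir / "ratios.tsv"))))
    comparisons = combine_replicate_table(ratios)
    kept, removed = filter_by_replicate_sd(
        comparisons, threshold=float(block.get("sd_threshold", 0.5))
    )
    categories = mio.read_category_map(
        _require(Path(block.get("categories", outdir / "binding_categories.tsv"))),
        column=block.get("category_column")
        or pd.read_csv(outdir / "binding_categories.tsv", sep="\t", nrows=0).columns[1],
    )
    strat = stratify_by_binding_category(kept, categories, test=block.get("test", "mww"))
    kept_genes = {c.gene for c in kept}
    comp_path = outdir / "expression_comparisons.tsv"
    pd.DataFrame(
        [
            {"gene": c.gene, "mean_log2": c.mean_log2, "sd": c.sd, "pass_filter": c.gene in kept_genes}
            for c in comparisons
        ]
    ).to_csv(comp_path, sep="\t", index=False)
    strat_path = outdir / "category_stratification.json"
    strat_path.write_text(
        json.dumps(
            {
                "summaries": strat.summaries.to_dict(orient="records"),
                "p_values": strat.p_values,
                "baseline": strat.baseline,
                "test": strat.test,
                "n_removed_by_filter": len(removed),
            },
            indent=2,
        )
    )
    return {"outputs": _record_outputs([comp_path, strat_path]), "records": len(comparisons)}


def _stage_scan(config: RunConfig, outdir: Path) -> dict:
    block = config.params.get("scan", {})
    seqs = mio.read_fasta(_require(Path(block.get("fasta", outdir / "transcripts.fasta"))))
    motifs = mio.read_motifs(_require(Path(block.get("motifs", outdir / "motifs.yaml"))))
    hits = []
    for tid, seq in seqs.items():
        for motif in motifs:
            hits.extend(
                scan_motif(
                    seq,
                    motif,
                    transcript=tid,
                    overlap_allowed=bool(block.get("overlap_allowed", True)),
                )
            )
    bed, report = outdir / "motif_hits.bed", outdir / "motif_hits.tsv"
    mio.write_motif_hits(hits, bed, report)
    return {"outputs": _record_outputs([bed, report]), "records": len(hits)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "interactome": _stage_interactome,
    "enrich": _stage_enrich,
    "rip": _stage_rip,
    "polysome": _stage_polysome,
    "turnover": _stage_turnover,
    "transcriptome": _stage_transcriptome,
    "scan": _stage_scan,
}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order; abort downstream on failure."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    failed = False
    for stage in config.stages:
        if failed:
            report.stages.append({"stage": stage, "status": "aborted"})
            continue
        start = time.monotonic()
        try:
            record = _STAGE_FUNCS[stage](config, outdir)
            record.update(
                {"stage": stage, "status": "ok", "elapsed_s": round(time.monotonic() - start, 3)}
            )
            report.stages.append(record)
        except Exception as exc:  # recorded, then downstream aborted
            report.stages.append({"stage": stage, "status": "failed", "error": str(exc)})
            failed = True
    (outdir / "run_report.json").write_text(report.to_json())
    if failed:
        bad = next(r for r in report.stages if r["status"] == "failed")
        raise RuntimeError(f"stage {bad['stage']!r} failed: {bad['error']}")
    return report
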
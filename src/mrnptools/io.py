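"""Readers and writers for the pipeline's delimited-text interfaces.

All tabular data travel as TSV, metadata as YAML sidecars, structured
results as JSON, sequences as FASTA.  The same formats are written by the
synthetic-data generator and read by the analysis stages.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .interactome import Assay, BindingExperiment, BindingMatrix
from .motifs import MotifHit, MotifKind, MotifSpec
from .polysome import PolysomeProfile
from .simulate import GroundTruth

PathLike = Union[str, Path]

SPIKE_TARGET = "SPIKE"


# ---------------------------------------------------------------- binding

def write_binding_experiments(
    experiments: Sequence[BindingExperiment], counts_path: PathLike, meta_path: PathLike
) -> None:
    """Matrix TSV (rows = transcripts, columns = experiments) + YAML sidecar."""
    table = pd.DataFrame({e.label: e.values for e in experiments})
    table.index.name = "transcript"
    table.to_csv(counts_path, sep="\t")
    meta = [
        {"column": e.label, "rbp_id": e.rbp_id, "assay": e.assay.value, "replicate": e.replicate}
        for e in experiments
    ]
    Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_binding_experiments(
    counts_path: PathLike, meta_path: PathLike
) -> list[BindingExperiment]:
    table = pd.read_csv(counts_path, sep="\t", index_col="transcript")
    meta = yaml.safe_load(Path(meta_path).read_text())
    experiments = []
    for entry in meta:
        col = entry["column"]
        if col not in table.columns:
            raise ValueError(f"metadata column {col!r} absent from counts table")
        experiments.append(
            BindingExperiment(
                rbp_id=entry["rbp_id"],
                assay=Assay(entry["assay"]),
                replicate=int(entry["replicate"]),
                values=table[col],
            )
        )
    return experiments


def write_binding_matrix(matrix: BindingMatrix, outdir: PathLike, prefix: str = "binding") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "score": outdir / f"{prefix}_scores.tsv",
        "category": outdir / f"{prefix}_categories.tsv",
        "log": outdir / f"{prefix}_normalization_log.json",
    }
    matrix.score.rename_axis("transcript").to_csv(paths["score"], sep="\t")
    matrix.category.rename_axis("transcript").to_csv(paths["category"], sep="\t")
    paths["log"].write_text(json.dumps(matrix.normalization_log, indent=2))
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------- enrichment

def write_ranking(ranking: pd.Series, path: PathLike) -> None:
    df = ranking.rename("score").rename_axis("transcript").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_ranking(path: PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["score"].to_numpy(), index=df["transcript"])


def read_gene_set(path: PathLike, name: Optional[str] = None):
    """One id per line, or a single GMT-style line (name, description, ids)."""
    from .enrichment import GeneSet

    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) == 1 and "\t" in lines[0]:
        fields = lines[0].split("\t")
        return GeneSet(name or fields[0], fields[2:])
    return GeneSet(name or Path(path).stem, lines)


def write_gene_set(members: Sequence[str], path: PathLike) -> None:
    Path(path).write_text("\n".join(members) + "\n")


# ---------------------------------------------------------------- qPCR / RIP

def write_qpcr_wells(wells: pd.DataFrame, path: PathLike) -> None:
    wells.to_csv(path, sep="\t", index=False)


def read_qpcr_wells(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sample_map(sample_map: dict, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(sample_map, sort_keys=False))


def read_sample_map(path: PathLike) -> dict:
    return yaml.safe_load(Path(path).read_text())


# ---------------------------------------------------------------- polysome

def write_polysome_profiles(profiles: Sequence[PolysomeProfile], path: PathLike) -> None:
    """Long format: condition, target, fraction, quantity; spike rows use the
    reserved target name SPIKE."""
    rows = []
    for profile in profiles:
        for target in profile.quantities.index:
            for fraction in profile.quantities.columns:
                rows.append(
                    {
                        "condition": profile.condition,
                        "target": target,
                        "fraction": int(fraction),
                        "quantity": float(profile.quantities.loc[target, fraction]),
                    }
                )
        for fraction, q in profile.spike.items():
            rows.append(
                {
                    "condition": profile.condition,
                    "target": SPIKE_TARGET,
                    "fraction": int(fraction),
                    "quantity": float(q),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_polysome_profiles(
    path: PathLike, fraction_classes: Optional[Mapping[int, str]] = None
) -> list[PolysomeProfile]:
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for condition, grp in df.groupby("condition", sort=True):
        wide = grp.pivot(index="target", columns="fraction", values="quantity")
        wide.columns = [int(c) for c in wide.columns]
        wide = wide[sorted(wide.columns)]
        if SPIKE_TARGET not in wide.index:
            raise ValueError(f"no spike rows (target {SPIKE_TARGET!r}) for condition {condition!r}")
        spike = wide.loc[SPIKE_TARGET]
        quantities = wide.drop(index=SPIKE_TARGET)
        profiles.append(
            PolysomeProfile(
                condition=str(condition),
                quantities=quantities,
                spike=spike,
                fraction_classes=fraction_classes,
            )
        )
    return profiles


def read_fraction_classes(path: PathLike) -> dict[int, str]:
    raw = yaml.safe_load(Path(path).read_text())
    return {int(k): str(v) for k, v in raw.items()}


# ---------------------------------------------------------------- turnover

def write_chase_table(series_list, path: PathLike) -> None:
    rows = []
    for s in series_list:
        for t, a in zip(s.times, s.amounts):
            rows.append(
                {"protein": s.protein, "condition": s.condition, "time_min": float(t), "amount": float(a)}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_chase_table(path: PathLike):
    from .turnover import ChaseSeries

    df = pd.read_csv(path, sep="\t")
    out = []
    for (protein, condition), grp in df.groupby(["protein", "condition"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            ChaseSeries(
                protein=str(protein),
                condition=str(condition),
                times=grp["time_min"].to_numpy(),
                amounts=grp["amount"].to_numpy(),
            )
        )
    return out


# ---------------------------------------------------------------- microarray

def write_ratio_table(ratios: pd.DataFrame, path: PathLike) -> None:
    ratios.to_csv(path, sep="\t", index=False)


def read_ratio_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_category_map(path: PathLike, column: str) -> dict[str, str]:
    """Per-gene categories from a written category matrix, one column."""
    df = pd.read_csv(path, sep="\t", index_col="transcript")
    if column not in df.columns:
        raise ValueError(f"column {column!r} absent from category matrix")
    return df[column].to_dict()


# ---------------------------------------------------------------- sequences / motifs

def write_fasta(sequences: Mapping[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=tid, description="") for tid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_motifs(path: PathLike) -> list[MotifSpec]:
    raw = yaml.safe_load(Path(path).read_text())
    specs = []
    for entry in raw:
        specs.append(
            MotifSpec(
                motif_id=entry["motif_id"],
                kind=MotifKind(entry["kind"]),
                pattern=entry["pattern"],
                repeat_count=entry.get("repeat_count"),
            )
        )
    return specs


def write_motifs(motifs: Sequence[MotifSpec], path: PathLike) -> None:
    raw = []
    for m in motifs:
        entry = {"motif_id": m.motif_id, "kind": m.kind.value, "pattern": m.pattern}
        if m.repeat_count is not None:
            entry["repeat_count"] = m.repeat_count
        raw.append(entry)
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def write_motif_hits(hits: Sequence[MotifHit], bed_path: PathLike, report_path: PathLike) -> None:
    """BED-like 0-based half-open TSV plus a 1-based inclusive report."""
    with open(bed_path, "w") as fh:
        for h in hits:
            start0, end0 = h.bed_interval
            fh.write(f"{h.transcript}\t{start0}\t{end0}\t{h.motif_id}\t.\t+\n")
    rows = [
        {
            "transcript": h.transcript,
            "start": h.start,
            "end": h.end,
            "matched": h.matched,
            "motif_id": h.motif_id,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=["transcript", "start", "end", "matched", "motif_id"]).to_csv(
        report_path, sep="\t", index=False
    )


# ---------------------------------------------------------------- ground truth

def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    Path(path).write_text(json.dumps(truth.to_jsonable(), indent=2, sort_keys=True))


def read_ground_truth(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
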
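"""RT-qPCR relative quantification for RNA immunoprecipitation experiments.

Ct values convert to arbitrary-unit relative quantities via the amplification
efficiency E (quantity = dilution x E^-Ct).  Percent of IP expresses the
immunoprecipitated quantity as a percentage of the total input (the measured
input aliquot scaled up by the share of material it represents).  Fold over
control divides bait-normalized percent-of-IP values by the matching no-tag
control, which is therefore exactly 1.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "QpcrWell",
    "RipQuantification",
    "ct_to_relative_quantity",
    "average_technical_replicates",
    "percent_ip",
    "fold_over_control",
    "quantify_rip",
]

#: Technical-replicate Ct spread above which a warning is raised (cycles).
CT_REPLICATE_SD_WARN = 0.5


@dataclass
class QpcrWell:
    target: str
    sample: str
    ct: float
    dilution_factor: float = 1.0
    efficiency: float = 2.0
    input_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct):
            raise ValueError("ct must be finite")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must lie in (1, 2]")
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be positive")
        if not (0.0 < self.input_fraction <= 1.0):
            raise ValueError("input_fraction must lie in (0, 1]")


@dataclass
class RipQuantification:
    target: str
    sample: str
    percent_ip: float
    fold_over_no_tag: float


def ct_to_relative_quantity(well: QpcrWell) -> float:
    """Arbitrary-unit quantity: dilution_factor x efficiency^(-ct)."""
    return well.dilution_factor * well.efficiency ** (-well.ct)


def average_technical_replicates(wells: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates on the Ct scale per (target, sample).

    Expects columns target, sample, ct and optionally dilution_factor,
    efficiency, input_fraction (which must agree within a group).  A
    between-replicate Ct standard deviation above 0.5 cycles warns.
    """
    required = {"target", "sample", "ct"}
    if not required.issubset(wells.columns):
        raise ValueError(f"wells table needs columns {sorted(required)}")
    out = []
    for (target, sample), grp in wells.groupby(["target", "sample"], sort=True):
        if len(grp) > 1:
            sd = float(grp["ct"].std(ddof=1))
            if sd > CT_REPLICATE_SD_WARN:
                _warnings.warn(
                    f"technical replicates for {target}/{sample} spread "
                    f"{sd:.2f} cycles (> {CT_REPLICATE_SD_WARN})",
                    stacklevel=2,
                )
        row = {"target": target, "sample": sample, "ct": float(grp["ct"].mean())}
        for col in ("dilution_factor", "efficiency", "input_fraction"):
            if col in grp.columns:
                vals = grp[col].unique()
                if len(vals) > 1:
                    raise ValueError(f"inconsistent {col} for {target}/{sample}")
                row[col] = float(vals[0])
        out.append(row)
    return pd.DataFrame(out)


def percent_ip(ip_quantity: float, input_quantity: float, input_fraction: float = 1.0) -> float:
    """IP recovery as a percentage of the total input material."""
    if input_quantity <= 0:
        raise ValueError("input_quantity must be positive")
    if not (0.0 < input_fraction <= 1.0):
        raise ValueError("input_fraction must lie in (0, 1]")
    if ip_quantity < 0:
        raise ValueError("ip_quantity must be non-negative")
    return 100.0 * ip_quantity / (input_quantity / input_fraction)


def fold_over_control(
    percent_ips: Mapping[str, Mapping[str, float]],
    bait_recovery: Mapping[str, float],
    no_tag: str,
    pseudocount: Optional[float] = None,
) -> list[RipQuantification]:
    """Bait-normalize percent-of-IP values, then express relative to no-tag.

    ``percent_ips`` maps sample -> target -> percent of IP.  Each value is
    divided by its sample's bait recovery and by the no-tag value for the
    same target, so the no-tag control comes out exactly 1.  A zero no-tag
    value errors unless a pseudocount is configured (then warns).
    """
    if no_tag not in percent_ips:
        raise ValueError(f"no-tag sample {no_tag!r} absent from percent_ips")
    for sample in percent_ips:
        if sample not in bait_recovery:
            raise ValueError(f"missing bait recovery for sample {sample!r}")
        if bait_recovery[sample] <= 0:
            raise ValueError("bait recoveries must be positive")
    results: list[RipQuantification] = []
    ref = {
        t: v / bait_recovery[no_tag] for t, v in percent_ips[no_tag].items()
    }
    for sample in percent_ips:
        for target, pct in percent_ips[sample].items():
            if target not in ref:
                raise ValueError(f"target {target!r} missing from no-tag sample")
            denom = ref[target]
            if denom == 0:
                if pseudocount is None:
                    raise ValueError(
                        f"no-tag percent of IP is zero for {target!r}; "
                        "enable a pseudocount to proceed"
                    )
                _warnings.warn(
                    f"zero no-tag value for {target!r}; using pseudocount",
                    stacklevel=2,
                )
                denom = pseudocount
            if sample == no_tag:
                fold = 1.0
            else:
                fold = (pct / bait_recovery[sample]) / denom
            results.append(
                RipQuantification(
                    target=target, sample=sample, percent_ip=pct, fold_over_no_tag=fold
                )
            )
    return results


def quantify_rip(wells: pd.DataFrame, sample_map: dict) -> pd.DataFrame:
    """Full RIP quantification from a well table plus a sample map.

    ``sample_map`` has the shape::

        pairs: [{ip: ip_tag, input: input_tag}, {ip: ip_notag, input: input_notag}]
        bait_recovery: {ip_tag: 0.8, ip_notag: 0.25}
        no_tag_ip: ip_notag

    Technical replicates are averaged on Ct; quantities, percent of IP and
    fold over no-tag are computed per target.
    """
    avg = average_technical_replicates(wells)
    avg = avg.set_index(["sample", "target"])

    def quantity(sample: str, target: str) -> QpcrWell:
        try:
            row = avg.loc[(sample, target)]
        except KeyError:
            raise ValueError(f"no wells for sample {sample!r}, target {target!r}") from None
        return QpcrWell(
            target=target,
            sample=sample,
            ct=float(row["ct"]),
            dilution_factor=float(row.get("dilution_factor", 1.0)),
            efficiency=float(row.get("efficiency", 2.0)),
            input_fraction=float(row.get("input_fraction", 1.0)),
        )

    percent_by_sample: dict[str, dict[str, float]] = {}
    for pair in sample_map["pairs"]:
        ip_sample, input_sample = pair["ip"], pair["input"]
        targets = sorted({t for s, t in avg.index if s == ip_sample})
        percent_by_sample[ip_sample] = {}
        for target in targets:
            ip_well = quantity(ip_sample, target)
            in_well = quantity(input_sample, target)
            percent_by_sample[ip_sample][target] = percent_ip(
                ct_to_relative_quantity(ip_well),
                ct_to_relative_quantity(in_well),
                in_well.input_fraction,
            )
    results = fold_over_control(
        percent_by_sample,
        sample_map["bait_recovery"],
        sample_map["no_tag_ip"],
        pseudocount=sample_map.get("pseudocount"),
    )
    return pd.DataFrame(
        [
            {
                "target": r.target,
                "sample": r.sample,
                "percent_ip": r.percent_ip,
                "fold_over_no_tag": r.fold_over_no_tag,
            }
            for r in results
        ]
    ).sort_values(["sample", "target"], ignore_index=True)
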
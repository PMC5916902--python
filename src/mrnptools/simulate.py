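"""Seeded synthetic-data generator with ground truth for every pipeline stage.

Each generator emulates the statistical structure its downstream analysis
assumes, so the whole pipeline can be exercised end to end with known
planted parameters:

* binding experiments — CRAC-style counts are overdispersed (gamma-Poisson)
  draws whose expectation is proportional to transcript expression times an
  RBP-specific binding affinity, scaled to an expected library depth; the
  expression term is the confound the harmonization must remove.  RIP-style
  experiments emit noisy rank scores monotone in affinity; CLIP-style
  experiments emit binary calls thresholded on affinity.
* polysome profiles — per-transcript fraction quantities are a two-component
  mixture: (1 - theta) of the mass in a light-fraction peak and theta in a
  polysomal peak (discretized Gaussian bumps renormalized over fractions),
  multiplied by fraction-specific spike recovery factors and multiplicative
  lognormal noise; the spike RNA is emitted per fraction with the same
  recovery factors.
* chase series — amounts 2^(-t / half_life) with multiplicative lognormal
  noise; amount at t = 0 is 1 before noise.
* RIP-qPCR tables — Ct values generated as offset - log_E(quantity) + noise
  for input/IP wells of a bait-tagged and a no-tag sample, constructed so the
  noiseless roundtrip through the qPCR module returns the planted fold
  enrichments exactly.
* dye-swap replicate log2 ratios with a per-gene inconsistency parameter
  (the planted between-replicate SD), for the consistency filter.

One global seed expands into per-stage child seeds through a fixed
derivation: numpy SeedSequence(seed, spawn_key=(stage_index,)) with stage
indices binding=0, polysome=1, chase=2, qpcr=3, microarray=4, sequences=5.
Identical (config, seed) therefore reproduces each stage independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .interactome import Assay, BindingExperiment
from .polysome import PolysomeProfile
from .turnover import ChaseSeries

__all__ = [
    "RbpSpec",
    "PolysomeSpecs",
    "ChaseSpecs",
    "QpcrSpecs",
    "MicroarraySpecs",
    "SimulationConfig",
    "GroundTruth",
    "stage_rng",
    "simulate_binding_experiments",
    "simulate_polysome_profiles",
    "simulate_chase_series",
    "simulate_rip_qpcr",
    "simulate_dye_swap_ratios",
    "simulate_sequences",
]

STAGE_KEYS = {
    "binding": 0,
    "polysome": 1,
    "chase": 2,
    "qpcr": 3,
    "microarray": 4,
    "sequences": 5,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for one stage, derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STAGE_KEYS[stage],)))


@dataclass
class RbpSpec:
    """One simulated RBP dataset: assay type, depth and affinity prior."""

    rbp_id: str
    n_replicates: int = 2
    depth: float = 2e6  # expected total count per CRAC library
    affinity_meanlog: float = 0.0
    affinity_sdlog: float = 1.0
    assay: Assay = Assay.CRAC_COUNT
    rip_noise_sd: float = 0.5  # log-affinity noise before ranking (RIP)
    clip_bound_quantile: float = 0.75  # affinity quantile above which CLIP calls bound

    def __post_init__(self) -> None:
        self.assay = Assay(self.assay)
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def default_rbp_panel() -> list[RbpSpec]:
    """A specific binder among generic mRNA-binding factors.

    One RBP with a wide affinity spread (the specific binder whose targets
    the harmonization should recover) and two factors that bind most
    transcripts with similar, near-uniform affinity, as generic export or
    packaging factors do.  Two replicates each.
    """
    return [
        RbpSpec("rbp_specific", n_replicates=2, affinity_sdlog=1.5),
        RbpSpec("rbp_generic1", n_replicates=2, affinity_sdlog=0.3),
        RbpSpec("rbp_generic2", n_replicates=2, affinity_sdlog=0.3),
    ]


@dataclass
class PolysomeSpecs:
    n_fractions: int = 14
    light_peak_fraction: int = 3
    poly_peak_fraction: int = 11
    peak_width: float = 1.2  # fractions; Gaussian sigma of each bump
    noise_cv: float = 0.1
    spike_perturbation: float = 0.3  # fraction recovery in [1 - p, 1 + p]

    def __post_init__(self) -> None:
        if self.n_fractions < 3:
            raise ValueError("n_fractions must be >= 3")


@dataclass
class ChaseSpecs:
    time_points: tuple = (0.0, 15.0, 30.0, 60.0, 90.0)  # minutes
    noise_cv: float = 0.05


@dataclass
class QpcrSpecs:
    efficiency: float = 2.0
    ct_noise_sd: float = 0.2  # cycles
    n_technical_replicates: int = 3
    input_fraction: float = 0.1
    ct_offset: float = 30.0  # Ct of a unit quantity
    base_percent_ip: float = 0.05  # no-tag background recovery, %
    bait_recovery: tuple = (("ip_tag", 0.8), ("ip_notag", 0.25))

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must lie in (1, 2]")


@dataclass
class MicroarraySpecs:
    noise_sd: float = 0.15  # per-replicate log2 measurement noise
    n_replicates: int = 2  # second replicate dye-swapped


@dataclass
class SimulationConfig:
    n_transcripts: int = 2000
    rbp_specs: list = field(default_factory=default_rbp_panel)
    expression_meanlog: float = 0.0
    expression_sdlog: float = 1.5
    dispersion: float = 0.2
    seed: int = 0
    polysome_specs: PolysomeSpecs = field(default_factory=PolysomeSpecs)
    chase_specs: ChaseSpecs = field(default_factory=ChaseSpecs)
    qpcr_specs: QpcrSpecs = field(default_factory=QpcrSpecs)
    microarray_specs: MicroarraySpecs = field(default_factory=MicroarraySpecs)

    def __post_init__(self) -> None:
        if self.n_transcripts < 2:
            raise ValueError("n_transcripts must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        self.rbp_specs = [
            spec if isinstance(spec, RbpSpec) else RbpSpec(**spec)
            for spec in self.rbp_specs
        ]
        if isinstance(self.polysome_specs, dict):
            self.polysome_specs = PolysomeSpecs(**self.polysome_specs)
        if isinstance(self.chase_specs, dict):
            self.chase_specs = ChaseSpecs(**self.chase_specs)
        if isinstance(self.qpcr_specs, dict):
            self.qpcr_specs = QpcrSpecs(**self.qpcr_specs)
        if isinstance(self.microarray_specs, dict):
            self.microarray_specs = MicroarraySpecs(**self.microarray_specs)

    def transcript_ids(self) -> list[str]:
        width = max(4, len(str(self.n_transcripts)))
        return [f"TX{i:0{width}d}" for i in range(1, self.n_transcripts + 1)]


@dataclass
class GroundTruth:
    """Planted parameters of a simulation, for recovery tests."""

    affinity: dict = field(default_factory=dict)  # (transcript, rbp) -> float
    expression: dict = field(default_factory=dict)  # transcript -> float
    member_sets: dict = field(default_factory=dict)  # name -> {members, shift_sd}
    translated_proportion: dict = field(default_factory=dict)  # (target, condition) -> float
    half_life: dict = field(default_factory=dict)  # (protein, condition) -> minutes
    true_fold_enrichment: dict = field(default_factory=dict)  # (target, bait) -> float
    inconsistent_genes: dict = field(default_factory=dict)  # gene -> planted replicate SD
    log2_fold: dict = field(default_factory=dict)  # gene -> planted log2 ratio
    motif_sites: dict = field(default_factory=dict)  # transcript -> [(start, end)]

    def to_jsonable(self) -> dict:
        def keyed(d: dict) -> dict:
            return {"|".join(map(str, k)) if isinstance(k, tuple) else k: v for k, v in d.items()}

        out = {name: keyed(val) for name, val in asdict(self).items()}
        return out


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def simulate_binding_experiments(
    config: SimulationConfig,
    geneset_size: int = 0,
    geneset_shift_sd: float = 1.5,
) -> tuple[list[BindingExperiment], GroundTruth]:
    """Simulated RBP-binding datasets plus their planted parameters.

    CRAC-type counts: mu = depth * affinity * expression (normalized over
    transcripts); with dispersion d > 0 the rate is Gamma(1/d, d * mu) and
    the count Poisson; d = 0 gives deterministic half-up rounding of mu.
    Optionally plants a gene set of ``geneset_size`` transcripts whose
    log-affinity for the first RBP is shifted up by ``geneset_shift_sd``
    affinity-prior SDs, recorded in ``member_sets``.
    """
    rng = stage_rng(config.seed, "binding")
    transcripts = config.transcript_ids()
    n = config.n_transcripts
    expression = rng.lognormal(config.expression_meanlog, config.expression_sdlog, n)
    truth = GroundTruth(expression=dict(zip(transcripts, expression.tolist())))
    experiments: list[BindingExperiment] = []
    affinities: dict[str, np.ndarray] = {}
    for spec in config.rbp_specs:
        affinities[spec.rbp_id] = rng.lognormal(spec.affinity_meanlog, spec.affinity_sdlog, n)
    if geneset_size:
        if geneset_size >= n:
            raise ValueError("planted gene set must be smaller than the universe")
        focal = config.rbp_specs[0]
        members = rng.choice(n, size=geneset_size, replace=False)
        affinities[focal.rbp_id] = affinities[focal.rbp_id].copy()
        affinities[focal.rbp_id][members] *= math.exp(geneset_shift_sd * focal.affinity_sdlog)
        truth.member_sets["planted_targets"] = {
            "members": [transcripts[i] for i in sorted(members)],
            "shift_sd": geneset_shift_sd,
            "rbp_id": focal.rbp_id,
        }
    for spec in config.rbp_specs:
        aff = affinities[spec.rbp_id]
        for t, a in zip(transcripts, aff.tolist()):
            truth.affinity[(t, spec.rbp_id)] = a
        for rep in range(1, spec.n_replicates + 1):
            if spec.assay is Assay.CRAC_COUNT:
                weight = aff * expression
                mu = spec.depth * weight / weight.sum()
                if config.dispersion == 0:
                    counts = np.floor(mu + 0.5)  # half-up rounding
                else:
                    lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mu)
                    counts = rng.poisson(lam).astype(float)
                values = pd.Series(counts, index=transcripts)
            elif spec.assay is Assay.RIP_SCORE:
                noisy = np.log(aff) + rng.normal(0.0, spec.rip_noise_sd, n)
                # rank percentile in (0, 1], monotone in noisy affinity
                ranks = noisy.argsort().argsort() + 1
                values = pd.Series(ranks / n, index=transcripts)
            else:  # CLIP_CALL: deterministic threshold on affinity
                cutoff = np.quantile(aff, spec.clip_bound_quantile)
                values = pd.Series((aff >= cutoff).astype(float), index=transcripts)
            experiments.append(
                BindingExperiment(rbp_id=spec.rbp_id, assay=spec.assay, replicate=rep, values=values)
            )
    return experiments, truth


def _peak_profile(n_fractions: int, center: int, width: float) -> np.ndarray:
    f = np.arange(1, n_fractions + 1, dtype=float)
    bump = np.exp(-((f - center) ** 2) / (2.0 * width * width))
    return bump / bump.sum()


def simulate_polysome_profiles(
    config: SimulationConfig,
    thetas: Mapping[str, Mapping[str, float]],
) -> tuple[list[PolysomeProfile], GroundTruth]:
    """Profiles for each condition in ``thetas`` (condition -> target -> theta).

    theta is the planted translated proportion: the share of a transcript's
    mass in the polysomal peak, the rest sitting in the light-fraction peak.
    """
    specs = config.polysome_specs
    rng = stage_rng(config.seed, "polysome")
    light = _peak_profile(specs.n_fractions, specs.light_peak_fraction, specs.peak_width)
    poly = _peak_profile(specs.n_fractions, specs.poly_peak_fraction, specs.peak_width)
    fractions = list(range(1, specs.n_fractions + 1))
    truth = GroundTruth()
    profiles: list[PolysomeProfile] = []
    for condition, theta_map in thetas.items():
        for target, theta in theta_map.items():
            if not (0.0 <= theta <= 1.0):
                raise ValueError(f"theta for {target!r} outside [0, 1]")
        recovery = rng.uniform(
            1.0 - specs.spike_perturbation, 1.0 + specs.spike_perturbation, specs.n_fractions
        )
        rows = {}
        for target, theta in theta_map.items():
            mass = (1.0 - theta) * light + theta * poly
            noise = _lognormal_unit_mean(rng, specs.noise_cv, specs.n_fractions)
            rows[target] = mass * recovery * noise
            truth.translated_proportion[(target, condition)] = float(theta)
        spike = pd.Series(
            recovery * _lognormal_unit_mean(rng, specs.noise_cv, specs.n_fractions),
            index=fractions,
        )
        quantities = pd.DataFrame.from_dict(rows, orient="index", columns=fractions)
        profiles.append(
            PolysomeProfile(condition=condition, quantities=quantities, spike=spike)
        )
    return profiles, truth


def simulate_chase_series(
    config: SimulationConfig,
    half_life: float,
    protein: str = "protein",
    condition: str = "wt",
    rng: Optional[np.random.Generator] = None,
) -> ChaseSeries:
    """One cycloheximide-chase time course with planted half-life (minutes).

    ``half_life=math.inf`` yields a constant series (no decay).  Pass an
    explicit ``rng`` to draw several independent series from one stream.
    """
    if not (half_life > 0):
        raise ValueError("half_life must be positive")
    specs = config.chase_specs
    t = np.asarray(specs.time_points, dtype=float)
    if t[0] != 0:
        raise ValueError("chase time points must include t = 0 first")
    if rng is None:
        rng = stage_rng(config.seed, "chase")
    if math.isinf(half_life):
        amounts = np.ones_like(t)
    else:
        amounts = np.power(2.0, -t / half_life)
    amounts = amounts * _lognormal_unit_mean(rng, specs.noise_cv, t.shape[0])
    return ChaseSeries(protein=protein, condition=condition, times=t, amounts=amounts)


def simulate_rip_qpcr(
    config: SimulationConfig,
    fold_enrichment: Mapping[str, float],
) -> tuple[pd.DataFrame, dict, GroundTruth]:
    """qPCR well table + sample map with planted fold enrichments.

    Builds input and IP wells for a bait-tagged and a no-tag sample such
    that, with zero Ct noise, `mrnptools.qpcr.quantify_rip` returns exactly
    the planted fold-over-no-tag values.  Returns (wells, sample_map, truth).
    """
    specs = config.qpcr_specs
    rng = stage_rng(config.seed, "qpcr")
    bait = dict(specs.bait_recovery)
    truth = GroundTruth()
    rows = []
    for target, fold in fold_enrichment.items():
        if fold <= 0:
            raise ValueError("fold enrichments must be positive")
        truth.true_fold_enrichment[(target, "ip_tag")] = float(fold)
        # per-sample input abundance (arbitrary units); shared across samples
        q_input = float(rng.lognormal(0.0, 1.0))
        # no-tag background: base percent of IP, bait-normalized reference
        pct_notag = specs.base_percent_ip
        pct_tag = fold * pct_notag * bait["ip_tag"] / bait["ip_notag"]
        for sample, pct in (("ip_tag", pct_tag), ("ip_notag", pct_notag)):
            q_ip = pct / 100.0 * (q_input / specs.input_fraction)
            input_sample = "input_tag" if sample == "ip_tag" else "input_notag"
            for q, samp in ((q_input, input_sample), (q_ip, sample)):
                ct = -math.log(q, specs.efficiency) + specs.ct_offset
                for _ in range(specs.n_technical_replicates):
                    rows.append(
                        {
                            "target": target,
                            "sample": samp,
                            "ct": ct + rng.normal(0.0, specs.ct_noise_sd),
                            "dilution_factor": 1.0,
                            "efficiency": specs.efficiency,
                            "input_fraction": specs.input_fraction,
                        }
                    )
    # the Ct offset cancels in percent-of-IP ratios; fold over no-tag cancels
    # the bait recoveries and the base percent, leaving the planted fold
    wells = pd.DataFrame(rows)
    sample_map = {
        "pairs": [
            {"ip": "ip_tag", "input": "input_tag"},
            {"ip": "ip_notag", "input": "input_notag"},
        ],
        "bait_recovery": bait,
        "no_tag_ip": "ip_notag",
    }
    return wells, sample_map, truth


def simulate_dye_swap_ratios(
    config: SimulationConfig,
    log2_fold: Mapping[str, float],
    inconsistency: Optional[Mapping[str, float]] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Dye-swap duplicate log2 ratios with planted per-gene inconsistency.

    Each gene gets ``n_replicates`` measurements of its planted log2 fold;
    even-numbered replicates are dye-swapped (their stored ratio is the
    negated orientation).  ``inconsistency`` maps gene -> planted
    between-replicate SD: the two oriented replicates are offset by
    -+ sd * sqrt(2) / 2 around the fold, so the measured (n-1) SD equals the
    planted value exactly when measurement noise is zero.
    """
    specs = config.microarray_specs
    rng = stage_rng(config.seed, "microarray")
    inconsistency = dict(inconsistency or {})
    truth = GroundTruth(
        log2_fold={g: float(v) for g, v in log2_fold.items()},
        inconsistent_genes={g: float(v) for g, v in inconsistency.items()},
    )
    rows = []
    for gene, fold in log2_fold.items():
        sd = inconsistency.get(gene, 0.0)
        offsets = np.zeros(specs.n_replicates)
        if sd > 0 and specs.n_replicates >= 2:
            half = sd * math.sqrt(2.0) / 2.0
            offsets[0], offsets[1] = -half, half
        for rep in range(1, specs.n_replicates + 1):
            oriented = fold + offsets[rep - 1] + rng.normal(0.0, specs.noise_sd)
            swapped = rep % 2 == 0
            rows.append(
                {
                    "gene": gene,
                    "replicate": rep,
                    "log2_ratio": -oriented if swapped else oriented,
                    "dye_swapped": swapped,
                    "intensity": float(rng.normal(10.0, 1.5)),
                }
            )
    return pd.DataFrame(rows), truth


def simulate_sequences(
    config: SimulationConfig,
    n_sequences: int = 20,
    length: int = 500,
    motif: str = "CATCATCA",
    plant_fraction: float = 0.5,
) -> tuple[dict[str, str], GroundTruth]:
    """Random transcript sequences with the consensus site planted in a subset.

    Returns (id -> sequence) and the truth with 1-based planted coordinates.
    """
    rng = stage_rng(config.seed, "sequences")
    bases = np.array(list("ACGT"))
    truth = GroundTruth()
    seqs: dict[str, str] = {}
    ids = config.transcript_ids()[:n_sequences]
    n_planted = int(round(plant_fraction * len(ids)))
    for i, tid in enumerate(ids):
        seq = rng.choice(bases, size=length)
        if i < n_planted:
            start = int(rng.integers(0, length - len(motif)))
            seq[start : start + len(motif)] = list(motif)
            truth.motif_sites[tid] = [(start + 1, start + len(motif))]
        seqs[tid] = "".join(seq)
    return seqs, truth
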
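"""Generator contracts: determinism, zero-noise limits, planted structure."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mrnptools.interactome import Assay
from mrnptools.simulate import (
    RbpSpec,
    SimulationConfig,
    simulate_binding_experiments,
    simulate_chase_series,
    simulate_dye_swap_ratios,
    simulate_rip_qpcr,
    simulate_sequences,
)


class TestConfigValidation:
    def test_too_few_transcripts(self):
        with pytest.raises(ValueError, match="n_transcripts"):
            SimulationConfig(n_transcripts=1)

    def test_negative_dispersion(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimulationConfig(dispersion=-0.1)

    def test_nonpositive_depth(self):
        with pytest.raises(ValueError, match="depth"):
            RbpSpec("r", depth=0.0)

    def test_bad_efficiency(self):
        config = SimulationConfig()
        with pytest.raises(ValueError, match="efficiency"):
            config.qpcr_specs.__class__(efficiency=2.5)


class TestBindingSimulation:
    def test_determinism(self):
        config = SimulationConfig(n_transcripts=100, seed=42)
        a, truth_a = simulate_binding_experiments(config)
        b, truth_b = simulate_binding_experiments(config)
        for ea, eb in zip(a, b):
            pd.testing.assert_series_equal(ea.values, eb.values)
        assert truth_a.affinity == truth_b.affinity
        assert truth_a.expression == truth_b.expression

    def test_zero_dispersion_counts_proportional(self):
        config = SimulationConfig(n_transcripts=50, seed=3, dispersion=0.0)
        experiments, truth = simulate_binding_experiments(config)
        exp = experiments[0]
        ids = list(exp.values.index)
        aff = np.array([truth.affinity[(t, exp.rbp_id)] for t in ids])
        expr = np.array([truth.expression[t] for t in ids])
        depth = config.rbp_specs[0].depth
        mu = depth * aff * expr / (aff * expr).sum()
        assert np.array_equal(exp.values.to_numpy(), np.floor(mu + 0.5))

    def test_expression_confound_dominates_raw_counts(self):
        """By construction raw counts track expression better than affinity
        for the specific binder — the confound the harmonization removes."""
        config = SimulationConfig(n_transcripts=2000, seed=1)
        experiments, truth = simulate_binding_experiments(config)
        focal = config.rbp_specs[0].rbp_id
        for exp in experiments:
            if exp.rbp_id != focal:
                continue
            ids = list(exp.values.index)
            aff = np.array([truth.affinity[(t, exp.rbp_id)] for t in ids])
            expr = np.array([truth.expression[t] for t in ids])
            raw = exp.values.to_numpy()
            assert spearmanr(raw, expr).statistic > spearmanr(raw, aff).statistic

    def test_rip_and_clip_assays(self):
        config = SimulationConfig(
            n_transcripts=80,
            seed=9,
            rbp_specs=[
                RbpSpec("rip_rbp", n_replicates=1, assay=Assay.RIP_SCORE),
                RbpSpec("clip_rbp", n_replicates=1, assay=Assay.CLIP_CALL),
            ],
        )
        experiments, truth = simulate_binding_experiments(config)
        rip, clip = experiments
        assert rip.assay is Assay.RIP_SCORE
        assert 0 < rip.values.min() and rip.values.max() <= 1
        assert set(clip.values.unique()) <= {0.0, 1.0}
        # CLIP calls are thresholded on affinity: bound transcripts have
        # uniformly higher affinity than unbound ones
        aff = pd.Series({t: truth.affinity[(t, "clip_rbp")] for t in clip.values.index})
        assert aff[clip.values == 1].min() >= aff[clip.values == 0].max()

    def test_planted_gene_set_recorded(self):
        config = SimulationConfig(n_transcripts=100, seed=5)
        _, truth = simulate_binding_experiments(config, geneset_size=10)
        planted = truth.member_sets["planted_targets"]
        assert len(planted["members"]) == 10
        assert planted["shift_sd"] == 1.5


class TestChaseSimulation:
    def test_exact_exponential_without_noise(self):
        config = SimulationConfig(seed=0)
        config.chase_specs.noise_cv = 0.0
        config.chase_specs.time_points = (0.0, 30.0, 60.0)
        series = simulate_chase_series(config, half_life=30.0)
        assert np.allclose(series.amounts, [1.0, 0.5, 0.25])

    def test_infinite_half_life_constant_series(self):
        config = SimulationConfig(seed=0)
        config.chase_specs.noise_cv = 0.0
        series = simulate_chase_series(config, half_life=math.inf)
        assert np.all(series.amounts == 1.0)

    def test_nonpositive_half_life_errors(self):
        with pytest.raises(ValueError, match="half_life"):
            simulate_chase_series(SimulationConfig(seed=0), half_life=0.0)


class TestQpcrSimulation:
    def test_planted_fold_one_recovered(self):
        from mrnptools.qpcr import quantify_rip

        config = SimulationConfig(seed=2)
        config.qpcr_specs.ct_noise_sd = 0.0
        wells, sample_map, _ = simulate_rip_qpcr(config, {"t": 1.0})
        result = quantify_rip(wells, sample_map)
        fold = result[result["sample"] == "ip_tag"]["fold_over_no_tag"].iloc[0]
        assert fold == pytest.approx(1.0, rel=1e-9)

    def test_noisy_folds_spread_matches_lognormal_propagation(self):
        """Ct noise of sd cycles propagates to lognormal folds: the sd of
        log2(fold) over replicates should match the analytic combination of
        the four contributing wells (4 technical means of 3 wells each)."""
        from mrnptools.qpcr import quantify_rip

        sd_ct = 0.2
        n_rep = 3
        config = SimulationConfig(seed=4)
        config.qpcr_specs.ct_noise_sd = sd_ct
        config.qpcr_specs.n_technical_replicates = n_rep
        logs = []
        for i in range(60):
            config.seed = 1000 + i
            wells, sample_map, _ = simulate_rip_qpcr(config, {"t": 10.0})
            result = quantify_rip(wells, sample_map)
            fold = result[result["sample"] == "ip_tag"]["fold_over_no_tag"].iloc[0]
            logs.append(math.log2(fold))
        # four independent averaged Ct values enter the fold
        expected_sd = math.sqrt(4 * sd_ct**2 / n_rep)
        observed_sd = float(np.std(logs, ddof=1))
        assert observed_sd == pytest.approx(expected_sd, rel=0.35)
        assert np.mean(logs) == pytest.approx(math.log2(10.0), abs=3 * expected_sd / math.sqrt(60))


class TestDyeSwapSimulation:
    def test_swapped_replicates_store_negated_orientation(self):
        config = SimulationConfig(n_transcripts=2, seed=0)
        config.microarray_specs.noise_sd = 0.0
        ratios, _ = simulate_dye_swap_ratios(config, {"g": 0.8})
        by_rep = ratios.set_index("replicate")
        assert by_rep.loc[1, "log2_ratio"] == pytest.approx(0.8)
        assert by_rep.loc[2, "log2_ratio"] == pytest.approx(-0.8)
        assert bool(by_rep.loc[2, "dye_swapped"])


class TestSequenceSimulation:
    def test_planted_sites_present_at_recorded_coordinates(self):
        config = SimulationConfig(n_transcripts=30, seed=8)
        seqs, truth = simulate_sequences(config, n_sequences=10, motif="CATCATCA")
        assert len(truth.motif_sites) == 5
        for tid, sites in truth.motif_sites.items():
            for start, end in sites:
                assert seqs[tid][start - 1 : end] == "CATCATCA"
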
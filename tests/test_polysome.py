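"""Spike correction, fraction distributions and translated proportions."""

import numpy as np
import pandas as pd
import pytest

from mrnptools.polysome import (
    FractionClass,
    PolysomeProfile,
    compare_conditions,
    default_fraction_classes,
    fraction_distribution,
    spike_correct,
    summarize_profile,
    translated_proportion,
)
from mrnptools.simulate import SimulationConfig, simulate_polysome_profiles
from mrnptools.studies import polysome_recovery_study


def make_profile(quant_rows, spike=None, n_fractions=14, condition="wt"):
    fractions = list(range(1, n_fractions + 1))
    quantities = pd.DataFrame.from_dict(quant_rows, orient="index", columns=fractions)
    if spike is None:
        spike = pd.Series(1.0, index=fractions)
    else:
        spike = pd.Series(spike, index=fractions)
    return PolysomeProfile(condition=condition, quantities=quantities, spike=spike)


class TestSpikeCorrect:
    def test_uniform_spike_is_identity(self):
        profile = make_profile({"t": np.arange(1.0, 15.0)})
        corrected = spike_correct(profile)
        assert np.allclose(corrected.loc["t"], profile.quantities.loc["t"])

    def test_double_recovery_halves_quantities(self):
        spike = np.ones(14)
        spike[4] = 2.0  # fraction 5 recovered 2x the mean of the others
        profile = make_profile({"t": np.ones(14)}, spike=spike)
        corrected = spike_correct(profile)
        rel = spike[4] / spike.mean()
        assert corrected.loc["t", 5] == pytest.approx(1.0 / rel)

    def test_zero_spike_errors(self):
        spike = np.ones(14)
        spike[4] = 0.0
        with pytest.raises(ValueError, match="spike"):
            make_profile({"t": np.ones(14)}, spike=spike)

    def test_preserves_between_target_ratios(self):
        rng = np.random.default_rng(0)
        profile = make_profile(
            {"a": rng.random(14) + 0.1, "b": rng.random(14) + 0.1},
            spike=rng.random(14) + 0.5,
        )
        corrected = spike_correct(profile)
        before = profile.quantities.loc["a"] / profile.quantities.loc["b"]
        after = corrected.loc["a"] / corrected.loc["b"]
        assert np.allclose(before, after)


class TestDistribution:
    def test_single_nonzero_fraction(self):
        q = np.zeros(14)
        q[9] = 3.0
        dist = fraction_distribution(make_profile({"t": q}).quantities, "t")
        assert dist[10] == 1.0
        assert dist.sum() == 1.0

    def test_sums_to_one(self):
        rng = np.random.default_rng(1)
        profile = make_profile({"t": rng.random(14)})
        dist = fraction_distribution(spike_correct(profile), "t")
        assert dist.sum() == pytest.approx(1.0, rel=1e-9)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            fraction_distribution(make_profile({"t": np.zeros(14)}).quantities, "t")


class TestTranslatedProportion:
    def test_all_mass_in_polysomes(self):
        q = np.zeros(14)
        q[8:13] = 1.0  # fractions 9..13
        dist = fraction_distribution(make_profile({"t": q}).quantities, "t")
        summary = translated_proportion(dist, default_fraction_classes())
        assert summary.translated_proportion == pytest.approx(1.0)

    def test_all_mass_in_light_fractions(self):
        q = np.zeros(14)
        q[0:6] = 1.0
        dist = fraction_distribution(make_profile({"t": q}).quantities, "t")
        summary = translated_proportion(dist, default_fraction_classes())
        assert summary.translated_proportion == 0.0

    def test_uniform_mass_counts_polysome_fractions(self):
        dist = fraction_distribution(make_profile({"t": np.ones(14)}).quantities, "t")
        summary = translated_proportion(dist, default_fraction_classes())
        assert summary.translated_proportion == pytest.approx(5 / 14)
        assert summary.heavy_polysome_proportion == pytest.approx(3 / 14)

    def test_incomplete_class_map_errors(self):
        dist = fraction_distribution(make_profile({"t": np.ones(14)}).quantities, "t")
        classes = default_fraction_classes()
        del classes[14]
        with pytest.raises(ValueError, match="cover"):
            translated_proportion(dist, classes)


class TestCompare:
    def summary_for(self, quant, condition):
        profile = make_profile({"t": quant}, condition=condition)
        return summarize_profile(profile)[0]

    def test_identical_summaries_zero_deltas(self):
        rng = np.random.default_rng(2)
        q = rng.random(14)
        rep = compare_conditions(self.summary_for(q, "a"), self.summary_for(q, "b"))
        assert rep.delta_translated_proportion == 0.0
        assert (rep.delta_distribution == 0.0).all()

    def test_light_to_polysome_shift_is_positive(self):
        light = np.zeros(14)
        light[2] = 1.0
        poly = np.zeros(14)
        poly[10] = 1.0
        rep = compare_conditions(self.summary_for(light, "wt"), self.summary_for(poly, "mut"))
        assert rep.delta_translated_proportion > 0

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(3)
        a = self.summary_for(rng.random(14), "a")
        b = self.summary_for(rng.random(14), "b")
        fwd = compare_conditions(a, b)
        rev = compare_conditions(b, a)
        assert fwd.delta_translated_proportion == pytest.approx(
            -rev.delta_translated_proportion
        )
        assert np.allclose(fwd.delta_distribution, -rev.delta_distribution)

    def test_mismatched_fraction_counts_error(self):
        a = self.summary_for(np.ones(14), "a")
        profile13 = make_profile({"t": np.ones(13)}, n_fractions=13, condition="b")
        b = summarize_profile(profile13)[0]
        with pytest.raises(ValueError, match="fraction"):
            compare_conditions(a, b)


class TestSimulatedRecovery:
    def test_boundary_thetas_without_noise(self):
        config = SimulationConfig(seed=5)
        config.polysome_specs.noise_cv = 0.0
        config.polysome_specs.spike_perturbation = 0.0
        profiles, _ = simulate_polysome_profiles(config, {"wt": {"all": 1.0, "none": 0.0}})
        corrected = spike_correct(profiles[0])
        poly_peak = config.polysome_specs.poly_peak_fraction
        light_peak = config.polysome_specs.light_peak_fraction
        dist_all = fraction_distribution(corrected, "all")
        dist_none = fraction_distribution(corrected, "none")
        assert dist_all.idxmax() == poly_peak
        assert dist_none.idxmax() == light_peak
        # mass never leaks between the two peak neighbourhoods
        assert dist_all[light_peak] < 1e-6
        assert dist_none[poly_peak] < 1e-6

    def test_mass_conservation_without_perturbations(self):
        config = SimulationConfig(seed=6)
        config.polysome_specs.noise_cv = 0.0
        config.polysome_specs.spike_perturbation = 0.0
        profiles, _ = simulate_polysome_profiles(config, {"wt": {"t": 0.37}})
        assert profiles[0].quantities.loc["t"].sum() == pytest.approx(1.0, rel=1e-9)

    def test_theta_outside_unit_interval_errors(self):
        config = SimulationConfig(seed=6)
        with pytest.raises(ValueError, match="theta"):
            simulate_polysome_profiles(config, {"wt": {"t": 1.2}})

    def test_planted_theta_recovered_under_noise_and_spike_skew(self):
        out = polysome_recovery_study(seed=1)
        assert out["max_abs_error"] < 0.05
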
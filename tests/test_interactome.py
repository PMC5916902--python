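"""Harmonization of CRAC/RIP/CLIP datasets into the common binding matrix."""

import numpy as np
import pandas as pd
import pytest

from mrnptools.interactome import (
    Assay,
    BindingExperiment,
    Category,
    SCORED_CATEGORIES,
    assemble_binding_matrix,
    categorize_quartiles,
    hits_per_million,
    quartile_sizes,
    rescale_unit_interval,
    unit_norm_per_transcript,
)
from mrnptools.simulate import SimulationConfig, simulate_binding_experiments


def make_exp(values, assay=Assay.CRAC_COUNT, rbp="rbp1", rep=1):
    return BindingExperiment(rbp_id=rbp, assay=assay, replicate=rep, values=pd.Series(values))


class TestHitsPerMillion:
    def test_simple_proportions(self):
        out = hits_per_million(make_exp({"a": 10, "b": 90}))
        assert out.values["a"] == pytest.approx(100_000)
        assert out.values["b"] == pytest.approx(900_000)

    def test_uniform_counts(self):
        out = hits_per_million(make_exp({k: 1 for k in "abcd"}))
        assert (out.values == 250_000).all()

    def test_sums_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = {f"t{i}": int(c) for i, c in enumerate(rng.integers(0, 500, 100))}
        counts["t0"] = 1  # guarantee a positive library
        out = hits_per_million(make_exp(counts))
        assert out.values.sum() == pytest.approx(1e6, rel=1e-9)

    def test_empty_library_errors(self):
        with pytest.raises(ValueError, match="empty library"):
            hits_per_million(make_exp({"a": 0, "b": 0}))


class TestUnitNorm:
    def test_three_four_five(self):
        exps = [make_exp({"t": 3}, rep=1), make_exp({"t": 4}, rep=2)]
        out, flagged = unit_norm_per_transcript(exps)
        assert out[0].values["t"] == pytest.approx(0.6)
        assert out[1].values["t"] == pytest.approx(0.8)
        assert flagged == []

    def test_single_experiment_normalizes_to_one(self):
        out, _ = unit_norm_per_transcript([make_exp({"t": 7})])
        assert out[0].values["t"] == pytest.approx(1.0)

    def test_zero_vector_flagged_not_error(self):
        exps = [make_exp({"t": 0, "u": 3}, rep=1), make_exp({"t": 0, "u": 4}, rep=2)]
        out, flagged = unit_norm_per_transcript(exps)
        assert flagged == ["t"]
        assert out[0].values["t"] == 0.0
        assert out[0].values["u"] == pytest.approx(0.6)

    def test_mismatched_universe_errors(self):
        with pytest.raises(ValueError, match="mismatched"):
            unit_norm_per_transcript([make_exp({"a": 1}), make_exp({"b": 1}, rep=2)])

    def test_sum_of_squares_is_one(self):
        rng = np.random.default_rng(1)
        ids = [f"t{i}" for i in range(50)]
        exps = [
            make_exp(dict(zip(ids, rng.integers(1, 100, 50))), rep=r) for r in (1, 2, 3)
        ]
        out, _ = unit_norm_per_transcript(exps)
        mat = np.column_stack([e.values.to_numpy() for e in out])
        assert np.allclose((mat**2).sum(axis=1), 1.0, rtol=1e-9)


class TestRescale:
    def test_affine_map(self):
        out, warns = rescale_unit_interval(make_exp({"a": 2, "b": 4, "c": 6}))
        assert list(out.values) == pytest.approx([0.0, 0.5, 1.0])
        assert warns == []

    def test_idempotent_on_canonical_range(self):
        vals = {"a": 0.0, "b": 0.25, "c": 1.0}
        exp = make_exp(vals, assay=Assay.RIP_SCORE)
        out, _ = rescale_unit_interval(exp)
        assert dict(out.values) == pytest.approx(vals)

    def test_constant_degenerates_with_warning(self):
        out, warns = rescale_unit_interval(make_exp({"a": 5, "b": 5}))
        assert (out.values == 0.0).all()
        assert len(warns) == 1


class TestQuartiles:
    def test_even_split(self):
        exp = make_exp({f"t{i}": 8 - i for i in range(8)}, assay=Assay.RIP_SCORE)
        cats, _ = categorize_quartiles(exp)
        assert (cats.value_counts() == 2).all()
        assert cats["t0"] is Category.HIGH
        assert cats["t7"] is Category.VERY_LOW_NONE

    def test_remainder_goes_to_top(self):
        assert quartile_sizes(10) == [3, 3, 2, 2]
        exp = make_exp({f"t{i}": 10 - i for i in range(10)}, assay=Assay.RIP_SCORE)
        cats, _ = categorize_quartiles(exp)
        counts = cats.value_counts()
        assert counts[Category.HIGH] == 3
        assert counts[Category.MEDIUM] == 3
        assert counts[Category.LOW] == 2
        assert counts[Category.VERY_LOW_NONE] == 2

    def test_all_tied_warns_and_uses_id_order(self):
        exp = make_exp({k: 1.0 for k in "dcba"}, assay=Assay.RIP_SCORE)
        cats, warns = categorize_quartiles(exp)
        assert len(warns) == 1
        assert cats["a"] is Category.HIGH
        assert cats["d"] is Category.VERY_LOW_NONE

    def test_too_few_transcripts(self):
        with pytest.raises(ValueError, match="at least 4"):
            categorize_quartiles(make_exp({"a": 1, "b": 2, "c": 3}, assay=Assay.RIP_SCORE))

    def test_category_monotone_in_score(self):
        rng = np.random.default_rng(3)
        exp = make_exp(
            {f"t{i}": float(v) for i, v in enumerate(rng.random(37))}, assay=Assay.RIP_SCORE
        )
        cats, _ = categorize_quartiles(exp)
        rank_of = {c: i for i, c in enumerate(SCORED_CATEGORIES)}
        df = pd.DataFrame({"score": exp.values, "cat": cats.map(rank_of)})
        df = df.sort_values("score", ascending=False)
        assert (df["cat"].diff().dropna() >= 0).all()


class TestAssemble:
    def make_panel(self, seed=0, n=40):
        config = SimulationConfig(n_transcripts=n, seed=seed)
        experiments, truth = simulate_binding_experiments(config)
        return experiments, truth

    def test_deterministic(self):
        exps, _ = self.make_panel()
        a = assemble_binding_matrix(exps)
        b = assemble_binding_matrix(exps)
        pd.testing.assert_frame_equal(a.score, b.score)
        pd.testing.assert_frame_equal(a.category, b.category)

    def test_clip_passthrough(self):
        exps, _ = self.make_panel()
        clip = make_exp(
            {t: 1.0 if i % 2 else 0.0 for i, t in enumerate(exps[0].values.index)},
            assay=Assay.CLIP_CALL,
            rbp="clip_rbp",
        )
        matrix = assemble_binding_matrix(list(exps) + [clip])
        col = clip.label
        assert matrix.score[col].isna().all()
        called = matrix.category[col]
        assert set(called.unique()) == {"BOUND", "UNBOUND"}

    def test_transcript_order_invariance(self):
        exps, _ = self.make_panel()
        shuffled = [
            e.with_values(e.values.sample(frac=1.0, random_state=5)) for e in exps
        ]
        a = assemble_binding_matrix(exps)
        b = assemble_binding_matrix(shuffled, gene_order=list(a.score.index))
        pd.testing.assert_frame_equal(a.score, b.score)
        pd.testing.assert_frame_equal(a.category, b.category)

    def test_scores_in_unit_interval_with_endpoints(self):
        exps, _ = self.make_panel()
        matrix = assemble_binding_matrix(exps)
        for col in matrix.score.columns:
            s = matrix.score[col].dropna()
            assert s.min() == 0.0 and s.max() == 1.0
            assert ((s >= 0) & (s <= 1)).all()

    def test_normalization_log_records_steps(self):
        exps, _ = self.make_panel()
        matrix = assemble_binding_matrix(exps)
        steps = [entry["step"] for entry in matrix.normalization_log]
        assert steps[:3] == ["hits_per_million", "unit_norm_per_transcript", "rescale_unit_interval"]

    def test_confound_removal_beats_raw_hpm(self):
        """The normalized score must track planted affinity better than raw
        depth-normalized counts do, for every experiment."""
        from scipy.stats import spearmanr

        # at the full study scale; for the generic (narrow-affinity) factors
        # the comparison is noise-limited on smaller universes
        config = SimulationConfig(n_transcripts=2000, seed=7)
        exps, truth = simulate_binding_experiments(config)
        matrix = assemble_binding_matrix(exps)
        for exp in exps:
            aff = np.array([truth.affinity[(t, exp.rbp_id)] for t in matrix.transcripts])
            final = matrix.score[exp.label].to_numpy()
            raw = hits_per_million(exp).values.reindex(matrix.transcripts).to_numpy()
            assert spearmanr(final, aff).statistic > spearmanr(raw, aff).statistic
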
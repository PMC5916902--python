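"""Running-sum enrichment score and its permutation null."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from mrnptools.enrichment import (
    GeneSet,
    permutation_p_value,
    running_sum_enrichment_score,
)


def naive_running_sum_es(ordered_ids, members, scores=None, exponent=0.0):
    """Independent step-by-step walk used as the oracle.

    The unweighted walk runs in exact rational arithmetic so signed ties of
    equal magnitude are resolved without float accumulation error.
    """
    from fractions import Fraction

    members = set(members)
    n, s = len(ordered_ids), len(members)
    if exponent == 0:
        up, down = Fraction(1, s), Fraction(1, n - s)
        walk, best = Fraction(0), Fraction(0)
        for g in ordered_ids:
            walk = walk + up if g in members else walk - down
            if abs(walk) > abs(best) or (abs(walk) == abs(best) and walk > best):
                best = walk
        return float(best)
    weights = {g: abs(sc) ** exponent for g, sc in zip(ordered_ids, scores)}
    total = sum(w for g, w in weights.items() if g in members)
    walk, best = 0.0, 0.0
    for g in ordered_ids:
        if g in members:
            walk += weights[g] / total
        else:
            walk -= 1.0 / (n - s)
        if abs(walk) > abs(best) or (abs(walk) == abs(best) and walk > best):
            best = walk
    return best


def ranking_from_scores(scores):
    return pd.Series(scores, index=[f"g{i}" for i in range(len(scores))])


class TestEnrichmentScore:
    def test_perfect_top_segregation_saturates(self):
        ranked = ranking_from_scores(range(10, 0, -1))
        top5 = GeneSet("top", [f"g{i}" for i in range(5)])
        assert running_sum_enrichment_score(ranked, top5) == pytest.approx(1.0)

    def test_alternating_four_gene_universe(self):
        # members at ranks 2 and 4: walk -1/2, 0, -1/2, 0 -> es = -0.5
        ranked = ranking_from_scores([4.0, 3.0, 2.0, 1.0])
        s = GeneSet("alt", ["g1", "g3"])
        assert running_sum_enrichment_score(ranked, s) == pytest.approx(-0.5)

    def test_set_equal_to_universe_errors(self):
        ranked = ranking_from_scores([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="proper subset"):
            running_sum_enrichment_score(ranked, GeneSet("all", ["g0", "g1", "g2"]))

    def test_member_absent_from_ranking_errors(self):
        ranked = ranking_from_scores([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="absent"):
            running_sum_enrichment_score(ranked, GeneSet("bad", ["nope"]))

    def test_empty_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSet("empty", [])

    @pytest.mark.parametrize("exponent", [0.0, 1.0])
    def test_matches_naive_walk_oracle(self, exponent):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            scores = rng.normal(0, 1, n)
            ranked = ranking_from_scores(scores)
            s = int(rng.integers(1, n - 1))
            members = rng.choice(ranked.index.to_numpy(), size=s, replace=False)
            ordered = ranked.sort_values(ascending=False, kind="stable")
            expected = naive_running_sum_es(
                list(ordered.index), members, scores=ordered.to_numpy(), exponent=exponent
            )
            got = running_sum_enrichment_score(ranked, GeneSet("x", members), exponent)
            assert got == pytest.approx(expected, abs=1e-12)


class TestPermutationP:
    def test_p_floor_and_seed_recorded(self):
        ranked = ranking_from_scores(range(20, 0, -1))
        top = GeneSet("top", [f"g{i}" for i in range(4)])
        res = permutation_p_value(ranked, top, n_perm=99, seed=5)
        assert res.p_value >= 1.0 / 100
        assert res.seed == 5 and res.n_perm == 99
        assert res.es == pytest.approx(1.0)

    def test_nperm_zero_errors(self):
        ranked = ranking_from_scores(range(5, 0, -1))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_p_value(ranked, GeneSet("s", ["g0"]), n_perm=0)

    def test_deterministic_given_seed(self):
        ranked = ranking_from_scores(np.random.default_rng(2).normal(size=30))
        s = GeneSet("s", ["g1", "g5", "g9"])
        a = permutation_p_value(ranked, s, n_perm=500, seed=7)
        b = permutation_p_value(ranked, s, n_perm=500, seed=7)
        assert a.p_value == b.p_value and a.es == b.es

    def test_sampled_p_matches_exhaustive_enumeration(self):
        """On universe 8 / set size 3 the sampled tail frequency must sit
        inside the 99% binomial band around the exhaustive probability."""
        rng = np.random.default_rng(13)
        scores = rng.normal(0, 1, 8)
        ranked = ranking_from_scores(scores)
        ordered = ranked.sort_values(ascending=False, kind="stable")
        members = ["g0", "g3", "g6"]
        obs = naive_running_sum_es(list(ordered.index), members)
        tail = 0
        n_subsets = 0
        for combo in itertools.combinations(ranked.index, 3):
            es = naive_running_sum_es(list(ordered.index), combo)
            tail += es >= obs
            n_subsets += 1
        assert n_subsets == 56
        q = tail / n_subsets
        n_perm = 9999
        res = permutation_p_value(ranked, GeneSet("s", members), n_perm=n_perm, seed=3)
        hits = round(res.p_value * (n_perm + 1) - 1)
        lo, hi = binom.ppf([0.005, 0.995], n_perm, q)
        assert lo <= hits <= hi

    def test_weighted_mode_runs_and_agrees_with_oracle_null(self):
        rng = np.random.default_rng(4)
        ranked = ranking_from_scores(rng.normal(0, 1, 30))
        s = GeneSet("s", ["g2", "g8", "g15"])
        res = permutation_p_value(ranked, s, n_perm=200, seed=1, weighting_exponent=1.0)
        assert 0 < res.p_value <= 1
        assert res.weighting_exponent == 1.0
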
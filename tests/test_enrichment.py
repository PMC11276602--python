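"""Unit and property tests for the KS running-sum scoring and NES."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_expression
from gsorigin import enrichment
from gsorigin.dataio import DataError, GeneSetCollection
from gsorigin.enrichment import (
    RankedProfile,
    enrichment_score,
    featurize,
    normalize_score,
    rank_genes,
)


def brute_force_es(ranking, members):
    """Independent oracle: walk the full running sum step by step in exact
    rational arithmetic (ties between the peak and the trough are resolved
    in favor of the peak)."""
    from fractions import Fraction

    member_set = set(members)
    n = len(ranking)
    m = sum(1 for g in ranking if g in member_set)
    assert 1 <= m < n
    best = Fraction(0)
    running = Fraction(0)
    for g in ranking:
        running += Fraction(1, m) if g in member_set else -Fraction(1, n - m)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return float(best)


class TestRankGenes:
    def test_descending_order(self):
        m = make_expression(np.array([[3.0], [1.0], [2.0]]), ["a", "b", "c"], ["s1"])
        assert rank_genes(m, "s1").ranking == ("a", "c", "b")

    def test_lexicographic_tie_break(self):
        m = make_expression(np.array([[2.0], [2.0]]), ["b", "a"], ["s1"])
        assert rank_genes(m, "s1").ranking == ("a", "b")

    def test_monotone_transform_invariance(self):
        vals = np.abs(np.random.default_rng(0).normal(size=(20, 1))) + 0.1
        m = make_expression(vals, [f"g{i}" for i in range(20)], ["s1"])
        m_log = make_expression(np.log2(vals), [f"g{i}" for i in range(20)], ["s1"])
        assert rank_genes(m, "s1").ranking == rank_genes(m_log, "s1").ranking

    def test_unknown_sample(self):
        m = make_expression(np.array([[1.0]]), ["g1"], ["s1"])
        with pytest.raises(DataError, match="unknown sample"):
            rank_genes(m, "nope")


class TestEnrichmentScore:
    universe10 = RankedProfile(tuple(f"g{i:02d}" for i in range(10)))

    def test_maximal_top_concentration(self):
        assert enrichment_score(self.universe10, {"g00", "g01", "g02"}) == pytest.approx(1.0)

    def test_maximal_bottom_concentration(self):
        assert enrichment_score(self.universe10, {"g07", "g08", "g09"}) == pytest.approx(-1.0)

    def test_hand_enumerated_example(self):
        # members at ranks 1, 4, 9: peak 8/21 after rank 4, trough -4/21
        es = enrichment_score(self.universe10, {"g00", "g03", "g08"})
        assert es == pytest.approx(8 / 21)

    def test_equals_brute_force_on_all_small_configurations(self):
        for n in range(2, 13):
            ranking = tuple(f"g{i:02d}" for i in range(n))
            profile = RankedProfile(ranking)
            for m in range(1, min(4, n - 1) + 1):
                for members in itertools.combinations(ranking, m):
                    fast = enrichment_score(profile, members)
                    assert fast == pytest.approx(brute_force_es(ranking, members), abs=1e-12)

    def test_genes_outside_universe_ignored(self):
        es_with = enrichment_score(self.universe10, {"g00", "g03", "g08", "NOT_THERE"})
        assert es_with == pytest.approx(8 / 21)

    @pytest.mark.parametrize("members", [set(), {f"g{i:02d}" for i in range(10)}])
    def test_degenerate_sets_rejected(self, members):
        with pytest.raises(DataError):
            enrichment_score(self.universe10, members)

    def test_bounds_and_invariance_on_fuzzed_profiles(self):
        """ES stays in [-1, 1] and is invariant under strictly increasing
        per-sample transforms, over 1000 random profiles."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(5, 60))
            genes = [f"g{i:03d}" for i in range(n)]
            vals = rng.normal(size=(n, 1))
            m_count = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=m_count, replace=False))
            m1 = make_expression(vals, genes, ["s"])
            m2 = make_expression(np.exp(vals) * 3 + 7, genes, ["s"])
            p1, p2 = rank_genes(m1, "s"), rank_genes(m2, "s")
            es = enrichment_score(p1, members)
            assert -1.0 <= es <= 1.0
            assert enrichment_score(p2, members) == es

    def test_matches_external_prerank_implementation(self):
        """Cross-check against gseapy's unweighted prerank ES on random
        tie-free profiles."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(3)
        genes = [f"g{i:02d}" for i in range(50)]
        for draw in range(3):
            rnk = pd.Series(rng.normal(size=50), index=genes).sort_values(ascending=False)
            members = list(rng.choice(genes, 8, replace=False))
            res = gseapy.prerank(rnk=rnk, gene_sets={"S": members}, weight=0,
                                 permutation_num=2, min_size=2, max_size=50, seed=1,
                                 outdir=None, no_plot=True)
            external = float(res.res2d.loc[res.res2d.Term == "S", "ES"].iloc[0])
            ours = enrichment_score(RankedProfile(tuple(rnk.index)), members)
            assert ours == pytest.approx(external, abs=1e-9)


class TestNormalizeScore:
    profile20 = RankedProfile(tuple(f"g{i:02d}" for i in range(20)))

    def test_zero_es_maps_to_zero(self):
        assert normalize_score(0.0, 5, self.profile20, n_null=50, seed=1) == 0.0

    def test_unit_es_gives_nes_at_least_one(self):
        nes = normalize_score(1.0, 5, self.profile20, n_null=50, seed=1)
        assert nes >= 1.0

    def test_sign_preserved(self):
        assert normalize_score(-0.4, 5, self.profile20, n_null=50, seed=1) < 0

    def test_deterministic_given_seed(self):
        a = normalize_score(0.5, 5, self.profile20, n_null=100, seed=7)
        b = normalize_score(0.5, 5, self.profile20, n_null=100, seed=7)
        assert a == b

    def test_monte_carlo_null_oracle(self):
        """NES equals ES / empirical mean |ES| of random same-size sets,
        checked against an independent large-sample Monte Carlo estimate."""
        rng = np.random.default_rng(99)
        genes = list(self.profile20.ranking)
        draws = []
        for _ in range(10000):
            members = rng.choice(genes, size=5, replace=False)
            draws.append(abs(enrichment_score(self.profile20, set(members))))
        mc_mean = float(np.mean(draws))
        se = float(np.std(draws, ddof=1) / math.sqrt(len(draws)))
        es = enrichment_score(self.profile20, {"g00", "g02", "g04", "g06", "g08"})
        nes = normalize_score(es, 5, self.profile20, n_null=10000, seed=5)
        # both the package null and the oracle are 10k-draw estimates: allow
        # 3 combined standard errors
        tol = 3 * math.sqrt(2) * se * abs(es) / mc_mean**2
        assert nes == pytest.approx(es / mc_mean, abs=tol)

    def test_null_signed_es_centered(self):
        """Random gene sets have mean signed ES near zero."""
        rng = np.random.default_rng(7)
        profile = RankedProfile(tuple(f"g{i:03d}" for i in range(100)))
        draws = [
            enrichment_score(profile, set(rng.choice(profile.ranking, 10, replace=False)))
            for _ in range(2000)
        ]
        se = np.std(draws, ddof=1) / math.sqrt(len(draws))
        assert abs(np.mean(draws)) < 3 * se


class TestFeaturize:
    def gene_sets(self):
        return GeneSetCollection(sets={
            "S1": ["g00", "g01", "g02", "g03", "g04"],
            "S2": ["g05", "g06", "g07", "g08", "g09", "g10"],
            "TOO_SMALL": ["g00", "g11"],
        })

    def matrix(self, n=20, s=2, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(n)]
        return make_expression(rng.normal(size=(n, s)), genes, [f"smp{j}" for j in range(s)])

    def test_shape_and_dropping(self):
        em = featurize(self.matrix(), self.gene_sets(), min_set_size=5)
        assert em.scores.shape == (2, 2)
        assert em.params["dropped_sets"] == ["TOO_SMALL"]

    def test_no_surviving_sets_is_error(self):
        with pytest.raises(DataError, match="no gene set"):
            featurize(self.matrix(), self.gene_sets(), min_set_size=50)

    def test_column_independence_under_sample_permutation(self):
        m = self.matrix(s=4)
        em = featurize(m, self.gene_sets())
        perm = ["smp2", "smp0", "smp3", "smp1"]
        em_perm = featurize(m.subset_samples(perm), self.gene_sets())
        assert (em.scores[perm].to_numpy() == em_perm.scores.to_numpy()).all()

    def test_exact_monotone_transform_invariance(self):
        m = self.matrix(s=3, seed=5)
        transformed = make_expression(np.exp(m.values.to_numpy() / 2.0), m.genes, m.samples)
        a = featurize(m, self.gene_sets())
        b = featurize(transformed, self.gene_sets())
        assert (a.scores.to_numpy() == b.scores.to_numpy()).all()

    def test_matches_per_sample_scalar_path(self):
        """The vectorized matrix path agrees with rank_genes +
        enrichment_score + normalize_score applied one sample at a time."""
        m = self.matrix(s=3, seed=8)
        gs = self.gene_sets()
        em = featurize(m, gs, min_set_size=5, n_null=50, seed=3)
        for sample in m.samples:
            profile = rank_genes(m, sample)
            for name in em.gene_sets:
                present = [g for g in gs.sets[name] if g in set(m.genes)]
                es = enrichment_score(profile, present)
                nes = normalize_score(es, len(present), profile, n_null=50, seed=3)
                assert em.scores.loc[name, sample] == pytest.approx(nes, abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_scores_always_finite(self, seed):
        m = self.matrix(n=15, s=2, seed=seed)
        em = featurize(m, self.gene_sets(), n_null=20)
        assert np.isfinite(em.scores.to_numpy()).all()
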
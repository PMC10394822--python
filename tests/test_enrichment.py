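"""Ranking statistic, running-sum enrichment score, permutation GSEA, ORA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from cimpkit import (
    ExpressionMatrix, GeneSetCollection, RankedList, ValidationError,
    enrichment_score, gsea, overrepresentation_test, signal_to_noise_ranking,
)


def brute_force_running_sum(stats, in_set, weight_p=1.0):
    """Independent step-by-step evaluation of the weighted running sum."""
    N, k = len(stats), sum(in_set)
    nr = sum(abs(s) ** weight_p for s, m in zip(stats, in_set) if m)
    hit = miss = 0.0
    dev = []
    for s, m in zip(stats, in_set):
        if m:
            hit += (abs(s) ** weight_p / nr) if nr > 0 else 1.0 / k
        else:
            miss += 1.0 / (N - k)
        dev.append(hit - miss)
    peak = max(abs(d) for d in dev)
    best = next(i for i, d in enumerate(dev) if abs(d) >= peak - 1e-12)
    return dev, dev[best]


def _expr_two_groups(rng, n_genes=60, na=10, nb=10, shift_genes=(), shift=0.0):
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    log2 = rng.normal(5.0, 1.0, size=(n_genes, na + nb))
    for g in shift_genes:
        log2[genes.index(g), :na] += shift
    em = ExpressionMatrix(pd.DataFrame(log2, index=genes, columns=samples),
                          scale="log2")
    return em, samples[:na], samples[na:]


class TestSignalToNoise:
    def test_floor_rule_hand_example(self):
        # group a constant 2, group b constant 1: floors 0.2*|mu| apply
        df = pd.DataFrame([[2.0] * 3 + [1.0] * 3], index=["g1"],
                          columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        em = ExpressionMatrix(df, scale="log2")
        ranked = signal_to_noise_ranking(em, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert ranked.statistics[0] == pytest.approx((2 - 1) / (0.4 + 0.2))

    def test_identical_groups_give_zero(self):
        df = pd.DataFrame([[4.0, 5.0, 6.0, 4.0, 5.0, 6.0]], index=["g1"],
                          columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        em = ExpressionMatrix(df, scale="log2")
        ranked = signal_to_noise_ranking(em, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert ranked.statistics[0] == 0.0

    def test_label_swap_negates_and_reverses(self):
        rng = np.random.default_rng(0)
        em, a, b = _expr_two_groups(rng)
        fwd = signal_to_noise_ranking(em, a, b)
        rev = signal_to_noise_ranking(em, b, a)
        fwd_map = dict(zip(fwd.gene_ids, fwd.statistics))
        rev_map = dict(zip(rev.gene_ids, rev.statistics))
        for g in fwd.gene_ids:
            assert rev_map[g] == pytest.approx(-fwd_map[g])

    def test_overlapping_groups_rejected(self):
        rng = np.random.default_rng(0)
        em, a, b = _expr_two_groups(rng)
        with pytest.raises(ValidationError, match="overlap"):
            signal_to_noise_ranking(em, a, [a[0]] + b[1:])

    def test_ties_broken_by_gene_id(self):
        df = pd.DataFrame(np.zeros((3, 4)), index=["gb", "ga", "gc"],
                          columns=["a1", "a2", "b1", "b2"])
        em = ExpressionMatrix(df, scale="log2")
        ranked = signal_to_noise_ranking(em, ["a1", "a2"], ["b1", "b2"])
        assert list(ranked.gene_ids) == ["ga", "gb", "gc"]


class TestEnrichmentScore:
    def test_single_gene_at_top_gives_plus_one(self):
        ranked = RankedList(np.array(["g1", "g2", "g3", "g4"], dtype=object),
                            np.array([3.0, 2.0, 1.0, 0.5]))
        assert enrichment_score(ranked, ["g1"]).es == pytest.approx(1.0)

    def test_single_gene_at_bottom_gives_minus_one(self):
        ranked = RankedList(np.array(["g1", "g2", "g3", "g4"], dtype=object),
                            np.array([3.0, 2.0, 1.0, 0.5]))
        assert enrichment_score(ranked, ["g4"]).es == pytest.approx(-1.0)

    def test_running_sum_ends_at_zero(self):
        rng = np.random.default_rng(1)
        stats = np.sort(rng.normal(size=20))[::-1]
        ranked = RankedList(np.array([f"g{i}" for i in range(20)], dtype=object),
                            stats)
        es = enrichment_score(ranked, [f"g{i}" for i in (2, 7, 11)])
        assert es.running_sum[-1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_seeded_instance(self):
        rng = np.random.default_rng(4)
        stats = np.sort(rng.normal(size=10))[::-1]
        genes = np.array([f"g{i}" for i in range(10)], dtype=object)
        ranked = RankedList(genes, stats)
        members = ["g1", "g4", "g8"]
        in_set = [g in members for g in genes]
        dev, es_oracle = brute_force_running_sum(stats, in_set)
        res = enrichment_score(ranked, members)
        assert res.es == pytest.approx(es_oracle, abs=1e-12)
        assert np.allclose(res.running_sum, dev, atol=1e-12)

    @settings(max_examples=100)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle_random_instances(self, instance_seed):
        rng = np.random.default_rng(instance_seed)
        n = int(rng.integers(5, 51))
        k = int(rng.integers(1, n))
        stats = np.sort(rng.normal(size=n))[::-1]
        genes = np.array([f"g{i:02d}" for i in range(n)], dtype=object)
        members = list(rng.choice(genes, size=k, replace=False))
        in_set = [g in set(members) for g in genes]
        _, es_oracle = brute_force_running_sum(stats, in_set)
        res = enrichment_score(RankedList(genes, stats), members)
        assert res.es == pytest.approx(es_oracle, abs=1e-12)
        assert -1.0 <= res.es <= 1.0

    def test_disjoint_or_total_set_rejected(self):
        ranked = RankedList(np.array(["g1", "g2"], dtype=object),
                            np.array([1.0, 0.5]))
        with pytest.raises(ValidationError):
            enrichment_score(ranked, ["nope"])
        with pytest.raises(ValidationError):
            enrichment_score(ranked, ["g1", "g2"])


class TestGsea:
    def test_planted_set_enriched(self):
        rng = np.random.default_rng(0)
        planted = [f"g{i:03d}" for i in range(12)]
        em, a, b = _expr_two_groups(rng, n_genes=150, na=15, nb=15,
                                    shift_genes=planted, shift=1.0)
        sets = {"PLANTED": planted}
        for j in range(15):
            sets[f"NULL{j}"] = list(rng.choice(
                [f"g{i:03d}" for i in range(12, 150)], 12, replace=False))
        res = gsea(em, a, b, GeneSetCollection.from_dict(sets),
                   n_permutations=500, seed=11)
        by_name = {r.set_name: r for r in res}
        assert by_name["PLANTED"].nes > 0
        assert by_name["PLANTED"].fdr_q < 0.05
        # null sets keep honest q-values: the planted set's extreme NES must
        # not drag less extreme sets' q toward zero
        null_q = [r.fdr_q for r in res if r.set_name != "PLANTED"]
        assert np.median(null_q) > 0.2

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        em, a, b = _expr_two_groups(rng, n_genes=80)
        sets = GeneSetCollection.from_dict(
            {f"S{j}": [f"g{i:03d}" for i in range(j * 5, j * 5 + 8)] for j in range(5)})
        r1 = gsea(em, a, b, sets, n_permutations=200, seed=7)
        r2 = gsea(em, a, b, sets, n_permutations=200, seed=7)
        for x, y in zip(r1, r2):
            assert (x.set_name, x.es, x.nes, x.nominal_p, x.fdr_q) == \
                (y.set_name, y.es, y.nes, y.nominal_p, y.fdr_q)

    def test_label_antisymmetry_of_es(self):
        rng = np.random.default_rng(3)
        em, a, b = _expr_two_groups(rng, n_genes=60)
        sets = GeneSetCollection.from_dict(
            {"S": [f"g{i:03d}" for i in range(10)]})
        fwd = gsea(em, a, b, sets, n_permutations=100,
                   permutation_type="gene_set", seed=5)[0]
        rev = gsea(em, b, a, sets, n_permutations=100,
                   permutation_type="gene_set", seed=5)[0]
        assert rev.es == pytest.approx(-fwd.es, abs=1e-12)

    def test_small_groups_auto_switch_to_gene_set_permutation(self):
        rng = np.random.default_rng(4)
        em, a, b = _expr_two_groups(rng, n_genes=40, na=3, nb=3)
        sets = GeneSetCollection.from_dict({"S": [f"g{i:03d}" for i in range(8)]})
        res = gsea(em, a, b, sets, n_permutations=100, seed=1)  # must not fail
        assert len(res) == 1


class TestOverrepresentation:
    def test_matches_exact_hypergeometric_sum(self):
        universe = [f"u{i}" for i in range(12)]
        sets = GeneSetCollection.from_dict({"S": universe[:5]})
        query = universe[:4]
        res = overrepresentation_test(query, universe, sets)
        N, m, n, k = 12, 5, 4, 4
        exact = sum(hypergeom.pmf(x, N, m, n) for x in range(k, min(m, n) + 1))
        assert res.loc[0, "p_value"] == pytest.approx(exact, abs=1e-12)

    def test_disjoint_query_gives_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        sets = GeneSetCollection.from_dict({"S": universe[:3]})
        res = overrepresentation_test(universe[5:8], universe, sets)
        assert res.loc[0, "p_value"] == 1.0

    def test_empty_query_rejected(self):
        with pytest.raises(ValidationError):
            overrepresentation_test([], ["a"], GeneSetCollection.from_dict({"S": ["a"]}))

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="outside universe"):
            overrepresentation_test(["z"], ["a", "b"],
                                    GeneSetCollection.from_dict({"S": ["a"]}))

    def test_bh_q_monotone_in_raw_p(self):
        rng = np.random.default_rng(6)
        universe = [f"u{i}" for i in range(100)]
        sets = {f"S{j}": list(rng.choice(universe, 10, replace=False))
                for j in range(20)}
        query = list(rng.choice(universe, 25, replace=False))
        res = overrepresentation_test(query, universe,
                                      GeneSetCollection.from_dict(sets))
        ordered = res.sort_values("p_value")
        assert (np.diff(ordered["bh_q"].to_numpy()) >= -1e-12).all()
        assert (ordered["bh_q"] >= ordered["p_value"] - 1e-12).all()
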
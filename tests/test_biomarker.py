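import itertools
import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from ranksig.biomarker import (
    biomarker_union,
    differential_stats,
    discover_biomarker,
    ora_enrichment,
    pathway_restricted_search,
)
from ranksig.classify import CVConfig, GAConfig, PermutationConfig
from ranksig.io import CohortLabels, ExpressionMatrix, GeneSetCollection
from ranksig.ranks import ESParams, Signature
from tests.conftest import strong_cohort


def exact_ranksum_pvalue(x, y):
    """Enumeration oracle: two-sided exact rank-sum p over all assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)
    observed = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2.0
    lo = hi = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        stat = ranks[list(combo)].sum()
        lo += stat <= observed
        hi += stat >= observed
        total += 1
    return min(1.0, 2 * min(lo, hi) / total)


def _sig(sample, up, down):
    return Signature(sample, list(up), list(down), len(up))


class TestBiomarkerUnion:
    def test_simple_union(self):
        sigs = [_sig("s1", ["a"], ["b"]), _sig("s2", ["b"], ["c"])]
        assert biomarker_union(sigs) == {"a", "b", "c"}

    def test_identical_signatures_idempotent(self):
        sigs = [_sig(f"s{i}", ["a", "b"], ["c", "d"]) for i in range(5)]
        assert biomarker_union(sigs) == {"a", "b", "c", "d"}

    def test_oracle_membership_fold(self, rng):
        probes = [f"p{i:02d}" for i in range(30)]
        sigs = []
        for i in range(20):
            chosen = rng.choice(30, size=6, replace=False)
            sigs.append(_sig(f"s{i}", [probes[j] for j in chosen[:3]], [probes[j] for j in chosen[3:]]))
        # independent oracle: membership flags accumulated probe by probe
        flags = {p: False for p in probes}
        for sig in sigs:
            for p in list(sig.up_set) + list(sig.down_set):
                flags[p] = True
        assert biomarker_union(sigs) == {p for p, f in flags.items() if f}

    def test_superset_of_each_signature(self, rng):
        sigs = [
            _sig(f"s{i}", [f"p{i}a", f"p{i}b"], [f"p{i}c", f"p{i}d"]) for i in range(4)
        ]
        union = biomarker_union(sigs)
        for sig in sigs:
            assert sig.probes <= union

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            biomarker_union([])


class TestDifferentialStats:
    def _matrix(self, rows, samples):
        return ExpressionMatrix([f"p{i}" for i in range(len(rows))], samples, np.array(rows))

    def test_identical_classes(self):
        m = self._matrix([[1.0, 2.0, 1.0, 2.0]], ["a1", "a2", "b1", "b2"])
        labels = CohortLabels({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, ["A", "B"])
        out = differential_stats(m, labels)
        assert out.loc[0, "log2fc"] == 0.0
        assert out.loc[0, "pvalue"] == pytest.approx(1.0)
        assert out.loc[0, "direction"] == "unchanged"

    def test_two_vs_two_exact(self):
        m = self._matrix([[1.0, 2.0, 3.0, 4.0]], ["a1", "a2", "b1", "b2"])
        labels = CohortLabels({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, ["A", "B"])
        out = differential_stats(m, labels)
        assert out.loc[0, "pvalue"] == pytest.approx(2 / 6)
        assert out.loc[0, "log2fc"] == pytest.approx(-2.0)
        assert out.loc[0, "direction"] == "up in B"

    def test_exact_matches_enumeration_6v6(self, rng):
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(loc=0.5, size=6)
            m = self._matrix([np.concatenate([x, y])], [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)])
            labels = CohortLabels(
                {f"a{i}": "A" for i in range(6)} | {f"b{i}": "B" for i in range(6)}, ["A", "B"]
            )
            out = differential_stats(m, labels)
            assert out.loc[0, "pvalue"] == pytest.approx(exact_ranksum_pvalue(x, y), abs=1e-12)

    def test_exact_pvalues_on_discrete_grid(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        m = self._matrix([np.concatenate([x, y])], [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)])
        labels = CohortLabels(
            {f"a{i}": "A" for i in range(6)} | {f"b{i}": "B" for i in range(6)}, ["A", "B"]
        )
        p = differential_stats(m, labels).loc[0, "pvalue"]
        total = math.comb(12, 6)
        assert (p * total / 2) == pytest.approx(round(p * total / 2), abs=1e-6)

    def test_asymptotic_close_to_exact_12v12(self, rng):
        # groups of 12 route to the normal approximation; scipy's exact
        # computation is the independent reference
        x = rng.normal(size=12)
        y = rng.normal(loc=0.8, size=12)
        samples = [f"a{i}" for i in range(12)] + [f"b{i}" for i in range(12)]
        m = self._matrix([np.concatenate([x, y])], samples)
        labels = CohortLabels(
            {f"a{i}": "A" for i in range(12)} | {f"b{i}": "B" for i in range(12)}, ["A", "B"]
        )
        ours = differential_stats(m, labels).loc[0, "pvalue"]
        reference = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(reference, abs=0.02)

    def test_small_class_rejected(self):
        # only one sample of class B present in the matrix columns
        m2 = self._matrix([[1.0, 2.0, 3.0]], ["a1", "a2", "b1"])
        with pytest.raises(ValueError):
            differential_stats(
                m2, CohortLabels({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, ["A", "B"])
            )


class TestORA:
    def test_saturated_list(self):
        universe = {f"G{i}" for i in range(20)}
        coll = GeneSetCollection({"S1": ("d", {f"G{i}" for i in range(5)})})
        out = ora_enrichment(universe, coll, universe).table
        assert out.loc[0, "pvalue"] == pytest.approx(1.0)

    def test_closed_form_tail(self):
        universe = {f"G{i}" for i in range(20)}
        inside = {f"G{i}" for i in range(5)}
        coll = GeneSetCollection({"S1": ("d", inside)})
        out = ora_enrichment(inside, coll, universe).table
        assert out.loc[0, "pvalue"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_holm_stepdown_hand_example(self):
        from ranksig.biomarker import holm_adjust

        # hand application of the step-down rule
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.5]), [0.03, 0.04, 0.5], atol=1e-15
        )
        np.testing.assert_allclose(
            holm_adjust([0.5, 0.01, 0.02]), [0.5, 0.03, 0.04], atol=1e-15
        )

    def test_holm_rule_applied_in_table(self):
        universe = {f"G{i}" for i in range(40)}
        coll = GeneSetCollection(
            {
                "A": ("d", {f"G{i}" for i in range(10)}),
                "B": ("d", {f"G{i}" for i in range(10, 20)}),
                "C": ("d", {f"G{i}" for i in range(20, 30)}),
            }
        )
        out = ora_enrichment({f"G{i}" for i in range(8)}, coll, universe).table
        raw = out.sort_values("pvalue")["pvalue"].to_numpy()
        adj = out.sort_values("pvalue")["adjusted_p"].to_numpy()
        m = len(raw)
        running = 0.0
        for i in range(m):
            running = max(running, (m - i) * raw[i])
            assert adj[i] == pytest.approx(min(running, 1.0))

    def test_adjusted_geq_raw_and_monotone(self, rng):
        universe = {f"G{i}" for i in range(100)}
        sets = {
            f"S{k}": ("d", set(rng.choice(sorted(universe), size=15, replace=False)))
            for k in range(8)
        }
        coll = GeneSetCollection(sets)
        query = set(rng.choice(sorted(universe), size=20, replace=False))
        out = ora_enrichment(query, coll, universe).table
        assert (out["adjusted_p"] >= out["pvalue"] - 1e-15).all()
        ordered = out.sort_values("pvalue")
        assert ordered["adjusted_p"].is_monotonic_increasing

    def test_overlap_bounds(self, rng):
        universe = {f"G{i}" for i in range(50)}
        coll = GeneSetCollection({"S": ("d", {f"G{i}" for i in range(10)})})
        query = {f"G{i}" for i in range(5, 25)}
        row = ora_enrichment(query, coll, universe).table.iloc[0]
        assert row["overlap"] <= min(row["set_size"], row["list_size"])

    def test_empty_universe_rejected(self):
        coll = GeneSetCollection({"S": ("d", {"G1"})})
        with pytest.raises(ValueError, match="universe"):
            ora_enrichment({"G1"}, coll, set())

    def test_query_outside_universe_rejected(self):
        coll = GeneSetCollection({"S": ("d", {"G1"})})
        with pytest.raises(ValueError, match="outside"):
            ora_enrichment({"G9"}, coll, {"G1", "G2"})


class TestPathwayRestrictedSearch:
    def _setup(self, seed=0):
        m, labels, pmap, coll, _, truth = strong_cohort(seed)
        ga = GAConfig(
            population_size=20, generations=6, pool_size=16, s_min=3, s_max=6,
            init_density=1.0, seed=seed,
        )
        return m, labels, pmap, coll, truth, ga, CVConfig(k=5, seed=seed)

    def test_all_genes_equals_unrestricted(self):
        m, labels, pmap, coll, truth, ga, cv = self._setup(1)
        all_genes = pmap.all_genes()
        restricted = pathway_restricted_search(m, labels, all_genes, pmap, ga, cv)
        # restriction to every mapped probe: same probe subset as running the
        # pipeline on the mapped submatrix directly
        mapped = [p for p in m.probe_ids if pmap.genes_for(p)]
        direct = discover_biomarker(m.restrict_probes(mapped), labels, ga, cv)
        assert restricted.probes == direct.probes
        assert restricted.accuracy == direct.accuracy

    def test_disjoint_gene_set_errors(self):
        m, labels, pmap, coll, truth, ga, cv = self._setup(2)
        with pytest.raises(ValueError, match="map"):
            pathway_restricted_search(m, labels, {"NOT_A_GENE"}, pmap, ga, cv)

    def test_signal_vs_signal_free_pathways(self):
        wins = 0
        for seed in range(5):
            m, labels, pmap, coll, truth, ga, cv = self._setup(seed)
            perm = PermutationConfig(n_permutations=100, seed=seed)
            hit = pathway_restricted_search(
                m, labels, coll.genes(truth.enriched_set), pmap, ga, cv, ESParams(), perm
            )
            other = [n for n in coll.names() if n != truth.enriched_set][0]
            null = pathway_restricted_search(
                m, labels, coll.genes(other), pmap, ga, cv, ESParams(), perm
            )
            wins += hit.accuracy == 1.0 and null.permutation_p > 0.05
        assert wins >= 3


class TestDiscoverBiomarker:
    def test_recovers_planted_probes(self):
        m, labels, pmap, coll, _, truth = strong_cohort(3)
        ga = GAConfig(
            population_size=30, generations=10, pool_size=12, s_min=5, s_max=6,
            init_density=1.0, seed=3,
        )
        res = discover_biomarker(
            m, labels, ga, CVConfig(k=5, seed=3), ESParams(),
            PermutationConfig(n_permutations=100, seed=3), pmap,
        )
        planted = set(truth.differential)
        found = set(res.probes)
        assert res.accuracy == 1.0
        assert res.permutation_p == 0.0099
        assert len(found & planted) / len(found) >= 0.8
        assert len(found & planted) / len(planted) >= 0.8
        assert "genes" in res.table.columns

    def test_directions_consistent_with_log2fc(self):
        m, labels, *_ = strong_cohort(4)
        ga = GAConfig(population_size=10, generations=3, pool_size=10, s_min=2, s_max=4, seed=4)
        res = discover_biomarker(m, labels, ga, CVConfig(k=5, seed=4))
        cls1, cls2 = labels.class_order
        for _, row in res.table.iterrows():
            if row["log2fc"] > 0:
                assert row["direction"] == f"up in {cls1}"
            elif row["log2fc"] < 0:
                assert row["direction"] == f"up in {cls2}"

    def test_biomarker_is_union_of_signatures(self):
        m, labels, *_ = strong_cohort(5)
        ga = GAConfig(population_size=10, generations=3, pool_size=10, s_min=2, s_max=4, seed=5)
        res = discover_biomarker(m, labels, ga, CVConfig(k=5, seed=5))
        assert set(res.probes) == biomarker_union(res.signatures)
        assert set(res.probes) <= set(res.selected_probes)
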
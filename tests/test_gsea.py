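"""Preranked GSEA: enrichment score oracle, permutation null, determinism."""

import numpy as np
import pytest

from phosphosig.differential import DifferentialResult
from phosphosig.errors import FormatError
from phosphosig.gsea import (
    RankedList,
    _null_es,
    enrichment_score,
    gsea_preranked,
    make_ranked_list,
)
from phosphosig.io_formats import GeneSetCollection


def brute_force_es(stats, hits, weight_exp=1.0):
    """Independent O(N) running-sum oracle (deliberately naive loop)."""
    stats = np.asarray(stats, dtype=float)
    n = stats.size
    n_hit = int(np.sum(hits))
    denom = sum(abs(stats[i]) ** weight_exp for i in range(n) if hits[i])
    running, cur = [], 0.0
    for i in range(n):
        if hits[i]:
            if denom > 0:
                cur += abs(stats[i]) ** weight_exp / denom
            else:
                cur += 1.0 / n_hit
        else:
            cur -= 1.0 / (n - n_hit)
        running.append(cur)
    hi, lo = max(running), min(running)
    return hi if hi >= -lo else lo


def _result(fid, t):
    return DifferentialResult(fid, log2fc=t / 5, s2=0.1, t_mod=t, df_total=10.0,
                              p_value=0.5, q_value=0.5)


class TestMakeRankedList:
    def test_phosphosites_collapse_to_best_site_per_gene(self):
        results = [_result("GENEA_S10", 3.1), _result("GENEA_T22", -0.2),
                   _result("GENEB_S5", 1.0)]
        ranked = make_ranked_list(results, level="phosphosite")
        assert ranked.ids == ["GENEA", "GENEB"]
        assert ranked.stats[0] == pytest.approx(3.1)

    def test_ties_broken_by_id(self):
        results = [_result("B", 1.0), _result("A", 1.0), _result("C", 2.0)]
        ranked = make_ranked_list(results)
        assert ranked.ids == ["C", "A", "B"]

    def test_zero_variance_features_excluded(self):
        r = _result("A", 1.0)
        bad = DifferentialResult("B", 0.0, 0.0, float("nan"), 10.0, 1.0, 1.0,
                                 zero_variance=True)
        ranked = make_ranked_list([r, bad])
        assert ranked.ids == ["A"]


class TestEnrichmentScore:
    def test_top_ranked_singleton_running_sum(self):
        ranked = RankedList(["A", "B", "C", "D"], np.array([4.0, 3.0, 2.0, 1.0]))
        es, running = enrichment_score(ranked, {"A"})
        np.testing.assert_allclose(running, [1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12)
        assert es == 1.0

    def test_bottom_ranked_singleton_is_negative(self):
        ranked = RankedList(["A", "B", "C", "D"], np.array([4.0, 3.0, 2.0, 1.0]))
        es, running = enrichment_score(ranked, {"D"})
        assert es == pytest.approx(brute_force_es(ranked.stats, [0, 0, 0, 1]))
        assert es < 0

    def test_weight_zero_reduces_to_classic_ks(self):
        rng = np.random.default_rng(1)
        stats = np.sort(rng.normal(size=12))[::-1]
        ranked = RankedList([f"g{i}" for i in range(12)], stats)
        members = {"g1", "g4", "g5"}
        hits = [gid in members for gid in ranked.ids]
        es, _ = enrichment_score(ranked, members, weight_exp=0.0)
        assert es == pytest.approx(brute_force_es(stats, hits, 0.0), abs=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            stats = np.sort(rng.normal(size=n))[::-1]
            ids = [f"g{i}" for i in range(n)]
            size = int(rng.integers(1, n))
            members = set(rng.choice(ids, size=size, replace=False))
            ranked = RankedList(ids, stats)
            es, _ = enrichment_score(ranked, members)
            hits = [g in members for g in ids]
            assert es == pytest.approx(brute_force_es(stats, hits), abs=1e-12)

    def test_sign_reversal_negates_score(self):
        rng = np.random.default_rng(3)
        stats = np.sort(rng.normal(size=20))[::-1]
        ids = [f"g{i}" for i in range(20)]
        members = {"g2", "g3", "g11"}
        es_fwd, _ = enrichment_score(RankedList(ids, stats), members)
        es_rev, _ = enrichment_score(
            RankedList(ids[::-1], -stats[::-1]), members
        )
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    @pytest.mark.parametrize("members", [set(), {"A", "B", "C"}])
    def test_degenerate_overlap_rejected(self, members):
        ranked = RankedList(["A", "B", "C"], np.array([3.0, 2.0, 1.0]))
        with pytest.raises(FormatError):
            enrichment_score(ranked, members)


class TestNullEs:
    def test_vectorized_null_matches_direct_scoring(self):
        """The hit-position formula must agree with the full running sum."""
        rng = np.random.default_rng(11)
        stats = np.sort(rng.normal(size=60))[::-1]
        ids = [f"g{i}" for i in range(60)]
        ranked = RankedList(ids, stats)
        nulls = _null_es(stats, size=8, n_perm=50, rng=np.random.default_rng(0),
                         weight_exp=1.0)
        # regenerate the same draws to compare against the direct path
        rng2 = np.random.default_rng(0)
        pos = np.sort(rng2.integers(0, 60, size=(50, 8)), axis=1)
        bad = (np.diff(pos, axis=1) == 0).any(axis=1)
        while bad.any():
            pos[bad] = np.sort(rng2.integers(0, 60, size=(int(bad.sum()), 8)), axis=1)
            bad = (np.diff(pos, axis=1) == 0).any(axis=1)
        for row, es_null in zip(pos, nulls):
            members = {ids[i] for i in row}
            es_direct, _ = enrichment_score(ranked, members)
            assert es_null == pytest.approx(es_direct, abs=1e-12)


class TestGseaPreranked:
    def _ranked(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        stats = np.sort(rng.normal(size=n))[::-1]
        return RankedList([f"g{i}" for i in range(n)], stats)

    def test_top_loaded_set_is_significant_and_positive(self):
        ranked = self._ranked()
        sets = GeneSetCollection()
        sets.add("TOP", "", [f"g{i}" for i in range(12)])
        sets.add("RANDOM", "", [f"g{i}" for i in range(5, 300, 25)])
        res = {e.set_name: e for e in gsea_preranked(ranked, sets, n_perm=500, seed=1)}
        assert res["TOP"].es > 0 and res["TOP"].nes > 0
        # one-sided within sign: the floor is 1/(1 + #same-sign nulls)
        assert res["TOP"].p_value < 0.01
        assert res["TOP"].p_value < res["RANDOM"].p_value
        assert res["TOP"].leading_edge[0] == "g0"

    def test_p_value_floor_respected(self):
        ranked = self._ranked()
        sets = GeneSetCollection()
        sets.add("TOP", "", [f"g{i}" for i in range(10)])
        res = gsea_preranked(ranked, sets, n_perm=200, seed=2)
        assert all(e.p_value >= 1 / (200 + 1) for e in res)

    def test_same_seed_reproduces_results(self):
        ranked = self._ranked()
        sets = GeneSetCollection()
        for s in range(6):
            sets.add(f"S{s}", "", [f"g{i}" for i in range(s, 300, 17)])
        a = gsea_preranked(ranked, sets, n_perm=300, seed=5)
        b = gsea_preranked(ranked, sets, n_perm=300, seed=5)
        assert [(e.set_name, e.es, e.nes, e.p_value, e.fdr) for e in a] == [
            (e.set_name, e.es, e.nes, e.p_value, e.fdr) for e in b
        ]

    def test_size_bounds_exclude_sets(self):
        ranked = self._ranked()
        sets = GeneSetCollection()
        sets.add("TINY", "", ["g1", "g2"])
        sets.add("OK", "", [f"g{i}" for i in range(20)])
        res = gsea_preranked(ranked, sets, n_perm=100, min_size=5, seed=0)
        assert [e.set_name for e in res] == ["OK"]

    def test_no_eligible_sets_rejected(self):
        ranked = self._ranked()
        sets = GeneSetCollection()
        sets.add("TINY", "", ["g1"])
        with pytest.raises(FormatError):
            gsea_preranked(ranked, sets, n_perm=100, seed=0)

    def test_nested_top_sets_monotone_es(self):
        """For sets of top-ranked genes with all-positive stats, the smaller
        nested set concentrates harder and scores at least as high."""
        stats = np.linspace(5, 0.1, 100)
        ranked = RankedList([f"g{i}" for i in range(100)], stats)
        es_small, _ = enrichment_score(ranked, {f"g{i}" for i in range(5)})
        es_large, _ = enrichment_score(ranked, {f"g{i}" for i in range(20)})
        assert es_small >= es_large
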
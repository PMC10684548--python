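import math
from math import comb

import numpy as np
import pytest

from phagemosaic.annotation import (
    STATUS_ASSIGNED,
    DomainArchitecture,
    FunctionalAnnotation,
)
from phagemosaic.enrichment import (
    ContingencyTable,
    class_family_enrichment,
    domain_enrichment,
    fisher_one_tailed,
    mosaic_network,
    odds_ratio,
    recent_network,
)
from phagemosaic.families import FamilyPartition
from phagemosaic.mosaicism import MosaicCall, Tier


def fisher_greater_oracle(a, b, c, d):
    """Exact one-sided p by explicit hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(r1 + r2, c1)
    return sum(comb(r1, k) * comb(r2, c1 - k) for k in range(a, hi + 1)) / denom


class TestOddsRatio:
    @pytest.mark.parametrize("table,expected", [
        ((5, 5, 1, 9), 9.0),
        ((3, 7, 3, 7), 1.0),
        ((4, 6, 0, 10), math.inf),
        ((0, 10, 5, 5), 0.0),
    ])
    def test_direct_arithmetic(self, table, expected):
        assert odds_ratio(ContingencyTable(*table)) == expected

    def test_reciprocal_property_for_positive_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 50, size=4))
            fwd = odds_ratio(ContingencyTable(a, b, c, d))
            rev = odds_ratio(ContingencyTable(c, d, a, b))
            assert fwd * rev == pytest.approx(1.0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)


class TestFisherOneTailed:
    def test_single_most_extreme_table_closed_form(self):
        p = fisher_one_tailed(ContingencyTable(10, 0, 0, 10))
        assert p == pytest.approx(1 / comb(20, 10), rel=1e-9)

    def test_least_extreme_table_is_one(self):
        assert fisher_one_tailed(ContingencyTable(0, 10, 10, 0)) == pytest.approx(1.0)

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if a + b + c + d == 0:
                continue
            p = fisher_one_tailed(ContingencyTable(a, b, c, d))
            assert abs(p - fisher_greater_oracle(a, b, c, d)) <= 1e-10


def arch(rid, *t_groups):
    return DomainArchitecture(rhmm_id=rid, t_groups=frozenset(t_groups))


def ann(rid, cls):
    return FunctionalAnnotation(rhmm_id=rid, status=STATUS_ASSIGNED,
                                simplified_class=cls)


class TestDomainEnrichment:
    def test_planted_over_representation(self):
        # topology tau in 8/10 mosaic and 1/20 non-mosaic unique architectures
        archs, mosaic_keys = [], set()
        for i in range(10):
            ts = ("5.1.1", f"10{i}.1.1") if i < 8 else (f"20{i}.1.1", f"30{i}.1.1")
            a = arch(f"m{i}", *ts)
            archs.append(a)
            mosaic_keys.add(a.architecture_key)
        for i in range(20):
            ts = ("5.1.1", f"40{i}.1.1") if i < 1 else (f"50{i}.1.1",)
            archs.append(arch(f"n{i}", *ts))
        results = {r.feature: r for r in domain_enrichment(archs, mosaic_keys)}
        tau = results["5.1.1"]
        assert (tau.table.a, tau.table.b, tau.table.c, tau.table.d) == (8, 2, 1, 19)
        assert tau.odds_ratio == pytest.approx((8 / 2) / (1 / 19))

    def test_topology_in_all_architectures_gives_infinite_branch(self):
        archs = [arch("m0", "5.1.1", "6.1.1"), arch("n0", "5.1.1", "7.1.1")]
        keys = {archs[0].architecture_key, archs[1].architecture_key}
        results = {r.feature: r for r in domain_enrichment(archs, keys)}
        assert math.isnan(results["5.1.1"].odds_ratio) or math.isinf(
            results["5.1.1"].odds_ratio
        )

    def test_units_are_unique_architectures_and_tables_recount(self):
        rng = np.random.default_rng(6)
        pool = [f"{x}.1.1" for x in range(2, 12)]
        archs = []
        for i in range(60):
            ts = rng.choice(pool, size=int(rng.integers(1, 4)), replace=False)
            archs.append(arch(f"r{i}", *ts))
        uniq = {a.architecture_key: a.t_groups for a in archs if a.t_groups}
        keys = sorted(uniq)
        mosaic_keys = set(keys[: len(keys) // 3])
        results = {r.feature: r for r in domain_enrichment(archs, mosaic_keys)}
        # independent tally straight from the deduplicated dict
        for t in pool:
            with_t = {k for k, ts in uniq.items() if t in ts}
            if not with_t:
                assert t not in results
                continue
            tab = results[t].table
            assert tab.a == len(with_t & mosaic_keys)
            assert tab.c == len(with_t - mosaic_keys)
            assert tab.a + tab.b == len(mosaic_keys)
            assert tab.c + tab.d == len(uniq) - len(mosaic_keys)

    def test_bonferroni_uses_number_of_domains_tested(self):
        archs = [arch("a", "5.1.1", "6.1.1"), arch("b", "7.1.1")]
        results = domain_enrichment(archs, {archs[0].architecture_key})
        assert all(r.n_tests == 3 for r in results)
        for r in results:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * 3))


class TestClassFamilyEnrichment:
    def test_hand_counted_six_family_fixture(self):
        # families: f0..f5; classes A/B/C; mosaic: f0, f1, f2
        members = {
            0: [("r0", "A"), ("r1", "B")],
            1: [("r2", "A")],
            2: [("r3", "C")],
            3: [("r4", "A")],
            4: [("r5", "B"), ("r6", "C")],
            5: [("r7", "B")],
        }
        part = FamilyPartition.from_groups(
            [{rid for rid, _ in v} for v in members.values()]
        )
        anns = {rid: ann(rid, cls) for v in members.values() for rid, cls in v}
        flag_members = {"r0", "r2", "r3"}
        flags = {
            fid: ({"ecod"} if any(m in flag_members for m in fam) else set())
            for fid, fam in part.families.items()
        }
        results = {
            r.feature: r
            for r in class_family_enrichment(flags, part, anns, {"A", "B", "C"})
        }
        # class A: mosaic families with A = 2 (f0,f1); mosaic without = 1 (f2);
        # non-mosaic with A = 1 (f3); non-mosaic without = 2 (f4,f5)
        t = results["A"].table
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)
        t = results["C"].table
        assert (t.a, t.b, t.c, t.d) == (1, 2, 1, 2)
        assert all(r.n_tests == 3 for r in results.values())

    def test_class_absent_from_mosaic_families_gets_zero_odds(self):
        part = FamilyPartition.from_groups([{"r0"}, {"r1"}])
        anns = {"r0": ann("r0", "A"), "r1": ann("r1", "B")}
        flags = {part.member_to_family["r0"]: {"ecod"},
                 part.member_to_family["r1"]: set()}
        results = {r.feature: r
                   for r in class_family_enrichment(flags, part, anns, {"A", "B"})}
        assert results["B"].odds_ratio == 0.0
        assert results["B"].p_raw == pytest.approx(1.0)


def call(a, b, tier=Tier.BASELINE, basis="ecod", p_id=None):
    return MosaicCall(id_a=min(a, b), id_b=max(a, b), basis=basis, tier=tier,
                      fragment_p_id=p_id)


class TestMosaicNetwork:
    def _setup(self, n_arch_pairs, tier=Tier.BASELINE):
        archs, anns, calls = {}, {}, []
        for i in range(n_arch_pairs):
            a, b = f"a{i}", f"b{i}"
            archs[a] = arch(a, f"{i}.1.1", "90.1.1")
            archs[b] = arch(b, f"{i + 50}.1.1", "90.1.1")
            anns[a] = ann(a, "endolysin")
            anns[b] = ann(b, "tail spike")
            calls.append(call(a, b, tier=tier))
        return calls, archs, anns

    @pytest.mark.parametrize("n,linked", [(4, True), (3, False)])
    def test_minimum_architecture_pairs_boundary(self, n, linked):
        calls, archs, anns = self._setup(n)
        g = mosaic_network(calls, archs, anns)
        assert g.has_edge("endolysin", "tail spike") is linked

    def test_contemporary_flag_from_single_pair(self):
        calls, archs, anns = self._setup(4)
        calls[0] = call("a0", "b0", tier=Tier.CONTEMPORARY, p_id=0.55)
        g = mosaic_network(calls, archs, anns)
        assert g.edges["endolysin", "tail spike"]["contemporary"] is True

    def test_without_contemporary_support_flag_false(self):
        calls, archs, anns = self._setup(4)
        g = mosaic_network(calls, archs, anns)
        assert g.edges["endolysin", "tail spike"]["contemporary"] is False

    def test_call_order_invariance(self):
        calls, archs, anns = self._setup(5)
        g1 = mosaic_network(calls, archs, anns)
        g2 = mosaic_network(list(reversed(calls)), archs, anns)
        assert set(g1.edges) == set(g2.edges)

    def test_generic_classes_excluded(self):
        calls, archs, anns = self._setup(4)
        for a in anns:
            if anns[a].simplified_class == "tail spike":
                anns[a] = ann(a, "tail")
        g = mosaic_network(calls, archs, anns)
        assert g.number_of_edges() == 0

    def test_node_size_counts_distinct_architectures(self):
        calls, archs, anns = self._setup(4)
        g = mosaic_network(calls, archs, anns)
        assert g.nodes["endolysin"]["n_architectures"] == 4


class TestRecentNetwork:
    @pytest.mark.parametrize("p_id,linked", [(0.70, True), (0.69, False),
                                             (0.90, True)])
    def test_tier_boundary(self, p_id, linked):
        from phagemosaic.mosaicism import recency_tier

        c = call("a", "b", basis="sequence", tier=recency_tier(p_id), p_id=p_id)
        anns = {"a": ann("a", "endolysin")}
        g = recent_network([c], anns)
        assert g.has_edge("endolysin", "unknown") is linked

    def test_unannotated_rhmms_map_to_unknown_node(self):
        c = call("a", "b", basis="sequence", tier=Tier.RECENT_VERY_HIGH, p_id=0.95)
        g = recent_network([c], {})
        assert g.has_edge("unknown", "unknown") or ("unknown" in g)


class TestTypeIError:
    def test_null_permutation_rejection_rate(self):
        """With mosaic flags assigned at random, one-sided Fisher should
        reject at ~5%: the rate over 1000 features must sit inside the
        binomial 99% band around 0.05."""
        rng = np.random.default_rng(2024)
        n_mosaic, n_non, n_feat = 10000, 15000, 1000
        hits = 0
        for _ in range(n_feat):
            nf = int(rng.integers(4000, 12001))
            a = int(rng.hypergeometric(n_mosaic, n_non, nf))
            t = ContingencyTable(a, n_mosaic - a, nf - a, n_non - (nf - a))
            if fisher_one_tailed(t) < 0.05:
                hits += 1
        rate = hits / n_feat
        half = 2.576 * math.sqrt(0.05 * 0.95 / n_feat)
        assert 0.05 - half <= rate <= 0.05 + half
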
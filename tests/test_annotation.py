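import numpy as np
import pytest

from phagemosaic.annotation import (
    STATUS_AMBIGUOUS,
    STATUS_ASSIGNED,
    STATUS_UNKNOWN,
    architecture,
    assign_domains,
    assign_function,
    class_domain_presence,
    eligible_classes,
)
from phagemosaic.io import FunctionMap, PhrogEntry, parse_ecod_id
from phagemosaic.pairs import PairComparison
from conftest import make_hit


def pc(rhmm, target, p=0.99, cov=0.9):
    a, b = sorted((rhmm, target))
    return PairComparison(
        id_a=a, id_b=b, p=p, p_id=0.4, qcov=cov, scov=cov,
        cov_min=cov, cov_max=cov, aligned_len_a=100, aligned_len_b=100,
    )


@pytest.fixture
def fmap():
    entries = {}
    for name, cls, cat, n in [
        ("endolysin v1", "endolysin", "lysis", 600),
        ("tail fibre v1", "tail fibre", "tail", 700),
        ("tail spike v1", "tail spike", "tail", 700),
        ("tail generic", "tail", "tail", 900),
        ("major capsid-ish", "structural protein", "other", 900),
    ]:
        entries[name] = PhrogEntry(name, cls, cat, n)
    return FunctionMap(entries=entries)


class TestAssignFunction:
    def test_specific_class_with_generic_companion_assigned(self, fmap):
        ann = assign_function(
            "r1", [pc("r1", "tail fibre v1"), pc("r1", "major capsid-ish")],
            [], fmap,
        )
        assert ann.status == STATUS_ASSIGNED
        assert ann.simplified_class == "tail fibre"

    def test_two_specific_classes_discarded(self, fmap):
        ann = assign_function(
            "r1", [pc("r1", "endolysin v1"), pc("r1", "tail spike v1")], [], fmap
        )
        assert ann.status == STATUS_AMBIGUOUS
        assert ann.simplified_class is None

    def test_antidefence_hit_overrides_class(self, fmap):
        ann = assign_function(
            "r1", [pc("r1", "endolysin v1")], [pc("r1", "anti-CRISPR")], fmap
        )
        assert ann.status == STATUS_ASSIGNED
        assert ann.antidefence_class == "anti-CRISPR"
        assert ann.simplified_class == "anti-CRISPR"

    def test_antidefence_without_phrog_evidence_does_not_fire(self, fmap):
        ann = assign_function("r1", [], [pc("r1", "anti-CRISPR")], fmap)
        assert ann.status == STATUS_UNKNOWN

    def test_generic_only_assigned_generic(self, fmap):
        ann = assign_function("r1", [pc("r1", "tail generic")], [], fmap)
        assert ann.status == STATUS_ASSIGNED
        assert ann.simplified_class == "tail"

    def test_no_qualifying_hits_unknown(self, fmap):
        ann = assign_function("r1", [pc("r1", "endolysin v1", p=0.90)], [], fmap)
        assert ann.status == STATUS_UNKNOWN

    @pytest.mark.parametrize("p,cov,assigned", [
        (0.95, 0.8, True),   # inclusive thresholds
        (0.9499, 0.8, False),
        (0.95, 0.79, False),
    ])
    def test_qualification_boundaries(self, fmap, p, cov, assigned):
        ann = assign_function("r1", [pc("r1", "endolysin v1", p=p, cov=cov)], [], fmap)
        assert (ann.status == STATUS_ASSIGNED) is assigned

    def test_order_independent(self, fmap):
        hits = [pc("r1", "tail fibre v1"), pc("r1", "major capsid-ish"),
                pc("r1", "tail generic")]
        first = assign_function("r1", hits, [], fmap)
        second = assign_function("r1", list(reversed(hits)), [], fmap)
        assert first.simplified_class == second.simplified_class
        assert first.status == second.status

    def test_unmapped_phrog_class_rejected(self, fmap):
        with pytest.raises(KeyError):
            assign_function("r1", [pc("r1", "mystery phrog")], [], fmap)


class TestEligibleClasses:
    def test_bounds(self):
        entries = {
            "a1": PhrogEntry("a1", "A", "c", 600),
            "b1": PhrogEntry("b1", "B", "c", 600),
            "c1": PhrogEntry("c1", "C", "c", 499),
        }
        fmap = FunctionMap(entries=entries)
        from phagemosaic.annotation import FunctionalAnnotation

        anns = []
        for cls, n in [("A", 25), ("B", 19), ("C", 100)]:
            anns += [
                FunctionalAnnotation(rhmm_id=f"{cls}{i}", status=STATUS_ASSIGNED,
                                     simplified_class=cls)
                for i in range(n)
            ]
        got = eligible_classes(anns, fmap)
        # A passes both bounds; B has too few rHMMs; C too few PHROG seqs
        assert got == {"A"}

    def test_inclusive_at_exact_bounds(self):
        fmap = FunctionMap(entries={"a1": PhrogEntry("a1", "A", "c", 500)})
        from phagemosaic.annotation import FunctionalAnnotation

        anns = [
            FunctionalAnnotation(rhmm_id=f"A{i}", status=STATUS_ASSIGNED,
                                 simplified_class="A")
            for i in range(20)
        ]
        assert eligible_classes(anns, fmap) == {"A"}


class TestAssignDomains:
    def _emap(self):
        return {"d1": parse_ecod_id("219.1.1"), "d2": parse_ecod_id("4.1.1")}

    def _hit(self, p, scov, subject="d1"):
        slen = 100
        se = int(round(scov * slen))
        return make_hit(q="r1", s=subject, p=p, qs=1, qe=se, ss=1, se=se,
                        qlen=400, slen=slen, tag="ecod")

    @pytest.mark.parametrize("p,scov,kept", [
        (0.96, 0.75, True),
        (0.96, 0.69, False),
        (0.949, 0.90, False),
        (0.95, 0.70, True),   # inclusive at both
    ])
    def test_threshold_boundaries(self, p, scov, kept):
        got = assign_domains([self._hit(p, scov)], self._emap())
        assert bool(got) is kept

    def test_sorted_by_query_start(self):
        hits = [
            make_hit(q="r1", s="d2", p=0.99, qs=200, qe=299, ss=1, se=100,
                     qlen=400, slen=100, tag="ecod"),
            make_hit(q="r1", s="d1", p=0.99, qs=10, qe=109, ss=1, se=100,
                     qlen=400, slen=100, tag="ecod"),
        ]
        got = assign_domains(hits, self._emap())
        assert [d.ecod.t_id for d in got] == ["219.1.1", "4.1.1"]

    def test_unknown_subject_rejected(self):
        with pytest.raises(KeyError):
            assign_domains([self._hit(0.99, 0.9, subject="dX")], self._emap())


class TestArchitecture:
    def _domain(self, t, qs=1, qe=100):
        hits = assign_domains(
            [make_hit(q="r1", s="d", p=0.99, qs=qs, qe=qe, ss=1, se=100,
                      qlen=500, slen=100, tag="ecod")],
            {"d": parse_ecod_id(t)},
        )
        return hits[0]

    def test_key_is_sorted_t_groups(self):
        arch = architecture("r1", [self._domain("219.1.1"), self._domain("4.1.1", 200, 300)])
        assert arch.architecture_key == "219.1.1|4.1.1"
        assert arch.x_groups == {219, 4}

    def test_duplicate_t_groups_collapse(self):
        arch = architecture("r1", [self._domain("219.1.1"), self._domain("219.1.1", 200, 300)])
        assert arch.t_groups == {"219.1.1"}

    def test_identity_invariant_under_permutation_and_duplication(self):
        d1, d2 = self._domain("219.1.1"), self._domain("4.1.1", 200, 300)
        a = architecture("r1", [d1, d2])
        b = architecture("r1", [d2, d1, d1])
        assert a.t_groups == b.t_groups
        assert a.architecture_key == b.architecture_key

    def test_empty_architecture_is_falsy(self):
        assert not architecture("r1", [])


class TestClassDomainPresence:
    def _setup(self, counts, min_rhmms=5, min_classes=None, level="T"):
        """counts: dict (class, t_id) -> n rHMMs carrying the domain."""
        from phagemosaic.annotation import FunctionalAnnotation

        archs, anns = [], {}
        i = 0
        per_rhmm: dict[str, tuple[str, set]] = {}
        for (cls, t), n in counts.items():
            for _ in range(n):
                rid = f"r{i:04d}"
                i += 1
                cls_prev, ts = per_rhmm.get(rid, (cls, set()))
                ts.add(t)
                per_rhmm[rid] = (cls, ts)
        for rid, (cls, ts) in per_rhmm.items():
            hits = []
            for j, t in enumerate(sorted(ts)):
                hits.extend(
                    assign_domains(
                        [make_hit(q=rid, s="d", p=0.99, qs=1 + 120 * j,
                                  qe=100 + 120 * j, ss=1, se=100, qlen=1000,
                                  slen=100, tag="ecod")],
                        {"d": parse_ecod_id(t)},
                    )
                )
            archs.append(architecture(rid, hits))
            anns[rid] = FunctionalAnnotation(rhmm_id=rid, status=STATUS_ASSIGNED,
                                             simplified_class=cls)
        return class_domain_presence(archs, anns, level=level,
                                     min_rhmms=min_rhmms, min_classes=min_classes)

    def test_count_at_threshold_reported(self):
        mat = self._setup({("endolysin", "219.1.1"): 5})
        assert mat.loc["endolysin", "219.1.1"] == 5

    def test_count_below_threshold_zeroed(self):
        mat = self._setup({("endolysin", "219.1.1"): 4})
        assert mat.empty or "219.1.1" not in mat.columns

    def test_min_classes_filter(self):
        counts = {
            ("endolysin", "219.1.1"): 6,
            ("tail fibre", "219.1.1"): 6,
            ("DNA polymerase", "219.1.1"): 6,
            ("endolysin", "4.1.1"): 6,
        }
        mat = self._setup(counts, min_classes=3)
        assert list(mat.columns) == ["219.1.1"]

    def test_matrix_matches_direct_recount(self):
        rng = np.random.default_rng(17)
        classes = ["c1", "c2", "c3"]
        t_groups = ["10.1.1", "11.1.1", "12.1.1", "13.1.1"]
        counts = {}
        for cls in classes:
            for t in t_groups:
                counts[(cls, t)] = int(rng.integers(0, 10))
        mat = self._setup({k: v for k, v in counts.items() if v}, min_rhmms=1)
        for (cls, t), n in counts.items():
            got = mat.loc[cls, t] if (cls in mat.index and t in mat.columns) else 0
            assert got == n
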
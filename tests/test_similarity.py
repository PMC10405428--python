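"""IC, Resnik and BMA against brute-force oracles."""

import itertools
import math

import pytest

import cardphen as cp
from cardphen.classify import classify_original_ontology, classify_revised
from cardphen.ontology import OntologyError, SubsumptionGraph
from cardphen.similarity import AnnotationCorpus, bma, compute_ic, resnik


def _diamond():
    """root <- {a, b} <- leaf hierarchy for hand computation."""
    return SubsumptionGraph(
        ["X:root", "X:a", "X:b", "X:leaf1", "X:leaf2"],
        [
            ("X:a", "X:root"),
            ("X:b", "X:root"),
            ("X:leaf1", "X:a"),
            ("X:leaf2", "X:b"),
        ],
    )


def _corpus(profiles, kind="gene"):
    c = AnnotationCorpus()
    for eid, prof in profiles.items():
        for cid in prof:
            c.add(eid, cid, kind)
    return c


class TestIC:
    def test_root_has_zero_ic_when_all_profiles_reach_it(self):
        corpus = _corpus({f"G:{i}": ["X:leaf1"] for i in range(4)})
        ic = compute_ic(corpus, _diamond())
        assert ic["X:root"] == 0.0

    def test_quarter_probability_is_two_bits(self):
        profiles = {"G:1": ["X:leaf1"], "G:2": ["X:leaf2"], "G:3": ["X:leaf2"], "G:4": ["X:leaf2"]}
        ic = compute_ic(_corpus(profiles), _diamond())
        assert ic["X:leaf1"] == pytest.approx(2.0)  # -log2(1/4)
        assert ic["X:a"] == pytest.approx(2.0)

    def test_unknown_annotation_class_is_an_error(self):
        with pytest.raises(OntologyError, match="X:nope"):
            compute_ic(_corpus({"G:1": ["X:nope"]}), _diamond())

    def test_unused_classes_have_no_entry(self):
        ic = compute_ic(_corpus({"G:1": ["X:leaf1"]}), _diamond())
        assert "X:leaf2" not in ic and "X:b" not in ic

    def test_matches_brute_force_counting_on_demo_corpus(self, demo):
        g = classify_original_ontology(demo)
        pids = sorted(demo.eq_definitions)
        profiles = {
            f"E:{i}": [pids[i % 4], pids[(i + 1) % 4]] for i in range(8)
        }
        corpus = _corpus(profiles)
        ic = compute_ic(corpus, g)
        # independent counting: for each class, how many entities have it or a
        # descendant (w.r.t. the closed graph) in their direct profile
        closed = g.closure()
        for cid in g.nodes:
            n = sum(
                1 for prof in profiles.values()
                if any(closed.entails(p, cid) for p in prof)
            )
            if n == 0:
                assert cid not in ic
            else:
                assert ic[cid] == pytest.approx(-math.log2(n / 8))

    def test_monotone_along_every_edge(self, demo, config):
        g = classify_revised(cp.rewrite_ontology(demo, config))
        pids = sorted(cp.detect_cardinality_phenotypes(demo, config), key=lambda d: d.phenotype_id)
        corpus = _corpus({f"E:{i}": [d.phenotype_id] for i, d in enumerate(pids)})
        ic = compute_ic(corpus, g)
        for sub, sup in g.edges:
            if sub in ic and sup in ic:
                assert ic[sub] >= ic[sup] - 1e-12


class TestResnik:
    @pytest.fixture()
    def setup(self):
        profiles = {"G:1": ["X:leaf1"], "G:2": ["X:leaf2"], "G:3": ["X:leaf1", "X:leaf2"], "G:4": ["X:a"]}
        h = _diamond()
        return h, compute_ic(_corpus(profiles), h)

    def test_self_similarity_is_own_ic(self, setup):
        h, ic = setup
        assert resnik("X:leaf1", "X:leaf1", ic, h) == ic["X:leaf1"]

    def test_siblings_meeting_only_at_root_score_zero(self, setup):
        h, ic = setup
        assert resnik("X:leaf1", "X:leaf2", ic, h) == 0.0

    def test_all_pairs_match_brute_force(self, setup):
        h, ic = setup
        for a, b in itertools.product(sorted(h.nodes), repeat=2):
            expected = max(
                (ic.ic[c] for c in h.ancestors(a) & h.ancestors(b) if c in ic.ic),
                default=0.0,
            )
            assert resnik(a, b, ic, h) == pytest.approx(expected)

    def test_bounded_by_min_ic(self, setup):
        h, ic = setup
        for a, b in itertools.product(sorted(h.nodes), repeat=2):
            if a in ic.ic and b in ic.ic:
                assert resnik(a, b, ic, h) <= min(ic.ic[a], ic.ic[b]) + 1e-12

    def test_unknown_class_is_an_error(self, setup):
        h, ic = setup
        with pytest.raises(OntologyError):
            resnik("X:ghost", "X:leaf1", ic, h)


class TestBMA:
    @pytest.fixture()
    def setup(self):
        profiles = {
            "G:1": ["X:leaf1", "X:a"],
            "G:2": ["X:leaf2"],
            "G:3": ["X:leaf1", "X:leaf2", "X:b"],
            "G:4": ["X:root"],
        }
        h = _diamond()
        return h, compute_ic(_corpus(profiles), h)

    def test_singleton_profiles_reduce_to_resnik(self, setup):
        h, ic = setup
        assert bma({"X:leaf1"}, {"X:leaf2"}, ic, h) == pytest.approx(
            resnik("X:leaf1", "X:leaf2", ic, h)
        )

    def test_symmetric(self, setup):
        h, ic = setup
        p, q = {"X:leaf1", "X:a", "X:b"}, {"X:leaf2", "X:root"}
        assert bma(p, q, ic, h) == pytest.approx(bma(q, p, ic, h))

    def test_termwise_expansion(self, setup):
        """Match a literal term-by-term expansion of the two-sided average."""
        h, ic = setup
        p = ["X:leaf1", "X:a", "X:b"]  # g_n = 3
        q = ["X:leaf2", "X:root"]      # d_n = 2
        r = lambda x, y: resnik(x, y, ic, h)
        left = sum(max(r(x, y) for y in q) for x in p) / (2 * 3)
        right = sum(max(r(y, x) for x in p) for y in q) / (2 * 2)
        assert bma(p, q, ic, h) == pytest.approx(left + right)

    def test_permutation_invariant(self, setup):
        h, ic = setup
        assert bma(["X:a", "X:leaf1"], ["X:root", "X:leaf2"], ic, h) == \
            bma(["X:leaf1", "X:a"], ["X:leaf2", "X:root"], ic, h)

    def test_empty_profile_is_an_error(self, setup):
        h, ic = setup
        with pytest.raises(OntologyError):
            bma([], ["X:leaf1"], ic, h)


class TestHierarchyChangeEffect:
    def test_absence_ancestors_differ_and_change_ic(self, demo, config):
        """Revising the classification changes IC only through ancestor sets."""
        g_orig = classify_original_ontology(demo)
        g_rev = classify_revised(cp.rewrite_ontology(demo, config))
        abs_t, abs_nk = "MP:0008070", "MP:0008041"
        assert abs_t in g_orig.ancestors(abs_nk)
        assert abs_t not in g_rev.ancestors(abs_nk)
        assert abs_nk in g_rev.ancestors(abs_t)
        profiles = {"G:1": [abs_nk], "G:2": [abs_t], "G:3": ["MP:0005018"], "G:4": ["MP:0008040"]}
        corpus = _corpus(profiles)
        ic_o = compute_ic(corpus, g_orig)
        ic_r = compute_ic(corpus, g_rev)
        # under the original order abs_T counts the abs_NK annotator too;
        # under the revised order the direction flips, so abs_T becomes rarer
        assert ic_r[abs_t] > ic_o[abs_t]
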
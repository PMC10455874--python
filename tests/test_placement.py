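"""Newick parsing, monophyly, query-clade collapsing, placement, verdicts."""

import random

import pytest

from p25screen.placement import (
    GroupAssignment,
    NewickParseError,
    Placement,
    PlacementResult,
    Verdict,
    classify_placement,
    collapse_query_clades,
    is_monophyletic,
    node_support,
    parse_newick,
    synthesize_verdict,
)
from p25screen.screen import HitClassification
from p25screen.synth import gen_placement_tree


# --- independent mini-parser oracle (no dendropy) --------------------------

def mini_parse(text):
    """Nested-tuple newick parser; drops lengths and labels."""
    text = text.strip().rstrip(";")
    pos = 0

    def node():
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children = [node()]
            while text[pos] == ",":
                pos += 1
                children.append(node())
            assert text[pos] == ")"
            pos += 1
            # skip label/length
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            return tuple(children)
        start = pos
        while pos < len(text) and text[pos] not in ",():":
            pos += 1
        name = text[start:pos]
        while pos < len(text) and text[pos] not in ",()":
            pos += 1
        return name

    return node()


def clades_of(node):
    """All clade leaf-sets in a nested-tuple tree."""
    if isinstance(node, tuple):
        sets, leaves = [], set()
        for c in node:
            s, l = clades_of(c)
            sets.extend(s)
            leaves |= l
        sets.append(frozenset(leaves))
        return sets, leaves
    return [frozenset([node])], {node}


def random_tuple_tree(labels, rng):
    items = list(labels)
    while len(items) > 1:
        i, j = sorted(rng.sample(range(len(items)), 2))
        b = items.pop(j)
        a = items.pop(i)
        items.append((a, b))
    return items[0]


def emit(node, support="1.0"):
    if isinstance(node, tuple):
        return "(" + ",".join(emit(c, support) for c in node) + ")" + support
    return str(node)


class TestParseNewick:
    def test_two_leaves(self):
        t = parse_newick("(A,B);")
        assert {l.taxon.label for l in t.leaf_node_iter()} == {"A", "B"}
        assert len(t.seed_node.child_nodes()) == 2

    def test_internal_support_and_lengths(self):
        t = parse_newick("((A:1,B:1)0.99:1,C:2);")
        internals = [n for n in t.preorder_node_iter() if not n.is_leaf()]
        supports = {node_support(n) for n in internals}
        assert 0.99 in supports

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A,B")

    def test_trailing_garbage_rejected(self):
        with pytest.raises(NewickParseError):
            parse_newick("(A,B);(C,D);")

    def test_bootstrap_style_support_scaled(self):
        t = parse_newick("((A,B)95,C);")
        internals = [n for n in t.preorder_node_iter() if not n.is_leaf()]
        assert 0.95 in {node_support(n) for n in internals}


class TestIsMonophyletic:
    @pytest.mark.parametrize(
        "newick,leafset,expected",
        [
            ("((a1,a2),b);", {"a1", "a2"}, True),
            ("((a1,b),a2);", {"a1", "a2"}, False),
            ("((a1,a2),b);", {"b"}, True),
        ],
    )
    def test_examples(self, newick, leafset, expected):
        assert is_monophyletic(parse_newick(newick), leafset) is expected

    def test_unknown_leaf_rejected(self):
        with pytest.raises(ValueError):
            is_monophyletic(parse_newick("(a,b);"), {"z"})

    def test_agrees_with_bipartition_enumeration_oracle(self):
        """Exhaustive subsets of random trees up to 8 leaves vs mini-parser."""
        rng = random.Random(0)
        from itertools import combinations

        for n in range(4, 9):
            for _ in range(5):
                labels = [f"t{i}" for i in range(n)]
                tup = random_tuple_tree(labels, rng)
                newick = emit(tup) + ";"
                tree = parse_newick(newick)
                clades, _ = clades_of(mini_parse(newick))
                clade_set = set(clades)
                for k in range(1, n + 1):
                    for subset in combinations(labels, k):
                        expected = frozenset(subset) in clade_set
                        assert is_monophyletic(tree, set(subset)) is expected


class TestCollapseQueryClades:
    def assignment(self, queries, groups):
        return GroupAssignment(leaf_to_group=groups, query_set=set(queries))

    def test_adjacent_queries_become_one_pseudo_leaf(self):
        t = parse_newick("((q1,q2),f1);")
        ct, mapping = collapse_query_clades(t, self.assignment(["q1", "q2"], {"f1": "G"}))
        leaves = {l.taxon.label for l in ct.leaf_node_iter()}
        assert "f1" in leaves and len(leaves) == 2
        pseudo = (leaves - {"f1"}).pop()
        assert mapping[pseudo] == ("q1", "q2")

    def test_no_adjacent_queries_unchanged(self):
        t = parse_newick("((q1,f1),(q2,f2));")
        ct, mapping = collapse_query_clades(
            t, self.assignment(["q1", "q2"], {"f1": "G", "f2": "G"})
        )
        assert {l.taxon.label for l in ct.leaf_node_iter()} == {"q1", "f1", "q2", "f2"}
        assert mapping == {"q1": ("q1",), "q2": ("q2",)}

    def test_maximal_clade_of_three(self):
        t = parse_newick("((q1,(q2,q3)),f1);")
        ct, mapping = collapse_query_clades(
            t, self.assignment(["q1", "q2", "q3"], {"f1": "G"})
        )
        assert len(list(ct.leaf_node_iter())) == 2
        assert ("q1", "q2", "q3") in mapping.values()

    def test_all_query_tree_rejected(self):
        t = parse_newick("(q1,q2);")
        with pytest.raises(ValueError, match="reference context"):
            collapse_query_clades(t, self.assignment(["q1", "q2"], {}))


def assign(queries, **leaf_groups):
    return GroupAssignment(leaf_to_group=leaf_groups, query_set=set(queries))


class TestClassifyPlacement:
    def test_nested_inside_foreign_clade(self):
        t = parse_newick("((q,f1)0.99,(f2,f3)0.98);")
        a = assign(["q"], f1="G", f2="G", f3="G")
        res = classify_placement(t, a, "q")
        assert res.placement is Placement.nested and res.focal_group == "G"
        assert res.support_at_decision == 0.99

    def test_sister_to_foreign_clade(self):
        t = parse_newick("((q,f1)0.99,(h1,h2)0.97);")
        a = assign(["q"], f1="G", h1="H", h2="H")
        res = classify_placement(t, a, "q")
        assert res.placement is Placement.sister and res.focal_group == "G"

    def test_low_support_gives_unresolved(self):
        t = parse_newick("((q,(f1,f2))0.30,(h1,h2));")
        a = assign(["q"], f1="G", f2="G", h1="H", h2="H")
        res = classify_placement(t, a, "q")
        assert res.placement is Placement.unresolved
        assert res.support_at_decision == pytest.approx(0.30)
        assert res.focal_group is None

    def test_collapsed_query_clade_sister_to_fungi(self):
        t = parse_newick("(((q1,q2)1.0,(fun1,fun2)1.0)0.99,((myz1,myz2)1.0,out)1.0);")
        a = assign(
            ["q1", "q2"], fun1="fungi", fun2="fungi", myz1="myzozoa", myz2="myzozoa",
            out="outgroup",
        )
        res = classify_placement(t, a, "q1")
        assert res.placement is Placement.sister and res.focal_group == "fungi"
        assert set(res.members) == {"q1", "q2"}

    def test_multi_group_sibling_is_outside(self):
        t = parse_newick("((q,((f1,f2)1.0,(h1,h2)1.0)1.0)1.0,x);")
        a = assign(["q"], f1="G", f2="G", h1="H", h2="H", x="X")
        res = classify_placement(t, a, "q")
        assert res.placement is Placement.outside and res.focal_group is None

    def test_missing_group_assignment_rejected(self):
        t = parse_newick("((q,f1),f2);")
        with pytest.raises(ValueError, match="group"):
            classify_placement(t, assign(["q"], f1="G"), "q")

    def test_unknown_query_rejected(self):
        t = parse_newick("((q,f1),f2);")
        with pytest.raises(ValueError, match="'z'"):
            classify_placement(t, assign(["q"], f1="G", f2="G"), "z")

    def test_rotation_invariance(self):
        """Child-order rotations of the newick never change the call."""
        rng = random.Random(1)
        for cls in (Placement.nested, Placement.sister, Placement.outside):
            for seed in range(5):
                newick, a, _ = gen_placement_tree(cls, 8, seed)
                base = classify_placement(parse_newick(newick), a, "QUERY_1")

                def rotate(node):
                    if isinstance(node, tuple):
                        kids = [rotate(c) for c in node]
                        rng.shuffle(kids)
                        return tuple(kids)
                    return node

                for _ in range(20):
                    rotated = emit(rotate(mini_parse(newick))) + ";"
                    res = classify_placement(parse_newick(rotated), a, "QUERY_1")
                    assert res.placement is base.placement
                    assert res.focal_group == base.focal_group


class TestSynthesizeVerdict:
    @pytest.mark.parametrize(
        "placement,hitclass,expected",
        [
            (Placement.nested, HitClassification.likely_contamination, Verdict.contamination),
            (Placement.nested, HitClassification.evident_contamination, Verdict.contamination),
            (Placement.nested, HitClassification.candidate_foreign, Verdict.contamination_or_hgt),
            (Placement.sister, HitClassification.likely_contamination, Verdict.contamination),
            (Placement.sister, HitClassification.candidate_foreign, Verdict.unresolved),
            (Placement.outside, HitClassification.candidate_foreign, Verdict.putative_ortholog),
            (Placement.outside, HitClassification.evident_contamination, Verdict.contamination_or_hgt),
            (Placement.unresolved, HitClassification.candidate_foreign, Verdict.unresolved),
        ],
    )
    def test_verdict_table(self, placement, hitclass, expected):
        assert synthesize_verdict(placement, hitclass) is expected

    def test_table_is_total(self):
        for p in Placement:
            for h in HitClassification:
                assert synthesize_verdict(p, h) in Verdict

    def test_accepts_placement_result(self):
        res = PlacementResult(Placement.nested, "G", 0.99)
        assert (
            synthesize_verdict(res, HitClassification.likely_contamination)
            is Verdict.contamination
        )
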
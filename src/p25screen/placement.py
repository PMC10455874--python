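"""Phylogenetic placement of query leaves and the contamination/HGT verdict.

If a plant sequence in a tree of TPPP-like proteins were a genuine ortholog,
it should sit *outside* the animal/fungal/protist clades; a sequence *nested
within* a foreign clade points to contamination or horizontal transfer, and a
sequence *sister* to a foreign clade is the ambiguous middle ground.  This
module formalizes that reading of a support-annotated tree:

* ``nested``  — the query's sibling subtree is a single foreign group G and
  the next split up also contains G (the query interrupts G);
* ``sister``  — the sibling subtree is pure G but the surrounding context is
  not G (the query attaches to G's stem edge);
* ``outside`` — the sibling subtree already mixes two or more groups;
* ``unresolved`` — the decision node's support is below ``min_support``.

Only the query's local neighborhood (parent and grandparent nodes) is
consulted; co-clustering query leaves are collapsed to a single pseudo-leaf
first so that identical contaminants in several assemblies are judged as one
unit.  The final verdict combines placement with the alignment-level hit
classification: high-identity hits nested in or sister to a foreign clade are
contamination (a transfer old enough to be fixed would have diverged),
low-identity nested hits leave contamination vs HGT open, and low-identity
hits placed outside the foreign groups are putative orthologs.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field

import dendropy

from .screen import HitClassification

__all__ = [
    "GroupAssignment",
    "Placement",
    "PlacementResult",
    "Verdict",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "node_support",
    "is_monophyletic",
    "collapse_query_clades",
    "classify_placement",
    "synthesize_verdict",
    "reroot_at_outgroup",
]

QUERY_GROUP = "query"


class NewickParseError(ValueError):
    pass


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; numeric internal node labels are supports.

    Underscores in labels are preserved verbatim.
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"newick parse failed: {exc}") from exc
    # reject trailing garbage dendropy silently tolerates after the first tree
    semi = text.find(";")
    if semi != -1 and text[semi + 1 :].strip():
        raise NewickParseError(
            f"trailing content after tree at offset {semi + 1}"
        )
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def node_support(node: dendropy.Node) -> float | None:
    """Support at an internal node, read from its label.

    Values above 1 are interpreted as percentages (bootstrap-style) and
    divided by 100; Bayesian posteriors pass through unchanged.
    """
    if node.label is None:
        return None
    try:
        val = float(node.label)
    except ValueError:
        return None
    return val / 100.0 if val > 1.0 else val


def _leaf_labels(node: dendropy.Node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def _all_leaves(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


@dataclass
class GroupAssignment:
    """Leaf -> taxonomic group map plus the set of query (self) leaves."""

    leaf_to_group: dict[str, str]
    query_set: set[str] = field(default_factory=set)

    def group_of(self, label: str) -> str:
        if label in self.query_set:
            return QUERY_GROUP
        try:
            return self.leaf_to_group[label]
        except KeyError:
            raise ValueError(f"leaf {label!r} has no group assignment") from None

    def validate_against(self, tree: dendropy.Tree) -> None:
        leaves = _all_leaves(tree)
        missing = {l for l in leaves if l not in self.query_set and l not in self.leaf_to_group}
        if missing:
            raise ValueError(f"leaves without group assignment: {sorted(missing)}")


def is_monophyletic(tree: dendropy.Tree, leafset: set[str]) -> bool:
    """True iff some node's leaf descendants are exactly ``leafset``."""
    leaves = _all_leaves(tree)
    unknown = set(leafset) - leaves
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if not leafset:
        raise ValueError("empty leaf set")
    target = set(leafset)
    for node in tree.preorder_node_iter():
        if _leaf_labels(node) == target:
            return True
    return False


def collapse_query_clades(
    tree: dendropy.Tree, assignment: GroupAssignment
) -> tuple[dendropy.Tree, dict[str, tuple[str, ...]]]:
    """Replace each maximal query-only clade by a single pseudo-leaf.

    Returns the collapsed tree (a structural copy; the input is untouched)
    and a map pseudo-leaf label -> original member labels.  Single query
    leaves keep their own label.  Raises if every leaf is a query (no
    reference context to place against).
    """
    tree = tree.clone(depth=1)
    queries = assignment.query_set
    if _all_leaves(tree) <= queries:
        raise ValueError("all leaves are queries: no reference context")
    mapping: dict[str, tuple[str, ...]] = {}
    counter = 0
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        labels = _leaf_labels(node)
        if labels <= queries:
            members = tuple(sorted(labels))
            if node.is_leaf():
                mapping[node.taxon.label] = members
                continue
            counter += 1
            name = f"QCLADE_{counter}"
            mapping[name] = members
            node.clear_child_nodes()
            taxon = dendropy.Taxon(label=name)
            tree.taxon_namespace.add_taxon(taxon)
            node.taxon = taxon
            node.label = None
            continue
        stack.extend(node.child_nodes())
    return tree, mapping


class Placement(str, enum.Enum):
    nested = "nested"
    sister = "sister"
    outside = "outside"
    unresolved = "unresolved"


@dataclass(frozen=True)
class PlacementResult:
    placement: Placement
    focal_group: str | None = None
    support_at_decision: float | None = None
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        has_focal = self.focal_group is not None
        if has_focal != (self.placement in (Placement.nested, Placement.sister)):
            raise ValueError("focal_group must be set iff placement is nested/sister")


def _groups_under(node: dendropy.Node, assignment: GroupAssignment,
                  mapping: dict[str, tuple[str, ...]]) -> set[str]:
    """Non-query groups among a node's descendant leaves."""
    out = set()
    for lf in node.leaf_iter():
        label = lf.taxon.label
        if label in mapping or label in assignment.query_set:
            continue
        out.add(assignment.group_of(label))
    return out


def classify_placement(
    tree: dendropy.Tree,
    assignment: GroupAssignment,
    query: str,
    min_support: float = 0.5,
    outgroup: str | None = None,
) -> PlacementResult:
    """Nested / sister / outside / unresolved call for one query leaf.

    The tree is treated as rooted as written unless ``outgroup`` is given.
    Query-only clades are collapsed first; ``query`` may name any member of a
    collapsed clade.  A polytomy's sibling set is the union of its subtrees'
    groups (conservative: pushes toward outside).
    """
    assignment.validate_against(tree)
    if query not in _all_leaves(tree):
        raise ValueError(f"query leaf {query!r} not in tree")
    if outgroup is not None:
        tree = reroot_at_outgroup(tree, outgroup)
    ctree, mapping = collapse_query_clades(tree, assignment)
    # locate the (pseudo-)leaf holding the query
    target = None
    for lf in ctree.leaf_node_iter():
        label = lf.taxon.label
        if label == query or query in mapping.get(label, ()):
            target = lf
            break
    if target is None:  # pragma: no cover - guarded by membership check above
        raise ValueError(f"query leaf {query!r} not found after collapsing")
    members = mapping.get(target.taxon.label, (query,))
    parent = target.parent_node
    if parent is None:
        raise ValueError("query is the entire tree; nothing to place against")
    support = node_support(parent)
    sibling_groups: set[str] = set()
    for child in parent.child_nodes():
        if child is target:
            continue
        sibling_groups |= _groups_under(child, assignment, mapping)
    if not sibling_groups:
        return PlacementResult(Placement.unresolved, None, support, members)
    if len(sibling_groups) >= 2:
        placement, focal = Placement.outside, None
    else:
        (focal,) = sibling_groups
        grand = parent.parent_node
        above: set[str] = set()
        if grand is not None:
            for child in grand.child_nodes():
                if child is parent:
                    continue
                above |= _groups_under(child, assignment, mapping)
        placement = Placement.nested if focal in above else Placement.sister
    if support is not None and support < min_support:
        return PlacementResult(Placement.unresolved, None, support, members)
    return PlacementResult(placement, focal, support, members)


class Verdict(str, enum.Enum):
    contamination = "contamination"
    contamination_or_hgt = "contamination_or_hgt"
    putative_ortholog = "putative_ortholog"
    unresolved = "unresolved"


_CONTAM_CLASSES = (
    HitClassification.evident_contamination,
    HitClassification.likely_contamination,
)


def synthesize_verdict(
    placement: PlacementResult | Placement, hitclass: HitClassification
) -> Verdict:
    """Combine tree placement with the alignment-level hit class.

    The table is total over every (placement, hit class) pair; a ``self``
    best hit is treated as a putative ortholog signal and a hitless query as
    unresolved, whatever the placement.
    """
    p = placement.placement if isinstance(placement, PlacementResult) else placement
    if hitclass is HitClassification.self:
        return Verdict.putative_ortholog
    if hitclass is HitClassification.no_hit:
        return Verdict.unresolved
    if p is Placement.unresolved:
        return Verdict.unresolved
    if p is Placement.nested:
        if hitclass in _CONTAM_CLASSES:
            return Verdict.contamination
        return Verdict.contamination_or_hgt
    if p is Placement.sister:
        if hitclass in _CONTAM_CLASSES:
            return Verdict.contamination
        return Verdict.unresolved
    # outside
    if hitclass in _CONTAM_CLASSES:
        return Verdict.contamination_or_hgt  # conflicting evidence, flagged
    return Verdict.putative_ortholog


def reroot_at_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Return a copy rerooted with ``outgroup`` as the sister of the rest."""
    tree = tree.clone(depth=1)
    node = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == outgroup:
            node = lf
            break
    if node is None:
        raise ValueError(f"outgroup leaf {outgroup!r} not in tree")
    tree.to_outgroup_position(node, update_bipartitions=False)
    return tree
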
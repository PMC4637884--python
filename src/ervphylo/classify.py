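"""Reference-anchored ERV class assignment on rooted phylogenies.

ERVs are assigned to Class I or Class II by where they fall relative to
exogenous reference taxa in a rooted tree: an ERV grouped exclusively with
gammaretrovirus references is Class I, exclusively with betaretrovirus
references Class II. Class I trees root to an epsilonretrovirus (e.g.
walleye dermal sarcoma virus) and Class II trees to an alpharetrovirus
(e.g. avian leukosis virus); epsilon/alpha/other references therefore serve
as outgroups but never anchor a class call.

The grouping criterion is operationalized as the smallest ancestral clade
of the ERV tip that contains at least one reference tip: if every reference
in that clade is gamma the call is class1, if every one is beta it is
class2, and anything mixed or non-anchoring (a "blurred relationship")
yields unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import dendropy
import pandas as pd

from ervphylo.treeio import AnnotatedTree, ValidationError, leaf_label

__all__ = ["ClassCall", "assign_class", "root_by_outgroup", "write_class_calls"]

ANCHOR_CLASSES = {"gamma": "class1", "beta": "class2"}


@dataclass(frozen=True)
class ClassCall:
    """Class assignment for one ERV tip."""

    erv_id: str
    assigned_class: str  # "class1", "class2" or "unassigned"
    anchor_refs: frozenset[str]


def assign_class(tree: AnnotatedTree) -> list[ClassCall]:
    """Assign each ERV tip to class1, class2 or unassigned.

    For every ERV tip the smallest ancestral clade containing >=1 reference
    tip is found; the call is class1 iff every reference in it is gamma,
    class2 iff every one is beta, otherwise unassigned. The result is
    invariant under child-order rotations and ERV relabeling.
    """
    refs_below: dict[int, list] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            info = tree.tip_info(node)
            refs_below[id(node)] = [info] if info.role == "reference" else []
        else:
            acc = []
            for child in node.child_nodes():
                acc.extend(refs_below[id(child)])
            refs_below[id(node)] = acc
    if not refs_below[id(tree.root)]:
        raise ValidationError("tree contains no reference tips; cannot anchor classes")

    calls = []
    for leaf in tree.erv_leaves():
        info = tree.tip_info(leaf)
        node = leaf.parent_node
        while node is not None and not refs_below[id(node)]:
            node = node.parent_node
        anchors = refs_below[id(node)]
        classes = {r.ref_class for r in anchors}
        if len(classes) == 1 and next(iter(classes)) in ANCHOR_CLASSES:
            assigned = ANCHOR_CLASSES[next(iter(classes))]
        else:
            assigned = "unassigned"
        calls.append(
            ClassCall(
                erv_id=info.erv_id if info.erv_id is not None else info.label,
                assigned_class=assigned,
                anchor_refs=frozenset(r.ref_name for r in anchors),
            )
        )
    return calls


def root_by_outgroup(tree: AnnotatedTree, outgroup_name: str) -> AnnotatedTree:
    """Re-root on the stem edge of the named tip.

    ``outgroup_name`` matches either the full tip label or, for reference
    tips, the bare reference name. Support values are carried over to the
    corresponding bipartitions (supports annotate splits, which rerooting
    does not change).
    """
    work = tree.clone()
    target: Optional[dendropy.Node] = None
    for leaf in work.leaves():
        info = work.tip_info(leaf)
        if info.label == outgroup_name or info.ref_name == outgroup_name:
            target = leaf
            break
    if target is None:
        raise ValidationError(f"outgroup tip {outgroup_name!r} not found in tree")

    support_by_split = _split_supports(work.tree)

    edge = target.edge
    if edge.length is not None:
        half = edge.length / 2.0
        work.tree.reroot_at_edge(edge, length1=half, length2=half)
    else:
        work.tree.reroot_at_edge(edge)
    work.tree.suppress_unifurcations()

    _restore_split_supports(work.tree, support_by_split)
    return AnnotatedTree(work.tree, tree.host_table)


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf_label(l) for l in node.leaf_iter())


def _split_supports(tree: dendropy.Tree) -> dict[frozenset, str]:
    """Map each internal edge's unrooted split to its support label."""
    all_leaves = _leafset(tree.seed_node)
    out: dict[frozenset, str] = {}
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None or node.label in (None, ""):
            continue
        clade = _leafset(node)
        key = frozenset({clade, all_leaves - clade})
        out[key] = node.label
    return out


def _restore_split_supports(tree: dendropy.Tree, support_by_split: dict[frozenset, str]) -> None:
    all_leaves = _leafset(tree.seed_node)
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            node.label = None
            continue
        clade = _leafset(node)
        key = frozenset({clade, all_leaves - clade})
        node.label = support_by_split.get(key)


def write_class_calls(calls: list[ClassCall], path: Union[str, Path]) -> None:
    """Emit class calls as TSV: erv_id, assigned_class, anchors."""
    df = pd.DataFrame(
        {
            "erv_id": [c.erv_id for c in calls],
            "assigned_class": [c.assigned_class for c in calls],
            "anchors": [",".join(sorted(c.anchor_refs)) for c in calls],
        }
    )
    df.to_csv(path, sep="\t", index=False)
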
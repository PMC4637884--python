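"""Transmission-pattern classification: positions, rules, oracle, summary."""

import itertools

import pytest

from ervphylo.patterns import (
    PatternCall,
    admit_clade,
    classify_clade,
    load_clade_assignments,
    position_tips,
    summarize_patterns,
)
from ervphylo.treeio import AnnotatedTree, ValidationError

# ---------------------------------------------------------------------------
# Independent brute-force oracle on nested-tuple trees ("F" = focal leaf,
# "N" = non-focal leaf), written from the stated rule definitions without
# touching the package's position machinery.
# ---------------------------------------------------------------------------


def _oracle_positions(shape):
    """Leaf index -> position class, by direct depth/side counting."""
    leaves = []

    def collect(node, depth):
        if node == "L" or isinstance(node, str):
            leaves.append(depth)
            return [len(leaves) - 1]
        idx = []
        for child in node:
            idx.extend(collect(child, depth + 1))
        return idx

    side_indices = []
    if isinstance(shape, str):
        raise ValueError("need >= 2 tips")
    for child in shape:
        side_indices.append(collect(child, 1))
    min_side = min(len(s) for s in side_indices)
    basal = set(
        i for s in side_indices if len(s) == min_side for i in s
    )
    max_depth = max(leaves)
    out = {}
    for i, d in enumerate(leaves):
        if i in basal:
            out[i] = "basal"
        elif d == max_depth:
            out[i] = "terminal"
        else:
            out[i] = "internal"
    return out


def _oracle_pattern(shape, labels):
    """Rules (originated/transmitted/received/none) evaluated literally."""
    pos = _oracle_positions(shape)
    focal = [i for i, lab in enumerate(labels) if lab == "F"]
    nonfocal = [i for i, lab in enumerate(labels) if lab == "N"]
    if not focal or not nonfocal:
        return "none"
    classes = {pos[i] for i in focal}
    if "basal" in classes and ({"internal", "terminal"} & classes):
        return "originated_from"
    if classes == {"internal"}:
        return "transmitted_via"
    if classes == {"terminal"}:
        return "received_by"
    return "none"


def _shapes(n):
    """All rooted binary tree shapes with n leaves (canonical nested tuples)."""
    if n == 1:
        return ["L"]
    out = set()
    for i in range(1, n // 2 + 1):
        for left in _shapes(i):
            for right in _shapes(n - i):
                out.add(tuple(sorted((left, right), key=repr)))
    return sorted(out, key=repr)


def _leaf_count(shape):
    if shape == "L":
        return 1
    return sum(_leaf_count(c) for c in shape)


def shape_to_newick(shape, labels, panel):
    """Build treeio Newick with distinct species per tip: F -> bats, N -> rodents."""
    bats = iter(panel.species_of_group("Chiroptera"))
    rodents = iter(panel.species_of_group("Rodentia"))
    counter = itertools.count()

    def rec(node):
        if node == "L":
            i = next(counter)
            sp = next(bats) if labels[i] == "F" else next(rodents)
            return f"{sp}|t{i}:0.1"
        inner = ",".join(rec(c) for c in node)
        return f"({inner})0.95:0.1"

    return rec(shape) + ";"


def all_cases(max_tips):
    for n in range(2, max_tips + 1):
        for shape in _shapes(n):
            for labels in itertools.product("FN", repeat=n):
                yield shape, labels


def run_exhaustive_comparison(max_tips, panel):
    mismatches = []
    for shape, labels in all_cases(max_tips):
        tree = AnnotatedTree.from_newick(shape_to_newick(shape, labels, panel), panel)
        got = classify_clade(tree, "Chiroptera", panel).pattern
        want = _oracle_pattern(shape, labels)
        if got != want:
            mismatches.append((shape, labels, got, want))
    return mismatches


# ---------------------------------------------------------------------------


def tree_of(nwk, panel):
    return AnnotatedTree.from_newick(nwk, panel)


class TestPositionTips:
    def test_five_tip_ladder(self, panel_hosts):
        t = tree_of(
            "((((bat01|a:0.1,bat02|b:0.1)0.9:0.1,bat03|c:0.1)0.9:0.1,bat04|d:0.1)0.9:0.1,"
            "bat05|e:0.1)0.9;",
            panel_hosts,
        )
        pos = {p.label.split("|")[1]: p.position_class for p in position_tips(t)}
        assert pos == {"a": "terminal", "b": "terminal", "c": "internal",
                       "d": "internal", "e": "basal"}

    def test_cherry_both_basal(self, panel_hosts):
        t = tree_of("(bat01|a:0.1,rodent01|b:0.1);", panel_hosts)
        assert {p.position_class for p in position_tips(t)} == {"basal"}

    def test_balanced_four_tip_tie_all_basal(self, panel_hosts):
        t = tree_of(
            "((bat01|a:0.1,bat02|b:0.1)0.9:0.1,(rodent01|c:0.1,rodent02|d:0.1)0.9:0.1);",
            panel_hosts,
        )
        assert {p.position_class for p in position_tips(t)} == {"basal"}

    def test_all_four_tip_shapes_match_oracle(self, panel_hosts):
        assert run_exhaustive_comparison(4, panel_hosts) == []

    def test_single_tip_rejected(self, panel_hosts):
        with pytest.raises(ValidationError):
            position_tips(tree_of("(bat01|a:0.1);", panel_hosts))


class TestClassifyClade:
    def test_focal_parallel_to_two_nonfocals_is_none(self, panel_hosts):
        t = tree_of(
            "(bat01|a:0.1,(rodent01|b:0.1,carnivore01|c:0.1)0.95:0.1)0.95;", panel_hosts
        )
        assert classify_clade(t, "Chiroptera", panel_hosts).pattern == "none"

    def test_focal_with_nested_focal_is_originated_from(self, panel_hosts):
        t = tree_of(
            "(bat01|a:0.1,(bat02|b:0.1,rodent01|c:0.1)0.95:0.1)0.95;", panel_hosts
        )
        call = classify_clade(t, "Chiroptera", panel_hosts)
        assert call.pattern == "originated_from"
        assert call.basal_tips == ("bat01|a",)
        assert call.terminal_tips == ("bat02|b",)

    def test_terminal_focal_in_four_tip_ladder_is_received_by(self, panel_hosts):
        t = tree_of(
            "(((bat01|a:0.1,rodent01|b:0.1)0.95:0.1,rodent02|c:0.1)0.95:0.1,"
            "rodent03|d:0.1)0.95;",
            panel_hosts,
        )
        assert classify_clade(t, "Chiroptera", panel_hosts).pattern == "received_by"

    def test_internal_focal_is_transmitted_via(self, panel_hosts):
        t = tree_of(
            "((((rodent01|a:0.1,rodent02|b:0.1)0.95:0.1,bat01|c:0.1)0.95:0.1,"
            "rodent03|d:0.1)0.95:0.1,rodent04|e:0.1)0.95;",
            panel_hosts,
        )
        assert classify_clade(t, "Chiroptera", panel_hosts).pattern == "transmitted_via"

    def test_single_host_clade_is_none(self, panel_hosts):
        t = tree_of("(bat01|a:0.1,(bat02|b:0.1,bat03|c:0.1)0.9:0.1)0.9;", panel_hosts)
        assert classify_clade(t, "Chiroptera", panel_hosts).pattern == "none"

    def test_no_focal_tips_is_none(self, panel_hosts):
        t = tree_of("(rodent01|a:0.1,carnivore01|b:0.1)0.9;", panel_hosts)
        assert classify_clade(t, "Chiroptera", panel_hosts).pattern == "none"

    def test_unknown_focal_group_is_an_error(self, panel_hosts):
        t = tree_of("(bat01|a:0.1,rodent01|b:0.1)0.9;", panel_hosts)
        with pytest.raises(ValidationError, match="Pterosauria"):
            classify_clade(t, "Pterosauria", panel_hosts)

    def test_dual_classification_across_focal_groups(self, panel_hosts):
        # one clade: received_by for bats, transmitted_via for rodents
        t = tree_of(
            "((((bat01|a:0.1,carnivore01|b:0.1)0.95:0.1,rodent01|c:0.1)0.95:0.1,"
            "carnivore02|d:0.1)0.95:0.1,carnivore03|e:0.1)0.95;",
            panel_hosts,
        )
        assert classify_clade(t, "Chiroptera", panel_hosts).pattern == "received_by"
        assert classify_clade(t, "Rodentia", panel_hosts).pattern == "transmitted_via"

    def test_invariant_under_rotation_and_relabeling(self, panel_hosts):
        a = tree_of(
            "(bat01|a:0.1,(bat02|b:0.1,rodent01|c:0.1)0.95:0.1)0.95;", panel_hosts
        )
        b = tree_of(
            "((rodent05|x:0.1,bat07|y:0.1)0.95:0.1,bat03|z:0.1)0.95;", panel_hosts
        )
        assert (
            classify_clade(a, "Chiroptera", panel_hosts).pattern
            == classify_clade(b, "Chiroptera", panel_hosts).pattern
            == "originated_from"
        )

    def test_matches_oracle_on_all_five_tip_cases(self, panel_hosts):
        assert run_exhaustive_comparison(5, panel_hosts) == []


class TestAdmitClade:
    def test_all_inter_host_nodes_high(self, panel_hosts):
        t = tree_of(
            "((bat01|a:0.1,rodent01|b:0.1)0.95:0.1,rodent02|c:0.1)0.95;", panel_hosts
        )
        assert admit_clade(t, 0.90)

    def test_exactly_at_threshold_fails(self, panel_hosts):
        t = tree_of(
            "((bat01|a:0.1,rodent01|b:0.1)0.90:0.1,rodent02|c:0.1)0.95;", panel_hosts
        )
        assert not admit_clade(t, 0.90)

    def test_low_same_host_cherry_does_not_block(self, panel_hosts):
        t = tree_of(
            "((bat01|a:0.1,bat01|b:0.1)0.3:0.1,rodent01|c:0.1)0.95;", panel_hosts
        )
        assert admit_clade(t, 0.90)

    def test_inter_host_nodes_found_exhaustively(self, panel_hosts):
        # oracle: every internal node with >= 2 species below must be > 0.9
        t = tree_of(
            "(((bat01|a:0.1,bat02|b:0.1)0.5:0.1,rodent01|c:0.1)0.95:0.1,"
            "rodent02|d:0.1)0.95;",
            panel_hosts,
        )
        # the 0.5 node separates bat01 from bat02 (two species) -> fails
        assert not admit_clade(t, 0.90)

    def test_missing_support_on_inter_host_node_fails(self, panel_hosts):
        t = tree_of("((bat01|a:0.1,rodent01|b:0.1):0.1,rodent02|c:0.1)0.95;", panel_hosts)
        assert not admit_clade(t, 0.90)


class TestSummary:
    def test_reference_assignments_counts(self):
        summary = summarize_patterns(load_clade_assignments())
        assert summary.count("Rodentia", "originated_from") == 14
        assert summary.count("Chiroptera", "received_by") == 7
        assert summary.count("Rodentia", "received_by") == 1
        assert summary.count("Chiroptera", "originated_from") == 3
        assert summary.count("Chiroptera", "transmitted_via") == 3
        assert summary.count("Rodentia", "transmitted_via") == 3
        assert summary.class_count("class2", "Rodentia", "originated_from") == 9
        assert summary.n_unique_clades == 30
        assert summary.n_clades_by_class == {"class1": 16, "class2": 14}

    def test_empty_calls_all_zero(self):
        summary = summarize_patterns([])
        assert summary.n_unique_clades == 0
        assert summary.counts == {}

    def test_one_call_per_clade_and_focal_group(self):
        calls = load_clade_assignments()
        assert len({(c.clade_id, c.focal_group) for c in calls}) == len(calls)

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValidationError):
            PatternCall("1.1", "Chiroptera", "teleported_by")
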
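"""Six-way classification of cross-species retroviral transmission patterns.

For a rooted cross-species ERV clade and a focal host group (bats =
Chiroptera, rodents = Rodentia), the position of the focal tips determines
the clade's transmission pattern:

* ``originated_from`` — focal branches sit at the base of the clade *and*
  also appear internally or at the end. The 3-tip topology
  ``(focal,(nonfocal,nonfocal))`` is excluded (the focal branch is merely
  parallel to the two non-focal ones), whereas ``(focal,(focal,nonfocal))``
  qualifies.
* ``transmitted_via`` — every focal branch is internal: neither basal nor
  at the end.
* ``received_by`` — every focal branch sits at the end of the clade.
* ``none`` — anything else, including single-host clades and clades
  without focal tips.

Tip positions are formalized by node depth in the rooted clade: *basal*
tips attach on the root-split side with the smaller tip count (a tie makes
both sides basal), *terminal* tips attach at maximal depth, everything else
is *internal*; a tip qualifying as both basal and terminal counts as basal.
Rules are evaluated in the order originated_from → transmitted_via →
received_by so each (clade, focal group) receives at most one pattern;
one clade may still receive different patterns for different focal groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import dendropy
import pandas as pd

from ervphylo.treeio import AnnotatedTree, HostTable, ValidationError

__all__ = [
    "PATTERNS",
    "TipPosition",
    "PatternCall",
    "PatternSummary",
    "position_tips",
    "classify_clade",
    "admit_clade",
    "summarize_patterns",
    "load_clade_assignments",
    "write_pattern_calls",
    "read_pattern_calls",
]

PATTERNS = ("originated_from", "transmitted_via", "received_by", "none")

DEFAULT_MIN_SUPPORT = 0.90


@dataclass(frozen=True)
class TipPosition:
    """Position class of one tip within a rooted clade."""

    label: str
    position_class: str  # "basal", "internal" or "terminal"


@dataclass(frozen=True)
class PatternCall:
    """Transmission-pattern call for one clade and one focal host group.

    The three tip tuples record which *focal* tips were basal, internal and
    terminal — the machine-readable rationale for the call.
    """

    clade_id: str
    focal_group: str
    pattern: str
    basal_tips: tuple[str, ...] = ()
    internal_tips: tuple[str, ...] = ()
    terminal_tips: tuple[str, ...] = ()

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValidationError(f"unknown pattern {self.pattern!r}")

    @property
    def erv_class(self) -> Optional[str]:
        """Class carried by the clade-id prefix convention ('1.x' / '2.x')."""
        if self.clade_id.startswith("1."):
            return "class1"
        if self.clade_id.startswith("2."):
            return "class2"
        return None


def position_tips(clade: AnnotatedTree) -> list[TipPosition]:
    """Classify every tip of a rooted clade as basal, internal or terminal.

    Depth is counted in nodes from the clade root (root = 0). Collapsed
    same-host tips count as single tips. Requires >= 2 tips.
    """
    root = clade.root
    leaves = clade.leaves()
    if len(leaves) < 2:
        raise ValidationError("position_tips requires a clade with >= 2 tips")

    depth: dict[int, int] = {id(root): 0}
    for node in clade.tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + 1

    sides = [set(id(l) for l in child.leaf_iter()) for child in root.child_nodes()]
    min_count = min(len(s) for s in sides)
    basal_ids = set().union(*(s for s in sides if len(s) == min_count))

    max_depth = max(depth[id(l)] for l in leaves)
    out = []
    for leaf in leaves:
        if id(leaf) in basal_ids:
            cls = "basal"
        elif depth[id(leaf)] == max_depth:
            cls = "terminal"
        else:
            cls = "internal"
        out.append(TipPosition(label=_label(leaf), position_class=cls))
    return out


def _label(leaf: dendropy.Node) -> str:
    from ervphylo.treeio import leaf_label

    return leaf_label(leaf) or ""


def _tip_group(info, host_table: HostTable) -> str:
    if info.species_id is not None:
        return host_table.group_of(info.species_id)
    # family-collapsed tip: the family's species share one host group
    groups = {
        host_table.group_of(sp)
        for sp in host_table.species
        if host_table.family_of(sp) == info.family
    }
    if len(groups) != 1:
        raise ValidationError(
            f"family {info.family!r} spans multiple host groups: {sorted(groups)}"
        )
    return groups.pop()


def classify_clade(
    clade: AnnotatedTree,
    focal_group: str,
    host_table: HostTable,
    clade_id: str = "",
    require_nonbasal_focal: bool = True,
) -> PatternCall:
    """Call the transmission pattern of one rooted ERV clade.

    ``require_nonbasal_focal`` keeps the originated_from rule two-sided
    (a basal focal tip *and* a non-basal one are both required); setting it
    False lets a lone basal focal tip qualify, except in the literal 3-tip
    ``(focal,(nonfocal,nonfocal))`` topology, which is never originated_from.
    """
    if focal_group not in host_table.groups:
        raise ValidationError(f"focal group {focal_group!r} not present in host table")
    leaves = clade.leaves()
    infos = [clade.tip_info(l) for l in leaves]
    if any(i.role != "erv" for i in infos):
        raise ValidationError("pattern classification expects ERV-only clades")

    group_by_label = {_label(l): _tip_group(i, host_table) for l, i in zip(leaves, infos)}
    focal_labels = {lab for lab, g in group_by_label.items() if g == focal_group}
    nonfocal_labels = set(group_by_label) - focal_labels

    def call(pattern, fpos=()):
        basal = tuple(sorted(p.label for p in fpos if p.position_class == "basal"))
        internal = tuple(sorted(p.label for p in fpos if p.position_class == "internal"))
        terminal = tuple(sorted(p.label for p in fpos if p.position_class == "terminal"))
        return PatternCall(clade_id, focal_group, pattern, basal, internal, terminal)

    if not focal_labels or not nonfocal_labels:
        return call("none")

    positions = position_tips(clade)
    fpos = [p for p in positions if p.label in focal_labels]
    f_basal = any(p.position_class == "basal" for p in fpos)
    f_internal = any(p.position_class == "internal" for p in fpos)
    f_terminal = any(p.position_class == "terminal" for p in fpos)

    # (a) originated_from
    if f_basal:
        if f_internal or f_terminal:
            return call("originated_from", fpos)
        if not require_nonbasal_focal and not _is_three_tip_parallel(
            clade, focal_labels
        ):
            return call("originated_from", fpos)
    # (b) transmitted_via
    if fpos and not f_basal and not f_terminal:
        return call("transmitted_via", fpos)
    # (c) received_by
    if fpos and not f_basal and not f_internal:
        return call("received_by", fpos)
    return call("none", fpos)


def _is_three_tip_parallel(clade: AnnotatedTree, focal_labels: set[str]) -> bool:
    """True for the literal (focal,(nonfocal,nonfocal)) 3-tip topology."""
    leaves = clade.leaves()
    if len(leaves) != 3:
        return False
    root_children = clade.root.child_nodes()
    lone = [c for c in root_children if c.is_leaf()]
    if len(lone) != 1:
        return False
    return _label(lone[0]) in focal_labels and sum(
        1 for l in leaves if _label(l) in focal_labels
    ) == 1


def admit_clade(clade: AnnotatedTree, min_support: float = DEFAULT_MIN_SUPPORT) -> bool:
    """Check the clade-admission criterion on node supports.

    True iff every internal node separating tips of different hosts (a
    divergence point of viruses from >= 2 distinct host species) carries
    support strictly greater than ``min_support`` (default 0.90). Nodes
    uniting tips of a single host are not gated; a missing support on an
    inter-host node fails admission.
    """
    for node in clade.tree.preorder_internal_node_iter():
        hosts = set()
        for leaf in node.leaf_iter():
            info = clade.tip_info(leaf)
            if not info.is_erv:
                continue
            hosts.add(info.species_id if info.species_id is not None else ("family", info.family))
        if len(hosts) >= 2:
            support = AnnotatedTree.support(node)
            if support is None or not (support > min_support):
                return False
    return True


@dataclass
class PatternSummary:
    """Aggregated pattern counts.

    ``counts`` maps (focal_group, pattern) to the number of calls;
    ``class_counts`` additionally splits by ERV class carried in the
    clade-id prefix; ``n_clades_by_class`` counts unique clades per class.
    """

    counts: dict[tuple[str, str], int]
    class_counts: dict[tuple[str, str, str], int]
    n_unique_clades: int
    n_clades_by_class: dict[str, int]

    def count(self, focal_group: str, pattern: str) -> int:
        return self.counts.get((focal_group, pattern), 0)

    def class_count(self, erv_class: str, focal_group: str, pattern: str) -> int:
        return self.class_counts.get((erv_class, focal_group, pattern), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"focal_group": g, "pattern": p, "count": n}
            for (g, p), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["focal_group", "pattern", "count"])

    def format_report(self) -> str:
        lines = ["pattern counts (focal_group, pattern, n):"]
        for (g, p), n in sorted(self.counts.items()):
            lines.append(f"  {g}\t{p}\t{n}")
        lines.append("per-class counts (class, focal_group, pattern, n):")
        for (c, g, p), n in sorted(self.class_counts.items()):
            lines.append(f"  {c}\t{g}\t{p}\t{n}")
        lines.append(f"unique clades: {self.n_unique_clades}")
        for c, n in sorted(self.n_clades_by_class.items()):
            lines.append(f"  {c} clades: {n}")
        return "\n".join(lines)


def summarize_patterns(calls: Sequence[PatternCall]) -> PatternSummary:
    """Count pattern calls per focal group, per ERV class, and unique clades."""
    counts: dict[tuple[str, str], int] = {}
    class_counts: dict[tuple[str, str, str], int] = {}
    clades: set[str] = set()
    clades_by_class: dict[str, set[str]] = {}
    for c in calls:
        counts[(c.focal_group, c.pattern)] = counts.get((c.focal_group, c.pattern), 0) + 1
        if c.clade_id:
            clades.add(c.clade_id)
        cls = c.erv_class
        if cls is not None:
            key = (cls, c.focal_group, c.pattern)
            class_counts[key] = class_counts.get(key, 0) + 1
            clades_by_class.setdefault(cls, set()).add(c.clade_id)
    return PatternSummary(
        counts=counts,
        class_counts=class_counts,
        n_unique_clades=len(clades),
        n_clades_by_class={k: len(v) for k, v in clades_by_class.items()},
    )


def load_clade_assignments(path: Union[str, Path, None] = None) -> list[PatternCall]:
    """Load clade-to-pattern assignments (default: the packaged reference set).

    The packaged fixture transcribes the published assignments of 30
    well-supported cross-species ERV clades (16 Class I, 14 Class II) to the
    six transmission patterns; clade 2.11 appears under two focal groups.
    """
    if path is None:
        source = resources.files("ervphylo.data").joinpath("clade_assignments.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"clade_id", "focal_group", "pattern"}
    if not required.issubset(df.columns):
        raise ValidationError(f"clade assignment table needs columns {sorted(required)}")
    return [
        PatternCall(clade_id=r.clade_id, focal_group=r.focal_group, pattern=r.pattern)
        for r in df.itertuples(index=False)
    ]


_CALL_COLUMNS = [
    "clade_id",
    "focal_group",
    "pattern",
    "basal_tips",
    "internal_tips",
    "terminal_tips",
]


def write_pattern_calls(calls: Sequence[PatternCall], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "clade_id": [c.clade_id for c in calls],
            "focal_group": [c.focal_group for c in calls],
            "pattern": [c.pattern for c in calls],
            "basal_tips": [",".join(c.basal_tips) for c in calls],
            "internal_tips": [",".join(c.internal_tips) for c in calls],
            "terminal_tips": [",".join(c.terminal_tips) for c in calls],
        },
        columns=_CALL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_pattern_calls(path: Union[str, Path]) -> list[PatternCall]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        PatternCall(
            clade_id=r.clade_id,
            focal_group=r.focal_group,
            pattern=r.pattern,
            basal_tips=tuple(x for x in r.basal_tips.split(",") if x),
            internal_tips=tuple(x for x in r.internal_tips.split(",") if x),
            terminal_tips=tuple(x for x in r.terminal_tips.split(",") if x),
        )
        for r in df.itertuples(index=False)
    ]
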
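"""Support-thresholded clade collapse and the per-host diversity index.

To expose informative phylogenetic signal, monophyletic sets of ERV tips
from the same host species (and optionally the same host family, e.g.
Pteropodidae or Muridae) whose stem node carries sufficient support
(Shimodaira–Hasegawa value >= threshold, default 0.70 "moderate"; 0.90 is
"high") are collapsed into a single branch labeled
``<species_or_family>|COLLAPSED:n=<k>``.

The per-host phylogenetic diversity index is then the number of
phylogenetic positions (post-collapse lineages) a species occupies divided
by that species' ERV copy number: hosts whose few copies spread over many
independent positions score high, hosts with many near-identical copies in
one clade score low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import dendropy
import pandas as pd

from ervphylo.treeio import AnnotatedTree, HostTable, ValidationError

__all__ = [
    "CollapseConfig",
    "DiversityRecord",
    "collapse_tree",
    "diversity_index",
    "write_diversity_table",
]

logger = logging.getLogger(__name__)

SUPPORT_MODERATE = 0.70
SUPPORT_HIGH = 0.90


@dataclass(frozen=True)
class CollapseConfig:
    """Collapse rule parameters.

    ``collapse_threshold`` gates on the support of the clade's root node
    (the MRCA of its tips). ``family_groups`` lists host families eligible
    for family-level collapse; species-level collapse is applied first and
    family-level collapse then operates on the partially collapsed tree.
    """

    min_clade_size: int = 2
    support_moderate: float = SUPPORT_MODERATE
    support_high: float = SUPPORT_HIGH
    collapse_threshold: float = SUPPORT_MODERATE
    family_groups: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0.0 <= self.collapse_threshold <= 1.0):
            raise ValidationError(f"collapse_threshold {self.collapse_threshold} outside [0, 1]")
        if self.min_clade_size < 2:
            raise ValidationError("min_clade_size must be >= 2")


@dataclass(frozen=True)
class DiversityRecord:
    """Phylogenetic positions, copy number and their ratio for one species."""

    species_id: str
    positions: int
    copy_number: int
    index: Optional[float]  # None when copy_number == 0 (undefined)


def _clade_token(tree: AnnotatedTree, node: dendropy.Node, level: str,
                 family_groups: frozenset[str]) -> Optional[tuple[str, int]]:
    """Token and represented-tip count if the clade is homogeneous at ``level``.

    Species level: every leaf is an ERV tip attributed to one species.
    Family level: every leaf is an ERV tip of one family in family_groups.
    Reference/outgroup tips poison a clade at either level.
    """
    token: Optional[str] = None
    total = 0
    for leaf in node.leaf_iter():
        info = tree.tip_info(leaf)
        if not info.is_erv:
            return None
        key = info.species_id if level == "species" else info.family
        if key is None:
            return None
        if token is None:
            token = key
        elif key != token:
            return None
        total += info.n_collapsed
    if token is None:
        return None
    if level == "family" and token not in family_groups:
        return None
    return token, total


def _collapse_pass(tree: AnnotatedTree, level: str, cfg: CollapseConfig) -> bool:
    """One top-down pass collapsing maximal homogeneous clades; True if any."""
    family_groups = frozenset(cfg.family_groups)
    changed = False

    def walk(node: dendropy.Node) -> None:
        nonlocal changed
        if node.is_leaf():
            return
        hit = _clade_token(tree, node, level, family_groups)
        if hit is not None:
            token, total = hit
            if total >= cfg.min_clade_size:
                support = AnnotatedTree.support(node)
                if support is None:
                    logger.info(
                        "skipping collapsible %s clade %r (n=%d): missing support",
                        level, token, total,
                    )
                elif support >= cfg.collapse_threshold:
                    _collapse_node(tree.tree, node, f"{token}|COLLAPSED:n={total}")
                    changed = True
                    return  # nothing below survives
        for child in list(node.child_nodes()):
            walk(child)

    walk(tree.tree.seed_node)
    return changed


def _collapse_node(tree: dendropy.Tree, node: dendropy.Node, label: str) -> None:
    node.set_child_nodes([])
    node.taxon = None
    node.label = label


def collapse_tree(
    tree: AnnotatedTree, host_table: HostTable, cfg: CollapseConfig = CollapseConfig()
) -> AnnotatedTree:
    """Collapse supported same-species (then same-family) clades.

    Every maximal clade whose ERV tips all belong to one species — or, for
    families listed in ``cfg.family_groups``, to one family — with
    represented tip count >= ``min_clade_size`` and stem support >=
    ``collapse_threshold`` is replaced by a single tip recording the species
    (or family) and the number of tips collapsed. Maximality means no
    collapsed clade is nested inside another collapsible one. Candidate
    clades with missing support are skipped (logged), not an error;
    reference and outgroup tips never collapse. The operation is idempotent
    and conserves the total represented ERV tip count.
    """
    work = tree.clone()
    _collapse_pass(work, "species", cfg)
    if cfg.family_groups:
        _collapse_pass(work, "family", cfg)
    # serialize + reparse to normalize the taxon namespace and re-validate
    return AnnotatedTree.from_newick(work.as_newick(), host_table)


def diversity_index(
    tree: AnnotatedTree,
    host_table: HostTable,
    cfg: CollapseConfig = CollapseConfig(),
    erv_class: str = "class1",
    apply_collapse: bool = True,
) -> list[DiversityRecord]:
    """Per-species phylogenetic positions / copy number.

    ``positions`` counts post-collapse tips attributed to the species
    (a collapsed clade is one position, a singleton tip is one position).
    Family-collapsed tips carry no single species and are not attributed.
    The index is reported as missing (None) when the copy number is zero;
    a species absent from the tree scores 0.0.
    """
    if apply_collapse:
        tree = collapse_tree(tree, host_table, cfg)
    counts: dict[str, int] = {sp: 0 for sp in host_table.species}
    for leaf in tree.erv_leaves():
        info = tree.tip_info(leaf)
        if info.species_id is not None:
            counts[info.species_id] += 1
    records = []
    for sp in host_table.species:
        copies = host_table.copy_number(sp, erv_class)
        positions = counts[sp]
        index = None if copies == 0 else positions / copies
        records.append(DiversityRecord(sp, positions, copies, index))
    return records


def write_diversity_table(records: Sequence[DiversityRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "positions": [r.positions for r in records],
            "copy_number": [r.copy_number for r in records],
            "index": [r.index if r.index is not None else "NA" for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
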
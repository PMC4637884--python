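"""Input/output for host-labeled, support-annotated phylogenies.

Naming convention (enforced everywhere downstream):

* ERV tips are labeled ``<species_id>|<erv_id>``; the species token must
  resolve in the :class:`HostTable`.
* Reference / outgroup tips are labeled ``REF:<class>:<name>`` with class
  one of ``gamma``, ``beta``, ``epsilon``, ``alpha``, ``other``.
* Collapsed tips (written by :mod:`ervphylo.collapse`) are labeled
  ``<species_or_family>|COLLAPSED:n=<k>``.

Node support values (e.g. Shimodaira–Hasegawa test values in [0, 1]) are
read from internal-node labels, the dialect FastTree emits. Values outside
[0, 1] are rejected, not rescaled. Trees are treated as rooted; rootedness
comments in the input are honored but a bare Newick string is forced rooted.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import dendropy
import pandas as pd

__all__ = [
    "ErvPhyloError",
    "TreeParseError",
    "ValidationError",
    "HostTable",
    "TipInfo",
    "AnnotatedTree",
    "read_host_table",
    "read_tree",
    "write_tree",
    "leaf_label",
    "quote_label",
    "REF_CLASSES",
    "HOST_TABLE_COLUMNS",
]


class ErvPhyloError(Exception):
    """Base class for all package errors."""


class TreeParseError(ErvPhyloError, ValueError):
    """Raised when a Newick file cannot be parsed."""


class ValidationError(ErvPhyloError, ValueError):
    """Raised when parsed data violates the package's conventions."""


REF_CLASSES = frozenset({"gamma", "beta", "epsilon", "alpha", "other"})

HOST_TABLE_COLUMNS = [
    "species_id",
    "family",
    "host_group",
    "copies_class1",
    "copies_class2",
]

_COLLAPSED_RE = re.compile(r"^COLLAPSED:n=(\d+)$")


class HostTable:
    """Species → family → host-group mapping with per-species ERV copy counts.

    Grounds every host-aware operation: host-group lookup for pattern
    classification, family lookup for family-level collapse, copy numbers
    for the phylogenetic diversity index.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in HOST_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"host table missing columns: {missing}")
        df = df[HOST_TABLE_COLUMNS].copy()
        df["species_id"] = df["species_id"].astype(str)
        df["family"] = df["family"].astype(str)
        df["host_group"] = df["host_group"].astype(str)
        dup = df["species_id"][df["species_id"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate species_id in host table: {sorted(set(dup))}")
        for col in ("copies_class1", "copies_class2"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
            if (df[col] < 0).any():
                bad = df.loc[df[col] < 0, "species_id"].tolist()
                raise ValidationError(f"negative {col} for species: {bad}")
        self._df = df.reset_index(drop=True)
        self._group = dict(zip(df["species_id"], df["host_group"]))
        self._family = dict(zip(df["species_id"], df["family"]))
        self._copies = {
            "class1": dict(zip(df["species_id"], df["copies_class1"])),
            "class2": dict(zip(df["species_id"], df["copies_class2"])),
        }

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "HostTable":
        """Build from (species_id, family, host_group, copies1, copies2) rows."""
        return cls(pd.DataFrame(list(records), columns=HOST_TABLE_COLUMNS))

    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def species(self) -> list[str]:
        return self._df["species_id"].tolist()

    @property
    def families(self) -> set[str]:
        return set(self._df["family"])

    @property
    def groups(self) -> set[str]:
        return set(self._df["host_group"])

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._group

    def group_of(self, species_id: str) -> str:
        try:
            return self._group[species_id]
        except KeyError:
            raise ValidationError(f"unknown species_id: {species_id!r}") from None

    def family_of(self, species_id: str) -> str:
        try:
            return self._family[species_id]
        except KeyError:
            raise ValidationError(f"unknown species_id: {species_id!r}") from None

    def copy_number(self, species_id: str, erv_class: str) -> int:
        if erv_class not in ("class1", "class2"):
            raise ValidationError(f"unknown ERV class: {erv_class!r}")
        try:
            return self._copies[erv_class][species_id]
        except KeyError:
            raise ValidationError(f"unknown species_id: {species_id!r}") from None

    def group_counts(self) -> dict[str, int]:
        """Number of species per host group."""
        return self._df["host_group"].value_counts().to_dict()

    def species_of_group(self, group: str) -> list[str]:
        return self._df.loc[self._df["host_group"] == group, "species_id"].tolist()

    def to_tsv(self, path: Union[str, Path]) -> None:
        self._df.to_csv(path, sep="\t", index=False)


def read_host_table(path: Union[str, Path]) -> HostTable:
    """Read a host metadata table from TSV.

    Expected header: ``species_id family host_group copies_class1
    copies_class2``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str, "family": str, "host_group": str})
    return HostTable(df)


@dataclass(frozen=True)
class TipInfo:
    """Decoded identity of one tree tip."""

    label: str
    role: str  # "erv" or "reference"
    species_id: Optional[str] = None  # set for species-attributed ERV tips
    family: Optional[str] = None  # host family (also set for family-collapsed tips)
    erv_id: Optional[str] = None
    ref_class: Optional[str] = None
    ref_name: Optional[str] = None
    n_collapsed: int = 1  # number of original ERV tips this tip represents

    @property
    def is_erv(self) -> bool:
        return self.role == "erv"

    @property
    def is_collapsed(self) -> bool:
        return self.erv_id is None and self.role == "erv"


def parse_tip_label(label: str, host_table: HostTable) -> TipInfo:
    """Decode a tip label per the package convention; raise on violations."""
    if label.startswith("REF:"):
        parts = label.split(":", 2)
        if len(parts) != 3 or not parts[2]:
            raise ValidationError(f"malformed reference label: {label!r} (want REF:<class>:<name>)")
        _, ref_class, name = parts
        if ref_class not in REF_CLASSES:
            raise ValidationError(
                f"unknown reference class {ref_class!r} in {label!r}; expected one of {sorted(REF_CLASSES)}"
            )
        return TipInfo(label=label, role="reference", ref_class=ref_class, ref_name=name)
    if "|" not in label:
        raise ValidationError(
            f"tip label {label!r} does not follow '<species_id>|<erv_id>' or 'REF:<class>:<name>'"
        )
    token, rest = label.split("|", 1)
    m = _COLLAPSED_RE.match(rest)
    if m:
        n = int(m.group(1))
        if token in host_table:
            return TipInfo(
                label=label,
                role="erv",
                species_id=token,
                family=host_table.family_of(token),
                n_collapsed=n,
            )
        if token in host_table.families:
            return TipInfo(label=label, role="erv", family=token, n_collapsed=n)
        raise ValidationError(f"collapsed tip token {token!r} is neither a species nor a family")
    if token not in host_table:
        raise ValidationError(f"unknown species token {token!r} in tip label {label!r}")
    return TipInfo(
        label=label,
        role="erv",
        species_id=token,
        family=host_table.family_of(token),
        erv_id=rest,
    )


class AnnotatedTree:
    """A rooted phylogeny whose tips are decoded against a :class:`HostTable`.

    Wraps a :class:`dendropy.Tree`. Internal-node labels hold support values
    (kept as the original strings so that writing preserves the printed
    precision); :meth:`support` parses them on demand.
    """

    def __init__(self, tree: dendropy.Tree, host_table: HostTable):
        self._tree = tree
        self._host_table = host_table
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, host_table: HostTable) -> "AnnotatedTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                suppress_leaf_node_taxa=True,  # duplicate labels OK (collapsed tips)
                preserve_underscores=True,
                rooting="force-rooted",
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise TreeParseError(f"could not parse Newick: {exc}") from exc
        return cls(tree, host_table)

    def _validate(self) -> None:
        if self._tree.seed_node is None:
            raise ValidationError("tree has no root")
        bad_labels = []
        self._tips: dict[int, TipInfo] = {}
        for leaf in self._tree.leaf_node_iter():
            label = _leaf_label(leaf)
            if label is None:
                bad_labels.append("<unlabeled tip>")
                continue
            try:
                self._tips[id(leaf)] = parse_tip_label(label, self._host_table)
            except ValidationError as exc:
                bad_labels.append(str(exc))
        if bad_labels:
            raise ValidationError(
                "tree contains unresolvable tip labels:\n  " + "\n  ".join(bad_labels)
            )
        for node in self._tree.preorder_internal_node_iter():
            if node.label is not None and node.label != "":
                try:
                    val = float(node.label)
                except ValueError:
                    raise ValidationError(
                        f"internal node label {node.label!r} is not a support value"
                    ) from None
                if not (0.0 <= val <= 1.0):
                    raise ValidationError(
                        f"support {val} outside [0, 1]; values are not rescaled"
                    )

    # -- accessors ----------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def host_table(self) -> HostTable:
        return self._host_table

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def leaves(self) -> list[dendropy.Node]:
        return list(self._tree.leaf_node_iter())

    def tip_info(self, leaf: dendropy.Node) -> TipInfo:
        key = id(leaf)
        if key not in self._tips:  # leaf created after parsing (e.g. collapse)
            label = _leaf_label(leaf)
            if label is None:
                raise ValidationError("unlabeled tip")
            self._tips[key] = parse_tip_label(label, self._host_table)
        return self._tips[key]

    def erv_leaves(self) -> list[dendropy.Node]:
        return [l for l in self.leaves() if self.tip_info(l).is_erv]

    def reference_leaves(self) -> list[dendropy.Node]:
        return [l for l in self.leaves() if self.tip_info(l).role == "reference"]

    def n_erv_tips(self) -> int:
        """Total ERV tips represented, counting collapsed tips by their n."""
        return sum(self.tip_info(l).n_collapsed for l in self.erv_leaves())

    @staticmethod
    def support(node: dendropy.Node) -> Optional[float]:
        """Support value of an internal node, or None if absent."""
        if node.is_leaf() or node.label in (None, ""):
            return None
        return float(node.label)

    @staticmethod
    def set_support(node: dendropy.Node, value: Optional[float]) -> None:
        if value is None:
            node.label = None
            return
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"support {value} outside [0, 1]")
        node.label = _format_support(value)

    # -- serialization ------------------------------------------------

    def as_newick(self) -> str:
        return _to_newick(self._tree)

    def clone(self) -> "AnnotatedTree":
        return AnnotatedTree.from_newick(self.as_newick(), self._host_table)


_NEEDS_QUOTING = re.compile(r"[\s:;,()\[\]']")


def quote_label(label: str) -> str:
    """Quote a tip label for safe embedding in hand-built Newick text."""
    if _NEEDS_QUOTING.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def leaf_label(leaf: dendropy.Node) -> Optional[str]:
    """The tip's label, whether stored as a node label or a taxon."""
    if leaf.label:
        return leaf.label
    if leaf.taxon is not None and leaf.taxon.label:
        return leaf.taxon.label
    return None


_leaf_label = leaf_label


def _format_support(value: float) -> str:
    # shortest repr that round-trips; "0.95" stays "0.95"
    return repr(float(value))


def _to_newick(tree: dendropy.Tree) -> str:
    out = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_internal_node_labels=False,
        suppress_leaf_node_labels=False,
    )
    return out.strip() + "\n"


def read_tree(path: Union[str, Path], host_table: HostTable) -> AnnotatedTree:
    """Read a rooted, support-annotated, host-labeled Newick tree.

    Raises :class:`TreeParseError` on malformed Newick and
    :class:`ValidationError` (listing every offending label) when a tip
    does not resolve against the host table or the naming convention.
    """
    text = Path(path).read_text()
    return AnnotatedTree.from_newick(text, host_table)


def write_tree(tree: AnnotatedTree, path: Union[str, Path]) -> None:
    """Write the tree as Newick with supports as internal-node labels.

    Writing is idempotent: write → read → write produces identical bytes.
    """
    Path(path).write_text(tree.as_newick())
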
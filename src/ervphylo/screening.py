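"""Candidate filtering for ERV genome-mining hit tables.

Operates on tabular homology-search records (BLAST outfmt-6 style), not on
sequences. Four filters mirror the mining workflow:

* :func:`admit_hits` — admit hits with E-value strictly below 1e-5.
* :func:`length_filter` — keep hits whose alignment lies inside the class
  Pol window and is long enough: Class I (gammaretrovirus-like) positions
  85–971 on the reticuloendotheliosis virus Pol, ≥887 aa; Class II
  (betaretrovirus-like) positions 5–741 on the Jaagsiekte sheep retrovirus
  Pol, ≥737 aa.
* :func:`reciprocal_exclude` — reciprocal-best-hit false-positive removal:
  a query whose minimum-E-value hit is a host protein is discarded.
* :func:`strict_filter` — the strict mining cut-offs: coverage > 80%,
  E-value < 1e-100, identity > 60% (all strict inequalities).

Boundary semantics: E-value admission is strict ``<`` (hits *lower than*
the cut-off are collected); the strict filter uses strict inequalities;
length windows are inclusive 1-based amino-acid coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from ervphylo.treeio import ValidationError

__all__ = [
    "HitRecord",
    "ScreenConfig",
    "admit_hits",
    "length_filter",
    "reciprocal_exclude",
    "strict_filter",
    "screen_queries",
    "group_by_query",
    "read_hit_table",
    "write_hit_table",
    "hits_from_blast6",
]

SUBJECT_CATEGORIES = ("retroviral", "host_protein")


@dataclass(frozen=True)
class HitRecord:
    """One homology-search hit.

    Alignment coordinates are 1-based inclusive amino-acid positions on the
    class reference Pol (the subject), so ``aln_end - aln_start + 1`` is the
    aligned length.
    """

    query_id: str
    subject_id: str
    subject_category: str  # "retroviral" or "host_protein"
    evalue: float
    query_coverage: float  # percent in [0, 100]
    identity: float  # percent in [0, 100]
    aln_start: int
    aln_end: int

    def __post_init__(self):
        if self.subject_category not in SUBJECT_CATEGORIES:
            raise ValidationError(
                f"subject_category {self.subject_category!r} not in {SUBJECT_CATEGORIES}"
            )
        if self.evalue < 0 or math.isnan(self.evalue):
            raise ValidationError(f"negative E-value: {self.evalue}")
        for name, v in (("query_coverage", self.query_coverage), ("identity", self.identity)):
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name} {v} outside [0, 100]")
        if self.aln_start < 1 or self.aln_end < self.aln_start:
            raise ValidationError(
                f"bad alignment span {self.aln_start}-{self.aln_end} (1-based, end >= start)"
            )

    @property
    def aln_length(self) -> int:
        return self.aln_end - self.aln_start + 1


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the screening filters (defaults are the study's)."""

    admit_evalue: float = 1e-5
    class1_window: tuple[int, int] = (85, 971)
    class1_min_len: int = 887
    class2_window: tuple[int, int] = (5, 741)
    class2_min_len: int = 737
    strict_coverage: float = 80.0
    strict_evalue: float = 1e-100
    strict_identity: float = 60.0

    def __post_init__(self):
        for window, min_len in (
            (self.class1_window, self.class1_min_len),
            (self.class2_window, self.class2_min_len),
        ):
            span = window[1] - window[0] + 1
            if min_len > span:
                raise ValidationError(f"min_len {min_len} exceeds window span {span}")

    def window(self, erv_class: str) -> tuple[int, int]:
        return {"class1": self.class1_window, "class2": self.class2_window}[erv_class]

    def min_len(self, erv_class: str) -> int:
        return {"class1": self.class1_min_len, "class2": self.class2_min_len}[erv_class]


def admit_hits(hits: Sequence[HitRecord], cfg: ScreenConfig = ScreenConfig()) -> list[HitRecord]:
    """Keep hits with E-value strictly below the admission cut-off.

    A hit at exactly the cut-off (default 1e-5) is removed; order preserved.
    """
    return [h for h in hits if h.evalue < cfg.admit_evalue]


def length_filter(
    hits: Sequence[HitRecord], erv_class: str, cfg: ScreenConfig = ScreenConfig()
) -> list[HitRecord]:
    """Keep hits contained in the class Pol window with sufficient length.

    The alignment must lie inside the inclusive window and its length
    (``aln_end - aln_start + 1``) must reach the class minimum.
    """
    if erv_class not in ("class1", "class2"):
        raise ValidationError(f"unknown ERV class: {erv_class!r}")
    lo, hi = cfg.window(erv_class)
    min_len = cfg.min_len(erv_class)
    return [
        h for h in hits if h.aln_start >= lo and h.aln_end <= hi and h.aln_length >= min_len
    ]


def reciprocal_exclude(
    per_query_hits: Mapping[str, Sequence[HitRecord]],
) -> tuple[set[str], set[str]]:
    """Reciprocal top-hit false-positive exclusion.

    A query is discarded iff its minimum-E-value hit is a host protein.
    Ties at the minimum E-value between a host and a retroviral subject are
    resolved conservatively: the query is discarded (the false-positive risk
    outweighs the loss of one candidate).

    Returns ``(kept, discarded)`` query-id sets partitioning the input.
    """
    kept: set[str] = set()
    discarded: set[str] = set()
    for query_id, hits in per_query_hits.items():
        if not hits:
            raise ValidationError(f"query {query_id!r} has an empty hit list")
        best = min(h.evalue for h in hits)
        top = [h for h in hits if h.evalue == best]
        if any(h.subject_category == "host_protein" for h in top):
            discarded.add(query_id)
        else:
            kept.add(query_id)
    return kept, discarded


def strict_filter(hits: Sequence[HitRecord], cfg: ScreenConfig = ScreenConfig()) -> list[HitRecord]:
    """Apply the strict mining cut-offs (all inequalities strict).

    Keeps hits with coverage > 80%, E-value < 1e-100 and identity > 60%.
    """
    return [
        h
        for h in hits
        if h.query_coverage > cfg.strict_coverage
        and h.evalue < cfg.strict_evalue
        and h.identity > cfg.strict_identity
    ]


def screen_queries(
    hits: Sequence[HitRecord],
    erv_class: str,
    cfg: ScreenConfig = ScreenConfig(),
    strict: bool = False,
) -> tuple[set[str], list[HitRecord]]:
    """Full screening composition: admit → length → reciprocal exclusion.

    Queries whose hits are all removed by admission or the length filter
    simply drop out; the reciprocal rule is applied to the surviving hits of
    each remaining query. With ``strict`` the strict mining cut-offs are
    applied to the surviving hits at the end. Returns the kept query ids and
    their surviving hits.
    """
    surviving = length_filter(admit_hits(hits, cfg), erv_class, cfg)
    grouped = group_by_query(surviving)
    kept, _discarded = reciprocal_exclude(grouped)
    out = [h for h in surviving if h.query_id in kept]
    if strict:
        out = strict_filter(out, cfg)
        kept = {h.query_id for h in out}
    return kept, out


def group_by_query(hits: Iterable[HitRecord]) -> dict[str, list[HitRecord]]:
    """Group a flat hit list into the per-query mapping reciprocal_exclude takes."""
    out: dict[str, list[HitRecord]] = {}
    for h in hits:
        out.setdefault(h.query_id, []).append(h)
    return out


# -- tabular I/O -------------------------------------------------------

_HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "subject_category",
    "evalue",
    "query_coverage",
    "identity",
    "aln_start",
    "aln_end",
]

# standard 12-column tabular search output, extended with query coverage
# and the subject category needed for reciprocal exclusion
_BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qcovs",
    "subject_category",
]


def read_hit_table(path: Union[str, Path]) -> list[HitRecord]:
    """Read the package's native hit-table TSV (header = HitRecord fields)."""
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "subject_id": str})
    missing = [c for c in _HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"hit table missing columns: {missing}")
    return [
        HitRecord(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            subject_category=str(r.subject_category),
            evalue=float(r.evalue),
            query_coverage=float(r.query_coverage),
            identity=float(r.identity),
            aln_start=int(r.aln_start),
            aln_end=int(r.aln_end),
        )
        for r in df.itertuples(index=False)
    ]


def write_hit_table(hits: Sequence[HitRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame([{c: getattr(h, c) for c in _HIT_COLUMNS} for h in hits],
                      columns=_HIT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def hits_from_blast6(path: Union[str, Path]) -> list[HitRecord]:
    """Ingest extended 14-column tabular search output into HitRecords.

    Columns: the standard 12 (qseqid .. bitscore) plus ``qcovs`` and
    ``subject_category``. Subject coordinates (sstart/send) are taken as the
    alignment span on the reference Pol; reversed spans are normalized.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_BLAST6_COLUMNS, comment="#")
    records = []
    for r in df.itertuples(index=False):
        s, e = int(r.sstart), int(r.send)
        if s > e:
            s, e = e, s
        records.append(
            HitRecord(
                query_id=str(r.qseqid),
                subject_id=str(r.sseqid),
                subject_category=str(r.subject_category),
                evalue=float(r.evalue),
                query_coverage=float(r.qcovs),
                identity=float(r.pident),
                aln_start=s,
                aln_end=e,
            )
        )
    return records
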
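"""Synthetic data with known ground truth.

Three generators feed the validation suite:

* :func:`simulate_clade` — a birth–death tree whose lineages carry a host
  group that switches as a continuous-time Markov jump process (uniform
  destination among the other groups). Output is a host-annotated,
  support-annotated tree plus a :class:`SwitchTruth` ledger of every switch
  event, the ground truth for transmission-pattern validation.
* :func:`simulate_hit_table` — homology-hit tables with planted true
  positives and decoys that each violate exactly one screening rule
  (including exact boundary values), the ground truth for the screening
  composition.
* :func:`simulate_reference_tree` — ERV tips planted inside homogeneous
  gamma/beta reference clades, with an optional fraction planted between
  the classes ("blurred"), the ground truth for class assignment.

All randomness flows through a single integer seed; equal seeds give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from ervphylo.screening import HitRecord, ScreenConfig
from ervphylo.treeio import AnnotatedTree, HostTable, ValidationError, quote_label

__all__ = [
    "SimConfig",
    "SwitchEvent",
    "SwitchTruth",
    "SimulationError",
    "default_host_table",
    "default_host_groups",
    "simulate_clade",
    "simulate_hit_table",
    "simulate_reference_tree",
    "replay_tip_hosts",
]


class SimulationError(ValidationError):
    """Raised when a conditioned simulation fails to converge."""


# -- host metadata ------------------------------------------------------

# Synthetic host panel mirroring the study's sampling depth: 10 bats,
# 12 rodents, 8 carnivorans, 6 even-toed ungulates, 5 primates, 4 cetaceans.
# Copy numbers are synthetic stand-ins chosen so that rodents carry roughly
# 2x the Class I and 14x the Class II copies of bats.
_HOST_PANEL: list[tuple[str, str, str, int, int]] = (
    [(f"bat{i:02d}", fam, "Chiroptera", 900 + 20 * i, 180 + 5 * i)
     for i, fam in enumerate(
         ["Pteropodidae", "Pteropodidae", "Pteropodidae",
          "Vespertilionidae", "Vespertilionidae", "Vespertilionidae", "Vespertilionidae",
          "Rhinolophidae", "Megadermatidae", "Mormoopidae"], start=1)]
    + [(f"rodent{i:02d}", fam, "Rodentia", 1900 + 30 * i, 2700 + 40 * i)
       for i, fam in enumerate(
           ["Muridae", "Muridae", "Cricetidae", "Cricetidae",
            "Sciuridae", "Sciuridae", "Caviidae", "Caviidae",
            "Dipodidae", "Spalacidae", "Heterocephalidae", "Castoridae"], start=1)]
    + [(f"carnivore{i:02d}", fam, "Carnivora", 700 + 25 * i, 500 + 15 * i)
       for i, fam in enumerate(
           ["Felidae", "Felidae", "Canidae", "Canidae",
            "Mustelidae", "Ursidae", "Phocidae", "Ailuridae"], start=1)]
    + [(f"ungulate{i:02d}", fam, "Artiodactyla", 1100 + 25 * i, 600 + 20 * i)
       for i, fam in enumerate(
           ["Bovidae", "Bovidae", "Suidae", "Camelidae", "Cervidae", "Giraffidae"], start=1)]
    + [(f"primate{i:02d}", fam, "Primates", 800 + 20 * i, 900 + 30 * i)
       for i, fam in enumerate(
           ["Hominidae", "Hominidae", "Cercopithecidae", "Cercopithecidae", "Lemuridae"],
           start=1)]
    + [(f"cetacean{i:02d}", fam, "Cetacea", 600 + 20 * i, 400 + 10 * i)
       for i, fam in enumerate(
           ["Delphinidae", "Delphinidae", "Balaenopteridae", "Physeteridae"], start=1)]
)


def default_host_table() -> HostTable:
    """The synthetic host panel (species, family, group, copy numbers)."""
    return HostTable.from_records(_HOST_PANEL)


def default_host_groups() -> dict[str, tuple[str, ...]]:
    """Group → species tuple mapping derived from the default host panel."""
    table = default_host_table()
    return {g: tuple(table.species_of_group(g)) for g in sorted(table.groups)}


# -- birth–death host-switch simulator ---------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the birth–death + host-switch clade simulator.

    Rates are per lineage per unit time. ``n_tips_target`` stops the process
    at a fixed extant tip count (conditioned on survival by rejection
    sampling with at most ``max_restarts`` restarts).
    """

    birth_rate: float = 1.0
    death_rate: float = 0.0
    switch_rate: float = 0.1
    host_groups: Optional[Mapping[str, Sequence[str]]] = None
    n_tips_target: int = 8
    support_mean: float = 0.95
    support_noise: float = 0.05
    origin_group: Optional[str] = None
    seed: int = 0
    max_restarts: int = 1000

    def __post_init__(self):
        if self.birth_rate <= 0 or self.death_rate < 0 or self.switch_rate < 0:
            raise ValidationError("rates must satisfy birth > 0, death >= 0, switch >= 0")
        if not all(np.isfinite([self.birth_rate, self.death_rate, self.switch_rate])):
            raise ValidationError("rates must be finite")
        if self.n_tips_target < 3:
            raise ValidationError("n_tips_target must be >= 3")

    def groups(self) -> dict[str, tuple[str, ...]]:
        if self.host_groups is None:
            return default_host_groups()
        return {g: tuple(sp) for g, sp in self.host_groups.items()}


@dataclass(frozen=True)
class SwitchEvent:
    """One host switch: at ``time`` the lineage ``edge_id`` jumped groups."""

    time: float
    edge_id: int
    donor_group: str
    recipient_group: str


@dataclass(frozen=True)
class SwitchTruth:
    """Ground-truth ledger of the host-switch process.

    ``parent`` is the complete lineage genealogy (lineage id → parent id,
    root = 0) and ``tip_lineages`` maps each ERV tip id to its lineage, so
    tip host labels can be replayed independently from the events alone.
    """

    origin_group: str
    events: tuple[SwitchEvent, ...]
    parent: dict[int, int]
    tip_lineages: dict[str, int]
    tip_species: dict[str, str]


@dataclass
class _Lineage:
    lid: int
    parent: Optional[int]
    birth_time: float
    host: str
    end_time: Optional[float] = None
    children: tuple[int, int] | None = None
    extinct: bool = False


def simulate_clade(
    cfg: SimConfig, until_time: Optional[float] = None
) -> tuple[AnnotatedTree, SwitchTruth]:
    """Simulate one host-annotated clade with its switch ledger.

    By default the process runs until ``cfg.n_tips_target`` extant lineages
    exist; with ``until_time`` it runs to that fixed time instead (still
    conditioned on survival). With ``switch_rate`` 0 every tip inherits the
    origin group and the ledger is empty.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = cfg.groups()
    if not groups:
        raise ValidationError("host_groups must be non-empty")
    names = sorted(groups)
    origin = cfg.origin_group if cfg.origin_group is not None else names[0]
    if origin not in groups:
        raise ValidationError(f"origin_group {origin!r} not among host groups")

    for _ in range(cfg.max_restarts):
        result = _run_once(cfg, rng, origin, names, until_time)
        if result is not None:
            lineages, events, t_stop = result
            return _build_outputs(cfg, rng, groups, origin, lineages, events, t_stop)
    raise SimulationError(
        f"no surviving clade after {cfg.max_restarts} restarts "
        f"(birth {cfg.birth_rate}, death {cfg.death_rate})"
    )


def _run_once(cfg, rng, origin, names, until_time):
    lineages: dict[int, _Lineage] = {0: _Lineage(0, None, 0.0, origin)}
    active: list[int] = [0]
    events: list[SwitchEvent] = []
    next_id = 1
    t = 0.0
    per_lineage = cfg.birth_rate + cfg.death_rate + cfg.switch_rate

    while True:
        if until_time is None and len(active) >= cfg.n_tips_target:
            break
        if not active:
            return None  # extinct — reject and restart
        total = len(active) * per_lineage
        t_next = t + rng.exponential(1.0 / total)
        if until_time is not None and t_next > until_time:
            t = until_time
            break
        t = t_next
        lid = active[rng.integers(len(active))]
        lin = lineages[lid]
        u = rng.random() * per_lineage
        if u < cfg.birth_rate:
            lin.end_time = t
            kids = (next_id, next_id + 1)
            for k in kids:
                lineages[k] = _Lineage(k, lid, t, lin.host)
            lin.children = kids
            active.remove(lid)
            active.extend(kids)
            next_id += 2
        elif u < cfg.birth_rate + cfg.death_rate:
            lin.end_time = t
            lin.extinct = True
            active.remove(lid)
        else:
            others = [g for g in names if g != lin.host]
            if others:
                new_host = others[rng.integers(len(others))]
                events.append(SwitchEvent(t, lid, lin.host, new_host))
                lin.host = new_host
    for lid in active:
        lineages[lid].end_time = t
    return lineages, events, t


def _build_outputs(cfg, rng, groups, origin, lineages, events, t_stop):
    # prune extinct subtrees bottom-up
    def alive(lid: int) -> bool:
        lin = lineages[lid]
        if lin.children is None:
            return not lin.extinct
        return any(alive(c) for c in lin.children)

    species_pool = groups
    tip_lineages: dict[str, int] = {}
    tip_species: dict[str, str] = {}

    def newick(lid: int, stem: float) -> str:
        lin = lineages[lid]
        length = (lin.end_time - lin.birth_time) + stem
        if lin.children is not None:
            kids = [c for c in lin.children if alive(c)]
            if len(kids) == 2:
                inner = ",".join(newick(c, 0.0) for c in kids)
                support = float(np.clip(
                    rng.normal(cfg.support_mean, cfg.support_noise), 0.0, 1.0))
                return f"({inner}){support:.3f}:{length:.6f}"
            # one surviving child: suppress this unifurcation
            return newick(kids[0], length)
        pool = species_pool[lin.host]
        species = pool[rng.integers(len(pool))]
        erv_id = f"e{lin.lid}"
        tip_lineages[erv_id] = lin.lid
        tip_species[erv_id] = species
        return f"{species}|{erv_id}:{length:.6f}"

    if not alive(0):
        raise SimulationError("internal error: pruning an extinct clade")
    text = newick(0, 0.0) + ";"
    host_table = default_host_table() if cfg.host_groups is None else _panel_subset(groups)
    tree = AnnotatedTree.from_newick(text, host_table)
    truth = SwitchTruth(
        origin_group=origin,
        events=tuple(events),
        parent={l.lid: l.parent for l in lineages.values() if l.parent is not None},
        tip_lineages=tip_lineages,
        tip_species=tip_species,
    )
    return tree, truth


def _panel_subset(groups: Mapping[str, Sequence[str]]) -> HostTable:
    """Host table covering custom group→species mappings (synthetic copies)."""
    records = []
    for g in sorted(groups):
        for sp in groups[g]:
            records.append((sp, f"{g}_fam", g, 1000, 1000))
    return HostTable.from_records(records)


def replay_tip_hosts(truth: SwitchTruth) -> dict[str, str]:
    """Recompute each tip's host group from the ledger alone.

    Walks every tip's lineage chain back to the root and applies the
    recorded switch events in time order — the consistency check that the
    emitted tip labels and the ledger agree.
    """
    events_by_lineage: dict[int, list[SwitchEvent]] = {}
    for ev in truth.events:
        events_by_lineage.setdefault(ev.edge_id, []).append(ev)
    out: dict[str, str] = {}
    for erv_id, lid in truth.tip_lineages.items():
        chain = [lid]
        while chain[-1] in truth.parent:
            chain.append(truth.parent[chain[-1]])
        host = truth.origin_group
        for anc in reversed(chain):
            for ev in sorted(events_by_lineage.get(anc, []), key=lambda e: e.time):
                host = ev.recipient_group
        out[erv_id] = host
    return out


def pattern_recovery_study(
    n_clades: int = 500,
    n_tips: int = 5,
    switch_rate: float = 0.1,
    origin_group: str = "Rodentia",
    seed: int = 0,
    collapse_first: bool = True,
) -> dict:
    """Single-switch transmission-pattern recovery study.

    Simulates clades until ``n_clades`` of them contain exactly one host
    switch whose recipient group survives to the tips, collapses same-host
    clades (as the analysis workflow does before reading patterns), then
    classifies each clade with the recipient group focal. Returns the
    outcome frequencies: the fraction classified ``received_by`` (the
    planted direction), the other patterns, and the abstention rate
    (pattern ``none``).

    Clades are 5 tips by default — the scale of the depicted transmission
    cartoons. A uniformly placed single switch often leaves the recipient
    lineage basal or astride position classes, so abstention is common;
    recovery is judged among the committed pattern calls.
    """
    from ervphylo.collapse import CollapseConfig, collapse_tree
    from ervphylo.patterns import classify_clade

    host_table = default_host_table()
    ccfg = CollapseConfig()
    counts: dict[str, int] = {}
    made = 0
    sub_seed = int(seed) % (2**31 - 1)
    attempts = 0
    max_attempts = 200 * n_clades
    while made < n_clades:
        attempts += 1
        if attempts > max_attempts:
            raise SimulationError("single-switch clade conditioning did not converge")
        cfg = SimConfig(
            n_tips_target=n_tips,
            switch_rate=switch_rate,
            origin_group=origin_group,
            seed=sub_seed,
        )
        sub_seed = (sub_seed + 1) % (2**31 - 1)
        tree, truth = simulate_clade(cfg)
        if len(truth.events) != 1:
            continue
        recipient = truth.events[0].recipient_group
        groups = {
            host_table.group_of(tree.tip_info(l).species_id) for l in tree.erv_leaves()
        }
        if recipient not in groups or len(groups) != 2:
            continue  # the switched lineage went extinct or swept the clade
        made += 1
        if collapse_first:
            tree = collapse_tree(tree, host_table, ccfg)
        call = classify_clade(tree, recipient, host_table)
        counts[call.pattern] = counts.get(call.pattern, 0) + 1
    committed = {p: c for p, c in counts.items() if p != "none"}
    modal = max(committed, key=committed.get) if committed else "none"
    return {
        "n_clades": made,
        "counts": counts,
        "frequencies": {p: c / made for p, c in counts.items()},
        "received_by_frequency": counts.get("received_by", 0) / made,
        "abstention_frequency": counts.get("none", 0) / made,
        "modal_committed_pattern": modal,
    }


# -- planted hit tables -------------------------------------------------


def simulate_hit_table(
    n_true: int,
    n_host_decoys: int,
    cfg: ScreenConfig = ScreenConfig(),
    seed: int = 0,
    erv_class: str = "class1",
) -> tuple[list[HitRecord], set[str]]:
    """Plant ``n_true`` passing queries and ``n_host_decoys`` failing ones.

    True queries pass the full admit → length → reciprocal composition
    (some deliberately carry a *secondary* host-protein hit, exercising the
    reciprocal rule). Decoys cycle through failure modes: best hit is a host
    protein, E-value at/above the admission cut-off (including exactly the
    cut-off), alignment one residue short of the class minimum, and
    alignment extending outside the class window. Returns the flat hit list
    and the planted-pass query-id set.
    """
    if n_true < 0 or n_host_decoys < 0:
        raise ValidationError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = cfg.window(erv_class)
    min_len = cfg.min_len(erv_class)
    hits: list[HitRecord] = []
    truth: set[str] = set()

    def span(extra: int = 0) -> tuple[int, int]:
        # alignment of length min_len + extra placed inside the window
        length = min(min_len + extra, hi - lo + 1)
        start = int(rng.integers(lo, hi - length + 2))
        return start, start + length - 1

    def loge() -> float:
        return 10.0 ** -float(rng.uniform(20, 180))

    for i in range(n_true):
        q = f"T{i:03d}"
        truth.add(q)
        s, e = span(int(rng.integers(0, hi - lo + 2 - min_len)))
        best = loge()
        hits.append(HitRecord(q, f"retro_{i}", "retroviral", best,
                              float(rng.uniform(50, 100)), float(rng.uniform(30, 95)), s, e))
        if i % 2 == 0:
            # a worse host-protein hit must not trip the reciprocal rule
            hits.append(HitRecord(q, f"hostp_{i}", "host_protein", best * 10.0,
                                  float(rng.uniform(50, 100)), float(rng.uniform(30, 95)), s, e))

    for i in range(n_host_decoys):
        q = f"D{i:03d}"
        mode = i % 4
        if mode == 0:  # reciprocal false positive: best hit is a host protein
            s, e = span()
            best = loge()
            hits.append(HitRecord(q, f"hostp_d{i}", "host_protein", best,
                                  80.0, 70.0, s, e))
            hits.append(HitRecord(q, f"retro_d{i}", "retroviral", best * 100.0,
                                  80.0, 70.0, s, e))
        elif mode == 1:  # fails admission; i == 1 sits exactly at the cut-off
            s, e = span(0)
            ev = cfg.admit_evalue if i == 1 else float(cfg.admit_evalue * rng.uniform(1, 1e3))
            hits.append(HitRecord(q, f"retro_d{i}", "retroviral", ev, 80.0, 70.0, s, e))
        elif mode == 2:  # one residue short of the class minimum length
            start = lo
            hits.append(HitRecord(q, f"retro_d{i}", "retroviral", loge(),
                                  80.0, 70.0, start, start + min_len - 2))
        else:  # extends outside the class window
            if lo > 1:
                s, e = lo - 1, lo - 1 + min_len
            else:
                s, e = hi - min_len, hi + 1
            hits.append(HitRecord(q, f"retro_d{i}", "retroviral", loge(),
                                  80.0, 70.0, s, e))
    return hits, truth


# -- planted reference trees --------------------------------------------


def simulate_reference_tree(
    n_erv: int,
    classes: Sequence[str] = ("gamma", "beta"),
    seed: int = 0,
    blurred_fraction: float = 0.0,
    n_refs_per_class: int = 3,
) -> tuple[AnnotatedTree, dict[str, str]]:
    """Plant ERV tips inside homogeneous reference clades.

    Builds a rooted tree with an epsilonretrovirus outgroup and one clade of
    ``n_refs_per_class`` references per anchoring class; each non-blurred
    ERV is inserted into one class clade (intended class recorded), and a
    ``blurred_fraction`` of ERVs is planted between the class clades so
    their smallest reference-containing clade mixes classes (intended
    "unassigned"). Returns the tree and the erv_id → intended-class map.
    """
    if n_erv < 1:
        raise ValidationError("n_erv must be >= 1")
    allowed = {"gamma": "class1", "beta": "class2"}
    if any(c not in allowed for c in classes):
        raise ValidationError(f"classes must be among {sorted(allowed)}")
    rng = np.random.default_rng(seed)
    host_table = default_host_table()
    species = host_table.species

    n_blurred = int(round(blurred_fraction * n_erv))
    n_assigned = n_erv - n_blurred
    truth: dict[str, str] = {}

    def erv_label(idx: int) -> str:
        sp = species[rng.integers(len(species))]
        return f"{sp}|erv{idx:03d}"

    def join_random(items: list[str]) -> str:
        items = list(items)
        while len(items) > 1:
            i = int(rng.integers(len(items)))
            a = items.pop(i)
            j = int(rng.integers(len(items)))
            b = items.pop(j)
            support = float(np.clip(rng.normal(0.95, 0.03), 0.0, 1.0))
            items.append(f"({a}:0.1,{b}:0.1){support:.3f}")
        return items[0]

    idx = 0
    class_clades = []
    for k, ref_class in enumerate(classes):
        members = [quote_label(f"REF:{ref_class}:{ref_class.upper()}REF{j}")
                   for j in range(n_refs_per_class)]
        for _ in range(n_assigned // len(classes) + (1 if k < n_assigned % len(classes) else 0)):
            label = erv_label(idx)
            truth[label.split("|", 1)[1]] = allowed[ref_class]
            members.append(label)
            idx += 1
        class_clades.append(join_random(members))

    core = join_random(class_clades) if len(class_clades) > 1 else class_clades[0]
    for _ in range(n_blurred):
        label = erv_label(idx)
        truth[label.split("|", 1)[1]] = "unassigned"
        support = float(np.clip(rng.normal(0.95, 0.03), 0.0, 1.0))
        core = f"({label}:0.1,{core}:0.1){support:.3f}"
        idx += 1
    outgroup = quote_label("REF:epsilon:WDSV")
    text = f"({outgroup}:0.2,{core}:0.1);"
    return AnnotatedTree.from_newick(text, host_table), truth
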
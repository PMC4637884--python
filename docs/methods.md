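# Methods

This note records the models and procedures the package implements, the
parameters that matter, the design choices made where the published
description left the design open, and what the synthetic-data validation
does and does not establish.

## Data model

Trees are rooted phylogenies in Newick with node supports stored as
internal-node labels (the FastTree dialect for Shimodaira–Hasegawa test
values). Supports must lie in [0, 1]; out-of-range values are rejected
rather than rescaled, because silent rescaling would hide unit confusion
(e.g. percent bootstrap vs SH proportion). Tip labels carry the host
binding: `<species_id>|<erv_id>` for ERV tips, `REF:<class>:<name>` for
exogenous reference or outgroup taxa (class one of gamma, beta, epsilon,
alpha, other), and `<species_or_family>|COLLAPSED:n=<k>` for collapsed
lineages. Every species token must resolve in a host table mapping species →
family → host group with per-class ERV copy numbers. Multifurcations are
accepted and preserved. Supports are kept as their original label strings so
a read–write cycle preserves printed precision, and a write–read–write cycle
is byte-identical.

## Screening

Filters act on tabular homology-hit records, not sequences; running the
search tools themselves is out of scope. Thresholds (defaults in
`ScreenConfig`):

| parameter | default | semantics |
|---|---|---|
| admission E-value | 1e-5 | strict `<` (a hit at exactly 1e-5 is removed) |
| Class I Pol window | 85–971 (1-based, inclusive) | alignment contained in window |
| Class I minimum length | 887 aa | `aln_end − aln_start + 1 ≥ 887` |
| Class II Pol window | 5–741 | as above |
| Class II minimum length | 737 aa | as above |
| strict coverage / E / identity | 80 %, 1e-100, 60 % | all strict inequalities |

Class windows are coordinates on the class reference Pol
(reticuloendotheliosis virus for Class I, Jaagsiekte sheep retrovirus for
Class II). Reciprocal exclusion discards a query whose minimum-E-value hit
is a host protein. When a host and a retroviral subject tie exactly at the
minimum E-value the query is discarded: the cost of admitting one false
positive into a genome-scale phylogeny exceeds the cost of losing one true
candidate, and a tie gives no evidence either way. All filters are
idempotent and per-query decisions depend only on that query's hits.

## Class assignment

The grouping criterion "an ERV belongs with its exogenous counterparts" is
operationalized as the *smallest ancestral clade containing at least one
reference tip*: all references gamma → class1, all beta → class2, anything
else → unassigned. This rule is deterministic, ignores support values, and
reproduces the intended behaviour on planted test trees; a support-weighted
variant was considered and rejected because the admission gate for pattern
analysis already enforces support downstream. Epsilon/alpha references are
legitimate rooting outgroups but never anchor a class; an ERV whose nearest
references are only epsilon/alpha is unassigned. Re-rooting on an outgroup
transfers supports by unrooted bipartition, which is the invariant object a
support value describes; the root node itself carries no support after
re-rooting.

## Collapse

A clade collapses when (i) all its tips are ERV tips of one species — or,
in the family pass, of one family listed in `family_groups` — (ii) the
represented tip count (collapsed tips count by their `n`) is at least
`min_clade_size`, and (iii) the support of the clade's root node (the MRCA
of its tips) is at least `collapse_threshold`. Choices worth stating:

* `min_clade_size` defaults to 2. The published account is internally
  inconsistent (*n* > 2 in prose, *n* ≥ 2 in the figure legend); the legend
  governs the displayed trees, so ≥ 2 is the default and the knob is exposed.
* `collapse_threshold` defaults to 0.70 ("moderate" support); 0.90 ("high")
  is the other published operating point, exposed as `support_high`.
* The gating node is the clade's own root. Attributing the support of the
  stem's parent or child nodes instead would gate on splits that do not
  correspond to the collapsed clade.
* Species-level collapse runs before family-level collapse; the family pass
  operates on the partially collapsed tree and absorbs species-collapsed
  tips. Maximality holds: no collapsed clade is nested inside another
  collapsible one (verified against an exhaustive clade-enumeration oracle).
* A candidate clade with a missing support is skipped and logged — missing
  evidence is not evidence of monophyly, and hard failure would make a
  single unlabeled node poison a genome-scale tree.
* Reference and outgroup tips never collapse.

Collapse conserves the represented ERV tip count and is idempotent.

## Diversity index

`index(s) = positions(s) / copies(s)` with `positions` the number of
post-collapse tips attributed to species *s* (a collapsed clade is one
position). The index is undefined (reported as missing) when the copy
number is zero; a species absent from the tree scores 0.0. Family-collapsed
tips are attributed to no single species and are excluded from per-species
positions — the index is a per-species quantity and splitting a family tip
across members would be arbitrary; compute the index on a species-level
collapse (the default `family_groups=()`) when every position must count.

## Transmission patterns

"Basal / internal / terminal" have no formal published definition; the
package formalizes them by node depth in the rooted clade, chosen because it
reproduces the three published example topologies exactly:

* **basal** — tips on the root-split side with the smaller tip count; a tie
  makes both sides basal (a tie gives no rooting-order information);
* **terminal** — tips at maximal node depth (root = 0);
* **internal** — everything else; a tip qualifying as both basal and
  terminal (a 2-tip clade) counts as basal.

Rules are evaluated in fixed order to prevent double labeling within one
focal group: originated_from (some focal tip basal *and* some focal tip
internal-or-terminal) → transmitted_via (all focal tips internal) →
received_by (all focal tips terminal) → none. The two-sided originated_from
requirement makes the literal 3-tip exclusion `(focal,(nonfocal,nonfocal))`
a theorem rather than a special case, while `(focal,(focal,nonfocal))`
qualifies; `require_nonbasal_focal=False` relaxes the rule to a lone basal
focal tip, in which case only the literal 3-tip topology stays excluded.
Larger focal-basal clades with no second focal tip fall to "none" under the
default rule, consistent with that exclusion. Clade admission — every node
separating tips of different hosts must have support strictly greater than
0.90 (missing support fails) — is exposed separately (`admit_clade`) so
pattern classification itself stays support-free.

## Simulator

`simulate_clade` runs a continuous-time birth–death process (Gillespie
algorithm) conditioned on survival by rejection sampling (restart cap
1,000), with a host-group trait that jumps at `switch_rate` per lineage per
unit time to a uniformly chosen other group. Defaults: birth 1.0 / time
unit, death 0.0, switch 0.1, 8 extant tips. The host panel mirrors the
study's sampling depth (10 bats, 12 rodents, 8 carnivorans, 6 even-toed
ungulates, 5 primates, 4 cetaceans) with synthetic copy numbers chosen so
rodents carry roughly 2× the Class I and 14× the Class II copies of bats.
Tips draw a uniform species within their group; supports draw from a normal
(mean 0.95, sd 0.05) truncated to [0, 1]. Every switch is recorded in a
ledger (time, lineage, donor, recipient) together with the full lineage
genealogy, so tip host labels can be replayed from the ledger alone — the
consistency contract the tests verify. All randomness flows through one
integer seed; equal seeds give byte-identical Newick.

The generator emulates *topology and host labeling only*. It does not
simulate sequences, alignment or tree-estimation error, insertion ages, LTR
structure, copy-number dynamics, or non-uniform switch preferences between
host groups. Passing validation therefore shows the analysis rules behave
correctly on trees whose hosts evolved by the stated process — not that
real trees satisfy the process.

`simulate_hit_table` plants queries that pass the full screening
composition and decoys that each violate exactly one rule, including exact
boundary values (E = 1e-5, alignment one residue short, alignment one
position outside the window). `simulate_reference_tree` plants ERVs inside
homogeneous gamma/beta reference clades, with an optional fraction planted
between the class clades to exercise the "blurred" (unassigned) path.

## Validation problem sizes

The suite checks the pattern classifier exhaustively on every rooted binary
shape with ≤ 6 tips × every focal/non-focal labeling (524 cases) against an
independently written brute-force evaluator, and the collapse operation on
1,000 random trees of ≤ 12 tips against an exhaustive clade-enumeration
oracle. The Yule sanity check compares the mean tip count of 1,000
fixed-time simulations to e^(λT). The single-switch recovery study uses 500
clades of 5 tips (the scale of the published pattern cartoons) at switch
rate 0.1, with species-level collapse applied before classification as in
the analysis workflow. In that study the classifier abstains ("none") on
roughly 6 of 10 clades — a uniformly placed single switch often leaves the
recipient lineage basal or spanning position classes, where the rules
deliberately refuse a call — and among committed calls the planted
direction, received_by, is the modal pattern (frequency ≈ 0.19 of all
clades, with transmitted_via ≈ 0.16 and originated_from 0). The suite
asserts the modality and reports the frequencies rather than asserting a
fixed recovery number.

## Known limitations

* Pattern positions are purely topological; branch lengths and node ages are
  ignored, so a "terminal" tip on a long pendant branch is treated like a
  recent one.
* The class-assignment rule ignores supports; a poorly supported reference
  attachment still anchors a call (the admission gate applies only to
  pattern clades).
* Family-level collapse assumes each family maps to one host group; a
  host table violating that raises an error during pattern classification.
* The diversity index inherits whatever ascertainment bias the copy numbers
  carry; it is a descriptive ratio, not a model-based estimator.
* The simulator's uniform-destination switch process cannot represent
  asymmetric host preferences; recovery frequencies under biased switching
  were not studied.
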
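"""Mate-pair reconciliation: the LCA rule plus strategies SI-SIV.

Upstream binners classify the two mates of a pair independently, so the pair
often ends up with two different taxa.  When the two assignments sit on
different lineages, both mates are moved to their lowest common ancestor.
When they sit on one lineage — one taxon an ancestor of the other — four
reconciliation strategies are available.  Writing Tx for the more specific
(deeper) of the two taxa, Ty for the less specific, and Tx+1 for the taxon one
canonical rank above Tx (clamped so it is never less specific than Ty):

* SI   — both mates take Tx (most specific, trusts the deep assignment);
* SII  — the Tx mate keeps Tx, the Ty mate moves down to Tx+1;
* SIII — both mates take Tx+1;
* SIV  — both mates take Ty (most conservative).

An unassigned mate is modelled as an assignment to the taxonomy root, which
makes a pair with one unassigned mate an ordinary same-lineage pair with
Ty = root: SI rescues the unassigned mate to its partner's taxon, while SIV
discards the pair's information and leaves both unassigned.  Results equal to
the root are reported as unassigned.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import InputError, UsageError
from .taxonomy import TaxonId, TaxonomyTree

#: Sentinel for "no assignment"; interchangeable with assignment-to-root.
ABSENT = None


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    taxon_id: TaxonId | None  # None = unassigned


@dataclass(frozen=True)
class PairAssignment:
    pair_id: str
    x: ReadAssignment
    y: ReadAssignment


class Strategy(enum.Enum):
    SI = "SI"
    SII = "SII"
    SIII = "SIII"
    SIV = "SIV"


class PairRelation(enum.Enum):
    SAME_TAXON = "same_taxon"
    SAME_LINEAGE = "same_lineage"
    DIVERGENT = "divergent"
    ONE_UNASSIGNED = "one_unassigned"
    BOTH_UNASSIGNED = "both_unassigned"


def _effective(tree: TaxonomyTree, taxon_id: TaxonId | None) -> TaxonId:
    """Project an assignment for rank algebra: ABSENT -> root, node -> nearest
    canonically ranked ancestor-or-self."""
    if taxon_id is None:
        return tree.root_id
    return tree.canonical_node(taxon_id)


def classify_pair(tree: TaxonomyTree, pair: PairAssignment) -> PairRelation:
    """Classify the relation between the two mates' assignments."""
    ex = _effective(tree, pair.x.taxon_id)
    ey = _effective(tree, pair.y.taxon_id)
    x_unset = ex == tree.root_id
    y_unset = ey == tree.root_id
    if x_unset and y_unset:
        return PairRelation.BOTH_UNASSIGNED
    if x_unset or y_unset:
        return PairRelation.ONE_UNASSIGNED
    if ex == ey:
        return PairRelation.SAME_TAXON
    if tree.is_ancestor_or_self(ex, ey) or tree.is_ancestor_or_self(ey, ex):
        return PairRelation.SAME_LINEAGE
    return PairRelation.DIVERGENT


def _emit(tree: TaxonomyTree, taxon_id: TaxonId) -> TaxonId | None:
    return None if taxon_id == tree.root_id else taxon_id


def reconcile_pair(
    tree: TaxonomyTree, pair: PairAssignment, strategy: Strategy
) -> PairAssignment:
    """Apply the divergent-lineage LCA rule or the chosen same-lineage strategy.

    Same-taxon and both-unassigned pairs are returned unchanged.  Divergent
    pairs go to the LCA of the two taxa for every strategy.  Same-lineage
    pairs (including one-unassigned, where the absent mate holds the root)
    follow SI-SIV as described in the module docstring.
    """
    if not isinstance(strategy, Strategy):
        raise UsageError(f"unknown strategy {strategy!r}; valid: "
                         + ", ".join(s.value for s in Strategy))
    relation = classify_pair(tree, pair)
    if relation in (PairRelation.SAME_TAXON, PairRelation.BOTH_UNASSIGNED):
        return pair

    ex = _effective(tree, pair.x.taxon_id)
    ey = _effective(tree, pair.y.taxon_id)

    if relation is PairRelation.DIVERGENT:
        anc = tree.lca(ex, ey)
        out = _emit(tree, anc)
        return PairAssignment(
            pair.pair_id,
            ReadAssignment(pair.x.read_id, out),
            ReadAssignment(pair.y.read_id, out),
        )

    # Same lineage (possibly with one mate at the root): orient Tx deep, Ty high.
    if tree.is_ancestor_or_self(ex, ey):
        t_deep, t_high = ey, ex
        deep_is_x = False
    else:
        t_deep, t_high = ex, ey
        deep_is_x = True

    if strategy is Strategy.SI:
        rx = ry = t_deep
    elif strategy is Strategy.SIV:
        rx = ry = t_high
    else:
        t_mid = tree.step_up(t_deep)
        # Clamp: Tx+1 must not be less specific than Ty.
        if tree.canonical_rank(t_mid).ordinal > tree.canonical_rank(t_high).ordinal:
            t_mid = t_high
        if strategy is Strategy.SIII:
            rx = ry = t_mid
        else:  # SII: deep mate keeps Tx, high mate moves to Tx+1
            rx, ry = (t_deep, t_mid) if deep_is_x else (t_mid, t_deep)

    return PairAssignment(
        pair.pair_id,
        ReadAssignment(pair.x.read_id, _emit(tree, rx)),
        ReadAssignment(pair.y.read_id, _emit(tree, ry)),
    )


@dataclass
class ReconciliationReport:
    """Tally of pair relations seen by reconcile_table, plus orphan reads."""

    relation_counts: Counter = field(default_factory=Counter)
    n_pairs: int = 0
    n_orphans: int = 0

    def as_rows(self) -> list[tuple[str, int]]:
        rows = [(rel.value, self.relation_counts.get(rel, 0)) for rel in PairRelation]
        rows.append(("orphan_reads", self.n_orphans))
        return rows


def parse_mate_suffix(read_id: str) -> tuple[str, int] | None:
    """Split '<pair>/1' / '<pair>/2' into (pair_id, mate); None for orphans."""
    if len(read_id) > 2 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2], int(read_id[-1])
    return None


def reconcile_table(
    tree: TaxonomyTree,
    assignments: Sequence[ReadAssignment] | Iterable[ReadAssignment],
    strategy: Strategy,
) -> tuple[list[ReadAssignment], ReconciliationReport]:
    """Reconcile a whole assignment table under the mate-suffix convention.

    Reads pair up via '/1' and '/2' id suffixes; reads whose mate never
    appears (or whose id carries no suffix) pass through unchanged and are
    counted as orphans.  Duplicate read ids are an input error.
    """
    assignments = list(assignments)
    seen: set[str] = set()
    for a in assignments:
        if a.read_id in seen:
            raise InputError(f"duplicate read id {a.read_id!r}")
        seen.add(a.read_id)

    mates: dict[str, dict[int, int]] = {}
    for idx, a in enumerate(assignments):
        parsed = parse_mate_suffix(a.read_id)
        if parsed is not None:
            mates.setdefault(parsed[0], {})[parsed[1]] = idx

    report = ReconciliationReport()
    out: list[ReadAssignment | None] = list(assignments)
    for pair_id, slots in mates.items():
        if len(slots) != 2:
            continue
        pair = PairAssignment(pair_id, assignments[slots[1]], assignments[slots[2]])
        rec = reconcile_pair(tree, pair, strategy)
        report.relation_counts[classify_pair(tree, pair)] += 1
        report.n_pairs += 1
        out[slots[1]] = rec.x
        out[slots[2]] = rec.y
    report.n_orphans = len(assignments) - 2 * report.n_pairs
    return [a for a in out if a is not None], report
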
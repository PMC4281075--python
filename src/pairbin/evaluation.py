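"""Rank-bucketed scoring of taxonomic assignments against truth labels.

An assignment is *correct* when the assigned taxon lies on the truth
organism's lineage (ancestor-or-self).  Correct assignments are bucketed by
how specific they are — genus-and-below, family/order, class/phylum, or
superkingdom — with off-lineage assignments counted as wrong and absent or
root-level assignments as unassigned.  Summaries report per-bucket counts and
percentages (one decimal place) over all reads in the truth table, before and
after reconciliation.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import InputError, UsageError
from .strategies import ReadAssignment
from .taxonomy import Rank, TaxonId, TaxonomyTree


class EvalBucket(enum.Enum):
    GENUS_AND_BELOW = "genus_and_below"
    FAMILY_ORDER = "family_order"
    CLASS_PHYLUM = "class_phylum"
    SUPERKINGDOM = "superkingdom"
    WRONG = "wrong"
    UNASSIGNED = "unassigned"


#: Buckets whose reads are on the truth lineage.
CORRECT_BUCKETS = (
    EvalBucket.GENUS_AND_BELOW,
    EvalBucket.FAMILY_ORDER,
    EvalBucket.CLASS_PHYLUM,
    EvalBucket.SUPERKINGDOM,
)

_RANK_BUCKET = {
    Rank.SPECIES: EvalBucket.GENUS_AND_BELOW,
    Rank.GENUS: EvalBucket.GENUS_AND_BELOW,
    Rank.FAMILY: EvalBucket.FAMILY_ORDER,
    Rank.ORDER: EvalBucket.FAMILY_ORDER,
    Rank.CLASS: EvalBucket.CLASS_PHYLUM,
    Rank.PHYLUM: EvalBucket.CLASS_PHYLUM,
    Rank.SUPERKINGDOM: EvalBucket.SUPERKINGDOM,
}


def judge(tree: TaxonomyTree, assigned: TaxonId | None, truth: TaxonId) -> EvalBucket:
    """Bucket one assignment against the truth organism."""
    tree.lineage(truth)  # truth must resolve
    if assigned is None or assigned == tree.root_id:
        return EvalBucket.UNASSIGNED
    if not tree.is_ancestor_or_self(assigned, truth):
        return EvalBucket.WRONG
    rank = tree.canonical_rank(assigned)
    if rank is Rank.ROOT:
        return EvalBucket.UNASSIGNED
    return _RANK_BUCKET[rank]


@dataclass(frozen=True)
class EvalSummary:
    counts: Mapping[EvalBucket, int]
    total: int

    @property
    def percentages(self) -> dict[EvalBucket, float]:
        if self.total == 0:
            return {b: 0.0 for b in EvalBucket}
        return {b: 100.0 * self.counts.get(b, 0) / self.total for b in EvalBucket}

    @property
    def n_correct(self) -> int:
        return sum(self.counts.get(b, 0) for b in CORRECT_BUCKETS)

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "bucket": [b.value for b in EvalBucket],
                "count": [self.counts.get(b, 0) for b in EvalBucket],
                "percent": [round(pct[b], 1) for b in EvalBucket],
            }
        )

    def __str__(self) -> str:
        lines = [f"{'bucket':<17}{'count':>8}{'percent':>9}"]
        pct = self.percentages
        for b in EvalBucket:
            lines.append(f"{b.value:<17}{self.counts.get(b, 0):>8}{pct[b]:>8.1f}%")
        lines.append(f"{'total':<17}{self.total:>8}")
        return "\n".join(lines)


def summarize(
    tree: TaxonomyTree,
    assignments: Iterable[ReadAssignment],
    truths: Mapping[str, TaxonId],
) -> EvalSummary:
    """Score every read in the truth table.

    Reads present in the truth table but missing from the assignments count
    as unassigned; assignments for read ids absent from the truth table are
    an input error.
    """
    by_read = {}
    for a in assignments:
        by_read[a.read_id] = a.taxon_id
    unknown = [rid for rid in by_read if rid not in truths]
    if unknown:
        shown = ", ".join(sorted(unknown)[:5])
        raise InputError(
            f"{len(unknown)} assignment(s) for read ids absent from truth: {shown}"
        )
    counts: Counter = Counter()
    for read_id, truth_taxon in truths.items():
        counts[judge(tree, by_read.get(read_id), truth_taxon)] += 1
    return EvalSummary(dict(counts), total=len(truths))


def compare(before: EvalSummary, after: EvalSummary) -> pd.DataFrame:
    """Per-bucket absolute and relative change between two summaries.

    The ratio is NaN where the before-count is zero.  Both summaries must
    cover the same number of reads.
    """
    if before.total != after.total:
        raise UsageError(
            f"summaries cover different totals ({before.total} vs {after.total})"
        )
    rows = []
    for b in EvalBucket:
        nb = before.counts.get(b, 0)
        na = after.counts.get(b, 0)
        rows.append(
            {
                "bucket": b.value,
                "before": nb,
                "after": na,
                "delta": na - nb,
                "ratio": (na / nb) if nb else float("nan"),
            }
        )
    return pd.DataFrame(rows)
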
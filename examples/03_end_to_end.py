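"""Full pipeline: simulate -> bin -> reconcile -> evaluate.

Bins simulated short-clone mates independently with a noisy test binner,
then shows how each reconciliation strategy changes the rank-bucketed
accuracy summary relative to the unreconciled assignments.
"""

from pairbin import (
    BinnerConfig,
    EvalBucket,
    SimConfig,
    Strategy,
    assign_reads,
    build_index,
    make_short_clones,
    random_genomes,
    reconcile_table,
    sample_fragments,
    summarize,
)
from pairbin.fixtures import panel_taxonomy

tree, species = panel_taxonomy(20)
genomes = random_genomes(20, 50_000, seed=101, organism_taxon_ids=species)
genome_map = {g.genome_id: g.organism_taxon_id for g in genomes}

config = SimConfig(n_fragments=2_000, seed=101)
pairs = make_short_clones(sample_fragments(genomes, config), config)
reads = [m for p in pairs for m in (p.mate1, p.mate2)]
truths = {r.read_id: r.organism_taxon_id for r in reads}

index = build_index(genomes, k=12)
binner = BinnerConfig(k=12, rank_degrade_prob=0.4)  # noisy, rank-varying binner
assignments = assign_reads(index, tree, genome_map, reads, binner, seed=101)

before = summarize(tree, assignments, truths)
print("before reconciliation:")
print(before)

for strategy in Strategy:
    reconciled, report = reconcile_table(tree, assignments, strategy)
    after = summarize(tree, reconciled, truths)
    pct = after.percentages
    print(f"\n{strategy.value}: correct {after.n_correct}/{after.total} "
          f"(specific {pct[EvalBucket.GENUS_AND_BELOW]:.1f}%, "
          f"unassigned {pct[EvalBucket.UNASSIGNED]:.1f}%, "
          f"wrong {pct[EvalBucket.WRONG]:.1f}%)")

print(
    "\nSI recovers the most specific correct assignments (it rescues pairs\n"
    "with one unassigned or shallow mate); SII/SIII trade some specificity\n"
    "for caution; SIV is most conservative and leaves the most reads\n"
    "unassigned whenever one mate carried no information."
)
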
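# Methods

## Rank algebra

All logic runs over the seven-rank canonical ladder (species, genus, family,
order, class, phylum, superkingdom) plus the tree root, ordered by an integer
ordinal with species = 0 (most specific) and root = 7. Real taxonomies
contain nodes outside this ladder (strains, subspecies, "no rank" clades);
these are kept in the tree but are transparent to rank logic: every
assignment is first projected to its nearest canonically ranked ancestor, and
`step_up` (the T<sub>x+1</sub> operator) climbs to the next canonical rank
*present on the lineage*, skipping gaps, returning the root when no canonical
ancestor remains. Lineages are cached per tree, making LCA a linear zip of
two root-to-node paths — adequate for taxonomies of millions of nodes since
paths are at most tens of nodes deep.

The root doubles as the representation of "unassigned": an absent assignment
enters the algebra as the root and any result equal to the root leaves it as
unassigned. This single convention yields both the LCA-to-root behaviour for
maximally divergent pairs and the strategy behaviour for half-assigned pairs
(SI rescues the lost mate; SIV loses the pair) without special cases.

## Reconciliation semantics

A pair is classified as same-taxon, same-lineage, divergent, one-unassigned
or both-unassigned after canonical projection. Divergent pairs take the LCA
under *every* strategy — the LCA rule is prior to, and independent of, the
strategy choice. Same-lineage pairs follow SI–SIV with T<sub>x</sub>/
T<sub>y</sub> determined by projected rank; T<sub>x+1</sub> is clamped to
T<sub>y</sub> whenever one canonical step would overshoot it, so SII and SIII
degenerate to SIV for adjacent-rank pairs. Ties after projection are
same-taxon and pass through unchanged. These rules give four provable
invariants, enforced in the test suite by exhaustive enumeration against an
independent brute-force implementation: specificity is monotone from SI to
SIV, outputs never exceed the specificity of the deeper input (containment),
two on-lineage ("correct") inputs can never be reconciled into an off-lineage
output, and every strategy is idempotent.

Batch reconciliation pairs reads by the `/1`–`/2` id suffix convention;
orphan reads pass through unchanged and are counted, and each run reports a
tally of pair relations.

## Simulator

The simulator emulates a benchmark design in which a simulated microbiome is
assembled by drawing DNA fragments in equal proportions from a panel of
reference genomes (floor division with the remainder to the first genomes in
input order, so per-genome counts never differ by more than one). Defaults
are 20,000 fragments of exactly 400 bp; fragment length is fixed rather than
drawn from a distribution because only an approximate average is specified —
a ±10 % uniform jitter option exists but is off by default. Short-clone
pairs are the two 150 bp end-slices of each fragment; long-clone pairs keep
the fragment's first 150 bp and place the mate so the outer span (mate 1
start to mate 2 end) is uniform on [2000, 5000] bp. Mate 2 is always
reverse-complemented (FR orientation, the Illumina paired-end convention).
When a long-clone mate would overrun the genome's 3′ end the pair is mirrored
upstream; pairs that fit in neither direction are skipped with a warning
(with the default 100 kbp synthetic genomes this does not occur).

Sequencing error is substitution-only at 0.01 per base by default, with the
replacement base drawn uniformly from the three alternatives — never the
original — so the configured rate is exactly the expected mismatch rate
against the source, which makes rate recovery a sharp binomial test. `N`
positions are left untouched. Mates are mutated independently rather than
inheriting the parent fragment's mutations, on the reasoning that each
sequencing read carries its own errors; `simulate_all` therefore derives all
three read sets from one *unmutated* fragment draw. Coordinates are 0-based
half-open on the forward strand. Each dataset draws from its own named
random stream derived from (seed, stream-id), so datasets are individually
and jointly byte-reproducible under a fixed seed.

The synthetic genomes are i.i.d. base sequences at a configurable GC
fraction. They have no repeats, no shared homology and no compositional
structure, so k-mer classification on them is far easier than on real
genomes: passing end-to-end tests demonstrates the reconciliation mechanics
and the directional behaviour of the strategies, not classifier performance
on real data.

## Evaluation

An assignment is correct when it lies on the truth organism's lineage
(ancestor-or-self); correct assignments are bucketed by the canonical rank of
the assigned taxon (genus-and-below, family/order, class/phylum), off-lineage
assignments are wrong, and absent/root assignments are unassigned. Correct
superkingdom-level assignments get their own bucket rather than being folded
into a neighbouring one, since the conventional summary grain stops at
class/phylum and leaves their treatment open. Percentages are reported to
one decimal place. Reads present in the truth table but missing from the
assignment table count as unassigned; assignments for unknown reads are an
error rather than being ignored.

## Test binner

The shared-k-mer binner exists so the pipeline is exercisable end-to-end
without external classifiers; it is explicitly not part of the method and not
a competitive tool. It scores genomes by shared canonical 12-mers, assigns
the top genome's organism when the runner-up trails by a relative margin
(default 0.2), otherwise the LCA of all near-tied genomes, and leaves zero-hit
reads unassigned. Its `rank_degrade_prob` knob moves a finished assignment
up the canonical ladder geometrically — each step taken with the given
probability — so raising it simultaneously produces shallower assignments and
(rarely) fully unassigned reads, the exact mixture of rank-varying mate
assignments the reconciliation strategies exist to repair. The geometric
form was chosen over a single-step move because a single step from
species-level assignments can never reach the root, and the degradation is
meant to cover the unassigned case too.

## Problem sizes and numerical choices

Exhaustive rule checks enumerate all 17 × 17 assignment pairs (16 toy-taxonomy
nodes plus absent) for all four strategies. LCA is validated on 100 random
rank-consistent trees of up to 200 nodes over all node pairs. The end-to-end
directional check uses 20 synthetic genomes of 50 kbp, 2,000 short-clone
pairs and degradation probability 0.4; the simulator fidelity check runs the
full default scale (20 genomes × 100 kbp, 20,000 of each read set, 20 Mbp of
sequence). Mutation-rate recovery is accepted within three binomial standard
deviations. Binner score ties are broken lexicographically by genome id to
keep runs reproducible.

## Limitations

The reconciliation quality on real data depends entirely on the upstream
binner's error profile; the harness quantifies the mechanics on synthetic
reads only and makes no claims about absolute accuracy on real metagenomes.
There is no indel or quality-score error model, no abundance skew beyond
equal proportions, and no handling of NCBI merged/deleted taxon ids (unknown
ids are rejected). Strategy choice is per run; no per-pair adaptive
selection is attempted.
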
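"""Shared k-mer test binner.

This is deliberately simple test scaffolding, not a competitive classifier:
it assigns each read to the organism of the genome sharing the most canonical
k-mers, falling back to the LCA of near-tied genomes, and can optionally
degrade assignments up the rank ladder at random.  Its purpose is to produce
the kind of noisy, rank-varying per-mate assignments that pair reconciliation
is designed to repair, so the full simulate -> bin -> reconcile -> evaluate
pipeline is exercisable end-to-end with zero external tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .simulator import Genome, SimulatedRead, revcomp
from .strategies import ReadAssignment
from .taxonomy import TaxonId, TaxonomyTree

logger = logging.getLogger(__name__)


@dataclass
class BinnerConfig:
    k: int = 12
    margin: float = 0.2  # relative score margin for the LCA fallback
    rank_degrade_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.margin <= 1.0:
            raise ConfigurationError("margin must lie in [0, 1]")
        if not 0.0 <= self.rank_degrade_prob <= 1.0:
            raise ConfigurationError("rank_degrade_prob must lie in [0, 1]")


@dataclass
class KmerIndex:
    k: int
    postings: dict[str, set[str]] = field(default_factory=dict)


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def build_index(genomes: Sequence[Genome], k: int = 12) -> KmerIndex:
    """Index the canonical k-mers of every genome."""
    if k < 4:
        raise ConfigurationError("k must be >= 4")
    if not genomes:
        raise ConfigurationError("cannot index an empty genome list")
    shortest = min(len(g.sequence) for g in genomes)
    if k > shortest:
        raise ConfigurationError(
            f"k={k} exceeds shortest genome length ({shortest} bp)"
        )
    index = KmerIndex(k=k)
    postings = index.postings
    for g in genomes:
        seq = g.sequence
        gid = g.genome_id
        for i in range(len(seq) - k + 1):
            key = canonical_kmer(seq[i : i + k])
            postings.setdefault(key, set()).add(gid)
    return index


def _degrade(tree: TaxonomyTree, taxon: TaxonId, prob: float,
             rng: np.random.Generator) -> TaxonId | None:
    """Climb the canonical ladder geometrically: each step taken with ``prob``."""
    current = taxon
    while current != tree.root_id and rng.random() < prob:
        current = tree.step_up(current)
    return None if current == tree.root_id else current


def assign_read(
    index: KmerIndex,
    tree: TaxonomyTree,
    genome_map: Mapping[str, TaxonId],
    read: SimulatedRead,
    config: BinnerConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ReadAssignment:
    """Assign one read by shared canonical k-mer counts.

    A clear winner (runner-up below (1 - margin) x top) takes its genome's
    organism taxon; near-ties take the LCA of all genomes within the margin;
    zero hits yield an unassigned read.  With rank_degrade_prob > 0 the final
    assignment is randomly moved up the canonical ladder (see module doc).
    """
    config = config or BinnerConfig(k=index.k)
    if len(read.sequence) < index.k:
        logger.warning("read %s shorter than k=%d; left unassigned",
                       read.read_id, index.k)
        return ReadAssignment(read.read_id, None)
    scores: dict[str, int] = {}
    seq = read.sequence
    k = index.k
    seen: set[str] = set()
    for i in range(len(seq) - k + 1):
        key = canonical_kmer(seq[i : i + k])
        if key in seen:
            continue
        seen.add(key)
        for gid in index.postings.get(key, ()):
            scores[gid] = scores.get(gid, 0) + 1
    if not scores:
        return ReadAssignment(read.read_id, None)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top_gid, top = ranked[0]
    cutoff = (1.0 - config.margin) * top
    contenders = [gid for gid, s in ranked if s >= cutoff]
    if len(contenders) == 1:
        taxon: TaxonId | None = genome_map[top_gid]
    else:
        taxon = genome_map[contenders[0]]
        for gid in contenders[1:]:
            taxon = tree.lca(taxon, genome_map[gid])
        if taxon == tree.root_id:
            taxon = None
    if taxon is not None and config.rank_degrade_prob > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        taxon = _degrade(tree, taxon, config.rank_degrade_prob, rng)
    return ReadAssignment(read.read_id, taxon)


def assign_reads(
    index: KmerIndex,
    tree: TaxonomyTree,
    genome_map: Mapping[str, TaxonId],
    reads: Sequence[SimulatedRead],
    config: BinnerConfig | None = None,
    seed: int = 0,
) -> list[ReadAssignment]:
    """Assign a batch of reads with one seeded rng for the degradation noise."""
    rng = np.random.default_rng([seed, 97])
    return [assign_read(index, tree, genome_map, r, config, rng) for r in reads]
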
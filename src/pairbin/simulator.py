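"""Simulated validation datasets with per-read truth labels.

Three read sets are generated from a simulated microbiome built by drawing
DNA fragments in equal proportions from a panel of reference genomes:

* long single-end fragments (400 bp by default), emulating a Roche 454-style
  sequencing run;
* "short-clone" mate pairs: two 150 bp reads cut from either end of each
  400 bp parent fragment (FR orientation, mate 2 reverse-complemented);
* "long-clone" mate pairs: one 150 bp read from a parent fragment and its
  mate placed 2-5 kbp away on the source genome.

Sequencing error is a per-base substitution model (1 in 100 bp by default);
a substituted position always receives a different base, so the configured
rate equals the expected observed mismatch rate against the source genome.
Every read carries its truth provenance (organism, genome, 0-based half-open
forward-strand coordinates, strand) for downstream scoring.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, InputError, UsageError
from .taxonomy import TaxonId

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    genome_id: str
    organism_taxon_id: TaxonId
    sequence: str


class CloneType(enum.Enum):
    SHORT = "short"
    LONG = "long"


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; defaults follow the validation design they emulate.

    n_fragments: fragments in the long-read set (each yields one mate pair
    in the clone sets).  fragment_length: parent fragment length in bp.
    mate_length: paired-read length in bp.  long_insert_min/max: outer span
    bounds for long clones in bp.  mutation_rate: per-base substitution
    probability.  length_jitter: optional +/- fraction of uniform length
    variation for fragments (0 = fixed length).
    """

    n_fragments: int = 20_000
    fragment_length: int = 400
    mate_length: int = 150
    long_insert_min: int = 2_000
    long_insert_max: int = 5_000
    mutation_rate: float = 0.01
    seed: int = 0
    equal_proportions: bool = True
    length_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigurationError("mutation_rate must lie in [0, 1]")
        if self.long_insert_min > self.long_insert_max:
            raise ConfigurationError("long_insert_min must be <= long_insert_max")
        if 2 * self.mate_length > self.fragment_length:
            raise ConfigurationError(
                "fragment_length must be >= 2 * mate_length for short clones"
            )
        if not 0.0 <= self.length_jitter < 1.0:
            raise ConfigurationError("length_jitter must lie in [0, 1)")


@dataclass(frozen=True)
class SimulatedRead:
    """A read plus its truth provenance on the forward strand of the source."""

    read_id: str
    sequence: str
    organism_taxon_id: TaxonId
    genome_id: str
    start: int  # 0-based, half-open [start, end)
    end: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class MatePair:
    pair_id: str
    mate1: SimulatedRead
    mate2: SimulatedRead
    clone_type: CloneType
    insert_span: int  # outer distance on the forward strand


# rng stream labels so each dataset draws independent, reproducible randomness
_STREAM_FRAGMENTS = 1
_STREAM_ROCHE = 2
_STREAM_SHORT = 3
_STREAM_LONG = 4
_STREAM_GENOMES = 5


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream])


def mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``rate``.

    A substituted base is drawn uniformly from the three alternatives, never
    the original, so the expected mismatch fraction equals ``rate``.  'N'
    positions are left untouched; characters outside {A,C,G,T,N} are an
    input error.
    """
    if not 0.0 <= rate <= 1.0:
        raise InputError("mutation rate must lie in [0, 1]")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    idx = _BASE_INDEX[arr]
    bad = (idx < 0) & (arr != ord("N"))
    if bad.any():
        pos = int(np.argmax(bad))
        raise InputError(f"invalid base {chr(arr[pos])!r} at position {pos}")
    if rate == 0.0 or arr.size == 0:
        return sequence
    hit = (rng.random(arr.size) < rate) & (idx >= 0)
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        arr[hit] = _BASES[(idx[hit] + shift) % 4]
    return arr.tobytes().decode("ascii")


def _per_genome_counts(n: int, n_genomes: int) -> list[int]:
    base, rem = divmod(n, n_genomes)
    return [base + (1 if i < rem else 0) for i in range(n_genomes)]


def sample_fragments(
    genomes: Sequence[Genome], config: SimConfig
) -> list[SimulatedRead]:
    """Draw unmutated fragments in equal proportions across genomes.

    Each genome contributes floor(n/G) fragments, with the remainder going to
    the first n mod G genomes in input order.  Start positions are uniform
    over the valid range; all fragments are forward-strand.
    """
    if not genomes:
        raise ConfigurationError("no genomes supplied")
    rng = _rng(config.seed, _STREAM_FRAGMENTS)
    counts = (
        _per_genome_counts(config.n_fragments, len(genomes))
        if config.equal_proportions
        else None
    )
    if counts is None:
        picks = rng.integers(0, len(genomes), size=config.n_fragments)
        counts = [int((picks == i).sum()) for i in range(len(genomes))]

    reads: list[SimulatedRead] = []
    serial = 0
    for genome, count in zip(genomes, counts):
        glen = len(genome.sequence)
        max_frag = config.fragment_length
        if config.length_jitter:
            max_frag = int(round(config.fragment_length * (1 + config.length_jitter)))
        if glen < max_frag:
            raise ConfigurationError(
                f"genome {genome.genome_id!r} ({glen} bp) shorter than "
                f"fragment length {max_frag} bp"
            )
        if count == 0:
            continue
        if config.length_jitter:
            lo = int(round(config.fragment_length * (1 - config.length_jitter)))
            lengths = rng.integers(lo, max_frag + 1, size=count)
        else:
            lengths = np.full(count, config.fragment_length, dtype=np.int64)
        for length in lengths:
            length = int(length)
            start = int(rng.integers(0, glen - length + 1))
            reads.append(
                SimulatedRead(
                    read_id=f"frag{serial:05d}",
                    sequence=genome.sequence[start : start + length],
                    organism_taxon_id=genome.organism_taxon_id,
                    genome_id=genome.genome_id,
                    start=start,
                    end=start + length,
                    strand="+",
                )
            )
            serial += 1
    return reads


def make_roche_set(
    genomes: Sequence[Genome], config: SimConfig
) -> list[SimulatedRead]:
    """Long single-end fragment reads (454-style), mutated at mutation_rate."""
    fragments = sample_fragments(genomes, config)
    return mutate_reads(fragments, config.mutation_rate, _rng(config.seed, _STREAM_ROCHE))


def mutate_reads(
    reads: Sequence[SimulatedRead], rate: float, rng: np.random.Generator
) -> list[SimulatedRead]:
    return [replace(r, sequence=mutate(r.sequence, rate, rng)) for r in reads]


def make_short_clones(
    parent_fragments: Sequence[SimulatedRead], config: SimConfig
) -> list[MatePair]:
    """Mate pairs cut from either end of each (unmutated) parent fragment.

    Mate 1 is the first mate_length bases; mate 2 the reverse complement of
    the last mate_length bases (FR orientation).  Mutations are applied to
    the two mates independently.  Truth coordinates refer to the forward
    strand of the source genome.
    """
    rng = _rng(config.seed, _STREAM_SHORT)
    L = config.mate_length
    pairs: list[MatePair] = []
    for parent in parent_fragments:
        plen = len(parent.sequence)
        if plen < 2 * L:
            raise ConfigurationError(
                f"fragment {parent.read_id!r} ({plen} bp) shorter than 2 x {L} bp"
            )
        pair_id = parent.read_id.replace("frag", "short", 1)
        m1_seq = mutate(parent.sequence[:L], config.mutation_rate, rng)
        m2_seq = mutate(revcomp(parent.sequence[plen - L :]), config.mutation_rate, rng)
        mate1 = SimulatedRead(
            f"{pair_id}/1", m1_seq, parent.organism_taxon_id, parent.genome_id,
            parent.start, parent.start + L, "+",
        )
        mate2 = SimulatedRead(
            f"{pair_id}/2", m2_seq, parent.organism_taxon_id, parent.genome_id,
            parent.end - L, parent.end, "-",
        )
        pairs.append(MatePair(pair_id, mate1, mate2, CloneType.SHORT, plen))
    return pairs


def make_long_clones(
    genomes: Sequence[Genome],
    parent_fragments: Sequence[SimulatedRead],
    config: SimConfig,
) -> list[MatePair]:
    """Mate pairs with 2-5 kbp outer spans on the source genome.

    Mate 1 is the first mate_length bases of a parent fragment; the insert
    span is drawn uniformly from [long_insert_min, long_insert_max] and mate 2
    is the reverse complement of the genome slice ending ``span`` bases after
    mate 1's start.  If that slice would overrun the genome, the pair is
    mirrored upstream instead; if neither direction fits, the pair is skipped
    with a warning.
    """
    by_id = {g.genome_id: g for g in genomes}
    rng = _rng(config.seed, _STREAM_LONG)
    L = config.mate_length
    pairs: list[MatePair] = []
    n_skipped = 0
    for parent in parent_fragments:
        genome = by_id.get(parent.genome_id)
        if genome is None:
            raise InputError(f"fragment {parent.read_id!r} references unknown genome "
                             f"{parent.genome_id!r}")
        glen = len(genome.sequence)
        span = int(rng.integers(config.long_insert_min, config.long_insert_max + 1))
        s1 = parent.start
        pair_id = parent.read_id.replace("frag", "long", 1)
        if s1 + span <= glen:
            m2_start, m2_end = s1 + span - L, s1 + span
            outer = span
        elif s1 + L - span >= 0:
            # mirror upstream: outer span runs from mate2.start to mate1.end
            m2_start, m2_end = s1 + L - span, s1 + L - span + L
            outer = span
        else:
            n_skipped += 1
            continue
        m1_seq = mutate(parent.sequence[:L], config.mutation_rate, rng)
        m2_seq = mutate(
            revcomp(genome.sequence[m2_start:m2_end]), config.mutation_rate, rng
        )
        mate1 = SimulatedRead(
            f"{pair_id}/1", m1_seq, parent.organism_taxon_id, parent.genome_id,
            s1, s1 + L, "+",
        )
        mate2 = SimulatedRead(
            f"{pair_id}/2", m2_seq, parent.organism_taxon_id, parent.genome_id,
            m2_start, m2_end, "-",
        )
        pairs.append(MatePair(pair_id, mate1, mate2, CloneType.LONG, outer))
    if n_skipped:
        logger.warning("%d long-clone pairs skipped: no valid placement", n_skipped)
    return pairs


def simulate_all(
    genomes: Sequence[Genome], config: SimConfig
) -> dict[str, list[SimulatedRead] | list[MatePair]]:
    """Build the three validation sets from one shared fragment draw."""
    fragments = sample_fragments(genomes, config)
    return {
        "roche": mutate_reads(
            fragments, config.mutation_rate, _rng(config.seed, _STREAM_ROCHE)
        ),
        "short": make_short_clones(fragments, config),
        "long": make_long_clones(genomes, fragments, config),
    }


# -- synthetic genomes ------------------------------------------------------


def random_genomes(
    n: int,
    length: int,
    seed: int,
    organism_taxon_ids: Sequence[TaxonId],
    gc_fraction: float = 0.5,
    prefix: str = "synthgenome",
) -> list[Genome]:
    """Generate random genomes bound round-robin to the given organisms.

    Purely synthetic sequences (i.i.d. bases at the requested GC fraction);
    they carry no real genomic structure and exist so the whole harness runs
    without downloads.
    """
    if not organism_taxon_ids:
        raise ConfigurationError("organism_taxon_ids must be non-empty")
    rng = _rng(seed, _STREAM_GENOMES)
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    probs = np.array([p_at, p_gc, p_gc, p_at])
    genomes = []
    for i in range(n):
        arr = _BASES[rng.choice(4, size=length, p=probs)]
        genomes.append(
            Genome(
                genome_id=f"{prefix}{i:03d}",
                organism_taxon_id=organism_taxon_ids[i % len(organism_taxon_ids)],
                sequence=arr.tobytes().decode("ascii"),
            )
        )
    return genomes


# -- on-disk output ---------------------------------------------------------

TRUTH_COLUMNS = ("read_id", "organism_taxon_id", "genome_id", "start", "end", "strand")


def _records(reads: Sequence[SimulatedRead]):
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)  # 'I'
        yield rec


def _write_seqs(reads: Sequence[SimulatedRead], path: Path, fmt: str) -> None:
    SeqIO.write(_records(reads), str(path), fmt)


def _write_truth(reads: Sequence[SimulatedRead], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.organism_taxon_id}\t{r.genome_id}\t"
                f"{r.start}\t{r.end}\t{r.strand}\n"
            )


def write_dataset(
    data: Sequence[SimulatedRead] | Sequence[MatePair],
    out_prefix: str | Path,
    fmt: str = "fastq",
) -> list[Path]:
    """Write reads or mate pairs plus a truth table.

    Single-end sets produce ``<prefix>.<fmt>``; pair sets produce
    ``<prefix>_R1.<fmt>`` and ``<prefix>_R2.<fmt>`` with '/1' and '/2' id
    suffixes.  A ``<prefix>_truth.tsv`` accompanies either.  FASTQ qualities
    are a constant 'I'.
    """
    if fmt not in ("fasta", "fastq"):
        raise UsageError(f"unsupported sequence format {fmt!r}; use 'fasta' or 'fastq'")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    data = list(data)
    paths: list[Path] = []
    if data and isinstance(data[0], MatePair):
        pairs: list[MatePair] = data  # type: ignore[assignment]
        r1 = out_prefix.with_name(out_prefix.name + f"_R1.{fmt}")
        r2 = out_prefix.with_name(out_prefix.name + f"_R2.{fmt}")
        _write_seqs([p.mate1 for p in pairs], r1, fmt)
        _write_seqs([p.mate2 for p in pairs], r2, fmt)
        truth = out_prefix.with_name(out_prefix.name + "_truth.tsv")
        _write_truth(
            [m for p in pairs for m in (p.mate1, p.mate2)], truth
        )
        paths = [r1, r2, truth]
    else:
        reads: list[SimulatedRead] = data  # type: ignore[assignment]
        main = out_prefix.with_name(out_prefix.name + f".{fmt}")
        _write_seqs(reads, main, fmt)
        truth = out_prefix.with_name(out_prefix.name + "_truth.tsv")
        _write_truth(reads, truth)
        paths = [main, truth]
    return paths
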
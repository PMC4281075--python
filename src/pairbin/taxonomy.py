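"""Taxonomy container and rank algebra.

The seven canonical ranks form a total order from most specific (species) to
least specific (superkingdom), with the tree root above all of them.  All
reconciliation and evaluation logic is defined over this ladder: ``lineage``,
``lca``, ``ancestor_at_rank`` and ``step_up`` are the primitive operations.
Nodes whose rank label is outside the seven canonical levels (strains,
subspecies, "no rank" clades) are retained in the tree but are transparent to
rank queries: they project onto their nearest canonically ranked ancestor.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .errors import IntegrityError, ParseError, TaxonNotFoundError, UsageError

logger = logging.getLogger(__name__)

TaxonId = int


class Rank(enum.Enum):
    """Taxonomic rank with an ordinal: 0 = species (most specific) up to 7 = root.

    ``NONCANONICAL`` covers every label outside the seven-level ladder; it has
    no ordinal and never participates in rank comparisons.
    """

    SPECIES = 0
    GENUS = 1
    FAMILY = 2
    ORDER = 3
    CLASS = 4
    PHYLUM = 5
    SUPERKINGDOM = 6
    ROOT = 7
    NONCANONICAL = None

    @property
    def ordinal(self) -> int:
        if self.value is None:
            raise UsageError("NONCANONICAL rank has no ordinal")
        return self.value

    @property
    def is_canonical(self) -> bool:
        """True for the seven named ranks; False for ROOT and NONCANONICAL."""
        return self.value is not None and self is not Rank.ROOT

    def __lt__(self, other: "Rank") -> bool:
        return self.ordinal < other.ordinal

    def __le__(self, other: "Rank") -> bool:
        return self.ordinal <= other.ordinal

    @classmethod
    def from_label(cls, label: str) -> "Rank":
        """Map a rank label (case-insensitive) to a Rank; unknown -> NONCANONICAL."""
        return _RANK_LABELS.get(label.strip().lower(), cls.NONCANONICAL)


_RANK_LABELS = {
    "species": Rank.SPECIES,
    "genus": Rank.GENUS,
    "family": Rank.FAMILY,
    "order": Rank.ORDER,
    "class": Rank.CLASS,
    "phylum": Rank.PHYLUM,
    "superkingdom": Rank.SUPERKINGDOM,
    "root": Rank.ROOT,
}

CANONICAL_RANKS = (
    Rank.SPECIES,
    Rank.GENUS,
    Rank.FAMILY,
    Rank.ORDER,
    Rank.CLASS,
    Rank.PHYLUM,
    Rank.SUPERKINGDOM,
)


@dataclass(frozen=True)
class Taxon:
    taxon_id: TaxonId
    name: str
    parent_id: TaxonId
    rank: Rank


class TaxonomyTree:
    """Rooted tree of taxa keyed by id.

    Exactly one node is its own parent (the root).  Canonical ranks never
    repeat or invert along a root-to-leaf path; non-canonical nodes may
    interleave anywhere.
    """

    def __init__(self, taxa: dict[TaxonId, Taxon]):
        self.taxa = taxa
        self.root_id = self._validate()
        self._lineage_cache: dict[TaxonId, tuple[TaxonId, ...]] = {}

    # -- construction / validation ------------------------------------------

    def _validate(self) -> TaxonId:
        if not self.taxa:
            raise IntegrityError("taxonomy is empty (no root)")
        roots = [t.taxon_id for t in self.taxa.values() if t.parent_id == t.taxon_id]
        if len(roots) != 1:
            raise IntegrityError(f"expected exactly one root, found {len(roots)}: {roots}")
        root = roots[0]
        for t in self.taxa.values():
            if t.parent_id not in self.taxa:
                raise IntegrityError(
                    f"taxon {t.taxon_id} references missing parent {t.parent_id}"
                )
        # Walk every node to the root; detects cycles and rank inversions.
        for t in self.taxa.values():
            seen = set()
            node = t
            last_canonical: Rank | None = t.rank if t.rank.is_canonical else None
            while node.taxon_id != root:
                if node.taxon_id in seen:
                    raise IntegrityError(f"cycle detected at taxon {node.taxon_id}")
                seen.add(node.taxon_id)
                node = self.taxa[node.parent_id]
                if node.rank.is_canonical:
                    if last_canonical is not None and node.rank <= last_canonical:
                        raise IntegrityError(
                            f"rank {node.rank.name} of ancestor {node.taxon_id} is not "
                            f"above {last_canonical.name} on the path from {t.taxon_id}"
                        )
                    last_canonical = node.rank
        return root

    # -- basic queries -------------------------------------------------------

    def __contains__(self, taxon_id: TaxonId) -> bool:
        return taxon_id in self.taxa

    def __len__(self) -> int:
        return len(self.taxa)

    def __iter__(self) -> Iterator[TaxonId]:
        return iter(self.taxa)

    def _get(self, taxon_id: TaxonId) -> Taxon:
        try:
            return self.taxa[taxon_id]
        except KeyError:
            raise TaxonNotFoundError(f"unknown taxon id {taxon_id!r}") from None

    def lineage(self, taxon_id: TaxonId) -> list[TaxonId]:
        """Root-to-taxon path, both endpoints inclusive."""
        cached = self._lineage_cache.get(taxon_id)
        if cached is None:
            node = self._get(taxon_id)
            path = [node.taxon_id]
            while node.taxon_id != self.root_id:
                node = self.taxa[node.parent_id]
                path.append(node.taxon_id)
            path.reverse()
            cached = tuple(path)
            self._lineage_cache[taxon_id] = cached
        return list(cached)

    def lca(self, a: TaxonId, b: TaxonId) -> TaxonId:
        """Lowest common ancestor: deepest node on both lineages."""
        la, lb = self.lineage(a), self.lineage(b)
        last = la[0]
        for x, y in zip(la, lb):
            if x != y:
                break
            last = x
        return last

    def is_ancestor_or_self(self, a: TaxonId, b: TaxonId) -> bool:
        """True iff ``a`` appears on the lineage of ``b``."""
        self._get(a)
        return a in self.lineage(b)

    def canonical_rank(self, taxon_id: TaxonId) -> Rank:
        """Rank of the node, projected through non-canonical nodes.

        A non-canonical node reports the rank of its nearest canonically
        ranked ancestor; the root reports ROOT.
        """
        node = self._get(taxon_id)
        while True:
            if node.taxon_id == self.root_id:
                return Rank.ROOT
            if node.rank.is_canonical:
                return node.rank
            node = self.taxa[node.parent_id]

    def canonical_node(self, taxon_id: TaxonId) -> TaxonId:
        """Nearest ancestor-or-self with a canonical rank (root if none)."""
        node = self._get(taxon_id)
        while node.taxon_id != self.root_id and not node.rank.is_canonical:
            node = self.taxa[node.parent_id]
        return node.taxon_id

    def ancestor_at_rank(self, taxon_id: TaxonId, rank: Rank) -> TaxonId | None:
        """Ancestor-or-self whose own rank equals ``rank``, or None if absent.

        Ranks never repeat along a lineage, so the answer is unique.
        """
        if rank is Rank.NONCANONICAL:
            raise UsageError("ancestor_at_rank requires a canonical rank or ROOT")
        if rank is Rank.ROOT:
            self._get(taxon_id)
            return self.root_id
        for tid in reversed(self.lineage(taxon_id)):
            if self.taxa[tid].rank is rank:
                return tid
        return None

    def step_up(self, taxon_id: TaxonId) -> TaxonId:
        """Ancestor at the next less-specific canonical rank on the lineage.

        Missing intermediate ranks are skipped; the root is returned when no
        canonical ancestor remains.  Calling on the root is an error.
        """
        if taxon_id == self.root_id:
            raise UsageError("step_up is undefined on the root")
        own = self.canonical_rank(taxon_id)
        node = self._get(taxon_id)
        while node.taxon_id != self.root_id:
            node = self.taxa[node.parent_id]
            if node.taxon_id == self.root_id:
                return self.root_id
            if node.rank.is_canonical and (own is Rank.ROOT or node.rank.ordinal > own.ordinal):
                return node.taxon_id
        return self.root_id

    def name_of(self, taxon_id: TaxonId) -> str:
        return self._get(taxon_id).name


# -- loaders ----------------------------------------------------------------


def _parse_int(field: str, path: Path, lineno: int) -> int:
    try:
        return int(field)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: expected integer taxon id, got {field!r}") from None


def load_ncbi_dump(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTree:
    """Load an NCBI-style taxdump (nodes.dmp + names.dmp).

    Fields are separated by ``\\t|\\t`` and records terminated by ``\\t|``.
    Only the tax_id / parent tax_id / rank columns of nodes.dmp and the
    "scientific name" rows of names.dmp are used.  Rank labels outside the
    seven canonical levels map to NONCANONICAL.
    """
    nodes_path, names_path = Path(nodes_path), Path(names_path)
    names: dict[TaxonId, str] = {}
    with open(names_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_dmp(line, names_path, lineno, minimum=4)
            if fields[3] == "scientific name":
                names[_parse_int(fields[0], names_path, lineno)] = fields[1]
    taxa: dict[TaxonId, Taxon] = {}
    with open(nodes_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_dmp(line, nodes_path, lineno, minimum=3)
            tid = _parse_int(fields[0], nodes_path, lineno)
            pid = _parse_int(fields[1], nodes_path, lineno)
            if tid in taxa:
                raise IntegrityError(f"{nodes_path}:{lineno}: duplicate taxon id {tid}")
            taxa[tid] = Taxon(tid, names.get(tid, str(tid)), pid, Rank.from_label(fields[2]))
    return TaxonomyTree(taxa)


def _split_dmp(line: str, path: Path, lineno: int, minimum: int) -> list[str]:
    fields = line.rstrip("\n").rstrip("\t|").split("\t|\t")
    if len(fields) < minimum:
        raise ParseError(f"{path}:{lineno}: expected >= {minimum} '\\t|\\t' fields, got {len(fields)}")
    return fields


def load_lineage_table(tsv_path: str | Path) -> TaxonomyTree:
    """Load a taxonomy from a simple lineage TSV.

    Header ``taxon_id  name  rank  parent_id``; one row per taxon.  Unknown
    rank labels map to NONCANONICAL with a logged warning; duplicate ids are
    an integrity error.  Equivalent content yields the same tree as the
    taxdump loader.
    """
    tsv_path = Path(tsv_path)
    taxa: dict[TaxonId, Taxon] = {}
    with open(tsv_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["taxon_id", "name", "rank", "parent_id"]
        if header != expected:
            raise ParseError(f"{tsv_path}:1: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ParseError(f"{tsv_path}:{lineno}: expected 4 columns, got {len(fields)}")
            tid = _parse_int(fields[0], tsv_path, lineno)
            if tid in taxa:
                raise IntegrityError(f"{tsv_path}:{lineno}: duplicate taxon id {tid}")
            rank = Rank.from_label(fields[2])
            if rank is Rank.NONCANONICAL and fields[2].strip().lower() not in _RANK_LABELS:
                logger.warning("%s:%d: unknown rank label %r mapped to NONCANONICAL",
                               tsv_path, lineno, fields[2])
            taxa[tid] = Taxon(tid, fields[1], _parse_int(fields[3], tsv_path, lineno), rank)
    return TaxonomyTree(taxa)


_RANK_TO_LABEL = {rank: label for label, rank in _RANK_LABELS.items()}


def rank_label(rank: Rank) -> str:
    """Lower-case label of a rank ('no rank' for NONCANONICAL)."""
    return _RANK_TO_LABEL.get(rank, "no rank")


def write_lineage_table(tree: TaxonomyTree, tsv_path: str | Path) -> None:
    """Write a tree in the lineage-TSV dialect accepted by load_lineage_table."""
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("taxon_id\tname\trank\tparent_id\n")
        for tid in sorted(tree.taxa):
            t = tree.taxa[tid]
            fh.write(f"{t.taxon_id}\t{t.name}\t{rank_label(t.rank)}\t{t.parent_id}\n")


def build_tree(rows: Iterable[tuple[TaxonId, str, str, TaxonId]]) -> TaxonomyTree:
    """Build a tree from (taxon_id, name, rank_label, parent_id) tuples."""
    out: dict[TaxonId, Taxon] = {}
    for tid, name, rank, pid in rows:
        if tid in out:
            raise IntegrityError(f"duplicate taxon id {tid}")
        out[tid] = Taxon(tid, name, pid, Rank.from_label(rank))
    return TaxonomyTree(out)
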
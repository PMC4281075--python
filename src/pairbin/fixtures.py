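"""Built-in toy taxonomy and synthetic genome bindings.

The toy taxonomy is a 16-node tree with two bacterial phyla and a pair of
sibling genera, giving full seven-rank paths that exercise every branch of the
pair-reconciliation rules without downloading a real taxonomy dump.  Node ids
follow the familiar NCBI numbering for recognisability (E. coli = 562, ...),
but the tree is synthetic.
"""

from __future__ import annotations

from .taxonomy import TaxonomyTree, build_tree

# (taxon_id, name, rank, parent_id); root is its own parent.
TOY_TAXONOMY_ROWS: tuple[tuple[int, str, str, int], ...] = (
    (1, "root", "root", 1),
    (2, "Bacteria", "superkingdom", 1),
    (1224, "Proteobacteria", "phylum", 2),
    (1236, "Gammaproteobacteria", "class", 1224),
    (91347, "Enterobacterales", "order", 1236),
    (543, "Enterobacteriaceae", "family", 91347),
    (561, "Escherichia", "genus", 543),
    (562, "Escherichia coli", "species", 561),
    (590, "Salmonella", "genus", 543),
    (28901, "Salmonella enterica", "species", 590),
    (1239, "Firmicutes", "phylum", 2),
    (91061, "Bacilli", "class", 1239),
    (186826, "Lactobacillales", "order", 91061),
    (1300, "Streptococcaceae", "family", 186826),
    (1301, "Streptococcus", "genus", 1300),
    (1313, "Streptococcus pneumoniae", "species", 1301),
)

#: Species-level leaves of the toy taxonomy, used to label synthetic genomes.
TOY_SPECIES: tuple[int, ...] = (562, 28901, 1313)


def toy_taxonomy() -> TaxonomyTree:
    """Return a fresh instance of the 16-node toy taxonomy."""
    return build_tree(TOY_TAXONOMY_ROWS)


def panel_taxonomy(n_species: int = 20) -> tuple[TaxonomyTree, tuple[int, ...]]:
    """Toy taxonomy extended with an n-organism panel for simulation runs.

    Adds ``n_species`` extra genus/species pairs, alternating between the two
    toy families, so a simulated microbiome can draw fragments from that many
    distinct organisms with full seven-rank lineages.  Returns the tree and
    the panel's species ids.
    """
    rows = list(TOY_TAXONOMY_ROWS)
    species: list[int] = []
    for i in range(n_species):
        genus_id = 900_000 + i
        species_id = 950_000 + i
        family = 543 if i % 2 == 0 else 1300
        rows.append((genus_id, f"Panelgenus {i}", "genus", family))
        rows.append((species_id, f"Panelgenus species {i}", "species", genus_id))
        species.append(species_id)
    return build_tree(rows), tuple(species)
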
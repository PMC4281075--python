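from __future__ import annotations

import pytest

from pairbin.fixtures import TOY_TAXONOMY_ROWS, toy_taxonomy


@pytest.fixture(scope="session")
def toy_tree():
    return toy_taxonomy()


@pytest.fixture(scope="session")
def toy_maps():
    """(parents, ranks) dicts of the toy taxonomy, for the brute-force oracles."""
    parents = {tid: pid for tid, _, _, pid in TOY_TAXONOMY_ROWS}
    ranks = {tid: rank for tid, _, rank, _ in TOY_TAXONOMY_ROWS}
    return parents, ranks


@pytest.fixture(scope="session")
def toy_lineage_tsv(tmp_path_factory):
    from pairbin.taxonomy import write_lineage_table

    path = tmp_path_factory.mktemp("tax") / "toy_lineage.tsv"
    write_lineage_table(toy_taxonomy(), path)
    return path
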
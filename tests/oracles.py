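"""Independent brute-force oracles used by the test suite.

Everything here works on plain dicts (taxon -> parent, taxon -> rank label)
and explicit lineage lists, never on the package's TaxonomyTree, so these
functions form an independent second route for every rank-algebra and
reconciliation rule the package implements.
"""

from __future__ import annotations

# Most specific first; index = ordinal (root last, index 7).
RANK_LADDER = [
    "species", "genus", "family", "order", "class", "phylum", "superkingdom", "root",
]
CANONICAL = set(RANK_LADDER[:-1])


def oracle_lineage(parents: dict[int, int], node: int) -> list[int]:
    path = [node]
    while parents[path[-1]] != path[-1]:
        path.append(parents[path[-1]])
    return path[::-1]


def oracle_lca(parents: dict[int, int], a: int, b: int) -> int:
    la = oracle_lineage(parents, a)
    lb = set(oracle_lineage(parents, b))
    common = [t for t in la if t in lb]
    return common[-1]


def oracle_project(parents: dict[int, int], ranks: dict[int, str], node: int) -> int:
    """Nearest ancestor-or-self with a canonical rank; root if none."""
    lineage = oracle_lineage(parents, node)
    for t in reversed(lineage):
        if ranks[t] in CANONICAL:
            return t
    return lineage[0]


def oracle_ordinal(parents: dict[int, int], ranks: dict[int, str], node: int) -> int:
    """Canonical-rank ordinal of a node (root = 7)."""
    proj = oracle_project(parents, ranks, node)
    if ranks[proj] not in CANONICAL:
        return RANK_LADDER.index("root")
    return RANK_LADDER.index(ranks[proj])


def oracle_step_up(parents: dict[int, int], ranks: dict[int, str], node: int) -> int:
    own = oracle_ordinal(parents, ranks, node)
    lineage = oracle_lineage(parents, node)
    for t in reversed(lineage[:-1]):
        if ranks[t] in CANONICAL and RANK_LADDER.index(ranks[t]) > own:
            return t
    return lineage[0]


def oracle_reconcile(
    parents: dict[int, int],
    ranks: dict[int, str],
    x: int | None,
    y: int | None,
    strategy: str,
) -> tuple[int | None, int | None]:
    """Brute-force pair reconciliation from explicit lineage lists.

    Returns the (x, y) output taxa, with None for unassigned.  Unassigned
    inputs are modelled as the root; outputs equal to the root come back as
    None.  Unchanged cases return the original inputs verbatim.
    """
    root = next(t for t, p in parents.items() if p == t)
    ex = root if x is None else oracle_project(parents, ranks, x)
    ey = root if y is None else oracle_project(parents, ranks, y)

    if ex == root and ey == root:
        return x, y  # both unassigned: unchanged
    if ex == ey:
        return x, y  # same taxon after projection: unchanged

    lx = oracle_lineage(parents, ex)
    ly = oracle_lineage(parents, ey)
    if ex not in ly and ey not in lx:  # divergent lineages -> LCA
        anc = oracle_lca(parents, ex, ey)
        out = None if anc == root else anc
        return out, out

    # Same lineage (one may be the root): Tx deeper, Ty higher.
    if ex in ly:
        t_deep, t_high = ey, ex
        deep_is_x = False
    else:
        t_deep, t_high = ex, ey
        deep_is_x = True

    def emit(t: int) -> int | None:
        return None if t == root else t

    if strategy == "SI":
        return emit(t_deep), emit(t_deep)
    if strategy == "SIV":
        return emit(t_high), emit(t_high)
    t_mid = oracle_step_up(parents, ranks, t_deep)
    if oracle_ordinal(parents, ranks, t_mid) > oracle_ordinal(parents, ranks, t_high):
        t_mid = t_high
    if strategy == "SIII":
        return emit(t_mid), emit(t_mid)
    if strategy == "SII":
        if deep_is_x:
            return emit(t_deep), emit(t_mid)
        return emit(t_mid), emit(t_deep)
    raise ValueError(f"unknown strategy {strategy!r}")


def oracle_judge(
    parents: dict[int, int], ranks: dict[int, str], assigned: int | None, truth: int
) -> str:
    """Bucket an assignment against truth via explicit lineage lists."""
    root = next(t for t, p in parents.items() if p == t)
    if assigned is None or assigned == root:
        return "unassigned"
    if assigned not in oracle_lineage(parents, truth):
        return "wrong"
    ordinal = oracle_ordinal(parents, ranks, assigned)
    if ordinal >= RANK_LADDER.index("root"):
        return "unassigned"
    return {
        0: "genus_and_below", 1: "genus_and_below",
        2: "family_order", 3: "family_order",
        4: "class_phylum", 5: "class_phylum",
        6: "superkingdom",
    }[ordinal]


def random_taxonomy_rows(rng, max_nodes: int = 200) -> list[tuple[int, str, str, int]]:
    """Random rank-consistent taxonomy as build_tree rows.

    Each node attaches to a uniformly chosen earlier node and takes either a
    canonical rank strictly more specific than its parent's projected rank,
    or (with probability 0.25) a non-canonical rank.
    """
    n = int(rng.integers(5, max_nodes + 1))
    rows = [(1, "root", "root", 1)]
    proj_ord = {1: RANK_LADDER.index("root")}
    ids = [1]
    for i in range(2, n + 1):
        pid = int(ids[rng.integers(0, len(ids))])
        p_ord = proj_ord[pid]
        if p_ord == 0 or rng.random() < 0.25:
            rank = "no rank"
            proj_ord[i] = p_ord
        else:
            ordinal = int(rng.integers(0, p_ord))
            rank = RANK_LADDER[ordinal]
            proj_ord[i] = ordinal
        rows.append((i, f"node{i}", rank, pid))
        ids.append(i)
    return rows
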
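"""Maximum-parsimony inference for binary character matrices.

Implements Fitch (unordered) parsimony scoring, exact tree search by
exhaustive enumeration and branch-and-bound, a seeded random-addition +
NNI/SPR heuristic, consistency/retention indices, nonparametric bootstrap
with majority-rule consensus, and strict/majority consensus trees.

Missing cells (``?``) contribute the full state set {0, 1} in Fitch sets,
so an all-missing character costs 0 steps on every tree.

Trees cross the public API as :class:`dendropy.Tree` objects; internally
the search enumerates nested-list topologies rooted at the first taxon,
scoring each with Fitch sets bit-packed two bits per character into Python
integers (one integer per node visit scores every character at once).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .coding import MISSING, CharacterDef, CharacterMatrix, filter_informative

__all__ = [
    "ParsimonyResult",
    "SearchError",
    "fitch_length",
    "char_min_steps",
    "char_max_steps",
    "ci_ri",
    "search_exhaustive",
    "search_branch_and_bound",
    "search_heuristic",
    "bootstrap",
    "strict_consensus",
    "majority_consensus",
    "rf_distance",
    "tree_splits",
    "canonical_newick",
    "read_newick",
    "write_newick",
]


class SearchError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Encoding: one Fitch state-set per cell, two bits per character


_SET0, _SET1, _SETQ = 1, 2, 3


def _encode_sets(cells: np.ndarray) -> np.ndarray:
    sets = np.empty(cells.shape, dtype=np.uint8)
    sets[cells == 0] = _SET0
    sets[cells == 1] = _SET1
    sets[cells == MISSING] = _SETQ
    return sets


def _pack_rows(sets: np.ndarray) -> tuple[list[int], int]:
    """Pack each taxon's per-character state sets into one big integer."""
    n_chars = sets.shape[1]
    mask01 = int("01" * n_chars, 2) if n_chars else 0
    packed = []
    for row in sets:
        v = 0
        for i, s in enumerate(row):
            v |= int(s) << (2 * i)
        packed.append(v)
    return packed, mask01


def _combine(sa: int, sb: int, mask01: int) -> tuple[int, int]:
    """Fitch combine of two packed state sets; returns (set, added steps)."""
    inter = sa & sb
    present = (inter | (inter >> 1)) & mask01
    steps = (present ^ mask01).bit_count()
    sel = present | (present << 1)
    return (inter & sel) | ((sa | sb) & ~sel), steps


# Nested-list topology: a leaf is a taxon index, an internal node is a
# 2-element list [left, right]; the implicit root joins the structure to
# taxon 0 (the tree is unrooted, rooted at leaf 0 for bookkeeping).


def _fitch_packed(node, packed: Sequence[int], mask01: int) -> tuple[int, int]:
    if isinstance(node, int):
        return packed[node], 0
    sa, ca = _fitch_packed(node[0], packed, mask01)
    sb, cb = _fitch_packed(node[1], packed, mask01)
    s, extra = _combine(sa, sb, mask01)
    return s, ca + cb + extra


def _tree_length(top, packed: Sequence[int], mask01: int) -> int:
    s, steps = _fitch_packed(top, packed, mask01)
    _, extra = _combine(s, packed[0], mask01)
    return steps + extra


def _copy(node):
    return node if isinstance(node, int) else [_copy(node[0]), _copy(node[1])]


def _leafset(node) -> int:
    if isinstance(node, int):
        return 1 << node
    return _leafset(node[0]) | _leafset(node[1])


def _split_key(top, n_taxa: int) -> frozenset[int]:
    """Nontrivial splits (as leaf bitmasks excluding taxon 0) of a topology."""
    splits: set[int] = set()

    def walk(node) -> int:
        if isinstance(node, int):
            return 1 << node
        bits = walk(node[0]) | walk(node[1])
        size = bits.bit_count()
        if 2 <= size <= n_taxa - 2:
            splits.add(bits)
        return bits

    walk(top)
    return frozenset(splits)


# ---------------------------------------------------------------------------
# dendropy conversion


def _label_taxa(m: CharacterMatrix) -> list[str]:
    return list(m.taxa)


def _to_dendropy(top, taxa: Sequence[str], tns: dendropy.TaxonNamespace) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=tns)
    lookup = {t.label: t for t in tns}

    def build(node) -> dendropy.Node:
        nd = dendropy.Node()
        if isinstance(node, int):
            nd.taxon = lookup[taxa[node]]
        else:
            nd.add_child(build(node[0]))
            nd.add_child(build(node[1]))
        return nd

    root = tree.seed_node
    leaf0 = dendropy.Node()
    leaf0.taxon = lookup[taxa[0]]
    root.add_child(leaf0)
    root.add_child(build(top))
    tree.is_rooted = False
    return tree


def _from_dendropy(tree: dendropy.Tree, taxa: Sequence[str]):
    """Convert a (rooted or unrooted) binary dendropy tree to a nested list."""
    index = {t: i for i, t in enumerate(taxa)}

    def conv(nd):
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label not in index:
                raise SearchError(f"leaf {nd.taxon} not among matrix taxa")
            return index[nd.taxon.label]
        kids = [conv(c) for c in nd.child_nodes()]
        node = kids[0]
        for k in kids[1:]:
            node = [node, k]
        return node

    root_kids = [conv(c) for c in tree.seed_node.child_nodes()]
    # peel taxon 0 off to make it the implicit root
    node = root_kids[0]
    for k in root_kids[1:]:
        node = [node, k]

    def peel(nd, target):
        # returns (found, rebuilt-subtree-without-target)
        if isinstance(nd, int):
            return (nd == target, None)
        f0, r0 = peel(nd[0], target)
        if f0:
            return (True, nd[1] if r0 is None else [r0, nd[1]])
        f1, r1 = peel(nd[1], target)
        if f1:
            return (True, nd[0] if r1 is None else [nd[0], r1])
        return (False, None)

    found, top = peel(node, 0)
    if not found:
        raise SearchError("matrix taxon missing from tree")
    return top


# ---------------------------------------------------------------------------
# Scoring public API (numpy per-character pass, works on dendropy trees)


def fitch_length(
    tree: dendropy.Tree, m: CharacterMatrix
) -> tuple[int, list[int]]:
    """Fitch tree length and per-character step counts.

    The score is independent of root placement; polytomies are resolved
    left-to-right (exact for binary trees).  Leaves must match the matrix
    taxa exactly.
    """
    sets = _encode_sets(m.cells)
    row = {t: i for i, t in enumerate(m.taxa)}
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if sorted(leaves) != sorted(m.taxa):
        raise SearchError(
            f"tree leaves do not match matrix taxa "
            f"(tree has {len(leaves)}, matrix has {len(m.taxa)})"
        )
    steps = np.zeros(m.n_characters, dtype=np.int64)

    def post(nd) -> np.ndarray:
        if nd.is_leaf():
            return sets[row[nd.taxon.label]].copy()
        kids = nd.child_nodes()
        acc = post(kids[0])
        for child in kids[1:]:
            other = post(child)
            inter = acc & other
            empty = inter == 0
            steps[empty] += 1
            acc = np.where(empty, acc | other, inter)
        return acc

    post(tree.seed_node)
    return int(steps.sum()), [int(s) for s in steps]


def char_min_steps(column: np.ndarray) -> int:
    """Minimum steps any tree needs: (#observed states − 1), 0 or 1."""
    col = np.asarray(column)
    observed = {int(v) for v in col if v != MISSING}
    return max(len(observed) - 1, 0)


def char_max_steps(column: np.ndarray) -> int:
    """Maximum steps attainable on any tree: min(#0s, #1s) over non-? cells."""
    col = np.asarray(column)
    return int(min((col == 0).sum(), (col == 1).sum()))


def ci_ri(
    tree: dendropy.Tree, m: CharacterMatrix, exclude_uninformative: bool = True
) -> tuple[float, float]:
    """Consistency index M/L and retention index (G−L)/(G−M).

    M is the sum of per-character minimum steps, G of maximum steps, L the
    observed tree length, all over the selected character set.  With no
    possible homoplasy (G = M) the RI is defined as 1; with L = 0 the CI is
    defined as 1.
    """
    if exclude_uninformative:
        m, _ = filter_informative(m)
    L, _ = fitch_length(tree, m)
    mins = sum(char_min_steps(m.cells[:, j]) for j in range(m.n_characters))
    maxs = sum(char_max_steps(m.cells[:, j]) for j in range(m.n_characters))
    ci = 1.0 if L == 0 else mins / L
    ri = 1.0 if maxs == mins else (maxs - L) / (maxs - mins)
    return ci, ri


# ---------------------------------------------------------------------------
# Tree search


@dataclass
class ParsimonyResult:
    """Outcome of a parsimony search.

    ``ci``/``ri`` are computed on the informative-only character set (the
    convention used for headline values); ``per_character_steps`` refers to
    the full matrix on the first optimal tree.
    """

    length: int
    per_character_steps: list[int]
    optimal_trees: list[dendropy.Tree]
    ci: float
    ri: float
    n_topologies_examined: int = 0
    method: str = ""

    @property
    def n_optimal(self) -> int:
        return len(self.optimal_trees)


def _greedy_addition(order: list[int], packed, mask01) -> list:
    top = order[1] if len(order) == 2 else [order[1], order[2]]
    for k in order[3:]:
        # candidate: insert at the root edge
        best = [top, k]
        best_len = _tree_length(best, packed, mask01)
        for parent, slot in _edges(top):
            old = parent[slot]
            parent[slot] = [old, k]
            clen = _tree_length(top, packed, mask01)
            if clen < best_len:
                best, best_len = _copy(top), clen
            parent[slot] = old
        top = best
    return top


def _edges(top):
    """All (parent, slot) insertion points strictly inside the topology."""
    out = []

    def walk(node):
        if isinstance(node, int):
            return
        for slot in (0, 1):
            out.append((node, slot))
            walk(node[slot])

    walk(top)
    return out


def _enumerate(
    packed,
    mask01,
    n_taxa: int,
    bound: int | None,
    keep_all: bool = True,
):
    """Stepwise-addition enumeration of all unrooted topologies.

    With *bound* set, partial trees longer than the bound are pruned
    (branch-and-bound; the Fitch length of a leaf-restricted tree never
    exceeds that of its completions).  Returns (best_length, tops, n_seen).
    """
    best = [bound if bound is not None else None]
    kept: list = []
    seen = [0]

    def consider(top, next_taxon):
        L = _tree_length(top, packed, mask01)
        if bound is not None and best[0] is not None and L > best[0]:
            return
        if next_taxon == n_taxa:
            seen[0] += 1
            if best[0] is None or L < best[0]:
                best[0] = L
                kept.clear()
            if L == best[0] and keep_all:
                kept.append(_copy(top))
            return
        k = next_taxon
        consider([top, k], next_taxon + 1)
        for parent, slot in _edges(top):
            old = parent[slot]
            parent[slot] = [old, k]
            consider(top, next_taxon + 1)
            parent[slot] = old

    if n_taxa < 4:
        top = 1 if n_taxa == 2 else [1, 2]
        L = _tree_length(top, packed, mask01)
        return L, [top], 1
    consider([1, 2], 3)
    return best[0], kept, seen[0]


def _result(
    m: CharacterMatrix,
    tops: list,
    length: int,
    n_seen: int,
    method: str,
) -> ParsimonyResult:
    taxa = _label_taxa(m)
    tns = dendropy.TaxonNamespace(taxa)
    # deduplicate by unrooted topology
    unique: dict[frozenset, object] = {}
    for top in tops:
        unique.setdefault(_split_key(top, len(taxa)), top)
    trees = [_to_dendropy(top, taxa, tns) for top in unique.values()]
    L, steps = fitch_length(trees[0], m)
    assert L == length, "search length disagrees with rescoring"
    ci, ri = ci_ri(trees[0], m, exclude_uninformative=True)
    return ParsimonyResult(
        length=length,
        per_character_steps=steps,
        optimal_trees=trees,
        ci=ci,
        ri=ri,
        n_topologies_examined=n_seen,
        method=method,
    )


def search_exhaustive(m: CharacterMatrix, max_taxa: int = 10) -> ParsimonyResult:
    """Score every unrooted binary topology ((2n−5)!! of them)."""
    n = m.n_taxa
    if n > max_taxa:
        raise SearchError(
            f"{n} taxa exceed the exhaustive limit of {max_taxa}; "
            "use search_branch_and_bound"
        )
    if n < 2:
        raise SearchError("need at least two taxa")
    packed, mask01 = _pack_rows(_encode_sets(m.cells))
    length, tops, seen = _enumerate(packed, mask01, n, bound=None)
    return _result(m, tops, length, seen, "exhaustive")


def search_branch_and_bound(m: CharacterMatrix) -> ParsimonyResult:
    """Exact search: stepwise addition with Fitch lower-bound pruning.

    The initial upper bound comes from a short heuristic search, so only
    partial trees that already exceed a known achievable length are pruned;
    all optimal topologies are returned, deduplicated by topology.
    """
    n = m.n_taxa
    if n < 2:
        raise SearchError("need at least two taxa")
    packed, mask01 = _pack_rows(_encode_sets(m.cells))
    if n >= 4:
        warm = search_heuristic(m, n_starts=3, seed=0)
        bound = warm.length
    else:
        bound = None
    length, tops, seen = _enumerate(packed, mask01, n, bound=bound)
    return _result(m, tops, length, seen, "branch_and_bound")


def _nni_neighbors(top):
    """Yield copies of all NNI rearrangements of the topology."""
    spots = []

    def walk(node):
        if isinstance(node, int):
            return
        for slot in (0, 1):
            child = node[slot]
            if not isinstance(child, int):
                spots.append((node, slot))
            walk(node[slot])

    walk(top)
    for parent, slot in spots:
        child = parent[slot]
        sib = parent[1 - slot]
        for csub in (0, 1):
            # swap the sibling with one grandchild
            parent[1 - slot], child[csub] = child[csub], sib
            yield _copy(top)
            child[csub] = parent[1 - slot]
            parent[1 - slot] = sib


def _spr_neighbors(top):
    """Yield copies of all subtree-prune-regraft rearrangements."""
    n_positions = []

    def collect(node, parent, slot):
        n_positions.append((node, parent, slot))
        if not isinstance(node, int):
            collect(node[0], node, 0)
            collect(node[1], node, 1)

    collect(top, None, None)
    for node, parent, slot in n_positions:
        if parent is None:
            continue
        sib = parent[1 - slot]

        # remove `parent`, splicing `sib` into its place (fresh structure)
        def rebuild(cur):
            if cur is parent:
                return _copy(sib)
            if isinstance(cur, int):
                return cur
            return [rebuild(cur[0]), rebuild(cur[1])]

        pruned = rebuild(top)
        moved = _copy(node)
        yield [_copy(pruned), moved]
        for p2, s2 in _edges(pruned):
            old = p2[s2]
            p2[s2] = [old, moved]
            yield _copy(pruned)
            p2[s2] = old


def search_heuristic(
    m: CharacterMatrix, n_starts: int = 10, seed: int | None = None
) -> ParsimonyResult:
    """Random-addition starting trees refined by NNI and SPR hill-climbing.

    Seeded and reproducible; the best length found is an upper bound on the
    exact optimum.  All distinct local optima at the best length are
    returned.
    """
    if seed is None:
        raise SearchError("heuristic search requires an explicit seed")
    n = m.n_taxa
    if n < 2:
        raise SearchError("need at least two taxa")
    packed, mask01 = _pack_rows(_encode_sets(m.cells))
    rng = random.Random(seed)
    best_len: int | None = None
    best: dict[frozenset, object] = {}
    n_seen = 0
    for _ in range(max(1, n_starts)):
        if n < 4:
            top = 1 if n == 2 else [1, 2]
        else:
            order = [0] + rng.sample(range(1, n), n - 1)
            # addition is relative to the implicit root leaf `order[0]` = 0
            top = _greedy_addition(order, packed, mask01)
        cur_len = _tree_length(top, packed, mask01)
        improved = True
        while improved and n >= 4:
            improved = False
            for gen in (_nni_neighbors, _spr_neighbors):
                cand_best, cand_len = None, cur_len
                for cand in gen(top):
                    n_seen += 1
                    L = _tree_length(cand, packed, mask01)
                    if L < cand_len:
                        cand_best, cand_len = cand, L
                if cand_best is not None:
                    top, cur_len = cand_best, cand_len
                    improved = True
                    break
        if best_len is None or cur_len < best_len:
            best_len = cur_len
            best = {}
        if cur_len == best_len:
            best.setdefault(_split_key(top, n), top)
    return _result(m, list(best.values()), best_len, n_seen, "heuristic")


# ---------------------------------------------------------------------------
# Splits, consensus, bootstrap


def tree_splits(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """Nontrivial unrooted splits as frozensets of leaf labels.

    Each split is normalised to the side not containing the
    lexicographically first leaf.
    """
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    first = labels[0]
    n = len(labels)
    full = frozenset(labels)
    splits: set[frozenset[str]] = set()

    def walk(nd) -> set[str]:
        if nd.is_leaf():
            return {nd.taxon.label}
        below: set[str] = set()
        for c in nd.child_nodes():
            below |= walk(c)
        side = full - below if first in below else set(below)
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
        return below

    walk(tree.seed_node)
    return frozenset(splits)


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds (symmetric split difference) between two trees."""
    s1, s2 = tree_splits(t1), tree_splits(t2)
    return len(s1 ^ s2)


def _tree_from_splits(
    leaves: Sequence[str],
    splits: list[tuple[frozenset[str], float]],
) -> dendropy.Tree:
    """Build a tree from mutually compatible splits, annotating support."""
    tns = dendropy.TaxonNamespace(sorted(leaves))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    root = tree.seed_node
    nodes: dict[frozenset[str], dendropy.Node] = {frozenset(leaves): root}
    ordered = sorted(splits, key=lambda sf: -len(sf[0]))
    containers: list[tuple[frozenset[str], dendropy.Node]] = [
        (frozenset(leaves), root)
    ]
    for side, support in ordered:
        parent = min(
            (s for s in containers if side <= s[0]), key=lambda s: len(s[0])
        )[1]
        nd = dendropy.Node()
        nd.label = f"{support:g}"
        nd.support = support
        parent.add_child(nd)
        containers.append((side, nd))
        nodes[side] = nd
    lookup = {t.label: t for t in tns}
    for leaf in leaves:
        parent = min(
            (s for s in containers if leaf in s[0]), key=lambda s: len(s[0])
        )[1]
        nd = dendropy.Node()
        nd.taxon = lookup[leaf]
        parent.add_child(nd)
    return tree


def _check_same_leaves(trees: Sequence[dendropy.Tree]) -> list[str]:
    if not trees:
        raise SearchError("no trees given")
    leaf_sets = [
        frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in trees
    ]
    if len(set(leaf_sets)) != 1:
        raise SearchError("trees have differing leaf sets")
    return sorted(leaf_sets[0])


def strict_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Tree containing exactly the splits present in every input tree."""
    leaves = _check_same_leaves(trees)
    common = set(tree_splits(trees[0]))
    for t in trees[1:]:
        common &= tree_splits(t)
    return _tree_from_splits(leaves, [(s, 100.0) for s in common])


def majority_consensus(
    trees: Sequence[dendropy.Tree], threshold: float = 0.5
) -> dendropy.Tree:
    """Splits occurring in more than *threshold* of the trees, annotated
    with their frequency (percent) as node support."""
    leaves = _check_same_leaves(trees)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for s in tree_splits(t):
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    chosen = [
        (s, 100.0 * c / n) for s, c in counts.items() if c / n > threshold
    ]
    return _tree_from_splits(leaves, chosen)


def bootstrap(
    m: CharacterMatrix,
    replicates: int = 1000,
    seed: int | None = None,
    search: str = "heuristic",
    n_starts: int = 3,
) -> dendropy.Tree:
    """Nonparametric bootstrap: character columns are resampled with
    replacement, the search is rerun per replicate, and clade frequencies
    are reported on a majority-rule consensus (support in percent).

    When a replicate yields several optimal trees each contributes
    1/#optima to that replicate's split tally.
    """
    if replicates < 1:
        raise SearchError("need at least one bootstrap replicate")
    if seed is None:
        raise SearchError("bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)
    weights: dict[frozenset[str], float] = {}
    leaves: list[str] = list(m.taxa)
    for rep in range(replicates):
        idx = rng.integers(0, m.n_characters, size=m.n_characters)
        cells = m.cells[:, idx]
        boot = CharacterMatrix(
            list(m.taxa),
            [CharacterDef(j + 1, f"bs{j + 1}") for j in range(cells.shape[1])],
            cells,
        )
        if search == "bnb":
            res = search_branch_and_bound(boot)
        else:
            res = search_heuristic(
                boot, n_starts=n_starts, seed=int(rng.integers(0, 2**31 - 1))
            )
        w = 1.0 / len(res.optimal_trees)
        for t in res.optimal_trees:
            for s in tree_splits(t):
                weights[s] = weights.get(s, 0.0) + w
    chosen = [
        (s, 100.0 * c / replicates)
        for s, c in weights.items()
        if c / replicates > 0.5
    ]
    return _tree_from_splits(leaves, chosen)


# ---------------------------------------------------------------------------
# Newick plumbing


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def canonical_newick(tree: dendropy.Tree) -> str:
    """Label-sorted Newick string identifying the unrooted topology."""

    def key(nd):
        if nd.is_leaf():
            return nd.taxon.label
        return min(key(c) for c in nd.child_nodes())

    def render(nd) -> str:
        if nd.is_leaf():
            return nd.taxon.label
        parts = sorted(nd.child_nodes(), key=key)
        return "(" + ",".join(render(c) for c in parts) + ")"

    # root at the lexicographically first leaf for a canonical orientation
    first = min(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    t2 = tree.clone(depth=1)
    first2 = min(t2.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    t2.reroot_at_edge(first2.edge, update_bipartitions=False)
    return render(t2.seed_node) + ";"
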
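"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest

from karyophylo.coding import MISSING, CharacterDef, CharacterMatrix
from karyophylo.karyotype import (
    Karyotype,
    Morphology,
    PaintedChromosome,
    SegmentID,
    proposed_ancestral_karyotype,
)


@pytest.fixture
def akp() -> Karyotype:
    return proposed_ancestral_karyotype()


def make_karyotype(n_bi: int, n_acro: int, taxon: str = "TOY", sex: bool = True) -> Karyotype:
    """Generic complement of *n_bi* bi-armed and *n_acro* acrocentric pairs."""
    pairs = []
    for i in range(1, n_bi + 1):
        pairs.append(
            PaintedChromosome(
                (SegmentID("REF", i, "p"), SegmentID("REF", i, "q")),
                Morphology.SUBMETACENTRIC,
                1,
            )
        )
    for i in range(n_bi + 1, n_bi + n_acro + 1):
        pairs.append(PaintedChromosome((SegmentID("REF", i),)))
    sex_pair = (
        (PaintedChromosome((SegmentID("REF", "X"),), Morphology.METACENTRIC, 1),)
        if sex
        else ()
    )
    return Karyotype(taxon, tuple(pairs), sex_pair)


def random_matrix(
    rng: np.random.Generator, n_taxa: int, n_chars: int, missing_frac: float = 0.1
) -> CharacterMatrix:
    cells = rng.integers(0, 2, size=(n_taxa, n_chars)).astype(np.int8)
    if missing_frac:
        cells[rng.random((n_taxa, n_chars)) < missing_frac] = MISSING
    return CharacterMatrix(
        [f"T{i}" for i in range(n_taxa)],
        [CharacterDef(j + 1, f"c{j + 1}") for j in range(n_chars)],
        cells,
    )


def matrix_from_rows(taxa: list[str], rows: list[str]) -> CharacterMatrix:
    """Build a matrix from strings of 0/1/? symbols."""
    code = {"0": 0, "1": 1, "?": MISSING}
    cells = np.array([[code[c] for c in row] for row in rows], dtype=np.int8)
    chars = [CharacterDef(j + 1, f"c{j + 1}") for j in range(cells.shape[1])]
    return CharacterMatrix(taxa, chars, cells)


def quartet_tree(newick: str, taxa: list[str], rooted: bool = False) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    tree.is_rooted = rooted
    return tree


def random_binary_tree(
    rng: np.random.Generator, taxa: list[str], rooted: bool = False
) -> dendropy.Tree:
    """Uniform-ish random binary topology by sequential random attachment."""
    tops = list(taxa)
    node = [tops[0], tops[1]]
    structure = node
    nodes = [structure]
    for label in tops[2:]:
        target = nodes[int(rng.integers(0, len(nodes)))]
        slot = int(rng.integers(0, 2))
        new = [target[slot], label]
        target[slot] = new
        nodes.append(new)

    def render(nd) -> str:
        if isinstance(nd, str):
            return nd
        return f"({render(nd[0])},{render(nd[1])})"

    return quartet_tree(render(structure) + ";", taxa, rooted=rooted)


# ---------------------------------------------------------------------------
# Independent brute-force oracles


def brute_force_parsimony(tree: dendropy.Tree, column: np.ndarray, taxa: list[str]) -> int:
    """Minimum mutation count by enumerating every internal-state assignment
    (missing leaves may also take either state)."""
    observed = {t: int(v) for t, v in zip(taxa, column)}
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    free_leaves = [
        nd for nd in tree.leaf_node_iter() if observed[nd.taxon.label] == MISSING
    ]
    free = internals + free_leaves
    best = None
    for combo in itertools.product((0, 1), repeat=len(free)):
        state = dict(zip(map(id, free), combo))
        for nd in tree.leaf_node_iter():
            if observed[nd.taxon.label] != MISSING:
                state[id(nd)] = observed[nd.taxon.label]
        changes = 0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and state[id(nd)] != state[id(nd.parent_node)]:
                changes += 1
        best = changes if best is None else min(best, changes)
    return best


def brute_force_mpr_sets(
    tree: dendropy.Tree, column: np.ndarray, taxa: list[str]
) -> dict[int, set[int]]:
    """Per-internal-node MPR state sets: states achieving the global minimum
    when that node's state is fixed."""
    observed = {t: int(v) for t, v in zip(taxa, column)}
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    free_leaves = [
        nd for nd in tree.leaf_node_iter() if observed[nd.taxon.label] == MISSING
    ]
    free = internals + free_leaves
    scores: dict[tuple, int] = {}
    for combo in itertools.product((0, 1), repeat=len(free)):
        state = dict(zip(map(id, free), combo))
        for nd in tree.leaf_node_iter():
            if observed[nd.taxon.label] != MISSING:
                state[id(nd)] = observed[nd.taxon.label]
        changes = sum(
            1
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
            and state[id(nd)] != state[id(nd.parent_node)]
        )
        scores[combo] = changes
    overall = min(scores.values())
    sets: dict[int, set[int]] = {id(nd): set() for nd in internals}
    for combo, sc in scores.items():
        if sc == overall:
            for nd, s in zip(free, combo):
                if id(nd) in sets:
                    sets[id(nd)].add(s)
    return sets


def brute_force_mk_lik(tree: dendropy.Tree, column: np.ndarray, taxa: list[str]) -> float:
    """Mk likelihood of one character by summing over all internal-state
    assignments (and both states of missing leaves)."""
    from karyophylo.bayes import transition_matrix

    observed = {t: int(v) for t, v in zip(taxa, column)}
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    free_leaves = [
        nd for nd in tree.leaf_node_iter() if observed[nd.taxon.label] == MISSING
    ]
    free = internals + free_leaves
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(free)):
        state = dict(zip(map(id, free), combo))
        for nd in tree.leaf_node_iter():
            if observed[nd.taxon.label] != MISSING:
                state[id(nd)] = observed[nd.taxon.label]
        p = 0.5  # stationary probability of the root state
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            P = transition_matrix(nd.edge.length)
            p *= P[state[id(nd.parent_node)], state[id(nd)]]
        total += p
    return total
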
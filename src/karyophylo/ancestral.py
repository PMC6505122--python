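"""Ancestral-state reconstruction and ancestral-karyotype assembly.

Character states are reconstructed on a rooted tree with the Fitch
downpass/uppass, giving the most-parsimonious-reconstruction (MPR) state
set at every node.  The association characters whose state resolves to
"present" at a chosen node are then chained into linear chromosomes; the
remaining reference segments stay in the free acrocentric form.  Together
with morphology assignment (a chromosome is bi-armed when it spans both
arms of a reference chromosome or joins segments across a declared
centromere) this yields an ancestral karyotype proposal whose 2n and FN
are computed by the karyotype module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .coding import MISSING, CharacterMatrix, CharKind
from .karyotype import (
    Karyotype,
    KaryotypeError,
    Morphology,
    PaintedChromosome,
    SegmentID,
    SyntenicAssociation,
    compute_2n,
    compute_fn,
)

__all__ = [
    "AncestralStates",
    "AncestralKaryotypeProposal",
    "AncestralError",
    "AssemblyConflict",
    "reconstruct_states",
    "assemble_akp",
    "root_on_outgroup",
]

_SET0, _SET1, _SETQ = 1, 2, 3


class AncestralError(ValueError):
    pass


class AssemblyConflict(AncestralError):
    """An association set that cannot be chained into linear chromosomes."""


def root_on_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Return a copy of *tree* rooted on the edge leading to *outgroup*."""
    t = tree.clone(depth=1)
    leaf = next(
        (lf for lf in t.leaf_node_iter() if lf.taxon.label == outgroup), None
    )
    if leaf is None:
        raise AncestralError(f"outgroup {outgroup!r} not among tree leaves")
    t.reroot_at_edge(leaf.edge, update_bipartitions=False)
    t.is_rooted = True
    return t


@dataclass
class AncestralStates:
    """MPR state sets per node and character.

    ``node_states[node]`` is a uint8 array over characters with bitmask
    values 1 (state 0), 2 (state 1) and 3 (ambiguous {0, 1}).  Leaf sets
    equal the observed matrix states, with the full set for ``?``.
    """

    tree: dendropy.Tree
    matrix: CharacterMatrix
    node_states: Mapping[dendropy.Node, np.ndarray]

    def states(self, node: dendropy.Node) -> np.ndarray:
        return self.node_states[node]

    def root_states(self) -> np.ndarray:
        return self.node_states[self.tree.seed_node]

    def ingroup_root(self, outgroup: str) -> dendropy.Node:
        """The root's child whose subtree excludes *outgroup*."""
        kids = self.tree.seed_node.child_nodes()
        for nd in kids:
            leaves = {lf.taxon.label for lf in nd.leaf_iter()}
            if outgroup not in leaves:
                return nd
        raise AncestralError(f"no root child excludes outgroup {outgroup!r}")

    def ambiguous(self, node: dendropy.Node) -> np.ndarray:
        return self.node_states[node] == _SETQ


def reconstruct_states(tree: dendropy.Tree, m: CharacterMatrix) -> AncestralStates:
    """Fitch downpass + uppass MPR sets on a rooted tree.

    The tree must be rooted (outgroup rooting; see :func:`root_on_outgroup`)
    with a bifurcating root.  Deterministic.
    """
    if not tree.is_rooted or len(tree.seed_node.child_nodes()) != 2:
        raise AncestralError(
            "tree must be rooted (bifurcating root); root it on the outgroup first"
        )
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if leaves != sorted(m.taxa):
        raise AncestralError("tree leaves do not match matrix taxa")
    row = {t: i for i, t in enumerate(m.taxa)}
    sets = np.empty(m.cells.shape, dtype=np.uint8)
    sets[m.cells == 0] = _SET0
    sets[m.cells == 1] = _SET1
    sets[m.cells == MISSING] = _SETQ

    prelim: dict[dendropy.Node, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            prelim[nd] = sets[row[nd.taxon.label]].copy()
        else:
            kids = nd.child_nodes()
            acc = prelim[kids[0]].copy()
            for c in kids[1:]:
                inter = acc & prelim[c]
                union = acc | prelim[c]
                acc = np.where(inter != 0, inter, union).astype(np.uint8)
            prelim[nd] = acc

    final: dict[dendropy.Node, np.ndarray] = {}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            final[nd] = prelim[nd].copy()
            continue
        if nd.is_leaf():
            final[nd] = prelim[nd].copy()
            continue
        fp = final[nd.parent_node]
        s = prelim[nd]
        kids = nd.child_nodes()
        kid_union = np.zeros_like(s)
        kid_inter = np.full_like(s, _SETQ)
        for c in kids:
            kid_union |= prelim[c]
            kid_inter &= prelim[c]
        out = np.empty_like(s)
        case1 = (fp & s) == fp  # parent's final set fits inside prelim
        case2 = kid_inter != 0  # children intersected during the downpass
        out[:] = s | (fp & kid_union)
        out[case2 & ~case1] = (s | (fp & kid_union))[case2 & ~case1]
        out[~case2 & ~case1] = (s | fp)[~case2 & ~case1]
        out[case1] = fp[case1]
        final[nd] = out
    return AncestralStates(tree=tree, matrix=m, node_states=final)


@dataclass
class AncestralKaryotypeProposal:
    """An assembled ancestral complement with provenance.

    ``provenance`` maps each chromosome's index in the karyotype's
    autosome list to the association character labels supporting it;
    ``ambiguous_characters`` lists characters whose MPR set at the chosen
    node was {0, 1} and had to be resolved by rule.
    """

    karyotype: Karyotype
    provenance: dict[int, list[str]]
    ambiguous_characters: list[str]

    @property
    def diploid_number(self) -> int:
        return compute_2n(self.karyotype)

    @property
    def fundamental_number(self) -> int:
        return compute_fn(self.karyotype)


_P_PARTS = {"p", "p prox", "p dist"}
_Q_PARTS = {"q", "q prox", "q dist"}


def _is_centromere_boundary(
    a: SegmentID, b: SegmentID, centric: set[SyntenicAssociation]
) -> bool:
    if SyntenicAssociation(a, b) in centric:
        return True
    return (
        a.probe == b.probe
        and a.chromosome == b.chromosome
        and (
            (a.part.value in _P_PARTS and b.part.value in _Q_PARTS)
            or (a.part.value in _Q_PARTS and b.part.value in _P_PARTS)
        )
    )


def assemble_akp(
    states: AncestralStates,
    node: dendropy.Node | None = None,
    segments: Sequence[SegmentID] | None = None,
    whole_syntenies: Sequence[SegmentID] = (),
    centric_associations: Iterable[SyntenicAssociation] = (),
    resolve_ambiguous: str = "absent",
    sex_chromosomes: Sequence[PaintedChromosome] = (),
    taxon: str = "ancestor",
) -> AncestralKaryotypeProposal:
    """Assemble the ancestral karyotype implied by the states at *node*.

    Association characters resolving to present are chained into linear
    chromosomes (a segment participating in three associations is a
    conflict); *whole_syntenies* become single-segment chromosomes and all
    remaining *segments* stay as free acrocentrics.  A chromosome is
    bi-armed iff it spans p and q material of one reference chromosome or
    joins segments across a junction listed in *centric_associations*.
    Ambiguous {0, 1} root states resolve to the plesiomorphic absence by
    default (``resolve_ambiguous="absent"``), or to presence with
    ``"present"``; either way they are reported.
    """
    if node is None:
        node = states.tree.seed_node
    if segments is None:
        raise AncestralError("the full reference segment list is required")
    if resolve_ambiguous not in ("absent", "present"):
        raise AncestralError(f"unknown ambiguity rule {resolve_ambiguous!r}")
    centric = set(centric_associations)
    seg_pool = list(segments)
    seg_set = set(seg_pool)
    if len(seg_set) != len(seg_pool):
        raise AncestralError("duplicate segments in reference list")

    node_sets = states.states(node)
    present: list[tuple[SyntenicAssociation, str]] = []
    ambiguous: list[str] = []
    for j, char in enumerate(states.matrix.characters):
        if char.kind is not CharKind.ASSOCIATION:
            continue
        s = int(node_sets[j])
        if s == _SETQ:
            ambiguous.append(char.label)
            if resolve_ambiguous == "absent":
                continue
        elif s != _SET1:
            continue
        assoc = SyntenicAssociation.parse(char.label)
        if assoc.a not in seg_set or assoc.b not in seg_set:
            raise AncestralError(
                f"character {char.label!r} uses segments outside the reference list"
            )
        present.append((assoc, char.label))

    # chain the present associations into paths
    adjacency: dict[SegmentID, list[tuple[SegmentID, str]]] = {}
    for assoc, label in present:
        adjacency.setdefault(assoc.a, []).append((assoc.b, label))
        adjacency.setdefault(assoc.b, []).append((assoc.a, label))
    overloaded = [s for s, nb in adjacency.items() if len(nb) > 2]
    if overloaded:
        chars = sorted(
            {lab for s in overloaded for _, lab in adjacency[s]}
        )
        raise AssemblyConflict(
            f"segments {[str(s) for s in overloaded]} join more than two "
            f"neighbours; conflicting characters: {chars}"
        )

    visited: set[SegmentID] = set()
    chains: list[tuple[list[SegmentID], list[str]]] = []
    for start in sorted(adjacency, key=lambda s: s.render()):
        if start in visited or len(adjacency[start]) != 1:
            continue
        chain, labels = [start], []
        visited.add(start)
        prev, cur = None, start
        while True:
            nxt = [(s, lab) for s, lab in adjacency[cur] if s != prev]
            if not nxt:
                break
            (nseg, lab) = nxt[0]
            if nseg in visited:
                raise AssemblyConflict(
                    f"cycle through segment {nseg}; character {lab!r}"
                )
            labels.append(lab)
            chain.append(nseg)
            visited.add(nseg)
            prev, cur = cur, nseg
        chains.append((chain, labels))
    cyclic = set(adjacency) - visited
    if cyclic:
        raise AssemblyConflict(
            f"associations form a cycle over {[str(s) for s in sorted(cyclic, key=str)]}"
        )

    autosomes: list[PaintedChromosome] = []
    provenance: dict[int, list[str]] = {}
    used: set[SegmentID] = set()
    for chain, labels in chains:
        boundaries = [
            i + 1
            for i, (a, b) in enumerate(zip(chain, chain[1:]))
            if _is_centromere_boundary(a, b, centric)
        ]
        if boundaries:
            ci = boundaries[0]
            # orient p material first when the boundary is a p/q split
            left, right = chain[ci - 1], chain[ci]
            if (
                left.probe == right.probe
                and left.chromosome == right.chromosome
                and left.part.value in _Q_PARTS
            ):
                chain = list(reversed(chain))
                ci = len(chain) - ci
            chrom = PaintedChromosome(
                tuple(chain), Morphology.SUBMETACENTRIC, ci
            )
        else:
            chrom = PaintedChromosome(tuple(chain))
        provenance[len(autosomes)] = labels
        autosomes.append(chrom)
        used |= set(chain)

    for seg in whole_syntenies:
        if seg in used:
            continue
        autosomes.append(PaintedChromosome((seg,)))
        used.add(seg)
    for seg in seg_pool:
        if seg not in used:
            autosomes.append(PaintedChromosome((seg,)))
            used.add(seg)

    karyo = Karyotype(taxon, tuple(autosomes), tuple(sex_chromosomes))
    counts = karyo.segment_multiset()
    if set(counts) != seg_set or any(v != 1 for v in counts.values()):
        raise AncestralError("assembly did not use each segment exactly once")
    return AncestralKaryotypeProposal(
        karyotype=karyo, provenance=provenance, ambiguous_characters=ambiguous
    )
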
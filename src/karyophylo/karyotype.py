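"""Painted karyotypes and the rearrangement algebra.

A karyotype is modelled at chromosome-painting resolution: every chromosome
of a target species is an ordered list of segments homologous to whole
chromosomes (or chromosome arms) of a reference species whose paint probes
were hybridised onto it.  From this representation the module derives the
classical cytogenetic bookkeeping quantities — the diploid number 2n and the
fundamental number FN (autosomal arm count) — the set of syntenic
associations (two reference segments adjacent on one chromosome, the binary
phylogenetic character used throughout the package), and an algebra of
chromosomal rearrangements (Robertsonian and tandem fusions, fissions,
inversions, whole-arm reciprocal translocations) that can be applied to a
karyotype and greedily counted between two karyotypes.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Part",
    "Morphology",
    "EventKind",
    "SegmentID",
    "PaintedChromosome",
    "Karyotype",
    "SyntenicAssociation",
    "RearrangementEvent",
    "EventCount",
    "KaryotypeError",
    "compute_2n",
    "compute_fn",
    "list_associations",
    "apply_event",
    "inverse_event",
    "count_events",
    "centric_junctions",
    "proposed_ancestral_karyotype",
    "read_karyotype_tsv",
    "write_karyotype_tsv",
]


class KaryotypeError(ValueError):
    """Raised for ill-formed karyotypes or invalid rearrangement events."""


class Part(str, enum.Enum):
    """Sub-chromosomal resolution of a paint segment.

    ``WHOLE`` is a whole reference chromosome; ``P``/``Q`` are arms;
    the ``*_PROX``/``*_DIST`` values split an arm into proximal and distal
    blocks, the finest granularity used in painting maps (e.g. "13q prox").
    """

    WHOLE = "whole"
    P = "p"
    Q = "q"
    P_PROX = "p prox"
    P_DIST = "p dist"
    Q_PROX = "q prox"
    Q_DIST = "q dist"


_PART_SUFFIX = {
    Part.WHOLE: "",
    Part.P: "p",
    Part.Q: "q",
    Part.P_PROX: "p prox",
    Part.P_DIST: "p dist",
    Part.Q_PROX: "q prox",
    Part.Q_DIST: "q dist",
}

_SEGMENT_RE = re.compile(
    r"^\s*(?P<probe>[A-Za-z]{2,5})\s+(?P<chrom>\d+|[XYxy])\s*"
    r"(?P<arm>[pq])?\s*(?P<block>prox|dist)?\s*$"
)


@dataclass(frozen=True, order=True)
class SegmentID:
    """A paint segment: one reference-species chromosome (arm/block).

    Renders as ``"<probe> <chromosome><part>"`` (e.g. ``"PHA 13q prox"``)
    and round-trips through :meth:`parse`.
    """

    probe: str
    chromosome: int | str
    part: Part = Part.WHOLE

    def __post_init__(self) -> None:
        if isinstance(self.chromosome, str):
            chrom = self.chromosome.upper()
            if chrom.isdigit():
                object.__setattr__(self, "chromosome", int(chrom))
            elif chrom in ("X", "Y"):
                object.__setattr__(self, "chromosome", chrom)
            else:
                raise KaryotypeError(f"bad chromosome label: {self.chromosome!r}")
        elif self.chromosome < 1:
            raise KaryotypeError("chromosome number must be positive")
        object.__setattr__(self, "probe", self.probe.upper())
        object.__setattr__(self, "part", Part(self.part))

    def render(self) -> str:
        suffix = _PART_SUFFIX[self.part]
        return f"{self.probe} {self.chromosome}{suffix}"

    __str__ = render

    @classmethod
    def parse(cls, text: str) -> "SegmentID":
        m = _SEGMENT_RE.match(text)
        if m is None:
            raise KaryotypeError(f"unparseable segment label: {text!r}")
        arm, block = m.group("arm"), m.group("block")
        if arm is None:
            if block is not None:
                raise KaryotypeError(f"block without arm in segment label: {text!r}")
            part = Part.WHOLE
        else:
            part = Part(arm if block is None else f"{arm} {block}")
        return cls(m.group("probe"), m.group("chrom"), part)


class Morphology(str, enum.Enum):
    METACENTRIC = "metacentric"
    SUBMETACENTRIC = "submetacentric"
    SUBTELOCENTRIC = "subtelocentric"
    ACROCENTRIC = "acrocentric"

    @property
    def biarmed(self) -> bool:
        # subtelocentric counts as bi-armed: two-way bi-armed/acrocentric
        # bookkeeping is what the FN arithmetic uses
        return self is not Morphology.ACROCENTRIC


@dataclass(frozen=True)
class PaintedChromosome:
    """One chromosome (pair) as an ordered pter→qter list of paint segments.

    ``centromere_index`` is the number of segments on the p side of the
    centromere: 0 for acrocentrics; for bi-armed chromosomes it is in
    ``1..len(segments)`` (the value ``len(segments)`` marks a centromere
    falling inside the last listed segment — a bi-armed chromosome whose
    paint resolution does not split it at the centromere).
    """

    segments: tuple[SegmentID, ...]
    morphology: Morphology = Morphology.ACROCENTRIC
    centromere_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "morphology", Morphology(self.morphology))
        if not self.segments:
            raise KaryotypeError("chromosome must carry at least one segment")
        ci = self.centromere_index
        if self.morphology is Morphology.ACROCENTRIC:
            if ci != 0:
                raise KaryotypeError("acrocentric ⇔ centromere_index == 0")
        else:
            if not 1 <= ci <= len(self.segments):
                raise KaryotypeError(
                    f"bi-armed chromosome needs centromere_index in "
                    f"1..{len(self.segments)}, got {ci}"
                )

    @property
    def biarmed(self) -> bool:
        return self.morphology.biarmed

    @property
    def p_arm(self) -> tuple[SegmentID, ...]:
        return self.segments[: self.centromere_index]

    @property
    def q_arm(self) -> tuple[SegmentID, ...]:
        return self.segments[self.centromere_index :]

    def render(self) -> str:
        return ";".join(s.render() for s in self.segments)


@dataclass(frozen=True)
class Karyotype:
    """A species' chromosomal complement, one entry per homologous pair."""

    taxon: str
    autosome_pairs: tuple[PaintedChromosome, ...]
    sex_chromosomes: tuple[PaintedChromosome, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "autosome_pairs", tuple(self.autosome_pairs))
        object.__setattr__(self, "sex_chromosomes", tuple(self.sex_chromosomes))

    @property
    def probes(self) -> frozenset[str]:
        return frozenset(
            s.probe for c in self.autosome_pairs + self.sex_chromosomes for s in c.segments
        )

    def segment_multiset(self, include_sex: bool = False) -> Counter:
        chroms = self.autosome_pairs + (self.sex_chromosomes if include_sex else ())
        return Counter(s for c in chroms for s in c.segments)


def compute_2n(k: Karyotype) -> int:
    """Diploid number: two per autosomal pair plus the diploid sex pair."""
    return 2 * len(k.autosome_pairs) + 2


def compute_fn(k: Karyotype) -> int:
    """Fundamental number: autosomal arms over the diploid complement.

    Each bi-armed autosomal pair contributes 4 arms, each acrocentric pair
    2; sex chromosomes are excluded.  (A complement of 15 bi-armed pairs
    therefore has FN = 60.)
    """
    n_bi = sum(c.biarmed for c in k.autosome_pairs)
    n_acro = len(k.autosome_pairs) - n_bi
    return 4 * n_bi + 2 * n_acro


@dataclass(frozen=True)
class SyntenicAssociation:
    """Unordered adjacency of two reference segments on one chromosome.

    Canonicalised so that ``{8q, 12q}`` and ``{12q, 8q}`` compare equal;
    renders in the field's notation, e.g. ``"PHA 8q/12q"``.
    """

    a: SegmentID
    b: SegmentID

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise KaryotypeError("association needs two distinct segments")
        if self.b.render() < self.a.render():
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)

    def render(self) -> str:
        if self.a.probe == self.b.probe:
            right = self.b.render()[len(self.b.probe) + 1 :]
            return f"{self.a.render()}/{right}"
        return f"{self.a.render()}/{self.b.render()}"

    __str__ = render

    @classmethod
    def parse(cls, text: str) -> "SyntenicAssociation":
        left, _, right = text.partition("/")
        if not right:
            raise KaryotypeError(f"not an association label: {text!r}")
        a = SegmentID.parse(left)
        try:
            b = SegmentID.parse(right)
        except KaryotypeError:
            b = SegmentID.parse(f"{a.probe} {right}")  # probe elided on the right
        return cls(a, b)


def list_associations(
    k: Karyotype, reference: str, include_sex: bool = False
) -> set[SyntenicAssociation]:
    """All syntenic associations of *k* with probe *reference*.

    Every adjacent pair of reference-probe segments on one chromosome yields
    one canonical association; chromosomes carrying a single reference
    segment (whole-chromosome syntenies) contribute none.
    """
    reference = reference.upper()
    if reference not in k.probes:
        raise KaryotypeError(f"probe {reference!r} absent from karyotype of {k.taxon}")
    chroms = k.autosome_pairs + (k.sex_chromosomes if include_sex else ())
    out: set[SyntenicAssociation] = set()
    for chrom in chroms:
        ref_segs = [s for s in chrom.segments if s.probe == reference]
        for left, right in zip(ref_segs, ref_segs[1:]):
            if left != right:
                out.add(SyntenicAssociation(left, right))
    return out


# ---------------------------------------------------------------------------
# Rearrangement events


class EventKind(str, enum.Enum):
    ROBERTSONIAN_FUSION = "robertsonian_fusion"
    TANDEM_FUSION = "tandem_fusion"
    FISSION = "fission"
    INVERSION = "inversion"
    WART = "wart"


@dataclass(frozen=True)
class RearrangementEvent:
    """A typed karyotype mutation with its operands.

    ``operands`` index ``autosome_pairs`` of the karyotype the event is
    applied to.  Extra fields are interpreted per kind:

    * fission: ``split_index`` (segment-boundary, 1..len-1 of the donor) and
      ``distal_only`` — False is a centric fission (bi-armed → two
      acrocentrics, split at the centromere), True detaches a terminal block
      that does not carry the centromere (the donor keeps its morphology and
      a new acrocentric pair appears).
    * inversion: ``span`` = half-open segment range reversed; ``pericentric``
      marks spans containing the centromere, and ``new_centromere_index``
      optionally repositions the centromere (morphology may toggle).
    * wart (whole-arm reciprocal translocation): ``arms`` names the exchanged
      arm ("p"/"q") of each operand.
    """

    kind: EventKind
    operands: tuple[int, ...]
    split_index: int | None = None
    distal_only: bool = False
    span: tuple[int, int] | None = None
    pericentric: bool = False
    new_centromere_index: int | None = None
    arms: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", EventKind(self.kind))
        object.__setattr__(self, "operands", tuple(self.operands))


@dataclass(frozen=True)
class EventCount:
    fissions: int = 0
    fusions: int = 0
    inversions: int = 0

    @property
    def total(self) -> int:
        return self.fissions + self.fusions + self.inversions


def _check_operands(k: Karyotype, e: RearrangementEvent, n: int) -> None:
    if len(e.operands) != n:
        raise KaryotypeError(f"{e.kind.value} takes {n} operand(s)")
    for i in e.operands:
        if not 0 <= i < len(k.autosome_pairs):
            raise KaryotypeError(f"operand index {i} out of range")
    if n == 2 and e.operands[0] == e.operands[1]:
        raise KaryotypeError("operands must be distinct pairs")


def apply_event(k: Karyotype, e: RearrangementEvent) -> Karyotype:
    """Apply one rearrangement, returning a new karyotype.

    Conservation contracts (autosomal 2n/FN deltas):

    ==========================  =====  =====
    event                        Δ2n    ΔFN
    ==========================  =====  =====
    robertsonian_fusion          −2      0
    tandem_fusion                −2     −2
    fission (centric)            +2      0
    fission (distal_only)        +2     +2
    inversion                     0      0 (±2 on morphology toggle)
    wart                          0      0
    ==========================  =====  =====
    """
    pairs = list(k.autosome_pairs)
    if e.kind is EventKind.ROBERTSONIAN_FUSION:
        _check_operands(k, e, 2)
        i, j = e.operands
        a, b = pairs[i], pairs[j]
        if a.biarmed or b.biarmed:
            raise KaryotypeError("robertsonian fusion requires two acrocentric operands")
        # a's centromere-proximal end meets b's: a becomes the (reversed) p arm
        fused = PaintedChromosome(
            tuple(reversed(a.segments)) + b.segments,
            Morphology.METACENTRIC,
            centromere_index=len(a.segments),
        )
        pairs[i] = fused
        del pairs[j]
    elif e.kind is EventKind.TANDEM_FUSION:
        _check_operands(k, e, 2)
        i, j = e.operands
        acceptor, donor = pairs[i], pairs[j]
        if donor.biarmed:
            raise KaryotypeError("tandem fusion donor must be acrocentric")
        fused = PaintedChromosome(
            acceptor.segments + donor.segments,
            acceptor.morphology,
            acceptor.centromere_index,
        )
        pairs[i] = fused
        del pairs[j]
    elif e.kind is EventKind.FISSION:
        _check_operands(k, e, 1)
        (i,) = e.operands
        donor = pairs[i]
        s = e.split_index if e.split_index is not None else donor.centromere_index
        if not 1 <= s <= len(donor.segments) - 1:
            raise KaryotypeError(f"split point {s} outside chromosome")
        head, tail = donor.segments[:s], donor.segments[s:]
        if not e.distal_only:
            if not donor.biarmed:
                raise KaryotypeError("centric fission requires a bi-armed donor")
            if s != donor.centromere_index:
                raise KaryotypeError("centric fission must split at the centromere")
            # p-arm piece re-reads cen→pter as a new acrocentric
            pairs[i] = PaintedChromosome(tuple(reversed(head)))
            pairs.append(PaintedChromosome(tail))
        else:
            ci = donor.centromere_index
            if donor.biarmed and s < ci:
                # distal block of the p arm breaks off; donor keeps both arms
                new = PaintedChromosome(tuple(reversed(head)))
                pairs[i] = PaintedChromosome(tail, donor.morphology, ci - s)
            elif donor.biarmed and s > ci:
                new = PaintedChromosome(tail)
                pairs[i] = PaintedChromosome(head, donor.morphology, ci)
            elif donor.biarmed:
                raise KaryotypeError(
                    "distal fission split point must not fall on the centromere"
                )
            else:  # acrocentric donor: distal block of the single arm
                new = PaintedChromosome(tail)
                pairs[i] = PaintedChromosome(head)
            pairs.append(new)
    elif e.kind is EventKind.INVERSION:
        _check_operands(k, e, 1)
        (i,) = e.operands
        chrom = pairs[i]
        if e.span is None:
            raise KaryotypeError("inversion needs a span")
        lo, hi = e.span
        if not 0 <= lo < hi <= len(chrom.segments):
            raise KaryotypeError(f"inversion span {e.span} outside chromosome")
        segs = (
            chrom.segments[:lo]
            + tuple(reversed(chrom.segments[lo:hi]))
            + chrom.segments[hi:]
        )
        ci = chrom.centromere_index
        if e.pericentric:
            if e.new_centromere_index is not None:
                ci = e.new_centromere_index
            elif lo < ci < hi:
                ci = lo + hi - ci
            if ci == 0:
                morph = Morphology.ACROCENTRIC
            elif chrom.morphology is Morphology.ACROCENTRIC:
                morph = Morphology.SUBMETACENTRIC
            else:
                morph = chrom.morphology
        else:
            if lo < ci < hi:
                raise KaryotypeError("paracentric span must not contain the centromere")
            morph = chrom.morphology
        pairs[i] = PaintedChromosome(segs, morph, ci)
    elif e.kind is EventKind.WART:
        _check_operands(k, e, 2)
        i, j = e.operands
        a, b = pairs[i], pairs[j]
        if not (a.biarmed and b.biarmed):
            raise KaryotypeError("WART requires two bi-armed operands")
        if a.centromere_index >= len(a.segments) or b.centromere_index >= len(b.segments):
            raise KaryotypeError("WART operands need segment-resolved arms")
        arm_a, arm_b = e.arms if e.arms is not None else ("p", "p")
        pa, qa = a.p_arm, a.q_arm
        pb, qb = b.p_arm, b.q_arm
        give_a = pa if arm_a == "p" else qa
        give_b = pb if arm_b == "p" else qb
        if not (give_a and give_b):
            raise KaryotypeError("WART arm is empty at paint resolution")
        # exchange whole arms, preserving pter→qter reading of each product
        new_a_p = give_b if arm_a == "p" else pa
        new_a_q = qa if arm_a == "p" else give_b
        new_b_p = give_a if arm_b == "p" else pb
        new_b_q = qb if arm_b == "p" else give_a
        # a q arm moved into p position (or vice versa) flips reading direction
        if arm_a == "p" and arm_b == "q":
            new_a_p = tuple(reversed(give_b))
            new_b_q = tuple(reversed(give_a))
        elif arm_a == "q" and arm_b == "p":
            new_a_q = tuple(reversed(give_b))
            new_b_p = tuple(reversed(give_a))
        pairs[i] = PaintedChromosome(
            new_a_p + new_a_q, a.morphology, len(new_a_p)
        )
        pairs[j] = PaintedChromosome(
            new_b_p + new_b_q, b.morphology, len(new_b_p)
        )
    else:  # pragma: no cover
        raise KaryotypeError(f"unknown event kind {e.kind}")
    return replace(k, autosome_pairs=tuple(pairs))


def inverse_event(k: Karyotype, e: RearrangementEvent) -> RearrangementEvent | None:
    """The event undoing *e* on ``apply_event(k, e)``, when well defined.

    Fusions invert to fissions of the fused pair and vice versa; paracentric
    inversions are self-inverse.  Returns None for events whose inverse is
    not expressible as a single event (e.g. tandem fusion into mid-arm).
    """
    if e.kind is EventKind.ROBERTSONIAN_FUSION:
        i = e.operands[0]
        return RearrangementEvent(EventKind.FISSION, (i,), distal_only=False)
    if e.kind is EventKind.INVERSION and not e.pericentric:
        return RearrangementEvent(EventKind.INVERSION, e.operands, span=e.span)
    if e.kind is EventKind.FISSION and not e.distal_only:
        i = e.operands[0]
        return RearrangementEvent(
            EventKind.ROBERTSONIAN_FUSION, (i, len(k.autosome_pairs))
        )
    if e.kind is EventKind.WART:
        return RearrangementEvent(EventKind.WART, e.operands, arms=e.arms)
    return None


def centric_junctions(k: Karyotype, include_sex: bool = False) -> set[SyntenicAssociation]:
    """Segment adjacencies of *k* that straddle a centromere.

    Useful as morphology hints when re-assembling an ancestral complement
    from association characters: a chromosome re-formed across one of these
    junctions is bi-armed.
    """
    out: set[SyntenicAssociation] = set()
    chroms = k.autosome_pairs + (k.sex_chromosomes if include_sex else ())
    for c in chroms:
        ci = c.centromere_index
        if c.biarmed and 1 <= ci <= len(c.segments) - 1:
            left, right = c.segments[ci - 1], c.segments[ci]
            if left != right:
                out.add(SyntenicAssociation(left, right))
    return out


def count_events(derived: Karyotype, ancestor: Karyotype) -> EventCount:
    """Greedy lower-bound rearrangement count between two painted karyotypes.

    Compares autosomal complements sharing one reference probe set:

    * each ancestral chromosome whose segments end up on k ≥ 2 derived
      chromosomes contributes k − 1 fissions;
    * each derived chromosome drawing segments from k ≥ 2 ancestral
      chromosomes contributes k − 1 fusions;
    * a derived chromosome is counted as carrying an inversion when any of
      its maximal single-source segment runs is not a contiguous
      subsequence (forward or reversed) of its ancestral source order.

    This is a parsimony-flavoured tally, not an exact rearrangement
    distance; it matches the true history when events do not reuse the same
    chromosomes.
    """
    anc_sets = [c.segments for c in ancestor.autosome_pairs]
    der_sets = [c.segments for c in derived.autosome_pairs]
    if Counter(s for c in anc_sets for s in c) != Counter(s for c in der_sets for s in c):
        raise KaryotypeError(
            f"probe/segment sets differ between {derived.taxon} and {ancestor.taxon}"
        )
    seg_to_anc: dict[SegmentID, int] = {}
    for ai, segs in enumerate(anc_sets):
        for s in segs:
            if s in seg_to_anc:
                raise KaryotypeError(f"segment {s} duplicated in ancestor")
            seg_to_anc[s] = ai
    seg_to_der: dict[SegmentID, int] = {}
    for di, segs in enumerate(der_sets):
        for s in segs:
            if s in seg_to_der:
                raise KaryotypeError(f"segment {s} duplicated in derived karyotype")
            seg_to_der[s] = di

    fissions = 0
    for segs in anc_sets:
        targets = {seg_to_der[s] for s in segs}
        fissions += len(targets) - 1
    fusions = 0
    for segs in der_sets:
        sources = {seg_to_anc[s] for s in segs}
        fusions += len(sources) - 1

    inversions = 0
    anc_pos = {s: (seg_to_anc[s], i) for segs in anc_sets for i, s in enumerate(segs)}
    for segs in der_sets:
        ok = True
        run_start = 0
        for i in range(1, len(segs) + 1):
            if i == len(segs) or seg_to_anc[segs[i]] != seg_to_anc[segs[run_start]]:
                run = segs[run_start:i]
                positions = [anc_pos[s][1] for s in run]
                up = all(b == a + 1 for a, b in zip(positions, positions[1:]))
                down = all(b == a - 1 for a, b in zip(positions, positions[1:]))
                if not (up or down):
                    ok = False
                run_start = i
        if not ok:
            inversions += 1
    return EventCount(fissions=fissions, fusions=fusions, inversions=inversions)


# ---------------------------------------------------------------------------
# Reference complements and serialization


def _bi(segs: str, ci: int, morph: Morphology = Morphology.SUBMETACENTRIC) -> PaintedChromosome:
    return PaintedChromosome(
        tuple(SegmentID.parse(t) for t in segs.split(";")), morph, ci
    )


def _acro(segs: str) -> PaintedChromosome:
    return PaintedChromosome(tuple(SegmentID.parse(t) for t in segs.split(";")))


def proposed_ancestral_karyotype() -> Karyotype:
    """The putative ancestral complement of Phyllostomidae in PHA paint.

    2n = 42 / FN = 60: ten bi-armed autosomal pairs (conserved bi-armed
    whole chromosomes PHA 7–11, 13p+q prox, 14, and the fusion products
    carrying the ancestral associations PHA 6q/3q, 6p/4q and 5p/2q), ten
    free acrocentric pairs, and a bi-armed X — eleven bi-armed pairs
    counting the X.
    """
    biarmed = [
        _bi("PHA 3q;PHA 6q", 1),
        _bi("PHA 6p;PHA 4q", 1),
        _bi("PHA 5p;PHA 2q", 1),
        _bi("PHA 7p;PHA 7q", 1),
        _bi("PHA 8p;PHA 8q", 1),
        _bi("PHA 9p;PHA 9q", 1),
        _bi("PHA 10p;PHA 10q", 1),
        _bi("PHA 11p;PHA 11q", 1),
        _bi("PHA 13p;PHA 13q prox", 1),
        _bi("PHA 14p;PHA 14q", 1),
    ]
    acro = [
        _acro("PHA 1p"),
        _acro("PHA 1q"),
        _acro("PHA 2p"),
        _acro("PHA 3p"),
        _acro("PHA 4p"),
        _acro("PHA 5q"),
        _acro("PHA 12p"),
        _acro("PHA 12q"),
        _acro("PHA 13q dist"),
        _acro("PHA 15"),
    ]
    x = PaintedChromosome(
        (SegmentID("PHA", "X"),), Morphology.METACENTRIC, centromere_index=1
    )
    return Karyotype("AKP", tuple(biarmed + acro), (x,))


_TSV_COLUMNS = ["taxon", "pair_id", "morphology", "centromere_index", "segments"]


def write_karyotype_tsv(karyotypes: Iterable[Karyotype] | Karyotype, path: str | Path) -> None:
    """One row per chromosome pair; sex pairs get ids ``SX1``, ``SX2``…"""
    if isinstance(karyotypes, Karyotype):
        karyotypes = [karyotypes]
    rows = []
    for k in karyotypes:
        for i, c in enumerate(k.autosome_pairs, start=1):
            rows.append((k.taxon, str(i), c.morphology.value, c.centromere_index, c.render()))
        for i, c in enumerate(k.sex_chromosomes, start=1):
            rows.append((k.taxon, f"SX{i}", c.morphology.value, c.centromere_index, c.render()))
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_karyotype_tsv(path: str | Path) -> list[Karyotype]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise KaryotypeError(f"karyotype TSV missing columns: {sorted(missing)}")
    out: list[Karyotype] = []
    for taxon, group in df.groupby("taxon", sort=False):
        autosomes, sex = [], []
        for _, row in group.iterrows():
            chrom = PaintedChromosome(
                tuple(SegmentID.parse(t) for t in str(row["segments"]).split(";")),
                Morphology(row["morphology"]),
                int(row["centromere_index"]),
            )
            (sex if str(row["pair_id"]).startswith("SX") else autosomes).append(chrom)
        out.append(Karyotype(str(taxon), tuple(autosomes), tuple(sex)))
    return out
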
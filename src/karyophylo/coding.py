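"""Binary syntenic-association character matrices.

Chromosome-painting homology maps are turned into taxa × characters binary
matrices: each character is the presence/absence of one syntenic
association with a reference complement (plus optional pre-declared
inversion or morphology characters).  The module also handles a-priori
polarization against an outgroup, filtering to parsimony-informative
characters, and NEXUS/TSV (de)serialization.

Cells take values 0, 1 or ``?`` (missing: the taxon was not painted with
the probes the character is defined on); internally ``?`` is stored as −1.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .karyotype import Karyotype, KaryotypeError, SyntenicAssociation, list_associations

__all__ = [
    "CharKind",
    "CharacterDef",
    "CharacterMatrix",
    "MatrixError",
    "MISSING",
    "build_matrix",
    "polarize",
    "filter_informative",
    "read_nexus",
    "write_nexus",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

MISSING = -1


class MatrixError(ValueError):
    pass


class CharKind(str, enum.Enum):
    ASSOCIATION = "association"
    INVERSION = "inversion"
    MORPHOLOGY = "morphology"


@dataclass(frozen=True)
class CharacterDef:
    id: int
    label: str
    kind: CharKind = CharKind.ASSOCIATION


@dataclass
class CharacterMatrix:
    """Taxa × binary characters with 0/1/? cells.

    ``cells`` is an int8 array with −1 (:data:`MISSING`) standing for ``?``.
    ``metadata`` carries provenance such as the polarization flip mask.
    """

    taxa: list[str]
    characters: list[CharacterDef]
    cells: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.taxa), len(self.characters)):
            raise MatrixError(
                f"cell block {self.cells.shape} inconsistent with "
                f"{len(self.taxa)} taxa × {len(self.characters)} characters"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixError("duplicate taxon codes")
        labels = [c.label for c in self.characters]
        if len(set(labels)) != len(labels):
            raise MatrixError("duplicate character labels")
        bad = ~np.isin(self.cells, (0, 1, MISSING))
        if bad.any():
            raise MatrixError("cells must be 0, 1 or ? (−1)")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.cells[self.taxa.index(taxon)]
        except ValueError:
            raise MatrixError(f"taxon {taxon!r} not in matrix") from None

    def column(self, label_or_index: str | int) -> np.ndarray:
        if isinstance(label_or_index, str):
            labels = [c.label for c in self.characters]
            label_or_index = labels.index(label_or_index)
        return self.cells[:, label_or_index]

    def drop_taxa(self, taxa: Iterable[str]) -> "CharacterMatrix":
        drop = set(taxa)
        keep = [i for i, t in enumerate(self.taxa) if t not in drop]
        return CharacterMatrix(
            [self.taxa[i] for i in keep],
            list(self.characters),
            self.cells[keep, :],
            dict(self.metadata),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.cells, index=self.taxa, columns=[c.label for c in self.characters]
        )
        return df.astype(object).mask(df.values == MISSING, "?")


def build_matrix(
    karyotypes: Sequence[Karyotype],
    reference: str,
    extra_characters: Sequence[CharacterDef] = (),
    extra_cells: np.ndarray | None = None,
) -> CharacterMatrix:
    """Code presence/absence of every observed syntenic association.

    The character set is the union, over all input karyotypes, of the
    associations each shows with the *reference* probes.  A taxon scores 1
    for an association it carries, 0 for one it lacks while being painted
    with the reference, and ``?`` when the reference probes were never
    hybridised onto it.  Pre-declared inversion/morphology characters can be
    appended via *extra_characters*/*extra_cells* (taxon rows in input
    order); they are not auto-detected.
    """
    if len(karyotypes) < 2:
        raise MatrixError("need at least two karyotypes")
    taxa = [k.taxon for k in karyotypes]
    if len(set(taxa)) != len(taxa):
        raise MatrixError("duplicate taxon codes among karyotypes")
    reference = reference.upper()
    per_taxon: dict[str, set[SyntenicAssociation] | None] = {}
    universe: set[SyntenicAssociation] = set()
    for k in karyotypes:
        if reference in k.probes:
            assoc = list_associations(k, reference)
            universe |= assoc
            per_taxon[k.taxon] = assoc
        else:
            per_taxon[k.taxon] = None
    if not universe and not extra_characters:
        raise MatrixError(f"no syntenic associations with probe {reference!r} observed")
    ordered = sorted(universe, key=lambda a: a.render())
    characters = [
        CharacterDef(i + 1, a.render(), CharKind.ASSOCIATION)
        for i, a in enumerate(ordered)
    ]
    cells = np.empty((len(taxa), len(ordered)), dtype=np.int8)
    for r, k in enumerate(karyotypes):
        assoc = per_taxon[k.taxon]
        if assoc is None:
            cells[r, :] = MISSING
        else:
            cells[r, :] = [1 if a in assoc else 0 for a in ordered]
    if extra_characters:
        extra_cells = np.asarray(extra_cells, dtype=np.int8)
        if extra_cells.shape != (len(taxa), len(extra_characters)):
            raise MatrixError("extra character block has wrong shape")
        base = len(characters)
        characters += [
            CharacterDef(base + i + 1, c.label, c.kind)
            for i, c in enumerate(extra_characters)
        ]
        cells = np.hstack([cells, extra_cells])
    return CharacterMatrix(taxa, characters, cells, {"reference": reference})


def polarize(m: CharacterMatrix, outgroup: str) -> CharacterMatrix:
    """Recode characters so that state 0 is the outgroup (plesiomorphic) state.

    Exactly the columns where the outgroup scores 1 are flipped in every
    non-missing cell; the flip mask is stored under
    ``metadata["polarized_flips"]``, so applying :func:`polarize` twice
    restores the original cells.
    """
    out_row = m.row(outgroup)
    if (out_row == MISSING).any():
        raise MatrixError(f"outgroup {outgroup!r} has missing cells; cannot polarize")
    flips = out_row == 1
    cells = m.cells.copy()
    observed = cells != MISSING
    cells[:, flips] = np.where(
        observed[:, flips], 1 - cells[:, flips], cells[:, flips]
    )
    meta = dict(m.metadata)
    prev = meta.get("polarized_flips")
    meta["polarized_flips"] = flips ^ prev if prev is not None else flips
    meta["outgroup"] = outgroup
    return CharacterMatrix(list(m.taxa), list(m.characters), cells, meta)


def filter_informative(
    m: CharacterMatrix,
) -> tuple[CharacterMatrix, list[CharacterDef]]:
    """Keep parsimony-informative characters (≥2 taxa in each of ≥2 states)."""
    ones = (m.cells == 1).sum(axis=0)
    zeros = (m.cells == 0).sum(axis=0)
    keep = (ones >= 2) & (zeros >= 2)
    dropped = [c for c, k in zip(m.characters, keep) if not k]
    kept = [c for c, k in zip(m.characters, keep) if k]
    return (
        CharacterMatrix(list(m.taxa), kept, m.cells[:, keep], dict(m.metadata)),
        dropped,
    )


# ---------------------------------------------------------------------------
# NEXUS serialization


def _nexus_quote(label: str) -> str:
    if re.fullmatch(r"[\w.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus(m: CharacterMatrix, path: str | Path) -> None:
    """Write a standard-datatype NEXUS DATA block with CHARSTATELABELS."""
    lines = ["#NEXUS", "", "BEGIN DATA;"]
    lines.append(f"    DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_characters};")
    lines.append('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;')
    labels = ", ".join(
        f"{i + 1} {_nexus_quote(c.label)}" for i, c in enumerate(m.characters)
    )
    lines.append(f"    CHARSTATELABELS {labels};")
    lines.append("    MATRIX")
    width = max(len(_nexus_quote(t)) for t in m.taxa) + 2
    symbols = {0: "0", 1: "1", MISSING: "?"}
    for taxon, row in zip(m.taxa, m.cells):
        body = "".join(symbols[int(v)] for v in row)
        lines.append(f"        {_nexus_quote(taxon):<{width}}{body}")
    lines.append("    ;")
    lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")


_CHARSTATELABELS_RE = re.compile(
    r"CHARSTATELABELS\s+(?P<body>.*?);", re.IGNORECASE | re.DOTALL
)
_LABEL_ENTRY_RE = re.compile(r"(\d+)\s+('(?:[^']|'')*'|[^\s,/;]+)(?:\s*/[^,;]*)?")


def _strip_nexus_comments(text: str) -> str:
    out, depth = [], 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]" and depth:
            depth -= 1
        elif not depth:
            out.append(ch)
    return "".join(out)


def read_nexus(path: str | Path) -> CharacterMatrix:
    """Read a standard-data NEXUS matrix (sequential or interleaved).

    The cell block is parsed with dendropy; per-character labels are
    recovered from the CHARSTATELABELS command, which dendropy does not
    retain.
    """
    text = Path(path).read_text()
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy reports line numbers in its message
        raise MatrixError(f"NEXUS parse error in {path}: {exc}") from exc
    taxa = [t.label for t in dm.taxon_namespace]
    code = {"0": 0, "1": 1, "?": MISSING, "-": MISSING}
    rows = []
    for t in dm.taxon_namespace:
        try:
            rows.append([code[str(c)] for c in dm[t]])
        except KeyError as exc:
            raise MatrixError(f"non-binary symbol {exc} in NEXUS matrix {path}")
    cells = np.asarray(rows, dtype=np.int8)

    labels: dict[int, str] = {}
    stripped = _strip_nexus_comments(text)
    mlab = _CHARSTATELABELS_RE.search(stripped)
    if mlab:
        for num, lab in _LABEL_ENTRY_RE.findall(mlab.group("body")):
            if lab.startswith("'"):
                lab = lab[1:-1].replace("''", "'")
            labels[int(num)] = lab
    characters = [
        CharacterDef(i + 1, labels.get(i + 1, f"char{i + 1}"))
        for i in range(cells.shape[1])
    ]
    dims = re.search(r"NCHAR\s*=\s*(\d+)", stripped, re.IGNORECASE)
    if dims and int(dims.group(1)) != cells.shape[1]:
        raise MatrixError(
            f"NCHAR={dims.group(1)} but matrix has {cells.shape[1]} columns"
        )
    return CharacterMatrix(taxa, characters, cells)


def write_matrix_tsv(m: CharacterMatrix, path: str | Path) -> None:
    df = m.to_dataframe()
    df.index.name = "taxon"
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> CharacterMatrix:
    df = pd.read_csv(path, sep="\t", index_col="taxon", dtype=str)
    cells = df.replace("?", str(MISSING)).astype(np.int8).values
    characters = [CharacterDef(i + 1, lab) for i, lab in enumerate(df.columns)]
    return CharacterMatrix([str(t) for t in df.index], characters, cells)
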
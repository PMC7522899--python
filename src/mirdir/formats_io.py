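"""Readers and writers for the external formats the pipeline touches.

Sequence inputs (mature miRNA references, gene-family nucleotide sets,
protein references) are plain multi-record FASTA.  Secondary structures can
be ingested from Vienna dot-bracket fold files or from connectivity tables
(CT); qPCR threshold-cycle measurements come in as long-format delimited
tables with columns ``gene, condition, replicate, ct``.

Conventions
-----------
* miRNA-side sequences are stored RNA-normalized (T→U, upper case); gene
  sequences stay DNA.  Comparisons elsewhere map U↔T transparently.
* Coordinates are 0-based half-open internally; 1-based inclusive numbers
  appear only in rendered reports.
* Fold energies are ΔG in kcal/mol, negative for stable folds.  Published
  tables often print magnitudes; a positive energy on input is accepted and
  stored negated, with a warning.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGU")
DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

_PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """One FASTA record, alphabet-normalized for its molecule type."""

    id: str
    description: str
    sequence: str
    moltype: str  # "rna" | "dna" | "protein"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        alphabet = {
            "rna": RNA_ALPHABET,
            "dna": DNA_ALPHABET,
            "protein": PROTEIN_ALPHABET,
        }[self.moltype]
        bad = set(self.sequence) - alphabet
        if bad:
            raise ParseError(
                f"record {self.id!r}: characters {sorted(bad)} not allowed "
                f"for moltype {self.moltype!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FoldRecord:
    """A folded sequence: dot-bracket structure plus its ΔG in kcal/mol."""

    id: str
    sequence: str
    structure: str
    mfe_kcal_mol: float

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ParseError(
                f"fold {self.id!r}: structure length {len(self.structure)} "
                f"!= sequence length {len(self.sequence)}"
            )
        validate_dot_bracket(self.structure, name=self.id)


def validate_dot_bracket(structure: str, name: str = "?") -> None:
    """Check a dot-bracket string: only ``.()``, balanced, properly nested."""
    bad = set(structure) - set(".()")
    if bad:
        raise ParseError(f"fold {name!r}: illegal structure characters {sorted(bad)}")
    depth = 0
    for pos, ch in enumerate(structure):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(
                    f"fold {name!r}: unmatched ')' at position {pos}"
                )
    if depth != 0:
        raise ParseError(f"fold {name!r}: {depth} unmatched '(' bracket(s)")


def pair_table(structure: str) -> List[int]:
    """Partner index per position (-1 if unpaired) for a dot-bracket string."""
    validate_dot_bracket(structure)
    partner = [-1] * len(structure)
    stack: List[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            partner[i], partner[j] = j, i
    return partner


def normalize_sequence(seq: str, moltype: str) -> str:
    seq = seq.upper()
    if moltype == "rna":
        seq = seq.replace("T", "U")
    elif moltype == "dna":
        seq = seq.replace("U", "T")
    return seq


def read_fasta(path: _PathLike, moltype: str = "dna") -> List[SequenceRecord]:
    """Read a multi-record FASTA file.

    Sequences are upper-cased and alphabet-normalized (T→U for ``rna``,
    U→T for ``dna``).  Record order is preserved; duplicate ids are an
    error.
    """
    if moltype not in ("rna", "dna", "protein"):
        raise ValueError(f"unknown moltype {moltype!r}")
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description,
                sequence=normalize_sequence(str(rec.seq), moltype),
                moltype=moltype,
            )
        )
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: _PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.description or rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_ENERGY_SUFFIX = re.compile(r"^([.()]+)\s*(?:\(\s*(-?\d+(?:\.\d+)?)\s*\))?\s*$")
_DG_LINE = re.compile(r"^\s*d?G\s*=\s*(-?\d+(?:\.\d+)?)", re.IGNORECASE)


def read_fold(path: _PathLike) -> List[FoldRecord]:
    """Read a Vienna-style fold file.

    Dialect: ``>id`` header, sequence line, structure line.  The energy is
    taken either from a ``(-12.3)`` suffix on the structure line or from a
    separate ``dG = -12.3`` line following it.  A positive magnitude is
    stored negated (tables commonly print |ΔG|) with a logged warning.
    """
    lines = Path(path).read_text().splitlines()
    records: List[FoldRecord] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise ParseError(f"{path}:{i + 1}: expected '>' header, got {line[:30]!r}")
        rec_id = line[1:].split()[0] if line[1:].split() else f"fold{len(records)}"
        if i + 2 >= len(lines):
            raise ParseError(f"{path}:{i + 1}: truncated fold record {rec_id!r}")
        sequence = normalize_sequence(lines[i + 1].strip(), "rna")
        m = _ENERGY_SUFFIX.match(lines[i + 2].strip())
        if m is None:
            raise ParseError(
                f"{path}:{i + 3}: malformed structure line for {rec_id!r}"
            )
        structure, energy_str = m.group(1), m.group(2)
        i += 3
        if energy_str is None:
            if i < len(lines):
                dg = _DG_LINE.match(lines[i])
                if dg:
                    energy_str = dg.group(1)
                    i += 1
        if energy_str is None:
            raise ParseError(f"{path}: fold {rec_id!r} has no energy annotation")
        energy = float(energy_str)
        if energy > 0:
            logger.warning(
                "fold %s: positive energy %.2f interpreted as magnitude, storing %.2f",
                rec_id, energy, -energy,
            )
            energy = -energy
        if len(structure) != len(sequence):
            raise ParseError(
                f"{path}: fold {rec_id!r}: structure length {len(structure)} "
                f"!= sequence length {len(sequence)}"
            )
        records.append(FoldRecord(rec_id, sequence, structure, energy))
    if not records:
        raise ParseError(f"{path}: no fold records found")
    return records


def write_fold(records: Iterable[FoldRecord], path: _PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n{rec.structure} ({rec.mfe_kcal_mol:.2f})\n")


def read_connectivity_table(path: _PathLike) -> FoldRecord:
    """Read a single-structure connectivity table (CT) file into a FoldRecord.

    CT layout: header line ``N  dG = -x.y  name`` then N rows of
    ``index base prev next pair index``; a pair column of 0 means unpaired.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError):
        raise ParseError(f"{path}:1: CT header must start with the base count")
    dg = re.search(r"d?G\s*=\s*(-?\d+(?:\.\d+)?)", lines[0], re.IGNORECASE)
    energy = float(dg.group(1)) if dg else 0.0
    if energy > 0:
        energy = -energy
    name = header[-1] if len(header) > 1 and not dg else "ct"
    if len(lines) - 1 < n:
        raise ParseError(f"{path}: CT declares {n} bases but has {len(lines) - 1} rows")
    bases = []
    partners = []
    for row_no, ln in enumerate(lines[1 : n + 1], start=2):
        cols = ln.split()
        if len(cols) < 5:
            raise ParseError(f"{path}:{row_no}: CT row needs >=5 columns")
        bases.append(cols[1].upper().replace("T", "U"))
        partners.append(int(cols[4]))
    structure = []
    for i, p in enumerate(partners, start=1):
        if p == 0:
            structure.append(".")
        elif p > i:
            structure.append("(")
        else:
            if partners[p - 1] != i:
                raise ParseError(f"{path}: inconsistent pairing at base {i}")
            structure.append(")")
    return FoldRecord(name, "".join(bases), "".join(structure), energy)


def read_ct_table(path: _PathLike, reference_gene: str | None = None,
                  control_condition: str | None = None):
    """Read a long-format qPCR threshold-cycle table (CSV or TSV).

    Required columns: ``gene, condition, replicate, ct``.  Returns a
    :class:`mirdir.expression.CtTable`.  If ``reference_gene`` is given its
    presence in every condition is checked here.
    """
    import pandas as pd

    from .expression import CtTable

    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"gene": str, "condition": str})
    missing = {"gene", "condition", "replicate", "ct"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad_ct = pd.to_numeric(df["ct"], errors="coerce").isna()
    if bad_ct.any():
        row = int(bad_ct.idxmax()) + 2  # header + 1-based
        raise ParseError(f"{path}:{row}: non-numeric ct value {df['ct'][bad_ct.idxmax()]!r}")
    df["ct"] = df["ct"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    dup = df.duplicated(subset=["gene", "condition", "replicate"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["gene", "condition", "replicate"]].tolist()
        raise ParseError(f"{path}: duplicated (gene, condition, replicate) key {key}")
    table = CtTable(df=df, reference_gene=reference_gene,
                    control_condition=control_condition)
    if reference_gene is not None:
        table.check_reference()
    return table
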
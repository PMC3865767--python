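"""Domain types and readers/writers for sequences, alignments and partition tables.

Conventions used throughout the package:

* gap character is ``-`` (a ``.`` in input is normalised to ``-``);
* protein alphabet is the 20 canonical residues plus ``X`` (missing);
* coding sequences are unambiguous ``A/C/G/T`` only, since downstream
  synonymous/nonsynonymous counting is undefined on ambiguity codes;
* all user-facing coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGT")
GAP = "-"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))


class SequenceError(ValueError):
    """Raised on malformed sequence input (bad characters, duplicate ids...)."""


@dataclass(frozen=True)
class Sequence:
    """A protein sequence: unique id, uppercase residues, free-text description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be nonempty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in PROTEIN_ALPHABET:
                raise SequenceError(
                    f"illegal residue {ch!r} at position {pos} in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodingSequence:
    """An unambiguous coding DNA sequence, optionally with its terminal stop noted.

    The stored nucleotides never include the terminal stop codon; a premature
    (internal) in-frame stop is a hard error because, in this gene family, it
    is evidence of a pseudogene rather than something to trim silently.
    """

    id: str
    nucleotides: str
    includes_stop: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("coding sequence id must be nonempty")
        for pos, ch in enumerate(self.nucleotides, start=1):
            if ch not in NUCLEOTIDE_ALPHABET:
                raise SequenceError(
                    f"illegal nucleotide {ch!r} at position {pos} in CDS {self.id!r}"
                )
        if len(self.nucleotides) % 3 != 0:
            raise SequenceError(
                f"CDS {self.id!r} length {len(self.nucleotides)} not divisible by 3"
            )

    def codons(self) -> list[str]:
        nt = self.nucleotides
        return [nt[i : i + 3] for i in range(0, len(nt), 3)]

    def __len__(self) -> int:
        return len(self.nucleotides)


def translate(cds: CodingSequence) -> Sequence:
    """Translate a CDS under the standard genetic code.

    A terminal stop codon is dropped; an internal stop raises
    :class:`SequenceError`.
    """
    codons = cds.codons()
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    residues = []
    for idx, codon in enumerate(codons, start=1):
        if codon in STOP_CODONS:
            raise SequenceError(
                f"internal stop codon {codon} at codon {idx} in CDS {cds.id!r}"
            )
        residues.append(CODON_TO_AA[codon])
    return Sequence(id=cds.id, residues="".join(residues))


def _records(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return SeqIO.parse(str(path), "fasta")


def read_fasta(
    path: str | Path, alphabet_kind: Literal["protein", "cds"] = "protein"
) -> list[Sequence] | list[CodingSequence]:
    """Read a FASTA file into validated :class:`Sequence`/:class:`CodingSequence`.

    Ids are the first whitespace-delimited header token; residues are
    uppercased; a single terminal ``*`` on a CDS marks an encoded stop and is
    stripped (``includes_stop=True``). Duplicate ids and illegal characters
    are hard errors.
    """
    out: list = []
    seen: set[str] = set()
    for rec in _records(path):
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq).upper().replace(".", GAP)
        if alphabet_kind == "protein":
            out.append(Sequence(rec.id, raw, description=rec.description))
        elif alphabet_kind == "cds":
            includes_stop = raw.endswith("*")
            if includes_stop:
                raw = raw[:-1]
            out.append(CodingSequence(rec.id, raw, includes_stop=includes_stop))
        else:
            raise ValueError(f"unknown alphabet_kind {alphabet_kind!r}")
    return out


def write_fasta(records: Iterable[Sequence | CodingSequence], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.residues if isinstance(rec, Sequence) else rec.nucleotides
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class AlignedSet:
    """A multiple alignment: ordered map id -> equal-length gapped row.

    ``alphabet_kind`` is ``"protein"`` or ``"codon"`` (codon rows are
    nucleotide strings whose length is divisible by 3, with gap runs on codon
    boundaries).
    """

    rows: dict[str, str]
    alphabet_kind: Literal["protein", "codon"] = "protein"

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise SequenceError("an alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise SequenceError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        alphabet = (
            PROTEIN_ALPHABET if self.alphabet_kind == "protein" else NUCLEOTIDE_ALPHABET
        )
        for rid, row in self.rows.items():
            bad = set(row) - alphabet - {GAP}
            if bad:
                raise SequenceError(f"illegal characters {sorted(bad)} in row {rid!r}")
        if self.alphabet_kind == "codon" and self.ncols % 3 != 0:
            raise SequenceError("codon alignment length not divisible by 3")

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values())))

    def ungapped(self, rid: str) -> str:
        return self.rows[rid].replace(GAP, "")

    def column(self, col: int) -> str:
        """1-based column."""
        return "".join(row[col - 1] for row in self.rows.values())

    def take_columns(self, cols: list[int]) -> "AlignedSet":
        """Subset of 1-based columns, order preserved."""
        idx = [c - 1 for c in cols]
        return AlignedSet(
            {rid: "".join(row[i] for i in idx) for rid, row in self.rows.items()},
            alphabet_kind=self.alphabet_kind,
        )

    def subset(self, ids: Iterable[str]) -> "AlignedSet":
        return AlignedSet({rid: self.rows[rid] for rid in ids}, self.alphabet_kind)


def read_alignment(
    path: str | Path, alphabet_kind: Literal["protein", "codon"] = "protein"
) -> AlignedSet:
    """Read an aligned FASTA (gapped rows) into an :class:`AlignedSet`."""
    rows: dict[str, str] = {}
    for rec in _records(path):
        if rec.id in rows:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq).upper().replace(".", GAP)
    return AlignedSet(rows, alphabet_kind=alphabet_kind)


def write_alignment(msa: AlignedSet, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row in msa.rows.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


@dataclass(frozen=True)
class Partition:
    name: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if self.start_aa < 1 or self.end_aa < 1:
            raise SequenceError(f"partition {self.name!r}: coordinates must be >= 1")
        if self.start_aa > self.end_aa:
            raise SequenceError(
                f"partition {self.name!r}: start {self.start_aa} > end {self.end_aa}"
            )

    @property
    def width(self) -> int:
        return self.end_aa - self.start_aa + 1


@dataclass
class PartitionTable:
    """Named residue spans (1-based inclusive) on a reference protein."""

    partitions: list[Partition]
    reference_id: str | None = None
    exon_set: bool = False

    def __post_init__(self) -> None:
        if self.exon_set:
            spans = sorted((p.start_aa, p.end_aa) for p in self.partitions)
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise SequenceError(
                        f"exon partitions overlap: ...{e1} vs {s2}..."
                    )

    def __iter__(self):
        return iter(self.partitions)

    def __len__(self) -> int:
        return len(self.partitions)

    def max_end(self) -> int:
        return max(p.end_aa for p in self.partitions)


def read_partition_table(path: str | Path, exon_set: bool = False) -> PartitionTable:
    """Read a TSV with header and columns name/start/end (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 3:
        raise SequenceError("partition table needs at least 3 columns: name, start, end")
    name_col, start_col, end_col = df.columns[:3]
    parts = []
    for _, row in df.iterrows():
        try:
            start = int(row[start_col])
            end = int(row[end_col])
        except (TypeError, ValueError) as exc:
            raise SequenceError(
                f"non-integer coordinate in partition {row[name_col]!r}"
            ) from exc
        if not math.isclose(start, float(row[start_col])) or not math.isclose(
            end, float(row[end_col])
        ):
            raise SequenceError(f"non-integer coordinate in partition {row[name_col]!r}")
        parts.append(Partition(str(row[name_col]), start, end))
    return PartitionTable(parts, exon_set=exon_set)
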
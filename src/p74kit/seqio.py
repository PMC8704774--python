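"""Sequence/alignment I/O and validation.

Thin, validating layer over Bio.SeqIO / Bio.AlignIO.  Records are
uppercase-normalised on read; alignment coordinates are 1-based columns in
all outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_EXTENDED = PROTEIN_ALPHABET | {"X"}
DNA_ALPHABET = set("ACGT")
DNA_EXTENDED = DNA_ALPHABET | {"N"}
GAP = "-"

CONSENSUS_SYMBOLS = set("*:. ")


class SequenceError(ValueError):
    """Raised for malformed sequence records or files."""


@dataclass
class SequenceRecord:
    """A validated ungapped sequence (gaps allowed only inside an Alignment)."""

    id: str
    residues: str
    alphabet: str = "protein"  # "protein" | "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence record must have a non-empty id")
        if self.alphabet not in ("protein", "dna"):
            raise SequenceError(f"unknown alphabet {self.alphabet!r}")
        self.residues = self.residues.upper()

    def validate(self, allow_gaps: bool = False) -> None:
        allowed = PROTEIN_EXTENDED if self.alphabet == "protein" else DNA_EXTENDED
        if allow_gaps:
            allowed = allowed | {GAP}
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise SequenceError(
                    f"record {self.id!r}: illegal {self.alphabet} character "
                    f"{ch!r} at position {pos}"
                )
        ambiguous = "X" if self.alphabet == "protein" else "N"
        if ambiguous in self.residues:
            warnings.warn(
                f"record {self.id!r} contains ambiguous residue {ambiguous!r}; "
                "it never counts as identity in scoring",
                stacklevel=2,
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ConsensusLine:
    """Clustal conservation symbols: '*' identity, ':' strong, '.' weak, ' ' none."""

    symbols: str

    def __post_init__(self) -> None:
        bad = set(self.symbols) - CONSENSUS_SYMBOLS
        if bad:
            raise SequenceError(f"illegal consensus symbols: {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.symbols)


class Alignment:
    """Gapped, equal-length protein records with an optional consensus line.

    All-gap columns are dropped with a warning (the attached consensus line,
    if any, is trimmed at the same columns).
    """

    def __init__(
        self,
        records: Sequence[SequenceRecord],
        consensus: Optional[ConsensusLine] = None,
    ) -> None:
        records = list(records)
        if not records:
            raise SequenceError("alignment needs at least one record")
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            detail = ", ".join(f"{r.id}:{len(r)}" for r in records)
            raise SequenceError(f"ragged alignment (gapped lengths differ): {detail}")
        length = lengths.pop()
        ids = [r.id for r in records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SequenceError(f"duplicate record ids in alignment: {sorted(dupes)}")
        for r in records:
            r.validate(allow_gaps=True)
        if consensus is not None and len(consensus) != length:
            raise SequenceError(
                f"consensus length {len(consensus)} != alignment length {length}"
            )
        all_gap = [
            j for j in range(length) if all(r.residues[j] == GAP for r in records)
        ]
        if all_gap:
            warnings.warn(
                f"dropping {len(all_gap)} all-gap column(s): "
                f"{[j + 1 for j in all_gap]}",
                stacklevel=2,
            )
            keep = [j for j in range(length) if j not in set(all_gap)]
            records = [
                SequenceRecord(
                    r.id,
                    "".join(r.residues[j] for j in keep),
                    r.alphabet,
                    r.description,
                )
                for r in records
            ]
            if consensus is not None:
                consensus = ConsensusLine("".join(consensus.symbols[j] for j in keep))
            length = len(keep)
        self.records: list[SequenceRecord] = records
        self.length: int = length
        self.consensus = consensus

    def __len__(self) -> int:
        return self.length

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def column(self, col: int) -> str:
        """Residues of 1-based column *col*, in record order."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        return "".join(r.residues[col - 1] for r in self.records)


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a multi-FASTA file into validated :class:`SequenceRecord` objects."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        sr = SequenceRecord(
            rec.id, str(rec.seq), alphabet, description=rec.description
        )
        sr.validate(allow_gaps=False)
        records.append(sr)
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(recs, str(Path(path)), "fasta")


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a protein alignment from FASTA or Clustal ``.aln``.

    A Clustal conservation line, when present, is attached verbatim as the
    alignment's consensus.
    """
    path = Path(path)
    if format not in ("fasta", "clustal"):
        raise SequenceError(f"unsupported alignment format {format!r}")
    consensus = None
    if format == "clustal":
        msa = AlignIO.read(str(path), "clustal")
        records = [
            SequenceRecord(r.id, str(r.seq), "protein", description=r.description)
            for r in msa
        ]
        line = msa.column_annotations.get("clustal_consensus")
        if line is not None:
            consensus = ConsensusLine(line)
    else:
        raw = list(SeqIO.parse(str(path), "fasta"))
        if not raw:
            raise SequenceError(f"no alignment records found in {path}")
        records = [
            SequenceRecord(r.id, str(r.seq), "protein", description=r.description)
            for r in raw
        ]
    return Alignment(records, consensus=consensus)


def write_profile_table(profile, path: str | Path) -> None:
    """Write a profile as TSV: 1-based column, value(s), 6-decimal precision.

    Accepts any object exposing ``table_header()`` and ``table_rows()``
    (SimilarityProfile, HydropathyProfile).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(profile.table_header()) + "\n")
        for row in profile.table_rows():
            fh.write(
                "\t".join(
                    f"{v:.6f}" if isinstance(v, float) else str(v) for v in row
                )
                + "\n"
            )
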
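"""Readers and writers for FASTA, CT (connect) and dot-bracket files."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .energy_model import RnaSequence, SecondaryStructure

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_ct",
    "write_ct",
    "write_dotbracket_records",
    "read_dotbracket_records",
]


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a (multi-record, U/T tolerant) FASTA file as RNA sequences."""
    return [
        RnaSequence(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def write_ct(
    seq: RnaSequence,
    structure: SecondaryStructure,
    handle: TextIO,
    energy: float | None = None,
) -> None:
    """Write a structure in CT (connect) format (1-based partners)."""
    n = len(seq)
    partners = structure.partner_map(n)
    header = f"{n} {seq.id}"
    if energy is not None:
        header = f"{n} ENERGY = {energy:.2f} {seq.id}"
    print(header, file=handle)
    for i in range(n):
        print(
            f"{i + 1} {seq[i]} {i} {i + 2 if i + 1 < n else 0} "
            f"{partners[i] + 1} {i + 1}",
            file=handle,
        )


def read_ct(handle: TextIO) -> tuple[RnaSequence, SecondaryStructure]:
    lines = [ln for ln in handle.read().splitlines() if ln.strip()]
    header = lines[0].split()
    n = int(header[0])
    name = header[-1] if len(header) > 1 else "ct"
    chars, pairs = [], []
    for ln in lines[1:n + 1]:
        fields = ln.split()
        idx, base, partner = int(fields[0]) - 1, fields[1], int(fields[4]) - 1
        chars.append(base)
        if partner > idx:
            pairs.append((idx, partner))
    seq = RnaSequence(id=name, seq="".join(chars))
    structure = SecondaryStructure(pairs)
    structure.validate(seq)
    return seq, structure


def write_dotbracket_records(
    seq: RnaSequence,
    structures: Iterable[SecondaryStructure],
    energies: Iterable[float],
    handle: TextIO,
) -> None:
    """Dump an ensemble as multi-record dot-bracket with energy comments."""
    print(f">{seq.id}", file=handle)
    print(seq.seq, file=handle)
    for structure, energy in zip(structures, energies):
        print(f"{structure.to_dotbracket(len(seq))} # {energy:.2f}", file=handle)


def read_dotbracket_records(
    handle: TextIO,
) -> tuple[RnaSequence, list[SecondaryStructure], list[float]]:
    from .energy_model import parse_dotbracket

    lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError("expected a '>' header line")
    seq = RnaSequence(id=lines[0][1:].strip(), seq=lines[1].strip())
    structures, energies = [], []
    for ln in lines[2:]:
        db, _, comment = ln.partition("#")
        structures.append(parse_dotbracket(db.strip(), seq))
        energies.append(float(comment.strip()) if comment.strip() else float("nan"))
    return seq, structures, energies
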
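"""Mature miRNA sequence databases in the miRBase mature-FASTA dialect.

miRBase distributes mature miRNAs as RNA-alphabet FASTA with headers of the
form ``>hsa-let-7a-5p MIMAT0000062 Homo sapiens let-7a-5p``. The first
whitespace-delimited token is the name; the species is encoded as its prefix
(``hsa``, ``mmu``). Sequencing reads arrive in the DNA alphabet, so every
sequence entering the pipeline is normalized to uppercase RNA first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

_RNA = set("ACGU")
# IUPAC nucleotide letters accepted on input (T is translated to U).
_IUPAC = set("ACGTURYSWKMBDHVN")


class MalformedSequenceError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


def normalize_sequence(raw: str) -> str:
    """Normalize a nucleotide string to uppercase RNA (T -> U).

    Ambiguity codes (N, R, Y, ...) are preserved; downstream exact-match
    steps never match them. Raises :class:`MalformedSequenceError` naming
    the first offending position for any non-nucleotide character.
    """
    seq = raw.strip().upper().replace("T", "U")
    for pos, ch in enumerate(seq):
        if ch not in _IUPAC and ch != "U":
            raise MalformedSequenceError(
                f"non-nucleotide character {ch!r} at position {pos}"
            )
    return seq


def has_ambiguity(seq: str) -> bool:
    """True if the (normalized) sequence contains any non-ACGU letter."""
    return any(ch not in _RNA for ch in seq)


@dataclass(frozen=True)
class MatureMiRNA:
    """A named, species-tagged mature miRNA sequence.

    Attributes
    ----------
    name : miRBase-style identifier, e.g. ``hsa-miR-224-5p``.
    species : species code, the name prefix for miRBase-styled names.
    sequence : uppercase RNA string.
    accession : optional miRBase accession (``MIMAT...``).
    """

    name: str
    species: str
    sequence: str
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"{self.name}: sequence must be uppercase")
        if not self.species:
            raise ValueError(f"{self.name}: empty species code")
        if "-" in self.name and not self.name.startswith(self.species + "-"):
            raise ValueError(
                f"name {self.name!r} inconsistent with species {self.species!r}"
            )


@dataclass
class MiRNADatabase:
    """An ordered, name-unique collection of mature miRNAs of one species."""

    species: str
    entries: list[MatureMiRNA] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate miRNA names: {dup}")
        # sequence -> set of names carrying it (identical matures under
        # different names are legitimate in miRBase and kept distinct)
        self.index: dict[str, set[str]] = {}
        for e in self.entries:
            self.index.setdefault(e.sequence, set()).add(e.name)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def get(self, name: str) -> MatureMiRNA:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


def read_mature_fasta(path: str | Path, species: str) -> MiRNADatabase:
    """Read a miRBase-style mature FASTA, keeping one species.

    Only records whose name starts with ``species + "-"`` are retained;
    the number skipped is logged. Sequences are normalized to RNA.
    Duplicate names or an empty result are hard errors.
    """
    path = Path(path)
    entries: list[MatureMiRNA] = []
    seen: set[str] = set()
    skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if not name.startswith(species + "-"):
            skipped += 1
            continue
        if name in seen:
            raise ValueError(f"duplicate miRNA name {name!r} in {path}")
        seen.add(name)
        parts = rec.description.split()
        accession = parts[1] if len(parts) > 1 else None
        entries.append(
            MatureMiRNA(
                name=name,
                species=species,
                sequence=normalize_sequence(str(rec.seq)),
                accession=accession,
            )
        )
    if skipped:
        logger.info("%s: skipped %d non-%s records", path, skipped, species)
    if not entries:
        raise ValueError(f"no {species!r} records found in {path}")
    return MiRNADatabase(species=species, entries=entries)


def write_mature_fasta(db: MiRNADatabase, path: str | Path) -> None:
    """Write a database back to miRBase-style mature FASTA."""
    with open(path, "w") as fh:
        for e in db:
            header = f">{e.name}" + (f" {e.accession}" if e.accession else "")
            fh.write(f"{header}\n{e.sequence}\n")


def write_database_tsv(db: MiRNADatabase, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsequence\tspecies\taccession\n")
        for e in db:
            fh.write(f"{e.name}\t{e.sequence}\t{e.species}\t{e.accession or ''}\n")


def database_from_records(
    species: str, records: Iterable[tuple[str, str]]
) -> MiRNADatabase:
    """Build a database from (name, sequence) pairs; sequences are normalized."""
    entries = [
        MatureMiRNA(name=n, species=species, sequence=normalize_sequence(s))
        for n, s in records
    ]
    return MiRNADatabase(species=species, entries=entries)
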
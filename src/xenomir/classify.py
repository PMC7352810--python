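"""Zero-mismatch assignment of small-RNA reads to mature miRNAs.

Adapter-trimmed, size-selected small-RNA reads are at most mature length, so
a perfect alignment of a read against the mature reference reduces to exact
contiguous containment of the read within a mature sequence (equality
included). Matching is implemented with a substring index: every window of
length >= min_len of every mature sequence is keyed to the names carrying
it, so each read resolves in one dictionary lookup.

Each read is then resolved to one of the three datasets of the species
partition:

* any matched name conserved  -> the read counts toward every matched
  conserved name, tallied under the human-style name of the pair (so
  indistinguishable human/mouse sequences merge into one conserved entry);
* matches confined to human-specific names -> each matched name counted;
* symmetrically for mouse-specific;
* matches spanning both species with no conserved name -> ambiguous_cross;
* no match (or read < min_len, or read containing N) -> unassigned.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from xenomir.db import MiRNADatabase, has_ambiguity, normalize_sequence
from xenomir.orthology import SpeciesPartition

DEFAULT_MIN_LEN = 16


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str  # normalized RNA, may contain N

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ClassifiedCounts:
    """Per-sample read counts split by species-of-origin category."""

    sample_id: str
    human_specific: Counter = field(default_factory=Counter)
    mouse_specific: Counter = field(default_factory=Counter)
    conserved: Counter = field(default_factory=Counter)
    unassigned: int = 0
    ambiguous_cross: int = 0
    total_reads: int = 0

    @property
    def category_totals(self) -> dict[str, int]:
        return {
            "human_specific": sum(self.human_specific.values()),
            "mouse_specific": sum(self.mouse_specific.values()),
            "conserved": sum(self.conserved.values()),
        }


class SubstringIndex:
    """Maps every >=min_len window of the mature sequences to their names."""

    def __init__(self, dbs: Iterable[MiRNADatabase], min_len: int = DEFAULT_MIN_LEN):
        self.min_len = min_len
        self._table: dict[str, set[str]] = {}
        for db in dbs:
            for entry in db:
                seq = entry.sequence
                if has_ambiguity(seq):
                    continue  # ambiguity codes never matched under zero mismatches
                L = len(seq)
                for w in range(min_len, L + 1):
                    for start in range(L - w + 1):
                        self._table.setdefault(seq[start : start + w], set()).add(
                            entry.name
                        )

    def lookup(self, read_seq: str) -> set[str]:
        if len(read_seq) < self.min_len or has_ambiguity(read_seq):
            return set()
        return self._table.get(read_seq, set())


def match_read(
    read: ReadRecord,
    human_db: MiRNADatabase,
    mouse_db: MiRNADatabase,
    min_len: int = DEFAULT_MIN_LEN,
    index: SubstringIndex | None = None,
) -> set[str]:
    """All miRNA names (both species) containing the read exactly.

    Reads shorter than ``min_len`` or containing ambiguity codes match
    nothing. Pass a prebuilt :class:`SubstringIndex` when matching many
    reads against the same databases.
    """
    if index is None:
        index = SubstringIndex([human_db, mouse_db], min_len)
    return index.lookup(read.sequence)


def _resolve(
    matched: set[str], partition: SpeciesPartition, counts: ClassifiedCounts
) -> None:
    if not matched:
        counts.unassigned += 1
        return
    conserved = [n for n in matched if n in partition.conserved_names]
    if conserved:
        # count once per human-style pair name, merging hsa/mmu tallies
        human_names: set[str] = set()
        for n in conserved:
            human_names.update(partition.human_alias[n])
        for hn in sorted(human_names):
            counts.conserved[hn] += 1
        return
    human = matched & partition.human_specific_names
    mouse = matched & partition.mouse_specific_names
    if human and mouse:
        counts.ambiguous_cross += 1
    elif human:
        for n in human:
            counts.human_specific[n] += 1
    else:
        for n in mouse:
            counts.mouse_specific[n] += 1


def classify_reads(
    reads: Iterable[ReadRecord],
    partition: SpeciesPartition,
    human_db: MiRNADatabase,
    mouse_db: MiRNADatabase,
    min_len: int = DEFAULT_MIN_LEN,
    sample_id: str = "sample",
    index: SubstringIndex | None = None,
) -> ClassifiedCounts:
    """Classify a read stream into per-category count tables.

    Counting is order-free: identical read multisets give identical counts.
    Duplicate read sequences are matched once and weighted by multiplicity.
    """
    if index is None:
        index = SubstringIndex([human_db, mouse_db], min_len)
    counts = ClassifiedCounts(sample_id=sample_id)
    seq_tally: Counter = Counter()
    for read in reads:
        seq_tally[read.sequence] += 1
        counts.total_reads += 1
    for seq, mult in seq_tally.items():
        matched = index.lookup(seq)
        single = ClassifiedCounts(sample_id=sample_id)
        _resolve(matched, partition, single)
        counts.unassigned += single.unassigned * mult
        counts.ambiguous_cross += single.ambiguous_cross * mult
        for table in ("human_specific", "mouse_specific", "conserved"):
            src: Counter = getattr(single, table)
            dst: Counter = getattr(counts, table)
            for name, c in src.items():
                dst[name] += c * mult
    return counts


def read_sequences(path: str | Path) -> Iterator[ReadRecord]:
    """Stream reads from FASTA/FASTQ, plain or gzip, normalized to RNA."""
    path = Path(path)
    name = path.name.lower()
    opener = gzip.open if name.endswith(".gz") else open
    stem = name[:-3] if name.endswith(".gz") else name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield ReadRecord(read_id=rec.id, sequence=normalize_sequence(str(rec.seq)))


def counts_to_frame(counts_list: list[ClassifiedCounts], category: str):
    """Stack per-sample counters into a miRNA x sample DataFrame."""
    import pandas as pd

    series = {
        c.sample_id: pd.Series(dict(getattr(c, category)), dtype=float)
        for c in counts_list
    }
    df = pd.DataFrame(series).fillna(0).astype(int)
    return df.sort_index()
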
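"""Human-mouse conserved miRNA pairing by full-length perfect containment.

A human and a mouse mature miRNA form a "conserved" pair when the shorter
sequence is perfectly aligned along its entire length within the equal-or-
longer sequence of the other species — i.e. exact contiguous substring
containment with zero mismatches and no gaps. Sequence-identical pairs are a
special case. Exact substring search makes this deterministic, with none of
the seed-size artifacts of a heuristic short-read aligner.

Names touched by at least one pair are "conserved"; remaining human names
are human-specific and remaining mouse names mouse-specific, giving the
three-way partition under which xenograft reads are counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from xenomir.db import MatureMiRNA, MiRNADatabase, has_ambiguity


class Relation(str, Enum):
    IDENTICAL = "identical"
    HUMAN_IN_MOUSE = "human_in_mouse"
    MOUSE_IN_HUMAN = "mouse_in_human"


@dataclass(frozen=True, order=True)
class ConservedPair:
    human_name: str
    mouse_name: str
    relation: Relation


@dataclass
class SpeciesPartition:
    """Three-way disjoint partition of all database names.

    ``conserved_names`` holds names of both species that participate in at
    least one conserved pair; the other two sets hold the remaining names of
    each species. ``human_alias`` maps every conserved name (either species)
    to the sorted tuple of human-style names of its pairs, under which
    conserved counts are reported.
    """

    conserved_names: set[str]
    human_specific_names: set[str]
    mouse_specific_names: set[str]
    human_alias: dict[str, tuple[str, ...]]

    def category_of(self, name: str) -> str:
        if name in self.conserved_names:
            return "conserved"
        if name in self.human_specific_names:
            return "human_specific"
        if name in self.mouse_specific_names:
            return "mouse_specific"
        raise KeyError(name)


def is_conserved_pair(a: MatureMiRNA, b: MatureMiRNA) -> Relation | None:
    """Classify a cross-species pair by full-length perfect containment.

    Returns the relation, or None when neither sequence is an exact
    contiguous substring of the other. Ambiguity-containing sequences never
    pair (zero-mismatch semantics cannot match N). Same-species input is a
    usage error.
    """
    if a.species == b.species:
        raise ValueError(f"same-species pair: {a.name}, {b.name}")
    human, mouse = (a, b) if a.species == "hsa" else (b, a)
    if has_ambiguity(human.sequence) or has_ambiguity(mouse.sequence):
        return None
    if human.sequence == mouse.sequence:
        return Relation.IDENTICAL
    if human.sequence in mouse.sequence:
        return Relation.HUMAN_IN_MOUSE
    if mouse.sequence in human.sequence:
        return Relation.MOUSE_IN_HUMAN
    return None


def find_conserved_pairs(
    human_db: MiRNADatabase, mouse_db: MiRNADatabase
) -> list[ConservedPair]:
    """All cross-species pairs under the containment criterion.

    One-to-many pairing is allowed (a human miRNA contained in two mouse
    matures yields two pairs). Output is sorted by (human_name, mouse_name).
    """
    if not len(human_db) or not len(mouse_db):
        raise ValueError("both databases must be non-empty")
    pairs: list[ConservedPair] = []
    # substring index over mouse sequences keyed by human-length windows
    # would help at miRBase scale; at <5k x 5k the direct scan is fast enough
    for h in human_db:
        for m in mouse_db:
            rel = is_conserved_pair(h, m)
            if rel is not None:
                pairs.append(ConservedPair(h.name, m.name, rel))
    pairs.sort(key=lambda p: (p.human_name, p.mouse_name))
    return pairs


def partition_names(
    human_db: MiRNADatabase,
    mouse_db: MiRNADatabase,
    pairs: list[ConservedPair],
) -> SpeciesPartition:
    """Derive the three-way name partition from the pair list."""
    human_names = set(human_db.names)
    mouse_names = set(mouse_db.names)
    alias: dict[str, set[str]] = {}
    conserved: set[str] = set()
    for p in pairs:
        if p.human_name not in human_names or p.mouse_name not in mouse_names:
            raise ValueError(
                f"pair ({p.human_name}, {p.mouse_name}) references unknown name"
            )
        conserved.add(p.human_name)
        conserved.add(p.mouse_name)
        alias.setdefault(p.human_name, set()).add(p.human_name)
        alias.setdefault(p.mouse_name, set()).add(p.human_name)
    return SpeciesPartition(
        conserved_names=conserved,
        human_specific_names=human_names - conserved,
        mouse_specific_names=mouse_names - conserved,
        human_alias={k: tuple(sorted(v)) for k, v in alias.items()},
    )


def write_pairs_tsv(pairs: list[ConservedPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("human_name\tmouse_name\trelation\n")
        for p in pairs:
            fh.write(f"{p.human_name}\t{p.mouse_name}\t{p.relation.value}\n")


def read_pairs_tsv(path: str | Path) -> list[ConservedPair]:
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["human_name", "mouse_name", "relation"]:
            raise ValueError(f"unexpected pairs header in {path}: {header}")
        for line in fh:
            h, m, r = line.rstrip("\n").split("\t")[:3]
            pairs.append(ConservedPair(h, m, Relation(r)))
    return pairs
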
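"""Identify human-mouse conserved miRNA pairs by full-length containment.

Builds two tiny mature-miRNA databases, finds every cross-species pair in
which one sequence is an exact contiguous substring of the other (or they
are identical), and prints the resulting three-way species partition.
"""

from xenomir.db import database_from_records
from xenomir.orthology import find_conserved_pairs, partition_names

human = database_from_records(
    "hsa",
    [
        ("hsa-let-7a-5p", "UGAGGUAGUAGGUUGUAUAGUU"),   # identical in mouse
        ("hsa-miR-100-5p", "AACCCGUAGAUCCGAACUUGUG"),  # contained in mouse
        ("hsa-miR-humA", "CCCCAAAAGGGGUUUUCCCCA"),     # human-specific
    ],
)
mouse = database_from_records(
    "mmu",
    [
        ("mmu-let-7a-5p", "UGAGGUAGUAGGUUGUAUAGUU"),
        ("mmu-miR-100-5p", "GAACCCGUAGAUCCGAACUUGUGA"),
        ("mmu-miR-musA", "AUAUAUGCGCGCAUAUAUGCG"),     # mouse-specific
    ],
)

pairs = find_conserved_pairs(human, mouse)
for p in pairs:
    print(f"{p.human_name} ~ {p.mouse_name}  ({p.relation.value})")

part = partition_names(human, mouse, pairs)
print("conserved names:     ", sorted(part.conserved_names))
print("human-specific names:", sorted(part.human_specific_names))
print("mouse-specific names:", sorted(part.mouse_specific_names))
# Conserved miRNAs cannot be attributed to tumor or host by sequence alone;
# human-specific names are the unambiguous tumor-derived readout.
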
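import pytest

from xenomir.db import database_from_records
from xenomir.orthology import find_conserved_pairs, partition_names
from xenomir.simulate import SimulationConfig, simulate_databases, simulate_xenograft_reads


@pytest.fixture
def toy_dbs():
    """Hand-built 4+4 databases with one identical and one containment pair."""
    human = database_from_records(
        "hsa",
        [
            ("hsa-let-7a-5p", "UGAGGUAGUAGGUUGUAUAGUU"),  # identical in mouse
            ("hsa-miR-100-5p", "AACCCGUAGAUCCGAACUUGUG"),  # contained in mouse
            ("hsa-miR-humA", "CCCCAAAAGGGGUUUUCCCCA"),
            ("hsa-miR-humB", "GGGGUUUUAAAACCCCGGGGU"),
        ],
    )
    mouse = database_from_records(
        "mmu",
        [
            ("mmu-let-7a-5p", "UGAGGUAGUAGGUUGUAUAGUU"),
            ("mmu-miR-100-5p", "GAACCCGUAGAUCCGAACUUGUGA"),
            ("mmu-miR-musA", "AUAUAUGCGCGCAUAUAUGCG"),
            ("mmu-miR-musB", "CGCGCGAUAUAUGCGCGCAUC"),
        ],
    )
    return human, mouse


@pytest.fixture
def toy_partition(toy_dbs):
    human, mouse = toy_dbs
    pairs = find_conserved_pairs(human, mouse)
    return pairs, partition_names(human, mouse, pairs)


@pytest.fixture(scope="session")
def small_sim():
    """One seeded small simulation shared by read-level tests."""
    cfg = SimulationConfig(
        seed=11,
        n_human_specific=20,
        n_mouse_specific=25,
        n_conserved_identical=10,
        n_conserved_containment=5,
        library_size=5000,
    )
    human_db, mouse_db, truth = simulate_databases(cfg)
    samples, meta, truth = simulate_xenograft_reads(human_db, mouse_db, truth, cfg)
    return cfg, human_db, mouse_db, truth, samples, meta
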
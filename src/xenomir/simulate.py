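"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the xenograft study design: two mature-miRNA
databases with planted identical / containment orthologue pairs plus
species-unique entries; plasma small-RNA libraries at four timepoints
(tumor-free control, days 7/14/23 after implantation, two replicates each)
in which each read originates from the human (tumor) pool with a
timepoint-dependent probability, drawn from a long-tailed log-normal
per-miRNA abundance profile; an sEV compartment sampled at day 23; and an
external microarray-style intensity matrix with planted progression-trend
miRNAs.

Planted sequences are mutually substring-free across the two databases
except for the planted pairs themselves, so each error-free read matches
exactly its source miRNA (or its conserved partner) and classification can
be checked against the recorded truth read-for-read.
"""

from __future__ import annotations

import gzip
import json
import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from xenomir.classify import ReadRecord
from xenomir.db import MatureMiRNA, MiRNADatabase
from xenomir.expression import SampleMeta
from xenomir.orthology import ConservedPair, Relation
from xenomir.validation import ExternalProfileSet

_BASES = "ACGU"

# Timepoint tumor-read fractions sized so the late human-specific share of
# total plasma sits near the ~10-12% human signal seen in the xenograft.
DEFAULT_TUMOR_FRACTIONS = {"control": 0.0, "day7": 0.02, "day14": 0.06, "day23": 0.12}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_human_specific: int = 60
    n_mouse_specific: int = 80
    n_conserved_identical: int = 50
    n_conserved_containment: int = 15
    mature_len_range: tuple[int, int] = (19, 24)
    library_size: int = 100_000
    tumor_fraction_by_timepoint: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TUMOR_FRACTIONS)
    )
    abundance_lognormal_sigma: float = 1.5
    n_replicates: int = 2
    substitution_rate: float = 0.0  # per-base; errored reads land unassigned

    def __post_init__(self) -> None:
        for tp, f in self.tumor_fraction_by_timepoint.items():
            if not 0 <= f <= 1:
                raise ValueError(f"tumor fraction for {tp} outside [0,1]")
        if self.tumor_fraction_by_timepoint.get("control", 0.0) != 0.0:
            raise ValueError("control tumor fraction must be 0")


@dataclass
class SimulationTruth:
    pairs: list[ConservedPair] = field(default_factory=list)
    # sample_id -> {"human_specific": n, "mouse_specific": n, "conserved": n}
    category_totals: dict[str, dict[str, int]] = field(default_factory=dict)
    # sample_id -> source miRNA name -> reads drawn from it
    source_counts: dict[str, Counter] = field(default_factory=dict)
    # sample_id -> read_id -> (pool, source_name)
    read_origins: dict[str, dict[str, tuple[str, str]]] = field(default_factory=dict)
    # pool name -> per-miRNA sampling weights (the planted abundance profile)
    pool_weights: dict[str, dict[str, float]] = field(default_factory=dict)


def _random_seq(rng: random.Random, lo: int, hi: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(rng.randint(lo, hi)))


def _clashes(seq: str, accepted: list[str]) -> bool:
    return any(seq in other or other in seq for other in accepted)


def simulate_databases(
    cfg: SimulationConfig,
) -> tuple[MiRNADatabase, MiRNADatabase, SimulationTruth]:
    """Generate human/mouse databases with planted orthologue structure.

    Species-specific sequences are never substrings or superstrings of any
    opposite-species sequence; identical pairs share a sequence exactly;
    containment pairs extend the human sequence by 1-3 flanking nt on the
    mouse side. Deterministic under the config seed.
    """
    rng = random.Random(cfg.seed)
    lo, hi = cfg.mature_len_range
    if hi < lo or lo < 8:
        raise ValueError("infeasible mature length range")
    accepted: list[str] = []  # global substring-free pool (pairs excluded)
    truth = SimulationTruth()
    human_entries: list[MatureMiRNA] = []
    mouse_entries: list[MatureMiRNA] = []

    def draw(lo_: int, hi_: int, max_tries: int = 2000) -> str:
        for _ in range(max_tries):
            seq = _random_seq(rng, lo_, hi_)
            if not _clashes(seq, accepted):
                return seq
        raise RuntimeError("could not satisfy substring-freeness; widen length range")

    idx = 0
    for _ in range(cfg.n_conserved_identical):
        idx += 1
        seq = draw(lo, hi)
        accepted.append(seq)
        h = MatureMiRNA(f"hsa-miR-s{idx:04d}-5p", "hsa", seq)
        m = MatureMiRNA(f"mmu-miR-s{idx:04d}-5p", "mmu", seq)
        human_entries.append(h)
        mouse_entries.append(m)
        truth.pairs.append(ConservedPair(h.name, m.name, Relation.IDENTICAL))
    for _ in range(cfg.n_conserved_containment):
        idx += 1
        ext = rng.randint(1, 3)
        left = rng.randint(0, ext)
        hseq = draw(lo, max(lo, hi - ext))
        mseq = (
            _random_seq(rng, left, left)
            + hseq
            + _random_seq(rng, ext - left, ext - left)
        )
        tries = 0
        while _clashes(mseq, accepted):
            tries += 1
            if tries > 2000:
                raise RuntimeError("could not place containment pair")
            left = rng.randint(0, ext)
            mseq = (
                _random_seq(rng, left, left)
                + hseq
                + _random_seq(rng, ext - left, ext - left)
            )
        accepted.append(mseq)  # hseq is inside mseq by construction
        h = MatureMiRNA(f"hsa-miR-s{idx:04d}-3p", "hsa", hseq)
        m = MatureMiRNA(f"mmu-miR-s{idx:04d}-3p", "mmu", mseq)
        human_entries.append(h)
        mouse_entries.append(m)
        truth.pairs.append(ConservedPair(h.name, m.name, Relation.HUMAN_IN_MOUSE))
    for _ in range(cfg.n_human_specific):
        idx += 1
        seq = draw(lo, hi)
        accepted.append(seq)
        human_entries.append(MatureMiRNA(f"hsa-miR-s{idx:04d}-5p", "hsa", seq))
    for _ in range(cfg.n_mouse_specific):
        idx += 1
        seq = draw(lo, hi)
        accepted.append(seq)
        mouse_entries.append(MatureMiRNA(f"mmu-miR-s{idx:04d}-5p", "mmu", seq))

    if not human_entries or not mouse_entries:
        raise ValueError("each species needs at least one entry")
    return (
        MiRNADatabase("hsa", human_entries),
        MiRNADatabase("mmu", mouse_entries),
        truth,
    )


def _category(name: str, truth: SimulationTruth, human_db, mouse_db) -> str:
    paired = {p.human_name for p in truth.pairs} | {p.mouse_name for p in truth.pairs}
    if name in paired:
        return "conserved"
    return "human_specific" if name.startswith("hsa-") else "mouse_specific"


def simulate_xenograft_reads(
    human_db: MiRNADatabase,
    mouse_db: MiRNADatabase,
    truth: SimulationTruth,
    cfg: SimulationConfig,
    compartments: tuple[str, ...] = ("total_plasma",),
    sev_timepoints: tuple[str, ...] = ("day23",),
) -> tuple[dict[str, list[ReadRecord]], dict[str, SampleMeta], SimulationTruth]:
    """Draw per-sample error-free read sets with recorded provenance.

    Each sample draws ``library_size`` reads; a read comes from the human
    (tumor) pool with the timepoint's tumor fraction, otherwise from the
    mouse (host) pool. Pools share the conserved miRNAs. Per-miRNA sampling
    weights are log-normal, drawn once per (compartment, pool) so that
    replicates share a profile while the sEV cargo differs from total
    plasma. Reads are the full mature sequence unless a substitution rate
    is configured.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    conserved_h = [p.human_name for p in truth.pairs]
    conserved_m = [p.mouse_name for p in truth.pairs]
    human_pool = [e.name for e in human_db]  # human-specific + conserved (hsa)
    mouse_pool = [e.name for e in mouse_db]
    seqs = {e.name: e.sequence for e in list(human_db) + list(mouse_db)}
    paired = set(conserved_h) | set(conserved_m)

    def pool_weights(pool: list[str]) -> dict[str, float]:
        w = rng.lognormal(mean=0.0, sigma=cfg.abundance_lognormal_sigma, size=len(pool))
        return dict(zip(pool, w / w.sum()))

    samples: dict[str, list[ReadRecord]] = {}
    meta: dict[str, SampleMeta] = {}
    timepoints_by_comp = {
        "total_plasma": tuple(cfg.tumor_fraction_by_timepoint),
        "sev": sev_timepoints,
    }
    for comp in dict.fromkeys(list(compartments) + (["sev"] if sev_timepoints else [])):
        w_h = pool_weights(human_pool)
        w_m = pool_weights(mouse_pool)
        truth.pool_weights[f"{comp}:human"] = w_h
        truth.pool_weights[f"{comp}:mouse"] = w_m
        for tp in timepoints_by_comp[comp]:
            frac = cfg.tumor_fraction_by_timepoint[tp]
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{comp}_{tp}_r{rep}"
                meta[sid] = SampleMeta(sid, comp, tp, rep)
                n_human = int(rng.binomial(cfg.library_size, frac)) if frac else 0
                n_mouse = cfg.library_size - n_human
                reads: list[ReadRecord] = []
                origins: dict[str, tuple[str, str]] = {}
                src_counts: Counter = Counter()
                cat_totals = Counter()
                rid = 0
                for pool_name, pool, w, n in (
                    ("human", human_pool, w_h, n_human),
                    ("mouse", mouse_pool, w_m, n_mouse),
                ):
                    if n == 0:
                        continue
                    draws = rng.multinomial(n, [w[name] for name in pool])
                    for name, k in zip(pool, draws):
                        if k == 0:
                            continue
                        cat = (
                            "conserved"
                            if name in paired
                            else (
                                "human_specific"
                                if pool_name == "human"
                                else "mouse_specific"
                            )
                        )
                        for _ in range(int(k)):
                            rid += 1
                            read_id = f"{sid}.{rid}"
                            seq = seqs[name]
                            if cfg.substitution_rate > 0:
                                seq = _mutate(seq, cfg.substitution_rate, rng)
                            reads.append(ReadRecord(read_id, seq))
                            origins[read_id] = (pool_name, name)
                            src_counts[name] += 1
                            cat_totals[cat] += 1
                samples[sid] = reads
                truth.read_origins[sid] = origins
                truth.source_counts[sid] = src_counts
                truth.category_totals[sid] = {
                    "human_specific": cat_totals["human_specific"],
                    "mouse_specific": cat_totals["mouse_specific"],
                    "conserved": cat_totals["conserved"],
                }
    return samples, meta, truth


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in _BASES if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


def simulate_external_profiles(
    n_per_group: dict[str, int] | None = None,
    n_mirna: int = 100,
    trend_mirnas: list[str] | None = None,
    shift: float = 3.0,
    seed: int = 0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
) -> tuple[ExternalProfileSet, dict]:
    """Microarray-style log2 intensity matrix with planted trend miRNAs.

    Baseline intensities are Normal(baseline_mean, baseline_sd); planted
    trend miRNAs gain ``shift`` log2 units per ordered group step
    (healthy -> primary -> metastatic). Group sizes default to the clinical
    validation set's 8 healthy / 2 primary / 8 metastatic.
    """
    n_per_group = n_per_group or {"healthy": 8, "primary": 2, "metastatic": 8}
    rng = np.random.default_rng(seed)
    names = [f"miR-t{i:04d}" for i in range(1, n_mirna + 1)]
    trend_mirnas = trend_mirnas if trend_mirnas is not None else names[:3]
    unknown = set(trend_mirnas) - set(names)
    if unknown:
        raise ValueError(f"trend miRNAs not in simulated set: {sorted(unknown)}")
    cols = {}
    groups = {}
    for step, g in enumerate(("healthy", "primary", "metastatic")):
        for j in range(n_per_group.get(g, 0)):
            sid = f"{g}_{j + 1}"
            vals = rng.normal(baseline_mean, baseline_sd, size=n_mirna)
            for i, name in enumerate(names):
                if name in trend_mirnas:
                    vals[i] += shift * step
            cols[sid] = vals
            groups[sid] = g
    profiles = ExternalProfileSet(
        intensities=pd.DataFrame(cols, index=names),
        groups=groups,
        platform_note="synthetic log2 quantile-normalized-style intensities",
    )
    return profiles, {"trend_mirnas": list(trend_mirnas)}


def write_sample_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    """Write reads as FASTQ (gzip when the path ends in .gz); qualities flat."""
    path = Path(path)
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth_json(truth: SimulationTruth, path: str | Path) -> None:
    payload = {
        "pairs": [
            {"human_name": p.human_name, "mouse_name": p.mouse_name, "relation": p.relation.value}
            for p in truth.pairs
        ],
        "category_totals": truth.category_totals,
        "source_counts": {k: dict(v) for k, v in truth.source_counts.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
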
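"""End-to-end orchestration: simulate/load -> classify -> normalize ->
abundance -> external validation, with a machine-readable summary.

The stages compose exactly as the standalone functions do; the orchestrator
only wires file paths and collects the summary, so a manual composition of
the subcommands reproduces its outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from xenomir import abundance as ab
from xenomir import classify as cl
from xenomir import expression as ex
from xenomir import validation as va
from xenomir.db import MiRNADatabase, read_mature_fasta, write_mature_fasta
from xenomir.orthology import find_conserved_pairs, partition_names, write_pairs_tsv
from xenomir.simulate import (
    SimulationConfig,
    simulate_databases,
    simulate_external_profiles,
    simulate_xenograft_reads,
    write_sample_fastq,
    write_truth_json,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for an end-to-end run.

    With ``simulate = True`` the inputs are generated in the run directory
    from ``sim``; otherwise ``human_fasta``/``mouse_fasta``/``reads`` must
    point at existing files.
    """

    out_dir: str = "run"
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    human_fasta: str | None = None
    mouse_fasta: str | None = None
    reads: dict[str, str] = field(default_factory=dict)  # sample_id -> path
    meta_tsv: str | None = None
    min_len: int = cl.DEFAULT_MIN_LEN
    abundance_threshold: float = ab.DEFAULT_THRESHOLD
    validation: va.ValidationConfig = field(default_factory=va.ValidationConfig)
    external_matrix: str | None = None
    external_groups: str | None = None
    simulate_external: bool = True
    external_shift: float = 3.0
    seed: int = 0


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return (and write) the summary dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if cfg.simulate:
        sim_cfg = cfg.sim
        human_db, mouse_db, truth = simulate_databases(sim_cfg)
        samples, meta, truth = simulate_xenograft_reads(
            human_db, mouse_db, truth, sim_cfg
        )
        write_mature_fasta(human_db, out / "hsa_mature.fa")
        write_mature_fasta(mouse_db, out / "mmu_mature.fa")
        ex.write_meta_tsv(meta, out / "samples.tsv")
        write_truth_json(truth, out / "truth.json")
        reads_by_sample = samples
    else:
        if not (cfg.human_fasta and cfg.mouse_fasta and cfg.reads and cfg.meta_tsv):
            raise ValueError("non-simulated run needs database, reads and meta paths")
        human_db = read_mature_fasta(cfg.human_fasta, "hsa")
        mouse_db = read_mature_fasta(cfg.mouse_fasta, "mmu")
        meta = ex.read_meta_tsv(cfg.meta_tsv)
        reads_by_sample = {
            sid: list(cl.read_sequences(path)) for sid, path in cfg.reads.items()
        }

    # --- orthology --------------------------------------------------------
    pairs = find_conserved_pairs(human_db, mouse_db)
    partition = partition_names(human_db, mouse_db, pairs)
    write_pairs_tsv(pairs, out / "conserved_pairs.tsv")

    # --- classification ---------------------------------------------------
    index = cl.SubstringIndex([human_db, mouse_db], cfg.min_len)
    counts_list = [
        cl.classify_reads(
            reads, partition, human_db, mouse_db, cfg.min_len, sample_id=sid, index=index
        )
        for sid, reads in sorted(reads_by_sample.items())
    ]
    summary_rows = []
    for c in counts_list:
        row = {"sample_id": c.sample_id, **c.category_totals,
               "unassigned": c.unassigned, "ambiguous_cross": c.ambiguous_cross}
        summary_rows.append(row)
    pd.DataFrame(summary_rows).to_csv(out / "classification_summary.tsv", sep="\t", index=False)

    # --- normalization & abundance per category --------------------------
    abundant: dict[str, dict[str, list[str]]] = {}
    sev_query: list[str] = []
    growth_trend: list[str] = []
    for category in ("human_specific", "conserved"):
        frame = cl.counts_to_frame(counts_list, category)
        if frame.empty:
            continue
        cm = ex.CountMatrix(category=category, values=frame, meta=meta)
        cm = ex.remove_excluded_mirnas(cm)
        cpm = ex.cpm_normalize(cm)
        ex.write_matrix_tsv(cpm.values, out / f"{category}_cpm.tsv")
        mean = ex.average_replicates(cpm)

        if category == "conserved":
            ctrl = ex.columns_for(cpm, "total_plasma", "control")
            late = ex.columns_for(cpm, "total_plasma", "day23")
            if ctrl and late:
                growth_trend = sorted(ex.growth_trend_filter(cpm, ctrl, late))
                (out / "growth_trend.txt").write_text("\n".join(growth_trend) + "\n")

        abundant[category] = {}
        for comp in ("total_plasma", "sev"):
            col = f"{comp}_day23"
            if col not in mean.values.columns:
                continue
            vec = mean.values[col]
            if category == "conserved" and growth_trend:
                vec = vec.loc[vec.index.intersection(growth_trend)]
            if vec.sum() <= 0:
                continue
            prof = ab.percent_abundance(
                vec, threshold=cfg.abundance_threshold, compartment=comp, category=category
            )
            ab.write_profile_tsv(prof, out / f"{category}_{comp}_profile.tsv")
            sel = ab.select_abundant(prof)
            abundant[category][comp] = sel
            if comp == "sev":
                sev_query.extend(sel)

    # --- external validation ---------------------------------------------
    validation_summary = None
    if cfg.external_matrix and cfg.external_groups:
        profiles = va.load_profiles(cfg.external_matrix, cfg.external_groups)
        ext_truth = {}
    elif cfg.simulate_external:
        trend_n = min(3, len(sev_query)) if sev_query else 3
        planted = None
        if sev_query:
            # plant the first abundant sEV miRNAs (canonicalized) as trends
            names = [va.canonical_name(n) for n in sev_query]
            n_mirna = max(100, len(names))
            all_names = names + [
                f"mir-t{i:04d}" for i in range(1, n_mirna - len(names) + 1)
            ]
            profiles, ext_truth = _external_from_names(
                all_names, names[:trend_n], cfg.external_shift, cfg.seed
            )
            planted = names[:trend_n]
        else:
            profiles, ext_truth = simulate_external_profiles(
                shift=cfg.external_shift, seed=cfg.seed
            )
    else:
        profiles = None
        ext_truth = {}

    if profiles is not None and sev_query:
        expressed = va.expressed_filter(profiles, "metastatic", cfg.validation)
        count, fraction, table = va.overlap_validation(sev_query, expressed)
        table.to_csv(out / "validation_overlap.tsv", sep="\t", index=False)
        de = va.differential_expression(profiles, "metastatic", "primary")
        de.to_csv(out / "validation_de.tsv", sep="\t", index=False)
        trend = sorted(va.progression_trend(profiles))
        (out / "validation_trend.txt").write_text("\n".join(trend) + "\n")
        validation_summary = {
            "expressed_in_metastatic": len(expressed),
            "overlap_count": count,
            "overlap_fraction": fraction,
            "trend_mirnas": trend,
        }

    summary = {
        "conserved_pair_count": len(pairs),
        "n_human_specific_names": len(partition.human_specific_names),
        "n_mouse_specific_names": len(partition.mouse_specific_names),
        "n_conserved_names": len(partition.conserved_names),
        "classification": summary_rows,
        "abundant": abundant,
        "growth_trend": growth_trend,
        "validation": validation_summary,
        "seed": cfg.seed,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _external_from_names(names, trend_names, shift, seed):
    """External matrix over a caller-supplied miRNA universe."""
    import numpy as np

    rng = np.random.default_rng(seed + 7)
    n_per_group = {"healthy": 8, "primary": 2, "metastatic": 8}
    cols, groups = {}, {}
    for step, g in enumerate(("healthy", "primary", "metastatic")):
        for j in range(n_per_group[g]):
            sid = f"{g}_{j + 1}"
            vals = rng.normal(7.0, 1.0, size=len(names))
            for i, name in enumerate(names):
                if name in trend_names:
                    vals[i] += shift * step
            cols[sid] = vals
            groups[sid] = g
    return (
        va.ExternalProfileSet(intensities=pd.DataFrame(cols, index=list(names)), groups=groups),
        {"trend_mirnas": list(trend_names)},
    )
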
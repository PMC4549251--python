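"""End-to-end orchestration of the synthetic-data demo pipeline.

`run_pipeline(RunConfig)` generates a genome, a methylome with planted
class-graded PARP1 enrichment, nucleosome fragment pairs, a total-nucleosome
background library, then runs the full analysis: dedup, strand-offset
estimation, size filtering, midpoints, TSS profiles by expression class,
windowed correlation against a planted signal track, methylation-class
enrichment, and the 450K differential-methylation branch.  Every product is
written as TSV/BED/bedGraph under the output directory, and identical config
implies byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffmeth, fragments, io, methylome, profiles, synth, windows
from .intervals import IntervalSet

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of the demo pipeline, with the analysis defaults.

    Window width 2,000 bp, TSS flank 1,000 bp with 5 bp steps, promoter
    window (-500, +250), fragment-filter central mass 95%, coverage extension
    160 bp, DM threshold |log2 FC| > 1 — each default mirrors the analysis
    the pipeline reimplements.
    """

    seed: int = 0
    out_dir: str = "nucmeth_out"
    # genome
    n_chroms: int = 1
    chrom_length: int = 400_000
    gc_content: float = 0.41
    # fragments
    n_fragments: int = 50_000
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 20.0
    background_fraction: float = 0.3
    coverage_extension: int = 160
    filter_central: float = 0.95
    max_offset: int = 400
    # profiles / windows
    tss_flank: int = 1000
    tss_step: int = 5
    promoter_region: tuple[int, int] = (-500, 250)
    window_width: int = 2000
    target_corr: float = 0.35
    # methylome / diffmeth
    hemi_fraction: float = 0.5
    n_probes: int = 2000
    n_spiked_hyper: int = 60
    n_spiked_hypo: int = 25
    dm_effect_size: float = 1.5
    stages: tuple[str, ...] = (
        "synth", "fragments", "profiles", "windows", "methylome", "diffmeth"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages in dependency order; return the result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": asdict(config)}
    order = ["synth", "fragments", "profiles", "windows", "methylome", "diffmeth"]
    requested = [s for s in order if s in config.stages]
    for stage in config.stages:
        if stage not in order:
            raise ValueError(f"unknown stage {stage!r}")
    for stage in requested:
        deps = order[: order.index(stage)]
        missing = [d for d in deps if d not in requested]
        if missing:
            raise ValueError(f"stage {stage!r} requires stages {missing}")

    cfg = synth.SimulationConfig(
        seed=config.seed,
        n_fragments=config.n_fragments,
        fragment_length_mean=config.fragment_length_mean,
        fragment_length_sd=config.fragment_length_sd,
        background_fraction=config.background_fraction,
        dm_effect_size=config.dm_effect_size,
    )

    # ---- synth -----------------------------------------------------------
    genome = synth.make_genome(
        config.n_chroms, config.chrom_length, config.gc_content, seed=config.seed
    )
    calls, truth = synth.simulate_methylome(
        genome, cfg, hemi_fraction=config.hemi_fraction
    )
    dyads = synth.dyads_from_methylation_truth(truth, cfg)
    pairs = synth.simulate_nucleosome_fragments(genome, dyads, cfg)
    bg_cfg = synth.SimulationConfig(
        seed=config.seed + 1,
        n_fragments=config.n_fragments,
        fragment_length_mean=config.fragment_length_mean,
        fragment_length_sd=config.fragment_length_sd,
        background_fraction=1.0,
    )
    bg_pairs = synth.simulate_nucleosome_fragments(genome, dyads.iloc[:0], bg_cfg)
    io.write_pairs_bed(pairs, out / "fragments.bed")
    io.write_methylation_calls(calls, out / "methylation_calls.tsv")
    io.write_table(truth, out / "methylome_truth.tsv")
    logger.info("synth: %d fragments, %d methylation calls", len(pairs), len(calls))
    results["genome"] = genome
    results["truth"] = truth
    if requested == ["synth"]:
        return results

    # ---- fragments -------------------------------------------------------
    reads = fragments.reads_from_pairs(pairs)
    reads, n_dup = fragments.deduplicate(reads)
    offset = fragments.estimate_strand_offset(reads, max_offset=config.max_offset)
    kept, bounds = fragments.fragment_size_filter(pairs, central=config.filter_central)
    track, _ = fragments.midpoints_paired(kept, source_label="parp1")
    bg_track, _ = fragments.midpoints_paired(bg_pairs, source_label="background")
    cov = fragments.coverage_track(
        reads, genome.chrom_lengths, extension=config.coverage_extension
    )
    io.write_midpoints_bed(track, out / "midpoints.bed")
    io.write_bedgraph(cov, out / "coverage.bedgraph")
    logger.info(
        "fragments: offset %d bp, size bounds (%.1f, %.1f), %d dup removed",
        offset, bounds[0], bounds[1], n_dup,
    )
    results.update(offset=offset, size_bounds=bounds, midpoints=track)
    if "profiles" not in requested:
        return results

    # ---- profiles --------------------------------------------------------
    # expression-graded TSS panel derived from dyad weights (denser binding at
    # "high expression" promoters), anchored on site positions
    rng = np.random.default_rng(config.seed + 2)
    n_tss = min(400, len(truth))
    pick = rng.choice(len(truth), size=n_tss, replace=False)
    tss = IntervalSet(
        pd.DataFrame(
            {
                "chrom": truth["chrom"].to_numpy()[pick],
                "start": truth["pos"].to_numpy()[pick],
                "end": truth["pos"].to_numpy()[pick] + 1,
                "strand": rng.choice(["+", "-"], size=n_tss),
                "score": 0.0,
                "name": [f"gene{i}" for i in range(n_tss)],
            }
        )
    )
    profile = profiles.tss_profile(
        track, tss, flank=config.tss_flank, step=config.tss_step
    )
    occupancy = profiles.promoter_occupancy(track, tss, region=config.promoter_region)
    io.write_table(profile.to_frame(), out / "tss_profile.tsv")
    occupancy.rename_axis("gene").reset_index().to_csv(
        out / "promoter_occupancy.tsv", sep="\t", index=False
    )
    results.update(tss_profile=profile, occupancy=occupancy)
    if "windows" not in requested:
        return results

    # ---- windows ---------------------------------------------------------
    wins = windows.tile_genome(genome, width=config.window_width)
    density = windows.normalized_density(track, bg_track, wins, drop_empty=False)
    signal = synth.simulate_signal_track(
        wins, config.target_corr, density["log2_density"].to_numpy(),
        seed=config.seed + 3,
    )
    r, p = windows.pearson_corr(density["log2_density"].to_numpy(), signal)
    table = density.copy()
    table["external_signal"] = signal
    io.write_table(table, out / "window_table.tsv")
    logger.info("windows: planted r=%.2f recovered r=%.3f (p=%.2g)", config.target_corr, r, p)
    results.update(window_table=table, window_corr=(r, p))
    if "methylome" not in requested:
        return results

    # ---- methylome -------------------------------------------------------
    paired, unpaired = methylome.pair_strands(calls, genome)
    classes = methylome.classify_sites(paired)
    enr = methylome.enrichment_by_class(
        track, classes, genome_length=genome.total_length, width=config.window_width
    )
    io.write_table(classes, out / "methylation_classes.tsv")
    pd.DataFrame(
        {"class": enr.ordering, "central_ratio": [enr.central_ratio[c] for c in enr.ordering]}
    ).to_csv(out / "class_ordering.tsv", sep="\t", index=False)
    logger.info("methylome: %d sites classified, ordering %s", len(classes), enr.ordering)
    results.update(classes=classes, class_enrichment=enr)
    if "diffmeth" not in requested:
        return results

    # ---- diffmeth --------------------------------------------------------
    probe_table, probe_truth = synth.simulate_450k(
        config.n_probes,
        cfg=cfg,
        n_spiked_hyper=config.n_spiked_hyper,
        n_spiked_hypo=config.n_spiked_hypo,
    )
    beta = probe_table.pivot_table(index="probe_id", columns="sample", values="beta")
    detp = probe_table.pivot_table(index="probe_id", columns="sample", values="detection_p")
    beta_qc, ledger = diffmeth.qc_filter(beta, detp)
    untreated = [c for c in beta_qc.columns if c.startswith("untreated")]
    treated = [c for c in beta_qc.columns if c.startswith("treated")]
    b_u = beta_qc[untreated].mean(axis=1)
    b_t = beta_qc[treated].mean(axis=1)
    stat, pval = diffmeth.global_shift_test(b_t.to_numpy(), b_u.to_numpy())
    dm = diffmeth.classify_dm(b_t, b_u)
    dm.insert(0, "probe_id", dm.index)
    islands = diffmeth.detect_cpg_islands(genome.sequence[genome.chrom_names[0]])
    anno = probe_table.drop_duplicates("probe_id")[["probe_id", "chrom", "pos", "gene", "region"]]
    anno = anno.rename(columns={"region": "functional"}).copy()
    anno["cpg_context"] = diffmeth.annotate_island_context(
        anno["pos"].to_numpy() % config.chrom_length, islands
    )
    summary = diffmeth.summarize_dm(dm.reset_index(drop=True), anno)
    gene_sets = diffmeth.hyper_hypo_gene_sets(
        dm.reset_index(drop=True),
        anno.rename(columns={"functional": "region"})[["probe_id", "gene", "region"]],
    )
    io.write_table(dm.reset_index(drop=True), out / "dm_results.tsv")
    io.write_table(probe_truth, out / "dm_truth.tsv")
    io.write_intervals(islands, out / "cpg_islands.bed", fmt="BED")
    with open(out / "dm_summary.json", "w") as fh:
        json.dump(
            {
                "total": summary["total"],
                "global_shift": {"statistic": stat, "p": pval},
                "qc": {"masked": ledger["masked_measures"], "removed": ledger["removed_samples"]},
                "functional": summary["functional"]["count"].to_dict(),
                "cpg_context": summary["cpg_context"]["count"].to_dict(),
                "gene_sets": {
                    k: sorted(v) for k, v in gene_sets.items() if isinstance(v, set)
                },
            },
            fh,
            indent=2,
        )
    results.update(dm=dm, dm_truth=probe_truth, dm_summary=summary, gene_sets=gene_sets)
    return results
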
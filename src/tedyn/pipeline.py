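"""End-to-end orchestration: simulate -> annotate -> features -> rip ->
ltr burst analysis -> accumulation dynamics, with truth-recovery summaries.

This is the programmatic counterpart of the command-line stages; each step
delegates to the corresponding module and the returned bundle carries the
per-stage tables plus scalar summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import annotation, dynamics, features, ltr, rip
from .config import PipelineConfig
from .core import GenomeAssembly, HitRecord, Interval
from .simulate import SimConfig, TruthTable, assemble_genomes, generate_accumulation_table


def hits_from_frame(frame: pd.DataFrame) -> list[HitRecord]:
    """Convert an in-memory hit table (13-column dialect) to records."""
    records = []
    for row in frame.itertuples(index=False):
        sstart, send = int(row.sstart), int(row.send)
        lo, hi = min(sstart, send), max(sstart, send)
        records.append(
            HitRecord(
                query_id=str(row.qseqid),
                subject_contig=str(row.sseqid),
                identity=row.pident / 100.0,
                aln_length=int(row.length),
                gapless_query_coverage=(row.qend - row.qstart + 1) / row.qlen,
                evalue=float(row.evalue),
                subject_interval=Interval(str(row.sseqid), lo - 1, hi),
            )
        )
    return records


@dataclass
class PipelineResult:
    truth: TruthTable
    assemblies: dict[str, GenomeAssembly]
    filter_results: dict[str, annotation.FilterResult]
    compartment_maps: dict
    te_content: dict[str, pd.DataFrame]
    rip_track: pd.DataFrame
    pair_records: list[ltr.LTRPairRecord]
    poisson_null: Optional[ltr.PoissonNull]
    accumulation_fits: Optional[list[dynamics.AccumulationFit]]
    summary: dict = field(default_factory=dict)


def ltr_copies_from_assembly(assembly: GenomeAssembly) -> list[ltr.LtrSeqs]:
    """Extract analysable LTR pairs (both LTRs present) from planted copies."""
    out = []
    for copy in assembly.te_copies:
        if copy.ltr5 is None or copy.ltr3 is None:
            continue
        out.append(
            ltr.LtrSeqs(
                copy_id=copy.copy_id,
                ltr5=assembly.sequence_of(copy.ltr5),
                ltr3=assembly.sequence_of(copy.ltr3),
                compartment=copy.compartment,
            )
        )
    return out


def run_synthetic_pipeline(
    sim_config: SimConfig,
    config: Optional[PipelineConfig] = None,
    fit_accumulation: bool = True,
) -> PipelineResult:
    """Run the full analysis on one simulated a1/a2 genome pair."""
    cfg = config or PipelineConfig()
    a1, a2, truth, hit_frames = assemble_genomes(sim_config)
    assemblies = {"a1": a1, "a2": a2}

    # --- TE-candidate filtering on the emitted hit tables ---------------
    filter_results = {
        hap: annotation.filter_hits(hits_from_frame(frame), cfg.filter)
        for hap, frame in hit_frames.items()
    }

    # --- compartments ----------------------------------------------------
    nrr = [(iv, lab.split(":", 1)[1]) for iv, lab in truth.compartments
           if lab.startswith("NRR:")]
    par = [iv for iv, lab in truth.compartments if lab == "PAR"]
    compartment_maps = {}
    te_content = {}
    for hap, asm in assemblies.items():
        telomeres = [
            t for c in asm.contigs.values()
            for t in features.detect_telomeres(c, cfg.features)
        ]
        centromeres = []
        for c in asm.contigs.values():
            cen = features.detect_centromere(
                c, asm.bed_layers.get("centromere_hits", []), asm.genes,
                cfg.features,
            )
            if cen is not None:
                centromeres.append(cen)
        cmap = features.build_compartment_map(
            asm, nrr=nrr, par=par, centromeres=centromeres,
            telomeres=telomeres, cfg=cfg.features,
        )
        compartment_maps[hap] = cmap
        te_content[hap] = features.compartment_te_content(asm.te_copies, cmap)

    # --- RIP track on the mating-type contig ------------------------------
    mating = a1.contigs["mating_type"]
    track = rip.rip_window_track(
        mating.id, mating.sequence, cfg.rip.window_bp, cfg.rip.overlap_motif
    )
    rip_frame = rip.track_to_frame(track)

    # --- LTR burst-versus-conversion --------------------------------------
    copies = ltr_copies_from_assembly(a1)
    pair_records: list[ltr.LTRPairRecord] = []
    null = None
    if len(copies) >= cfg.ltr.min_copies:
        pair_records = ltr.ltr_pair_records(copies, cfg.ltr)
        null = ltr.build_poisson_null(
            pair_records, cfg.ltr.null_points, cfg.ltr.alpha_level,
            seed=sim_config.seed,
        )
        pair_records = ltr.classify_pairs(pair_records, null)

    # --- accumulation dynamics -------------------------------------------
    fits = None
    summary: dict = {}
    if fit_accumulation:
        y0, A, r, sd = sim_config.accumulation_params
        ages = np.linspace(0.1, 7.0, 21)
        table = generate_accumulation_table(y0, A, r, ages, sd, sim_config.seed)
        fits, best = dynamics.fit_accumulation_models(table, cfg=cfg.dynamics)
        summary["best_model"] = best.model
        if best.model == "negexp":
            plateau = dynamics.plateau_summary(best)
            summary["plateau_A"] = plateau["A"]
            summary["t95_my"] = plateau["t95_my"]

    # --- scalar summaries -------------------------------------------------
    content = te_content["a1"]
    nrr_rows = content[content["compartment"].str.startswith("NRR:")]
    summary["genome_te_percent"] = (
        100.0 * content["te_bases"].sum() / content["bases"].sum()
    )
    if nrr_rows["bases"].sum() > 0:
        summary["nrr_te_percent"] = (
            100.0 * nrr_rows["te_bases"].sum() / nrr_rows["bases"].sum()
        )
    auto = content[content["compartment"] == "autosome"]
    summary["autosome_te_percent"] = (
        100.0 * auto["te_bases"].sum() / auto["bases"].sum()
    )
    if pair_records:
        observed, expected, deficit = ltr.nrr_pair_deficit(
            pair_records, seed=sim_config.seed
        )
        summary["nrr_pair_deficit_percent"] = deficit
        classified = [r for r in pair_records if r.N1 is not None and r.N2 is not None]
        if classified:
            summary["conversion_fraction"] = sum(
                r.classification == "conversion_candidate" for r in classified
            ) / len(classified)
    return PipelineResult(
        truth=truth,
        assemblies=assemblies,
        filter_results=filter_results,
        compartment_maps=compartment_maps,
        te_content=te_content,
        rip_track=rip_frame,
        pair_records=pair_records,
        poisson_null=null,
        accumulation_fits=fits,
        summary=summary,
    )
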
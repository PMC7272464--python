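"""Stage orchestration: wiring the simulator, counting, QC and DE stages.

Each function is a pure function of (inputs on disk or in memory, config,
seed) and writes its outputs plus a machine-readable summary, so reruns with
the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import assign, barnyard, dge, expression, simulate, tags
from .config import RunConfig

log = logging.getLogger("platepool")


def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    """Generate reference, plate, ground truth and paired FASTQ files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = config.simulation
    ref = simulate.generate_reference(
        s.n_genes_per_species, s.transcript_length, s.mito_fraction, seed=config.seed
    )
    plate = simulate.design_plate(
        s.n_cells_per_species,
        s.n_negative,
        s.n_doublets,
        conditions=s.conditions,
        seed=config.seed,
    )
    truth = simulate.simulate_expression(
        plate,
        ref,
        mean_molecules_per_cell=s.mean_molecules_per_cell,
        ambient_fraction=s.ambient_fraction,
        dispersion=s.dispersion,
        seed=config.seed,
        profile_sigma=s.profile_sigma,
        doublet_ratio=s.doublet_ratio,
    )
    summary = simulate.simulate_reads(
        truth,
        ref,
        outdir / "reads_R1.fastq.gz",
        outdir / "reads_R2.fastq.gz",
        duplication_mean=s.duplication_mean,
        error_rate=s.error_rate,
        seed=config.seed,
    )
    ref.write(outdir / "reference.fasta", outdir / "genes.tsv")
    plate.write(outdir / "plate.tsv")
    truth.write(outdir / "truth_molecules.tsv", outdir / "truth_effects.tsv")
    log.info("simulated %(n_molecules)d molecules -> %(n_read_pairs)d read pairs", summary)
    return summary


def stage_count(
    config: RunConfig,
    r1_path,
    r2_path,
    fasta_path,
    gene_table_path,
    plate_path,
    outdir: Path,
) -> dict:
    """Tag, assign and collapse reads into the DGE matrix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = simulate.ReferenceSet.read(fasta_path, gene_table_path)
    plate = simulate.PlateDesign.read(plate_path)
    index = assign.build_index(ref, k=config.pipeline.index_k)

    tag_stats = tags.TagStats()
    assign_stats = assign.AssignStats()
    records = []
    for tagged in tags.tag_stream(r1_path, r2_path, plate.whitelist, tag_stats):
        a = assign.assign_read(tagged.read2, index, config.pipeline.max_mismatches)
        assign_stats.reads += 1
        if a.outcome == assign.ASSIGNED:
            assign_stats.assigned += 1
            records.append((tagged.barcode, tagged.umi, a.gene_id))
        elif a.outcome == assign.AMBIGUOUS:
            assign_stats.ambiguous += 1
        else:
            assign_stats.unassigned += 1

    matrix = dge.build_dge(records, plate.whitelist, gene_ids=sorted(ref.gene_ids))
    matrix.write_mtx(outdir / "dge")
    summary = {
        "tagging": tag_stats.as_dict(),
        "assignment": assign_stats.as_dict(),
        "n_genes": matrix.shape[0],
        "n_cells": matrix.shape[1],
        "total_molecules": int(matrix.counts.sum()),
    }
    (outdir / "count_summary.json").write_text(json.dumps(summary, indent=2))
    if tag_stats.reads_seen == 0:
        log.warning("input FASTQ pair was empty; wrote an all-zero DGE")
    return summary


def stage_barnyard(
    config: RunConfig, dge_dir, gene_table_path, plate_path, outdir: Path
) -> dict:
    """Cell stats, species calls, ambient estimate, doublet flags."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = dge.DGEMatrix.read_mtx(dge_dir)
    gene_table = pd.read_csv(gene_table_path, sep="\t")
    plate = simulate.PlateDesign.read(plate_path)
    report = barnyard.run_barnyard(matrix, gene_table, plate, config.qc)
    report.stats.to_csv(outdir / "cell_stats.tsv", sep="\t", index=False)
    # barnyard scatter: per-cell molecules on each species, for plotting
    report.stats[
        ["barcode", "molecules_A", "molecules_B", "species_call", "well_kind"]
    ].to_csv(outdir / "barnyard_scatter.tsv", sep="\t", index=False)
    summary = report.summary()
    (outdir / "barnyard_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def stage_qc(config: RunConfig, dge_dir, barnyard_dir, outdir: Path) -> dict:
    """Apply the enabled filters and write the filtered DGE."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = dge.DGEMatrix.read_mtx(dge_dir)
    stats = pd.read_csv(Path(barnyard_dir) / "cell_stats.tsv", sep="\t")
    keep = (
        stats["keep_transcripts"]
        & stats["keep_gene_mito"]
        & ~stats["doublet_flag"]
        & (stats["well_kind"] != "negative")
    )
    kept_barcodes = stats.loc[keep, "barcode"].tolist()
    col = {bc: i for i, bc in enumerate(matrix.cell_barcodes)}
    keep_idx = [col[bc] for bc in kept_barcodes]
    filtered = dge.DGEMatrix(
        matrix.counts[:, keep_idx], list(matrix.gene_ids), kept_barcodes
    )
    filtered.write_mtx(outdir / "dge_filtered")
    stats.assign(keep=keep).to_csv(outdir / "qc_table.tsv", sep="\t", index=False)
    summary = {
        "n_input_wells": int(len(stats)),
        "n_sorted_cells": int((stats["well_kind"] != "negative").sum()),
        "n_kept": int(keep.sum()),
        "retention_pct": round(
            100.0 * keep.sum() / max((stats["well_kind"] != "negative").sum(), 1), 1
        ),
    }
    (outdir / "qc_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def stage_de(
    config: RunConfig,
    dge_dir,
    qc_table_path,
    control_condition: str,
    outdir: Path,
    s_markers: list[str] | None = None,
    g2m_markers: list[str] | None = None,
) -> dict:
    """Normalize, test each drug against the control, write DE tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = dge.DGEMatrix.read_mtx(dge_dir)
    qc_table = pd.read_csv(qc_table_path, sep="\t", keep_default_na=False)
    meta = qc_table.set_index("barcode").loc[matrix.cell_barcodes]
    norm = expression.cpm_log_normalize(matrix)
    conditions = meta["condition"].astype(str)
    contrasts = sorted(c for c in conditions.unique() if c and c != control_condition)
    control_cells = [bc for bc, c in zip(matrix.cell_barcodes, conditions) if c == control_condition]
    de_results: dict[str, pd.DataFrame] = {}
    for cond in contrasts:
        cells = [bc for bc, c in zip(matrix.cell_barcodes, conditions) if c == cond]
        table = expression.wilcoxon_de(norm, cells, control_cells, config.analysis)
        table.to_csv(outdir / f"de_{cond}_vs_{control_condition}.tsv", sep="\t", index=False)
        de_results[cond] = table
    heat_genes = expression.heatmap_gene_set(de_results, config.analysis.heatmap_alpha)
    (outdir / "heatmap_genes.txt").write_text("".join(g + "\n" for g in heat_genes))
    profiles, corr = expression.pseudobulk_profiles(norm, list(conditions))
    profiles.to_csv(outdir / "pseudobulk_profiles.tsv", sep="\t")
    corr.to_csv(outdir / "pseudobulk_correlation.tsv", sep="\t")
    summary = {
        "contrasts": {
            cond: {
                "n_up": int((t["direction"] == "up").sum()),
                "n_down": int((t["direction"] == "down").sum()),
            }
            for cond, t in de_results.items()
        },
        "n_heatmap_genes": len(heat_genes),
    }
    if s_markers and g2m_markers:
        phases = expression.score_cell_cycle(norm, s_markers, g2m_markers, seed=config.seed)
        phases.to_csv(outdir / "cell_cycle.tsv", sep="\t", index=False)
        summary["phase_counts"] = phases["phase"].value_counts().to_dict()
    (outdir / "de_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def stage_report(outdir: Path) -> dict:
    """Collect every stage's machine-readable summary into one document."""
    outdir = Path(outdir)
    report: dict = {}
    for name in ("count_summary", "barnyard_summary", "qc_summary", "de_summary"):
        for path in sorted(outdir.rglob(name + ".json")):
            report[name] = json.loads(path.read_text())
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
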
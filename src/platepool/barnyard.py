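"""Per-cell QC statistics, species classification, ambient estimation, filters.

In a species-mixing ("barnyard") design, every molecule maps to exactly one
of two species, so each cell's *specificity* for a species is the fraction
of its molecules from that species. Cells above the calling threshold
(default 0.9, strict) for either species are classified; the rest are
unidentified. Wells that received beads but no cell ("negative controls")
measure ambient RNA — freely floating transcripts captured during pooling —
as the ratio of their mean transcript count to that of identified cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dge import DGEMatrix
from .simulate import PlateDesign

UNIDENTIFIED = "unidentified"


@dataclass
class QCThresholds:
    """Cell-filtering and species-calling thresholds.

    transcript window: total molecules per cell within [low, high] (inclusive);
    gene filter: number of detected genes must *exceed* min_genes and be at
    most max_genes; mito filter: mitochondrial molecule fraction strictly
    below max_mito; species call: specificity strictly greater than
    specificity_call. specificity_report is a stricter descriptive threshold
    used only in summaries, never for calling.
    """

    transcript_low: int = 5_000
    transcript_high: int = 60_000
    min_genes: int = 500
    max_genes: int = 6_000
    max_mito: float = 0.05
    specificity_call: float = 0.9
    specificity_report: float = 0.95
    doublet_mad_factor: float = 3.0

    def __post_init__(self) -> None:
        if not self.transcript_low < self.transcript_high:
            raise ValueError("transcript_low must be < transcript_high")
        if not 0 < self.specificity_call < 1 or not 0 < self.specificity_report < 1:
            raise ValueError("specificity thresholds must be in (0, 1)")
        if not 0 < self.max_mito <= 1:
            raise ValueError("max_mito must be in (0, 1]")


def compute_cell_stats(
    dge: DGEMatrix,
    gene_table: pd.DataFrame,
    plate: PlateDesign | None = None,
) -> pd.DataFrame:
    """One QC record per cell column of the DGE.

    Columns: barcode, well_kind, condition, n_transcripts, n_genes,
    mito_ratio, molecules_A, molecules_B, specificity_A, specificity_B.
    Ratios are NaN for cells with zero molecules (flagged, not an error).
    Requires every DGE gene to be annotated in gene_table (gene_id, species,
    is_mito).
    """
    meta = gene_table.set_index("gene_id")
    missing = [g for g in dge.gene_ids if g not in meta.index]
    if missing:
        raise ValueError(f"genes missing from the annotation table: {missing[:5]}")
    species = meta.loc[dge.gene_ids, "species"].to_numpy()
    is_mito = meta.loc[dge.gene_ids, "is_mito"].to_numpy(dtype=bool)

    counts = dge.counts.tocsc()
    totals = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = np.asarray(counts[is_mito].sum(axis=0)).ravel() if is_mito.any() else np.zeros_like(totals)
    mol_a = np.asarray(counts[species == "A"].sum(axis=0)).ravel()
    mol_b = np.asarray(counts[species == "B"].sum(axis=0)).ravel()

    with np.errstate(invalid="ignore", divide="ignore"):
        mito_ratio = np.where(totals > 0, mito / np.maximum(totals, 1), np.nan)
        spec_a = np.where(totals > 0, mol_a / np.maximum(totals, 1), np.nan)
        spec_b = np.where(totals > 0, mol_b / np.maximum(totals, 1), np.nan)

    stats = pd.DataFrame(
        {
            "barcode": dge.cell_barcodes,
            "n_transcripts": totals.astype(np.int64),
            "n_genes": n_genes.astype(np.int64),
            "mito_ratio": mito_ratio,
            "molecules_A": mol_a.astype(np.int64),
            "molecules_B": mol_b.astype(np.int64),
            "specificity_A": spec_a,
            "specificity_B": spec_b,
        }
    )
    if plate is not None:
        well_info = {w.barcode: w for w in plate.wells}
        stats["well_kind"] = [
            well_info[bc].kind if bc in well_info else "cell" for bc in stats["barcode"]
        ]
        stats["condition"] = [
            well_info[bc].condition if bc in well_info else "" for bc in stats["barcode"]
        ]
        stats["true_species"] = [
            "+".join(well_info[bc].species) if bc in well_info else ""
            for bc in stats["barcode"]
        ]
    else:
        stats["well_kind"] = "cell"
        stats["condition"] = ""
        stats["true_species"] = ""
    return stats


def classify_species(stats: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.Series:
    """Species call per cell: strict '> threshold' on either specificity.

    Cells with zero molecules are unidentified (no data to call on).
    """
    t = thresholds or QCThresholds()
    call = np.full(len(stats), UNIDENTIFIED, dtype=object)
    has_data = stats["n_transcripts"].to_numpy() > 0
    call[has_data & (stats["specificity_A"].to_numpy() > t.specificity_call)] = "A"
    call[has_data & (stats["specificity_B"].to_numpy() > t.specificity_call)] = "B"
    return pd.Series(call, index=stats.index, name="species_call")


def filter_transcript_window(
    stats: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.Series:
    """Keep cells whose transcript total lies within [low, high], inclusive."""
    t = thresholds or QCThresholds()
    n = stats["n_transcripts"]
    return ((n >= t.transcript_low) & (n <= t.transcript_high)).rename("keep_transcripts")


def filter_gene_mito(
    stats: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.Series:
    """Keep cells with n_genes strictly above min_genes (and <= max_genes)
    and mitochondrial ratio strictly below max_mito."""
    t = thresholds or QCThresholds()
    genes_ok = (stats["n_genes"] > t.min_genes) & (stats["n_genes"] <= t.max_genes)
    mito = stats["mito_ratio"].fillna(0.0)
    return (genes_ok & (mito < t.max_mito)).rename("keep_gene_mito")


def estimate_ambient(stats: pd.DataFrame, species_call: pd.Series | None = None) -> float:
    """Ambient-RNA level: mean negative-well transcripts over mean identified-cell transcripts."""
    if species_call is None:
        species_call = classify_species(stats)
    negatives = stats.loc[stats["well_kind"] == "negative", "n_transcripts"]
    if negatives.empty:
        raise ValueError("ambient estimate unavailable: the plate has no negative-control wells")
    identified = stats.loc[
        (stats["well_kind"] != "negative") & (species_call != UNIDENTIFIED),
        "n_transcripts",
    ]
    if identified.empty:
        raise ValueError("ambient estimate unavailable: no species-identified cells")
    neg_mean = float(negatives.mean())
    if neg_mean == 0.0:
        return 0.0
    return neg_mean / float(identified.mean())


def flag_doublets(
    stats: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    species_call: pd.Series | None = None,
) -> pd.Series:
    """Flag likely heterogeneous doublets among non-negative wells.

    A doublet shares one barcode between two cells, so it shows mixed
    species (unidentified) *and* an abnormally high transcript total. The
    default rule is the union of a fixed test (unidentified and total above
    the transcript window) and a robust-outlier test (unidentified and total
    above median + doublet_mad_factor * scaled MAD of identified cells).
    With fewer than 3 identified cells the robust branch is skipped with a
    warning.
    """
    t = thresholds or QCThresholds()
    if species_call is None:
        species_call = classify_species(stats, t)
    candidate = (stats["well_kind"] != "negative") & (species_call == UNIDENTIFIED)
    n = stats["n_transcripts"]
    flags = candidate & (n > t.transcript_high)
    identified = stats.loc[
        (stats["well_kind"] != "negative") & (species_call != UNIDENTIFIED),
        "n_transcripts",
    ]
    if len(identified) >= 3:
        med = float(identified.median())
        mad = float((identified - med).abs().median()) * 1.4826  # normal-consistent
        flags = flags | (candidate & (n > med + t.doublet_mad_factor * mad))
    else:
        warnings.warn(
            "fewer than 3 identified cells: doublet flagging degrades to the "
            "fixed transcript-ceiling test only",
            stacklevel=2,
        )
    return flags.rename("doublet_flag")


@dataclass
class BarnyardReport:
    """Bundle of the barnyard stage outputs plus descriptive summaries."""

    stats: pd.DataFrame  # cell stats + species_call + filter + doublet columns
    ambient_fraction: float | None
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def summary(self) -> dict:
        s = self.stats
        cells = s[s["well_kind"] != "negative"]
        identified = cells[cells["species_call"] != UNIDENTIFIED]
        unidentified = cells[cells["species_call"] == UNIDENTIFIED]
        negatives = s[s["well_kind"] == "negative"]
        t = self.thresholds

        def _mean(frame, col):
            return float(frame[col].mean()) if len(frame) else float("nan")

        return {
            "n_wells": int(len(s)),
            "n_cell_wells": int(len(cells)),
            "n_negative_wells": int(len(negatives)),
            "n_identified": int(len(identified)),
            "n_unidentified": int(len(unidentified)),
            "n_species_A": int((identified["species_call"] == "A").sum()),
            "n_species_B": int((identified["species_call"] == "B").sum()),
            "n_high_specificity": int(
                (
                    identified[["specificity_A", "specificity_B"]].max(axis=1)
                    > t.specificity_report
                ).sum()
            ),
            "mean_genes_identified": _mean(identified, "n_genes"),
            "mean_transcripts_identified": _mean(identified, "n_transcripts"),
            "mean_genes_negative": _mean(negatives, "n_genes"),
            "mean_transcripts_negative": _mean(negatives, "n_transcripts"),
            "mean_genes_unidentified": _mean(unidentified, "n_genes"),
            "mean_transcripts_unidentified": _mean(unidentified, "n_transcripts"),
            "ambient_fraction": self.ambient_fraction,
            "n_doublet_flags": int(s["doublet_flag"].sum()),
        }


def run_barnyard(
    dge: DGEMatrix,
    gene_table: pd.DataFrame,
    plate: PlateDesign,
    thresholds: QCThresholds | None = None,
) -> BarnyardReport:
    """Full barnyard pass: stats, calls, filters, ambient, doublets."""
    t = thresholds or QCThresholds()
    stats = compute_cell_stats(dge, gene_table, plate)
    call = classify_species(stats, t)
    stats["species_call"] = call
    stats["keep_transcripts"] = filter_transcript_window(stats, t)
    stats["keep_gene_mito"] = filter_gene_mito(stats, t)
    stats["doublet_flag"] = flag_doublets(stats, t, call)
    try:
        ambient = estimate_ambient(stats, call)
    except ValueError:
        ambient = None
    return BarnyardReport(stats, ambient, t)
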
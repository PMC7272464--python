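"""Synthetic two-species plate simulator with ground truth.

Emulates a pooled microwell protocol in which each well's capture beads carry
a 6-base cell barcode and a 7-base unique molecular identifier (UMI), mRNA is
captured on poly-T tails, and sequencing produces a 20-base Read 1
(barcode + UMI + poly-T pad) paired with a 50-base Read 2 transcript fragment.

The simulator produces four linked artifacts:

* a :class:`ReferenceSet` of species-labelled transcripts (the stand-in for a
  concatenated two-genome reference),
* a :class:`PlateDesign` assigning barcodes, species, treatment conditions and
  negative-control / doublet status to wells,
* a :class:`GroundTruth` table of individual captured molecules
  (barcode, gene, UMI), including ambient background molecules, and
* paired FASTQ files with configurable PCR duplication and substitution error.

Every stage downstream of read generation can therefore be checked against a
known answer, including exact digital-expression recovery in the noise-free
limit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import (
    ALPHABET,
    FastqWriter,
    apply_substitutions,
    decode_kmer,
    derive_rng,
    random_dna,
)

BARCODE_LEN = 6
UMI_LEN = 7
READ1_LEN = 20
READ2_LEN = 50
POLY_T_PAD = "T" * (READ1_LEN - BARCODE_LEN - UMI_LEN)

SPECIES = ("A", "B")


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


class WhitelistError(RuntimeError):
    """Raised when a barcode whitelist with the requested properties cannot be built."""


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transcript:
    gene_id: str
    species: str
    sequence: str
    is_mito: bool


@dataclass
class ReferenceSet:
    """Species-labelled transcript sequences, the two-genome reference analog."""

    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        ids = [t.gene_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate gene_id in reference")
        for t in self.transcripts:
            if not t.gene_id.startswith(t.species + "_"):
                raise ConfigurationError(
                    f"gene_id {t.gene_id!r} does not carry its species prefix {t.species}_"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [t.gene_id for t in self.transcripts]

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [t.gene_id for t in self.transcripts],
                "species": [t.species for t in self.transcripts],
                "is_mito": [t.is_mito for t in self.transcripts],
            }
        )

    def sequences(self) -> dict[str, str]:
        return {t.gene_id: t.sequence for t in self.transcripts}

    # -- serialization ------------------------------------------------------

    def write(self, fasta_path, gene_table_path) -> None:
        with open(fasta_path, "w") as fh:
            for t in self.transcripts:
                fh.write(f">{t.gene_id}\n{t.sequence}\n")
        self.gene_table().to_csv(gene_table_path, sep="\t", index=False)

    @classmethod
    def read(cls, fasta_path, gene_table_path) -> "ReferenceSet":
        table = pd.read_csv(gene_table_path, sep="\t")
        meta = {
            row.gene_id: (row.species, bool(row.is_mito))
            for row in table.itertuples(index=False)
        }
        transcripts = []
        current_id, chunks = None, []
        with open(fasta_path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if current_id is not None:
                        species, is_mito = meta[current_id]
                        transcripts.append(
                            Transcript(current_id, species, "".join(chunks), is_mito)
                        )
                    current_id, chunks = line[1:].split()[0], []
                else:
                    chunks.append(line)
        if current_id is not None:
            species, is_mito = meta[current_id]
            transcripts.append(Transcript(current_id, species, "".join(chunks), is_mito))
        return cls(transcripts)


def generate_reference(
    n_genes_per_species: int,
    transcript_length: int = 300,
    mito_fraction: float = 0.02,
    seed: int = 0,
) -> ReferenceSet:
    """Generate a random two-species transcript reference.

    Each species contributes ``n_genes_per_species`` genes, of which
    ``floor(n * mito_fraction)`` are flagged mitochondrial (ids ``X_MTnnnn``,
    others ``X_GENEnnnn``). Sequences are i.i.d. uniform DNA; at the default
    length of 300 bases, cross-gene sequence collisions are vanishingly rare,
    so each gene is effectively uniquely mappable.
    """
    if n_genes_per_species < 2:
        raise ConfigurationError("n_genes_per_species must be >= 2")
    if transcript_length < READ2_LEN:
        raise ConfigurationError(f"transcript_length must be >= {READ2_LEN}")
    if not 0 <= mito_fraction < 1:
        raise ConfigurationError("mito_fraction must be in [0, 1)")
    rng = derive_rng(seed, "reference")
    n_mito = int(np.floor(n_genes_per_species * mito_fraction))
    transcripts = []
    for species in SPECIES:
        for i in range(n_genes_per_species):
            if i < n_mito:
                gene_id = f"{species}_MT{i + 1:04d}"
                is_mito = True
            else:
                gene_id = f"{species}_GENE{i - n_mito + 1:04d}"
                is_mito = False
            transcripts.append(
                Transcript(gene_id, species, random_dna(rng, transcript_length), is_mito)
            )
    return ReferenceSet(transcripts)


# ---------------------------------------------------------------------------
# Plate design and barcode whitelist
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Well:
    well_id: str
    barcode: str
    kind: str  # "cell" | "negative" | "doublet"
    species: tuple[str, ...]  # () for negative, 1 for cell, 2 for doublet
    condition: str  # "" when untreated/unassigned


@dataclass
class PlateDesign:
    wells: list[Well]

    def __post_init__(self) -> None:
        barcodes = [w.barcode for w in self.wells]
        if len(set(barcodes)) != len(barcodes):
            raise ConfigurationError("well barcodes must be unique")
        for w in self.wells:
            expected = {"cell": 1, "negative": 0, "doublet": 2}[w.kind]
            if len(w.species) != expected:
                raise ConfigurationError(
                    f"well {w.well_id}: kind {w.kind} requires {expected} species, got {len(w.species)}"
                )

    @property
    def whitelist(self) -> list[str]:
        """Barcodes in plate order (the canonical cell ordering downstream)."""
        return [w.barcode for w in self.wells]

    def wells_of_kind(self, kind: str) -> list[Well]:
        return [w for w in self.wells if w.kind == kind]

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well_id": [w.well_id for w in self.wells],
                "barcode": [w.barcode for w in self.wells],
                "kind": [w.kind for w in self.wells],
                "species": ["+".join(w.species) for w in self.wells],
                "condition": [w.condition for w in self.wells],
            }
        )

    def write(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "PlateDesign":
        wells = []
        for row in table.itertuples(index=False):
            species = tuple(s for s in str(row.species).split("+") if s and s != "nan")
            condition = "" if pd.isna(row.condition) else str(row.condition)
            wells.append(Well(str(row.well_id), row.barcode, row.kind, species, condition))
        return cls(wells)

    @classmethod
    def read(cls, path) -> "PlateDesign":
        return cls.from_table(pd.read_csv(path, sep="\t", keep_default_na=False))


def _all_barcode_words() -> np.ndarray:
    return np.array(
        list(itertools.product(range(4), repeat=BARCODE_LEN)), dtype=np.int8
    )


def make_whitelist(
    n: int,
    min_distance: int = 3,
    seed: int = 0,
    max_restarts: int = 40,
    allow_distance2_fill: bool = False,
) -> list[str]:
    """Build ``n`` unique 6-mer barcodes with pairwise Hamming distance control.

    A whitelist at pairwise distance >= 3 makes single-substitution correction
    provably unambiguous. The 6-mer code space does not admit arbitrarily
    large distance-3 sets (randomized greedy saturates near ~100 codewords),
    so large plates can opt into ``allow_distance2_fill``: a maximal
    distance-3 core is kept and remaining barcodes are added at distance >= 2
    from everything chosen. Distance >= 2 still guarantees that a single
    substitution is never *mis*-corrected to a wrong well (an observed barcode
    one step from two whitelist entries is rejected as ambiguous).
    """
    if n < 1:
        raise ConfigurationError("whitelist size must be >= 1")
    if n > 4**BARCODE_LEN:
        raise ConfigurationError("whitelist size exceeds the 6-mer barcode space")
    if min_distance not in (2, 3):
        raise ConfigurationError("min_distance must be 2 or 3")
    words = _all_barcode_words()
    rng = derive_rng(seed, "whitelist")
    best: list[int] = []
    for _ in range(max_restarts):
        order = rng.permutation(len(words))
        alive3 = np.ones(len(words), dtype=bool)
        alive2 = np.ones(len(words), dtype=bool)
        chosen: list[int] = []
        stages = [3] if min_distance == 3 else [2]
        if min_distance == 3 and allow_distance2_fill:
            stages = [3, 2]
        for stage in stages:
            mask = alive3 if stage == 3 else alive2
            for i in order:
                if len(chosen) >= n:
                    break
                if not mask[i]:
                    continue
                d = (words != words[i]).sum(axis=1)
                alive3 &= d >= 3
                alive2 &= d >= 2
                chosen.append(i)
        if len(chosen) >= n:
            return ["".join(ALPHABET[b] for b in words[i]) for i in chosen[:n]]
        if len(chosen) > len(best):
            best = chosen
    raise WhitelistError(
        f"could not build {n} barcodes at pairwise Hamming distance >= {min_distance} "
        f"(best attempt: {len(best)}); the 6-mer space supports roughly 100 codewords "
        "at distance 3 — reduce the plate size or pass allow_distance2_fill=True"
    )


def design_plate(
    n_cells_per_species: int,
    n_negative: int = 0,
    n_doublets: int = 0,
    conditions: Sequence[str] | Mapping[str, int] | None = None,
    seed: int = 0,
    species: Sequence[str] = SPECIES,
) -> PlateDesign:
    """Lay out a plate: cell wells per species, negative controls, doublets.

    ``conditions`` assigns treatment labels to cell wells, either as a list of
    labels (wells split as evenly as possible, randomized assignment) or a
    mapping label -> number of wells. Doublet wells pair the first two species.

    Barcodes come from :func:`make_whitelist`; plates small enough for a full
    distance-3 whitelist get one, larger plates get a distance-3 core filled
    at distance >= 2 (see make_whitelist).
    """
    if n_cells_per_species < 0 or n_negative < 0 or n_doublets < 0:
        raise ConfigurationError("well counts must be non-negative")
    species = tuple(species)
    n_cells = n_cells_per_species * len(species)
    n_wells = n_cells + n_negative + n_doublets
    if n_wells < 1:
        raise ConfigurationError("plate must contain at least one well")
    if n_doublets and len(species) < 2:
        raise ConfigurationError("doublet wells require at least two species")

    rng = derive_rng(seed, "plate")
    try:
        barcodes = make_whitelist(n_wells, min_distance=3, seed=seed)
    except WhitelistError:
        barcodes = make_whitelist(
            n_wells, min_distance=3, seed=seed, allow_distance2_fill=True
        )

    condition_labels = _assign_conditions(n_cells, conditions, rng)

    wells = []
    idx = 0
    cell_i = 0
    for sp in species:
        for _ in range(n_cells_per_species):
            wells.append(
                Well(f"W{idx + 1:03d}", barcodes[idx], "cell", (sp,), condition_labels[cell_i])
            )
            idx += 1
            cell_i += 1
    for _ in range(n_negative):
        wells.append(Well(f"W{idx + 1:03d}", barcodes[idx], "negative", (), ""))
        idx += 1
    for _ in range(n_doublets):
        wells.append(
            Well(f"W{idx + 1:03d}", barcodes[idx], "doublet", species[:2], "")
        )
        idx += 1
    return PlateDesign(wells)


def _assign_conditions(
    n_cells: int,
    conditions: Sequence[str] | Mapping[str, int] | None,
    rng: np.random.Generator,
) -> list[str]:
    if not conditions:
        return [""] * n_cells
    if isinstance(conditions, Mapping):
        total = sum(conditions.values())
        if total != n_cells:
            raise ConfigurationError(
                f"condition well counts sum to {total}, but the plate has {n_cells} cell wells"
            )
        labels = [lab for lab, k in conditions.items() for _ in range(k)]
    else:
        labels = [conditions[i % len(conditions)] for i in range(n_cells)]
    labels = list(np.array(labels, dtype=object)[rng.permutation(n_cells)])
    return labels


# ---------------------------------------------------------------------------
# Ground-truth expression
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Individual simulated molecules plus the planted condition-effect table.

    ``molecules`` columns: barcode, gene_id, umi, source ("cell" or "ambient").
    ``effects`` columns: gene_id, condition, log2fc.
    """

    molecules: pd.DataFrame
    effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "condition", "log2fc"])
    )

    def counts(self) -> pd.DataFrame:
        """Molecule counts per (barcode, gene_id) — the expected noise-free DGE."""
        return (
            self.molecules.groupby(["barcode", "gene_id"], sort=True)
            .size()
            .rename("count")
            .reset_index()
        )

    def write(self, molecules_path, effects_path=None) -> None:
        self.molecules.to_csv(molecules_path, sep="\t", index=False)
        if effects_path is not None:
            self.effects.to_csv(effects_path, sep="\t", index=False)

    @classmethod
    def read(cls, molecules_path, effects_path=None) -> "GroundTruth":
        molecules = pd.read_csv(molecules_path, sep="\t")
        effects = (
            pd.read_csv(effects_path, sep="\t")
            if effects_path is not None and Path(effects_path).exists()
            else pd.DataFrame(columns=["gene_id", "condition", "log2fc"])
        )
        return cls(molecules, effects)


def _species_profiles(
    ref: ReferenceSet, rng: np.random.Generator, profile_sigma: float
) -> dict[str, np.ndarray]:
    """Per-species relative gene abundances (lognormal weights, normalized)."""
    profiles = {}
    gene_species = np.array([t.species for t in ref.transcripts])
    n = len(ref.transcripts)
    for sp in sorted(set(gene_species)):
        w = np.where(gene_species == sp, np.exp(rng.normal(0.0, profile_sigma, n)), 0.0)
        profiles[sp] = w / w.sum()
    return profiles


_UMI_SPACE = 4**UMI_LEN


def _umi_neighbors(code: int) -> list[int]:
    """The 21 codes at Hamming distance exactly 1 from a 7-mer code."""
    out = []
    for pos in range(UMI_LEN):
        shift = 2 * pos
        current = (code >> shift) & 3
        for b in range(4):
            if b != current:
                out.append(code ^ ((current ^ b) << shift))
    return out


def _draw_umis(
    k: int, rng: np.random.Generator, min_distance: int
) -> list[int]:
    """Draw k distinct UMI codes, optionally pairwise Hamming distance >= 2.

    With ``min_distance=2`` every molecule of a (well, gene) pair stays its own
    Hamming-1 equivalence class, so noise-free UMI collapse recovers molecule
    counts exactly; duplicate-avoidance alone (``min_distance=1``) permits
    near-collisions that collapse would merge.
    """
    if k > _UMI_SPACE // 8:
        raise ConfigurationError(
            f"{k} molecules for one (well, gene) pair exceeds the separable 7-mer UMI capacity"
        )
    taken: set[int] = set()
    chosen: list[int] = []
    attempts = 0
    max_attempts = 200 * k + 10_000
    while len(chosen) < k:
        attempts += 2 * (k - len(chosen)) + 8
        if attempts > max_attempts:
            raise ConfigurationError(
                f"UMI rejection sampling stalled at {len(chosen)}/{k} for one (well, gene) pair"
            )
        for code in rng.integers(0, _UMI_SPACE, size=2 * (k - len(chosen)) + 8):
            code = int(code)
            if code in taken:
                continue
            chosen.append(code)
            taken.add(code)
            if min_distance >= 2:
                taken.update(_umi_neighbors(code))
            if len(chosen) == k:
                break
    return chosen


def simulate_expression(
    plate: PlateDesign,
    ref: ReferenceSet,
    mean_molecules_per_cell: int = 5000,
    ambient_fraction: float = 0.05,
    de_spec: pd.DataFrame | Sequence[tuple] | None = None,
    dispersion: float = 0.1,
    seed: int = 0,
    profile_sigma: float = 1.0,
    doublet_ratio: float = 1.0,
    umi_min_distance: int = 2,
) -> GroundTruth:
    """Simulate the molecules captured in every well of a plate.

    Per cell well, the total molecule count is negative-binomial
    (Gamma–Poisson) with the stated mean and dispersion (variance
    ``m + dispersion * m**2``), allocated to genes multinomially according to
    the well's species profile; condition effects multiply a gene's rate by
    ``2**log2fc`` before allocation. Doublet wells superimpose two cells, one
    per species, the second scaled by ``doublet_ratio``. Every well
    additionally receives ambient molecules — Poisson with mean
    ``ambient_fraction * mean_molecules_per_cell`` — drawn from the pooled
    two-species profile regardless of the well's own species, so negative
    wells contain ambient material only.

    UMIs are uniform random 7-mers, drawn per (well, gene); by default they
    are kept at pairwise Hamming distance >= 2 within a (well, gene) pair
    (see ``umi_min_distance``), so noise-free processing recovers the truth
    exactly. Cross-well and cross-gene collisions are unconstrained.
    """
    if not 0 <= ambient_fraction < 1:
        raise ConfigurationError("ambient_fraction must be in [0, 1)")
    if mean_molecules_per_cell <= 0:
        raise ConfigurationError("mean_molecules_per_cell must be positive")
    if dispersion < 0:
        raise ConfigurationError("dispersion must be non-negative")
    if umi_min_distance not in (1, 2):
        raise ConfigurationError("umi_min_distance must be 1 or 2")

    rng = derive_rng(seed, "expression")
    gene_ids = np.array(ref.gene_ids)
    profiles = _species_profiles(ref, rng, profile_sigma)
    pooled = np.mean(list(profiles.values()), axis=0)
    pooled = pooled / pooled.sum()

    effects = _normalize_de_spec(de_spec, ref, plate)
    # per (condition) multiplicative factors per gene, applied on top of the
    # species profile and renormalized at allocation time
    factor_by_condition: dict[str, np.ndarray] = {}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for condition, group in effects.groupby("condition"):
        f = np.ones(len(gene_ids))
        for row in group.itertuples(index=False):
            f[gene_index[row.gene_id]] = 2.0 ** row.log2fc
        factor_by_condition[condition] = f

    mean = float(mean_molecules_per_cell)
    rows_bc: list[str] = []
    rows_gene: list[str] = []
    rows_umi: list[str] = []
    rows_source: list[str] = []

    def draw_total() -> int:
        if dispersion == 0:
            return int(rng.poisson(mean))
        lam = rng.gamma(1.0 / dispersion, mean * dispersion)
        return int(rng.poisson(lam))

    def allocate(total: int, weights: np.ndarray) -> np.ndarray:
        if total == 0:
            return np.zeros(len(weights), dtype=np.int64)
        return rng.multinomial(total, weights / weights.sum())

    for well in plate.wells:
        gene_counts = np.zeros(len(gene_ids), dtype=np.int64)
        if well.kind in ("cell", "doublet"):
            scales = (1.0,) if well.kind == "cell" else (1.0, doublet_ratio)
            for sp, scale in zip(well.species, scales):
                total = draw_total()
                total = int(np.round(total * scale))
                w = profiles[sp]
                if well.condition and well.condition in factor_by_condition:
                    w = w * factor_by_condition[well.condition]
                gene_counts += allocate(total, w)
        if ambient_fraction > 0:
            n_ambient = int(rng.poisson(ambient_fraction * mean))
            ambient_counts = allocate(n_ambient, pooled)
        else:
            ambient_counts = np.zeros(len(gene_ids), dtype=np.int64)

        # draw UMIs jointly per (well, gene) so the within-pair distance
        # constraint covers cell + ambient molecules together
        combined = gene_counts + ambient_counts
        for gi in np.flatnonzero(combined):
            codes = _draw_umis(int(combined[gi]), rng, umi_min_distance)
            n_cell = int(gene_counts[gi])
            gene = gene_ids[gi]
            for j, code in enumerate(codes):
                rows_bc.append(well.barcode)
                rows_gene.append(gene)
                rows_umi.append(decode_kmer(code, UMI_LEN))
                rows_source.append("cell" if j < n_cell else "ambient")

    molecules = pd.DataFrame(
        {
            "barcode": rows_bc,
            "gene_id": rows_gene,
            "umi": rows_umi,
            "source": rows_source,
        }
    )
    return GroundTruth(molecules, effects)


def _normalize_de_spec(
    de_spec, ref: ReferenceSet, plate: PlateDesign
) -> pd.DataFrame:
    if de_spec is None:
        return pd.DataFrame(columns=["gene_id", "condition", "log2fc"])
    if not isinstance(de_spec, pd.DataFrame):
        de_spec = pd.DataFrame(de_spec, columns=["gene_id", "condition", "log2fc"])
    known_genes = set(ref.gene_ids)
    known_conditions = {w.condition for w in plate.wells if w.condition}
    bad_genes = set(de_spec["gene_id"]) - known_genes
    if bad_genes:
        raise ConfigurationError(f"effect table references unknown genes: {sorted(bad_genes)}")
    bad_cond = set(de_spec["condition"]) - known_conditions
    if bad_cond:
        raise ConfigurationError(
            f"effect table references unknown conditions: {sorted(bad_cond)}"
        )
    return de_spec.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------


def simulate_reads(
    truth: GroundTruth,
    ref: ReferenceSet,
    out_r1,
    out_r2,
    duplication_mean: float = 3.0,
    error_rate: float = 0.0,
    seed: int = 0,
    jitter_max: int = 150,
) -> dict[str, int]:
    """Emit paired FASTQ reads for every ground-truth molecule.

    Read 1 is ``barcode(6) + UMI(7) + "TTTTTTT"`` (the oligo continues into a
    poly-T tail; the pad carries no information). Read 2 is a 50-base window of
    the molecule's transcript taken near the 3' end — the window start is
    jittered uniformly over the last ``jitter_max`` bases, reflecting a
    3'-biased capture protocol. Each molecule is sequenced ``k >= 1`` times
    with ``k - 1 ~ Poisson(duplication_mean - 1)`` (PCR/optical duplicates),
    and every base of both mates is substituted independently at
    ``error_rate``. Returns a summary with molecule and read-pair counts.
    """
    if duplication_mean < 1:
        raise ConfigurationError("duplication_mean must be >= 1")
    if not 0 <= error_rate < 1:
        raise ConfigurationError("error_rate must be in [0, 1)")
    rng = derive_rng(seed, "reads")
    seqs = ref.sequences()
    for gene_id, seq in seqs.items():
        if len(seq) < READ2_LEN:
            raise ConfigurationError(
                f"transcript {gene_id} shorter than Read-2 length {READ2_LEN}"
            )

    mol = truth.molecules
    n_mol = len(mol)
    dup = rng.poisson(duplication_mean - 1.0, size=n_mol) + 1
    serial = 0
    with FastqWriter(out_r1) as w1, FastqWriter(out_r2) as w2:
        for (bc, gene, umi), k in zip(
            zip(mol["barcode"], mol["gene_id"], mol["umi"]), dup
        ):
            tseq = seqs[gene]
            span = min(jitter_max, len(tseq) - READ2_LEN)
            r1_clean = bc + umi + POLY_T_PAD
            for _ in range(int(k)):
                j = int(rng.integers(0, span + 1)) if span > 0 else 0
                start = len(tseq) - READ2_LEN - j
                r2 = tseq[start : start + READ2_LEN]
                r1 = r1_clean
                if error_rate > 0:
                    r1 = apply_substitutions(r1, rng, error_rate)
                    r2 = apply_substitutions(r2, rng, error_rate)
                name = f"r{serial}"
                w1.write(name, r1)
                w2.write(name, r2)
                serial += 1
    return {"n_molecules": int(n_mol), "n_read_pairs": int(serial)}
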
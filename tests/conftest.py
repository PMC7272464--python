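from pathlib import Path

import numpy as np
import pytest

import platepool as pp
from platepool import pipeline
from platepool.config import RunConfig


@pytest.fixture(scope="session")
def small_ref() -> pp.ReferenceSet:
    return pp.generate_reference(20, transcript_length=120, mito_fraction=0.1, seed=42)


@pytest.fixture(scope="session")
def small_plate() -> pp.PlateDesign:
    return pp.design_plate(4, n_negative=2, n_doublets=0, seed=42)


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory):
    """A small noise-free simulated run processed through counting and QC.

    ambient 0, error 0, duplication 2x: downstream results must equal the
    ground truth exactly.
    """
    out = tmp_path_factory.mktemp("clean_run")
    cfg = RunConfig(seed=2024)
    cfg.simulation.n_genes_per_species = 40
    cfg.simulation.n_cells_per_species = 8
    cfg.simulation.n_negative = 4
    cfg.simulation.mean_molecules_per_cell = 400
    cfg.simulation.ambient_fraction = 0.0
    cfg.simulation.error_rate = 0.0
    cfg.simulation.duplication_mean = 2.0
    pipeline.stage_simulate(cfg, out)
    pipeline.stage_count(
        cfg,
        out / "reads_R1.fastq.gz",
        out / "reads_R2.fastq.gz",
        out / "reference.fasta",
        out / "genes.tsv",
        out / "plate.tsv",
        out,
    )
    return cfg, out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def load_clean_artifacts(out: Path):
    ref = pp.ReferenceSet.read(out / "reference.fasta", out / "genes.tsv")
    plate = pp.PlateDesign.read(out / "plate.tsv")
    truth = pp.GroundTruth.read(out / "truth_molecules.tsv")
    dge = pp.DGEMatrix.read_mtx(out / "dge")
    return ref, plate, truth, dge
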
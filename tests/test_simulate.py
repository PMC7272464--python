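"""Simulator: reference generation, plate/whitelist design, expression, reads."""

import gzip
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import platepool as pp
from platepool._utils import hamming
from platepool.simulate import POLY_T_PAD, ConfigurationError, WhitelistError


class TestReference:
    def test_forced_counts_no_mito(self):
        ref = pp.generate_reference(2, transcript_length=100, mito_fraction=0.0, seed=1)
        assert len(ref.transcripts) == 4
        table = ref.gene_table()
        assert table.groupby("species").size().to_dict() == {"A": 2, "B": 2}
        assert not table.is_mito.any()

    def test_determinism(self):
        a = pp.generate_reference(5, 80, 0.2, seed=1)
        b = pp.generate_reference(5, 80, 0.2, seed=1)
        assert a.transcripts == b.transcripts
        c = pp.generate_reference(5, 80, 0.2, seed=2)
        assert a.transcripts != c.transcripts

    def test_mito_count_floor_rule(self):
        # floor(n * fraction) mitochondrial genes per species
        ref = pp.generate_reference(10, 100, mito_fraction=0.2, seed=7)
        per_species = ref.gene_table().groupby("species").is_mito.sum().to_dict()
        assert per_species == {"A": 2, "B": 2}
        for n, frac in [(7, 0.1), (9, 0.5), (20, 0.33)]:
            ref = pp.generate_reference(n, 60, frac, seed=3)
            expected = int(np.floor(n * frac))
            assert ref.gene_table().groupby("species").is_mito.sum().eq(expected).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_genes_per_species=1),
            dict(n_genes_per_species=5, transcript_length=30),
            dict(n_genes_per_species=5, mito_fraction=1.0),
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ConfigurationError):
            pp.generate_reference(**{"transcript_length": 100, "seed": 0, **kwargs})

    def test_sequence_lengths_and_prefixes(self, small_ref):
        for t in small_ref.transcripts:
            assert len(t.sequence) >= pp.READ2_LEN
            assert t.gene_id.startswith(t.species + "_")

    def test_fasta_roundtrip(self, small_ref, tmp_path):
        small_ref.write(tmp_path / "ref.fasta", tmp_path / "genes.tsv")
        back = pp.ReferenceSet.read(tmp_path / "ref.fasta", tmp_path / "genes.tsv")
        assert back.transcripts == small_ref.transcripts


class TestWhitelist:
    def test_distance3_exhaustive_scan(self):
        wl = pp.make_whitelist(48, min_distance=3, seed=5)
        assert len(set(wl)) == 48
        assert min(hamming(a, b) for a, b in combinations(wl, 2)) >= 3

    def test_two_well_design_distance(self):
        plate = pp.design_plate(1, n_negative=1, seed=0, species=("A",))
        assert len(plate.wells) == 2
        assert hamming(plate.wells[0].barcode, plate.wells[1].barcode) >= 3

    def test_oversized_distance3_request_fails_with_named_constraint(self):
        with pytest.raises(WhitelistError, match="distance"):
            pp.make_whitelist(300, min_distance=3, seed=0, max_restarts=3)

    def test_large_plate_falls_back_to_distance2(self):
        wl = pp.make_whitelist(224, min_distance=3, seed=0, allow_distance2_fill=True)
        assert len(set(wl)) == 224
        assert min(hamming(a, b) for a, b in combinations(wl, 2)) >= 2


class TestPlateDesign:
    def test_barnyard_plate_well_counts(self):
        plate = pp.design_plate(96, n_negative=32, n_doublets=0, seed=1)
        assert len(plate.wells) == 224
        kinds = pd.Series([w.kind for w in plate.wells]).value_counts().to_dict()
        assert kinds == {"cell": 192, "negative": 32}
        assert min(hamming(a, b) for a, b in combinations(plate.whitelist, 2)) >= 2

    def test_small_plate_keeps_distance3(self, small_plate):
        assert min(hamming(a, b) for a, b in combinations(small_plate.whitelist, 2)) >= 3

    def test_well_kind_species_invariants(self):
        plate = pp.design_plate(2, n_negative=2, n_doublets=2, seed=9)
        for w in plate.wells:
            if w.kind == "negative":
                assert w.species == ()
            elif w.kind == "doublet":
                assert len(w.species) == 2 and len(set(w.species)) == 2
            else:
                assert len(w.species) == 1

    def test_condition_assignment_counts(self):
        plate = pp.design_plate(
            8, conditions={"drug": 3, "ctrl": 5}, seed=4, species=("A",)
        )
        labels = pd.Series([w.condition for w in plate.wells if w.kind == "cell"])
        assert labels.value_counts().to_dict() == {"ctrl": 5, "drug": 3}

    def test_condition_count_mismatch_raises(self):
        with pytest.raises(ConfigurationError):
            pp.design_plate(4, conditions={"drug": 5}, seed=4, species=("A",))

    def test_table_roundtrip(self, small_plate, tmp_path):
        small_plate.write(tmp_path / "plate.tsv")
        back = pp.PlateDesign.read(tmp_path / "plate.tsv")
        assert back.wells == small_plate.wells


class TestExpression:
    def test_zero_ambient_leaves_negatives_empty(self, small_ref, small_plate):
        truth = pp.simulate_expression(
            small_plate, small_ref, 100, ambient_fraction=0.0, seed=3
        )
        neg_barcodes = {w.barcode for w in small_plate.wells_of_kind("negative")}
        assert not truth.molecules["barcode"].isin(neg_barcodes).any()
        assert (truth.molecules["source"] == "cell").all()

    def test_umi_triples_unique(self, small_ref, small_plate):
        truth = pp.simulate_expression(small_plate, small_ref, 200, 0.05, seed=3)
        assert not truth.molecules.duplicated(["barcode", "gene_id", "umi"]).any()

    def test_empty_effect_table_single_law(self, small_ref):
        plate = pp.design_plate(6, conditions=["x", "y"], seed=1, species=("A",))
        truth = pp.simulate_expression(plate, small_ref, 100, 0.0, de_spec=None, seed=2)
        assert truth.effects.empty

    def test_unknown_gene_or_condition_rejected(self, small_ref):
        plate = pp.design_plate(4, conditions=["drug"], seed=1, species=("A",))
        with pytest.raises(ConfigurationError, match="unknown genes"):
            pp.simulate_expression(
                plate, small_ref, 50, 0.0, de_spec=[("NOPE", "drug", 1.0)], seed=0
            )
        gene = small_ref.gene_ids[0]
        with pytest.raises(ConfigurationError, match="unknown conditions"):
            pp.simulate_expression(
                plate, small_ref, 50, 0.0, de_spec=[(gene, "mystery", 1.0)], seed=0
            )

    def test_ambient_level_recovered_monte_carlo(self, small_ref):
        # negative-well mean over cell-well mean should sit near the simulated
        # ambient fraction (the ratio's expectation is a/(1+a), 4.8% below a)
        plate = pp.design_plate(48, n_negative=16, seed=6)
        truth = pp.simulate_expression(plate, small_ref, 2000, 0.05, seed=6)
        per_well = truth.molecules.groupby("barcode").size()
        neg = {w.barcode for w in plate.wells_of_kind("negative")}
        neg_mean = per_well.reindex(neg).fillna(0).mean()
        cell_mean = per_well.reindex(
            [w.barcode for w in plate.wells_of_kind("cell")]
        ).fillna(0).mean()
        assert abs(neg_mean / cell_mean - 0.05) / 0.05 < 0.2

    def test_doublet_well_mixes_both_species(self, small_ref):
        plate = pp.design_plate(2, n_doublets=1, seed=8)
        truth = pp.simulate_expression(plate, small_ref, 300, 0.0, seed=8)
        dbl = plate.wells_of_kind("doublet")[0]
        species = truth.molecules.loc[
            truth.molecules["barcode"] == dbl.barcode, "gene_id"
        ].str[0]
        assert set(species) == {"A", "B"}

    def test_planted_effect_shifts_counts(self, small_ref):
        plate = pp.design_plate(40, conditions={"drug": 20, "ctrl": 20}, seed=5, species=("A",))
        gene = sorted(g for g in small_ref.gene_ids if g.startswith("A_"))[5]
        truth = pp.simulate_expression(
            plate, small_ref, 1000, 0.0, de_spec=[(gene, "drug", 2.0)], seed=5
        )
        cond = {w.barcode: w.condition for w in plate.wells}
        mol = truth.molecules
        mol = mol[mol["gene_id"] == gene]
        per_cond = mol.groupby(mol["barcode"].map(cond)).size()
        assert per_cond["drug"] > 2 * per_cond["ctrl"]


class TestReads:
    def test_read_layout_and_counts_no_duplication(self, small_ref, small_plate, tmp_path):
        truth = pp.simulate_expression(small_plate, small_ref, 50, 0.0, seed=4)
        summary = pp.simulate_reads(
            truth, small_ref, tmp_path / "r1.fastq.gz", tmp_path / "r2.fastq.gz",
            duplication_mean=1.0, error_rate=0.0, seed=4,
        )
        assert summary["n_read_pairs"] == summary["n_molecules"] == len(truth.molecules)
        r1 = gzip.open(tmp_path / "r1.fastq.gz", "rt").read().splitlines()
        r2 = gzip.open(tmp_path / "r2.fastq.gz", "rt").read().splitlines()
        seqs1 = r1[1::4]
        seqs2 = r2[1::4]
        mol = truth.molecules
        transcripts = small_ref.sequences()
        for i, (seq1, seq2) in enumerate(zip(seqs1, seqs2)):
            row = mol.iloc[i]
            assert seq1 == row.barcode + row.umi + POLY_T_PAD
            assert len(seq1) == pp.READ1_LEN and len(seq2) == pp.READ2_LEN
            assert seq2 in transcripts[row.gene_id]  # exact substring, zero noise

    def test_duplication_inflates_reads(self, small_ref, small_plate, tmp_path):
        truth = pp.simulate_expression(small_plate, small_ref, 80, 0.0, seed=4)
        s = pp.simulate_reads(
            truth, small_ref, tmp_path / "a1.fastq.gz", tmp_path / "a2.fastq.gz",
            duplication_mean=3.0, error_rate=0.0, seed=4,
        )
        assert s["n_read_pairs"] > s["n_molecules"]

    def test_byte_identical_reruns(self, small_ref, small_plate, tmp_path):
        truth = pp.simulate_expression(small_plate, small_ref, 60, 0.0, seed=4)
        for d in ("x", "y"):
            (tmp_path / d).mkdir()
            pp.simulate_reads(
                truth, small_ref,
                tmp_path / d / "r1.fastq.gz", tmp_path / d / "r2.fastq.gz",
                duplication_mean=2.0, error_rate=0.01, seed=4,
            )
        assert (tmp_path / "x/r1.fastq.gz").read_bytes() == (tmp_path / "y/r1.fastq.gz").read_bytes()
        assert (tmp_path / "x/r2.fastq.gz").read_bytes() == (tmp_path / "y/r2.fastq.gz").read_bytes()

    def test_invalid_parameters(self, small_ref, small_plate, tmp_path):
        truth = pp.simulate_expression(small_plate, small_ref, 10, 0.0, seed=1)
        with pytest.raises(ConfigurationError):
            pp.simulate_reads(truth, small_ref, tmp_path / "a", tmp_path / "b",
                              duplication_mean=0.5)
        with pytest.raises(ConfigurationError):
            pp.simulate_reads(truth, small_ref, tmp_path / "a", tmp_path / "b",
                              error_rate=1.0)
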
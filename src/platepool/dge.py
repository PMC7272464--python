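"""Digital gene expression: UMI collapse and matrix construction/serialization.

Reads that survived tagging and gene assignment are reduced to molecules by
collapsing UMIs within each (cell, gene): distinct UMI sequences joined by
Hamming distance <= 1 form one equivalence class, and the matrix entry is
the number of classes. Collapse uses connected components of the distance-1
graph — identical duplicates fall into one vertex, and chains of distance-1
neighbors merge transitively.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._utils import ALPHABET


def _variants(umi: str) -> list[str]:
    out = []
    for i, original in enumerate(umi):
        for b in ALPHABET:
            if b != original:
                out.append(umi[:i] + b + umi[i + 1 :])
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def collapse_umis(umis: Iterable[str]) -> int:
    """Number of Hamming-1 equivalence classes in a UMI multiset.

    Two distinct UMIs are linked when their Hamming distance is exactly 1;
    the count is the number of connected components. Linking is found by
    enumerating each UMI's single-substitution variants against a hash of the
    distinct sequences (O(m * L * |alphabet|) instead of O(m^2 * L)).
    """
    distinct: dict[str, int] = {}
    for u in umis:
        if u not in distinct:
            distinct[u] = len(distinct)
    if not distinct:
        return 0
    lengths = {len(u) for u in distinct}
    if len(lengths) != 1:
        raise ValueError(f"mixed UMI lengths in one collapse group: {sorted(lengths)}")
    uf = _UnionFind(len(distinct))
    for umi, idx in distinct.items():
        for variant in _variants(umi):
            other = distinct.get(variant)
            if other is not None:
                uf.union(idx, other)
    return len({uf.find(i) for i in range(len(distinct))})


@dataclass
class DGEMatrix:
    """Genes x cells matrix of UMI-collapsed molecule counts."""

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise ValueError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_barcodes)} cells"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.gene_ids, columns=self.cell_barcodes
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, DGEMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_barcodes == other.cell_barcodes
            and (self.counts != other.counts).nnz == 0
        )

    # -- serialization ------------------------------------------------------

    def write_mtx(self, out_dir) -> None:
        """Matrix Market triplet + genes.tsv + barcodes.tsv (sparse convention)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(out_dir / "matrix.mtx"), self.counts.tocoo())
        (out_dir / "genes.tsv").write_text("".join(g + "\n" for g in self.gene_ids))
        (out_dir / "barcodes.tsv").write_text(
            "".join(b + "\n" for b in self.cell_barcodes)
        )

    @classmethod
    def read_mtx(cls, in_dir) -> "DGEMatrix":
        in_dir = Path(in_dir)
        counts = sp.csr_matrix(scipy.io.mmread(str(in_dir / "matrix.mtx")))
        gene_ids = (in_dir / "genes.tsv").read_text().splitlines()
        barcodes = (in_dir / "barcodes.tsv").read_text().splitlines()
        if counts.shape != (len(gene_ids), len(barcodes)):
            raise ValueError(
                f"{in_dir}: matrix is {counts.shape} but identifier files list "
                f"{len(gene_ids)} genes and {len(barcodes)} barcodes"
            )
        return cls(counts, gene_ids, barcodes)

    def write_dense(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_dense(cls, path) -> "DGEMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(
            sp.csr_matrix(frame.to_numpy(dtype=np.int64)),
            [str(g) for g in frame.index],
            [str(c) for c in frame.columns],
        )


def build_dge(
    records: Iterable[tuple[str, str, str]],
    whitelist: Iterable[str],
    gene_ids: Iterable[str] | None = None,
) -> DGEMatrix:
    """Build the DGE from (barcode, umi, gene_id) records.

    Cells are ordered by the whitelist (zero columns kept for quiet wells);
    genes are ordered lexicographically unless an explicit gene universe is
    given. A record with a barcode missing from the whitelist is an upstream
    contract violation and raises.
    """
    barcodes = list(dict.fromkeys(whitelist))
    cell_index = {bc: i for i, bc in enumerate(barcodes)}
    groups: dict[tuple[str, str], list[str]] = {}
    seen_genes: set[str] = set()
    for barcode, umi, gene_id in records:
        if barcode not in cell_index:
            raise ValueError(f"record barcode {barcode!r} is not on the whitelist")
        groups.setdefault((barcode, gene_id), []).append(umi)
        seen_genes.add(gene_id)
    if gene_ids is None:
        genes = sorted(seen_genes)
    else:
        genes = list(gene_ids)
        missing = seen_genes - set(genes)
        if missing:
            raise ValueError(f"records reference genes outside the gene universe: {sorted(missing)}")
    gene_index = {g: i for i, g in enumerate(genes)}
    rows, cols, vals = [], [], []
    for (barcode, gene_id), umis in groups.items():
        n = collapse_umis(umis)
        if n:
            rows.append(gene_index[gene_id])
            cols.append(cell_index[barcode])
            vals.append(n)
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(genes), len(barcodes)), dtype=np.int64
    )
    return DGEMatrix(counts, genes, barcodes)


def truth_to_dge(truth, whitelist: Iterable[str], gene_ids: Iterable[str]) -> DGEMatrix:
    """Expected noise-free DGE from ground-truth molecules (simple tally).

    Counts rows per (barcode, gene) without any UMI collapse — under the
    simulator's default UMI separation this is exactly what a perfect
    pipeline should reconstruct.
    """
    counts = truth.counts()
    barcodes = list(dict.fromkeys(whitelist))
    genes = list(gene_ids)
    cell_index = {bc: i for i, bc in enumerate(barcodes)}
    gene_index = {g: i for i, g in enumerate(genes)}
    rows = [gene_index[g] for g in counts["gene_id"]]
    cols = [cell_index[b] for b in counts["barcode"]]
    mat = sp.csr_matrix(
        (counts["count"].to_numpy(), (rows, cols)),
        shape=(len(genes), len(barcodes)),
        dtype=np.int64,
    )
    return DGEMatrix(mat, genes, barcodes)
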
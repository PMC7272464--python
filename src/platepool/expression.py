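"""Drug-response expression analysis: normalization, PCA, clustering,
Wilcoxon differential expression, cell-cycle scoring, batch removal,
pseudobulk profiles.

All analysis operates on log2(CPM + 1) values: each cell's counts are scaled
to one million (counts per million) before the log transform, so library-size
differences between cells do not masquerade as expression differences.
Differential expression uses the two-sided Wilcoxon rank-sum test per gene
with Benjamini–Hochberg control of the false discovery rate, and a gene is
called up- or down-regulated when |log2 fold change| > 0.25 and FDR < 0.05
(fold change taken as the difference of group means on the log2(CPM+1)
scale).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from ._utils import derive_rng
from .dge import DGEMatrix


@dataclass
class AnalysisParams:
    """Knobs of the analysis stack with their standard defaults."""

    n_pcs: int = 4  # principal components 1..4
    cluster_resolution: float = 1.5
    n_neighbors: int = 20
    n_variable_genes: int = 2000
    de_alpha: float = 0.05  # FDR cutoff for DE calls
    lfc_cut: float = 0.25  # |log2FC| cutoff for DE calls
    heatmap_alpha: float = 0.05  # FDR cutoff for the heatmap gene union
    exact_max_n: int = 8  # exact rank-sum enumeration up to this group size

    def __post_init__(self) -> None:
        if self.n_pcs < 1 or self.n_variable_genes < 1 or self.n_neighbors < 1:
            raise ValueError("counts/components must be positive")
        for a in (self.de_alpha, self.heatmap_alpha):
            if not 0 < a < 1:
                raise ValueError("alpha values must be in (0, 1)")


@dataclass
class NormalizedMatrix:
    """log2(CPM+1) values with provenance to the source DGE ordering."""

    values: np.ndarray  # genes x cells, float64
    gene_ids: list[str]
    cell_barcodes: list[str]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_barcodes)


def cpm_log_normalize(dge: DGEMatrix) -> NormalizedMatrix:
    """value(g, c) = log2(1e6 * count(g, c) / total(c) + 1).

    Every included cell must have a nonzero total; zero-total cells must be
    filtered out upstream (their CPM is undefined).
    """
    counts = dge.counts.toarray().astype(np.float64)
    totals = counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"zero-total cell(s) present, e.g. {dge.cell_barcodes[zero[0]]!r}; "
            "filter empty cells before normalizing"
        )
    values = np.log2(1e6 * counts / totals + 1.0)
    return NormalizedMatrix(values, list(dge.gene_ids), list(dge.cell_barcodes))


def select_variable_genes(
    norm: NormalizedMatrix, n: int = 2000, n_bins: int = 20
) -> list[str]:
    """Top-n genes by binned dispersion of CPM.

    Dispersion = variance / mean of CPM per gene, z-scored within bins of
    similar mean expression so that highly expressed genes do not dominate
    purely through their scale. Ranking is deterministic; ties break by
    gene id.
    """
    if n > len(norm.gene_ids):
        raise ValueError("cannot select more variable genes than genes present")
    cpm = 2.0**norm.values - 1.0
    mean = cpm.mean(axis=1)
    var = cpm.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    # with small panels, fewer bins keep enough genes per bin to z-score
    n_bins = max(1, min(n_bins, len(mean) // 10))
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.arange(len(mean)) * n_bins // max(len(mean), 1)
    z = np.zeros(len(mean))
    for b in np.unique(bins):
        m = bins == b
        d = disp[m]
        sd = d.std()
        z[m] = (d - d.mean()) / sd if sd > 0 else 0.0
    ranking = sorted(zip(-z, norm.gene_ids, range(len(z))))
    return [g for _, g, _ in ranking[:n]]


def run_pca(
    norm: NormalizedMatrix,
    params: AnalysisParams | None = None,
    genes: list[str] | None = None,
) -> np.ndarray:
    """Cells x n_pcs embedding of per-gene-centered log values.

    Components are ordered by decreasing explained variance, and each
    component's sign is fixed so that its largest-magnitude gene loading is
    positive — full determinism instead of the usual sign ambiguity.
    """
    p = params or AnalysisParams()
    values = norm.values
    if genes is not None:
        idx = [norm.gene_ids.index(g) for g in genes]
        values = values[idx]
    x = values.T  # cells x genes
    if x.shape[0] < p.n_pcs + 1:
        raise ValueError(
            f"PCA with {p.n_pcs} components needs more than {p.n_pcs} cells, got {x.shape[0]}"
        )
    pca = PCA(n_components=p.n_pcs, svd_solver="full")
    embedding = pca.fit_transform(x)  # centers features (genes) internally
    for j in range(embedding.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            embedding[:, j] *= -1.0
    return embedding


def cluster_cells(
    embedding: np.ndarray,
    resolution: float = 1.5,
    n_neighbors: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Shared-nearest-neighbor graph + modularity clustering.

    Builds a k-nearest-neighbor graph in the embedding, weights edges by the
    Jaccard overlap of neighborhoods (the SNN construction), and optimizes
    modularity with a resolution parameter (Leiden, RB-configuration null
    model) under a fixed seed. Labels are 0-based, relabeled by decreasing
    cluster size.
    """
    import igraph
    import leidenalg

    n = embedding.shape[0]
    if n < 1:
        raise ValueError("clustering requires at least one cell")
    if n == 1:
        return np.zeros(1, dtype=int)
    k = min(n_neighbors, n - 1)
    if np.allclose(embedding, embedding[0]):
        warnings.warn("all embedding points identical: returning a single cluster")
        return np.zeros(n, dtype=int)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neighbor_sets = [set(row) for row in idx]  # includes self
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            shared = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = shared / union
            if w > 0:
                edges.append((i, j))
                weights.append(w)
    graph = igraph.Graph(n=n, edges=edges)
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    labels = np.array(partition.membership)
    order = np.argsort([-np.sum(labels == c) for c in range(labels.max() + 1)], kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(c)] for c in labels], dtype=int)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum differential expression
# ---------------------------------------------------------------------------


def rank_sum_p(a: np.ndarray, b: np.ndarray, exact_max_n: int = 8) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one gene.

    Groups up to ``exact_max_n`` each are tested by exhaustive enumeration of
    the permutation null of the rank-sum statistic (ties handled by midranks,
    two-sided by symmetry around the null mean). Larger groups use the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    if n1 <= exact_max_n and n2 <= exact_max_n:
        dev = abs(w - mu)
        hits = 0
        total = 0
        for comb in combinations(range(n1 + n2), n1):
            total += 1
            ws = ranks[list(comb)].sum()
            if abs(ws - mu) >= dev - 1e-9:
                hits += 1
        return hits / total
    # normal approximation with tie and continuity corrections
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    return float(2.0 * sps.norm.sf(max(z, 0.0)))


def _vectorized_ranksum_p(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Normal-approximation rank-sum p across all genes at once (rows=genes)."""
    n1, n2 = xa.shape[1], xb.shape[1]
    n = n1 + n2
    pooled = np.concatenate([xa, xb], axis=1)
    ranks = sps.rankdata(pooled, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    # tie correction per gene
    srt = np.sort(pooled, axis=1)
    tie_term = np.empty(pooled.shape[0])
    for g in range(pooled.shape[0]):
        _, counts = np.unique(srt[g], return_counts=True)
        tie_term[g] = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = np.zeros(len(w))
    ok = var > 0
    z[ok] = (np.abs(w[ok] - mu) - 0.5) / np.sqrt(var[ok])
    p = np.ones(len(w))
    p[ok] = 2.0 * sps.norm.sf(np.maximum(z[ok], 0.0))
    return np.minimum(p, 1.0)


def wilcoxon_de(
    norm: NormalizedMatrix,
    group_a: list[str],
    group_b: list[str],
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Per-gene two-sided rank-sum DE between two cell groups.

    Returns a DataFrame (gene, log2fc, p_value, fdr, direction) where
    log2fc = mean(A) - mean(B) on the log2(CPM+1) scale, fdr is
    Benjamini–Hochberg across the genes tested (those with nonzero counts in
    the union of the two groups), and direction applies the
    |log2FC| > lfc_cut and FDR < de_alpha rule ('up', 'down', or 'ns').
    Genes excluded from testing are reported with p = fdr = NaN.
    """
    p = params or AnalysisParams()
    if not group_a or not group_b:
        raise ValueError("both groups must contain at least one cell")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 cells for a rank-sum test")
    col = {bc: i for i, bc in enumerate(norm.cell_barcodes)}
    ia = [col[c] for c in group_a]
    ib = [col[c] for c in group_b]
    xa = norm.values[:, ia]
    xb = norm.values[:, ib]
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    expressed = (xa.sum(axis=1) + xb.sum(axis=1)) > 0

    n1, n2 = len(ia), len(ib)
    pvals = np.full(len(norm.gene_ids), np.nan)
    if n1 <= p.exact_max_n and n2 <= p.exact_max_n:
        for g in np.flatnonzero(expressed):
            pvals[g] = rank_sum_p(xa[g], xb[g], p.exact_max_n)
    else:
        idx = np.flatnonzero(expressed)
        if idx.size:
            pvals[idx] = _vectorized_ranksum_p(xa[idx], xb[idx])

    fdr = np.full(len(pvals), np.nan)
    tested = ~np.isnan(pvals)
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    direction = np.full(len(pvals), "ns", dtype=object)
    sig = tested & (fdr < p.de_alpha)
    direction[sig & (log2fc > p.lfc_cut)] = "up"
    direction[sig & (log2fc < -p.lfc_cut)] = "down"

    return pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
        }
    )


# ---------------------------------------------------------------------------
# Cell-cycle scoring
# ---------------------------------------------------------------------------


def score_cell_cycle(
    norm: NormalizedMatrix,
    s_markers: list[str],
    g2m_markers: list[str],
    seed: int = 0,
    n_background_per_marker: int = 25,
    n_bins: int = 25,
) -> pd.DataFrame:
    """Assign each cell a phase in {G1, S, G2M} from marker-gene scores.

    The S score is the mean marker expression minus the mean expression of an
    expression-matched background set (background genes sampled, with a fixed
    seed, from the same mean-expression bin as each marker); likewise G2M.
    A cell's phase is the argmax of the two scores if that maximum is
    positive, else G1. Markers absent from the matrix are dropped with a
    warning; if none remain for a list, that is an error.
    """
    rng = derive_rng(seed, "cell-cycle")
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    mean_expr = norm.values.mean(axis=1)
    n_bins = max(1, min(n_bins, len(mean_expr) // 10))
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(len(mean_expr), dtype=int)
    bins[order] = np.arange(len(mean_expr)) * n_bins // max(len(mean_expr), 1)

    def score(markers: list[str], label: str) -> np.ndarray:
        present = [g for g in markers if g in gene_pos]
        dropped = set(markers) - set(present)
        if dropped:
            warnings.warn(f"{label} markers absent from the matrix: {sorted(dropped)}")
        if not present:
            raise ValueError(f"no {label} marker genes present in the matrix")
        midx = np.array([gene_pos[g] for g in present])
        background: list[int] = []
        marker_set = set(midx)
        for mi in midx:
            pool = np.flatnonzero(bins == bins[mi])
            pool = np.array([g for g in pool if g not in marker_set])
            if pool.size == 0:
                continue
            take = min(n_background_per_marker, pool.size)
            background.extend(rng.choice(pool, size=take, replace=False))
        if not background:
            raise ValueError(f"no background genes available for {label} scoring")
        return norm.values[midx].mean(axis=0) - norm.values[np.array(background)].mean(axis=0)

    s_score = score(s_markers, "S")
    g2m_score = score(g2m_markers, "G2M")
    phase = np.where(
        np.maximum(s_score, g2m_score) <= 0,
        "G1",
        np.where(s_score > g2m_score, "S", "G2M"),
    )
    return pd.DataFrame(
        {
            "barcode": norm.cell_barcodes,
            "s_score": s_score,
            "g2m_score": g2m_score,
            "phase": phase,
        }
    )


# ---------------------------------------------------------------------------
# Batch-effect removal and pseudobulk
# ---------------------------------------------------------------------------


def remove_batch_effect(
    norm: NormalizedMatrix,
    batch: list[str],
    condition: list[str] | None = None,
) -> NormalizedMatrix:
    """Subtract per-gene additive batch effects, preserving condition effects.

    Fits, per gene, a linear model value ~ intercept + condition + batch with
    the batch factor coded sum-to-zero, then subtracts only the fitted batch
    terms. With a single batch the output equals the input. A design in which
    batch is aliased with condition is rejected by a rank check.
    """
    n_cells = len(norm.cell_barcodes)
    if len(batch) != n_cells:
        raise ValueError("one batch label per cell is required")
    batch = np.asarray(batch, dtype=object)
    levels = sorted(set(batch))
    if len(levels) == 1:
        return NormalizedMatrix(norm.values.copy(), list(norm.gene_ids), list(norm.cell_barcodes))

    # sum-to-zero coding: columns for levels[1:], last level = -sum(others)
    bmat = np.zeros((n_cells, len(levels) - 1))
    for j, lev in enumerate(levels[1:]):
        bmat[batch == lev, j] = 1.0
    bmat[batch == levels[0], :] = -1.0

    design_cols = [np.ones((n_cells, 1))]
    if condition is not None:
        if len(condition) != n_cells:
            raise ValueError("one condition label per cell is required")
        condition = np.asarray(condition, dtype=object)
        clevels = sorted(set(condition))
        cmat = np.zeros((n_cells, len(clevels) - 1))
        for j, lev in enumerate(clevels[1:]):
            cmat[condition == lev, j] = 1.0
        design_cols.append(cmat)
    design_cols.append(bmat)
    x = np.hstack(design_cols)
    rank_full = np.linalg.matrix_rank(x)
    if rank_full < x.shape[1]:
        raise ValueError(
            "batch is confounded with condition (design matrix is rank-deficient); "
            "batch effects cannot be separated"
        )
    coef, *_ = np.linalg.lstsq(x, norm.values.T, rcond=None)  # (p, genes)
    batch_part = bmat @ coef[-bmat.shape[1] :, :]  # cells x genes
    adjusted = norm.values - batch_part.T
    return NormalizedMatrix(adjusted, list(norm.gene_ids), list(norm.cell_barcodes))


def pseudobulk_profiles(
    norm: NormalizedMatrix, condition: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean log2(CPM+1) per condition plus the pairwise Pearson correlations.

    Returns (profiles, correlations): profiles is conditions x genes;
    correlations holds Pearson r over genes for every condition pair (R^2 is
    r squared).
    """
    if len(condition) != len(norm.cell_barcodes):
        raise ValueError("one condition label per cell is required")
    condition = np.asarray(condition, dtype=object)
    levels = sorted(set(condition))
    rows = {}
    for lev in levels:
        mask = condition == lev
        if not mask.any():
            raise ValueError(f"condition {lev!r} has no cells")
        rows[lev] = norm.values[:, mask].mean(axis=1)
    profiles = pd.DataFrame(rows, index=norm.gene_ids).T
    corr = profiles.T.corr(method="pearson")
    return profiles, corr


def heatmap_gene_set(
    de_results: dict[str, pd.DataFrame], heatmap_alpha: float = 0.05
) -> list[str]:
    """Union of genes significant (FDR < alpha) in any contrast, sorted."""
    genes: set[str] = set()
    for contrast, table in de_results.items():
        sig = table.loc[table["fdr"] < heatmap_alpha, "gene"]
        genes.update(sig)
    return sorted(genes)
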
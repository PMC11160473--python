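"""Cell filtering, normalization, HVG selection, PCA, and graph clustering.

The two-stage cell filter reproduces the source protocol: a lenient pass
(< 750 detected genes, > 12,500 UMIs, or > 2.5% mitochondrial reads removes a
cell) optionally tightened by a stringent pass (> 2,750 genes, > 9,500 UMIs,
or > 1.25% mito). "Detected gene" means nonzero count. The latent space is
plain PCA over batch-aware highly variable genes; the downstream statistics
depend only on the resulting kNN graph.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix, genes_of_class

logger = logging.getLogger("antseq")

STAGE_LENIENT = "lenient"
STAGE_STRINGENT = "stringent"


@dataclass
class QCThresholds:
    stage1_min_genes: int = 750
    stage1_max_umis: int = 12500
    stage1_max_pct_mito: float = 2.5
    stage2_max_genes: int = 2750
    stage2_max_umis: int = 9500
    stage2_max_pct_mito: float = 1.25

    def __post_init__(self):
        if self.stage2_max_umis > self.stage1_max_umis:
            raise ValueError("stage-2 UMI bound must be inside the stage-1 bound")
        if self.stage2_max_pct_mito > self.stage1_max_pct_mito:
            raise ValueError("stage-2 mito bound must be inside the stage-1 bound")

    @classmethod
    def from_config(cls, config) -> "QCThresholds":
        return cls(
            config.stage1_min_genes, config.stage1_max_umis,
            config.stage1_max_pct_mito, config.stage2_max_genes,
            config.stage2_max_umis, config.stage2_max_pct_mito,
        )


def compute_cell_qc(counts: CountMatrix, annotation: pd.DataFrame,
                    meta: pd.DataFrame) -> pd.DataFrame:
    """Attach n_genes_detected, n_umis and pct_mito to the cell metadata."""
    X = counts.values
    meta = meta.loc[counts.cell_ids].copy()
    meta["n_genes_detected"] = np.asarray((X > 0).sum(axis=1)).ravel()
    meta["n_umis"] = np.asarray(X.sum(axis=1)).ravel()
    mito = [g for g in genes_of_class(annotation, "mito") if g in set(counts.gene_ids)]
    if mito:
        midx = counts.gene_index(mito)
        mcounts = np.asarray(X[:, midx].sum(axis=1)).ravel()
    else:
        mcounts = np.zeros(counts.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        meta["pct_mito"] = np.where(
            meta["n_umis"] > 0, 100.0 * mcounts / meta["n_umis"].to_numpy(), 0.0
        )
    return meta


def filter_cells(counts: CountMatrix, meta: pd.DataFrame,
                 thresholds: QCThresholds, stage: str = STAGE_STRINGENT):
    """Remove cells violating the QC bounds (strict inequalities).

    Returns ``(filtered counts, filtered meta, removal log)`` where the log
    has one row per (cell, rule) that fired.
    """
    if stage not in (STAGE_LENIENT, STAGE_STRINGENT):
        raise ValueError(f"unknown QC stage {stage!r}")
    meta = meta.loc[counts.cell_ids]
    rules = [
        ("min_genes", meta["n_genes_detected"] < thresholds.stage1_min_genes),
        ("max_umis", meta["n_umis"] > thresholds.stage1_max_umis),
        ("max_pct_mito", meta["pct_mito"] > thresholds.stage1_max_pct_mito),
    ]
    if stage == STAGE_STRINGENT:
        rules += [
            ("max_genes", meta["n_genes_detected"] > thresholds.stage2_max_genes),
            ("max_umis_stringent", meta["n_umis"] > thresholds.stage2_max_umis),
            ("max_pct_mito_stringent",
             meta["pct_mito"] > thresholds.stage2_max_pct_mito),
        ]
    log_rows = []
    removed = np.zeros(counts.n_cells, dtype=bool)
    for name, fired in rules:
        fired = fired.to_numpy()
        removed |= fired
        for cid in meta.index[fired]:
            log_rows.append((cid, name))
    keep = ~removed
    log = pd.DataFrame(log_rows, columns=["cell_id", "rule"])
    logger.info("filter_cells(%s): removed %d of %d cells",
                stage, int(removed.sum()), counts.n_cells)
    return counts.subset_cells(keep), meta.loc[keep].copy(), log


def remove_rrna_genes(counts: CountMatrix, rrna_ids) -> CountMatrix:
    """Drop the named genes (e.g. large-subunit rRNA) from the matrix."""
    present = set(counts.gene_ids)
    absent = [g for g in rrna_ids if g not in present]
    if absent:
        logger.warning("remove_rrna_genes: %d listed gene(s) absent from matrix: %s",
                       len(absent), absent[:5])
    drop = set(rrna_ids) & present
    keep = [i for i, g in enumerate(counts.gene_ids) if g not in drop]
    if len(keep) == counts.n_genes:
        return counts
    return counts.subset_genes(keep)


def normalize_cp10k_log1p(counts: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """ln(1 + scale * count / cell_total), dense (cells x genes)."""
    X = counts.values
    if counts.mode != "single_nucleus":
        raise ValueError("normalize_cp10k_log1p expects single-nucleus counts")
    totals = np.asarray(X.sum(axis=1), dtype=float).ravel()
    if (totals == 0).any():
        bad = [counts.cell_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(f"zero-total cell(s) reached normalization: {bad}")
    dense = np.asarray(X.todense(), dtype=float)
    return np.log1p(scale * dense / totals[:, None])


# ---------------------------------------------------------------------------
# highly variable genes

def _hvg_rank_one_batch(norm: np.ndarray, gene_ids, window: int = 151) -> np.ndarray:
    """Rank genes (0 = most variable) by standardized variance: variance of
    log-normalized values over a rolling-median mean-variance trend."""
    mean = norm.mean(axis=0)
    var = norm.var(axis=0, ddof=1)
    order = np.argsort(mean, kind="stable")
    half = window // 2
    trend_sorted = np.empty_like(var)
    var_sorted = var[order]
    n = len(var)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        trend_sorted[i] = np.median(var_sorted[lo:hi])
    trend = np.empty_like(trend_sorted)
    trend[order] = np.maximum(trend_sorted, 1e-12)
    std_var = np.where(var > 0, var / trend, 0.0)
    # rank descending by standardized variance, ties by gene_id order
    key = pd.DataFrame({"sv": -std_var, "gid": list(gene_ids)})
    ranked = key.sort_values(["sv", "gid"], kind="stable").index.to_numpy()
    ranks = np.empty(n)
    ranks[ranked] = np.arange(n)
    return ranks


def select_hvgs(counts: CountMatrix, batch_labels: pd.Series, n_top: int = 2000,
                min_batch_cells: int = 50, scale: float = 1e4) -> list:
    """Batch-aware HVG selection: per-batch standardized-variance ranks are
    combined across batches by median rank; ties break by gene_id order."""
    gene_ids = counts.gene_ids
    if n_top > len(gene_ids):
        logger.warning("n_top=%d exceeds %d genes; selecting all genes",
                       n_top, len(gene_ids))
        n_top = len(gene_ids)
    batch_labels = batch_labels.loc[counts.cell_ids]
    rank_cols = []
    for batch in sorted(batch_labels.unique()):
        idx = np.flatnonzero((batch_labels == batch).to_numpy())
        if idx.size < min_batch_cells:
            logger.warning("batch %r has %d (<%d) cells; excluded from HVG ranking",
                           batch, idx.size, min_batch_cells)
            continue
        sub = counts.subset_cells(idx)
        norm = normalize_cp10k_log1p(sub, scale=scale)
        rank_cols.append(_hvg_rank_one_batch(norm, gene_ids))
    if not rank_cols:
        raise ValueError("no batch large enough for HVG ranking")
    med = np.median(np.column_stack(rank_cols), axis=1)
    key = pd.DataFrame({"rank": med, "gid": gene_ids})
    chosen = key.sort_values(["rank", "gid"], kind="stable").head(n_top)["gid"]
    return list(chosen)


# ---------------------------------------------------------------------------
# PCA and kNN/Leiden

def pca_embed(norm_hvg: np.ndarray, n_pcs: int = 30):
    """Center- and unit-scale genes, then project onto top right singular
    vectors. Returns (latent, explained-variance fractions, elbow suggestion).

    The elbow suggestion is the first PC at which the drop in explained
    variance falls below 5% of the previous drop.
    """
    X = np.asarray(norm_hvg, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    rank = min(Xs.shape)
    if n_pcs > rank:
        logger.warning("n_pcs=%d exceeds rank %d; truncating", n_pcs, rank)
        n_pcs = rank
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each PC is positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = S**2
    evr = var / var.sum() if var.sum() > 0 else var
    latent = U[:, :n_pcs] * S[:n_pcs]
    elbow = n_pcs
    for k in range(2, len(evr)):
        prev_drop = evr[k - 2] - evr[k - 1]
        drop = evr[k - 1] - evr[k]
        if prev_drop > 0 and drop < 0.05 * prev_drop:
            elbow = k
            break
    return latent, evr[:n_pcs], elbow


@dataclass
class Embedding:
    latent: np.ndarray
    neighbor_indices: np.ndarray  # (cells, n_neighbors), self excluded
    neighbor_weights: np.ndarray
    clusters: np.ndarray  # contiguous integer labels from 0
    explained_variance: np.ndarray | None = None

    @property
    def n_neighbors(self) -> int:
        return self.neighbor_indices.shape[1]


def knn_cluster(latent: np.ndarray, n_neighbors: int = 15,
                resolution: float = 5.0, seed: int = 0) -> Embedding:
    """Exact Euclidean kNN graph (union-symmetrized, unit weights) plus Leiden
    community detection with an RB-modularity resolution parameter."""
    n = latent.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1, algorithm="brute")
    nn.fit(latent)
    _, idx = nn.kneighbors(latent)
    # drop self by index (ties at distance 0 may put self anywhere in the list)
    neigh = np.empty((n, n_neighbors), dtype=int)
    for i in range(n):
        row = [j for j in idx[i] if j != i][:n_neighbors]
        if len(row) < n_neighbors:  # self absent (duplicate points)
            row = list(idx[i][:n_neighbors])
        neigh[i] = row
    edges = set()
    for i in range(n):
        for j in neigh[i]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    raw = np.array(part.membership)
    # contiguous labels ordered by first appearance (determinism)
    remap, nxt = {}, 0
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = nxt
            nxt += 1
        labels[i] = remap[c]
    return Embedding(
        latent=latent,
        neighbor_indices=neigh,
        neighbor_weights=np.ones_like(neigh, dtype=float),
        clusters=labels,
    )
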
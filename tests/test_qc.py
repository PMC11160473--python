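import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import antseq as a
from antseq.io import make_cell_meta, make_gene_annotation
from antseq.qc import QCThresholds, STAGE_LENIENT, STAGE_STRINGENT


def _toy(cells):
    """cells: list of (n_genes_detected, n_umis, pct_mito) synthetic rows."""
    meta = pd.DataFrame(
        cells, columns=["n_genes_detected", "n_umis", "pct_mito"],
        index=pd.Index([f"c{i}" for i in range(len(cells))], name="cell_id"),
    )
    meta["library_id"] = "lib1"
    meta["genotype"] = "WT"
    counts = a.CountMatrix(sp.eye(len(cells), 3, dtype=np.int64, format="csr"),
                           list(meta.index), ["g1", "g2", "g3"])
    return counts, meta


@pytest.mark.parametrize(
    "row,stage,kept,rule",
    [
        ((740, 5000, 1.0), STAGE_LENIENT, False, "min_genes"),
        ((750, 9000, 1.0), STAGE_LENIENT, True, None),  # strict "fewer than"
        ((1000, 12500, 1.0), STAGE_LENIENT, True, None),
        ((1000, 12501, 1.0), STAGE_LENIENT, False, "max_umis"),
        ((1000, 5000, 2.6), STAGE_LENIENT, False, "max_pct_mito"),
        ((3000, 5000, 1.0), STAGE_LENIENT, True, None),
        ((3000, 5000, 1.0), STAGE_STRINGENT, False, "max_genes"),
        ((1000, 9501, 1.0), STAGE_STRINGENT, False, "max_umis_stringent"),
        ((1000, 5000, 1.3), STAGE_STRINGENT, False, "max_pct_mito_stringent"),
    ],
)
def test_filter_cell_boundaries(row, stage, kept, rule):
    counts, meta = _toy([row])
    fc, fm, log = a.filter_cells(counts, meta, QCThresholds(), stage=stage)
    assert (fc.n_cells == 1) is kept
    if rule:
        assert rule in set(log["rule"])


def test_filter_unknown_stage():
    counts, meta = _toy([(1000, 5000, 1.0)])
    with pytest.raises(ValueError, match="stage"):
        a.filter_cells(counts, meta, QCThresholds(), stage="extreme")


def test_filter_is_idempotent(sn_small, annotation):
    counts, meta, _ = sn_small
    meta = a.compute_cell_qc(counts, annotation, meta)
    fc, fm, _ = a.filter_cells(counts, meta, QCThresholds())
    fc2, _, log2 = a.filter_cells(fc, fm, QCThresholds())
    assert fc2.n_cells == fc.n_cells and log2.empty


def test_stage2_bounds_inside_stage1():
    with pytest.raises(ValueError):
        QCThresholds(stage2_max_umis=20000)


def test_remove_rrna_genes(caplog):
    counts = a.CountMatrix(
        sp.csr_matrix(np.arange(20).reshape(2, 10)),
        ["c1", "c2"], [f"g{i}" for i in range(10)],
    )
    assert a.remove_rrna_genes(counts, []) is counts
    out = a.remove_rrna_genes(counts, ["g3", "g7"])
    assert out.gene_ids == [f"g{i}" for i in range(10) if i not in (3, 7)]
    import logging
    with caplog.at_level(logging.WARNING, logger="antseq"):
        out2 = a.remove_rrna_genes(counts, ["absent"])
    assert out2.gene_ids == counts.gene_ids
    assert any("absent" in r.message for r in caplog.records)


def test_cp10k_log1p_hand_example():
    counts = a.CountMatrix(sp.csr_matrix(np.array([[1, 1, 2]])), ["c1"],
                           ["g1", "g2", "g3"])
    norm = a.normalize_cp10k_log1p(counts)
    assert np.allclose(norm[0], [np.log(2501), np.log(2501), np.log(5001)])


def test_cp10k_depth_invariance_and_monotonicity():
    base = np.array([[1, 0, 3, 6]])
    c1 = a.CountMatrix(sp.csr_matrix(base), ["c"], list("abcd"))
    c2 = a.CountMatrix(sp.csr_matrix(base * 7), ["c"], list("abcd"))
    assert np.allclose(a.normalize_cp10k_log1p(c1), a.normalize_cp10k_log1p(c2))
    # strictly monotone per cell
    n = a.normalize_cp10k_log1p(c1)[0]
    order = np.argsort(base[0])
    assert all(np.diff(n[order]) >= 0)
    assert n[1] == 0.0  # zero counts map to zero


def test_cp10k_zero_total_cell_errors():
    counts = a.CountMatrix(sp.csr_matrix(np.array([[0, 0], [1, 2]])),
                           ["c1", "c2"], ["g1", "g2"])
    with pytest.raises(ValueError, match="zero-total"):
        a.normalize_cp10k_log1p(counts)


# ---------------------------------------------------------------------------
# HVG selection

def test_hvg_bimodal_gene_ranked_first():
    rng = np.random.default_rng(0)
    n = 200
    flat = rng.poisson(5.0, size=(n, 30))
    bimodal = np.r_[rng.poisson(0.2, n // 2), rng.poisson(15.0, n // 2)]
    mat = np.column_stack([bimodal, flat])
    counts = a.CountMatrix(sp.csr_matrix(mat), [f"c{i}" for i in range(n)],
                           [f"g{i:02d}" for i in range(31)])
    batches = pd.Series("b1", index=counts.cell_ids)
    top = a.select_hvgs(counts, batches, n_top=1)
    assert top == ["g00"]


def test_hvg_constant_gene_never_beats_varying():
    rng = np.random.default_rng(1)
    mat = rng.poisson(4.0, size=(120, 10))
    mat[:, 0] = 7  # constant expression
    counts = a.CountMatrix(sp.csr_matrix(mat), [f"c{i}" for i in range(120)],
                           [f"g{i}" for i in range(10)])
    batches = pd.Series("b1", index=counts.cell_ids)
    top = a.select_hvgs(counts, batches, n_top=9)
    assert "g0" not in top


def test_hvg_small_batch_excluded(caplog, sn_small):
    import logging
    counts, meta, _ = sn_small
    batches = pd.Series("big", index=counts.cell_ids)
    batches.iloc[:10] = "tiny"
    with caplog.at_level(logging.WARNING, logger="antseq"):
        a.select_hvgs(counts, batches, n_top=50)
    assert any("tiny" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# PCA + clustering

def test_pca_two_antipodal_points():
    X = np.array([[1.0, 2.0], [-1.0, -2.0]])
    latent, evr, _ = a.pca_embed(X, n_pcs=2)
    assert evr[0] > 1 - 1e-12


def test_pca_preserves_distances_of_low_rank_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 4)) @ rng.normal(size=(4, 30))
    latent, _, _ = a.pca_embed(X, n_pcs=4)
    from scipy.spatial.distance import pdist
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    assert np.allclose(pdist(Xs), pdist(latent), atol=1e-8)


def test_pca_isotropic_cloud_flat_spectrum():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(4000, 5))
    _, evr, _ = a.pca_embed(X, n_pcs=5)
    assert np.allclose(evr, 0.2, atol=0.02)


def test_pca_elbow_on_rank_one_data():
    rng = np.random.default_rng(3)
    X = np.outer(rng.normal(size=100), rng.normal(size=20))
    X += 1e-6 * rng.normal(size=X.shape)
    _, _, elbow = a.pca_embed(X, n_pcs=10)
    assert elbow in (1, 2)


def test_pca_truncates_beyond_rank(caplog):
    import logging
    X = np.random.default_rng(0).normal(size=(5, 3))
    with caplog.at_level(logging.WARNING, logger="antseq"):
        latent, _, _ = a.pca_embed(X, n_pcs=10)
    assert latent.shape[1] == 3


def test_knn_cluster_two_blobs():
    rng = np.random.default_rng(4)
    X = np.r_[rng.normal(0, 0.1, (60, 2)), rng.normal(5, 0.1, (60, 2))]
    emb = a.knn_cluster(X, n_neighbors=10, resolution=0.1, seed=0)
    labels = emb.clusters
    assert len(set(labels)) == 2
    assert len(set(labels[:60])) == 1 and len(set(labels[60:])) == 1
    # neighbor lists exclude self, exact size
    assert emb.neighbor_indices.shape == (120, 10)
    assert all(i not in emb.neighbor_indices[i] for i in range(120))


def test_knn_duplicates_share_cluster():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(40, 3))
    X2 = np.r_[X, X]
    emb = a.knn_cluster(X2, n_neighbors=5, resolution=0.5, seed=0)
    assert all(emb.clusters[i] == emb.clusters[i + 40] for i in range(40))


def test_knn_resolution_monotone_cluster_count():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(150, 5))
    lo = a.knn_cluster(X, n_neighbors=10, resolution=0.2, seed=0)
    hi = a.knn_cluster(X, n_neighbors=10, resolution=20.0, seed=0)
    assert len(set(hi.clusters)) >= len(set(lo.clusters))


def test_knn_too_many_neighbors():
    with pytest.raises(ValueError, match="n_neighbors"):
        a.knn_cluster(np.zeros((5, 2)), n_neighbors=5)
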
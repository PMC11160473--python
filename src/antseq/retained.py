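"""Or genes retained in orco mutants: cross-platform fold-change concordance
and neighbor-gene coexpression scoring.

An Or gene counts as retained when its mutant/WT log2 fold change clears an
explicit cutoff on *both* platforms: single-nucleus CP10k means over cells
and bulk FPKM means over samples, each computed only for genes with nonzero
expression in both genotypes on that platform. The default cutoffs (-1, -1:
fold change above 0.5x) stand in for the source study's unprinted "arbitrary
cutoff" and are exposed in the config. Retained Ors are then scored for
leaky regulation: overlap (Jaccard on nonzero masks over nonneuronal cells)
with the nearest non-Or gene on the same scaffold.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .io import CountMatrix
from .qc import normalize_cp10k_log1p  # noqa: F401  (CP10k shares the scale)

logger = logging.getLogger("antseq")


def _cp10k(counts: CountMatrix, scale: float = 1e4) -> np.ndarray:
    X = counts.values
    totals = np.asarray(X.sum(axis=1), dtype=float).ravel()
    totals[totals == 0] = 1.0
    return np.asarray(X.todense(), dtype=float) * scale / totals[:, None]


def cross_platform_fc(sn_counts: CountMatrix, sn_meta: pd.DataFrame,
                      bulk_fpkm: pd.DataFrame, bulk_design: pd.DataFrame,
                      or_genes) -> pd.DataFrame:
    """Per-Or-gene mutant/WT log2 fold change on each platform.

    Single-nucleus means are CP10k averaged over all cells of a genotype;
    bulk means are FPKM averaged over samples. A platform's fold change is
    reported only for genes with nonzero mean in both genotypes there.
    """
    or_genes = [g for g in or_genes if g in set(sn_counts.gene_ids)]
    cp = _cp10k(sn_counts)
    meta = sn_meta.loc[sn_counts.cell_ids]
    gidx = sn_counts.gene_index(or_genes)
    wt_rows = (meta["genotype"] == "WT").to_numpy()
    mut_rows = (meta["genotype"] == "mutant").to_numpy()
    mean_sn_wt = cp[wt_rows][:, gidx].mean(axis=0)
    mean_sn_mut = cp[mut_rows][:, gidx].mean(axis=0)

    design = bulk_design.loc[bulk_fpkm.columns]
    wt_cols = design.index[design["genotype"] == "WT"]
    mut_cols = design.index[design["genotype"] == "mutant"]
    bulk_or = bulk_fpkm.reindex(or_genes)
    mean_bk_wt = bulk_or[wt_cols].mean(axis=1).to_numpy()
    mean_bk_mut = bulk_or[mut_cols].mean(axis=1).to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        fc_sn = np.where(
            (mean_sn_wt > 0) & (mean_sn_mut > 0),
            np.log2(mean_sn_mut / mean_sn_wt), np.nan,
        )
        fc_bk = np.where(
            (mean_bk_wt > 0) & (mean_bk_mut > 0),
            np.log2(mean_bk_mut / mean_bk_wt), np.nan,
        )
    rec = pd.DataFrame(
        {
            "log2fc_sn": fc_sn, "log2fc_bulk": fc_bk,
            "mean_sn_WT": mean_sn_wt, "mean_sn_mut": mean_sn_mut,
            "mean_bulk_WT": mean_bk_wt, "mean_bulk_mut": mean_bk_mut,
        },
        index=pd.Index(or_genes, name="gene_id"),
    )
    rec = rec[~(rec["log2fc_sn"].isna() & rec["log2fc_bulk"].isna())]
    if rec.empty:
        raise ValueError("no Or gene has nonzero expression in both genotypes "
                         "on either platform")
    rec["retained"] = False
    return rec


def concordance(records: pd.DataFrame) -> dict:
    """Squared Pearson and Spearman correlation between the two platforms'
    log2 fold changes (genes with records on both)."""
    both = records.dropna(subset=["log2fc_sn", "log2fc_bulk"])
    out = {"n": int(len(both)), "pearson_r2": np.nan, "spearman_r2": np.nan,
           "pearson_sign": np.nan}
    if len(both) < 3:
        raise ValueError("need >= 3 genes with fold changes on both platforms")
    x, y = both["log2fc_sn"].to_numpy(), both["log2fc_bulk"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance on one axis; concordance undefined")
        return out
    r, _ = pearsonr(x, y)
    rho, _ = spearmanr(x, y)
    out.update(pearson_r2=float(r**2), spearman_r2=float(rho**2),
               pearson_sign=float(np.sign(r)))
    return out


def select_retained(records: pd.DataFrame, cutoff_sn: float = -1.0,
                    cutoff_bulk: float = -1.0) -> list:
    """Genes whose log2 fold change is above both cutoffs (both platforms
    must have records), sorted by min(log2fc) descending. Sets the
    ``retained`` flag on the records in place."""
    both = records.dropna(subset=["log2fc_sn", "log2fc_bulk"])
    ok = both[(both["log2fc_sn"] > cutoff_sn) & (both["log2fc_bulk"] > cutoff_bulk)]
    ordered = ok.assign(key=ok[["log2fc_sn", "log2fc_bulk"]].min(axis=1))
    ordered = ordered.sort_values("key", ascending=False)
    retained = list(ordered.index)
    records["retained"] = records.index.isin(retained)
    return retained


def neighbor_coexpression(sn_counts: CountMatrix, nonneuronal_cells,
                          annotation: pd.DataFrame, retained_genes) -> pd.DataFrame:
    """For each retained Or: nearest non-Or gene on the same scaffold
    (midpoint distance), Jaccard overlap of nonzero cells over nonneuronal
    cells, and the fraction of the Or's total counts found in nonneuronal
    cells."""
    pos = {c: i for i, c in enumerate(sn_counts.cell_ids)}
    nn_idx = np.array([pos[c] for c in nonneuronal_cells], dtype=int)
    X = sn_counts.values
    mid = (annotation["start"] + annotation["end"]) / 2.0
    rows = []
    present = set(sn_counts.gene_ids)
    for or_gene in retained_genes:
        if or_gene not in present or or_gene not in annotation.index:
            logger.warning("retained gene %s missing from matrix/annotation", or_gene)
            continue
        scaffold = annotation.at[or_gene, "scaffold"]
        same = annotation[(annotation["scaffold"] == scaffold)
                          & (annotation["gene_class"] != "tuning_Or")
                          & (annotation.index != or_gene)]
        gi = sn_counts.gene_index([or_gene])[0]
        or_col = np.asarray(X[:, gi].todense()).ravel()
        or_nn = or_col[nn_idx] > 0
        total = or_col.sum()
        nn_frac = float(or_col[nn_idx].sum() / total) if total > 0 else np.nan
        if same.empty:
            rows.append((or_gene, None, np.nan, np.nan, nn_frac))
            continue
        dist = (mid.loc[same.index] - mid.loc[or_gene]).abs()
        neighbor = dist.idxmin()
        gj = sn_counts.gene_index([neighbor])[0]
        nb_nn = np.asarray(X[nn_idx, gj].todense()).ravel() > 0
        union = int((or_nn | nb_nn).sum())
        jac = float((or_nn & nb_nn).sum() / union) if union else 0.0
        rows.append((or_gene, neighbor, float(dist.min()), jac, nn_frac))
    return pd.DataFrame(
        rows, columns=["or_gene_id", "neighbor_gene_id", "genomic_distance",
                       "jaccard", "nonneuronal_fraction_of_or_expression"],
    ).set_index("or_gene_id")
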
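"""Bulk RNA-seq normalization, trajectory summaries, and PC-loading gene sets.

Normalization re-implements the DESeq2 median-of-ratios estimator; the
variance-stabilizing transform is approximated by log1p of normalized counts
(the downstream use — ranking PCA loadings — is robust to the exact
transform). Stage-biased gene sets follow the published recipe: the k genes
with the largest positive PC1 loading are the early set, the k most negative
PC2 loadings the intermediate set, and the k most negative PC1 loadings the
late set, with PC signs oriented against developmental stage rank so
"positive PC1" means early.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MODE_BULK, CountMatrix

logger = logging.getLogger("antseq")

STAGE_ORDER = {"D10": 0, "D15": 1, "D20": 2, "D25": 3, "adult": 4}


def size_factors_median_of_ratios(counts: CountMatrix) -> pd.Series:
    """DESeq2-style size factors: per-sample median of count/geometric-mean
    ratios over genes nonzero in every sample."""
    X = np.asarray(counts.values, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    all_nonzero = (X > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ref = np.exp(np.log(X[all_nonzero]).mean(axis=1))
    factors = np.median(X[all_nonzero] / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.cell_ids, name="size_factor")


def normalize_bulk(counts: CountMatrix, factors: pd.Series = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors_median_of_ratios(counts)
    X = np.asarray(counts.values, dtype=float)
    return pd.DataFrame(
        X / factors.to_numpy()[None, :], index=counts.gene_ids,
        columns=counts.cell_ids,
    )


def fpkm(counts: CountMatrix, gene_lengths: pd.Series,
         mapped_totals: pd.Series = None) -> pd.DataFrame:
    """count * 1e9 / (length_bases * per-sample mapped total)."""
    X = np.asarray(counts.values, dtype=float)
    lengths = gene_lengths.loc[counts.gene_ids].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if mapped_totals is None:
        totals = X.sum(axis=0)
    else:
        totals = mapped_totals.loc[counts.cell_ids].to_numpy(dtype=float)
    if (totals == 0).any():
        raise ValueError("zero mapped total for some sample")
    return pd.DataFrame(
        X * 1e9 / (lengths[:, None] * totals[None, :]),
        index=counts.gene_ids, columns=counts.cell_ids,
    )


@dataclass
class TrajectorySummary:
    summary: pd.DataFrame  # (genotype, stage) -> mean, sd over genes
    profiles: pd.DataFrame  # genes x (genotype, stage) max-scaled means


def scaled_trajectory(norm: pd.DataFrame, design: pd.DataFrame,
                      gene_set) -> TrajectorySummary:
    """Average each gene over replicates within (genotype, stage), scale to
    its maximum across all conditions, then summarize mean +- SD across
    genes per condition."""
    gene_set = [g for g in gene_set if g in norm.index]
    if not gene_set:
        raise ValueError("empty gene set")
    design = design.loc[norm.columns]
    stages = sorted(design["stage"].unique(), key=lambda s: STAGE_ORDER[s])
    genotypes = [g for g in ("WT", "het", "mutant") if g in set(design["genotype"])]
    cond_means = {}
    for gt in genotypes:
        for st in stages:
            cols = design.index[(design["genotype"] == gt) & (design["stage"] == st)]
            if len(cols):
                cond_means[(gt, st)] = norm.loc[gene_set, cols].mean(axis=1)
    prof = pd.DataFrame(cond_means)
    gmax = prof.max(axis=1)
    dropped = gmax[gmax == 0].index
    if len(dropped):
        logger.info("scaled_trajectory: dropping %d all-zero gene(s)", len(dropped))
        prof = prof.drop(index=dropped)
        gmax = gmax.drop(index=dropped)
    prof = prof.div(gmax, axis=0)
    summary = pd.DataFrame(
        {"mean": prof.mean(axis=0), "sd": prof.std(axis=0, ddof=1)}
    )
    return TrajectorySummary(summary=summary, profiles=prof)


@dataclass
class StageGeneSets:
    early: list
    intermediate: list
    late: list
    loadings: pd.DataFrame  # genes x (PC1, PC2), sign-oriented


def _sample_pca(vst: pd.DataFrame):
    """PCA over samples (genes centered). Returns (scores, loadings, evr)."""
    X = vst.to_numpy(dtype=float).T  # samples x genes
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    evr = var / var.sum() if var.sum() > 0 else var
    scores = U * S
    return scores, Vt, evr


def stage_gene_sets(norm: pd.DataFrame, design: pd.DataFrame,
                    loading_set_size: int = 750) -> StageGeneSets:
    """Early / intermediate / late stage-biased gene sets from whole-
    transcriptome PC loadings; sets are made disjoint with priority
    early > intermediate > late, and each set is restricted to loadings of
    the correct sign (truncated with a warning when fewer qualify)."""
    if norm.shape[1] < 3:
        raise ValueError("need at least 3 samples for stage PCA")
    design = design.loc[norm.columns]
    vst = np.log1p(norm)
    scores, Vt, _ = _sample_pca(vst)
    stage_rank = design["stage"].map(STAGE_ORDER).to_numpy(dtype=float)
    # orient PC1 against stage (early samples positive), PC2 against a
    # mid-stage indicator (intermediate-peaking genes load negative)
    pc1, pc2 = Vt[0].copy(), Vt[1].copy()
    s1, s2 = scores[:, 0].copy(), scores[:, 1].copy()
    if np.corrcoef(s1, stage_rank)[0, 1] > 0:
        pc1, s1 = -pc1, -s1
    mid = (design["stage"] == "D15").to_numpy(dtype=float)
    if np.corrcoef(s2, mid)[0, 1] > 0:
        pc2, s2 = -pc2, -s2
    loadings = pd.DataFrame({"PC1": pc1, "PC2": pc2}, index=norm.index)

    def take(series, sign, k, exclude):
        vals = series[~series.index.isin(exclude)]
        vals = vals[vals > 0] if sign > 0 else vals[vals < 0]
        if len(vals) < k:
            logger.warning("only %d genes with the requested loading sign "
                           "(asked for %d)", len(vals), k)
            k = len(vals)
        ordered = (vals * sign).sort_values(ascending=False)
        return list(ordered.index[:k])

    # disjointness priority: early and late are defined on the dominant
    # stage axis (PC1) and claim their genes first; intermediate then takes
    # the most negative PC2 loadings among the remainder, so a low-variance
    # PC2 cannot steal stage-axis genes
    early = take(loadings["PC1"], +1, loading_set_size, set())
    late = take(loadings["PC1"], -1, loading_set_size, set(early))
    intermediate = take(loadings["PC2"], -1, loading_set_size,
                        set(early) | set(late))
    return StageGeneSets(early, intermediate, late, loadings)


def or_pca(norm: pd.DataFrame, design: pd.DataFrame, or_genes):
    """PCA of samples restricted to Or genes (trajectory plotting aid).
    Returns (per-sample coordinates, explained-variance fractions)."""
    or_genes = [g for g in or_genes if g in norm.index]
    if len(or_genes) < 2:
        raise ValueError("need at least 2 Or genes for Or-only PCA")
    vst = np.log1p(norm.loc[or_genes])
    scores, _, evr = _sample_pca(vst)
    k = min(scores.shape[1], 10)
    coords = pd.DataFrame(
        scores[:, :k], index=norm.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return coords, evr[:k]
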
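"""Per-cell receptor "expressing / not expressing" calls.

Each neuronal cell is tested gene by gene: the gene's log-normalized
expression over the focal cell plus its graph neighbors is compared against a
single fixed set of 100 randomly chosen WT nonneuronal cells with a one-sided
Mann-Whitney U test (alternative: neighborhood stochastically greater). A
raw p-value cutoff (0.05) labels the cell as expressing the gene; no
multiple-testing correction is applied, faithfully to the source protocol
(documented as anti-conservative). Rank tests are invariant to the monotone
log transform, so testing log-normalized values equals testing CP10k.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io import RECEPTOR_CLASSES, genes_of_class

logger = logging.getLogger("antseq")

EXACT_MAX_N = 12  # total sample size up to which the exact branch is used


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 0.5 #{ties}."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_greater(x, y) -> float:
    """One-sided (greater) Mann-Whitney p-value.

    For n+m <= ``EXACT_MAX_N`` the p-value is exact: every C(n+m, n) split of
    the pooled values is enumerated and ties contribute through midranks, so
    tied data are handled without approximation. Larger samples use the
    tie-corrected normal approximation with continuity correction. Fully
    tied data (e.g. all zeros) give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("empty neighborhood sample")
    if y.size == 0:
        raise ValueError("empty background sample")
    pooled = np.concatenate([x, y])
    if pooled.max() == pooled.min():
        return 1.0
    n, m = x.size, y.size
    if n + m <= EXACT_MAX_N:
        u_obs = _u_statistic(x, y)
        total = comb(n + m, n)
        hits = 0
        idx_all = range(n + m)
        for subset in combinations(idx_all, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(subset)] = True
            if _u_statistic(pooled[mask], pooled[~mask]) >= u_obs - 1e-9:
                hits += 1
        return hits / total
    res = mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def call_gene_in_cell(neighborhood_values, background_values, alpha: float = 0.05):
    """Test one gene in one cell's neighborhood. Returns ``(p, call)``."""
    p = mann_whitney_greater(neighborhood_values, background_values)
    return p, bool(p < alpha)


# ---------------------------------------------------------------------------
# background set

@dataclass
class BackgroundSet:
    cell_ids: list
    draw_seed: int

    @property
    def size(self) -> int:
        return len(self.cell_ids)


def draw_background(meta: pd.DataFrame, nonneuronal: pd.Series,
                    size: int = 100, seed: int = 0) -> BackgroundSet:
    """Uniform sample (without replacement) of WT nonneuronal cells, reused
    for every gene and every focal cell in a run."""
    nonneuronal = nonneuronal.loc[meta.index]
    eligible = meta.index[(meta["genotype"] == "WT") & nonneuronal.to_numpy()]
    if len(eligible) < size:
        raise ValueError(
            f"only {len(eligible)} eligible WT nonneuronal cells; "
            f"{size} required (shortfall {size - len(eligible)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=size, replace=False)
    return BackgroundSet(list(eligible[np.sort(chosen)]), seed)


# ---------------------------------------------------------------------------
# call matrix

@dataclass
class CallMatrix:
    calls: pd.DataFrame  # bool, cells x receptor genes
    pvals: pd.DataFrame
    alpha: float


def receptor_gene_list(annotation: pd.DataFrame, gene_ids) -> list:
    present = set(gene_ids)
    rec = [g for g in genes_of_class(annotation, *RECEPTOR_CLASSES)]
    missing = [g for g in rec if g not in present]
    for g in missing:
        logger.warning("receptor gene %s absent from matrix; column skipped", g)
    return [g for g in rec if g in present]


def build_call_matrix(norm: np.ndarray, cell_ids, gene_ids, embedding,
                      background: BackgroundSet, receptor_genes,
                      neuronal_mask, alpha: float = 0.05) -> CallMatrix:
    """Apply the neighborhood-vs-background test to every neuronal cell and
    receptor gene. Nonneuronal cells get all-false rows (they are classified
    at cluster level). Neighborhood = focal cell plus its graph neighbors,
    so every test is n_neighbors+1 vs background_size values and always takes
    the tie-corrected asymptotic branch; columns with no variation give p=1.
    """
    cell_ids = list(cell_ids)
    pos = {c: i for i, c in enumerate(cell_ids)}
    gpos = {g: j for j, g in enumerate(gene_ids)}
    rcols = np.array([gpos[g] for g in receptor_genes], dtype=int)
    bg_idx = np.array([pos[c] for c in background.cell_ids], dtype=int)
    bg = norm[np.ix_(bg_idx, rcols)]

    n_cells = len(cell_ids)
    pvals = np.ones((n_cells, len(rcols)))
    neuronal_mask = np.asarray(neuronal_mask, dtype=bool)
    for i in np.flatnonzero(neuronal_mask):
        nb_rows = np.concatenate([[i], embedding.neighbor_indices[i]])
        sub = norm[np.ix_(nb_rows, rcols)]
        stacked = np.vstack([sub, bg])
        varying = stacked.max(axis=0) > stacked.min(axis=0)
        if varying.any():
            with np.errstate(invalid="ignore", divide="ignore"):
                res = mannwhitneyu(
                    sub[:, varying], bg[:, varying],
                    alternative="greater", method="asymptotic", axis=0,
                )
            p = np.ones(len(rcols))
            p[varying] = np.nan_to_num(res.pvalue, nan=1.0)
            pvals[i] = p
    calls = pvals < alpha
    calls_df = pd.DataFrame(calls, index=cell_ids, columns=list(receptor_genes))
    pvals_df = pd.DataFrame(pvals, index=cell_ids, columns=list(receptor_genes))
    return CallMatrix(calls_df, pvals_df, alpha)
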
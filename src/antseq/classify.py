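"""Cluster-level gating of major cell classes, per-cell receptor-combination
categories, and WT/mutant survival accounting.

A cluster is neuronal iff it expresses all four neuron markers
(nSyb/fne/Syt1/onecut analogues) simultaneously; nonneuronal clusters are
then labeled glia (repo), muscle (Mhc), epithelium (grh), or support (sv) by
the same rule, first match in that order. "Cluster expresses marker" means
>= 25% of member cells have a nonzero count AND the cluster mean normalized
expression exceeds the overall mean — a desk-scale reconstruction; the
source protocol prints no threshold.

Neuronal cells are then placed into receptor-combination categories by a
first-match-wins rule table over the predicates {any tuning Or, orco, any
tuning Ir, any irco, any Gr, Rh50, nompC}. The default table reconstructs
the published category list; it is data, not code, and can be edited.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .io import genes_of_class
from .simulate import NEURONAL_CATEGORIES, NONNEURONAL_CATEGORIES

logger = logging.getLogger("antseq")

PREDICATES = ("any_or", "orco", "any_ir", "any_irco", "any_gr", "rh50", "nompc")


@dataclass
class MarkerPanel:
    neuron: list
    glia: list
    muscle: list
    epithelium: list
    support: list

    @classmethod
    def from_annotation(cls, annotation: pd.DataFrame) -> "MarkerPanel":
        return cls(
            neuron=genes_of_class(annotation, "neuron_marker"),
            glia=genes_of_class(annotation, "glia_marker"),
            muscle=genes_of_class(annotation, "muscle_marker"),
            epithelium=genes_of_class(annotation, "epithelium_marker"),
            support=genes_of_class(annotation, "support_marker"),
        )


def default_category_rules() -> list:
    """Ordered (category, predicate->bool) rules; ``None``/absent = don't
    care. First match wins; the trailing catch-alls make the table
    exhaustive."""
    return [
        # nompC/Rh50 co-calls with co-receptors resolve in favor of the
        # specific marker (the published predicate ordering is unstated)
        ("mechanosensory", {"nompc": True, "any_or": False}),
        ("ammonia_Rh50", {"rh50": True, "any_or": False}),
        ("orco_Ir_irco", {"orco": True, "any_ir": True, "any_irco": True}),
        ("OrX_orco_Gr", {"any_or": True, "orco": True, "any_gr": True}),
        ("OrX_orco_irco", {"any_or": True, "orco": True, "any_irco": True}),
        ("OrX_orco", {"any_or": True, "orco": True}),
        ("orco_only", {"orco": True}),
        ("Ir_irco", {"any_ir": True, "any_irco": True, "any_gr": False}),
        ("Gr_only", {"any_gr": True, "any_ir": False, "any_irco": False}),
        # remaining chemoreceptor combinations (e.g. Gr with co-receptor)
        ("Gr_or_Ir_with_coreceptor", {"any_gr": True}),
        ("Gr_or_Ir_with_coreceptor", {"any_ir": True}),
        ("Gr_or_Ir_with_coreceptor", {"any_irco": True}),
        ("neuron_unclassified", {}),
    ]


def _rules_exhaustive(rules) -> bool:
    return any(not preds for _, preds in rules)


def gate_clusters(norm: np.ndarray, counts_csr, gene_ids, clusters,
                  panel: MarkerPanel, min_frac: float = 0.25) -> dict:
    """Label each cluster neuronal / glia / muscle / epithelium / support /
    other_nonneuronal. Returns {cluster_id: label}."""
    gene_ids = list(gene_ids)
    gpos = {g: j for j, g in enumerate(gene_ids)}
    clusters = np.asarray(clusters)
    overall_mean = norm.mean(axis=0)
    nz = np.asarray((counts_csr > 0).todense())

    def expresses(cluster_idx, gene) -> bool:
        j = gpos[gene]
        frac = nz[cluster_idx, j].mean()
        return frac >= min_frac and norm[cluster_idx, j].mean() > overall_mean[j]

    labels = {}
    for c in sorted(set(clusters.tolist())):
        idx = np.flatnonzero(clusters == c)
        if idx.size == 0:
            raise ValueError(f"cluster {c} is empty")
        if all(expresses(idx, g) for g in panel.neuron):
            labels[c] = "neuronal"
            continue
        for label, markers in (
            ("glia", panel.glia), ("muscle", panel.muscle),
            ("epithelium", panel.epithelium), ("support", panel.support),
        ):
            if markers and all(expresses(idx, g) for g in markers):
                labels[c] = label
                break
        else:
            labels[c] = "other_nonneuronal"
    return labels


def call_predicates(call_row: pd.Series, gene_classes: pd.Series) -> dict:
    """Collapse per-gene calls into the seven receptor-class predicates."""
    cls = gene_classes.loc[call_row.index]
    called = call_row.astype(bool)
    return {
        "any_or": bool(called[cls == "tuning_Or"].any()),
        "orco": bool(called[cls == "orco"].any()),
        "any_ir": bool(called[cls == "tuning_Ir"].any()),
        "any_irco": bool(called[cls == "irco"].any()),
        "any_gr": bool(called[cls == "Gr"].any()),
        "rh50": bool(called[cls == "Rh50"].any()),
        "nompc": bool(called[cls == "nompC"].any()),
    }


def assign_category(predicates: dict, cluster_class: str, rules=None) -> str:
    """Nonneuronal cells keep their cluster label; neuronal cells take the
    first matching rule."""
    if cluster_class != "neuronal":
        return cluster_class
    if rules is None:
        rules = default_category_rules()
    if not _rules_exhaustive(rules):
        raise ValueError("rule table is not exhaustive (no catch-all rule)")
    for label, wanted in rules:
        if all(predicates[k] == v for k, v in wanted.items()):
            return label
    raise AssertionError("unreachable: exhaustive rule table had no match")


def assign_categories(call_matrix, annotation: pd.DataFrame, clusters,
                      cluster_labels: dict, rules=None) -> pd.Series:
    """Vectorized category assignment for all cells."""
    calls = call_matrix.calls
    cls = annotation["gene_class"]
    col_cls = cls.loc[calls.columns]
    mats = {
        "any_or": calls.loc[:, col_cls == "tuning_Or"].any(axis=1),
        "orco": calls.loc[:, col_cls == "orco"].any(axis=1),
        "any_ir": calls.loc[:, col_cls == "tuning_Ir"].any(axis=1),
        "any_irco": calls.loc[:, col_cls == "irco"].any(axis=1),
        "any_gr": calls.loc[:, col_cls == "Gr"].any(axis=1),
        "rh50": calls.loc[:, col_cls == "Rh50"].any(axis=1),
        "nompc": calls.loc[:, col_cls == "nompC"].any(axis=1),
    }
    clusters = np.asarray(clusters)
    out = []
    for i, cell in enumerate(calls.index):
        cluster_class = cluster_labels[clusters[i]]
        preds = {k: bool(v.iloc[i]) for k, v in mats.items()}
        out.append(assign_category(preds, cluster_class, rules))
    return pd.Series(out, index=calls.index, name="category")


# ---------------------------------------------------------------------------
# survival accounting

def survival_table(categories: pd.Series, meta: pd.DataFrame):
    """Per-category WT/mutant tallies.

    Returns ``(table, summary)``. The table holds counts, within-genotype
    fractions (each genotype's fractions sum to 1), the mutant/WT count ratio
    (the survival readout when both genotypes start from equal-size
    pre-ablation cohorts), a depletion odds ratio with Haldane-Anscombe 0.5
    correction when any cell of the 2x2 is zero, and a two-sided
    hypergeometric (Fisher) p — the latter two are extensions; the source
    study reports proportions without a test. The summary carries the
    overall neuron fraction per genotype.
    """
    meta = meta.loc[categories.index]
    gt = meta["genotype"]
    n_wt_total = int((gt == "WT").sum())
    n_mut_total = int((gt == "mutant").sum())
    rows = []
    order = [c for c in (*NEURONAL_CATEGORIES, *NONNEURONAL_CATEGORIES)
             if c in set(categories)]
    extra = [c for c in pd.unique(categories) if c not in order]
    for cat in order + sorted(extra):
        in_cat = categories == cat
        n_wt = int((in_cat & (gt == "WT")).sum())
        n_mut = int((in_cat & (gt == "mutant")).sum())
        if n_wt == 0 and n_mut == 0:
            logger.info("category %s has no cells; excluded from table", cat)
            continue
        f_wt = n_wt / n_wt_total if n_wt_total else np.nan
        f_mut = n_mut / n_mut_total if n_mut_total else np.nan
        ratio = n_mut / n_wt if n_wt > 0 else np.nan
        a, b = n_mut, n_mut_total - n_mut
        c, d = n_wt, n_wt_total - n_wt
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds = (a / b) / (c / d)
        _, p = fisher_exact(
            [[n_mut, n_mut_total - n_mut], [n_wt, n_wt_total - n_wt]],
            alternative="two-sided",
        )
        rows.append((cat, n_wt, n_mut, f_wt, f_mut, ratio, odds, p))
    table = pd.DataFrame(
        rows,
        columns=["category", "n_WT", "n_mutant", "fraction_of_genotype_WT",
                 "fraction_of_genotype_mutant", "mutant_to_wt_ratio",
                 "depletion_odds_ratio", "p"],
    ).set_index("category")
    neuronal = set(NEURONAL_CATEGORIES)
    is_neuron = categories.isin(neuronal)
    summary = {
        "neuron_fraction_WT":
            float(is_neuron[gt == "WT"].mean()) if n_wt_total else np.nan,
        "neuron_fraction_mutant":
            float(is_neuron[gt == "mutant"].mean()) if n_mut_total else np.nan,
        "n_WT": n_wt_total,
        "n_mutant": n_mut_total,
    }
    return table, summary
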
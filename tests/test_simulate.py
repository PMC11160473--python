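import numpy as np
import pandas as pd
import pytest

import antseq as a
from antseq.simulate import (
    CellProgram,
    NEURONAL_CATEGORIES,
    default_cell_programs,
    retained_or_genes,
)


def test_default_programs_cover_categories(annotation):
    programs = default_cell_programs(annotation)
    labels = {p.category_label for p in programs}
    assert {"mechanosensory", "ammonia_Rh50", "Gr_only", "Ir_irco",
            "orco_Ir_irco", "OrX_orco", "OrX_orco_Gr", "OrX_orco_irco",
            "orco_only", "glia", "muscle", "epithelium", "support",
            "other_nonneuronal"} <= labels
    assert abs(sum(p.weight for p in programs) - 1) < 1e-9


def test_mixture_weights_must_sum_to_one(annotation):
    programs = default_cell_programs(annotation)
    programs[0].weight += 0.2
    with pytest.raises(ValueError, match="sum"):
        a.simulate_antennal_snrnaseq(annotation, programs, n_per_genotype=50)


def test_unknown_program_gene_rejected(annotation):
    bad = CellProgram("p", "glia", {"not_a_gene": 1.0}, {"WT": 1, "mutant": 1}, 1.0)
    with pytest.raises(ValueError, match="unknown genes"):
        a.simulate_antennal_snrnaseq(annotation, [bad], n_per_genotype=10)


def test_survival_probability_bounds():
    with pytest.raises(ValueError):
        CellProgram("p", "glia", {}, {"WT": 1.2, "mutant": 0.0}, 1.0)


def test_full_survival_gives_identical_mixtures(annotation):
    programs = default_cell_programs(annotation)
    for p in programs:
        p.genotype_survival = {"WT": 1.0, "mutant": 1.0}
    counts, meta, truth = a.simulate_antennal_snrnaseq(
        annotation, programs, n_per_genotype=4000, seed=0
    )
    gt = meta["genotype"]
    fw = truth.cell_category[gt == "WT"].value_counts(normalize=True)
    fm = truth.cell_category[gt == "mutant"].value_counts(normalize=True)
    assert (gt == "mutant").sum() == 4000  # nothing thinned
    diff = (fw - fm).abs().max()
    assert diff < 0.03


def test_realized_mixture_converges_to_weights(annotation):
    """Law of large numbers at n=10,000 (WT side): 2 pp tolerance."""
    programs = default_cell_programs(annotation)
    counts, meta, truth = a.simulate_antennal_snrnaseq(
        annotation, programs, n_per_genotype=10000, seed=2
    )
    wt = truth.cell_category[meta["genotype"] == "WT"]
    want = pd.Series(0.0, index=wt.unique())
    for p in programs:
        if p.category_label in want.index:
            want[p.category_label] += p.weight
    got = wt.value_counts(normalize=True)
    assert (got - want).abs().max() < 0.02


def test_poisson_limit_of_dispersion():
    """variance/mean -> 1 as the NB size parameter grows."""
    ann = a.make_gene_annotation([("g1", "other", "s", 1, 100, "+")])
    prog = CellProgram("p", "glia", {"g1": 5.0}, {"WT": 1, "mutant": 1}, 1.0)
    counts, _, _ = a.simulate_antennal_snrnaseq(
        ann, [prog], n_per_genotype=4000, seed=3, dispersion=1e6,
        depth_sigma=1e-9, batch_sigma=0.0,
    )
    x = np.asarray(counts.values.todense(), float).ravel()
    assert abs(x.var() / x.mean() - 1) < 0.05


def test_depth_distribution_matches_lognormal(annotation):
    """Per-cell depth spread matches the configured log-normal within 5%."""
    counts, meta, _ = a.simulate_antennal_snrnaseq(
        annotation, n_per_genotype=2500, seed=4, depth_sigma=0.2
    )
    tot = np.asarray(counts.values.sum(axis=1), float).ravel()
    assert abs(np.std(np.log(tot)) - 0.2) / 0.2 < 0.3  # plus count noise


def test_counts_nonnegative_integers(sn_small):
    counts, _, _ = sn_small
    assert counts.values.min() >= 0
    assert counts.values.dtype.kind == "i"


def test_mutant_cohort_is_thinned(sn_small):
    counts, meta, truth = sn_small
    gt = meta["genotype"]
    assert (gt == "WT").sum() == 400
    assert 0.25 * 400 < (gt == "mutant").sum() < 0.55 * 400
    # ablated categories almost absent from the mutant
    mut = truth.cell_category[gt == "mutant"]
    assert (mut == "OrX_orco").mean() < 0.05


# ---------------------------------------------------------------------------
# bulk time course

def test_bulk_or_collapse_contract(annotation, bulk_fixture):
    counts, design, truth = bulk_fixture
    df = pd.DataFrame(counts.values, index=counts.gene_ids,
                      columns=counts.cell_ids)
    or_like = truth.bulk_class[truth.bulk_class == "or_like"].index
    mut = design[design["genotype"] == "mutant"]
    d15 = df.loc[or_like, mut.index[mut["stage"] == "D15"]].mean(axis=1).mean()
    d20 = df.loc[or_like, mut.index[mut["stage"] == "D20"]].mean(axis=1).mean()
    assert d20 <= 0.2 * d15


def test_bulk_early_peaks_at_d10(annotation, bulk_fixture):
    counts, design, truth = bulk_fixture
    df = pd.DataFrame(counts.values, index=counts.gene_ids,
                      columns=counts.cell_ids)
    early = truth.bulk_class[truth.bulk_class == "early"].index
    for gt in ("WT", "mutant"):
        sub = design[design["genotype"] == gt]
        means = {st: df.loc[early, sub.index[sub["stage"] == st]].to_numpy().mean()
                 for st in ("D10", "D15", "D20", "D25")}
        assert max(means, key=means.get) == "D10"


def test_bulk_depth_factor_recovered_by_size_factors(annotation):
    """A sample simulated at 2x depth gets ~2x the size factor of its
    replicate (median-of-ratios oracle on the generator)."""
    counts, design, _ = a.simulate_bulk_timecourse(
        annotation, n_reps=2, seed=9, depth_sigma=1e-9
    )
    vals = counts.values.copy()
    j = list(counts.cell_ids).index("WT_D10_r2")
    vals[:, j] *= 2
    doubled = a.CountMatrix(vals, counts.cell_ids, counts.gene_ids, mode="bulk")
    f = a.size_factors_median_of_ratios(doubled)
    assert abs(f["WT_D10_r2"] / f["WT_D10_r1"] - 2) < 0.05


def test_bulk_few_replicates_warns(annotation, caplog):
    import logging
    with caplog.at_level(logging.WARNING, logger="antseq"):
        a.simulate_bulk_timecourse(annotation, n_reps=1, seed=0)
    assert any("replicate" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# tandem-cluster pair

def test_cluster_pair_clean_case():
    la, lb, tab, truth = a.simulate_cluster_pair(30, 0.0, 0.0, seed=0)
    assert len(lb) == 30
    for i, g in enumerate(la):
        rows = tab[tab["query"] == g]
        best_bit = rows.loc[rows["bit_score"].idxmax(), "subject"]
        best_id = rows.loc[rows["pct_identity"].idxmax(), "subject"]
        assert best_bit == best_id == truth.id_matching[g]


def test_cluster_pair_truncated_gene_scores_wrong_but_identity_right():
    for seed in range(5):
        la, lb, tab, truth = a.simulate_cluster_pair(20, 0.1, 0.0, seed=seed)
        for g in truth.truncated_genes:
            rows = tab[tab["query"] == g]
            best_bit = rows.loc[rows["bit_score"].idxmax(), "subject"]
            best_id = rows.loc[rows["pct_identity"].idxmax(), "subject"]
            assert best_id == truth.id_matching[g]
            assert best_bit != truth.id_matching[g]


def test_cluster_pair_collapsed_bookkeeping():
    la, lb, tab, truth = a.simulate_cluster_pair(100, 0.0, 0.05, seed=1)
    collapsed = [g for g, m in truth.id_matching.items() if m is None]
    assert sorted(collapsed) == sorted(truth.collapsed_genes)
    assert len(collapsed) == 5
    assert len(lb) == 95
    assert not set(tab["subject"]) & (set(f"LOC{90001+i}" for i in range(100))
                                      - set(lb))


def test_cluster_pair_fraction_precondition():
    with pytest.raises(ValueError):
        a.simulate_cluster_pair(10, 0.6, 0.5, seed=0)
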
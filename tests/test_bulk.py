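import numpy as np
import pandas as pd
import pytest

import antseq as a
from antseq.bulk import normalize_bulk


def _bulk(values, samples=None, genes=None):
    values = np.asarray(values)
    samples = samples or [f"s{i+1}" for i in range(values.shape[1])]
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    return a.CountMatrix(values, samples, genes, mode="bulk")


def test_size_factors_hand_example():
    cm = _bulk(np.array([[2, 4], [4, 8], [8, 16]]))
    f = a.size_factors_median_of_ratios(cm)
    assert f["s1"] == pytest.approx(0.7071, abs=1e-4)
    assert f["s2"] == pytest.approx(1.4142, abs=1e-4)
    assert f["s2"] / f["s1"] == pytest.approx(2.0, abs=1e-9)


def test_size_factors_identity_and_equivariance():
    rng = np.random.default_rng(0)
    base = rng.integers(5, 100, size=(40, 4))
    same = _bulk(np.repeat(base[:, :1], 4, axis=1))
    assert np.allclose(a.size_factors_median_of_ratios(same), 1.0)
    cm = _bulk(base)
    f = a.size_factors_median_of_ratios(cm)
    doubled = base.copy()
    doubled[:, 2] *= 2
    f2 = a.size_factors_median_of_ratios(_bulk(doubled))
    # doubling one sample doubles its factor relative to every other sample
    assert f2["s3"] / f2["s1"] == pytest.approx(2 * f["s3"] / f["s1"])
    # global scaling leaves the factors (reference rescales too) unchanged
    f3 = a.size_factors_median_of_ratios(_bulk(base * 5))
    assert np.allclose(f3, f.to_numpy())
    assert np.allclose(normalize_bulk(_bulk(base * 5)),
                       5 * normalize_bulk(cm).to_numpy())


def test_size_factors_need_common_nonzero_gene():
    cm = _bulk(np.array([[0, 3], [5, 0]]))
    with pytest.raises(ValueError, match="nonzero"):
        a.size_factors_median_of_ratios(cm)


def test_fpkm_unit_case_and_scaling():
    cm = _bulk(np.array([[100], [0]]))
    lengths = pd.Series([1000.0, 500.0], index=["g1", "g2"])
    totals = pd.Series([1e6], index=["s1"])
    out = a.fpkm(cm, lengths, totals)
    assert out.at["g1", "s1"] == pytest.approx(100.0)
    assert out.at["g2", "s1"] == 0.0
    out2 = a.fpkm(cm, lengths * 2, totals)
    assert out2.at["g1", "s1"] == pytest.approx(50.0)
    with pytest.raises(ValueError, match="total"):
        a.fpkm(cm, lengths, pd.Series([0.0], index=["s1"]))


def _design(stages, genotypes, reps=1):
    rows = []
    for gt in genotypes:
        for st_ in stages:
            for r in range(1, reps + 1):
                rows.append((f"{gt}_{st_}_r{r}", st_, gt, r))
    return pd.DataFrame(rows, columns=["sample_id", "stage", "genotype",
                                       "replicate"]).set_index("sample_id")


def test_scaled_trajectory_max_scaling():
    design = _design(["D10", "D15", "D20", "D25"], ["WT"])
    norm = pd.DataFrame([[10, 20, 40, 40]], index=["g1"], columns=design.index)
    ts = a.scaled_trajectory(norm, design, ["g1"])
    assert np.allclose(ts.profiles.loc["g1"], [0.25, 0.5, 1.0, 1.0])
    assert (ts.summary["mean"] <= 1).all() and (ts.summary["mean"] >= 0).all()


def test_scaled_trajectory_identical_shapes_zero_sd():
    design = _design(["D10", "D15"], ["WT"])
    norm = pd.DataFrame([[5, 10], [50, 100]], index=["g1", "g2"],
                        columns=design.index)
    ts = a.scaled_trajectory(norm, design, ["g1", "g2"])
    assert np.allclose(ts.summary["sd"], 0.0)


def test_scaled_trajectory_drops_all_zero_genes():
    design = _design(["D10", "D15"], ["WT"])
    norm = pd.DataFrame([[5, 10], [0, 0]], index=["g1", "g2"],
                        columns=design.index)
    ts = a.scaled_trajectory(norm, design, ["g1", "g2"])
    assert list(ts.profiles.index) == ["g1"]


def test_or_trajectory_mutant_collapse(annotation, bulk_fixture):
    counts, design, truth = bulk_fixture
    normed = normalize_bulk(counts)
    or_like = list(truth.bulk_class[truth.bulk_class == "or_like"].index)
    ts = a.scaled_trajectory(normed, design, or_like)
    s = ts.summary["mean"]
    assert s[("mutant", "D20")] < 0.5 * s[("mutant", "D15")]
    assert s[("WT", "D20")] > 0.5 * s[("WT", "D15")]


def test_stage_gene_sets_two_gene_toy():
    design = _design(["D10", "D15", "D20", "D25"], ["WT"])
    norm = pd.DataFrame(
        [[100, 60, 30, 10], [10, 30, 60, 100]],
        index=["gA", "gB"], columns=design.index,
    )
    sets = a.stage_gene_sets(norm, design, loading_set_size=1)
    assert sets.early == ["gA"] and sets.late == ["gB"]


def test_stage_gene_sets_disjoint_and_order_invariant(annotation, bulk_fixture):
    counts, design, _ = bulk_fixture
    normed = normalize_bulk(counts)
    sets = a.stage_gene_sets(normed, design, loading_set_size=150)
    s1, s2, s3 = map(set, (sets.early, sets.intermediate, sets.late))
    assert not (s1 & s2 or s1 & s3 or s2 & s3)
    perm = np.random.default_rng(0).permutation(len(normed))
    sets_p = a.stage_gene_sets(normed.iloc[perm], design, loading_set_size=150)
    assert set(sets_p.early) == s1 and set(sets_p.late) == s3


def test_stage_gene_sets_requires_three_samples():
    design = _design(["D10"], ["WT"], reps=2)
    norm = pd.DataFrame([[1, 2]], index=["g"], columns=design.index)
    with pytest.raises(ValueError, match="3 samples"):
        a.stage_gene_sets(norm, design)


def test_or_pca_identical_genotypes_overlap():
    design = _design(["D10", "D15"], ["WT", "mutant"], reps=1)
    prof = np.array([[10.0, 50, 10, 50], [40, 5, 40, 5], [7, 7, 7, 7]])
    norm = pd.DataFrame(prof, index=["Or1", "Or2", "Or3"], columns=design.index)
    coords, evr = a.or_pca(norm, design, ["Or1", "Or2", "Or3"])
    wt = coords.loc[["WT_D10_r1", "WT_D15_r1"]].to_numpy()
    mut = coords.loc[["mutant_D10_r1", "mutant_D15_r1"]].to_numpy()
    assert np.abs(wt - mut).max() < 1e-8
    with pytest.raises(ValueError, match="2 Or genes"):
        a.or_pca(norm, design, ["Or1"])


def test_or_pca_separates_collapsed_mutant(annotation, bulk_fixture):
    counts, design, truth = bulk_fixture
    normed = normalize_bulk(counts)
    or_genes = a.genes_of_class(annotation, "tuning_Or")
    coords, _ = a.or_pca(normed, design, or_genes)
    late = design[(design["stage"].isin(["D20", "D25"]))]
    wt = coords.loc[late.index[late["genotype"] == "WT"], ["PC1", "PC2"]]
    mut = coords.loc[late.index[late["genotype"] == "mutant"], ["PC1", "PC2"]]
    from sklearn.metrics import silhouette_score
    X = np.r_[wt.to_numpy(), mut.to_numpy()]
    labels = [0] * len(wt) + [1] * len(mut)
    assert silhouette_score(X, labels) > 0
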
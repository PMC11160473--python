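import numpy as np
import pytest

import antseq as a


@pytest.fixture(scope="session")
def annotation():
    return a.default_gene_annotation()


@pytest.fixture(scope="session")
def sn_small(annotation):
    """Small single-nucleus fixture for unit tests."""
    return a.simulate_antennal_snrnaseq(annotation, n_per_genotype=400, seed=5)


@pytest.fixture(scope="session")
def bulk_fixture(annotation):
    return a.simulate_bulk_timecourse(annotation, seed=5)


@pytest.fixture(scope="session")
def full_run(annotation, tmp_path_factory):
    """Default desk-scale end-to-end run (2,000 cells per genotype pre-
    ablation), shared by the acceptance tests."""
    counts, meta, truth = a.simulate_antennal_snrnaseq(
        annotation, n_per_genotype=2000, seed=1
    )
    cfg = a.PipelineConfig(rng_seed=1)
    out = tmp_path_factory.mktemp("full_run")
    res = a.run_pipeline(cfg, out, sn=(counts, meta), annotation=annotation,
                         stages=["survival"])
    return {"counts": counts, "meta": meta, "truth": truth, "config": cfg,
            "results": res}


def mann_whitney_enumeration_oracle(x, y):
    """Independent brute-force oracle: one-sided permutation p-value of the
    Mann-Whitney test via midranks over all distinct group assignments."""
    from itertools import combinations

    import scipy.stats as st

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = st.rankdata(pooled)

    def u_from_ranks(idx):
        r = ranks[list(idx)].sum()
        return r - n * (n + 1) / 2

    u_obs = u_from_ranks(range(n))
    hits = total = 0
    for idx in combinations(range(len(pooled)), n):
        total += 1
        if u_from_ranks(idx) >= u_obs - 1e-9:
            hits += 1
    return hits / total
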
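"""End-to-end pipeline: chains QC, embedding, receptor calling,
classification, survival accounting, bulk trajectory analysis, retained-Or
detection, and ID transfer, writing every intermediate table as TSV.

The whole run is a pure function of (inputs, config incl. rng_seed): all
random draws flow from per-stage substreams of the config seed, and output
files are written with fixed float formatting, so identical runs are
byte-identical.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bulk as bulk_mod
from . import calling, classify, lift, qc, retained
from .io import (
    CountMatrix,
    PipelineConfig,
    genes_of_class,
    write_tsv,
)

logger = logging.getLogger("antseq")

SN_STAGES = ("qc", "embed", "call", "classify", "survival")
ALL_STAGES = SN_STAGES + ("bulk", "retained", "lift")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _expand_stages(stages):
    if stages == "all":
        return list(ALL_STAGES)
    stages = list(stages)
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stage(s) {sorted(bad)}")
    # a single-nucleus stage implies its predecessors
    wanted = set(stages)
    for s in stages:
        if s in SN_STAGES:
            wanted.update(SN_STAGES[: SN_STAGES.index(s)])
    if "retained" in wanted:
        wanted.update(SN_STAGES[:4])  # needs calls/gating and bulk
        wanted.add("bulk")
    return [s for s in ALL_STAGES if s in wanted]


def run_pipeline(
    config: PipelineConfig,
    outdir,
    sn=None,
    bulk=None,
    pair=None,
    annotation: pd.DataFrame = None,
    rrna_ids=(),
    stages="all",
):
    """Execute the requested stages and write their outputs under ``outdir``.

    Parameters
    ----------
    sn : (CountMatrix, cell_meta) or None
        Single-nucleus counts plus metadata (library_id, genotype).
    bulk : (CountMatrix, design) or None
        Bulk counts (genes x samples) plus the sample design table.
    pair : (list_a, list_b, similarity table) or None
        Ordered tandem-cluster gene lists with the precomputed similarity
        table for ID transfer.
    annotation : gene annotation table (required for sn/bulk/retained).

    Returns a dict with every in-memory result keyed by stage.
    """
    config.validate()
    stages = _expand_stages(stages)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_used.yaml")
    results: dict = {"stages": stages}

    def fail(stage, exc):
        raise PipelineError(stage, exc) from exc

    need_sn = [s for s in stages if s in SN_STAGES]
    if need_sn and sn is None:
        raise ValueError(f"stages {need_sn} require single-nucleus inputs")
    if ("bulk" in stages or "retained" in stages) and bulk is None:
        raise ValueError("bulk/retained stages require bulk inputs")
    if "lift" in stages and pair is None:
        raise ValueError("lift stage requires a cluster pair + similarity table")
    if need_sn or "bulk" in stages or "retained" in stages:
        if annotation is None:
            raise ValueError("gene annotation required")

    # --- single-nucleus branch -------------------------------------------
    if need_sn:
        counts, meta = sn
        try:
            meta = qc.compute_cell_qc(counts, annotation, meta)
            thresholds = qc.QCThresholds.from_config(config)
            counts_f, meta_f, removal = qc.filter_cells(
                counts, meta, thresholds, stage=qc.STAGE_STRINGENT
            )
            counts_f = qc.remove_rrna_genes(counts_f, rrna_ids)
            (out / "qc").mkdir(exist_ok=True)
            write_tsv(removal, out / "qc" / "removal_log.tsv", index=False)
            write_tsv(meta_f, out / "qc" / "cell_meta.tsv")
            results["qc"] = (counts_f, meta_f, removal)
        except PipelineError:
            raise
        except Exception as e:
            fail("qc", e)

    if "embed" in stages:
        try:
            norm = qc.normalize_cp10k_log1p(counts_f, scale=config.cp10k_scale)
            hvgs = qc.select_hvgs(counts_f, meta_f["library_id"],
                                  n_top=config.n_hvg, scale=config.cp10k_scale)
            hvg_idx = counts_f.gene_index(hvgs)
            latent, evr, elbow = qc.pca_embed(norm[:, hvg_idx], n_pcs=config.n_pcs)
            emb_seed = int(config.rng("embed").integers(2**31 - 1))
            embedding = qc.knn_cluster(
                latent, n_neighbors=config.n_neighbors,
                resolution=config.cluster_resolution, seed=emb_seed,
            )
            embedding.explained_variance = evr
            (out / "embed").mkdir(exist_ok=True)
            write_tsv(pd.DataFrame(latent, index=counts_f.cell_ids),
                      out / "embed" / "latent.tsv")
            write_tsv(
                pd.DataFrame({"cluster": embedding.clusters},
                             index=pd.Index(counts_f.cell_ids, name="cell_id")),
                out / "embed" / "clusters.tsv")
            results["embed"] = (norm, embedding, hvgs, elbow)
        except Exception as e:
            fail("embed", e)

    if "call" in stages:
        try:
            panel = classify.MarkerPanel.from_annotation(annotation)
            cluster_labels = classify.gate_clusters(
                norm, counts_f.values, counts_f.gene_ids,
                embedding.clusters, panel,
            )
            cell_class = pd.Series(
                [cluster_labels[c] for c in embedding.clusters],
                index=counts_f.cell_ids,
            )
            nonneuronal = cell_class != "neuronal"
            bg_seed = int(config.rng("background").integers(2**31 - 1))
            background = calling.draw_background(
                meta_f, nonneuronal, size=config.background_size, seed=bg_seed
            )
            rec_genes = calling.receptor_gene_list(annotation, counts_f.gene_ids)
            call_matrix = calling.build_call_matrix(
                norm, counts_f.cell_ids, counts_f.gene_ids, embedding,
                background, rec_genes, (~nonneuronal).to_numpy(),
                alpha=config.alpha,
            )
            (out / "call").mkdir(exist_ok=True)
            write_tsv(call_matrix.calls.astype(int), out / "call" / "calls.tsv")
            write_tsv(call_matrix.pvals, out / "call" / "pvals.tsv")
            results["call"] = (call_matrix, cluster_labels, cell_class, background)
        except Exception as e:
            fail("call", e)

    if "classify" in stages:
        try:
            categories = classify.assign_categories(
                call_matrix, annotation, embedding.clusters, cluster_labels
            )
            (out / "classify").mkdir(exist_ok=True)
            write_tsv(categories.to_frame(), out / "classify" / "categories.tsv")
            results["classify"] = categories
        except Exception as e:
            fail("classify", e)

    if "survival" in stages:
        try:
            table, summary = classify.survival_table(categories, meta_f)
            (out / "survival").mkdir(exist_ok=True)
            write_tsv(table, out / "survival" / "survival_table.tsv")
            write_tsv(pd.DataFrame(summary, index=[0]),
                      out / "survival" / "summary.tsv", index=False)
            results["survival"] = (table, summary)
        except Exception as e:
            fail("survival", e)

    # --- bulk branch ------------------------------------------------------
    if "bulk" in stages:
        try:
            bulk_counts, design = bulk
            factors = bulk_mod.size_factors_median_of_ratios(bulk_counts)
            normed = bulk_mod.normalize_bulk(bulk_counts, factors)
            lengths = (annotation["end"] - annotation["start"] + 1).astype(float)
            fpkm_tab = bulk_mod.fpkm(bulk_counts, lengths)
            or_genes = genes_of_class(annotation, "tuning_Or")
            traj = bulk_mod.scaled_trajectory(normed, design, or_genes)
            sets = bulk_mod.stage_gene_sets(
                normed, design, loading_set_size=config.loading_set_size
            )
            coords, or_evr = bulk_mod.or_pca(normed, design, or_genes)
            bdir = out / "bulk"
            bdir.mkdir(exist_ok=True)
            write_tsv(factors.to_frame(), bdir / "size_factors.tsv")
            write_tsv(traj.summary, bdir / "or_trajectory.tsv")
            for name in ("early", "intermediate", "late"):
                (bdir / f"stage_set_{name}.txt").write_text(
                    "".join(f"{g}\n" for g in getattr(sets, name))
                )
            write_tsv(coords, bdir / "or_pca.tsv")
            results["bulk"] = (factors, normed, fpkm_tab, traj, sets, coords)
        except Exception as e:
            fail("bulk", e)

    if "retained" in stages:
        try:
            or_genes = genes_of_class(annotation, "tuning_Or")
            records = retained.cross_platform_fc(
                counts_f, meta_f, fpkm_tab, design, or_genes
            )
            conc = retained.concordance(records)
            retained_list = retained.select_retained(
                records, config.fc_cutoff_sn, config.fc_cutoff_bulk
            )
            nonneuronal_cells = cell_class.index[cell_class != "neuronal"]
            coex = retained.neighbor_coexpression(
                counts_f, nonneuronal_cells, annotation, retained_list
            )
            rdir = out / "retained"
            rdir.mkdir(exist_ok=True)
            write_tsv(records, rdir / "fold_changes.tsv")
            write_tsv(pd.DataFrame(conc, index=[0]), rdir / "concordance.tsv",
                      index=False)
            (rdir / "retained.txt").write_text(
                "".join(f"{g}\n" for g in retained_list))
            write_tsv(coex, rdir / "coexpression.tsv")
            results["retained"] = (records, conc, retained_list, coex)
        except Exception as e:
            fail("retained", e)

    if "lift" in stages:
        try:
            list_a, list_b, similarity = pair
            rbh = lift.reciprocal_best_hits(similarity)
            assignments = lift.synteny_fill(
                rbh, list_a, list_b, similarity,
                min_identity=config.min_identity, gap_penalty=config.gap_penalty,
            )
            report = lift.transfer_report(assignments)
            ldir = out / "lift"
            ldir.mkdir(exist_ok=True)
            write_tsv(report["table"], ldir / "assignments.tsv")
            write_tsv(
                pd.DataFrame(report["tier_counts"], index=[0]),
                ldir / "tier_counts.tsv", index=False)
            results["lift"] = (assignments, report)
        except Exception as e:
            fail("lift", e)

    return results
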
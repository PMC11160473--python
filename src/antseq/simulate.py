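"""Ground-truth-labeled synthetic datasets.

Three generators mirror the three data modalities the analysis consumes:

* :func:`simulate_antennal_snrnaseq` — sparse negative-binomial UMI counts for
  WT and orco-mutant antennal nuclei, built from receptor-combination cell
  programs (orco/Or, orco/Ir/irco, Gr, nompC, Rh50, plus nonneuronal
  populations) with genotype-dependent ablation of Orco-dependent ORNs.
* :func:`simulate_bulk_timecourse` — pupal bulk RNA-seq counts over stages
  D10/D15/D20/D25 with early / intermediate / late programs and a
  mutant-specific post-D15 collapse of Or expression.
* :func:`simulate_cluster_pair` — two ordered tandem-cluster gene lists with a
  BLAST-like similarity table, including truncated-model and collapsed-region
  scenarios for the ID-transfer stage.

Counts are negative binomial parameterized by mean and size theta
(variance = mu + mu^2/theta); sparsity arises from small means, with no extra
zero-inflation. Ablation is simulated by *thinning*: both genotypes start
from equal-size cohorts and mutant cells of Orco-dependent programs are
dropped, so the mutant dataset is smaller — as the mutant library was in the
experiment this emulates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    MODE_BULK,
    MODE_SINGLE_NUCLEUS,
    CountMatrix,
    make_cell_meta,
    make_gene_annotation,
)

logger = logging.getLogger("antseq")

#: category labels assignable by the classifier; the generator uses a subset
NEURONAL_CATEGORIES = (
    "mechanosensory",
    "ammonia_Rh50",
    "Gr_only",
    "Ir_irco",
    "Gr_or_Ir_with_coreceptor",
    "OrX_orco",
    "OrX_orco_Gr",
    "OrX_orco_irco",
    "orco_Ir_irco",
    "orco_only",
    "neuron_unclassified",
)
NONNEURONAL_CATEGORIES = (
    "glia", "muscle", "epithelium", "support", "other_nonneuronal",
)

BULK_STAGES = ("D10", "D15", "D20", "D25")


@dataclass
class CellProgram:
    """One simulated cell type: which genes it expresses and how well it
    survives in each genotype."""

    name: str
    category_label: str
    expressed_genes: dict  # gene_id -> mean expected UMI at unit depth
    genotype_survival: dict  # {"WT": p, "mutant": p}
    weight: float  # mixture weight in the pre-ablation cohort
    baseline_noise: float = 0.0  # ambient RNA is deliberately not simulated

    def __post_init__(self):
        for g, p in self.genotype_survival.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"survival probability {p} for {g} outside [0,1]")


@dataclass
class SimTruth:
    """Ground truth emitted alongside each simulated dataset."""

    cell_category: pd.Series | None = None  # cell_id -> category label
    cell_program: pd.Series | None = None  # cell_id -> program name
    program_expressed: dict = field(default_factory=dict)  # name -> set(gene)
    bulk_class: pd.Series | None = None  # gene_id -> trajectory class
    id_matching: dict | None = None  # gene_A -> gene_B or None
    truncated_genes: list = field(default_factory=list)
    collapsed_genes: list = field(default_factory=list)

    def receptor_truth(self, cell_ids, receptor_genes) -> pd.DataFrame:
        """Boolean cells x receptor-genes matrix of true expression."""
        cols = list(receptor_genes)
        out = np.zeros((len(cell_ids), len(cols)), dtype=bool)
        colpos = {g: j for j, g in enumerate(cols)}
        for i, cell in enumerate(cell_ids):
            for g in self.program_expressed[self.cell_program[cell]]:
                j = colpos.get(g)
                if j is not None:
                    out[i, j] = True
        return pd.DataFrame(out, index=list(cell_ids), columns=cols)


# ---------------------------------------------------------------------------
# default gene panel and programs (desk scale)

N_TUNING_OR = 300
N_RETAINED_OR = 10  # Ors hosted by a nonneuronal (support) program
IRCO_GENES = ("Ir8a", "Ir25a.1", "Ir25a.2", "Ir76b")
NEURON_MARKERS = ("nSyb", "fne", "Syt1", "onecut")


def default_gene_annotation() -> pd.DataFrame:
    """1,200-gene desk-scale panel: 300 tuning Or (the last 10 on small
    scaffolds next to a non-Or 'leak partner' gene), orco, 4 ircos, 20 tuning
    Ir, 10 Gr, Rh50, nompC, 8 cell-class markers, 30 mitochondrial genes, and
    background/housekeeping genes."""
    rec = []
    gene_len = 2000
    spacing = 5000
    # 290 ORN-program-only Ors in ten 29-gene tandem clusters
    k = 0
    for s in range(10):
        for j in range(29):
            k += 1
            start = 1 + j * spacing
            rec.append((f"Or{k:03d}", "tuning_Or", f"scf_or{s + 1:02d}",
                        start, start + gene_len - 1, "+"))
    # 10 retained Ors, each beside one non-Or neighbor on its own scaffold
    for j in range(N_RETAINED_OR):
        k += 1
        scf = f"scf_leak{j + 1:02d}"
        rec.append((f"Or{k:03d}", "tuning_Or", scf, 1, gene_len, "+"))
        rec.append((f"leak{j + 1:02d}", "other", scf, 4001, 4000 + 1500, "+"))
    rec.append(("Orco", "orco", "scf_misc01", 1, 2000, "+"))
    for g in IRCO_GENES:
        rec.append((g, "irco", "scf_misc02", 1 + len(rec) * spacing,
                    len(rec) * spacing + 1500, "+"))
    for j in range(20):
        rec.append((f"Ir{j + 1:02d}", "tuning_Ir", "scf_misc03",
                    1 + j * spacing, j * spacing + 1500, "+"))
    for j in range(10):
        rec.append((f"Gr{j + 1:02d}", "Gr", "scf_misc04",
                    1 + j * spacing, j * spacing + 1500, "+"))
    rec.append(("Rh50", "Rh50", "scf_misc05", 1, 1500, "+"))
    rec.append(("nompC", "nompC", "scf_misc05", 5001, 6500, "+"))
    markers = [
        ("nSyb", "neuron_marker"), ("fne", "neuron_marker"),
        ("Syt1", "neuron_marker"), ("onecut", "neuron_marker"),
        ("repo", "glia_marker"), ("Mhc", "muscle_marker"),
        ("grh", "epithelium_marker"), ("sv", "support_marker"),
    ]
    for j, (g, cls) in enumerate(markers):
        rec.append((g, cls, "scf_misc06", 1 + j * spacing, j * spacing + 1500, "+"))
    for j in range(30):
        rec.append((f"mt{j + 1:02d}", "mito", "scf_mito",
                    1 + j * 1200, j * 1200 + 800, "+"))
    n_bg = 1200 - len(rec)
    for j in range(n_bg):
        rec.append((f"bg{j + 1:04d}", "other", f"scf_bg{j // 100 + 1:02d}",
                    1 + (j % 100) * spacing, (j % 100) * spacing + 1500, "+"))
    return make_gene_annotation(rec)


HK_MEAN = 3.5  # housekeeping genes, expressed by every cell
MITO_MEAN = 0.55  # per mito gene; yields ~0.56% mitochondrial reads
MARKER_MEAN = 2.5  # neuron markers
CLASS_MARKER_MEAN = 3.0  # repo/Mhc/grh/sv
RECEPTOR_MEAN = 3.0
RETAINED_OR_MEAN = 2.0
ABLATED_SURVIVAL = 0.005  # Orco-dependent programs in the mutant


#: identity-module shape: genes up/down per cell type and their fold factors
MODULE_UP, MODULE_DOWN = 40, 40
MODULE_UP_FACTOR, MODULE_DOWN_FACTOR = 4.0, 0.3
NEURON_MODULE_SIZE = 60


def default_cell_programs(annotation: pd.DataFrame) -> list:
    """Program templates mirroring the receptor-combination categories, with
    WT mixture weights chosen so neurons are 67% of the WT cohort and the
    Orco-independent neuron mass is 4.5% (expected mutant neuron fraction
    ~12-13% after ablation).

    Besides its receptor combination, every cell type carries an identity
    module — a fixed random subset of housekeeping genes shifted up or down —
    emulating the broad transcriptomic differences real cell types show
    beyond their receptors; without this, no neighborhood graph could
    recover cell types from receptor genes alone.
    """
    hk = [g for g in annotation.index
          if annotation.at[g, "gene_class"] == "other" and g.startswith("bg")]
    mito = [g for g in annotation.index if annotation.at[g, "gene_class"] == "mito"]
    base = {g: HK_MEAN for g in hk}
    base.update({g: MITO_MEAN for g in mito})
    neuron = {g: MARKER_MEAN for g in NEURON_MARKERS}
    # module draws are part of the program definitions, not of a simulation
    # run, hence the fixed internal seed
    mod_rng = np.random.default_rng(20240)
    neuron_module = mod_rng.choice(hk, size=NEURON_MODULE_SIZE, replace=False)
    neuron.update({g: HK_MEAN * MODULE_UP_FACTOR for g in neuron_module})
    module_pool = [g for g in hk if g not in set(neuron_module)]

    def prog(name, label, extra, surv_mut, weight, neuronal=True):
        genes = dict(base)
        if neuronal:
            genes.update(neuron)
        module = mod_rng.choice(module_pool, size=MODULE_UP + MODULE_DOWN,
                                replace=False)
        genes.update({g: HK_MEAN * MODULE_UP_FACTOR for g in module[:MODULE_UP]})
        genes.update({g: HK_MEAN * MODULE_DOWN_FACTOR for g in module[MODULE_UP:]})
        genes.update(extra)
        return CellProgram(name, label, genes,
                           {"WT": 1.0, "mutant": surv_mut}, weight)

    # every program keeps more cells per genotype than the default
    # neighborhood size, otherwise no kNN graph could give its cells
    # same-type neighborhoods
    R = RECEPTOR_MEAN
    programs = [
        prog("mech", "mechanosensory", {"nompC": R}, 1.0, 0.006),
        prog("amm", "ammonia_Rh50", {"Rh50": R}, 1.0, 0.006),
        prog("gr_a", "Gr_only", {"Gr02": R}, 1.0, 0.006),
        prog("ir_a", "Ir_irco", {"Ir03": R, "Ir25a.1": R, "Ir76b": R}, 1.0, 0.006),
        # the dominant Orco-independent ORN class (it fully survives, so its
        # mutant/WT count ratio is the cleanest survival readout)
        prog("oii_a", "orco_Ir_irco",
             {"Orco": R, "Ir01": R, "Ir8a": R, "Ir76b": R}, 1.0, 0.021),
        prog("orco_only", "orco_only", {"Orco": R}, ABLATED_SURVIVAL, 0.025),
    ]
    for j in range(12):  # the dominant Or/orco ORN types
        programs.append(
            prog(f"or{j + 1:02d}", "OrX_orco", {f"Or{j + 1:03d}": R, "Orco": R},
                 ABLATED_SURVIVAL, 0.47 / 12)
        )
    programs += [
        prog("orgr_a", "OrX_orco_Gr", {"Or013": R, "Gr01": R, "Orco": R},
             ABLATED_SURVIVAL, 0.035),
        prog("orgr_b", "OrX_orco_Gr", {"Or014": R, "Gr01": R, "Orco": R},
             ABLATED_SURVIVAL, 0.035),
        prog("orirco_a", "OrX_orco_irco", {"Or015": R, "Ir8a": R, "Orco": R},
             ABLATED_SURVIVAL, 0.03),
        prog("orirco_b", "OrX_orco_irco", {"Or016": R, "Ir8a": R, "Orco": R},
             ABLATED_SURVIVAL, 0.03),
    ]
    # nonneuronal populations; support cells host the "retained" Ors and
    # their genomic neighbors (leaky regulation scenario)
    retained = [f"Or{j:03d}" for j in range(N_TUNING_OR - N_RETAINED_OR + 1,
                                            N_TUNING_OR + 1)]
    leak = [f"leak{j + 1:02d}" for j in range(N_RETAINED_OR)]
    support_extra = {"sv": CLASS_MARKER_MEAN}
    support_extra.update({g: RETAINED_OR_MEAN for g in retained + leak})
    programs += [
        prog("glia", "glia", {"repo": CLASS_MARKER_MEAN}, 1.0, 0.07, neuronal=False),
        prog("muscle", "muscle", {"Mhc": CLASS_MARKER_MEAN}, 1.0, 0.03, neuronal=False),
        prog("epith", "epithelium", {"grh": CLASS_MARKER_MEAN}, 1.0, 0.09,
             neuronal=False),
        prog("support", "support", support_extra, 1.0, 0.12, neuronal=False),
        prog("other_nn", "other_nonneuronal", {}, 1.0, 0.02, neuronal=False),
    ]
    total = sum(p.weight for p in programs)
    assert abs(total - 1.0) < 1e-9, total
    return programs


def retained_or_genes() -> list:
    return [f"Or{j:03d}" for j in range(N_TUNING_OR - N_RETAINED_OR + 1,
                                        N_TUNING_OR + 1)]


# ---------------------------------------------------------------------------
# single-nucleus generator

def _nb_draw(rng, mu, theta):
    mu = np.asarray(mu, dtype=float)
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def simulate_antennal_snrnaseq(
    annotation: pd.DataFrame = None,
    programs: list = None,
    n_per_genotype: int = 2000,
    seed: int = 0,
    dispersion: float = 10.0,
    depth_sigma: float = 0.10,
    batch_sigma: float = 0.08,
):
    """Simulate a WT + mutant antennal single-nucleus dataset.

    Both genotypes start from ``n_per_genotype`` cells drawn from the program
    mixture; a cell is kept with its program's genotype survival probability,
    so Orco-dependent ORN classes are ablated from the mutant dataset. WT
    cells are split across two libraries with a per-gene multiplicative batch
    factor on the second.

    Returns ``(CountMatrix, cell_meta, SimTruth)``.
    """
    if annotation is None:
        annotation = default_gene_annotation()
    if programs is None:
        programs = default_cell_programs(annotation)
    wsum = sum(p.weight for p in programs)
    if abs(wsum - 1.0) > 1e-8:
        raise ValueError(f"program mixture weights sum to {wsum}, expected 1")
    for p in programs:
        missing = set(p.expressed_genes) - set(annotation.index)
        if missing:
            raise ValueError(f"program {p.name} expresses unknown genes {sorted(missing)}")

    rng = np.random.default_rng(seed)
    genes = list(annotation.index)
    gpos = {g: i for i, g in enumerate(genes)}
    weights = np.array([p.weight for p in programs])
    mean_rows = np.zeros((len(programs), len(genes)))
    for i, p in enumerate(programs):
        mean_rows[i, :] = p.baseline_noise
        for g, m in p.expressed_genes.items():
            mean_rows[i, gpos[g]] = m
    batch = np.exp(rng.normal(0.0, batch_sigma, size=len(genes)))  # library 2 only

    blocks, cell_ids, lib_ids, gts, progs_out = [], [], [], [], []
    for genotype in ("WT", "mutant"):
        draw = rng.choice(len(programs), size=n_per_genotype, p=weights)
        surv = np.array([programs[i].genotype_survival[genotype] for i in draw])
        keep = rng.random(n_per_genotype) < surv
        kept = draw[keep]
        if genotype == "WT":
            libs = np.where(rng.random(kept.size) < 0.5, "lib1", "lib2")
        else:
            libs = np.full(kept.size, "lib3")
        depth = np.exp(rng.normal(0.0, depth_sigma, size=kept.size))
        mu = mean_rows[kept] * depth[:, None]
        mu[libs == "lib2"] *= batch[None, :]
        counts = _nb_draw(rng, mu, dispersion)
        blocks.append(sp.csr_matrix(counts.astype(np.int64)))
        cell_ids += [f"{genotype}_{i:05d}" for i in range(kept.size)]
        lib_ids += list(libs)
        gts += [genotype] * kept.size
        progs_out += [programs[i].name for i in kept]

    cm = CountMatrix(sp.vstack(blocks), cell_ids, genes, MODE_SINGLE_NUCLEUS)
    meta = make_cell_meta(cell_ids, lib_ids, gts)
    by_name = {p.name: p for p in programs}
    truth = SimTruth(
        cell_category=pd.Series(
            [by_name[n].category_label for n in progs_out], index=cell_ids
        ),
        cell_program=pd.Series(progs_out, index=cell_ids),
        program_expressed={p.name: set(p.expressed_genes) for p in programs},
    )
    return cm, meta, truth


# ---------------------------------------------------------------------------
# bulk time-course generator

#: relative stage means (D10, D15, D20, D25)
TRAJECTORY_SHAPES = {
    "early": [1.0, 0.4, 0.12, 0.05],
    "intermediate": [0.08, 1.0, 0.25, 0.08],
    "late": [0.05, 0.25, 0.9, 1.0],
    "flat": [0.6, 0.6, 0.6, 0.6],
}
OR_LIKE_WT = [0.05, 0.6, 0.95, 1.0]
OR_LIKE_MUTANT = [0.05, 0.6, 0.08, 0.06]  # post-D15 collapse (<= 20% of peak)
N_STAGE_PROGRAM = 150  # genes per early/intermediate/late program at desk scale
#: Or transcripts come from sparse ORNs, so in whole-antenna bulk they sit
#: well below housekeeping levels (log-mean offset on the base expression)
OR_LOG_OFFSET = -4.5


def default_bulk_classes(annotation: pd.DataFrame) -> pd.Series:
    """Assign every gene a trajectory class: 120-gene early/intermediate/late
    programs drawn from background genes, 'Or-like' (mutant collapse) for all
    ORN-program Ors, and flat for everything else (including the
    nonneuronally retained Ors, which the mutant does not lose)."""
    cls = pd.Series("flat", index=annotation.index)
    bg = [g for g in annotation.index if g.startswith("bg")]
    cls[bg[:N_STAGE_PROGRAM]] = "early"
    cls[bg[N_STAGE_PROGRAM:2 * N_STAGE_PROGRAM]] = "intermediate"
    cls[bg[2 * N_STAGE_PROGRAM:3 * N_STAGE_PROGRAM]] = "late"
    retained = set(retained_or_genes())
    ors = [g for g in annotation.index
           if annotation.at[g, "gene_class"] == "tuning_Or" and g not in retained]
    cls[ors] = "or_like"
    return cls


def simulate_bulk_timecourse(
    annotation: pd.DataFrame = None,
    trajectory_classes: pd.Series = None,
    n_reps: int = 3,
    seed: int = 0,
    dispersion: float = 50.0,
    depth_sigma: float = 0.10,
    base_log_mean: float = 5.0,
    base_log_sigma: float = 1.0,
):
    """Simulate the pupal-antenna bulk time course (D10/D15/D20/D25 x WT,
    mutant x replicates). Returns ``(CountMatrix bulk, design, SimTruth)``."""
    if annotation is None:
        annotation = default_gene_annotation()
    if trajectory_classes is None:
        trajectory_classes = default_bulk_classes(annotation)
    if n_reps < 2:
        logger.warning(
            "fewer than 2 replicates per condition: downstream statistics degraded"
        )
    rng = np.random.default_rng(seed)
    genes = list(annotation.index)
    offsets = np.array([
        OR_LOG_OFFSET if trajectory_classes[g] == "or_like" else 0.0
        for g in genes
    ])
    base = np.exp(rng.normal(base_log_mean, base_log_sigma, size=len(genes)) + offsets)

    shape_wt = np.empty((len(genes), len(BULK_STAGES)))
    shape_mut = np.empty_like(shape_wt)
    for i, g in enumerate(genes):
        c = trajectory_classes[g]
        if c == "or_like":
            shape_wt[i] = OR_LIKE_WT
            shape_mut[i] = OR_LIKE_MUTANT
        else:
            shape_wt[i] = TRAJECTORY_SHAPES[c]
            shape_mut[i] = TRAJECTORY_SHAPES[c]

    cols, design_rows = [], []
    counts = []
    for genotype, shapes in (("WT", shape_wt), ("mutant", shape_mut)):
        for s, stage in enumerate(BULK_STAGES):
            for r in range(1, n_reps + 1):
                depth = float(np.exp(rng.normal(0.0, depth_sigma)))
                mu = base * shapes[:, s] * depth
                counts.append(_nb_draw(rng, mu, dispersion))
                sid = f"{genotype}_{stage}_r{r}"
                cols.append(sid)
                design_rows.append((sid, stage, genotype, r))
    values = np.column_stack(counts).astype(np.int64)
    cm = CountMatrix(values, cols, genes, MODE_BULK)
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "stage", "genotype", "replicate"]
    ).set_index("sample_id")
    truth = SimTruth(bulk_class=trajectory_classes.copy())
    return cm, design, truth


# ---------------------------------------------------------------------------
# tandem-cluster ID-transfer fixture

def simulate_cluster_pair(
    n_genes: int = 100,
    frac_truncated: float = 0.1,
    frac_collapsed: float = 0.05,
    seed: int = 0,
    window: int = 4,
    aln_length: int = 1200,
    truncation: float = 0.3,
):
    """Two ordered tandem-cluster gene lists with a similarity table.

    List B mirrors list A gene for gene, except that a fraction of B gene
    models are *truncated* (all their alignments shortened, deflating
    bit-scores so a neighboring paralog outscores the true partner while
    percent identity is preserved) and a fraction of B genes are *collapsed*
    (absent from B entirely, as when two near-identical tandem copies are
    merged in a new assembly).

    Returns ``(list_A, list_B, similarity table, SimTruth)``.
    """
    if frac_truncated < 0 or frac_collapsed < 0:
        raise ValueError("fractions must be nonnegative")
    if frac_truncated + frac_collapsed >= 1:
        raise ValueError("frac_truncated + frac_collapsed must be < 1")
    rng = np.random.default_rng(seed)
    a_ids = [f"OrA{i + 1:03d}" for i in range(n_genes)]
    b_ids = [f"LOC{90001 + i}" for i in range(n_genes)]

    n_trunc = int(round(frac_truncated * n_genes))
    n_coll = int(round(frac_collapsed * n_genes))
    special = rng.choice(n_genes, size=n_trunc + n_coll, replace=False)
    truncated = sorted(special[:n_trunc].tolist())
    collapsed = sorted(special[n_trunc:].tolist())
    collapsed_set = set(collapsed)
    truncated_set = set(truncated)

    true_identity = rng.uniform(86.0, 96.0, size=n_genes)
    rows = []
    for i in range(n_genes):
        for j in range(max(0, i - window), min(n_genes, i + window + 1)):
            if j in collapsed_set:
                continue
            if i == j:
                ident = true_identity[i]
                length = aln_length
            else:
                ident = 57.0 - 2.0 * (abs(i - j) - 1) + rng.normal(0.0, 1.5)
                ident = float(np.clip(ident, 50.0, 64.0))
                length = int(aln_length * 0.85)
            if j in truncated_set:
                length = int(length * truncation)
            bit = 2.0 * ident / 100.0 * length
            rows.append((a_ids[i], b_ids[j], round(ident, 2), length, round(bit, 1)))
    table = pd.DataFrame(
        rows, columns=["query", "subject", "pct_identity", "aln_length", "bit_score"]
    )
    b_present = [b_ids[j] for j in range(n_genes) if j not in collapsed_set]
    matching = {
        a_ids[i]: (None if i in collapsed_set else b_ids[i]) for i in range(n_genes)
    }
    truth = SimTruth(
        id_matching=matching,
        truncated_genes=[a_ids[i] for i in truncated],
        collapsed_genes=[a_ids[i] for i in collapsed],
    )
    return a_ids, b_present, table, truth
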
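"""On-disk formats, domain containers, and pipeline configuration.

Single-nucleus counts travel as MatrixMarket coordinate files (genes x cells,
the cellranger convention) with one-ID-per-line index files; everything else
is plain TSV. All readers round-trip bit-exactly with their writers.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from zlib import crc32

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("antseq")

MODE_SINGLE_NUCLEUS = "single_nucleus"
MODE_BULK = "bulk"

GENE_CLASSES = (
    "tuning_Or",
    "orco",
    "tuning_Ir",
    "irco",
    "Gr",
    "Rh50",
    "nompC",
    "neuron_marker",
    "glia_marker",
    "muscle_marker",
    "epithelium_marker",
    "support_marker",
    "mito",
    "other",
)

#: gene classes whose per-cell expressing/not-expressing status is tested
RECEPTOR_CLASSES = ("tuning_Or", "orco", "tuning_Ir", "irco", "Gr", "Rh50", "nompC")


class FormatError(ValueError):
    """Raised when an on-disk file violates the format contract."""


@dataclass
class CountMatrix:
    """Nonnegative integer counts with row/column identifiers.

    In ``single_nucleus`` mode ``values`` is a sparse CSR matrix of shape
    (cells, genes) and ``cell_ids`` names the rows.  In ``bulk`` mode
    ``values`` is a dense (genes, samples) array and ``cell_ids`` holds the
    sample IDs (columns).
    """

    values: object
    cell_ids: list
    gene_ids: list
    mode: str = MODE_SINGLE_NUCLEUS

    def __post_init__(self):
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("cell/sample IDs are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene IDs are not unique")
        if self.mode == MODE_SINGLE_NUCLEUS:
            self.values = sp.csr_matrix(self.values)
            n_cells, n_genes = self.values.shape
        elif self.mode == MODE_BULK:
            self.values = np.asarray(self.values)
            n_genes, n_cells = self.values.shape
        else:
            raise FormatError(f"unknown mode {self.mode!r}")
        if n_cells != len(self.cell_ids):
            raise FormatError(
                f"matrix has {n_cells} cells/samples but {len(self.cell_ids)} IDs"
            )
        if n_genes != len(self.gene_ids):
            raise FormatError(
                f"matrix has {n_genes} genes but {len(self.gene_ids)} IDs"
            )
        data = self.values.data if sp.issparse(self.values) else self.values
        if np.asarray(data).size and np.asarray(data).min() < 0:
            raise FormatError("negative entries in count matrix")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_ids) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in gene_ids], dtype=int)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        if self.mode != MODE_SINGLE_NUCLEUS:
            raise ValueError("subset_cells only defined for single-nucleus matrices")
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[idx], [self.cell_ids[i] for i in idx], self.gene_ids, self.mode
        )

    def subset_genes(self, keep_idx) -> "CountMatrix":
        keep_idx = np.asarray(keep_idx, dtype=int)
        if self.mode == MODE_SINGLE_NUCLEUS:
            vals = self.values[:, keep_idx]
        else:
            vals = self.values[keep_idx]
        return CountMatrix(
            vals, self.cell_ids, [self.gene_ids[i] for i in keep_idx], self.mode
        )


def _read_ids(path: Path, what: str) -> list:
    ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicated ID in {what} file {path}")
    return ids


def read_count_matrix(path_matrix, path_cells, path_genes) -> CountMatrix:
    """Read a genes x cells MatrixMarket triplet plus ID index files."""
    m = scipy.io.mmread(str(path_matrix))
    cells = _read_ids(path_cells, "cell")
    genes = _read_ids(path_genes, "gene")
    if m.shape[0] != len(genes):
        raise FormatError(
            f"matrix {path_matrix} has {m.shape[0]} rows but gene file "
            f"{path_genes} lists {len(genes)} genes"
        )
    if m.shape[1] != len(cells):
        raise FormatError(
            f"matrix {path_matrix} has {m.shape[1]} columns but cell file "
            f"{path_cells} lists {len(cells)} cells"
        )
    vals = sp.csr_matrix(m.T).astype(np.int64)
    return CountMatrix(vals, cells, genes, MODE_SINGLE_NUCLEUS)


def write_count_matrix(cm: CountMatrix, path_matrix, path_cells, path_genes) -> None:
    if cm.mode != MODE_SINGLE_NUCLEUS:
        raise ValueError("MatrixMarket output is for single-nucleus matrices")
    coo = sp.coo_matrix(cm.values.T)  # genes x cells on disk
    scipy.io.mmwrite(str(path_matrix), coo, field="integer")
    Path(path_cells).write_text("".join(f"{c}\n" for c in cm.cell_ids))
    Path(path_genes).write_text("".join(f"{g}\n" for g in cm.gene_ids))


def read_bulk_counts(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        df.to_numpy(), list(df.columns), list(df.index), MODE_BULK
    )


def write_bulk_counts(cm: CountMatrix, path) -> None:
    df = pd.DataFrame(cm.values, index=cm.gene_ids, columns=cm.cell_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    """Deterministically formatted TSV output (fixed float precision)."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# ---------------------------------------------------------------------------
# gene annotation

def make_gene_annotation(records) -> pd.DataFrame:
    """Build/validate a gene annotation table.

    ``records`` is an iterable of (gene_id, gene_class, scaffold, start, end,
    strand) or a DataFrame with those columns. Coordinates are 1-based
    inclusive; exactly one gene of class ``orco`` is required when any
    receptor classes are present.
    """
    if isinstance(records, pd.DataFrame):
        ann = records.copy()
        if ann.index.name != "gene_id":
            ann = ann.set_index("gene_id") if "gene_id" in ann.columns else ann
    else:
        ann = pd.DataFrame(
            list(records),
            columns=["gene_id", "gene_class", "scaffold", "start", "end", "strand"],
        ).set_index("gene_id")
    if ann.index.duplicated().any():
        raise FormatError("duplicated gene_id in annotation")
    bad = set(ann["gene_class"]) - set(GENE_CLASSES)
    if bad:
        raise FormatError(f"unknown gene classes {sorted(bad)}")
    if (ann["start"] > ann["end"]).any():
        raise FormatError("annotation has start > end")
    n_orco = int((ann["gene_class"] == "orco").sum())
    if n_orco > 1:
        raise FormatError(f"annotation lists {n_orco} orco genes; exactly one allowed")
    return ann


def genes_of_class(annotation: pd.DataFrame, *classes) -> list:
    mask = annotation["gene_class"].isin(classes)
    return list(annotation.index[mask])


def read_gene_annotation(path) -> pd.DataFrame:
    return make_gene_annotation(pd.read_csv(path, sep="\t", index_col=0))


# ---------------------------------------------------------------------------
# cell metadata

GENOTYPES = ("WT", "mutant")


def make_cell_meta(cell_ids, library_id, genotype) -> pd.DataFrame:
    meta = pd.DataFrame(
        {"library_id": library_id, "genotype": genotype},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    bad = set(meta["genotype"]) - set(GENOTYPES)
    if bad:
        raise FormatError(f"unknown genotypes {sorted(bad)}")
    return meta


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """Flat bag of tunables. Defaults follow the source study's printed
    values where one exists; the rest are documented desk-scale choices."""

    # two-stage cell QC
    stage1_min_genes: int = 750
    stage1_max_umis: int = 12500
    stage1_max_pct_mito: float = 2.5
    stage2_max_genes: int = 2750
    stage2_max_umis: int = 9500
    stage2_max_pct_mito: float = 1.25
    # normalization / embedding
    cp10k_scale: float = 10000.0
    n_hvg: int = 2000
    n_pcs: int = 30
    n_neighbors: int = 15
    cluster_resolution: float = 5.0
    # receptor calling
    background_size: int = 100
    alpha: float = 0.05
    # bulk
    loading_set_size: int = 750
    # retained-Or log2 fold-change cutoffs
    fc_cutoff_sn: float = -1.0
    fc_cutoff_bulk: float = -1.0
    # id transfer
    min_identity: float = 60.0
    gap_penalty: float = 40.0
    # randomness
    rng_seed: int = 0

    def validate(self) -> "PipelineConfig":
        positive = [
            "stage1_min_genes", "stage1_max_umis", "stage1_max_pct_mito",
            "stage2_max_genes", "stage2_max_umis", "stage2_max_pct_mito",
            "cp10k_scale", "n_hvg", "n_pcs", "n_neighbors",
            "cluster_resolution", "background_size", "loading_set_size",
            "min_identity", "gap_penalty",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly inside (0, 1)")
        if self.stage2_max_umis > self.stage1_max_umis:
            raise ValueError("stage2 UMI bound must lie inside the stage1 bound")
        if self.stage2_max_pct_mito > self.stage1_max_pct_mito:
            raise ValueError("stage2 mito bound must lie inside the stage1 bound")
        if self.rng_seed < 0:
            raise ValueError("rng_seed must be nonnegative")
        return self

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage substream: reordering stages cannot change
        the draws any one stage sees."""
        key = crc32(stage.encode())
        return np.random.default_rng(np.random.SeedSequence(self.rng_seed, spawn_key=(key,)))

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise FormatError(f"unknown config keys {sorted(bad)}")
        return cls(**raw).validate()
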
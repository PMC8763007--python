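"""Readers, writers and shared containers for every format the pipeline touches.

The pipeline works with genes-by-cells matrices throughout.  On-disk formats
are the field's plain-text standards: MatrixMarket coordinate triplets for UMI
counts (the 10x Genomics layout: ``matrix.mtx`` + ``features.tsv`` +
``barcodes.tsv``), GMT for gene sets, and CSV for per-cell metadata and
composition tables.  MTX indices are 1-based on disk per the MatrixMarket
standard; everything in memory is 0-based.

Gene identifiers are matched by exact string equality only — no symbol-alias
resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("stromascope")

#: Expression-value conventions an ExpressionMatrix can carry.
TRANSFORM_TAGS = ("raw_tpm", "lognorm10k", "log2tpm10", "scaled")

#: Tissue and platform enumerations used in per-cell metadata.
TISSUES = ("tumor", "normal")
PLATFORMS = ("umi", "full_length")


class FormatError(ValueError):
    """A file violates the format it claims to be in."""


def _check_ids(ids: Sequence[str], what: str, n_expected: int) -> list[str]:
    ids = [str(x) for x in ids]
    if len(ids) != n_expected:
        raise ValueError(f"{what}: got {len(ids)} identifiers for {n_expected} rows/columns")
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what}: identifiers are not unique")
    return ids


@dataclass
class CountMatrix:
    """Genes × cells non-negative integer UMI counts.

    ``values`` may be a dense ndarray or any scipy sparse matrix; it is stored
    as CSR. Gene and cell identifiers are unique strings matching the matrix
    dimensions.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if not sp.issparse(v):
            v = sp.csr_matrix(np.asarray(v))
        v = v.tocsr()
        if v.nnz and v.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if v.nnz and not np.allclose(v.data, np.round(v.data)):
            raise ValueError("counts must be integers")
        self.values = v.astype(np.int64)
        self.gene_ids = _check_ids(self.gene_ids, "gene_ids", v.shape[0])
        self.cell_ids = _check_ids(self.cell_ids, "cell_ids", v.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.values[:, idx], self.gene_ids,
                           [self.cell_ids[i] for i in idx])

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.values[idx, :], [self.gene_ids[i] for i in idx],
                           self.cell_ids)


@dataclass
class ExpressionMatrix:
    """Genes × cells real values tagged with the transform that produced them.

    Construct only through the transform operations (``lognormalize``,
    ``tpm_transform``, ``regress_and_scale``, the simulator) so the tag stays
    truthful.
    """

    values: np.ndarray
    transform_tag: str
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (genes × cells)")
        if self.transform_tag not in TRANSFORM_TAGS:
            raise ValueError(f"unknown transform_tag {self.transform_tag!r}; "
                             f"expected one of {TRANSFORM_TAGS}")
        self.gene_ids = _check_ids(self.gene_ids, "gene_ids", self.values.shape[0])
        self.cell_ids = _check_ids(self.cell_ids, "cell_ids", self.values.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(self.values[:, idx], self.transform_tag,
                                self.gene_ids, [self.cell_ids[i] for i in idx])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in genes if g in pos]
        return ExpressionMatrix(self.values[idx, :], self.transform_tag,
                                [self.gene_ids[i] for i in idx], self.cell_ids)


#: Columns a metadata table must provide (besides the cell identifier).
METADATA_REQUIRED = ("cell_id", "sample_id", "cancer_type", "tissue", "platform")


@dataclass
class CellMetadata:
    """Per-cell metadata: sample, cancer type, tissue, age, platform.

    ``table`` is indexed by cell id; unknown columns are preserved as opaque
    extras. ``tissue`` ∈ {tumor, normal} (case-normalized on read),
    ``platform`` ∈ {umi, full_length}, ``age`` is years or NaN.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in METADATA_REQUIRED if c != "cell_id" and c not in t.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if t.index.has_duplicates:
            raise ValueError("duplicate cell ids in metadata")
        t["tissue"] = t["tissue"].astype(str).str.strip().str.lower()
        bad = set(t["tissue"]) - set(TISSUES)
        if bad:
            raise ValueError(f"tissue values outside {TISSUES}: {sorted(bad)}")
        t["platform"] = t["platform"].astype(str).str.strip().str.lower()
        bad = set(t["platform"]) - set(PLATFORMS)
        if bad:
            raise ValueError(f"platform values outside {PLATFORMS}: {sorted(bad)}")
        if "age" not in t.columns:
            t["age"] = np.nan
        t["age"] = pd.to_numeric(t["age"], errors="coerce")
        if (t["age"].dropna() < 0).any():
            raise ValueError("negative age in metadata")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSetCollection:
    """Named gene sets: map set-name → ordered unique gene list."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(str(g))
            self.sets[name] = list(seen)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# 10x MTX triplet
# ---------------------------------------------------------------------------

def _read_id_column(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def _validate_mtx(path: Path) -> None:
    """Check the MatrixMarket header against the body (guards truncation)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("%%MatrixMarket"):
            raise FormatError(f"{path}: missing MatrixMarket banner")
        line = fh.readline()
        while line.startswith("%"):
            line = fh.readline()
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"{path}: malformed size line {line!r}")
        nnz_declared = int(parts[2])
        n_entries = sum(1 for raw in fh if raw.strip())
    if n_entries != nnz_declared:
        raise FormatError(
            f"{path}: header declares {nnz_declared} entries but body has {n_entries}"
        )


def read_10x_mtx(dir_path: str | Path) -> CountMatrix:
    """Read a 10x-style MTX triplet directory into a genes × cells CountMatrix.

    Accepts either on-disk orientation (genes × cells or cells × genes) and
    transposes to genes × cells using the features/barcodes line counts.
    Raises :class:`FormatError` on a truncated or inconsistent triplet.
    """
    d = Path(dir_path)
    mtx = d / "matrix.mtx"
    feats = d / "features.tsv"
    if not feats.exists():
        feats = d / "genes.tsv"  # legacy 10x name
    bars = d / "barcodes.tsv"
    for p in (mtx, feats, bars):
        if not p.exists():
            raise FileNotFoundError(f"missing {p.name} in {d}")
    _validate_mtx(mtx)
    m = scipy.io.mmread(mtx)
    gene_ids = _read_id_column(feats)
    cell_ids = _read_id_column(bars)
    if m.shape == (len(gene_ids), len(cell_ids)):
        pass
    elif m.shape == (len(cell_ids), len(gene_ids)):
        m = m.T
    else:
        raise FormatError(
            f"matrix shape {m.shape} matches neither (genes={len(gene_ids)}, "
            f"cells={len(cell_ids)}) nor its transpose"
        )
    dense_ok = sp.issparse(m)
    arr = m.tocsr() if dense_ok else sp.csr_matrix(m)
    if arr.nnz and not np.allclose(arr.data, np.round(arr.data)):
        raise FormatError("matrix.mtx contains non-integer entries")
    logger.info("read_10x_mtx: %d genes × %d cells, %d nonzeros from %s",
                arr.shape[0], arr.shape[1], arr.nnz, d)
    return CountMatrix(arr, gene_ids, cell_ids)


def write_10x_mtx(counts: CountMatrix, dir_path: str | Path) -> None:
    """Write a CountMatrix as a 10x MTX triplet (genes × cells on disk)."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(d / "matrix.mtx", counts.values.tocoo(), field="integer")
    (d / "features.tsv").write_text("".join(f"{g}\t{g}\n" for g in counts.gene_ids))
    (d / "barcodes.tsv").write_text("".join(f"{c}\n" for c in counts.cell_ids))


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene...

    Gene order is preserved; duplicate genes within a set keep the first
    occurrence.  Two sets with the same name are an error (ambiguous).
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: GMT line has {len(fields)} fields, need ≥ 3")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{ln}: duplicate gene-set name {name!r}")
            genes = [g for g in fields[2:] if g]
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write(name + "\t" + description + "\t" + "\t".join(genes) + "\n")


# ---------------------------------------------------------------------------
# Metadata and composition CSV
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> CellMetadata:
    """Read a per-cell metadata CSV (requires the METADATA_REQUIRED columns)."""
    df = pd.read_csv(path, dtype={"cell_id": str, "sample_id": str})
    if "cell_id" not in df.columns:
        raise ValueError("metadata CSV must have a cell_id column")
    df = df.set_index("cell_id")
    return CellMetadata(df)


def write_metadata(meta: CellMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, index_label="cell_id")


def write_composition(table, path: str | Path) -> None:
    """Write a composition table (counts and fractions) to CSV."""
    from .composition import CompositionTable  # local import avoids a cycle

    if isinstance(table, CompositionTable):
        out = pd.concat(
            {"count": table.counts, "fraction": table.fractions}, axis=1
        )
        out.to_csv(path)
    else:
        pd.DataFrame(table).to_csv(path)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

#: Every tunable threshold of the pipeline with its default.  The QC bounds,
#: scale factors, HVG count and age cutoff follow the study design this
#: package implements; the rest are the field's standard settings.
DEFAULT_CONFIG: dict = {
    "qc": {"min_genes": 200, "max_genes": 6000, "max_mito": 0.25, "min_umi": 400},
    "normalize": {"scale_factor": 10000.0},
    "hvg": {"n_top": 2000, "loess_span": 0.3},
    "scale": {"clip_value": 10.0},
    "cell_cycle": {"n_bins": 25, "n_ctrl": 100},
    "pca": {"max_components": 50},
    "elbow": {"drop_tol": 0.001, "d_min": 10, "d_max": 50},
    "cluster": {"n_neighbors": 20, "resolution": 0.8},
    "subtype": {"alpha": 0.05, "n_perm": 1000, "similarity": "pearson"},
    "ssgsea": {"alpha": 0.25, "normalize": True, "rank_weights": True},
    "age": {"cutoff": 60},
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, overlaying user values on DEFAULT_CONFIG."""
    import copy

    import yaml

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if section in cfg and isinstance(values, Mapping):
                cfg[section].update(values)
            else:
                cfg[section] = values
    return cfg
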
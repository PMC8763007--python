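"""Signature-model classification of stromal subtypes with unknown rejection.

Endothelial cells are assigned to 5 subtypes (C1_ESM1 tip, C2_ACKR1 venous,
C3_CA4 capillary, C4_FBLN5 arterial, C5_PROX1 lymphatic) and fibroblasts/
myofibroblasts to common subtypes (C7_MYH11 myofibroblast, C8_RGS5 pericyte,
C9_CFD adipogenic, C10_COMP TGF-β-high, C11_SERPINE1 wound-healing) plus any
user-supplied tissue-specific models, by comparing each cell's expression of
the subtype-specific genes with a per-subtype model.

A model is a centroid profile over the union of all signature genes — the
per-gene mean of reference cells of that subtype, or a binary indicator
centroid (1 on the subtype's own signature genes, 0 elsewhere) when reference
expression is unavailable.  Comparison is Pearson correlation over the gene
union (Spearman available), which makes the similarity invariant to per-cell
affine transforms of expression.  "Not significantly similar to any model" is
operationalized as a per-model gene-permutation test: the cell's values over
the gene union are permuted n_perm times, p = (1 + #{null ≥ observed}) /
(n_perm + 1), and a cell is rejected as unknown when every model's p exceeds
alpha.  Rejection is off by default for ECs and on for fibroblasts, matching
the asymmetric design of the analysis this implements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io_core import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("stromascope")

UNKNOWN = "unknown"

#: SignatureSet is a GeneSetCollection: subtype name → ordered signature genes.
SignatureSet = GeneSetCollection


@dataclass
class SubtypeModelSet:
    """Per-subtype centroid profiles over the union of signature genes.

    ``centroids``: genes (union) × subtypes DataFrame; ``expression_tag``
    records the expression convention the centroids were built with
    ('lognorm10k', 'log2tpm10', or 'indicator').
    """

    centroids: pd.DataFrame
    expression_tag: str

    @property
    def subtype_names(self) -> list:
        return list(self.centroids.columns)

    @property
    def union_genes(self) -> list:
        return list(self.centroids.index)


@dataclass
class SubtypeAssignment:
    """Per-cell subtype labels with similarities and permutation p-values.

    ``table`` columns: label, similarity (best, in [-1, 1] or NaN for
    degenerate cells), p_min.  ``p_values``: cells × models.
    """

    table: pd.DataFrame
    p_values: pd.DataFrame

    def labels(self) -> pd.Series:
        return self.table["label"]


def _signature_union(signatures: SignatureSet) -> list:
    union: dict[str, None] = {}
    for _, genes in signatures.items():
        for g in genes:
            union.setdefault(g)
    return list(union)


def build_subtype_models(reference_expr: ExpressionMatrix, reference_labels,
                         signatures: SignatureSet) -> SubtypeModelSet:
    """Centroid models from labeled reference cells.

    Per subtype: the per-gene mean over that subtype's reference cells,
    restricted to the union of all signature genes present in the reference.
    Raises if a subtype has no reference cells; warns when ≥50% of the union
    is absent from the reference gene universe.
    """
    if reference_expr.transform_tag not in ("lognorm10k", "log2tpm10"):
        raise ValueError("reference expression must be lognorm10k or log2tpm10")
    labels = pd.Series(np.asarray(reference_labels, dtype=object),
                       index=reference_expr.cell_ids)
    union = _signature_union(signatures)
    present = [g for g in union if g in set(reference_expr.gene_ids)]
    if len(present) < 0.5 * len(union):
        logger.warning("build_subtype_models: %d / %d signature genes absent "
                       "from reference", len(union) - len(present), len(union))
    if not present:
        raise ValueError("no signature gene present in the reference")
    sub = reference_expr.subset_genes(present)
    cols = {}
    for name in signatures:
        mask = (labels == name).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"subtype {name!r} has no reference cells")
        cols[name] = sub.values[:, mask].mean(axis=1)
    centroids = pd.DataFrame(cols, index=pd.Index(present, name="gene_id"))
    return SubtypeModelSet(centroids=centroids,
                           expression_tag=reference_expr.transform_tag)


def build_indicator_models(signatures: SignatureSet) -> SubtypeModelSet:
    """Binary indicator centroids: 1 on a subtype's own genes, 0 elsewhere.

    The fallback when no reference expression is available — the model is the
    signature gene list itself.
    """
    union = _signature_union(signatures)
    centroids = pd.DataFrame(0.0, index=pd.Index(union, name="gene_id"),
                             columns=list(signatures.sets))
    for name, genes in signatures.items():
        centroids.loc[[g for g in genes if g in centroids.index], name] = 1.0
    return SubtypeModelSet(centroids=centroids, expression_tag="indicator")


def _standardize_rows(m: np.ndarray) -> np.ndarray:
    """Center and unit-norm rows; zero-variance rows become all-NaN."""
    c = m - m.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = c / norm
    out[norm.ravel() == 0, :] = np.nan
    return out


def classify_cells(expr: ExpressionMatrix, models: SubtypeModelSet,
                   allow_unknown: bool = False, alpha: float = 0.05,
                   n_perm: int = 1000, seed: int = 0,
                   method: str = "pearson") -> SubtypeAssignment:
    """Classify each cell against every subtype model over the gene union.

    similarity(cell, model) = Pearson (or Spearman) correlation over the
    signature-gene union; label = argmax similarity.  Per-model p-values come
    from a gene-permutation null of the cell's values over the union, with
    p = (1 + #{null ≥ observed}) / (n_perm + 1).  If ``allow_unknown`` and
    every model's p > alpha the cell is labeled ``unknown``.  Cells with zero
    variance over the union are ``unknown`` with NaN similarity (warned).
    """
    if models.expression_tag not in ("indicator",) and \
            expr.transform_tag != models.expression_tag:
        raise ValueError(
            f"expression convention {expr.transform_tag!r} does not match the "
            f"models' ({models.expression_tag!r})")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown similarity method {method!r}")
    union = models.union_genes
    sub = expr.subset_genes(union)
    missing = len(union) - sub.shape[0]
    if missing:
        logger.warning("classify_cells: %d signature genes absent from data", missing)
    cent = models.centroids.loc[sub.gene_ids].to_numpy().T  # models × genes
    x = sub.values.T  # cells × genes
    if method == "spearman":
        x = scipy.stats.rankdata(x, axis=1)
        cent = scipy.stats.rankdata(cent, axis=1)

    xs = _standardize_rows(x)
    cs = _standardize_rows(cent)
    if np.isnan(cs).any():
        raise ValueError("a model centroid is constant over the gene union")
    sims = xs @ cs.T  # cells × models (NaN rows for degenerate cells)

    rng = np.random.default_rng(seed)
    n_cells, n_genes = xs.shape
    exceed = np.zeros_like(sims)
    # one shared set of gene permutations per run keeps the null vectorizable
    for _ in range(n_perm):
        perm = rng.permutation(n_genes)
        null = xs[:, perm] @ cs.T
        exceed += null >= sims
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    model_names = models.subtype_names
    degenerate = np.isnan(sims).all(axis=1)
    if degenerate.any():
        logger.warning("classify_cells: %d cells have zero variance over the "
                       "signature union → unknown", int(degenerate.sum()))
    best = np.zeros(n_cells, dtype=int)
    best[~degenerate] = np.nanargmax(sims[~degenerate], axis=1)
    label = np.array([model_names[i] for i in best], dtype=object)
    best_sim = sims[np.arange(n_cells), best]
    p_min = np.where(degenerate, np.nan, np.nanmin(pvals, axis=1))
    if allow_unknown:
        label[(~degenerate) & (p_min > alpha)] = UNKNOWN
    label[degenerate] = UNKNOWN

    idx = pd.Index(expr.cell_ids, name="cell_id")
    table = pd.DataFrame({"label": label, "similarity": best_sim, "p_min": p_min},
                         index=idx)
    p_values = pd.DataFrame(pvals, index=idx, columns=model_names)
    p_values[degenerate] = np.nan
    return SubtypeAssignment(table=table, p_values=p_values)


def subtype_heatmap_matrix(expr: ExpressionMatrix, assignment: SubtypeAssignment,
                           signatures: SignatureSet):
    """Signature-gene × cell matrix ordered into subtype blocks, z-scored per gene.

    Rows are signature genes grouped by the subtype they mark; columns are
    cells grouped by assigned label (signature order, then unknown), each
    block sorted by cell id.  Returns ``(matrix, row_blocks, col_blocks)``
    where the block dicts map name → (start, stop) row/column slices.
    """
    gene_rows: list[str] = []
    row_blocks: dict[str, tuple] = {}
    seen: set[str] = set()
    present = set(expr.gene_ids)
    for name, genes in signatures.items():
        start = len(gene_rows)
        for g in genes:
            if g in present and g not in seen:
                gene_rows.append(g)
                seen.add(g)
        row_blocks[name] = (start, len(gene_rows))

    labels = assignment.table["label"]
    col_order: list[str] = []
    col_blocks: dict[str, tuple] = {}
    for name in list(signatures.sets) + [UNKNOWN]:
        cells = sorted(labels.index[labels == name])
        if not cells and name == UNKNOWN:
            continue
        start = len(col_order)
        col_order.extend(cells)
        col_blocks[name] = (start, len(col_order))

    sub = expr.subset_genes(gene_rows)
    pos = {c: i for i, c in enumerate(sub.cell_ids)}
    vals = sub.values[:, [pos[c] for c in col_order]]
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd
    matrix = pd.DataFrame(z, index=pd.Index(sub.gene_ids, name="gene_id"),
                          columns=col_order)
    return matrix, row_blocks, col_blocks
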
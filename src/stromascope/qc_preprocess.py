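"""Cell-level QC, normalization, cell-cycle scoring, HVG selection, scaling.

The filtering rules are those of the unified reprocessing pipeline this
package implements: keep cells with >200 and <6,000 detected genes, a
mitochondrial read fraction <25%, and (UMI platforms only) >400 UMIs — all
strict inequalities.  Log-normalization uses a scale factor of 10,000 with
natural-log log1p (the standard single-cell convention).  Full-length data
are converted to TPM and transformed as log2(TPM/10 + 1).  Highly variable
genes are ranked with the variance-stabilizing-transformation method (a
loess mean-variance trend on log10 scale, standardized and clipped), and the
selected genes are scaled by per-gene least-squares regression on nuisance
covariates followed by centering, unit-variance scaling and clipping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_core import CountMatrix, ExpressionMatrix

logger = logging.getLogger("stromascope")


@dataclass
class QCThresholds:
    """Exclusive bounds for cell filtering (the pipeline's defaults)."""

    min_genes: int = 200
    max_genes: int = 6000
    max_mito: float = 0.25
    min_umi: int = 400

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0 < self.max_mito <= 1:
            raise ValueError("max_mito must be in (0, 1]")


def compute_cell_qc(counts: CountMatrix, mito_gene_ids) -> pd.DataFrame:
    """Per-cell QC stats: n_genes_detected, n_umi, mito_fraction.

    ``mito_fraction`` is mito counts / total counts, defined as 0 for an
    all-zero cell.  An empty ``mito_gene_ids`` gives mito_fraction 0
    everywhere (with a warning logged).
    """
    mito = set(mito_gene_ids)
    unknown = mito - set(counts.gene_ids)
    if unknown:
        raise ValueError(f"mito genes absent from matrix: {sorted(unknown)[:5]}")
    v = counts.values
    n_genes = np.asarray((v > 0).sum(axis=0)).ravel()
    n_umi = np.asarray(v.sum(axis=0)).ravel()
    if mito:
        mask = np.fromiter((g in mito for g in counts.gene_ids), bool,
                           len(counts.gene_ids))
        mito_counts = np.asarray(v[mask, :].sum(axis=0)).ravel()
    else:
        logger.warning("compute_cell_qc: no mitochondrial genes supplied; "
                       "mito_fraction is 0 for all cells")
        mito_counts = np.zeros_like(n_umi)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_umi > 0, mito_counts / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {"n_genes_detected": n_genes.astype(int), "n_umi": n_umi.astype(int),
         "mito_fraction": frac},
        index=pd.Index(counts.cell_ids, name="cell_id"),
    )


def filter_cells(qc: pd.DataFrame, thresholds: QCThresholds | None = None,
                 platform: str = "umi") -> np.ndarray:
    """Boolean keep-mask over cells; all bounds are strict inequalities.

    The UMI floor applies only when ``platform == 'umi'``.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if platform not in ("umi", "full_length"):
        raise ValueError(f"unknown platform {platform!r}")
    keep = (
        (qc["n_genes_detected"] > thresholds.min_genes)
        & (qc["n_genes_detected"] < thresholds.max_genes)
        & (qc["mito_fraction"] < thresholds.max_mito)
    )
    if platform == "umi":
        keep &= qc["n_umi"] > thresholds.min_umi
    keep = keep.to_numpy()
    logger.info("filter_cells: kept %d / %d cells", int(keep.sum()), len(keep))
    return keep


def lognormalize(counts: CountMatrix, scale: float = 10000.0) -> ExpressionMatrix:
    """ln(1 + count / cell_total × scale), per cell.

    Requires no all-zero cells (filter first); raises naming the first
    offending cell otherwise.
    """
    totals = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        bad = counts.cell_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"cell {bad!r} has zero total counts; filter before normalizing")
    x = counts.dense().astype(float)
    x = np.log1p(x / totals[None, :] * scale)
    return ExpressionMatrix(x, "lognorm10k", counts.gene_ids, counts.cell_ids)


def tpm_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """FPKM/TPM → log2(TPM/10 + 1).

    Each cell is first rescaled to sum to 1e6 (the FPKM→TPM conversion; a
    no-op for data already in TPM), then transformed.
    """
    if expr.transform_tag != "raw_tpm":
        raise ValueError("tpm_transform expects raw length-normalized values (raw_tpm)")
    if (expr.values < 0).any():
        raise ValueError("negative values in length-normalized input")
    totals = expr.values.sum(axis=0)
    if (totals == 0).any():
        bad = expr.cell_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"cell {bad!r} has zero total expression")
    tpm = expr.values / totals[None, :] * 1e6
    out = np.log2(tpm / 10.0 + 1.0)
    return ExpressionMatrix(out, "log2tpm10", expr.gene_ids, expr.cell_ids)


def cell_cycle_scores(expr: ExpressionMatrix, s_genes, g2m_genes,
                      n_bins: int = 25, n_ctrl: int = 100,
                      seed: int = 0) -> pd.DataFrame:
    """S and G2M program scores per cell (set mean minus binned-control mean).

    For each program: score = mean expression of the program genes minus the
    mean of control genes drawn (with replacement, seeded) from the same
    average-expression bin as each program gene — so a program scores high
    only relative to transcriptionally comparable genes.
    """
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    avg = expr.values.mean(axis=1)
    # rank-based binning keeps bins near-equal-occupancy
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(avg), dtype=int)
    bins[order] = np.minimum((np.arange(len(avg)) * n_bins) // len(avg), n_bins - 1)
    by_bin = {b: np.flatnonzero(bins == b) for b in range(n_bins)}

    out = {}
    for name, genes in (("s_score", s_genes), ("g2m_score", g2m_genes)):
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if not idx:
            raise ValueError(f"{name}: no program genes found in the gene universe")
        ctrl_idx = []
        for gi in idx:
            pool = by_bin[bins[gi]]
            ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
        ctrl_idx = np.concatenate(ctrl_idx)
        set_mean = expr.values[idx, :].mean(axis=0)
        ctrl_mean = expr.values[ctrl_idx, :].mean(axis=0)
        out[name] = set_mean - ctrl_mean
    return pd.DataFrame(out, index=pd.Index(expr.cell_ids, name="cell_id"))


@dataclass
class HVGResult:
    """Per-gene VST statistics plus the selected top-n gene list."""

    stats: pd.DataFrame  # mean, variance, expected_variance, standardized_variance
    selected: list = field(default_factory=list)


def select_hvg_vst(counts: CountMatrix, n: int = 2000, loess_span: float = 0.3,
                   clip: float | None = None) -> HVGResult:
    """Rank genes by variance after a variance-stabilizing standardization.

    Fits a loess trend of log10(variance) on log10(mean) over genes with
    nonzero variance, standardizes each gene's counts by the trend-predicted
    standard deviation, clips standardized values at ``clip`` (default
    sqrt(n_cells)) and ranks genes by the variance of the clipped values.
    Returns the top ``n`` (all nonconstant genes, with a warning, if fewer).
    """
    x = counts.dense().astype(float)
    n_genes, n_cells = x.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells for variance estimation")
    if clip is None:
        clip = float(np.sqrt(n_cells))
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    nonzero = var > 0
    if nonzero.sum() < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")

    lx, ly = np.log10(mean[nonzero]), np.log10(var[nonzero])
    fit = lowess(ly, lx, frac=loess_span, return_sorted=False)
    expected_var = np.zeros(n_genes)
    expected_var[nonzero] = 10.0 ** fit

    std_var = np.zeros(n_genes)
    sd_pred = np.sqrt(expected_var[nonzero])
    z = (x[nonzero] - mean[nonzero, None]) / sd_pred[:, None]
    np.clip(z, -clip, clip, out=z)
    std_var[nonzero] = z.var(axis=1, ddof=1)

    stats = pd.DataFrame(
        {"mean": mean, "variance": var, "expected_variance": expected_var,
         "standardized_variance": std_var},
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    n_avail = int(nonzero.sum())
    if n_avail < n:
        logger.warning("select_hvg_vst: only %d nonconstant genes for n=%d",
                       n_avail, n)
    ranked = stats.loc[nonzero].sort_values(
        ["standardized_variance"], ascending=False, kind="stable")
    selected = list(ranked.index[: min(n, n_avail)])
    return HVGResult(stats=stats, selected=selected)


def regress_and_scale(expr: ExpressionMatrix, covariates: pd.DataFrame,
                      clip_value: float = 10.0) -> ExpressionMatrix:
    """Per-gene OLS residuals against nuisance covariates, then z-score + clip.

    ``covariates`` is indexed by cell id; string/categorical columns (sample
    identity) are expanded to indicator columns, numeric columns are used as
    is, and an intercept is always included.  Collinear designs are handled
    by the minimum-norm least-squares solution.  Residuals are centered to
    mean 0, scaled to unit variance and clipped at ±``clip_value``; constant
    genes come back as all-zero rows.
    """
    if len(covariates) != len(expr.cell_ids):
        raise ValueError(
            f"covariates have {len(covariates)} rows for {len(expr.cell_ids)} cells")
    cov = covariates.loc[list(expr.cell_ids)]

    cols = [np.ones(len(cov))]
    for c in cov.columns:
        col = cov[c]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True)
            cols.extend(dummies[d].to_numpy(dtype=float) for d in dummies)
        else:
            cols.append(col.to_numpy(dtype=float))
    design = np.column_stack(cols)

    y = expr.values.T  # cells × genes
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = (y - design @ beta).T  # genes × cells

    resid -= resid.mean(axis=1, keepdims=True)
    sd = resid.std(axis=1, ddof=0)
    nondeg = sd > 1e-12
    resid[nondeg] /= sd[nondeg, None]
    resid[~nondeg] = 0.0
    np.clip(resid, -clip_value, clip_value, out=resid)
    return ExpressionMatrix(resid, "scaled", expr.gene_ids, expr.cell_ids)
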
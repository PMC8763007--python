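"""Single-sample GSEA (ssGSEA) per cell, from scratch, plus group summaries.

For one cell and one gene set the score is the integrated difference between
two empirical distribution walks down the cell's expression-ranked gene list:
a weighted in-set CDF (weights = rank-normalized |expression|^alpha of the
in-set genes) and an unweighted out-of-set CDF.  With rank weighting the
score depends on the expression vector only through its ranking, so any
strictly monotone transform of expression leaves it unchanged.  ``alpha``
defaults to 0.25 and, in matrix mode, each set's scores are divided by their
max − min across the cells of the run — the conventions of the "2.0"
implementation of the method.  Raw |expression|^alpha weighting is available
behind a flag.

Ties (ubiquitous among the zero counts of sparse cells) are broken
deterministically by lexicographic gene name, or by a seeded shuffle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("stromascope")


@dataclass
class PathwayScore:
    """Cells × gene-set enrichment scores with the run's conventions."""

    scores: pd.DataFrame
    normalized: bool
    alpha: float


def _ranked_order(values: np.ndarray, gene_ids, tie_rule: str,
                  rng: np.random.Generator | None) -> np.ndarray:
    """Indices of genes in descending expression order with deterministic ties."""
    n = len(values)
    if tie_rule == "gene_name":
        # sort by (-value, name): lexicographically first name wins within a tie
        name_rank = np.argsort(np.argsort(np.asarray(gene_ids, dtype=object),
                                          kind="stable"), kind="stable")
        key = np.lexsort((name_rank, -values))
        return key
    if tie_rule == "random":
        if rng is None:
            if len(np.unique(values)) < n:
                raise ValueError("tie_rule='random' needs a seed when ties exist")
            rng = np.random.default_rng(0)
        jitter = rng.permutation(n)
        return np.lexsort((jitter, -values))
    raise ValueError(f"unknown tie_rule {tie_rule!r}")


def ssgsea_score(cell_expr_vector, gene_ids, gene_set, alpha: float = 0.25,
                 tie_rule: str = "gene_name", seed: int | None = None,
                 rank_weights: bool = True) -> float:
    """ssGSEA enrichment score of one gene set in one cell.

    Genes are ranked by expression descending; walking the ranked list, the
    running weighted in-set CDF minus the running out-of-set CDF is
    accumulated, and the score is the sum of those running differences.
    With ``rank_weights`` the weight of an in-set gene at (1-based) rank
    position j is (N − j + 1)^alpha; otherwise |expression|^alpha.

    Raises if the set misses the universe entirely or covers it completely.
    """
    values = np.asarray(cell_expr_vector, dtype=float)
    gene_ids = list(gene_ids)
    if len(values) != len(gene_ids):
        raise ValueError("expression vector and gene_ids differ in length")
    members = set(gene_set)
    in_set = np.fromiter((g in members for g in gene_ids), bool, len(gene_ids))
    n, k = len(values), int(in_set.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the gene universe")
    if k == n:
        raise ValueError("gene set equals the whole gene universe (degenerate)")

    rng = np.random.default_rng(seed) if seed is not None else None
    order = _ranked_order(values, gene_ids, tie_rule, rng)
    in_ranked = in_set[order]
    if rank_weights:
        w = (n - np.arange(n)).astype(float) ** alpha
    else:
        w = np.abs(values[order]) ** alpha
    w_in = np.where(in_ranked, w, 0.0)
    total_in = w_in.sum()
    if total_in == 0:
        # all in-set weights zero (raw weighting over zero expression)
        cdf_in = np.cumsum(in_ranked) / k
    else:
        cdf_in = np.cumsum(w_in) / total_in
    cdf_out = np.cumsum(~in_ranked) / (n - k)
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_matrix(expr: ExpressionMatrix, gene_sets: GeneSetCollection,
                  normalize: bool = True, alpha: float = 0.25,
                  tie_rule: str = "gene_name", seed: int | None = None,
                  rank_weights: bool = True) -> PathwayScore:
    """Score every cell against every gene set.

    If ``normalize``, all scores of a set are divided by their max − min
    across the cells of the run; a zero range leaves the raw scores (with a
    warning).
    """
    raw = np.empty((len(expr.cell_ids), len(gene_sets)))
    set_names = list(gene_sets.sets)
    for j, name in enumerate(set_names):
        genes = gene_sets[name]
        for i in range(len(expr.cell_ids)):
            raw[i, j] = ssgsea_score(expr.values[:, i], expr.gene_ids, genes,
                                     alpha=alpha, tie_rule=tie_rule, seed=seed,
                                     rank_weights=rank_weights)
    normalized = False
    if normalize:
        rng_ = raw.max(axis=0) - raw.min(axis=0)
        if (rng_ == 0).any():
            logger.warning("ssgsea_matrix: zero score range for set(s) %s; "
                           "returning raw scores",
                           [set_names[j] for j in np.flatnonzero(rng_ == 0)])
        else:
            raw = raw / rng_[None, :]
            normalized = True
    scores = pd.DataFrame(raw, index=pd.Index(expr.cell_ids, name="cell_id"),
                          columns=set_names)
    return PathwayScore(scores=scores, normalized=normalized, alpha=alpha)


def expression_of_genes(expr: ExpressionMatrix, genes) -> pd.DataFrame:
    """Cells × genes expression table for the per-gene summary mode.

    Raises KeyError naming the first requested gene absent from the universe.
    """
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    for g in genes:
        if g not in pos:
            raise KeyError(f"gene {g!r} absent from the gene universe")
    idx = [pos[g] for g in genes]
    return pd.DataFrame(expr.values[idx, :].T,
                        index=pd.Index(expr.cell_ids, name="cell_id"),
                        columns=list(genes))


def group_activity_summary(values, groups) -> pd.DataFrame:
    """Median and quartiles of each feature per cell group.

    ``values`` is a PathwayScore or a cells × features DataFrame (e.g. from
    :func:`expression_of_genes`); ``groups`` maps cell id → group name
    (EC subtypes, fibroblast subtypes, tumor cells, ...).  Groups with no
    scored cells are skipped with a warning.  Returns a tidy frame with
    columns group, feature, n, median, q25, q75.
    """
    if isinstance(values, PathwayScore):
        values = values.scores
    groups = pd.Series(groups)
    rows = []
    for name in pd.unique(groups):
        cells = groups.index[groups == name]
        cells = [c for c in cells if c in values.index]
        if not cells:
            logger.warning("group_activity_summary: group %r has no scored cells; "
                           "skipped", name)
            continue
        sub = values.loc[cells]
        for feat in values.columns:
            v = sub[feat].to_numpy(dtype=float)
            rows.append({"group": name, "feature": feat, "n": len(v),
                         "median": float(np.median(v)),
                         "q25": float(np.percentile(v, 25)),
                         "q75": float(np.percentile(v, 75))})
    return pd.DataFrame(rows)
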
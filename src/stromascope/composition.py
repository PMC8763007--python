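"""Composition tables and stratified comparisons of annotated cells.

Turns per-cell annotations into group × cell-type count/fraction tables
(per dataset and tissue, per age class), computes tumor-vs-normal fraction
differences, and checks the package's transcribed reference count tables for
cross-table consistency: summing a dataset's per-cell-type counts must
reproduce the dataset's declared tumor/normal cell totals.

Fraction denominators follow the analysis design: major-type fractions are
within-group over all cells; EC subtype fractions are over all classified
ECs; fibroblast "common-5" fractions are over cells assigned to the 5 common
subtypes only (unknown and tissue-specific subtypes excluded), via
``include_types``.

Age stratification: young = age < 60, old = age ≥ 60, unknown when missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger("stromascope")

AGE_CUTOFF = 60.0


@dataclass
class CompositionTable:
    """Group × cell-type counts and within-row fractions."""

    counts: pd.DataFrame
    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")


def composition_table(cells: pd.DataFrame, group_keys, type_field: str,
                      include_types=None) -> CompositionTable:
    """Count and within-group fraction of each type, per group.

    ``cells`` has one row per cell; ``group_keys`` name the grouping columns
    (e.g. ["dataset", "tissue"]); ``type_field`` names the cell-type column.
    ``include_types`` restricts both numerator and denominator to those types
    (the common-5 fibroblast convention).  Empty groups are dropped with a
    warning.
    """
    group_keys = list(group_keys)
    missing = [c for c in group_keys + [type_field] if c not in cells.columns]
    if missing:
        raise ValueError(f"cells table lacks columns {missing}")
    df = cells
    if include_types is not None:
        df = df[df[type_field].isin(list(include_types))]
    if df.empty:
        logger.warning("composition_table: no cells after type restriction")
    grouped = df.groupby(group_keys, observed=True)[type_field]
    counts = grouped.value_counts().unstack(fill_value=0)
    if include_types is not None:
        for t in include_types:
            if t not in counts.columns:
                counts[t] = 0
        counts = counts[list(include_types)]
    counts = counts.sort_index(axis=1).sort_index(axis=0)
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("composition_table: dropping %d empty groups", int(empty.sum()))
        counts = counts.loc[~empty]
        totals = totals.loc[~empty]
    fractions = counts.div(totals, axis=0)
    return CompositionTable(counts=counts, fractions=fractions)


def compare_groups(table: CompositionTable, group_a, group_b) -> pd.DataFrame:
    """Per-type fraction difference between two groups (a − b)."""
    for g in (group_a, group_b):
        if g not in table.fractions.index:
            raise KeyError(f"group {g!r} not in table")
    fa = table.fractions.loc[group_a]
    fb = table.fractions.loc[group_b]
    return pd.DataFrame({"fraction_a": fa, "fraction_b": fb, "delta": fa - fb})


def stratify_age(metadata) -> pd.Series:
    """Classify cells as young (<60), old (≥60) or unknown (age missing)."""
    table = metadata.table if hasattr(metadata, "table") else metadata
    age = pd.to_numeric(table["age"], errors="coerce")
    out = pd.Series("unknown", index=table.index, name="age_class", dtype=object)
    out[age < AGE_CUTOFF] = "young"
    out[age >= AGE_CUTOFF] = "old"
    return out


def consistency_check(per_type_counts: pd.DataFrame,
                      declared_totals: pd.Series) -> pd.DataFrame:
    """Compare per-dataset column sums against declared cell totals.

    ``per_type_counts``: cell types × dataset columns; ``declared_totals``:
    dataset → declared total.  Mismatches are reported, never raised — one
    reference row is known to be internally inconsistent (its totals
    duplicate another dataset's) and the report must surface that, not mask
    it.
    """
    rows = []
    for col in per_type_counts.columns:
        s = int(per_type_counts[col].sum())
        declared = declared_totals.get(col)
        declared = None if pd.isna(declared) else int(declared)
        rows.append({"dataset": col, "column_sum": s, "declared_total": declared,
                     "match": declared is not None and s == declared})
    if not rows:
        return pd.DataFrame(
            columns=["column_sum", "declared_total", "match"],
            index=pd.Index([], name="dataset"))
    report = pd.DataFrame(rows).set_index("dataset")
    n_bad = int((~report["match"]).sum())
    if n_bad:
        logger.warning("consistency_check: %d column(s) disagree with declared totals",
                       n_bad)
    return report


# ---------------------------------------------------------------------------
# Transcribed reference tables (shipped as package data)
# ---------------------------------------------------------------------------

def _load_csv(name: str, index_col) -> pd.DataFrame:
    path = resources.files("stromascope").joinpath("data", name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, index_col=index_col)


def load_reference_tables() -> dict:
    """The transcribed reference tables used for cross-table checks.

    Returns ``{"datasets": ..., "tumor_counts": ..., "normal_counts": ...}``:
    dataset-level totals (cells after QC, per-tissue totals, sample counts)
    and the per-cell-type count tables for tumor and adjacent-normal tissue.
    """
    return {
        "datasets": _load_csv("table1_datasets.csv", index_col="dataset"),
        "tumor_counts": _load_csv("table2_tumor_counts.csv", index_col="cell_type"),
        "normal_counts": _load_csv("table3_normal_counts.csv", index_col="cell_type"),
    }


def reference_consistency_report() -> pd.DataFrame:
    """Run consistency_check on the shipped reference tables, both tissues."""
    tabs = load_reference_tables()
    ds = tabs["datasets"]
    tumor = consistency_check(tabs["tumor_counts"], ds["n_cells_tumor"])
    tumor["tissue"] = "tumor"
    normal = consistency_check(tabs["normal_counts"], ds["n_cells_normal"])
    normal["tissue"] = "normal"
    return pd.concat([tumor, normal])
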
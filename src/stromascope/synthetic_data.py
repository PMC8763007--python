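"""Synthetic tumor-microenvironment scRNA-seq data with known ground truth.

Generates UMI count matrices (and full-length TPM tables) with the statistical
structure the downstream analysis assumes: a negative-binomial (gamma-Poisson)
count model with gene-level dispersion, per-cell sequencing-depth variation,
multiplicative per-(sample, gene) batch effects, planted major-cell-type marker
programs, planted endothelial and fibroblast/myofibroblast subtype signature
programs, optional S/G2M cell-cycle programs, and per-sample tumor/normal and
age labels.  Every planted fact is returned as ground truth so each pipeline
stage can be scored.

The model deliberately omits transcriptome-wide correlation structure,
doublets and ambient RNA: planted programs are disjoint gene blocks with
multiplicative fold changes on top of an otherwise independent-gene model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_core import (
    CellMetadata,
    CountMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    write_10x_mtx,
    write_gmt,
    write_metadata,
)

#: Default major-cell-type mixture, loosely shaped like a solid-tumor TME
#: (T-dominated immune compartment, moderate stromal fractions).
DEFAULT_MAJOR_PROPORTIONS = {
    "T": 0.30,
    "Myeloid": 0.15,
    "B": 0.10,
    "EC": 0.12,
    "Fibroblast": 0.12,
    "Myofibroblast": 0.06,
    "Epithelial": 0.15,
}

EC_SUBTYPES = ("C1_ESM1", "C2_ACKR1", "C3_CA4", "C4_FBLN5", "C5_PROX1")
FIBRO_SUBTYPES = ("C7_MYH11", "C8_RGS5", "C9_CFD", "C10_COMP", "C11_SERPINE1")

#: Major types whose cells carry a planted stromal subtype.
EC_MAJOR = "EC"
FIBRO_MAJORS = ("Fibroblast", "Myofibroblast")


class ConfigurationError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Everything the simulator needs; defaults are the study conditions.

    ``signature_log_fold_change`` is a log2 fold change applied
    multiplicatively to a cell's own planted program genes.  Depth and batch
    effects are log-normal; ``dispersion`` is the NB overdispersion phi in
    var = m + phi * m^2, shared across genes.
    """

    n_cells: int = 5000
    n_genes: int = 2000
    major_type_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_MAJOR_PROPORTIONS))
    subtype_proportions_within_ec: dict = field(
        default_factory=lambda: {s: 0.2 for s in EC_SUBTYPES})
    subtype_proportions_within_fibro: dict = field(
        default_factory=lambda: {s: 0.2 for s in FIBRO_SUBTYPES})
    n_signature_genes_per_subtype: int = 40
    signature_log_fold_change: float = 2.0
    n_marker_genes_per_major_type: int = 25
    n_samples: int = 8
    sample_effect_sd: float = 0.2
    mito_gene_fraction: float = 0.05
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.3
    sequencing_depth_mean: float = 5000.0
    sequencing_depth_sd: float = 0.3  # sd of log depth
    n_cell_cycle_genes: int = 20  # per phase (S and G2M)
    cell_cycle_fraction: float = 0.0  # fraction of cells given a cycle program
    cell_cycle_log_fold_change: float = 2.0
    tumor_fraction: float = 0.75
    age_range: tuple = (35, 85)
    cancer_type: str = "synthetic"
    platform: str = "umi"
    seed: int = 0

    def validate(self) -> None:
        for name, props in (
            ("major_type_proportions", self.major_type_proportions),
            ("subtype_proportions_within_ec", self.subtype_proportions_within_ec),
            ("subtype_proportions_within_fibro", self.subtype_proportions_within_fibro),
        ):
            total = float(sum(props.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} sums to {total}, not 1")
            if any(p < 0 for p in props.values()):
                raise ConfigurationError(f"{name} has a negative fraction")
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ConfigurationError("n_cells and n_genes must be positive")
        if not (0 <= self.mito_gene_fraction < 1):
            raise ConfigurationError("mito_gene_fraction must be in [0, 1)")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.platform not in ("umi", "full_length"):
            raise ConfigurationError(f"unknown platform {self.platform!r}")
        n_subtypes = (len(self.subtype_proportions_within_ec)
                      + len(self.subtype_proportions_within_fibro))
        n_special = (self.n_signature_genes_per_subtype * n_subtypes
                     + self.n_marker_genes_per_major_type * len(self.major_type_proportions)
                     + 2 * self.n_cell_cycle_genes
                     + int(self.mito_gene_fraction * self.n_genes))
        if n_special > self.n_genes:
            raise ConfigurationError(
                f"planted programs need {n_special} genes but n_genes = {self.n_genes}")


@dataclass
class PlantedSignatures:
    """Gene programs the simulator planted, in the shapes downstream stages eat."""

    subtypes: GeneSetCollection        # EC + fibro subtype → signature genes
    major_markers: GeneSetCollection   # major type → marker genes
    s_genes: list
    g2m_genes: list


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth for scoring every pipeline stage.

    ``cells``: indexed by cell id — major_type, subtype (None outside the
    stromal lineages), sample_id, tissue, age, is_cycling.
    ``genes``: indexed by gene id — marker_of, signature_of, cc_set, is_mito,
    relative_abundance (the baseline mean fraction of reads per gene).
    """

    cells: pd.DataFrame
    genes: pd.DataFrame

    def to_metadata(self, platform: str, cancer_type: str) -> CellMetadata:
        t = self.cells[["sample_id", "tissue", "age"]].copy()
        t["cancer_type"] = cancer_type
        t["platform"] = platform
        return CellMetadata(t)


def _plan_genes(cfg: SimConfig, rng: np.random.Generator):
    """Lay out the gene axis: mito, marker, signature, cell-cycle, background."""
    n_mito = int(cfg.mito_gene_fraction * cfg.n_genes)
    names, marker_of, signature_of, cc_set, is_mito = [], [], [], [], []

    def block(prefix, n, marker=None, signature=None, cc=None, mito=False):
        for i in range(n):
            names.append(f"{prefix}{i+1}")
            marker_of.append(marker)
            signature_of.append(signature)
            cc_set.append(cc)
            is_mito.append(mito)

    block("MT-SIM", n_mito, mito=True)
    for mt in cfg.major_type_proportions:
        block(f"MK-{mt}-", cfg.n_marker_genes_per_major_type, marker=mt)
    for st in list(cfg.subtype_proportions_within_ec) + list(
            cfg.subtype_proportions_within_fibro):
        block(f"SIG-{st}-", cfg.n_signature_genes_per_subtype, signature=st)
    block("CC-S-", cfg.n_cell_cycle_genes, cc="S")
    block("CC-G2M-", cfg.n_cell_cycle_genes, cc="G2M")
    block("BG-", cfg.n_genes - len(names))

    abundance = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    abundance /= abundance.sum()
    genes = pd.DataFrame(
        {"marker_of": marker_of, "signature_of": signature_of, "cc_set": cc_set,
         "is_mito": is_mito, "relative_abundance": abundance},
        index=pd.Index(names, name="gene_id"),
    )
    return genes


def _plan_cells(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cells
    majors = list(cfg.major_type_proportions)
    p = np.array([cfg.major_type_proportions[m] for m in majors], dtype=float)
    major = rng.choice(majors, size=n, p=p / p.sum())

    subtype = np.full(n, None, dtype=object)
    is_ec = major == EC_MAJOR
    if is_ec.any() and cfg.subtype_proportions_within_ec:
        ks = list(cfg.subtype_proportions_within_ec)
        ps = np.array([cfg.subtype_proportions_within_ec[k] for k in ks])
        subtype[is_ec] = rng.choice(ks, size=is_ec.sum(), p=ps / ps.sum())
    is_fib = np.isin(major, FIBRO_MAJORS)
    if is_fib.any() and cfg.subtype_proportions_within_fibro:
        ks = list(cfg.subtype_proportions_within_fibro)
        ps = np.array([cfg.subtype_proportions_within_fibro[k] for k in ks])
        subtype[is_fib] = rng.choice(ks, size=is_fib.sum(), p=ps / ps.sum())

    sample_idx = rng.integers(0, cfg.n_samples, size=n)
    n_tumor = int(round(cfg.tumor_fraction * cfg.n_samples))
    sample_tissue = np.array(["tumor"] * n_tumor
                             + ["normal"] * (cfg.n_samples - n_tumor))
    lo, hi = cfg.age_range
    sample_age = rng.integers(lo, hi + 1, size=cfg.n_samples)

    is_cycling = rng.random(n) < cfg.cell_cycle_fraction
    cc_phase = np.full(n, None, dtype=object)
    cc_phase[is_cycling] = rng.choice(["S", "G2M"], size=is_cycling.sum())

    return pd.DataFrame(
        {
            "major_type": major,
            "subtype": subtype,
            "sample_id": np.array([f"S{j+1}" for j in sample_idx]),
            "tissue": sample_tissue[sample_idx],
            "age": sample_age[sample_idx].astype(float),
            "is_cycling": is_cycling,
            "cc_phase": cc_phase,
        },
        index=pd.Index([f"cell{i+1}" for i in range(n)], name="cell_id"),
    )


def _mean_matrix(cfg: SimConfig, genes: pd.DataFrame, cells: pd.DataFrame,
                 rng: np.random.Generator) -> np.ndarray:
    """Expected counts per (gene, cell) before NB noise."""
    n_genes, n_cells = len(genes), len(cells)
    sd = cfg.sequencing_depth_sd
    depth = rng.lognormal(np.log(cfg.sequencing_depth_mean) - sd**2 / 2, sd, n_cells)

    mean = np.outer(genes["relative_abundance"].to_numpy(), depth)

    if cfg.sample_effect_sd > 0:
        s = cfg.sample_effect_sd
        sample_names = sorted(cells["sample_id"].unique())
        batch = {name: rng.lognormal(-s**2 / 2, s, n_genes) for name in sample_names}
        cell_sample = cells["sample_id"].to_numpy()
        for name in sample_names:
            cols = cell_sample == name
            mean[:, cols] *= batch[name][:, None]

    fc = 2.0 ** cfg.signature_log_fold_change
    marker_of = genes["marker_of"].to_numpy()
    signature_of = genes["signature_of"].to_numpy()
    for prog, rows in (("major_type", marker_of), ("subtype", signature_of)):
        labels = cells[prog].to_numpy()
        for lab in pd.unique(labels[pd.notna(labels)]):
            g = rows == lab
            c = labels == lab
            if g.any() and c.any():
                mean[np.ix_(g, c)] *= fc

    if cfg.cell_cycle_fraction > 0:
        cc_fc = 2.0 ** cfg.cell_cycle_log_fold_change
        cc_rows = genes["cc_set"].to_numpy()
        phases = cells["cc_phase"].to_numpy()
        for ph in ("S", "G2M"):
            g = cc_rows == ph
            c = phases == ph
            if g.any() and c.any():
                mean[np.ix_(g, c)] *= cc_fc
    return mean


def _nb_sample(mean: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def simulate_tme_counts(config: SimConfig):
    """Simulate a UMI-platform dataset.

    Returns ``(CountMatrix, GroundTruth, PlantedSignatures)``.  Counts are NB
    with mean = baseline abundance × cell depth × batch effect × planted fold
    changes and shared dispersion.  Identical config + seed gives bit-identical
    output.
    """
    config.validate()
    if config.platform != "umi":
        raise ConfigurationError("simulate_tme_counts requires platform='umi'")
    rng = np.random.default_rng(config.seed)
    genes = _plan_genes(config, rng)
    cells = _plan_cells(config, rng)
    mean = _mean_matrix(config, genes, cells, rng)
    counts = _nb_sample(mean, config.dispersion, rng)

    cm = CountMatrix(sp.csr_matrix(counts), list(genes.index), list(cells.index))
    truth = GroundTruth(cells=cells, genes=genes)
    sigs = _collect_signatures(config, genes)
    return cm, truth, sigs


def simulate_full_length(config: SimConfig):
    """Simulate a full-length-platform dataset on the TPM scale.

    Same generative model as the UMI path, then each cell's column is scaled
    to sum to 1e6 (gene lengths are taken as already normalized away).
    Returns ``(ExpressionMatrix[raw_tpm], GroundTruth, PlantedSignatures)``.
    """
    config.validate()
    if config.platform != "full_length":
        raise ConfigurationError("simulate_full_length requires platform='full_length'")
    rng = np.random.default_rng(config.seed)
    genes = _plan_genes(config, rng)
    cells = _plan_cells(config, rng)
    mean = _mean_matrix(config, genes, cells, rng)
    counts = _nb_sample(mean, config.dispersion, rng).astype(float)
    totals = counts.sum(axis=0)
    totals[totals == 0] = 1.0  # all-zero cells stay all-zero
    tpm = counts / totals * 1e6

    em = ExpressionMatrix(tpm, "raw_tpm", list(genes.index), list(cells.index))
    truth = GroundTruth(cells=cells, genes=genes)
    sigs = _collect_signatures(config, genes)
    return em, truth, sigs


def _collect_signatures(cfg: SimConfig, genes: pd.DataFrame) -> PlantedSignatures:
    sub: dict[str, list[str]] = {}
    for st in list(cfg.subtype_proportions_within_ec) + list(
            cfg.subtype_proportions_within_fibro):
        sub[st] = list(genes.index[genes["signature_of"] == st])
    markers = {mt: list(genes.index[genes["marker_of"] == mt])
               for mt in cfg.major_type_proportions}
    s_genes = list(genes.index[genes["cc_set"] == "S"])
    g2m = list(genes.index[genes["cc_set"] == "G2M"])
    return PlantedSignatures(
        subtypes=GeneSetCollection({k: v for k, v in sub.items() if v}),
        major_markers=GeneSetCollection({k: v for k, v in markers.items() if v}),
        s_genes=s_genes,
        g2m_genes=g2m,
    )


def write_fixture(dataset, out_dir: str | Path) -> None:
    """Write a simulated UMI dataset to disk as the pipeline's input formats.

    ``dataset`` is the ``(CountMatrix, GroundTruth, PlantedSignatures)`` triple
    from :func:`simulate_tme_counts`.  Writes the 10x MTX triplet, a per-cell
    metadata CSV, a ground-truth cell-label CSV, and a GMT of the planted
    subtype signatures and major-type markers.  The files round-trip through
    the io_core readers.
    """
    counts, truth, sigs = dataset
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_10x_mtx(counts, out)
    meta = truth.to_metadata(platform="umi", cancer_type="synthetic")
    write_metadata(meta, out / "metadata.csv")
    truth.cells.to_csv(out / "truth_cells.csv", index_label="cell_id")
    combined = dict(sigs.subtypes.items())
    combined.update({f"MAJOR:{k}": v for k, v in sigs.major_markers.items()})
    if sigs.s_genes:
        combined["CC:S"] = sigs.s_genes
    if sigs.g2m_genes:
        combined["CC:G2M"] = sigs.g2m_genes
    write_gmt(GeneSetCollection(combined), out / "signatures.gmt")
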
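"""Pseudo-bulk statistics from labeled single-cell totals.

When per-cell class labels (tumor / non-tumor) are available, the ratio of
mean total UMI counts between the two classes is a direct single-cell analogue
of the deconvolution-based TmS (with the ploidy ratio set aside). Confidence
intervals come from a stratified percentile bootstrap: tumor and non-tumor
cells are resampled separately, with replacement, at their original class
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataValidationError
from .io import log, lower_median


def cell_table_from_matrix(counts, labels: pd.DataFrame) -> pd.DataFrame:
    """Build a per-cell table from a genes x cells count matrix plus labels.

    ``counts`` is an ExpressionMatrix (e.g. read from an MTX triplet) whose
    columns are cells; ``labels`` needs columns cell_id, sample_id and
    cell_class. Per-cell total UMIs and detected-gene counts are computed by
    summing the matrix columns.
    """
    required = {"cell_id", "sample_id", "cell_class"}
    missing = required - set(labels.columns)
    if missing:
        raise DataValidationError(f"label table missing columns: {sorted(missing)}")
    arr = counts.values.to_numpy()
    totals = pd.Series(arr.sum(axis=0), index=counts.sample_ids)
    genes = pd.Series((arr > 0).sum(axis=0), index=counts.sample_ids)
    unmatched = sorted(set(labels["cell_id"]) - set(counts.sample_ids))
    if unmatched:
        raise DataValidationError(f"labels for unknown cell(s): {unmatched[:5]}")
    out = labels[["cell_id", "sample_id", "cell_class"]].copy()
    out["total_umi"] = out["cell_id"].map(totals)
    out["gene_count"] = out["cell_id"].map(genes)
    from .data import validate_cell_table
    return validate_cell_table(out)


@dataclass
class UmiRatioResult:
    sample_id: str
    ratio: float
    ci_lower: float
    ci_upper: float
    n_tumor: int
    n_nontumor: int
    n_boot: int


def normalize_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Equalize the median per-cell total UMI count across samples.

    Each sample's per-cell totals are rescaled so that its median equals the
    cohort reference median (the lower median of the per-sample medians, i.e.
    a value an actual sample attained). Rescaling is a positive multiplicative
    factor per sample, so within-sample cell rankings are preserved. Factors
    are logged.
    """
    medians = cells.groupby("sample_id")["total_umi"].median()
    if (medians <= 0).any():
        bad = medians[medians <= 0].index.tolist()
        raise DataValidationError(f"sample(s) with all-zero cells: {bad}")
    ref = lower_median(medians.to_numpy())
    factors = ref / medians
    out = cells.copy()
    out["total_umi"] = out["total_umi"].astype(float) * out["sample_id"].map(factors).astype(float)
    log.debug("normalize_cells: factors %s", factors.round(4).to_dict())
    return out


def _class_totals(cells: pd.DataFrame):
    sub = cells[cells["cell_class"] != "other"]
    tumor = sub.loc[sub["cell_class"] == "tumor", "total_umi"].to_numpy(dtype=float)
    nontumor = sub.loc[sub["cell_class"] == "nontumor", "total_umi"].to_numpy(dtype=float)
    for name, arr in (("tumor", tumor), ("nontumor", nontumor)):
        if arr.size == 0:
            raise DataValidationError(f"no cells of class {name!r}")
    return tumor, nontumor


def umi_ratio(cells: pd.DataFrame) -> float:
    """Mean total UMI of tumor cells over mean total UMI of non-tumor cells."""
    tumor, nontumor = _class_totals(cells)
    return float(tumor.mean() / nontumor.mean())


def bootstrap_ratio_ci(cells: pd.DataFrame, n_boot: int = 1000,
                       alpha: float = 0.05, seed: int = 0,
                       sample_id: str = "") -> UmiRatioResult:
    """Stratified percentile bootstrap CI for the tumor:non-tumor UMI ratio.

    Each of the ``n_boot`` replicates resamples tumor and non-tumor cells
    separately, with replacement, at the original class sizes; the CI is the
    (alpha/2, 1-alpha/2) percentile interval of the replicate ratios.
    Deterministic under ``seed``.
    """
    if n_boot < 1:
        raise DataValidationError("n_boot must be >= 1")
    tumor, nontumor = _class_totals(cells)
    rng = np.random.default_rng(seed)
    idx_t = rng.integers(0, tumor.size, size=(n_boot, tumor.size))
    idx_n = rng.integers(0, nontumor.size, size=(n_boot, nontumor.size))
    ratios = tumor[idx_t].mean(axis=1) / nontumor[idx_n].mean(axis=1)
    lo, hi = np.percentile(ratios, [100.0 * alpha / 2.0, 100.0 * (1.0 - alpha / 2.0)])
    return UmiRatioResult(
        sample_id=sample_id,
        ratio=umi_ratio(cells),
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_tumor=int(tumor.size),
        n_nontumor=int(nontumor.size),
        n_boot=n_boot,
    )


def per_sample_ratios(cells: pd.DataFrame, n_boot: int = 1000,
                      alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """UMI ratio with bootstrap CI for every sample in a cell table."""
    rows = []
    for i, (sid, grp) in enumerate(cells.groupby("sample_id", sort=True)):
        res = bootstrap_ratio_ci(grp, n_boot=n_boot, alpha=alpha,
                                 seed=seed + i, sample_id=str(sid))
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def compare_gene_counts(cells_a: pd.DataFrame, cells_b: pd.DataFrame,
                        alpha: float = 0.001):
    """Wilcoxon rank-sum comparison of gene counts between two cell sets.

    Utility for deciding whether two labeled clusters differ in the number of
    detectably expressed genes per cell (clusters that do not are candidates
    for merging). Returns ``(p_value, different)``.
    """
    a = cells_a["gene_count"].to_numpy(dtype=float)
    b = cells_b["gene_count"].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataValidationError("both cell sets must be non-empty")
    stat = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat.pvalue), bool(stat.pvalue < alpha)
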
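"""Core data containers shared by all stages.

The central object is :class:`ExpressionMatrix`, a thin validated wrapper around
a genes × samples :class:`pandas.DataFrame` of non-negative expression values,
with a per-sample role tag (``mixed`` / ``reference`` / ``spikein``) and an
explicit raw-vs-normalized state flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ROLES = ("mixed", "reference", "spikein")
VALID_CELL_CLASSES = ("tumor", "nontumor", "other")


class DataValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Genes × samples non-negative expression values.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as columns.
    sample_role
        Role per sample, aligned with ``values.columns``.
    normalized
        Whether sample-level scale normalization has been applied.
    """

    values: pd.DataFrame
    sample_role: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise DataValidationError(
                f"missing value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise DataValidationError(
                f"negative count at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        self.sample_role = pd.Series(self.sample_role, index=v.columns)
        bad = set(self.sample_role.unique()) - set(VALID_ROLES)
        if bad:
            raise DataValidationError(f"unknown sample roles: {sorted(bad)}")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_with_role(self, role: str) -> list:
        return self.sample_role[self.sample_role == role].index.tolist()

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)],
            self.sample_role[list(sample_ids)],
            normalized=self.normalized,
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)],
            self.sample_role,
            normalized=self.normalized,
        )

    def with_values(self, values: pd.DataFrame, normalized: bool | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values,
            self.sample_role.copy(),
            normalized=self.normalized if normalized is None else normalized,
        )


def make_expression_matrix(values: pd.DataFrame, role: str | pd.Series = "mixed",
                           normalized: bool = False) -> ExpressionMatrix:
    """Build an ExpressionMatrix with a uniform or per-sample role."""
    if isinstance(role, str):
        role = pd.Series(role, index=values.columns)
    return ExpressionMatrix(values, role, normalized=normalized)


def validate_purity_ploidy(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample purity/ploidy table.

    Requires columns ``sample_id, purity, ploidy, caller``; purity ρ must lie in
    (0, 1) and ploidy Ψ_T must be positive; (sample_id, caller) pairs unique.
    """
    required = ["sample_id", "purity", "ploidy", "caller"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise DataValidationError(f"purity/ploidy table missing columns: {missing}")
    t = table[required].copy()
    t["purity"] = t["purity"].astype(float)
    t["ploidy"] = t["ploidy"].astype(float)
    bad = t[(t["purity"] <= 0) | (t["purity"] >= 1)]
    if len(bad):
        raise DataValidationError(
            f"purity outside (0,1) for sample(s) {bad['sample_id'].tolist()[:5]}"
        )
    bad = t[t["ploidy"] <= 0]
    if len(bad):
        raise DataValidationError(
            f"non-positive ploidy for sample(s) {bad['sample_id'].tolist()[:5]}"
        )
    if t.duplicated(subset=["sample_id", "caller"]).any():
        d = t[t.duplicated(subset=["sample_id", "caller"])]["sample_id"].tolist()
        raise DataValidationError(f"duplicate (sample_id, caller) pairs: {d[:5]}")
    return t


def validate_cell_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-cell table: ids, class labels, total UMIs and gene counts.

    Invariant: ``total_umi >= gene_count >= 0`` — every detected gene carries at
    least one UMI.
    """
    required = ["cell_id", "sample_id", "cell_class", "total_umi", "gene_count"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise DataValidationError(f"cell table missing columns: {missing}")
    t = table[required].copy()
    bad = set(t["cell_class"].unique()) - set(VALID_CELL_CLASSES)
    if bad:
        raise DataValidationError(f"unknown cell classes: {sorted(bad)}")
    if (t["gene_count"] < 0).any():
        raise DataValidationError("negative gene_count")
    viol = t[t["total_umi"] < t["gene_count"]]
    if len(viol):
        raise DataValidationError(
            f"total_umi < gene_count for cell(s) {viol['cell_id'].tolist()[:5]}"
        )
    return t


@dataclass
class RunConfig:
    """Run-level configuration recorded into every output manifest."""

    normalization: str = "upper-quartile"
    n_signature_genes: int = 1500
    n_spikeins: int | None = None  # None → 10% of cohort size
    pi_tol: float = 1e-4
    max_iter: int = 50
    quad_nodes: int = 64
    seed: int = 0
    pi_cap: float = 0.85
    pi_top_percentile: float = 2.5
    psi_n: float = 2.0
    pseudo_count: float = 1.0
    max_zero_fraction: float = 0.2
    sigma_floor: float = 0.05
    polish: bool = True

    def __post_init__(self) -> None:
        if self.pi_tol <= 0 or self.quad_nodes <= 0:
            raise DataValidationError("tolerances must be positive")
        if not (0 < self.pi_cap < 1):
            raise DataValidationError("pi_cap must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def config_from_dict(d: dict) -> RunConfig:
    known = {k: v for k, v in d.items() if k in RunConfig.__dataclass_fields__}
    unknown = set(d) - set(known)
    if unknown:
        raise DataValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**known)
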
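"""TmS: tumor-specific total mRNA expression per haploid genome.

TmS combines the RNA-derived tumor transcript proportion pi with DNA-derived
tumor purity rho and ploidy Psi_T:

    TmS = [pi * (1 - rho) * Psi_N] / [rho * (1 - pi) * Psi_T]

with the non-tumor ploidy Psi_N assumed diploid (2) unless overridden (for
cell-line style benchmarks the ploidy ratio is set to 1). The module also
implements the extreme-pi sample filters, the two-caller consensus with
Cook's-distance outlier exclusion, and per-patient multi-region summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .data import DataValidationError
from .io import log


def compute_tms(pi, rho, psi_t, psi_n: float = 2.0):
    """TmS = [pi*(1-rho)*psi_n] / [rho*(1-pi)*psi_t]. Scalar or vectorized."""
    pi = np.asarray(pi, dtype=float)
    rho = np.asarray(rho, dtype=float)
    psi_t = np.asarray(psi_t, dtype=float)
    if np.any((pi <= 0) | (pi >= 1)) or np.any((rho <= 0) | (rho >= 1)):
        raise DataValidationError("pi and rho must lie strictly in (0, 1)")
    if np.any(psi_t <= 0) or np.any(np.asarray(psi_n) <= 0):
        raise DataValidationError("ploidies must be positive")
    out = (pi * (1.0 - rho) * psi_n) / (rho * (1.0 - pi) * psi_t)
    return float(out) if out.ndim == 0 else out


def filter_extreme_pi(pi: pd.Series, cap: float = 0.85,
                      top_percentile: float = 2.5) -> pd.Series:
    """Keep/drop flags for extreme transcript-proportion estimates.

    A sample is dropped when pi > ``cap`` or when pi lies strictly above the
    (100 - top_percentile) empirical percentile of the input vector (linear
    interpolation between order statistics). Both rules are evaluated on the
    same input vector. Returns a boolean Series (True = keep).
    """
    pi = pd.Series(pi)
    if len(pi) == 0:
        raise DataValidationError("empty pi vector")
    vals = pi.to_numpy(dtype=float)
    if np.any((vals <= 0) | (vals >= 1)):
        raise DataValidationError("pi values must lie in (0, 1)")
    cutoff = np.percentile(vals, 100.0 - top_percentile)
    keep = (vals <= cap) & (vals <= cutoff)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("pi filter: dropping %d of %d sample(s) (cap %.2f, pct %.1f)",
                 n_drop, len(vals), cap, top_percentile)
    return pd.Series(keep, index=pi.index, name="keep")


def tms_table(pi: pd.Series, purity_ploidy: pd.DataFrame, psi_n: float = 2.0,
              cap: float = 0.85, top_percentile: float = 2.5) -> pd.DataFrame:
    """Per-sample, per-caller TmS with filter status.

    Samples in ``pi`` without a purity/ploidy row are an error (the ids are
    listed); the extreme-pi filter is applied to the full pi vector first and
    recorded per row in ``filter_status`` (kept / extreme_pi).
    """
    unmatched = sorted(set(pi.index) - set(purity_ploidy["sample_id"]))
    if unmatched:
        raise DataValidationError(
            f"no purity/ploidy for sample(s): {unmatched}"
        )
    keep = filter_extreme_pi(pi, cap=cap, top_percentile=top_percentile)
    rows = []
    for _, pp in purity_ploidy.iterrows():
        sid = pp["sample_id"]
        if sid not in pi.index:
            continue
        p = float(pi.loc[sid])
        rows.append({
            "sample_id": sid,
            "pi": p,
            "purity": float(pp["purity"]),
            "ploidy": float(pp["ploidy"]),
            "psi_n": psi_n,
            "caller": pp["caller"],
            "tms": compute_tms(p, pp["purity"], pp["ploidy"], psi_n),
            "filter_status": "kept" if keep.loc[sid] else "extreme_pi",
        })
    return pd.DataFrame(rows)


def consensus_tms(table: pd.DataFrame, caller_a: str | None = None,
                  caller_b: str | None = None) -> pd.DataFrame:
    """Two-caller consensus TmS with Cook's-distance outlier exclusion.

    Fits ordinary least squares of log2(TmS_A) on log2(TmS_B) across samples
    with both callers present, drops samples with Cook's distance >= 4/n, and
    reports the geometric mean sqrt(TmS_A * TmS_B) for the kept samples.

    ``table`` needs columns sample_id, caller, tms. Returns one row per
    complete sample: tms_a, tms_b, cooks_distance, kept, consensus_tms.
    """
    t = table[table["tms"].notna()].copy()
    bad = t[t["tms"] <= 0]
    if len(bad):
        log.warning("consensus: rejecting %d row(s) with non-positive TmS", len(bad))
        t = t[t["tms"] > 0]
    callers = sorted(t["caller"].unique()) if caller_a is None else [caller_a, caller_b]
    if len(callers) != 2:
        raise DataValidationError(
            f"consensus needs exactly two callers, found {callers}"
        )
    wide = t.pivot_table(index="sample_id", columns="caller", values="tms")
    wide = wide.dropna(subset=callers)
    n = len(wide)
    if n < 3:
        raise DataValidationError(f"consensus needs >= 3 complete samples, got {n}")
    ya = np.log2(wide[callers[0]].to_numpy())
    yb = np.log2(wide[callers[1]].to_numpy())
    model = sm.OLS(ya, sm.add_constant(yb)).fit()
    # a numerically perfect fit leaves only float-epsilon residuals, whose
    # Cook's distances are meaningless ratios; points on an exact line are
    # not outliers
    resid_scale = max(float(np.sqrt(np.mean(ya ** 2))), 1.0)
    if np.abs(model.resid).max() <= 1e-9 * resid_scale:
        cooks = np.zeros(n)
    else:
        cooks = OLSInfluence(model).cooks_distance[0]
        cooks = np.where(np.isfinite(cooks), cooks, np.inf)
    threshold = 4.0 / n
    kept = cooks < threshold
    out = pd.DataFrame({
        "sample_id": wide.index,
        "tms_a": wide[callers[0]].to_numpy(),
        "tms_b": wide[callers[1]].to_numpy(),
        "cooks_distance": cooks,
        "kept": kept,
    })
    out["consensus_tms"] = np.where(
        kept, np.sqrt(out["tms_a"] * out["tms_b"]), np.nan
    )
    log.info("consensus: kept %d of %d sample(s) (Cook's threshold %.3e)",
             int(kept.sum()), n, threshold)
    return out


def multiregion_summary(regions: pd.DataFrame) -> pd.DataFrame:
    """Per-patient TmS summaries over multi-region designs.

    ``regions`` needs columns patient_id and tms (one row per tumor region).
    Reports TmS_max, TmS_med (median; mean of the central pair for even
    counts) and the range log2(TmS_max) - log2(TmS_min); the range is absent
    (NaN) for single-region patients.
    """
    if (regions["tms"] <= 0).any():
        bad = regions.loc[regions["tms"] <= 0, "patient_id"].tolist()
        raise DataValidationError(f"non-positive TmS for patient(s) {bad[:5]}")
    rows = []
    for pid, grp in regions.groupby("patient_id", sort=True):
        vals = grp["tms"].to_numpy(dtype=float)
        rng = (np.log2(vals.max()) - np.log2(vals.min())
               if len(vals) >= 2 else np.nan)
        rows.append({
            "patient_id": pid,
            "n_regions": len(vals),
            "tms_max": float(vals.max()),
            "tms_med": float(np.median(vals)),
            "tms_range": rng,
        })
    return pd.DataFrame(rows)
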
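"""Identifiability-based gene ranking for the intrinsic tumor signature.

A gene's tumor-component mean mu_T is identifiable when the log-likelihood is
sharply curved around its maximum. The curvature is measured as observed
Fisher information H_kk of the profiled log-likelihood, and converted into the
length of the asymptotic 95% profile-likelihood confidence interval,

    score_k = 2 * sqrt(2 * chi2_{0.95}(1) / H_kk),

so that smaller scores mean tighter intervals and better-identified genes.
Genes ranked by ascending score; the top K form the intrinsic tumor signature
set used for the final deconvolution fit.

A brute-force profile-likelihood CI (grid scan with full re-maximization of
all other parameters) is provided as an independent oracle for small
instances; the Fisher approximation is the production path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataValidationError, RunConfig
from .deconv import (
    SIGMA_T_BOUNDS,
    DeconvolutionFit,
    NumericalError,
    _gl_nodes,
    grid_loglik,
    vector_golden_max,
    vector_grid_then_golden_max,
)
from .io import log


def profiled_curvature(fun, x0: float, h: float = 1e-3) -> float:
    """Negative second derivative of ``fun`` at ``x0``.

    Central finite differences with one step of Richardson refinement:
    D = (4*D_{h/2} - D_h) / 3 where D_h is the standard 3-point estimate.
    Returns H = -d2 fun / dx2, positive for a local maximum.
    """
    def second(step):
        return (fun(x0 + step) - 2.0 * fun(x0) + fun(x0 - step)) / step ** 2

    d = (4.0 * second(h / 2.0) - second(h)) / 3.0
    return -d


def observed_fisher_information(fit: DeconvolutionFit, genes=None,
                                h: float = 1e-3) -> pd.Series:
    """Curvature H_kk of the profiled log-likelihood in each mu_Tk.

    The per-gene (mu_Tk, sigma_Tk) block of the observed information is
    evaluated by central finite differences (step ``h`` on the log2 scale,
    one Richardson refinement), with pi held at the fitted optimum (a single
    gene's contribution to pi is O(1/G)). Profiling sigma_Tk out of the block
    gives the curvature of the profiled log-likelihood,

        H_kk = l_mm - l_ms^2 / l_ss  (negated),

    which is the reciprocal of the (k, k) entry of the blockwise inverse.
    A valid asymptotic CI needs the block to be an interior maximum: genes
    whose sigma-direction curvature is not negative (a saddle or a boundary
    solution) and genes with non-positive or non-finite profiled curvature
    come back NaN (unidentifiable) and receive an infinite selection score
    downstream.
    """
    gp = fit.gene_params
    # identifiability is judged on the real cohort: virtual spike-ins exist
    # to stabilize pi and would otherwise inflate apparent curvature
    real = ~fit.pi.index.isin(fit.spikein_ids)
    pi = fit.pi.to_numpy()[real]
    Y = fit.Y[:, real]
    mu = gp["mu_t"].to_numpy()
    sg = gp["sigma_t"].to_numpy()
    mu_n = gp["mu_n"].to_numpy()
    sg_n = gp["sigma_n"].to_numpy()
    nodes = _gl_nodes(fit.config.quad_nodes)

    def L(m, s):
        return grid_loglik(Y, pi, m, s, mu_n, sg_n, nodes=nodes).sum(axis=1)

    l0 = L(mu, sg)

    def block(step):
        lmm = (L(mu + step, sg) - 2.0 * l0 + L(mu - step, sg)) / step ** 2
        lss = (L(mu, sg + step) - 2.0 * l0 + L(mu, sg - step)) / step ** 2
        lms = (L(mu + step, sg + step) - L(mu + step, sg - step)
               - L(mu - step, sg + step) + L(mu - step, sg - step)) / (4.0 * step ** 2)
        return np.stack([lmm, lss, lms])

    lmm, lss, lms = (4.0 * block(h / 2.0) - block(h)) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        profiled = lmm - lms ** 2 / lss
    hkk = np.where(lss < 0, -profiled, np.nan)
    hkk = np.where(np.isfinite(hkk) & (hkk > 0), hkk, np.nan)
    out = pd.Series(hkk, index=gp.index, name="H_kk")
    if genes is not None:
        out = out.loc[list(genes)]
    n_bad = int(out.isna().sum())
    if n_bad:
        log.info("Fisher information: %d gene(s) flagged unidentifiable", n_bad)
    return out


def gene_selection_score(h_kk, alpha: float = 0.05):
    """Length of the asymptotic (1-alpha) profile-likelihood CI of mu_Tk.

    score = 2*sqrt(2*q/H_kk) with q the chi-square(1) quantile at coverage
    1-alpha (3.8415 for alpha=0.05). Smaller = more identifiable. Non-positive
    or missing curvature maps to +inf.
    """
    q = stats.chi2.ppf(1.0 - alpha, df=1)
    h = np.asarray(h_kk, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = 2.0 * np.sqrt(2.0 * q / h)
    score = np.where(np.isfinite(score) & (h > 0), score, np.inf)
    if isinstance(h_kk, pd.Series):
        return pd.Series(score, index=h_kk.index, name="score")
    return score if score.ndim else float(score)


def rank_and_select(scores: pd.Series, k: int) -> pd.DataFrame:
    """Rank genes ascending by score (ties lexicographic by id); flag top k."""
    g = len(scores)
    if not (1 <= k <= g):
        raise DataValidationError(f"K={k} outside 1..{g}")
    tbl = pd.DataFrame({"gene_id": scores.index, "score": scores.to_numpy(dtype=float)})
    tbl = tbl.sort_values(["score", "gene_id"], kind="mergesort").reset_index(drop=True)
    tbl["rank"] = np.arange(1, g + 1)
    tbl["selected"] = tbl["rank"] <= k
    return tbl


def select_signature_genes(fit: DeconvolutionFit, k: int, alpha: float = 0.05) -> pd.DataFrame:
    """Score, rank and select the intrinsic tumor signature set from a fit."""
    hkk = observed_fisher_information(fit)
    scores = gene_selection_score(hkk, alpha=alpha)
    return rank_and_select(scores, k)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_profile_ci(mixed, ref_params, fit: DeconvolutionFit, gene: str,
                           alpha: float = 0.05, n_grid: int = 13,
                           span: float | None = None):
    """Profile-likelihood CI for mu_T of ``gene`` by grid scan and re-fit.

    At each grid value of mu_T the likelihood is re-maximized over all other
    parameters (pi for every sample and the tumor parameters of every other
    gene). The CI is the deviance set {mu: 2*(l_max - l_profile(mu)) <= 2*q}
    with q = chi2_{1-alpha}(1) -- the threshold whose quadratic expansion
    reproduces the asymptotic interval mu_hat +- sqrt(2*q/H) that the gene
    selection score approximates, so both lengths estimate the same interval.
    Endpoints are interpolated on sqrt(deviance) between grid points (linear
    in mu for a locally quadratic profile). Intended as a test oracle on
    small instances (G, M <= ~30), not as the production path.

    Returns ``(lower, upper, bounded)``; ``bounded`` is False when the scan
    range never crosses the threshold on one side.
    """
    if gene not in fit.gene_params.index:
        raise DataValidationError(f"gene {gene!r} not in fit")
    q = stats.chi2.ppf(1.0 - alpha, df=1)
    mu_hat = float(fit.gene_params.loc[gene, "mu_t"])
    if span is None:
        hkk = observed_fisher_information(fit, genes=[gene]).iloc[0]
        half = 1.5 * np.sqrt(2.0 * q / hkk) if np.isfinite(hkk) else 4.0
        span = max(float(half), 0.25)
    grid = mu_hat + np.linspace(-span, span, n_grid)

    cfg = fit.config
    refit_cfg = RunConfig(**{**cfg.to_dict(), "max_iter": 25, "pi_tol": 1e-5})
    genes = fit.gene_params.index.tolist()
    prof = np.empty(n_grid)
    for j, x in enumerate(grid):
        init = fit.gene_params[["mu_t", "sigma_t"]].copy()
        init.loc[gene, "mu_t"] = x
        prof[j] = _refit_with_fixed_mu(
            mixed, ref_params, genes, gene, x, init, refit_cfg,
            pi_init=fit.pi.to_numpy(),
        )
    l_max = max(prof.max(), float(fit.total_loglik))
    dev = 2.0 * (l_max - prof)
    threshold = 2.0 * q
    inside = dev <= threshold

    if not inside.any():
        return float("nan"), float("nan"), False

    def crossing(i0, i1):
        # interpolate on sqrt(deviance), which is linear in mu for a locally
        # quadratic profile (plain linear interpolation of a convex deviance
        # would bias the interval narrow)
        d0, d1 = np.sqrt(dev[i0]), np.sqrt(dev[i1])
        if d1 == d0:
            return grid[i1]
        frac = (np.sqrt(threshold) - d0) / (d1 - d0)
        return grid[i0] + frac * (grid[i1] - grid[i0])

    idx = np.where(inside)[0]
    lo_i, hi_i = idx[0], idx[-1]
    bounded = lo_i > 0 and hi_i < n_grid - 1
    lower = crossing(lo_i, lo_i - 1) if lo_i > 0 else grid[0]
    upper = crossing(hi_i, hi_i + 1) if hi_i < n_grid - 1 else grid[-1]
    return float(lower), float(upper), bool(bounded)


def _refit_with_fixed_mu(mixed, ref_params, genes, gene, mu_fixed, init, cfg,
                         pi_init=None) -> float:
    """Max log-likelihood with one gene's mu_T pinned (coordinate re-fit)."""
    from .deconv import _gl_nodes as gln  # local aliases for clarity

    sub = mixed.subset_genes(genes)
    Y = np.maximum(sub.values.to_numpy(dtype=float), cfg.pseudo_count)
    G, M = Y.shape
    k = genes.index(gene)
    mu_n = ref_params.loc[genes, "mu_n"].to_numpy(dtype=float)
    sigma_n = np.maximum(ref_params.loc[genes, "sigma_n"].to_numpy(dtype=float),
                         cfg.sigma_floor)
    mu_t = init.loc[genes, "mu_t"].to_numpy(dtype=float).copy()
    sigma_t = np.clip(init.loc[genes, "sigma_t"].to_numpy(dtype=float),
                      *SIGMA_T_BOUNDS)
    mu_t[k] = mu_fixed
    pi = np.full(M, 0.5) if pi_init is None else np.asarray(pi_init, dtype=float).copy()
    nodes = gln(cfg.quad_nodes)
    free = np.arange(G) != k
    mu_lo, mu_hi = mu_t - 5.0, mu_t + 5.0
    mu_lo[k] = mu_hi[k] = mu_fixed

    def ll(pi_v, mu_v, sig_v):
        return grid_loglik(Y, pi_v, mu_v, sig_v, mu_n, sigma_n, nodes=nodes)

    total = float(ll(pi, mu_t, sigma_t).sum())
    for _ in range(cfg.max_iter):
        pi_new, _ = vector_grid_then_golden_max(
            lambda p: ll(p, mu_t, sigma_t).sum(axis=0),
            np.full(M, 1e-3), np.full(M, 1.0 - 1e-3), tol=5e-5, prev=pi)
        d = float(np.max(np.abs(pi_new - pi)))
        pi = pi_new
        mu_t, _ = vector_grid_then_golden_max(
            lambda m: ll(pi, m, sigma_t).sum(axis=1), mu_lo, mu_hi,
            tol=1e-4, prev=mu_t)
        mu_t[k] = mu_fixed
        sigma_t, _ = vector_golden_max(
            lambda s: ll(pi, mu_t, s).sum(axis=1),
            np.full(G, SIGMA_T_BOUNDS[0]), np.full(G, SIGMA_T_BOUNDS[1]),
            tol=1e-4, prev=sigma_t)
        total_new = float(ll(pi, mu_t, sigma_t).sum())
        if total_new < total - 1e-8:
            raise NumericalError("profile re-fit likelihood decreased")
        total = total_new
        if d < cfg.pi_tol:
            break
    return total
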
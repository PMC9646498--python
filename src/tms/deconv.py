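"""Two-component transcriptome deconvolution under a log2-normal convolution model.

A mixed bulk expression value is modeled as

    Y_ig = pi_i * T_ig + (1 - pi_i) * N_ig

where the hidden tumor component T_ig and the non-tumor component N_ig are
log2-normal per gene: log2 T_ig ~ Normal(mu_T[g], sigma_T[g]^2) and
log2 N_ig ~ Normal(mu_N[g], sigma_N[g]^2). The non-tumor parameters are
estimated once from reference samples and held fixed; the per-sample tumor
transcript proportion pi_i and the per-gene tumor parameters are obtained by
coordinate-wise maximum likelihood (iterated conditional modes).

The density of Y is the convolution of the two scaled log2-normal kernels,

    f(y) = int_0^y f_N(t) f_T(y - t) dt,

where f_N is the density of (1-pi) N and f_T that of pi T. Written out in log2
units the normalizing constant carries an (ln 2)^-2 Jacobian in addition to
1/(2 pi sigma_N sigma_T); it is included here so that f integrates to one (the
location of the maximum is unaffected). Two evaluation routes exist: adaptive
quadrature (:func:`mixture_density`, the reference route) and a fixed
Gauss-Legendre grid used inside the fit so that coordinate ascent is monotone
on a single deterministic objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import logsumexp

from .data import DataValidationError, ExpressionMatrix, RunConfig
from .io import log

LN2 = np.log(2.0)
PI_EPS = 1e-3
SIGMA_T_BOUNDS = (0.05, 5.0)
MU_T_HALFWIDTH = 5.0


class NumericalError(RuntimeError):
    """Raised when the optimizer fails its ascent contract."""


# ---------------------------------------------------------------------------
# Reference (non-tumor) component
# ---------------------------------------------------------------------------

def estimate_reference_params(ref: ExpressionMatrix, pseudo_count: float = 1.0) -> pd.DataFrame:
    """Per-gene (mu_N, sigma_N) on the log2 scale from reference samples.

    Non-positive counts are replaced by ``pseudo_count`` before the log2
    transform; positive counts enter untouched. Genes that are all-zero across
    the reference are flagged ``usable=False`` and excluded from fitting
    downstream. Requires at least two reference samples (sigma_N is a sample
    standard deviation).
    """
    if ref.n_samples < 2:
        raise DataValidationError(
            f"need >= 2 reference samples, got {ref.n_samples}"
        )
    arr = ref.values.to_numpy(dtype=float)
    all_zero = (arr <= 0).all(axis=1)
    logged = np.log2(np.where(arr > 0, arr, pseudo_count))
    mu = logged.mean(axis=1)
    sigma = logged.std(axis=1, ddof=1)
    out = pd.DataFrame(
        {"mu_n": mu, "sigma_n": sigma, "usable": ~all_zero},
        index=ref.values.index,
    )
    if all_zero.any():
        log.info("reference: %d all-zero gene(s) flagged unusable", int(all_zero.sum()))
    return out


# ---------------------------------------------------------------------------
# Mixture density
# ---------------------------------------------------------------------------

def _check_finite(**params) -> None:
    for name, v in params.items():
        if not np.all(np.isfinite(v)):
            raise DataValidationError(f"non-finite parameter {name}={v}")


def mixture_density(y: float, pi: float, mu_t: float, sigma_t: float,
                    mu_n: float, sigma_n: float, rtol: float = 1e-6) -> float:
    """Density of Y = pi*T + (1-pi)*N at ``y`` by adaptive quadrature.

    T and N are log2-normal with the given log2-scale means and SDs. Returns 0
    for y <= 0 (outside the support). This is the reference evaluation route;
    the fitting path uses a fixed-grid version of the same integrand.
    """
    _check_finite(pi=pi, mu_t=mu_t, sigma_t=sigma_t, mu_n=mu_n, sigma_n=sigma_n)
    if not (0.0 < pi < 1.0) or sigma_t <= 0 or sigma_n <= 0:
        raise DataValidationError("require 0 < pi < 1 and positive sigmas")
    if y <= 0:
        return 0.0
    # pi*T is log2-normal with mean mu_t + log2(pi); equivalently a natural
    # lognormal with shape sigma*ln2 and log-scale ln(pi) + mu_t*ln2.
    m_n = np.log(1.0 - pi) + mu_n * LN2
    m_t = np.log(pi) + mu_t * LN2
    s_n = sigma_n * LN2
    s_t = sigma_t * LN2
    c = 1.0 / (2.0 * np.pi * s_n * s_t)

    def integrand(t):
        u = y - t
        z_n = (np.log(t) - m_n) / s_n
        z_t = (np.log(u) - m_t) / s_t
        return c / (t * u) * np.exp(-0.5 * (z_n * z_n + z_t * z_t))

    val, _ = integrate.quad(integrand, 0.0, y, epsrel=rtol, epsabs=0.0, limit=200)
    return float(val)


def _gl_nodes(n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    u = 0.5 * (x + 1.0)           # nodes on (0, 1)
    logw = np.log(0.5 * w)
    return u, logw


try:  # fast path: jit-compiled kernel (numerically identical layout per call)
    from numba import njit

    @njit(cache=True)
    def _conv_kernel(log2Y, pos, loc_n, loc_t, sigma_n, sigma_t,
                     log2u, log2v, kern_w, out):
        G, M = log2Y.shape
        K = log2u.shape[0]
        vals = np.empty(K)
        for g in range(G):
            sn = sigma_n[g]
            st = sigma_t[g]
            const = -np.log(2.0 * np.pi) - 2.0 * np.log(np.log(2.0)) \
                - np.log(sn * st)
            for m in range(M):
                if not pos[g, m]:
                    out[g, m] = -np.inf
                    continue
                a_n = log2Y[g, m] - loc_n[g, m]
                a_t = log2Y[g, m] - loc_t[g, m]
                hi = -np.inf
                for k in range(K):
                    z_n = (a_n + log2u[k]) / sn
                    z_t = (a_t + log2v[k]) / st
                    v = kern_w[k] - 0.5 * (z_n * z_n + z_t * z_t)
                    vals[k] = v
                    if v > hi:
                        hi = v
                acc = 0.0
                for k in range(K):
                    acc += np.exp(vals[k] - hi)
                out[g, m] = const - log2Y[g, m] * np.log(2.0) + hi + np.log(acc)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False


def grid_loglik(Y, pi, mu_t, sigma_t, mu_n, sigma_n, nodes=64):
    """Log density log f(Y_ig) on a fixed Gauss-Legendre grid, vectorized.

    Y has shape (G, M); ``pi`` has shape (M,); the gene parameters have shape
    (G,). Returns (G, M). Entries with Y <= 0 get -inf.
    """
    u, logw = _gl_nodes(nodes) if isinstance(nodes, int) else nodes
    Y = np.asarray(Y, dtype=float)
    pi = np.asarray(pi, dtype=float)
    mu_t = np.asarray(mu_t, dtype=float)
    sigma_t = np.asarray(sigma_t, dtype=float)
    mu_n = np.asarray(mu_n, dtype=float)
    sigma_n = np.asarray(sigma_n, dtype=float)

    pos = Y > 0
    logY = np.log(np.where(pos, Y, 1.0))
    log2Y = logY / LN2
    # effective log2-scale locations of (1-pi)*N and pi*T
    loc_n = mu_n[:, None] + np.log2(1.0 - pi)[None, :]
    loc_t = mu_t[:, None] + np.log2(pi)[None, :]
    log2u = np.log2(u)
    log2v = np.log2(1.0 - u)
    kern_w = logw - np.log(u) - np.log(1.0 - u)

    if _HAVE_NUMBA:
        out = np.empty_like(Y)
        _conv_kernel(np.ascontiguousarray(log2Y), pos, loc_n, loc_t,
                     sigma_n, sigma_t, log2u, log2v, kern_w, out)
        return out

    # t = Y*u is the normal-component value, Y*(1-u) the tumor one
    z_n = (log2Y[..., None] + log2u - loc_n[..., None]) / sigma_n[:, None, None]
    z_t = (log2Y[..., None] + log2v - loc_t[..., None]) / sigma_t[:, None, None]
    kern = kern_w - 0.5 * (z_n ** 2 + z_t ** 2)
    const = (-np.log(2.0 * np.pi) - 2.0 * np.log(LN2)
             - np.log(sigma_n * sigma_t))[:, None]
    ll = const - logY + logsumexp(kern, axis=-1)
    return np.where(pos, ll, -np.inf)


# ---------------------------------------------------------------------------
# Virtual spike-ins
# ---------------------------------------------------------------------------

def add_virtual_spikeins(mixed: ExpressionMatrix, ref: ExpressionMatrix,
                         n: int, seed: int, noise_sd: float = 0.1) -> ExpressionMatrix:
    """Append ``n`` near-pure-normal pseudo-samples to balance the pi range.

    Each spike-in is a reference sample drawn with replacement and perturbed
    by multiplicative log2-normal noise (SD ``noise_sd``), so that it behaves
    as a mixed sample with pi ~ 0. Deterministic under ``seed``.
    """
    if n < 0:
        raise DataValidationError("spike-in count must be >= 0")
    if n == 0:
        return mixed
    if ref.n_samples == 0:
        raise DataValidationError("spike-ins requested but reference is empty")
    rng = np.random.default_rng(seed)
    cols = rng.integers(0, ref.n_samples, size=n)
    base = ref.values.to_numpy(dtype=float)[:, cols]
    noisy = base * 2.0 ** rng.normal(0.0, noise_sd, size=base.shape)
    names = [f"spikein_{j + 1}" for j in range(n)]
    values = pd.concat(
        [mixed.values, pd.DataFrame(noisy, index=mixed.values.index, columns=names)],
        axis=1,
    )
    roles = pd.concat([mixed.sample_role, pd.Series("spikein", index=names)])
    log.info("appended %d virtual spike-in sample(s) (seed=%d)", n, seed)
    return ExpressionMatrix(values, roles, normalized=mixed.normalized)


# ---------------------------------------------------------------------------
# Vectorized bounded golden-section search
# ---------------------------------------------------------------------------

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def vector_golden_max(f, lo, hi, tol=1e-5, prev=None):
    """Elementwise golden-section maximization of f over [lo, hi].

    ``f`` maps a candidate vector to a vector of objective values; lo/hi are
    per-element bounds. If ``prev`` is given, each element keeps its previous
    iterate unless the new point strictly improves the objective (ties broken
    toward the previous iterate), which makes coordinate ascent monotone.
    Returns (x, f(x)).
    """
    a = np.array(lo, dtype=float)
    b = np.array(hi, dtype=float)
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc = f(c)
    fd = f(d)
    while np.max(b - a) > tol:
        left = fc >= fd
        # shrink to [a, d] where the left probe wins, else to [c, b]
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        d_new = np.where(left, c, a + _INVPHI * (b - a))
        c_new = np.where(left, b - _INVPHI * (b - a), d)
        f_carry = np.where(left, fc, fd)
        x_eval = np.where(left, c_new, d_new)
        f_eval = f(x_eval)
        c, d = c_new, d_new
        fc = np.where(left, f_eval, f_carry)
        fd = np.where(left, f_carry, f_eval)
    x = 0.5 * (a + b)
    fx = f(x)
    if prev is not None:
        f_prev = f(np.asarray(prev, dtype=float))
        keep = fx <= f_prev
        x = np.where(keep, prev, x)
        fx = np.where(keep, f_prev, fx)
    return x, fx


def vector_grid_then_golden_max(f, lo, hi, n_coarse=41, tol=1e-4, prev=None):
    """Coarse grid scan followed by local golden refinement, elementwise.

    Coordinate slices of the convolution likelihood in mu_T can be multimodal;
    a pure golden-section search then converges to the nearest local maximum.
    Scanning ``n_coarse`` equispaced points first and refining around the best
    one makes the update a global 1-D search at grid resolution.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    fracs = np.linspace(0.0, 1.0, n_coarse)
    best_x = lo.copy()
    best_f = f(lo)
    for frac in fracs[1:]:
        x = lo + frac * (hi - lo)
        fx = f(x)
        better = fx > best_f
        best_x = np.where(better, x, best_x)
        best_f = np.where(better, fx, best_f)
    step = (hi - lo) / (n_coarse - 1)
    return vector_golden_max(
        f, np.maximum(lo, best_x - step), np.minimum(hi, best_x + step),
        tol=tol, prev=prev,
    )


# ---------------------------------------------------------------------------
# Deconvolution fit
# ---------------------------------------------------------------------------

@dataclass
class DeconvolutionFit:
    """Result of the coordinate-ascent fit.

    ``pi`` covers every fitted column (including spike-ins); ``pi_mixed``
    restricts to the real mixed samples, which is what gets reported.
    """

    pi: pd.Series
    gene_params: pd.DataFrame   # mu_t, sigma_t, mu_n, sigma_n per fitted gene
    loglik_trace: list
    converged: bool
    n_iter: int
    spikein_ids: list
    config: RunConfig
    Y: np.ndarray = field(repr=False, default=None)

    @property
    def total_loglik(self) -> float:
        return self.loglik_trace[-1]

    @property
    def pi_mixed(self) -> pd.Series:
        return self.pi.drop(self.spikein_ids)

    @property
    def gene_subset(self) -> list:
        return self.gene_params.index.tolist()

    def loglik_matrix(self) -> np.ndarray:
        """Per-gene, per-sample log-likelihood contributions at the optimum."""
        gp = self.gene_params
        return grid_loglik(
            self.Y, self.pi.to_numpy(),
            gp["mu_t"].to_numpy(), gp["sigma_t"].to_numpy(),
            gp["mu_n"].to_numpy(), gp["sigma_n"].to_numpy(),
            nodes=self.config.quad_nodes,
        )


def filter_genes_for_fit(mixed: ExpressionMatrix, ref_params: pd.DataFrame,
                         max_zero_fraction: float = 0.2) -> list:
    """Genes usable for fitting: a usable reference fit and few zeros in mixed."""
    common = mixed.values.index.intersection(ref_params.index)
    arr = mixed.values.loc[common].to_numpy(dtype=float)
    zero_frac = (arr <= 0).mean(axis=1)
    ok = ref_params.loc[common, "usable"].to_numpy() & (zero_frac <= max_zero_fraction)
    return common[ok].tolist()


def _init_mu_t(Y: np.ndarray, mu_n: np.ndarray) -> np.ndarray:
    # moment guess at pi = 0.5: T ~ 2*median(Y) - 2^mu_n, floored well below N
    med = np.median(Y, axis=1)
    resid = np.maximum(2.0 * med - 2.0 ** mu_n, 2.0 ** (mu_n - 4.0))
    return np.log2(resid)


def fit_deconvolution(mixed: ExpressionMatrix, ref_params: pd.DataFrame,
                      gene_subset=None, config: RunConfig | None = None,
                      update_gene_params: bool = True,
                      init_tumor_params: pd.DataFrame | None = None) -> DeconvolutionFit:
    """Coordinate-ascent ML fit of per-sample pi and per-gene tumor parameters.

    Alternates bounded golden-section maximizations of each pi_i (given the
    gene parameters) and of each (mu_T, sigma_T) pair (given pi), each update
    accepted only if it improves the shared fixed-grid likelihood, so the
    total log-likelihood is non-decreasing by construction. Stops when
    ``max |delta pi| < config.pi_tol`` or after ``config.max_iter`` sweeps.

    Set ``update_gene_params=False`` (with ``init_tumor_params``) to estimate
    pi under known tumor component parameters.

    The joint likelihood has a near-flat ridge along coherent (mu_T, pi)
    trade-offs on which plain coordinate ascent can stall; after convergence a
    polish phase restarts the sweeps from mu_T shifted by a small fixed set of
    offsets and keeps any strictly better solution (``config.polish``).
    """
    config = config or RunConfig()
    if gene_subset is None:
        gene_subset = filter_genes_for_fit(mixed, ref_params, config.max_zero_fraction)
    gene_subset = list(gene_subset)
    if not gene_subset:
        raise DataValidationError("empty gene subset for deconvolution")
    missing = set(gene_subset) - set(ref_params.index)
    if missing:
        raise DataValidationError(
            f"no reference parameters for gene(s) {sorted(missing)[:5]}"
        )

    values = mixed.values.loc[gene_subset]
    sample_ids = mixed.sample_ids
    spikein_ids = mixed.samples_with_role("spikein")
    Y = np.maximum(values.to_numpy(dtype=float), config.pseudo_count)
    G, M = Y.shape

    mu_n = ref_params.loc[gene_subset, "mu_n"].to_numpy(dtype=float)
    sigma_n = np.maximum(
        ref_params.loc[gene_subset, "sigma_n"].to_numpy(dtype=float),
        config.sigma_floor,
    )

    if init_tumor_params is not None:
        mu_t = init_tumor_params.loc[gene_subset, "mu_t"].to_numpy(dtype=float).copy()
        sigma_t = init_tumor_params.loc[gene_subset, "sigma_t"].to_numpy(dtype=float).copy()
    else:
        mu_t = _init_mu_t(Y, mu_n)
        sigma_t = np.full(G, 0.5)
    sigma_t = np.clip(sigma_t, *SIGMA_T_BOUNDS)
    mu_lo, mu_hi = mu_t - MU_T_HALFWIDTH, mu_t + MU_T_HALFWIDTH
    # start at the no-tumor null: the first pi sweep is a global 1-D search,
    # so informative samples move immediately, while samples whose pi slice is
    # flat (e.g. pure-normal profiles, where tumor and normal labels swap
    # freely) stay pinned near zero by the tie-break toward the previous
    # iterate instead of drifting from an arbitrary interior start
    pi = np.full(M, 0.02)

    nodes = _gl_nodes(config.quad_nodes)

    def ll_matrix(pi_v, mu_v, sig_v):
        return grid_loglik(Y, pi_v, mu_v, sig_v, mu_n, sigma_n, nodes=nodes)

    def run_sweeps(pi, mu_t, sigma_t, max_iter, diagnose_first=False,
                   abandon_below=None):
        """Coordinate-ascent sweeps from the given state; monotone by design.

        ``abandon_below``: stop early once the optimistic projection
        (current total plus the latest per-sweep gain times the remaining
        sweeps) can no longer reach this target — used to cut short polish
        candidates that will not beat the incumbent solution.
        """
        total = float(ll_matrix(pi, mu_t, sigma_t).sum())
        subtrace = [total]
        converged = False
        n_iter = 0
        for it in range(max_iter):
            n_iter = it + 1
            pi_new, _ = vector_grid_then_golden_max(
                lambda p: ll_matrix(p, mu_t, sigma_t).sum(axis=0),
                np.full(M, PI_EPS), np.full(M, 1.0 - PI_EPS),
                tol=min(config.pi_tol, 1e-4) / 2.0, prev=pi,
            )
            delta_pi = float(np.max(np.abs(pi_new - pi)))
            pi = pi_new
            if update_gene_params:
                mu_t, _ = vector_grid_then_golden_max(
                    lambda m: ll_matrix(pi, m, sigma_t).sum(axis=1),
                    mu_lo, mu_hi, tol=1e-4, prev=mu_t)
                sigma_t, _ = vector_golden_max(
                    lambda s: ll_matrix(pi, mu_t, s).sum(axis=1),
                    np.full(G, SIGMA_T_BOUNDS[0]),
                    np.full(G, SIGMA_T_BOUNDS[1]), tol=1e-4, prev=sigma_t,
                )
            total_new = float(ll_matrix(pi, mu_t, sigma_t).sum())
            if total_new < total - 1e-8:
                if diagnose_first and it == 0:
                    per_gene = ll_matrix(pi, mu_t, sigma_t).sum(axis=1)
                    dump = pd.Series(per_gene, index=gene_subset).sort_values().head(20)
                    raise NumericalError(
                        "likelihood failed to improve in first iteration; "
                        f"worst per-gene log-likelihoods:\n{dump}"
                    )
                raise NumericalError(
                    f"likelihood decreased at iteration {n_iter}: "
                    f"{total} -> {total_new}"
                )
            gain = total_new - total
            total = total_new
            subtrace.append(total)
            if delta_pi < config.pi_tol:
                converged = True
                break
            # coordinate-ascent gains decay quickly, so a 5-sweep linear
            # extrapolation is already an optimistic reachability bound
            if (abandon_below is not None
                    and total + gain * min(max_iter - n_iter, 5) < abandon_below):
                break
        return pi, mu_t, sigma_t, total, subtrace, converged, n_iter

    pi, mu_t, sigma_t, total, trace, converged, n_iter = run_sweeps(
        pi, mu_t, sigma_t, config.max_iter, diagnose_first=True)

    if config.polish and update_gene_params:
        for _round in range(3):
            improved = False
            for delta in (0.25, -0.25):
                cand = run_sweeps(
                    pi, np.clip(mu_t + delta, mu_lo, mu_hi), sigma_t,
                    min(config.max_iter, 15), abandon_below=total)
                if cand[3] > total + 1e-6:
                    pi, mu_t, sigma_t, total = cand[:4]
                    converged, n_iter = cand[5], n_iter + cand[6]
                    trace.append(total)   # accepted milestones only: monotone
                    improved = True
            if not improved:
                break

    log.info(
        "deconvolution: %d genes, %d samples, %d iteration(s), loglik %.3f%s",
        G, M, n_iter, total, "" if converged else " (iteration cap reached)",
    )
    gene_params = pd.DataFrame(
        {"mu_t": mu_t, "sigma_t": sigma_t, "mu_n": mu_n, "sigma_n": sigma_n},
        index=pd.Index(gene_subset, name="gene_id"),
    )
    return DeconvolutionFit(
        pi=pd.Series(np.clip(pi, PI_EPS, 1.0 - PI_EPS), index=sample_ids, name="pi"),
        gene_params=gene_params,
        loglik_trace=trace,
        converged=converged,
        n_iter=n_iter,
        spikein_ids=spikein_ids,
        config=config,
        Y=Y,
    )
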
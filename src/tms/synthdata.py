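"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator draws bulk cohorts from the same log2-normal convolution model
that the deconvolution assumes, with planted gene classes that stress the
gene-selection step:

- ``unimodal``: a single well-separated tumor component (the genes the
  signature selection should find),
- ``multimodal_tumor``: the tumor mean differs across planted subtypes, so a
  single-mode fit is misspecified,
- ``high_variance_normal``: the non-tumor SD is inflated, washing out the
  tumor signal,
- ``non_differential``: tumor and non-tumor components coincide.

Per-sample truth (pi, purity, ploidy, TmS) satisfies the TmS identity exactly:
TmS = [pi*(1-rho)*psi_n] / [rho*(1-pi)*psi_t]. Either pi is drawn from its own
distribution and TmS follows, or a global tumor expression scale ``tms_scale``
is given and pi is obtained by inverting the identity. A per-sample
library-size factor emulates sequencing-depth variation that scale
normalization must remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DataValidationError, make_expression_matrix

GENE_CLASSES = ("unimodal", "multimodal_tumor", "high_variance_normal", "non_differential")


@dataclass
class SimulationConfig:
    """Knobs of the bulk cohort generator; defaults sized for routine runs."""

    n_genes: int = 500
    n_mixed: int = 60
    n_ref: int = 20
    class_props: dict = field(default_factory=lambda: {
        "unimodal": 0.25,
        "multimodal_tumor": 0.10,
        "high_variance_normal": 0.10,
        "non_differential": 0.55,
    })
    pi_low: float = 0.2
    pi_high: float = 0.8
    mu_n_mean: float = 6.0
    mu_n_sd: float = 1.5
    sigma_n_low: float = 0.2
    sigma_n_high: float = 0.6
    shift_low: float = 0.8          # log2 tumor shift for differential genes
    shift_high: float = 2.5
    hv_shift_high: float = 0.8      # |shift| cap for high-variance-normal genes
    sigma_t_low: float = 0.2
    sigma_t_high: float = 0.5
    n_subtypes: int = 2
    subtype_shift: float = 2.0      # log2 gap between subtype tumor means
    high_var_factor: float = 3.0    # sigma_N inflation for high-variance genes
    purity_low: float = 0.3
    purity_high: float = 0.9
    ploidy_low: float = 1.5
    ploidy_high: float = 4.5
    psi_n: float = 2.0
    tms_scale: float | None = None  # if set, pi is implied by the TmS identity
    library_sd: float = 0.2         # log2 SD of per-sample depth factors
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_props.values()) - 1.0) > 1e-9:
            raise DataValidationError("gene class proportions must sum to 1")
        unknown = set(self.class_props) - set(GENE_CLASSES)
        if unknown:
            raise DataValidationError(f"unknown gene classes: {sorted(unknown)}")
        if min(self.n_genes, self.n_mixed, self.n_ref) <= 0:
            raise DataValidationError("all counts must be positive")


@dataclass
class SimulatedTruth:
    samples: pd.DataFrame   # pi, purity, ploidy, psi_n, tms, subtype per sample
    genes: pd.DataFrame     # gene_class, mu_n, sigma_n, mu_t, sigma_t per gene


def _gene_class_counts(config: SimulationConfig) -> dict:
    # largest-remainder apportionment so counts are exact and deterministic
    raw = {c: config.class_props.get(c, 0.0) * config.n_genes for c in GENE_CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = config.n_genes - sum(counts.values())
    for c in sorted(GENE_CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def simulate_cohort(config: SimulationConfig):
    """Draw (mixed, reference, purity/ploidy table, truth) for one cohort."""
    rng = np.random.default_rng(config.seed)
    G, M, R = config.n_genes, config.n_mixed, config.n_ref

    counts = _gene_class_counts(config)
    gene_class = np.repeat(
        [c for c in GENE_CLASSES], [counts[c] for c in GENE_CLASSES]
    )
    gene_ids = [f"g{i + 1:05d}" for i in range(G)]

    mu_n = rng.normal(config.mu_n_mean, config.mu_n_sd, size=G)
    sigma_n = rng.uniform(config.sigma_n_low, config.sigma_n_high, size=G)
    sigma_n[gene_class == "high_variance_normal"] *= config.high_var_factor

    # unimodal signature-like genes are up-regulated in the tumor component
    # (the hidden component must contribute measurably to be identifiable);
    # multimodal genes shift either way; high-variance-normal genes carry at
    # most a weak shift, drowned by their inflated non-tumor noise
    shift = rng.uniform(config.shift_low, config.shift_high, size=G)
    mm = gene_class == "multimodal_tumor"
    shift[mm] *= rng.choice([-1.0, 1.0], size=int(mm.sum()))
    hv = gene_class == "high_variance_normal"
    shift[hv] = (rng.uniform(0.0, config.hv_shift_high, size=int(hv.sum()))
                 * rng.choice([-1.0, 1.0], size=int(hv.sum())))
    mu_t = mu_n + shift
    nd = gene_class == "non_differential"
    mu_t[nd] = mu_n[nd]
    sigma_t = rng.uniform(config.sigma_t_low, config.sigma_t_high, size=G)
    sigma_t[nd] = sigma_n[nd]

    # per-sample DNA truth and transcript proportion
    rho = rng.uniform(config.purity_low, config.purity_high, size=M)
    psi_t = rng.uniform(config.ploidy_low, config.ploidy_high, size=M)
    if config.tms_scale is None:
        pi = rng.uniform(config.pi_low, config.pi_high, size=M)
    else:
        odds = config.tms_scale * rho * psi_t / ((1.0 - rho) * config.psi_n)
        pi = odds / (1.0 + odds)
        bad = ~((pi > 0) & (pi < 1))
        if bad.any():
            raise DataValidationError(
                f"implied pi outside (0,1) for sample index {int(np.argwhere(bad)[0])}"
            )
    tms_true = (pi * (1.0 - rho) * config.psi_n) / (rho * (1.0 - pi) * psi_t)
    subtype = rng.integers(0, config.n_subtypes, size=M)

    # subtype-specific tumor means for multimodal genes, centered on mu_t
    offsets = (np.arange(config.n_subtypes) - (config.n_subtypes - 1) / 2.0) \
        * config.subtype_shift
    mm = gene_class == "multimodal_tumor"
    mu_t_sample = np.tile(mu_t[:, None], (1, M))
    mu_t_sample[mm, :] = mu_t[mm, None] + offsets[subtype][None, :]

    tumor = 2.0 ** rng.normal(mu_t_sample, sigma_t[:, None], size=(G, M))
    normal_mix = 2.0 ** rng.normal(mu_n[:, None], sigma_n[:, None], size=(G, M))
    mixed_vals = pi[None, :] * tumor + (1.0 - pi[None, :]) * normal_mix
    mixed_vals *= 2.0 ** rng.normal(0.0, config.library_sd, size=M)[None, :]

    ref_vals = 2.0 ** rng.normal(mu_n[:, None], sigma_n[:, None], size=(G, R))
    ref_vals *= 2.0 ** rng.normal(0.0, config.library_sd, size=R)[None, :]

    mixed_ids = [f"mix_{i + 1:03d}" for i in range(M)]
    ref_ids = [f"ref_{i + 1:03d}" for i in range(R)]
    mixed = make_expression_matrix(
        pd.DataFrame(mixed_vals, index=gene_ids, columns=mixed_ids), role="mixed")
    reference = make_expression_matrix(
        pd.DataFrame(ref_vals, index=gene_ids, columns=ref_ids), role="reference")

    purity_ploidy = pd.DataFrame({
        "sample_id": mixed_ids,
        "purity": rho,
        "ploidy": psi_t,
        "caller": "simulated",
    })
    truth = SimulatedTruth(
        samples=pd.DataFrame({
            "sample_id": mixed_ids, "pi": pi, "purity": rho, "ploidy": psi_t,
            "psi_n": config.psi_n, "tms": tms_true, "subtype": subtype,
        }),
        genes=pd.DataFrame({
            "gene_id": gene_ids, "gene_class": gene_class, "mu_n": mu_n,
            "sigma_n": sigma_n, "mu_t": mu_t, "sigma_t": sigma_t,
        }),
    )
    return mixed, reference, purity_ploidy, truth


def simulate_single_cell(n_tumor: int, n_nontumor: int, ratio: float,
                         dispersion: float = 0.3, seed: int = 0,
                         base_total: float = 2000.0,
                         sample_id: str = "S1") -> pd.DataFrame:
    """Per-cell totals with a known tumor:non-tumor mean UMI ratio.

    Totals are log-normal with equal log-scale dispersion in both classes, so
    the ratio of class means equals ``ratio`` exactly in expectation;
    ``dispersion`` is the log2-scale SD (0 puts every cell exactly at its
    class mean). Gene counts are a noisy concave monotone function of the
    total, mirroring the tight total-UMI / gene-count relationship seen in
    real cells.
    """
    if n_tumor <= 0 or n_nontumor <= 0:
        raise DataValidationError("cell counts must be positive")
    if ratio <= 0:
        raise DataValidationError("ratio must be positive")
    rng = np.random.default_rng(seed)
    # divide by the lognormal mean factor so E[total] hits the class mean
    mean_factor = np.exp(0.5 * (dispersion * np.log(2.0)) ** 2)

    def draw(n, mean):
        if dispersion == 0:
            return np.full(n, mean)
        return mean / mean_factor * 2.0 ** rng.normal(0.0, dispersion, size=n)

    totals = np.concatenate([
        draw(n_tumor, base_total * ratio), draw(n_nontumor, base_total)])
    classes = ["tumor"] * n_tumor + ["nontumor"] * n_nontumor
    noise = 2.0 ** rng.normal(0.0, 0.05, size=totals.size)
    gene_counts = np.minimum(
        np.round(2.0 * totals ** 0.8 * noise), np.floor(totals)
    ).astype(int)
    return pd.DataFrame({
        "cell_id": [f"c{i + 1:06d}" for i in range(totals.size)],
        "sample_id": sample_id,
        "cell_class": classes,
        "total_umi": totals,
        "gene_count": np.maximum(gene_counts, 0),
    })
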
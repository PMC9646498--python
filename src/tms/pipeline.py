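"""End-to-end orchestration: normalize -> spike-in -> pilot fit -> gene
selection -> final fit -> pi filter -> TmS -> (optional) consensus."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .data import DataValidationError, ExpressionMatrix, RunConfig
from .deconv import (
    DeconvolutionFit,
    add_virtual_spikeins,
    estimate_reference_params,
    filter_genes_for_fit,
    fit_deconvolution,
)
from .geneselect import select_signature_genes
from .io import log, scale_normalize
from .tmscore import consensus_tms, tms_table


@dataclass
class PipelineResult:
    ref_params: pd.DataFrame
    pilot_fit: DeconvolutionFit
    gene_scores: pd.DataFrame
    final_fit: DeconvolutionFit
    pi: pd.Series               # per real mixed sample
    tms: pd.DataFrame           # per sample x caller, with filter status
    consensus: pd.DataFrame | None

    @property
    def signature_genes(self) -> list:
        sel = self.gene_scores[self.gene_scores["selected"]]
        return sel["gene_id"].tolist()


def normalize_together(mixed: ExpressionMatrix, ref: ExpressionMatrix,
                       scheme: str = "upper-quartile"):
    """Scale-normalize mixed and reference samples on one common scale."""
    if set(mixed.gene_ids) != set(ref.gene_ids):
        raise DataValidationError("mixed and reference gene sets differ")
    ref = ref.subset_genes(mixed.gene_ids)
    combined = ExpressionMatrix(
        pd.concat([mixed.values, ref.values], axis=1),
        pd.concat([mixed.sample_role, ref.sample_role]),
    )
    norm = scale_normalize(combined, scheme)
    return norm.subset_samples(mixed.sample_ids), norm.subset_samples(ref.sample_ids)


def run_pipeline(mixed: ExpressionMatrix, ref: ExpressionMatrix,
                 purity_ploidy: pd.DataFrame, config: RunConfig | None = None,
                 k: int | None = None) -> PipelineResult:
    """Run the full TmS estimation on one cohort.

    ``k`` overrides ``config.n_signature_genes`` (clipped to the number of
    genes that survive the fitting filters, with a log message). Samples in
    the mixed matrix must all have purity/ploidy rows; unmatched ids raise.
    """
    config = config or RunConfig()
    unmatched = sorted(set(mixed.sample_ids) - set(purity_ploidy["sample_id"]))
    if unmatched:
        raise DataValidationError(f"no purity/ploidy for sample(s): {unmatched}")

    mixed_n, ref_n = normalize_together(mixed, ref, config.normalization)
    ref_params = estimate_reference_params(ref_n, config.pseudo_count)

    n_spike = config.n_spikeins
    if n_spike is None:
        n_spike = math.ceil(0.1 * mixed_n.n_samples)
    with_spikes = add_virtual_spikeins(mixed_n, ref_n, n_spike, config.seed)

    genes = filter_genes_for_fit(with_spikes, ref_params, config.max_zero_fraction)
    log.info("pipeline: %d gene(s) retained for the pilot fit", len(genes))
    pilot = fit_deconvolution(with_spikes, ref_params, genes, config)

    k = k if k is not None else config.n_signature_genes
    if k > len(genes):
        log.info("pipeline: K=%d exceeds %d retained genes; clipping", k, len(genes))
        k = len(genes)
    scores = select_signature_genes(pilot, k)
    signature = scores.loc[scores["selected"], "gene_id"].tolist()

    final = fit_deconvolution(with_spikes, ref_params, signature, config)
    pi = final.pi_mixed

    tms = tms_table(pi, purity_ploidy, psi_n=config.psi_n,
                    cap=config.pi_cap, top_percentile=config.pi_top_percentile)
    consensus = None
    if tms["caller"].nunique() == 2:
        kept = tms[tms["filter_status"] == "kept"]
        consensus = consensus_tms(kept)
    elif tms["caller"].nunique() > 2:
        log.info("pipeline: %d callers present; consensus needs exactly 2, skipping",
                 tms["caller"].nunique())
    return PipelineResult(
        ref_params=ref_params, pilot_fit=pilot, gene_scores=scores,
        final_fit=final, pi=pi, tms=tms, consensus=consensus,
    )
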
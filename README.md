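# tms — tumor-specific total mRNA expression from bulk RNA-seq

Bulk tumor samples are mixtures of tumor and non-tumor cells, and routine
normalization erases differences in *how much* mRNA each cell type produces.
`tms` recovers that hidden quantity: the **tumor-specific total mRNA
expression score (TmS)**, the ratio of total mRNA per haploid genome in tumor
cells to that of the surrounding non-tumor cells,

```
TmS = [ π (1 − ρ) Ψ_N ] / [ ρ (1 − π) Ψ_T ]
```

where

- **π** — tumor transcript proportion: the fraction of the bulk sample's
  mRNA that comes from tumor cells, estimated here by deconvolving the bulk
  expression matrix under a log2-normal convolution likelihood,
- **ρ** — tumor purity (fraction of cells that are tumor), from DNA callers,
- **Ψ_T**, **Ψ_N** — average tumor and non-tumor ploidy (Ψ_N defaults to the
  diploid 2).

The package is aimed at computational biologists with matched bulk RNA-seq
and DNA-derived purity/ploidy tables (or labeled single-cell data), and
provides:

- **Deconvolution** (`tms.deconv`): each mixed value is modeled as
  `Y = π·T + (1−π)·N` with `log2 T ~ N(μ_T, σ_T²)` and `log2 N ~ N(μ_N, σ_N²)`.
  The non-tumor parameters come from reference (adjacent-normal) samples; π
  and the tumor parameters are fitted by monotone coordinate ascent over a
  convolution likelihood evaluated by Gauss–Legendre quadrature (with an
  adaptive-quadrature reference implementation, `mixture_density`). Virtual
  "normal" spike-ins can be appended to stabilize cohorts whose π
  distribution is skewed.
- **Gene selection** (`tms.geneselect`): genes are ranked by the length of
  the asymptotic 95% profile-likelihood confidence interval of their tumor
  mean, `score = 2·sqrt(2·χ²₀.₉₅(1)/H_kk)` with `H_kk` the observed Fisher
  information of the profiled log-likelihood. The top-K genes (the
  *intrinsic tumor signature*) feed a final, more robust fit. A brute-force
  profile-likelihood CI is included as a small-instance oracle.
- **TmS assembly** (`tms.tmscore`): the TmS formula, extreme-π filters
  (cap at 0.85 and a top-2.5-percentile rule), a two-caller consensus
  (log-log regression, Cook's distance ≥ 4/n exclusion, geometric mean) and
  per-patient multi-region summaries (TmS_max, TmS_med, log2 range).
- **Pseudo-bulk utilities** (`tms.pseudobulk`): tumor:non-tumor mean
  total-UMI ratios from labeled single cells with stratified percentile
  bootstrap CIs.
- **A synthetic-data generator** (`tms.synthdata`) producing cohorts with
  known per-sample π/purity/ploidy/TmS and planted gene classes, so every
  stage is testable without downloads.

## A worked example

```python
import numpy as np
from tms import (RunConfig, SimulationConfig, estimate_reference_params,
                 fit_deconvolution, normalize_together, simulate_cohort)

cfg = SimulationConfig(n_genes=120, n_mixed=20, n_ref=12, seed=42)
mixed, reference, purity_ploidy, truth = simulate_cohort(cfg)

mixed_n, ref_n = normalize_together(mixed, reference)
ref_params = estimate_reference_params(ref_n)
fit = fit_deconvolution(mixed_n, ref_params, config=RunConfig(seed=42))

err = np.abs(fit.pi_mixed - truth.samples.set_index("sample_id")["pi"])
print(f"median |error|: {err.median():.4f}")
```

prints (from `examples/simulate_and_deconvolve.py`):

```
sample      true pi  estimated
mix_001       0.436      0.537
mix_002       0.248      0.268
mix_003       0.653      0.726
...
median |error| over 20 samples: 0.0609
log-likelihood: -10041.2 after 25 sweeps (converged: True)
```

Each row compares a sample's true tumor transcript proportion with its
estimate from the 120-gene fit; at this deliberately tiny size the typical
error is ~0.06, and it drops to ~0.02–0.03 at the default cohort size
(500 genes, 60 samples) with gene selection — see `scripts/acceptance.py`.

The `examples/` directory holds one short script per capability
(deconvolution, gene selection, TmS + consensus + multi-region, pseudo-bulk
ratios, and a synthetic two-cell-line mixing benchmark), each printing what
it computes and what the numbers mean.

## Command line

A thin CLI wraps the library for batch use:

```bash
tms simulate --seed 7 --out sim/
tms pipeline --mixed sim/mixed.tsv --ref sim/reference.tsv \
             --pp sim/purity_ploidy.tsv --k 250 --seed 7 --out run/
tms consensus --tms run/tms.tsv --out run/consensus.tsv
```

Subcommands: `simulate`, `normalize`, `deconvolve`, `select-genes`, `tms`,
`consensus`, `multiregion`, `pseudobulk`, `pipeline`. Exit codes: 0 success,
1 usage, 2 data/schema error, 3 numerical failure. Every output directory
receives a `manifest.json` (command, effective configuration, seed, package
version), and re-running a manifest's command reproduces its outputs at the
declared float precision.

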
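# Methods

## The quantity being estimated

For a cell population, let `S` be the average mRNA transcript count per cell
per haploid genome. For a mixed tumor sample with tumor (T) and non-tumor (N)
cell populations, the tumor-specific total mRNA expression score is
`TmS = S_T / S_N`. Taking the ratio cancels sample-level technical effects
(depth, library preparation) that scale both populations alike. Writing the
tumor transcript proportion `π` (the fraction of the sample's mRNA that is
tumor-derived), the tumor purity `ρ` (fraction of cells that are tumor) and
the average ploidies `Ψ_T`, `Ψ_N`,

    TmS = [π / (1 − π)] / [ρ Ψ_T / ((1 − ρ) Ψ_N)]
        = [π (1 − ρ) Ψ_N] / [ρ (1 − π) Ψ_T].

`ρ` and `Ψ_T` come from DNA callers (ASCAT/ABSOLUTE/Sequenza-style tables
are consumed as input); `Ψ_N` is assumed diploid unless overridden (for
cell-line mixtures the ploidy ratio is set to 1 and TmS is the per-cell RNA
content ratio). `π` is the estimand of the deconvolution module.

Because TmS depends on the DNA quantities only through `ρ Ψ_T / (1 − ρ)`,
it is robust to the purity/ploidy ambiguity that DNA callers often cannot
resolve (they pin down the product better than the factors); this invariance
is asserted as a property test.

## Deconvolution model

For sample `i` and gene `g`, the scale-normalized mixed expression is

    Y_ig = π_i · T_ig + (1 − π_i) · N_ig,

with log2-normal components `log2 T_ig ~ Normal(μ_Tg, σ_Tg²)` and
`log2 N_ig ~ Normal(μ_Ng, σ_Ng²)`. The density of `Y` is the convolution

    f(y) = ∫₀^y f_N(t) · f_T(y − t) dt,

of the densities of `(1 − π)N` and `πT`. Written in log2 units the
normalizing constant is `1 / (2π σ_N σ_T (ln 2)²)`; the `(ln 2)²` Jacobian
is required for `∫ f = 1` and is included here (the likelihood's argmax is
unaffected by the constant). Two evaluation routes exist:

- `mixture_density`: adaptive quadrature (`scipy.integrate.quad`,
  relative tolerance 1e-6) — the reference route, validated against
  10⁶-draw Monte-Carlo histograms;
- `grid_loglik`: a fixed 64-node Gauss–Legendre rule on `t ∈ (0, y)`,
  evaluated in log-space with a streaming log-sum-exp (JIT-compiled when
  numba is importable, with an equivalent vectorized numpy fallback that
  agrees to ~1e-14). The fitter uses only this route, so its objective is a
  single deterministic function. 64 nodes resolve component SDs down to
  ≈0.05 log2 units; degenerate unit tests that need SDs of 0.01 raise the
  node count through `RunConfig.quad_nodes`.

### Estimation

1. **Reference parameters.** `μ_Ng`, `σ_Ng` are the mean and sample SD of
   log2 reference expression, computed once and held fixed (the tumor
   component is the hidden one). Non-positive counts are replaced by a
   pseudo-count (default 1) before the log; genes all-zero in the reference
   are flagged unusable; a floor of 0.05 guards degenerate `σ_N`.
2. **Gene filtering.** Genes with more than 20% zeros among mixed samples
   are excluded from fitting.
3. **Coordinate ascent** (iterated conditional modes): alternate 1-D
   maximizations of each `π_i` given gene parameters and of each
   `(μ_Tg, σ_Tg)` given `π`. Because coordinate slices of a convolution
   likelihood can be multimodal, the `π` and `μ_T` updates first scan a
   41-point equispaced grid and then refine with golden-section inside the
   winning cell; `σ_T` uses golden-section on [0.05, 5]. Every update is
   accepted only if it improves the shared objective (ties broken toward the
   previous iterate), making the total log-likelihood non-decreasing by
   construction — this is asserted at every sweep. Iteration stops when
   `max_i |Δπ_i| < 1e-4` (default) or after 50 sweeps.
4. **Ridge polish.** The joint likelihood has a near-flat ridge along
   coherent `(μ_T up, π down)` trade-offs (`log2 π + μ_T` is only weakly
   separated when the normal component is uninformative), and coordinate
   ascent can stall on it. After convergence the sweeps are restarted from
   `μ_T ± 0.25` (a fixed, deterministic offset set); any strictly better
   solution is kept, for up to three rounds. Candidates are abandoned early
   once an optimistic 5-sweep linear extrapolation of their per-sweep gain
   cannot reach the incumbent. On a 10-gene instance this recovers ~3
   likelihood units that plain ICM leaves on the table; on 500-gene cohorts
   it typically finds nothing and costs a few rejected candidate sweeps.
5. **Initialization.** `μ_T` starts at a moment estimate
   (`log2(2·median(Y) − 2^{μ_N})`, floored), `σ_T` at 0.5, and `π` at the
   no-tumor null 0.02. Since the first `π` sweep is a global grid search,
   informative samples move immediately; samples whose `π` slice is flat
   (pure-normal profiles, where tumor and normal labels swap freely) stay
   pinned near zero by the tie-break rather than freezing at an arbitrary
   interior value.

`π̂` is reported on `(0.001, 0.999)`. Virtual "normal" **spike-ins** —
reference samples resampled with multiplicative log2-normal noise (SD 0.1),
appended as pseudo-mixed samples at a default count of 10% of the cohort —
anchor the low end of the `π` distribution in cohorts where every real
sample has substantial tumor content. Their fitted `π̂` (typically ≈0.01–0.05)
is excluded from all reported results.

## Gene selection

The deconvolution is only as good as the genes that enter it. A gene is
useful when its tumor mean `μ_Tk` is *identifiable*: the profile
log-likelihood in `μ_Tk` is sharply curved. The selection score is the
length of the asymptotic 95% profile-likelihood CI,

    score_k = 2 · sqrt(2 · χ²₀.₉₅(1) / H_kk),   χ²₀.₉₅(1) = 3.8415,

where `H_kk` is the curvature (observed Fisher information) of the profiled
log-likelihood at the optimum. `H_kk` is computed blockwise per gene: the
2×2 observed-information block in `(μ_Tk, σ_Tk)` is evaluated by central
finite differences (step 1e-3 on the log2 scale, one Richardson
refinement) with `π` fixed at the fitted optimum (one gene's influence on
`π̂` is O(1/G)), and `σ_Tk` is profiled out analytically:
`H_kk = −(l_μμ − l_μσ²/l_σσ)`. Genes whose block is not an interior maximum
(`l_σσ ≥ 0`, a saddle or boundary solution) or whose profiled curvature is
non-positive are flagged unidentifiable and receive an infinite score.
Spike-in samples are excluded from the information sums: they are a
π-stabilization device, and including them was observed to mask degenerate
genes by regularizing their blocks.

Genes are ranked by ascending score (ties broken lexicographically by id)
and the top K (default 1,500; 250 at the default synthetic-cohort size)
form the signature set for the final fit. Selection runs in two passes:
pilot fit on all retained genes → scoring → final fit on the signature.

A **brute-force profile CI** serves as the oracle on small instances: `μ_Tk`
is pinned on a grid and all other parameters re-maximized at each point
(warm-started from the fitted optimum); the CI is the deviance set
`{μ: 2(l_max − l_profile) ≤ 2·χ²₀.₉₅(1)}`, whose quadratic expansion
reproduces the asymptotic interval the score approximates, with endpoints
interpolated on √deviance (linear in `μ` for a quadratic profile; plain
linear interpolation of a convex deviance would bias the interval narrow).
On a 10-gene/20-sample instance the two routes agree within ~13–19% for
well-identified genes.

## Filters, consensus and multi-region summaries

- **Extreme-π filter**: samples with `π̂ > 0.85` or strictly above the
  97.5th empirical percentile (linear interpolation between order
  statistics; both rules applied to the same input vector) are dropped —
  deconvolution underestimates π near 1, so extreme values are unreliable.
- **Two-caller consensus**: ordinary least squares of `log2 TmS_A` on
  `log2 TmS_B` (statsmodels), samples with Cook's distance ≥ 4/n removed,
  consensus = `sqrt(TmS_A · TmS_B)` on the kept rows. A numerically perfect
  fit leaves only float-epsilon residuals whose Cook's distances are
  meaningless ratios; such fits are treated as outlier-free. With a single
  caller, consensus is skipped and the single-caller TmS is reported with a
  provenance flag.
- **Multi-region summaries** per patient: `TmS_max`, `TmS_med` (mean of the
  central pair for even region counts) and the range
  `log2(TmS_max) − log2(TmS_min)` (absent for single-region patients).

## Pseudo-bulk single-cell utilities

Per-cell total UMI counts proxy total mRNA content. After equalizing the
median per-cell total across samples (the reference is the lower median of
the per-sample medians, i.e. a value an actual sample attained — chosen so
factors stay interpretable; any fixed reference gives the same ratios), the
tumor:non-tumor ratio of mean totals is the single-cell analogue of TmS
(ploidy aside). CIs come from a stratified percentile bootstrap: tumor and
non-tumor cells resampled separately, with replacement, at the original
class sizes (default 1,000 replicates); percentile rather than BCa because
nothing in the procedure warrants the extra machinery. A Wilcoxon rank-sum
utility (`compare_gene_counts`, α = 0.001) supports merging cell clusters
that do not differ in genes detected per cell; cluster discovery itself is
out of scope — cell labels are inputs.

## Synthetic-data generator

`simulate_cohort` draws cohorts from the same log2-normal convolution model
the deconvolution assumes, with known per-sample truth and planted gene
classes that stress gene selection:

| knob | default | rationale |
|---|---|---|
| genes / mixed / reference | 500 / 60 / 20 | small-cohort scale; fits run in minutes on one CPU |
| gene classes (unimodal / multimodal / high-var-normal / non-differential) | 0.25 / 0.10 / 0.10 / 0.55 | most of a transcriptome is not strongly tumor-differential; the non-differential majority anchors scale normalization (an all-differential matrix biases upper-quartile normalization and hence π by ~0.1, an artifact no real transcriptome exhibits) |
| `μ_N` | Normal(6, 1.5²) log2 | bulk RNA-seq expression scale |
| `σ_N` | Uniform(0.2, 0.6) | typical biological + technical spread |
| unimodal tumor shift | +Uniform(0.8, 2.5) | signature-like genes are robustly expressed in the hidden component; a hidden component that contributes little (strongly down-regulated) is weakly identified by construction and would be a mislabeled "good" plant |
| multimodal genes | shift ±Uniform(0.8, 2.5), 2 subtypes ±1 apart | tumor-subtype heterogeneity that a single-mode fit cannot represent |
| high-variance-normal genes | σ_N tripled, shift ±Uniform(0, 0.8) | noisy non-tumor expression comparable to or exceeding the differential signal — the pathology only exists when noise rivals the shift |
| `σ_T` | Uniform(0.2, 0.5) | slightly tighter than σ_N |
| purity / ploidy | Uniform(0.3, 0.9) / Uniform(1.5, 4.5) | ranges typical of DNA-caller output |
| π | Uniform(0.2, 0.8), or implied by a TmS target via the identity | either π is primary and TmS follows, or `tms_scale` pins TmS and π is inverted |
| library-size factor | 2^Normal(0, 0.2²) per sample | depth variation that normalization must remove |

The truth table satisfies the TmS identity exactly by construction.
`simulate_single_cell` draws per-cell totals log-normal with equal
log-dispersion in both classes (so the mean ratio is exact) and gene counts
as a noisy concave monotone function of the total (Spearman ≈ 0.99,
mirroring the tight total/genes relationship of real cells).

What the generator does **not** emulate: count noise (values are continuous
intensities, not negative-binomial counts), batch effects, gene–gene
correlation, cohort-specific QC problems, and reference samples that are not
honest draws from the non-tumor component (e.g. tumor-contaminated
"adjacent normal"). Passing tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions plus the planted
violations (multimodality, inflated normal variance), not robustness to
every artifact of real cohorts.

## Numerical choices and degenerate inputs

- Monotonicity of the fit is enforced, not hoped for: every coordinate
  update and every polish candidate is accepted only on strict improvement
  of the same fixed-grid objective.
- Scale normalization reference is the lower median of per-sample
  statistics (upper-quartile of non-zero counts by default;
  median-of-totals available); normalizing twice is a no-op, and
  multiplying any sample by a constant does not change its normalized
  values, its π̂, or pseudo-bulk ratios.
- `y ≤ 0` has density 0 (not an error); non-finite parameters raise.
- Even-count medians use the mean of the central pair except where a
  realized sample value is explicitly wanted (normalization references).
- Ranking ties break lexicographically by gene id so output is
  deterministic.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); re-running any stage with the same seed and
  inputs is bit-identical.

## Known limitations

- π̂ of maximum likelihood on weakly identified, all-differential mixtures
  is biased toward smaller hidden-component fractions (observed ~0.04–0.10
  at 30 samples on a deliberately hard symmetric fixture); gene selection
  and spike-ins mitigate but do not eliminate this. The extreme-π filter
  exists because underestimation worsens as π → 1.
- With very few reference samples (2–5), reference-parameter noise leaks
  into π̂ (the fit can absorb it into a phantom tumor component); the
  pure-normal no-hallucination guarantee holds when the reference is well
  characterized (tens of samples).
- The Fisher-approximation CI is a local quadratic summary; on rugged
  small-sample likelihoods it deviates from the exact profile CI by
  ~10–20% even for well-identified genes.
- The two-caller consensus assumes exactly two callers; with one caller the
  single-caller TmS is passed through flagged, with three or more the
  consensus step is skipped.
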
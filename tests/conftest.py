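import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from tms.data import RunConfig
from tms.deconv import estimate_reference_params, fit_deconvolution
from tms.pipeline import normalize_together, run_pipeline
from tms.synthdata import SimulationConfig, simulate_cohort


def auc_from_scores(bad_scores, good_scores) -> float:
    """Rank-based AUC of a score separating 'bad' (higher) from 'good'.

    Computed from the Mann-Whitney U statistic, so +inf scores are handled
    through their ranks.
    """
    bad = np.asarray(bad_scores, dtype=float)
    good = np.asarray(good_scores, dtype=float)
    u = mannwhitneyu(bad, good, alternative="greater").statistic
    return float(u / (len(bad) * len(good)))


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded cohort shared by fast tests (60 genes, 12 samples)."""
    cfg = SimulationConfig(n_genes=60, n_mixed=12, n_ref=10, seed=7)
    mixed, ref, pp, truth = simulate_cohort(cfg)
    return mixed, ref, pp, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A converged deconvolution fit on the small cohort."""
    mixed, ref, pp, truth = small_cohort
    mixed_n, ref_n = normalize_together(mixed, ref)
    ref_params = estimate_reference_params(ref_n)
    fit = fit_deconvolution(mixed_n, ref_params, config=RunConfig(seed=7))
    return fit, truth


@pytest.fixture(scope="session")
def default_pipeline_result():
    """Full pipeline on the default-sized cohort (the expensive shared fit).

    G=500 genes, M=60 mixed, R=20 reference, pi ~ U(0.2, 0.8), seed 3, with
    the final fit restricted to the top-250 signature genes.
    """
    mixed, ref, pp, truth = simulate_cohort(SimulationConfig(seed=3))
    result = run_pipeline(mixed, ref, pp, RunConfig(seed=3), k=250)
    return result, truth
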
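import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import spearmanr

import tms
from tms.data import DataValidationError, RunConfig
from tms.deconv import (
    add_virtual_spikeins,
    estimate_reference_params,
    fit_deconvolution,
    grid_loglik,
    mixture_density,
)
from tms.pipeline import normalize_together


def _expr(arr, role="mixed", normalized=False):
    df = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                      columns=[f"s{i}" for i in range(arr.shape[1])])
    return tms.make_expression_matrix(df, role=role, normalized=normalized)


class TestReferenceParams:
    def test_constant_gene(self):
        ref = _expr(np.full((1, 4), 8.0), role="reference")
        out = estimate_reference_params(ref)
        assert out.loc["g0", "mu_n"] == pytest.approx(3.0)
        assert out.loc["g0", "sigma_n"] == pytest.approx(0.0)

    def test_two_values(self):
        # log2 of (2, 8) is (1, 3): mean 2, sample SD sqrt(2)
        ref = _expr(np.array([[2.0, 8.0]]), role="reference")
        out = estimate_reference_params(ref)
        assert out.loc["g0", "mu_n"] == pytest.approx(2.0)
        assert out.loc["g0", "sigma_n"] == pytest.approx(np.sqrt(2.0))

    def test_single_sample_errors(self):
        ref = _expr(np.array([[5.0]]), role="reference")
        with pytest.raises(DataValidationError, match=">= 2"):
            estimate_reference_params(ref)

    def test_all_zero_gene_flagged(self):
        ref = _expr(np.array([[0.0, 0.0], [4.0, 4.0]]), role="reference")
        out = estimate_reference_params(ref)
        assert not out.loc["g0", "usable"]
        assert out.loc["g1", "usable"]


class TestMixtureDensity:
    PARAMS = dict(pi=0.5, mu_t=5.0, sigma_t=0.5, mu_n=4.0, sigma_n=0.3)

    def test_zero_below_support(self):
        assert mixture_density(0.0, **self.PARAMS) == 0.0
        assert mixture_density(-3.0, **self.PARAMS) == 0.0

    def test_integrates_to_one(self):
        val, _ = integrate.quad(lambda y: mixture_density(y, **self.PARAMS),
                                0, np.inf, limit=300)
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_matches_fixed_grid_evaluation(self):
        for y in (8.0, 16.0, 30.0, 60.0):
            ll = grid_loglik(np.array([[y]]), np.array([0.5]),
                             np.array([5.0]), np.array([0.5]),
                             np.array([4.0]), np.array([0.3]), nodes=64)
            assert np.exp(ll[0, 0]) == pytest.approx(
                mixture_density(y, **self.PARAMS), rel=1e-6)

    def test_invalid_parameters_raise(self):
        with pytest.raises(DataValidationError):
            mixture_density(10.0, pi=1.5, mu_t=5, sigma_t=0.5, mu_n=4, sigma_n=0.3)
        with pytest.raises(DataValidationError):
            mixture_density(10.0, pi=0.5, mu_t=np.nan, sigma_t=0.5, mu_n=4, sigma_n=0.3)

    def test_monte_carlo_agreement(self):
        # empirical density of pi*2^N(mu_t, s_t) + (1-pi)*2^N(mu_n, s_n)
        rng = np.random.default_rng(42)
        n = 200_000
        draws = (0.5 * 2.0 ** rng.normal(5.0, 0.5, n)
                 + 0.5 * 2.0 ** rng.normal(4.0, 0.3, n))
        edges = np.quantile(draws, np.linspace(0.02, 0.98, 13))
        counts, _ = np.histogram(draws, bins=edges)
        for j in range(len(edges) - 1):
            p_model, _ = integrate.quad(
                lambda y: mixture_density(y, **self.PARAMS), edges[j], edges[j + 1])
            se = np.sqrt(n * p_model * (1 - p_model))
            assert abs(counts[j] - n * p_model) < 3 * se


class TestSpikeins:
    def test_zero_spikeins_noop(self, small_cohort):
        mixed, ref, _, _ = small_cohort
        assert add_virtual_spikeins(mixed, ref, 0, seed=1) is mixed

    def test_bookkeeping(self, small_cohort):
        mixed, ref, _, _ = small_cohort
        out = add_virtual_spikeins(mixed, ref, 5, seed=1)
        assert out.n_samples == mixed.n_samples + 5
        assert len(out.samples_with_role("spikein")) == 5

    def test_deterministic_under_seed(self, small_cohort):
        mixed, ref, _, _ = small_cohort
        a = add_virtual_spikeins(mixed, ref, 3, seed=9)
        b = add_virtual_spikeins(mixed, ref, 3, seed=9)
        assert a.values.equals(b.values)

    def test_empty_reference_errors(self, small_cohort):
        mixed, ref, _, _ = small_cohort
        empty = ref.subset_samples([])
        with pytest.raises(DataValidationError, match="empty"):
            add_virtual_spikeins(mixed, empty, 2, seed=1)

    def test_spikein_pi_small_and_rank_order_preserved(self, small_cohort):
        """Spike-ins fit near pi = 0 and barely disturb real samples' ranks."""
        mixed, ref, _, _ = small_cohort
        mixed_n, ref_n = normalize_together(mixed, ref)
        ref_params = estimate_reference_params(ref_n)
        cfg = RunConfig(seed=7)
        base = fit_deconvolution(mixed_n, ref_params, config=cfg)
        spiked = fit_deconvolution(add_virtual_spikeins(mixed_n, ref_n, 4, seed=7),
                                   ref_params, config=cfg)
        spike_pi = spiked.pi[spiked.spikein_ids]
        assert spike_pi.median() < 0.1
        rho = spearmanr(base.pi_mixed, spiked.pi_mixed[base.pi_mixed.index]).statistic
        assert rho >= 0.98


class TestFit:
    def test_likelihood_trace_monotone(self, small_fit):
        fit, _ = small_fit
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_pi_recovery_small_cohort(self, small_fit):
        fit, truth = small_fit
        err = np.abs(fit.pi_mixed.to_numpy()
                     - truth.samples["pi"].to_numpy())
        assert np.median(err) <= 0.07

    def test_zero_variance_closed_form(self):
        # sigma_T = sigma_N = 0.01, normal level 10, tumor level 50, y = 30:
        # in the zero-variance limit pi = (y - N) / (T - N) = 0.5
        em = _expr(np.array([[30.0]]), normalized=True)
        ref_params = pd.DataFrame(
            {"mu_n": [np.log2(10.0)], "sigma_n": [0.01], "usable": [True]},
            index=["g0"])
        init = pd.DataFrame({"mu_t": [np.log2(50.0)], "sigma_t": [0.01]},
                            index=["g0"])
        cfg = RunConfig(sigma_floor=0.01, max_zero_fraction=1.0, quad_nodes=1024)
        fit = fit_deconvolution(em, ref_params, ["g0"], cfg,
                                update_gene_params=False, init_tumor_params=init)
        assert float(fit.pi_mixed.iloc[0]) == pytest.approx(0.5, abs=0.02)

    def test_pure_normal_cohort_pi_near_zero(self):
        """No tumor content is hallucinated for pure-normal profiles.

        Premise: the reference distribution is well characterized (many
        reference samples); with a noisy reference the ML fit can absorb
        estimation error into a phantom tumor component.
        """
        rng = np.random.default_rng(11)
        G, M, R = 300, 30, 100
        mu_n = rng.normal(6, 1.5, G)
        sigma_n = rng.uniform(0.2, 0.6, G)
        ref = _expr(2.0 ** rng.normal(mu_n[:, None], sigma_n[:, None], (G, R)),
                    role="reference", normalized=True)
        mixed = _expr(2.0 ** rng.normal(mu_n[:, None], sigma_n[:, None], (G, M)),
                      normalized=True)
        fit = fit_deconvolution(mixed, estimate_reference_params(ref),
                                config=RunConfig(seed=11))
        assert fit.pi_mixed.max() <= 0.05

    def test_scale_invariance_of_pi(self, small_cohort):
        mixed, ref, _, _ = small_cohort
        cfg = RunConfig(seed=7)
        mixed_n, ref_n = normalize_together(mixed, ref)
        rp = estimate_reference_params(ref_n)
        base = fit_deconvolution(mixed_n, rp, config=cfg)
        scaled = mixed.with_values(mixed.values * 7.3)
        mixed_n2, ref_n2 = normalize_together(scaled, ref)
        rp2 = estimate_reference_params(ref_n2)
        again = fit_deconvolution(mixed_n2, rp2, config=cfg)
        assert np.allclose(base.pi_mixed, again.pi_mixed, atol=1e-6)

    def test_component_swap_symmetry(self):
        """Relabeling which component is 'reference' maps pi to 1 - pi.

        Uses well-separated components (shift 2.5, SD 0.25) so the check
        isolates labeling symmetry rather than the ML proportion bias that
        weakly identified all-differential mixtures exhibit.
        """
        rng = np.random.default_rng(13)
        G, M, R = 80, 20, 50
        mu_a = rng.normal(6, 1.0, G)
        mu_b = mu_a + rng.choice([-2.5, 2.5], G)
        sig = np.full(G, 0.25)
        pi = rng.uniform(0.3, 0.7, M)
        A = 2.0 ** rng.normal(mu_a[:, None], sig[:, None], (G, M))
        B = 2.0 ** rng.normal(mu_b[:, None], sig[:, None], (G, M))
        Y = pi * B + (1 - pi) * A           # A plays "normal", B "tumor"
        mixed = _expr(Y, normalized=True)
        ref_a = _expr(2.0 ** rng.normal(mu_a[:, None], sig[:, None], (G, R)),
                      role="reference", normalized=True)
        ref_b = _expr(2.0 ** rng.normal(mu_b[:, None], sig[:, None], (G, R)),
                      role="reference", normalized=True)
        cfg = RunConfig(seed=13)
        fit_a = fit_deconvolution(mixed, estimate_reference_params(ref_a), config=cfg)
        fit_b = fit_deconvolution(mixed, estimate_reference_params(ref_b), config=cfg)
        both = fit_a.pi_mixed + fit_b.pi_mixed
        assert np.median(np.abs(both - 1.0)) <= 0.05

    def test_missing_reference_params_error(self, small_cohort):
        mixed, ref, _, _ = small_cohort
        mixed_n, ref_n = normalize_together(mixed, ref)
        rp = estimate_reference_params(ref_n).iloc[:10]
        with pytest.raises(DataValidationError, match="no reference parameters"):
            fit_deconvolution(mixed_n, rp, gene_subset=mixed.gene_ids,
                              config=RunConfig(seed=7))

    def test_empty_gene_subset_error(self, small_cohort):
        mixed, ref, _, _ = small_cohort
        mixed_n, ref_n = normalize_together(mixed, ref)
        rp = estimate_reference_params(ref_n)
        with pytest.raises(DataValidationError, match="empty gene subset"):
            fit_deconvolution(mixed_n, rp, gene_subset=[], config=RunConfig(seed=7))
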
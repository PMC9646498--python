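import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tms.data import DataValidationError
from tms.tmscore import (
    compute_tms,
    consensus_tms,
    filter_extreme_pi,
    multiregion_summary,
    tms_table,
)

unit = st.floats(min_value=0.05, max_value=0.95)
pos = st.floats(min_value=0.5, max_value=8.0)


class TestComputeTms:
    def test_symmetric_point(self):
        assert compute_tms(0.5, 0.5, 2.0, 2.0) == pytest.approx(1.0)

    def test_worked_value(self):
        # (0.6 * 0.5 * 2) / (0.5 * 0.4 * 3) = 1.0
        assert compute_tms(0.6, 0.5, 3.0, 2.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("pi,rho", [(1.0, 0.5), (0.0, 0.5), (0.5, 1.0), (0.5, 0.0)])
    def test_boundary_errors(self, pi, rho):
        with pytest.raises(DataValidationError):
            compute_tms(pi, rho, 2.0)

    @given(pi=unit, rho=unit, psi_t=pos, eps=st.floats(min_value=0.01, max_value=0.04))
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, pi, rho, psi_t, eps):
        base = compute_tms(pi, rho, psi_t)
        assert compute_tms(pi + eps, rho, psi_t) > base          # increasing in pi
        assert compute_tms(pi, rho + eps, psi_t) < base          # decreasing in rho
        assert compute_tms(pi, rho, psi_t + eps) < base          # decreasing in ploidy
        assert compute_tms(pi, rho, psi_t, psi_n=2.0 + eps) > base

    @given(pi=unit, rho1=unit, rho2=unit, psi1=pos)
    @settings(max_examples=100, deadline=None)
    def test_depends_on_purity_ploidy_only_through_odds_times_ploidy(
            self, pi, rho1, rho2, psi1):
        # pairs (rho, psi) with equal rho*psi/(1-rho) give identical TmS
        target = rho1 * psi1 / (1 - rho1)
        psi2 = target * (1 - rho2) / rho2
        assert compute_tms(pi, rho1, psi1) == pytest.approx(
            compute_tms(pi, rho2, psi2), rel=1e-9)


class TestFilterExtremePi:
    def test_cap_rule(self):
        keep = filter_extreme_pi(pd.Series([0.5, 0.9]), cap=0.85)
        assert keep.tolist() == [True, False]

    def test_degenerate_equal_values(self):
        keep = filter_extreme_pi(pd.Series(np.full(200, 0.5)))
        assert keep.all()

    def test_percentile_rule_matches_sort(self):
        rng = np.random.default_rng(2)
        vals = pd.Series(rng.uniform(0, 0.8, 1000) + 1e-9)
        keep = filter_extreme_pi(vals, cap=0.85, top_percentile=2.5)
        # brute force: exactly the 25 largest values exceed the 97.5 percentile
        dropped = set(vals[~keep].index)
        largest = set(vals.sort_values(ascending=False).index[:25])
        assert dropped == largest

    def test_empty_vector_errors(self):
        with pytest.raises(DataValidationError):
            filter_extreme_pi(pd.Series([], dtype=float))


class TestConsensus:
    def test_cooks_threshold_value(self):
        # with n = 5,295 samples the drop threshold is 4/n = 7.554e-4
        assert 4.0 / 5295 == pytest.approx(7.554e-4, abs=1e-7)

    def test_perfect_agreement_all_kept(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0.5, 2.0, 30)
        table = pd.DataFrame({
            "sample_id": np.repeat([f"s{i}" for i in range(30)], 2),
            "caller": ["A", "B"] * 30,
            "tms": np.repeat(t, 2),
        })
        out = consensus_tms(table)
        assert out["kept"].all()
        assert np.allclose(out["consensus_tms"], out["tms_a"])

    def test_planted_outlier_dropped(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(0.5, 2.0, 50)
        tms_a = t * 2.0 ** rng.normal(0, 0.05, 50)
        tms_b = t * 2.0 ** rng.normal(0, 0.05, 50)
        ids = [f"s{i:02d}" for i in range(50)] + ["planted"]
        tms_a = np.append(tms_a, 100.0 * 1.0)
        tms_b = np.append(tms_b, 1.0)
        table = pd.DataFrame({
            "sample_id": np.repeat(ids, 2),
            "caller": ["A", "B"] * 51,
            "tms": np.column_stack([tms_a, tms_b]).ravel(),
        })
        out = consensus_tms(table).set_index("sample_id")
        assert not out.loc["planted", "kept"]
        assert out.drop("planted")["kept"].all()
        # independent Cook's-distance oracle from the hat matrix
        ya, yb = np.log2(tms_a), np.log2(tms_b)
        X = np.column_stack([np.ones_like(yb), yb])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        resid = ya - H @ ya
        lev = np.diag(H)
        mse = (resid ** 2).sum() / (len(ya) - 2)
        cooks = resid ** 2 / (2 * mse) * lev / (1 - lev) ** 2
        assert np.allclose(np.sort(cooks),
                           np.sort(out["cooks_distance"].to_numpy()), rtol=1e-8)

    def test_geometric_mean_between_inputs(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(0.5, 2.0, 20)
        table = pd.DataFrame({
            "sample_id": np.repeat([f"s{i}" for i in range(20)], 2),
            "caller": ["A", "B"] * 20,
            "tms": np.column_stack([t * 1.2, t * 0.8]).ravel(),
        })
        out = consensus_tms(table)
        kept = out[out["kept"]]
        lo = np.minimum(kept["tms_a"], kept["tms_b"])
        hi = np.maximum(kept["tms_a"], kept["tms_b"])
        assert ((kept["consensus_tms"] >= lo) & (kept["consensus_tms"] <= hi)).all()

    def test_too_few_rows_error(self):
        table = pd.DataFrame({"sample_id": ["a", "a", "b", "b"],
                              "caller": ["A", "B"] * 2, "tms": [1, 1, 2, 2]})
        with pytest.raises(DataValidationError, match=">= 3"):
            consensus_tms(table)


class TestMultiregion:
    def test_three_regions(self):
        out = multiregion_summary(pd.DataFrame(
            {"patient_id": ["p"] * 3, "tms": [1.0, 2.0, 4.0]})).iloc[0]
        assert out["tms_max"] == 4.0
        assert out["tms_med"] == 2.0
        assert out["tms_range"] == pytest.approx(2.0)   # log2(4) - log2(1)

    def test_single_region_no_range(self):
        out = multiregion_summary(pd.DataFrame(
            {"patient_id": ["p"], "tms": [3.0]})).iloc[0]
        assert out["tms_max"] == out["tms_med"] == 3.0
        assert np.isnan(out["tms_range"])

    def test_even_region_count_median(self):
        out = multiregion_summary(pd.DataFrame(
            {"patient_id": ["p"] * 4, "tms": [0.5, 1.5, 2.5, 8.0]})).iloc[0]
        assert out["tms_med"] == pytest.approx(2.0)
        assert out["tms_range"] == pytest.approx(4.0)   # log2(8 / 0.5)

    def test_nonpositive_errors(self):
        with pytest.raises(DataValidationError):
            multiregion_summary(pd.DataFrame({"patient_id": ["p"], "tms": [0.0]}))


class TestTmsTable:
    def test_unmatched_sample_listed(self):
        pi = pd.Series([0.4, 0.5], index=["s1", "s2"])
        pp = pd.DataFrame({"sample_id": ["s1"], "purity": [0.6],
                           "ploidy": [2.0], "caller": ["A"]})
        with pytest.raises(DataValidationError, match="s2"):
            tms_table(pi, pp)

    def test_recomputable_from_stored_fields(self):
        rng = np.random.default_rng(6)
        n = 40
        pi = pd.Series(rng.uniform(0.2, 0.8, n),
                       index=[f"s{i}" for i in range(n)])
        pp = pd.DataFrame({"sample_id": pi.index,
                           "purity": rng.uniform(0.3, 0.9, n),
                           "ploidy": rng.uniform(1.5, 4.0, n),
                           "caller": "A"})
        tbl = tms_table(pi, pp)
        recomputed = (tbl["pi"] * (1 - tbl["purity"]) * tbl["psi_n"]
                      / (tbl["purity"] * (1 - tbl["pi"]) * tbl["ploidy"]))
        assert np.allclose(tbl["tms"], recomputed, atol=1e-10)
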
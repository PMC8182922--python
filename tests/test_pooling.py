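import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

from ltfu import (MiceConfig, crude_prevalence, default_epice_like_config,
                  derive_outcomes, generate_cohort, percent_change,
                  prevalence_from_imputed, rubin_pool, run_mice, subgroup_estimates)


def straight_line_rubin(estimates, variances, df_com=None):
    """Independent textbook implementation of the pooling formulas."""
    m = len(estimates)
    qbar = sum(estimates) / m
    W = sum(variances) / m
    B = sum((q - qbar) ** 2 for q in estimates) / (m - 1)
    T = W + (1 + 1 / m) * B
    if B == 0:
        return qbar, W, B, T, float("inf")
    lam = (1 + 1 / m) * B / T
    df_old = (m - 1) / lam**2
    if df_com is not None:
        df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
        df = df_old * df_obs / (df_old + df_obs)
    else:
        df = df_old
    return qbar, W, B, T, df


class TestRubinPool:
    def test_agrees_with_straight_line_formulas(self):
        ests, variances = [0.18, 0.20, 0.22], [1e-4] * 3
        got = rubin_pool(ests, variances, scale="proportion")
        qbar, W, B, T, df = straight_line_rubin(ests, variances)
        assert abs(got.estimate - qbar) < 1e-12
        assert abs(got.W - W) < 1e-12
        assert abs(got.B - B) < 1e-12
        assert abs(got.T - T) < 1e-12
        assert abs(got.df - df) < 1e-9 or (np.isinf(got.df) and np.isinf(df))

    def test_agrees_with_straight_line_on_logit_scale(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.3, size=8)
        v = rng.uniform(1e-5, 1e-4, size=8)
        got = rubin_pool(p, v, df_com=999)
        ell = logit(p)
        vl = v / (p * (1 - p)) ** 2
        qbar, W, B, T, df = straight_line_rubin(list(ell), list(vl), df_com=999)
        assert got.estimate == pytest.approx(float(expit(qbar)), abs=1e-12)
        assert got.T == pytest.approx(T, abs=1e-12)
        assert got.df == pytest.approx(df, rel=1e-9)

    def test_identical_estimates_collapse(self):
        got = rubin_pool([0.2] * 5, [1e-4] * 5, scale="proportion")
        assert got.estimate == 0.2 and got.B == 0 and got.T == 1e-4

    def test_point_estimate_within_imputation_range(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(0.05, 0.6, size=10)
            got = rubin_pool(p, np.full(10, 1e-4))
            assert p.min() - 1e-12 <= got.estimate <= p.max() + 1e-12

    def test_interval_coverage_near_nominal(self):
        # proper-imputation sampling model: the observed-data estimate carries
        # variance W + B around the truth, and the m per-imputation estimates
        # scatter around it with the between-imputation variance B
        rng = np.random.default_rng(42)
        q, W, B = 0.3, 1e-4, 4e-5
        m, covered = 20, 0
        n_rep = 1000
        for _ in range(n_rep):
            center = q + np.sqrt(W + B) * rng.standard_normal()
            ests = center + np.sqrt(B) * rng.standard_normal(m)
            pe = rubin_pool(ests, np.full(m, W), scale="proportion")
            covered += pe.ci_low <= q <= pe.ci_high
        assert covered / n_rep == pytest.approx(0.95, abs=0.02)

    def test_boundary_estimate_continuity_adjusted(self):
        got = rubin_pool([0.0, 0.01, 0.02], [1e-4] * 3, n=100)
        assert 0 < got.estimate < 1
        with pytest.raises(ValueError, match="pass n"):
            rubin_pool([0.0, 0.01], [1e-4] * 2)

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            rubin_pool([0.2], [1e-4])


class TestCrudePrevalence:
    def test_paper_count_arithmetic(self):
        # 154 impaired of 837 analysed -> 18.4% [15.9;21.2]
        from conftest import paper_counts_cohort
        from ltfu import derive_outcomes as do
        t = do(paper_counts_cohort())
        c = crude_prevalence(t)
        assert c.estimate_pct == 18.4
        assert c.ci_pct == (15.9, 21.2)

    def test_degenerate_counts(self, small_cohort):
        t = small_cohort.copy()
        t.df["impaired_observed"] = 0
        c = crude_prevalence(t)
        assert c.estimate == 0.0 and c.ci_low == 0.0

    def test_even_split_gives_fifty_percent(self, small_cohort):
        t = small_cohort.copy()
        mask = (t.df["followed_up"] == 1) & t.df["impaired_observed"].notna()
        vals = np.zeros(int(mask.sum()), dtype=int)
        vals[: len(vals) // 2] = 1
        t.df.loc[t.df.index[mask], "impaired_observed"] = vals
        if len(vals) % 2 == 0:
            assert crude_prevalence(t).estimate_pct == 50.0
        else:
            assert crude_prevalence(t).estimate == pytest.approx(0.5, abs=1 / len(vals))


class TestPercentChange:
    @pytest.mark.parametrize("corrected, crude, expected", [
        (20.4, 18.4, 10.9),
        (19.4, 18.4, 5.4),
        (20.0, 18.4, 8.7),
        (21.9, 20.0, 9.5),
        (17.0, 17.0, 0.0),
    ])
    def test_published_table_arithmetic(self, corrected, crude, expected):
        from ltfu._util import round_half_up
        assert round_half_up(percent_change(corrected, crude), 1) == expected

    def test_zero_crude_rejected(self):
        with pytest.raises(ValueError):
            percent_change(10.0, 0.0)


class TestSubgroups:
    def test_total_is_mixture_of_strata(self, small_imputed):
        total = prevalence_from_imputed(small_imputed)
        subs = subgroup_estimates(small_imputed)
        df0 = small_imputed.datasets[0]
        n = len(df0)
        n_resp = int((df0["followed_up"] == 1).sum())
        mix = (subs["responders"].estimate * n_resp
               + subs["non_responders"].estimate * (n - n_resp)) / n
        assert total.estimate == pytest.approx(mix, abs=0.002)

    def test_all_responders_leaves_non_responder_stratum_empty(self):
        cfg = default_epice_like_config(n_children=300, seed=5)
        from dataclasses import replace
        cfg = replace(cfg, followup_coefs={"intercept": 50.0},
                      responder_outcome_missing_rate=0.05)
        t = derive_outcomes(generate_cohort(cfg))
        imp = run_mice(t, MiceConfig(m=3, n_iterations=2, seed=1))
        subs = subgroup_estimates(imp)
        assert "non_responders" not in subs and "responders" in subs

    def test_mar_imputation_understates_non_responders_under_mnar(self):
        # delta_true=0.4: impaired children under-respond; MAR imputation
        # pulls the non-responder estimate toward the responder level
        gaps = []
        for seed in range(6):
            cfg = default_epice_like_config(n_children=2500, seed=seed, delta_true=0.4)
            t = derive_outcomes(generate_cohort(cfg))
            imp = run_mice(t, MiceConfig(m=6, n_iterations=4, seed=100 + seed))
            subs = subgroup_estimates(imp)
            latent_nonresp = t.df.loc[t.df["followed_up"] == 0, "latent_impaired"].mean()
            gaps.append(subs["non_responders"].estimate - float(latent_nonresp))
        assert np.mean(gaps) < -0.01

    def test_subgroups_agree_when_attrition_unrelated_to_outcome(self):
        # response driven only by deprivation, which is null on the outcome
        from dataclasses import replace
        diffs = []
        for seed in range(6):
            cfg = default_epice_like_config(n_children=2500, seed=seed)
            cfg = replace(cfg, followup_coefs={
                "intercept": 0.3,
                "deprivation": {"q2": -0.27, "q3": -0.49, "q4": -0.94, "q5": -1.21}})
            t = derive_outcomes(generate_cohort(cfg))
            imp = run_mice(t, MiceConfig(m=6, n_iterations=4, seed=200 + seed))
            subs = subgroup_estimates(imp)
            diffs.append(subs["responders"].estimate - subs["non_responders"].estimate)
        assert abs(np.mean(diffs)) < 0.02


class TestPoolingProperties:
    """Hypothesis-driven invariants of the pooling arithmetic."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(st.lists(st.floats(min_value=0.01, max_value=0.99), min_size=2, max_size=30),
           st.floats(min_value=1e-6, max_value=1e-3))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_point_in_hull_and_total_variance_dominates_within(ests, var):
        pe = rubin_pool(ests, [var] * len(ests))
        assert min(ests) - 1e-9 <= pe.estimate <= max(ests) + 1e-9
        assert pe.T >= pe.W - 1e-15
        assert pe.B >= 0
        assert pe.ci_low <= pe.estimate <= pe.ci_high

    @staticmethod
    @given(st.floats(min_value=0.1, max_value=80.0),
           st.floats(min_value=0.1, max_value=80.0))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_percent_change_sign_tracks_direction(corrected, crude):
        change = percent_change(corrected, crude)
        if corrected > crude:
            assert change > 0
        elif corrected < crude:
            assert change < 0
        else:
            assert change == 0
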
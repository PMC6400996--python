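"""Inference layer: normality screen, ANOVAs, Holm, effect sizes, Bayes factors."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from ucmgait.stats import (
    ZeroVarianceError,
    _d_unb_from_t,
    d_unbiased,
    holm_correct,
    independent_t,
    jzs_bf_independent,
    jzs_bf_paired,
    ks_normality,
    mixed_anova_2x3,
    oneway_anova,
    paired_t,
    percent_change,
    run_full_inference,
)
from ucmgait.synthetic_data import SimulationSpec, generate_cohort


class TestKSNormality:
    def test_type_one_rate_on_normal_samples(self):
        rejections = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=500)
            _, p = ks_normality(x)
            rejections += p < 0.05
        assert rejections <= 6  # non-rejection in >= 94% of seeds

    def test_power_against_exponential(self):
        rejections = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=100)
            _, p = ks_normality(x)
            rejections += p < 0.05
        assert rejections >= 90

    def test_constant_sample_rejected(self):
        with pytest.raises(ZeroVarianceError):
            ks_normality(np.full(10, 1.0))


class TestOnewayAnova:
    def test_identical_groups_give_zero_f(self):
        f, p = oneway_anova([np.array([1.0, 2, 3])] * 3)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_sums_of_squares_oracle(self, rng):
        groups = [rng.normal(loc=i * 0.3, size=20) for i in range(3)]
        f, _ = oneway_anova(groups)
        grand = np.mean(np.concatenate(groups))
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ss_between / 2) / (ss_within / (60 - 3))
        assert f == pytest.approx(f_oracle, rel=1e-10)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ZeroVarianceError):
            oneway_anova([np.ones(5), np.ones(5)])


class TestPairedT:
    def test_closed_form(self):
        pre = np.zeros(3)
        post = np.array([1.0, 2.0, 3.0])
        t, df, p = paired_t(pre, post)
        assert t == pytest.approx(2 * math.sqrt(3), rel=1e-12)
        assert df == 2

    def test_zero_mean_difference_gives_zero_t(self):
        pre = np.array([1.0, 2.0, 3.0])
        t, _, p = paired_t(pre, pre + np.array([-1.0, 0.0, 1.0]))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        pre, post = rng.normal(size=10), rng.normal(size=10)
        t1, _, _ = paired_t(pre, post)
        t2, _, _ = paired_t(post, pre)
        assert t1 == pytest.approx(-t2, rel=1e-12)

    def test_constant_difference_rejected(self):
        with pytest.raises(ZeroVarianceError):
            paired_t(np.arange(5.0), np.arange(5.0) + 1.0)


def _toy_mixed(n=8, shift=None, seed=0, rho=0.75):
    """Balanced 3-group pre/post table with subject random intercepts."""
    rng = np.random.default_rng(seed)
    rows = []
    for gi, g in enumerate(("S-MRT", "I-FRT", "S-MRT_HIP")):
        for i in range(n):
            b = rng.normal(0, math.sqrt(rho))
            for session in ("pre", "post"):
                e = rng.normal(0, math.sqrt(1 - rho))
                y = b + e
                if shift and session == "post":
                    y += shift[gi]
                rows.append(
                    {"subject_id": f"{g}{i}", "group": g, "session": session, "y": y}
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_no_change_gives_zero_time_effects(self):
        df = _toy_mixed()
        df = df.pivot_table(index=["subject_id", "group"], columns="session", values="y")
        df["post"] = df["pre"]
        long = df.reset_index().melt(
            id_vars=["subject_id", "group"], value_vars=["pre", "post"],
            var_name="session", value_name="y",
        )
        aov = mixed_anova_2x3(long, "y")
        assert aov.f_time == 0.0 and aov.f_inter == 0.0
        assert aov.p_time == 1.0 and aov.p_inter == 1.0

    def test_balanced_data_matches_cell_means_oracle(self):
        """All split-plot F ratios from explicit sums of squares."""
        df = _toy_mixed(n=6, shift=(0.4, 0.0, -0.2), seed=3)
        aov = mixed_anova_2x3(df, "y")
        wide = df.pivot_table(index=["subject_id", "group"], columns="session", values="y")
        y = wide.to_numpy()  # (subjects, 2)
        groups = wide.index.get_level_values("group")
        gnames = sorted(set(groups))
        k, n_sub = len(gnames), y.shape[0]
        grand = y.mean()
        subj_mean = y.mean(axis=1)
        g_mean = {g: y[groups == g].mean() for g in gnames}
        n_g = {g: (groups == g).sum() for g in gnames}
        # between-subject stratum
        ss_group = sum(2 * n_g[g] * (g_mean[g] - grand) ** 2 for g in gnames)
        ss_subj = sum(
            2 * (subj_mean[i] - g_mean[groups[i]]) ** 2 for i in range(n_sub)
        )
        # within-subject stratum
        t_mean = y.mean(axis=0)
        gt_mean = {g: y[groups == g].mean(axis=0) for g in gnames}
        ss_time = n_sub * ((t_mean - grand) ** 2).sum()
        ss_inter = sum(
            n_g[g] * ((gt_mean[g] - g_mean[g] - t_mean + grand) ** 2).sum() for g in gnames
        )
        ss_err = sum(
            (y[i] - subj_mean[i] - gt_mean[groups[i]] + g_mean[groups[i]]) ** 2
            for i in range(n_sub)
        ).sum()
        f_group = (ss_group / (k - 1)) / (ss_subj / (n_sub - k))
        f_time = (ss_time / 1) / (ss_err / (n_sub - k))
        f_inter = (ss_inter / (k - 1)) / (ss_err / (n_sub - k))
        assert aov.f_group == pytest.approx(f_group, rel=1e-9)
        assert aov.f_time == pytest.approx(f_time, rel=1e-9)
        assert aov.f_inter == pytest.approx(f_inter, rel=1e-9)
        # SS partition closes on balanced data
        ss_tot = ((y - grand) ** 2).sum()
        assert ss_group + ss_subj + ss_time + ss_inter + ss_err == pytest.approx(
            ss_tot, rel=1e-9
        )

    def test_interaction_power_for_one_sd_shift(self):
        detected = 0
        for seed in range(100):
            df = _toy_mixed(n=20, shift=(1.0, 0.0, 0.0), seed=seed)
            aov = mixed_anova_2x3(df, "y")
            detected += aov.p_inter <= 0.05
        assert detected >= 80

    def test_incomplete_subject_excluded_and_listed(self):
        df = _toy_mixed(n=5)
        df = df[~((df.subject_id == "S-MRT0") & (df.session == "post"))]
        aov = mixed_anova_2x3(df, "y")
        assert aov.excluded_subjects == ["S-MRT0"]
        assert aov.n_per_group["S-MRT"] == 4


class TestHolm:
    def test_hand_enumerated_family(self):
        adj = holm_correct([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06], atol=1e-12)

    def test_single_p_unchanged(self):
        assert holm_correct([0.2]) == pytest.approx([0.2])

    def test_equal_family_scales_by_size(self):
        assert np.allclose(holm_correct([0.02] * 4), [0.08] * 4)
        assert np.allclose(holm_correct([0.5] * 3), [1.0] * 3)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=9)
        assert np.allclose(holm_correct(p), multipletests(p, method="holm")[1], atol=1e-12)

    def test_monotone_and_never_smaller_than_raw(self, rng):
        p = rng.uniform(size=12)
        adj = holm_correct(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            holm_correct([])


class TestDUnbiased:
    def test_reproduces_printed_gait_speed_effect(self):
        # pooled pre/post gait speed pairing: t = 3.74 with 67 pairs -> 0.45
        d, ci = _d_unb_from_t(3.74, 67)
        assert round(d, 2) == 0.45
        assert ci[0] == pytest.approx(0.21, abs=0.02)
        assert ci[1] == pytest.approx(0.71, abs=0.02)

    def test_correction_factor_at_df_66(self):
        assert 1 - 3 / (4 * 66 - 1) == pytest.approx(0.98859, abs=1e-5)

    def test_zero_t_gives_zero_d_and_symmetric_ci(self):
        d, ci = _d_unb_from_t(0.0, 30)
        assert d == 0.0
        assert ci[0] == pytest.approx(-ci[1], rel=1e-6)

    def test_data_route_agrees_with_t_route(self, rng):
        pre = rng.normal(size=25)
        post = pre + rng.normal(0.3, 0.5, size=25)
        t, df, _ = paired_t(pre, post)
        d1, ci1 = d_unbiased(pre, post)
        d2, ci2 = _d_unb_from_t(t, df + 1)
        assert d1 == pytest.approx(d2) and ci1 == pytest.approx(ci2)

    def test_correction_shrinks_toward_zero(self):
        for n in (5, 10, 50, 200):
            d, _ = _d_unb_from_t(2.0, n)
            assert abs(d) < 2.0 / math.sqrt(n)
        d_small, _ = _d_unb_from_t(2.0, 5)
        d_big, _ = _d_unb_from_t(2.0, 200)
        assert abs(d_small * math.sqrt(5) / 2.0) < abs(d_big * math.sqrt(200) / 2.0)


class TestJZSBayesFactor:
    def test_null_t_favors_null(self):
        assert jzs_bf_paired(0.0, 50) < 1.0

    def test_monotone_in_t(self):
        bfs = [jzs_bf_paired(t, 30) for t in np.linspace(0, 6, 13)]
        assert np.all(np.diff(bfs) > 0)

    def test_quadrature_matches_monte_carlo(self):
        t, n, r = 2.5, 40, 0.707
        bf = jzs_bf_paired(t, n, r)
        rng = np.random.default_rng(7)
        delta = r * rng.standard_cauchy(1_000_000)
        num = np.mean(sps.nct.pdf(t, n - 1, math.sqrt(n) * delta))
        bf_mc = num / sps.t.pdf(t, n - 1)
        assert bf == pytest.approx(bf_mc, rel=0.01)

    def test_agrees_with_pingouin(self):
        for t, n in [(1.2, 15), (3.74, 67), (-2.0, 25)]:
            assert jzs_bf_paired(t, n) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n, paired=True, r=0.707)), rel=1e-4
            )

    def test_independent_variant_agrees_with_pingouin(self):
        assert jzs_bf_independent(2.2, 20, 24) == pytest.approx(
            float(pg.bayesfactor_ttest(2.2, 20, 24, paired=False, r=0.707)), rel=1e-4
        )


class TestPercentChange:
    def test_simple_increase(self, spec):
        table = generate_cohort(spec, seed=0)
        df = table.df.copy()
        sel = (df.group == "S-MRT") & (df.condition == "ES")
        df.loc[sel & (df.session == "pre"), "dvz"] = 10.0
        df.loc[sel & (df.session == "post"), "dvz"] = 11.0
        from ucmgait.io_gait import OutcomeTable

        assert percent_change(OutcomeTable(df), "dvz", "S-MRT", "ES") == pytest.approx(10.0)

    def test_simple_decrease(self, spec):
        table = generate_cohort(spec, seed=0)
        df = table.df.copy()
        sel = (df.group == "I-FRT") & (df.condition == "US")
        df.loc[sel & (df.session == "pre"), "v_ort"] = 4.0
        df.loc[sel & (df.session == "post"), "v_ort"] = 3.0
        from ucmgait.io_gait import OutcomeTable

        assert percent_change(OutcomeTable(df), "v_ort", "I-FRT", "US") == pytest.approx(-25.0)

    def test_injected_bad_variance_reduction_recovered(self, spec):
        """The study-style 25% V_ORT drop for I-FRT on uneven ground."""
        changes = [
            percent_change(generate_cohort(spec, seed=s), "v_ort", "I-FRT", "US")
            for s in range(30)
        ]
        assert np.mean(changes) == pytest.approx(-25.0, abs=5.0)


class TestRunFullInference:
    def test_structure_and_gating_information(self, spec):
        table = generate_cohort(spec, seed=11)
        rep = run_full_inference(table)
        anova_keys = {(a.variable, a.condition) for a in rep.anovas}
        for v in ("dvz", "v_ucm", "v_ort", "v_tot"):
            for c in ("ES", "US", "US_ISB"):
                assert (v, c) in anova_keys
        assert set(rep.gait_speed) == {"ES", "US", "US_ISB"}
        assert len(rep.training_load) == 3
        # post-hoc families carry Holm-adjusted p >= raw p
        for results in rep.posthoc.values():
            for r in results:
                assert r.p_adj is not None and r.p_adj >= r.p_raw - 1e-15

    def test_study_style_cohort_flags_uneven_interactions(self, spec):
        table = generate_cohort(spec, seed=11)
        rep = run_full_inference(table, variables=("dvz", "v_ort"), secondary=())
        p_int = {(a.variable, a.condition): a.p_inter for a in rep.anovas}
        assert p_int[("v_ort", "US")] <= 0.05
        assert p_int[("v_ort", "US_ISB")] <= 0.05

    def test_parametric_screen_passes_for_gaussianish_outcomes(self, spec):
        table = generate_cohort(spec, seed=11)
        rep = run_full_inference(table, variables=("dvz",), secondary=())
        assert rep.parametric_ok["dvz:ES"]
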
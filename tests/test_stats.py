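"""t-tests, power, sphericity and the split-plot ANOVA against oracles."""

import numpy as np
import pandas as pd
import pytest

from hypnoeeg.stats import (MixedAnova, greenhouse_geisser_epsilon,
                            huynh_feldt_epsilon, mauchly_sphericity,
                            omega_squared, power_two_sample_t,
                            ttest_from_summary, ttest_independent)

# tiny split-plot dataset: 2 groups x 2 subjects x 3 stages.
# Sums of squares below were hand-computed from the cell/subject means
# (grand mean 47/12): SS_total = 419/12, SS_group = 169/12,
# SS_subj(group) = 29/6, SS_stage = 91/6, SS_inter = 1/6, SS_err = 2/3.
TINY_Y = np.array([[1.0, 2, 3], [2, 4, 5], [4, 5, 7], [3, 5, 6]])
TINY_GROUPS = np.array(["A", "A", "B", "B"])


def tiny_long():
    rows = []
    for i, (row, g) in enumerate(zip(TINY_Y, TINY_GROUPS)):
        for j, v in enumerate(row):
            rows.append({"subject_id": f"s{i}", "age_group": g,
                         "stage": f"t{j}", "value": v})
    return pd.DataFrame(rows)


class TestTTest:
    def test_identical_groups(self):
        res = ttest_independent([1.0, 2, 3], [1.0, 2, 3], variant="student")
        assert res.t == 0.0 and res.p == 1.0

    def test_pooled_hand_computation(self):
        # {1,2,3} vs {2,3,4}: diff -1, s_p^2 = 1, se = sqrt(2/3), t = -sqrt(3/2)
        res = ttest_independent([1.0, 2, 3], [2.0, 3, 4], variant="student")
        assert res.t == pytest.approx(-np.sqrt(1.5))
        assert res.df == 4
        from scipy.stats import t as tdist

        assert res.p == pytest.approx(2 * tdist.sf(np.sqrt(1.5), 4))

    def test_summary_matches_raw_student(self, rng):
        a = rng.standard_normal(18) + 0.5
        b = rng.standard_normal(12)
        raw = ttest_independent(a, b, variant="student")
        summ = ttest_from_summary(a.mean(), a.std(ddof=1), 18,
                                  b.mean(), b.std(ddof=1), 12, "student")
        assert summ.t == pytest.approx(raw.t, abs=1e-12)
        assert summ.p == pytest.approx(raw.p, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ttest_independent([2.0, 2.0], [2.0, 2.0])


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert power_two_sample_t(20, 0.0, 1.0, 0.05) == pytest.approx(0.05,
                                                                       abs=1e-9)

    def test_large_n_saturates(self):
        assert power_two_sample_t(1000, 15, 12) > 0.999

    def test_monotone_in_n_delta_sd(self):
        ns = [power_two_sample_t(n, 1.0, 1.0) for n in (5, 10, 20, 40)]
        assert ns == sorted(ns) and len(set(ns)) == 4
        ds = [power_two_sample_t(10, d, 1.0) for d in (0.2, 0.5, 1.0, 2.0)]
        assert ds == sorted(ds)
        sds = [power_two_sample_t(10, 1.0, s) for s in (0.5, 1.0, 2.0)]
        assert sds == sorted(sds, reverse=True)


# Mauchly toy dataset (6 subjects x 3 conditions); frozen oracle values were
# computed independently from det/trace of the Helmert-contrast covariance.
MAUCHLY_TOY = np.array([[2.0, 4, 6], [3, 7, 6], [5, 6, 9], [4, 9, 12],
                        [6, 8, 9], [5, 7, 11]])


class TestSphericity:
    def test_toy_dataset_hand_values(self):
        w, chi2, df, p = mauchly_sphericity(MAUCHLY_TOY)
        assert w == pytest.approx(0.9110204081632653, abs=1e-12)
        assert chi2 == pytest.approx(0.3727599201502843, abs=1e-10)
        assert df == 2
        assert p == pytest.approx(0.8299581840899626, abs=1e-10)

    def test_matches_pingouin(self, rng):
        data = rng.standard_normal((25, 4)) @ rng.standard_normal((4, 4))
        import pingouin as pg

        spher = pg.sphericity(pd.DataFrame(data))
        w, chi2, df, p = mauchly_sphericity(data)
        assert w == pytest.approx(float(spher.W), abs=1e-10)
        assert p == pytest.approx(float(spher.pval), abs=1e-10)

    def test_heterogeneous_variances_shrink_w(self, rng):
        data = rng.standard_normal((40, 3)) * np.array([0.2, 1.0, 5.0])
        w, *_ = mauchly_sphericity(data)
        assert w < 1.0

    def test_null_calibration_compound_symmetry(self):
        # under sphericity the test should reject at ~alpha
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(400):
            data = rng.standard_normal((200, 3)) + rng.standard_normal((200, 1))
            _, _, _, p = mauchly_sphericity(data)
            rejections += p < 0.05
        assert 0.025 <= rejections / 400 <= 0.075

    def test_epsilon_hand_chain(self):
        gg = greenhouse_geisser_epsilon(MAUCHLY_TOY)
        assert gg == pytest.approx(0.9182908545727134, abs=1e-12)
        # HF continuation exceeds 1 here (raw value 1.4256) -> capped
        assert huynh_feldt_epsilon(MAUCHLY_TOY) == 1.0

    def test_epsilon_matches_pingouin(self, rng):
        data = rng.standard_normal((12, 4)) @ rng.standard_normal((4, 4))
        import pingouin as pg

        assert greenhouse_geisser_epsilon(data) == pytest.approx(
            float(pg.epsilon(pd.DataFrame(data), correction="gg")), abs=1e-10)
        assert huynh_feldt_epsilon(data) == pytest.approx(
            float(pg.epsilon(pd.DataFrame(data), correction="hf")), abs=1e-10)

    def test_epsilon_lower_bound_under_rank_one(self, rng):
        shared = rng.standard_normal((40, 1)) * np.array([1.0, 2.0, 3.0])
        data = shared + 1e-6 * rng.standard_normal((40, 3))
        gg = greenhouse_geisser_epsilon(data)
        assert gg == pytest.approx(0.5, abs=0.01)  # 1/(k-1)


class TestMixedAnova:
    def test_tiny_dataset_hand_decomposition(self):
        res = MixedAnova(tiny_long()).fit(correction="none")
        g = res.effect("group")
        s = res.effect("stage")
        i = res.effect("interaction")
        assert g["ss"] == pytest.approx(169 / 12)
        assert s["ss"] == pytest.approx(91 / 6)
        assert i["ss"] == pytest.approx(1 / 6)
        assert res.ss_total == pytest.approx(419 / 12)
        assert g["F"] == pytest.approx(5.827586206896, rel=1e-9)
        assert s["F"] == pytest.approx(45.5, rel=1e-9)
        assert i["F"] == pytest.approx(0.5, rel=1e-9)
        assert g["p"] == pytest.approx(0.13716, abs=1e-4)
        assert s["p"] == pytest.approx(0.0017729, abs=1e-6)

    def test_omega_squared_tiny_dataset(self):
        res = MixedAnova(tiny_long()).fit(correction="none")
        ms_subj = (29 / 6) / 2
        ms_err = (2 / 3) / 4
        assert res.effect("group")["omega_sq"] == pytest.approx(
            (169 / 12 - ms_subj) / (419 / 12 + ms_subj))
        assert res.effect("stage")["omega_sq"] == pytest.approx(
            (91 / 6 - 2 * ms_err) / (419 / 12 + ms_err))

    def test_matches_pingouin_balanced(self, rng):
        import pingouin as pg

        n, k = 12, 5
        vals = rng.standard_normal((n, k)) + rng.standard_normal((n, 1))
        rows = []
        for i in range(n):
            for j in range(k):
                rows.append({"subject_id": i, "age_group": "A" if i < 6 else "B",
                             "stage": f"c{j}", "value": vals[i, j]})
        df = pd.DataFrame(rows)
        res = MixedAnova(df).fit(correction="none")
        ref = pg.mixed_anova(df, dv="value", within="stage",
                             between="age_group", subject="subject_id")
        assert res.effect("group")["F"] == pytest.approx(
            float(ref.loc[0, "F"]), rel=1e-9)
        assert res.effect("stage")["F"] == pytest.approx(
            float(ref.loc[1, "F"]), rel=1e-9)
        assert res.effect("interaction")["F"] == pytest.approx(
            float(ref.loc[2, "F"]), rel=1e-9)

    def test_unbalanced_groups_match_pingouin(self, rng):
        import pingouin as pg

        rows = []
        for i in range(30):
            for j in range(5):
                rows.append({"subject_id": i,
                             "age_group": "young" if i < 18 else "elderly",
                             "stage": f"c{j}",
                             "value": float(rng.standard_normal())})
        df = pd.DataFrame(rows)
        res = MixedAnova(df).fit(correction="none")
        ref = pg.mixed_anova(df, dv="value", within="stage",
                             between="age_group", subject="subject_id")
        assert res.effect("group")["F"] == pytest.approx(float(ref.loc[0, "F"]),
                                                         rel=1e-6)
        assert res.effect("stage")["F"] == pytest.approx(float(ref.loc[1, "F"]),
                                                         rel=1e-6)

    def test_correction_changes_only_within_effects(self, rng):
        n, k = 16, 4
        base = rng.standard_normal((n, 1)) * np.array([0.3, 1.0, 2.0, 4.0])
        # add a real stage effect so the corrected p is the conservative one
        vals = base + rng.standard_normal((n, k)) + np.array([0.0, 0.5, 1.0, 1.5])
        rows = [{"subject_id": i, "age_group": "A" if i < 8 else "B",
                 "stage": f"c{j}", "value": vals[i, j]}
                for i in range(n) for j in range(k)]
        df = pd.DataFrame(rows)
        unc = MixedAnova(df).fit(correction="none")
        cor = MixedAnova(df).fit(correction="always")
        assert cor.epsilon_hf < 1.0
        g_u, g_c = unc.effect("group"), cor.effect("group")
        assert g_c["F"] == pytest.approx(g_u["F"]) and g_c["p"] == pytest.approx(g_u["p"])
        s_u, s_c = unc.effect("stage"), cor.effect("stage")
        assert s_c["F"] == pytest.approx(s_u["F"])  # F unchanged, df scaled
        assert s_c["df_num"] == pytest.approx(s_u["df_num"] * cor.epsilon_hf)
        from scipy.stats import f as fdist

        expected_p = fdist.sf(s_u["F"], s_u["df_num"] * cor.epsilon_hf,
                              s_u["df_den"] * cor.epsilon_hf)
        assert s_c["p"] == pytest.approx(expected_p, rel=1e-12)

    def test_listwise_deletion_counted(self):
        df = tiny_long()
        df = df[~((df.subject_id == "s0") & (df.stage == "t2"))]
        extra = pd.DataFrame([
            {"subject_id": "s4", "age_group": "A", "stage": f"t{j}",
             "value": float(j)} for j in range(3)])
        res = MixedAnova(pd.concat([df, extra])).fit(correction="none")
        assert res.n_subjects == 4 and res.n_dropped == 1

    def test_all_identical_flagged_degenerate(self):
        df = tiny_long().assign(value=3.0)
        res = MixedAnova(df).fit(correction="none")
        assert res.degenerate
        assert np.isnan(res.effect("group")["F"])

    def test_group_with_single_subject_rejected(self):
        df = tiny_long()
        df = df[df.subject_id != "s3"]
        with pytest.raises(ValueError):
            MixedAnova(df).fit()

    def test_null_calibration_group_effect(self):
        # pure-noise stage tables: group effect must reject at ~alpha
        rng = np.random.default_rng(777)
        rej_group = rej_stage = 0
        n_rep = 400
        for _ in range(n_rep):
            vals = rng.standard_normal((30, 5)) + rng.standard_normal((30, 1))
            rows = [{"subject_id": i,
                     "age_group": "young" if i < 18 else "elderly",
                     "stage": f"c{j}", "value": vals[i, j]}
                    for i in range(30) for j in range(5)]
            res = MixedAnova(pd.DataFrame(rows)).fit()
            rej_group += res.effect("group")["p"] < 0.05
            rej_stage += res.effect("stage")["p"] < 0.05
        assert 0.025 <= rej_group / n_rep <= 0.075
        assert 0.025 <= rej_stage / n_rep <= 0.075


class TestOmegaSquared:
    def test_f_equal_one_near_zero(self):
        # F = 1 <=> SS_eff = df_eff * MS_err, so omega^2 = 0 exactly
        assert omega_squared(2.0, 2, 1.0, 100.0) == 0.0

    def test_negative_for_small_f(self):
        assert omega_squared(0.5, 2, 1.0, 100.0) < 0.0

    def test_bounded_below_one(self):
        # even an enormous effect cannot reach omega^2 = 1
        assert omega_squared(1e6, 1, 1.0, 1e6) < 1.0
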
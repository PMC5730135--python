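"""Reliability (ICC), paired differences, descriptives and Spearman layer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy import stats as sps

from dispquant import stats as st

SUBJECTS = np.array([1.0, 2.0, 3.5, 2.2, 4.1, 0.8, 3.3, 2.9])


def anova_icc_oracle(x, y):
    """From-scratch two-way ANOVA ICC(A,1) via an explicit OLS fit."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n = len(x)
    df = pd.DataFrame({"score": np.r_[x, y],
                       "subject": pd.Categorical(list(range(n)) * 2),
                       "session": pd.Categorical([0] * n + [1] * n)})
    table = sm.stats.anova_lm(ols("score ~ C(subject) + C(session)",
                                  df).fit())
    msr = table.loc["C(subject)", "mean_sq"]
    msc = table.loc["C(session)", "mean_sq"]
    mse = table.loc["Residual", "mean_sq"]
    k = 2
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_duplicated_sessions_give_exactly_one(self):
        res = st.icc_repeatability(SUBJECTS, SUBJECTS.copy())
        assert res.icc == 1.0
        assert res.model_tag == "ICC(A,1)"
        assert res.ci95 == (1.0, 1.0)

    def test_constant_offset_penalised_by_absolute_agreement(self):
        res = st.icc_repeatability(SUBJECTS, SUBJECTS + 1.0)
        assert res.icc < 1.0

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(0)
        y = SUBJECTS + rng.normal(0, 0.1, len(SUBJECTS))
        res = st.icc_repeatability(SUBJECTS, y)
        assert res.icc == pytest.approx(anova_icc_oracle(SUBJECTS, y),
                                        abs=1e-10)

    def test_matches_pingouin_reference(self):
        import pingouin as pg

        rng = np.random.default_rng(3)
        y = SUBJECTS + rng.normal(0, 0.2, len(SUBJECTS))
        res = st.icc_repeatability(SUBJECTS, y)
        df = pd.DataFrame({"s": np.r_[np.arange(8), np.arange(8)],
                           "r": ["a"] * 8 + ["b"] * 8,
                           "v": np.r_[SUBJECTS, y]})
        ref = pg.intraclass_corr(df, "s", "r", "v").set_index("Type")
        assert res.icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)

    def test_zero_variance_everywhere_is_undefined(self):
        with pytest.raises(ValueError, match="zero variance"):
            st.icc_repeatability(np.ones(6), np.ones(6))

    def test_icc_decreases_with_growing_jitter(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1.0, len(SUBJECTS))
        iccs = [st.icc_repeatability(SUBJECTS, SUBJECTS + sd * noise).icc
                for sd in (0.0, 0.05, 0.15, 0.4, 1.0)]
        assert all(a > b for a, b in zip(iccs, iccs[1:]))
        assert iccs[0] == 1.0


class TestDifferenceReport:
    def frame(self, values):
        return pd.DataFrame({"Area": values})

    def test_identical_sessions_all_zero(self):
        rep = st.difference_report(self.frame(SUBJECTS), self.frame(SUBJECTS))
        row = rep.loc["Area"]
        assert (row[["Min", "Max", "Mean", "SD"]] == 0).all()
        assert row["CI95_low"] == row["CI95_high"] == 0.0

    def test_constant_difference(self):
        rep = st.difference_report(self.frame(SUBJECTS),
                                   self.frame(SUBJECTS + 0.1))
        row = rep.loc["Area"]
        assert row["Mean"] == pytest.approx(0.1)
        assert row["SD"] == pytest.approx(0.0, abs=1e-12)
        assert row["CI95_low"] == pytest.approx(0.1)
        assert row["CI95_high"] == pytest.approx(0.1)

    def test_hand_computed_case(self):
        s1 = self.frame(np.zeros(4))
        s2 = self.frame(np.array([-0.1, 0.0, 0.1, 0.2]))
        rep = st.difference_report(s1, s2).loc["Area"]
        assert rep["Mean"] == pytest.approx(0.05)
        sd = np.std([-0.1, 0.0, 0.1, 0.2], ddof=1)
        assert rep["SD"] == pytest.approx(sd)
        half = sps.t.ppf(0.975, 3) * sd / 2.0
        assert rep["CI95_low"] == pytest.approx(0.05 - half)
        assert rep["CI95_high"] == pytest.approx(0.05 + half)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            st.difference_report(self.frame([1.0]), self.frame([1.0]))


class TestDescriptives:
    def test_two_subject_range(self):
        table = pd.DataFrame({"Pogonion": [6.08, 15.72]})
        desc = st.descriptives(table).loc["Pogonion"]
        assert desc["Min"] == 6.08
        assert desc["Max"] == 15.72
        assert desc["Mean"] == pytest.approx(10.90)

    def test_single_subject_has_no_sd(self):
        desc = st.descriptives(pd.DataFrame({"A": [2.5]})).loc["A"]
        assert desc["Min"] == desc["Max"] == desc["Mean"] == 2.5
        assert np.isnan(desc["SD"])

    def test_constant_column_sd_zero(self):
        desc = st.descriptives(pd.DataFrame({"A": [1.0, 1.0, 1.0]})).loc["A"]
        assert desc["SD"] == 0.0


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(8, dtype=float)
        assert st.spearman(x, np.exp(x)).rho == 1.0
        assert st.spearman(x, -np.exp(x)).rho == -1.0

    def test_exact_p_for_perfect_monotone_n8(self):
        res = st.spearman(np.arange(8), np.arange(8) ** 2)
        assert res.method == "exact-permutation"
        assert res.p_value == pytest.approx(2 / 40320, rel=1e-12)

    def test_exact_p_matches_scipy_enumeration(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=7), rng.normal(size=7)
        mine = st.spearman(x, y)
        ref = sps.permutation_test(
            (y,), lambda yy: sps.spearmanr(x, yy).statistic,
            permutation_type="pairings", n_resamples=np.inf)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_t_approximation_used_for_larger_n(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = st.spearman(x, y)
        assert res.method == "t-approximation"
        ref = sps.spearmanr(x, y)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_t_agree_for_moderate_rho(self):
        rng = np.random.default_rng(4)
        checked = 0
        while checked < 10:
            x, y = rng.normal(size=8), rng.normal(size=8)
            res = st.spearman(x, y)
            if abs(res.rho) >= 0.7:
                continue
            t_p = sps.spearmanr(x, y).pvalue
            assert abs(res.p_value - t_p) < 0.03  # sanity band, not identity
            checked += 1

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            st.spearman(np.ones(5), np.arange(5))

    @given(hst.permutations(list(range(6))))
    def test_invariant_to_monotone_transforms(self, perm):
        x = np.arange(6, dtype=float)
        y = np.asarray(perm, dtype=float)
        base = st.spearman(x, y)
        warped = st.spearman(np.exp(x / 3), y ** 3 if (y >= 0).all() else y)
        assert warped.rho == pytest.approx(base.rho, abs=1e-12)
        assert warped.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_ties_use_average_ranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = np.arange(8, dtype=float)
        assert st.spearman(x, y).rho == pytest.approx(
            sps.spearmanr(x, y).statistic, abs=1e-12)


class TestCorrelationMatrix:
    def hard_soft_table(self, n=8):
        rng = np.random.default_rng(0)
        hard = rng.uniform(1, 5, n)
        data = {a: hard * (0.9 if "Soft" in a or "Lip" in a or "Cheilion" in a
                           or "Nasal" in a else 1.0)
                for a in st.MAXILLARY_AREAS}
        return pd.DataFrame(data)

    def test_proportional_columns_fully_significant(self):
        cm = st.correlation_matrix(self.hard_soft_table(), "maxillary")
        iu = np.triu_indices(len(cm.areas), 1)
        assert np.allclose(cm.rho[iu], 1.0)
        assert cm.significant[iu].all()

    def test_missing_area_named_in_error(self):
        table = self.hard_soft_table().drop(columns=["Upper Lip"])
        with pytest.raises(ValueError, match="Upper Lip"):
            st.correlation_matrix(table, "maxillary")

    def test_lower_r_upper_p_layout(self):
        cm = st.correlation_matrix(self.hard_soft_table(), "maxillary")
        frame = cm.to_frame()
        k = len(cm.areas)
        assert frame.iloc[2, 0] == pytest.approx(cm.rho[2, 0])  # lower = rho
        assert frame.iloc[0, 2] == pytest.approx(cm.p[0, 2])    # upper = p
        assert np.isnan(np.diag(frame.to_numpy())).all()
        text = cm.render()
        assert "below" in text and "*" in text

    def test_mandibular_set_has_six_areas(self):
        assert len(st.MANDIBULAR_AREAS) == 6
        assert len(st.MAXILLARY_AREAS) == 9


def test_holm_adjustment_is_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.2, 0.9])
    adj = st.holm_adjust(p)
    assert np.all(adj >= p)
    assert np.all(adj <= 1.0)
    assert adj[0] == pytest.approx(0.005)


def test_measurement_table_loader_rejects_missing_cells(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("subject,A,B\ns1,1.0,2.0\ns2,,3.0\n")
    with pytest.raises(ValueError, match="missing"):
        st.load_measurements(path)
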
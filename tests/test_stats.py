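"""Split-plot ANOVA and t statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lickmicro.stats import MixedAnova, mixed_anova, t_paired, t_unpaired


def make_long(y, groups, subjects=None):
    """y: (N, b) responses; groups: length-N labels -> long DataFrame."""
    y = np.asarray(y, dtype=float)
    n, b = y.shape
    subjects = subjects or [f"s{i}" for i in range(n)]
    rows = [dict(subj=subjects[i], grp=groups[i], w=f"w{k}", y=y[i, k])
            for i in range(n) for k in range(b)]
    return pd.DataFrame(rows)


def splitplot_oracle(y, groups):
    """Textbook balanced split-plot sums of squares, written out directly.

    Independent of the implementation: uses the explicit mean-based
    formulas for a groups x n subjects x b within levels.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    a = len(levels)
    n = int((groups == levels[0]).sum())
    b = y.shape[1]
    grand = y.mean()
    ss_a = sum(n * b * (y[groups == g].mean() - grand) ** 2 for g in levels)
    ss_b = sum(a * n * (y[:, k].mean() - grand) ** 2 for k in range(b))
    ss_cells = sum(n * (y[groups == g][:, k].mean() - grand) ** 2
                   for g in levels for k in range(b))
    ss_ab = ss_cells - ss_a - ss_b
    subj_means = y.mean(axis=1)
    ss_subj_within = sum(
        b * (subj_means[i] - y[groups == groups[i]].mean()) ** 2
        for i in range(y.shape[0]))
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_a - ss_b - ss_ab - ss_subj_within
    return dict(A=ss_a, B=ss_b, AB=ss_ab, subj=ss_subj_within, err=ss_err,
                total=ss_total)


class TestMixedAnova:
    def test_all_identical_responses_give_zero_f(self):
        y = np.full((6, 2), 7.0)
        res = mixed_anova(make_long(y, ["A"] * 3 + ["B"] * 3),
                          dv="y", subject="subj", between="grp", within="w")
        for key in ("between", "within", "interaction"):
            assert res[key].F == 0.0
            assert res[key].p == 1.0

    def test_balanced_2x2_matches_hand_oracle(self):
        """4 subjects/group, hand-computable sums of squares to 1e-10."""
        y = np.array([[3.0, 5.0], [4.0, 7.0], [2.0, 4.0], [5.0, 8.0],
                      [6.0, 6.0], [7.0, 8.0], [8.0, 7.0], [9.0, 10.0]])
        groups = ["A"] * 4 + ["B"] * 4
        oracle = splitplot_oracle(y, groups)
        res = mixed_anova(make_long(y, groups), dv="y", subject="subj",
                          between="grp", within="w")
        assert res["between"].ss == pytest.approx(oracle["A"], abs=1e-10)
        assert res["within"].ss == pytest.approx(oracle["B"], abs=1e-10)
        assert res["interaction"].ss == pytest.approx(oracle["AB"], abs=1e-10)
        strata = {e.effect: e.ss for e in res.strata}
        assert strata["subjects-within-groups"] == pytest.approx(oracle["subj"], abs=1e-10)
        assert strata["subject-x-within residual"] == pytest.approx(oracle["err"], abs=1e-10)

    def test_random_balanced_matches_oracle_and_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(5):
            n, b = int(rng.integers(3, 8)), int(rng.integers(2, 5))
            y = rng.normal(size=(2 * n, b)) * 3 + rng.normal()
            groups = ["A"] * n + ["B"] * n
            long = make_long(y, groups)
            res = mixed_anova(long, dv="y", subject="subj", between="grp", within="w")
            oracle = splitplot_oracle(y, groups)
            assert res["between"].ss == pytest.approx(oracle["A"], rel=1e-9)
            assert res["within"].ss == pytest.approx(oracle["B"], rel=1e-9)
            assert res["interaction"].ss == pytest.approx(oracle["AB"], rel=1e-9)
            ref = pingouin.mixed_anova(long, dv="y", subject="subj",
                                       between="grp", within="w")
            f_by_source = dict(zip(ref["Source"], ref["F"]))
            assert res["between"].F == pytest.approx(f_by_source["grp"], rel=1e-8)
            assert res["within"].F == pytest.approx(f_by_source["w"], rel=1e-8)
            assert res["interaction"].F == pytest.approx(f_by_source["Interaction"], rel=1e-8)

    def test_stratum_decomposition_sums_to_total(self, rng):
        """SS between-subjects + SS within-subjects = SS total (1e-9 rel)."""
        n, b = 6, 3
        y = rng.normal(size=(2 * n, b)) * 2 + 5
        groups = ["A"] * n + ["B"] * n
        res = mixed_anova(make_long(y, groups), dv="y", subject="subj",
                          between="grp", within="w")
        ss = {e.effect: e.ss for e in res.strata}
        total = sum(ss.values())
        expected = ((y - y.mean()) ** 2).sum()
        assert total == pytest.approx(expected, rel=1e-9)

    def test_within_f_equals_paired_t_squared_single_group(self, rng):
        """2-level within factor, one group: F_within = t_paired^2."""
        y = rng.normal(size=(10, 2)) + [0.0, 0.8]
        res = mixed_anova(make_long(y, ["A"] * 10), dv="y", subject="subj",
                          between="grp", within="w")
        t = t_paired(y[:, 0], y[:, 1])
        assert res["within"].F == pytest.approx(t.t ** 2, rel=1e-9)
        assert res["within"].p == pytest.approx(t.p, rel=1e-9)
        assert "between" not in res.effects

    def test_response_shift_invariance(self, rng):
        y = rng.normal(size=(8, 2))
        groups = ["A"] * 4 + ["B"] * 4
        res1 = mixed_anova(make_long(y, groups), dv="y", subject="subj",
                           between="grp", within="w")
        res2 = mixed_anova(make_long(y + 137.0, groups), dv="y", subject="subj",
                           between="grp", within="w")
        for key in ("between", "within", "interaction"):
            assert res1[key].F == pytest.approx(res2[key].F, rel=1e-8, abs=1e-12)

    def test_incomplete_subjects_dropped_and_df_reflects_it(self, rng, caplog):
        y = rng.normal(size=(8, 2))
        groups = ["A"] * 4 + ["B"] * 4
        long = make_long(y, groups)
        long = long[~((long.subj == "s0") & (long.w == "w1"))]  # s0 incomplete
        with caplog.at_level("WARNING", logger="lickmicro"):
            res = mixed_anova(long, dv="y", subject="subj", between="grp", within="w")
        assert res.n_dropped == 1 and res.n_subjects == 7
        assert res["interaction"].df == 1
        strata = {e.effect: e.df for e in res.strata}
        assert strata["subjects-within-groups"] == 5  # 7 - 2 groups

    def test_single_subject_group_rejected(self):
        y = np.arange(6, dtype=float).reshape(3, 2)
        with pytest.raises(ValueError, match=">= 2 subjects"):
            mixed_anova(make_long(y, ["A", "B", "B"]), dv="y", subject="subj",
                        between="grp", within="w")

    def test_zero_residual_flag(self):
        # perfect subject+condition additivity in each group, but a real
        # group x condition effect -> infinite interaction F with p = 0
        y = np.array([[0.0, 1.0], [2.0, 3.0], [0.0, 5.0], [2.0, 7.0]])
        res = mixed_anova(make_long(y, ["A", "A", "B", "B"]), dv="y",
                          subject="subj", between="grp", within="w")
        assert math.isinf(res["interaction"].F)
        assert res["interaction"].p == 0.0
        assert res.zero_residual

    def test_summary_renders(self, rng):
        y = rng.normal(size=(8, 2))
        res = mixed_anova(make_long(y, ["A"] * 4 + ["B"] * 4), dv="y",
                          subject="subj", between="grp", within="w")
        text = res.summary()
        assert "Split-plot" in text and "grp x w" in text
        assert res.to_frame().shape[0] == len(res.strata)


class TestTTests:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        res = t_unpaired(x, x)
        assert res.t == 0.0 and res.p == 1.0

    def test_shifted_sample_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = x + 1.0
        # direct pooled-variance evaluation: sp2 = 1, se = sqrt(2/3)
        expected_t = -1.0 / math.sqrt(2.0 / 3.0)
        res = t_unpaired(x, y)
        assert res.t == pytest.approx(expected_t, rel=1e-12)
        assert res.df == 4

    def test_unpaired_matches_scipy(self, rng):
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(2, 20)))
            y = rng.normal(0.5, 1.2, size=int(rng.integers(2, 20)))
            res = t_unpaired(x, y)
            ref = sps.ttest_ind(x, y)  # pooled variance by default
            assert res.t == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)
            assert res.df == len(x) + len(y) - 2

    def test_paired_matches_scipy(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 20))
            x, y = rng.normal(size=n), rng.normal(0.3, 1, size=n)
            res = t_paired(x, y)
            ref = sps.ttest_rel(x, y)
            assert res.t == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)
            assert res.df == n - 1

    def test_paired_identical(self):
        res = t_paired([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_paired_constant_nonzero_difference_infinite(self):
        res = t_paired([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert math.isinf(res.t) and res.t > 0 and res.p == 0.0 and res.degenerate

    def test_shift_invariance(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=9)
        assert t_unpaired(x, y).t == pytest.approx(t_unpaired(x + 50, y + 50).t, rel=1e-9)

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            t_unpaired([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            t_paired([1.0, 2.0], [1.0])
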
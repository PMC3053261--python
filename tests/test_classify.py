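import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossfactor.classify import (
    ClassifyConfig,
    anova_table,
    anova_two_way,
    classify,
    fdr_adjust,
    overlap_shares,
    summarize_categories,
)
from crossfactor.io import ExpressionBundle
from conftest import make_design


def lstsq_anova_oracle(arr: np.ndarray) -> tuple[float, float, float]:
    """Independent model-comparison oracle: each effect's SS is the drop in
    residual SS when it is removed from the full two-factor model (balanced
    design, so type I/II/III coincide)."""
    r = arr.shape[2]
    y = arr.reshape(-1)
    i = np.repeat([0, 0, 1, 1], r)
    j = np.repeat([0, 1, 0, 1], r)
    one = np.ones_like(y)
    full = np.column_stack([one, i, j, i * j])

    def sse(X):
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid)

    sse_full = sse(full)
    # balanced-orthogonal contrasts: remove each centered effect column
    ic, jc = i - i.mean(), j - j.mean()
    ijc = ic * jc
    base = np.column_stack([one, ic, jc, ijc])
    ss = {}
    for name, keep in (("f1", [0, 2, 3]), ("f2", [0, 1, 3]), ("int", [0, 1, 2])):
        ss[name] = sse(base[:, keep]) - sse_full
    mse = sse_full / (4 * (r - 1))
    return tuple(ss[k] / mse for k in ("f1", "f2", "int"))


class TestAnovaTwoWay:
    def test_hand_derived_example(self):
        # ctrl {0,1}, cytokines {0,1}, knock-down {2,3}, both {2,3}
        arr = np.array([[[0, 1], [0, 1]], [[2, 3], [2, 3]]], float)
        rec = anova_two_way(arr)
        assert rec["F_factor1"] == pytest.approx(16.0)
        assert rec["F_factor2"] == pytest.approx(0.0)
        assert rec["F_interaction"] == pytest.approx(0.0)
        assert rec["df_resid"] == 4

    def test_all_equal_values_give_zero_f_and_p_one(self):
        arr = np.full((2, 2, 4), 7.0)
        rec = anova_two_way(arr)
        for eff in ("factor1", "factor2", "interaction"):
            assert rec[f"F_{eff}"] == 0.0
            assert rec[f"p_{eff}"] == 1.0

    @given(
        a=st.floats(min_value=0.1, max_value=5, allow_nan=False),
        b=st.floats(min_value=-100, max_value=100, allow_nan=False),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(2, 2, 3))
        r1, r2 = anova_two_way(arr), anova_two_way(a * arr + b)
        for eff in ("factor1", "factor2", "interaction"):
            assert r2[f"F_{eff}"] == pytest.approx(r1[f"F_{eff}"], rel=1e-9, abs=1e-9)
            assert r2[f"p_{eff}"] == pytest.approx(r1[f"p_{eff}"], rel=1e-9, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_least_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.normal(5, 2, size=(2, 2, 4))
        rec = anova_two_way(arr)
        f1, f2, f12 = lstsq_anova_oracle(arr)
        assert rec["F_factor1"] == pytest.approx(f1, rel=1e-10, abs=1e-10)
        assert rec["F_factor2"] == pytest.approx(f2, rel=1e-10, abs=1e-10)
        assert rec["F_interaction"] == pytest.approx(f12, rel=1e-10, abs=1e-10)

    @given(seed=st.integers(0, 10_000), r=st.integers(2, 6))
    @settings(max_examples=50, deadline=None)
    def test_sum_of_squares_conservation(self, seed, r):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(2, 2, r))
        rec = anova_two_way(arr)
        y = arr.reshape(-1)
        ss_total = float(((y - y.mean()) ** 2).sum())
        mse = rec["ms_resid"]
        df = 4 * (r - 1)
        ss_effects = (
            rec["F_factor1"] + rec["F_factor2"] + rec["F_interaction"]
        ) * mse + mse * df
        assert ss_effects == pytest.approx(ss_total, rel=1e-9)

    def test_unbalanced_or_underreplicated_rejected(self):
        with pytest.raises(ValueError):
            anova_two_way(np.zeros((2, 2, 1)))
        design = make_design(3).drop(index="s12")  # one cell left with 2 reps
        values = pd.DataFrame(
            np.ones((2, 11)), index=["p1", "p2"], columns=list(design.index)
        )
        with pytest.raises(ValueError, match="unbalanced"):
            anova_table(ExpressionBundle(values=values, design=design))


class TestFdrAdjust:
    def test_step_up_hand_enumeration(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_empty_input_empty_output(self):
        assert fdr_adjust([]).size == 0

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_q_dominates_p_and_is_monotone(self, pvals):
        p = np.array(pvals)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1 + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


def _fake_anova(rows):
    """Build a minimal anova table from (q1, q2, q12, d1, d2, c12) tuples."""
    df = pd.DataFrame(
        rows, columns=["q_factor1", "q_factor2", "q_interaction",
                       "delta1_log2", "delta2_log2", "interaction_log2"]
    )
    df.insert(0, "probeset_id", [f"p{i}" for i in range(len(df))])
    return df


class TestClassify:
    @pytest.mark.parametrize(
        "q1,q2,q12,expected",
        [
            (0.001, 0.5, 0.5, "A"),
            (0.5, 0.001, 0.5, "B"),
            (0.001, 0.001, 0.5, "C"),
            (0.5, 0.5, 0.004, "D"),
            (0.001, 0.001, 0.004, "D"),  # interaction dominates
            (0.5, 0.5, 0.5, "none"),
        ],
    )
    def test_category_rules(self, q1, q2, q12, expected):
        calls = classify(_fake_anova([(q1, q2, q12, 1.0, -1.0, 0.5)]))
        assert calls["category"].iloc[0] == expected

    def test_categories_partition_probesets(self):
        rng = np.random.default_rng(1)
        rows = [
            (rng.uniform(), rng.uniform(), rng.uniform(), 1.0, 1.0, 0.0)
            for _ in range(200)
        ]
        calls = classify(_fake_anova(rows))
        assert set(calls["category"]) <= {"A", "B", "C", "D", "none"}
        assert len(calls) == 200
        assert calls["category"].notna().all()

    def test_direction_and_fold(self):
        # A-gene with a +2 log2 marginal: up, 4-fold
        calls = classify(_fake_anova([(0.001, 0.9, 0.9, 2.0, 0.1, 0.0)]))
        assert calls["direction_factor1"].iloc[0] == "up"
        assert calls["direction_factor2"].iloc[0] == "n/a"
        assert calls["max_fold_change"].iloc[0] == pytest.approx(4.0)
        assert bool(calls["passes_2fold"].iloc[0])

    def test_fold_below_threshold_flagged(self):
        calls = classify(_fake_anova([(0.001, 0.9, 0.9, 0.5, 0.0, 0.0)]))
        assert not bool(calls["passes_2fold"].iloc[0])


class TestSummaries:
    def test_overlap_share_fdr_row(self):
        shares = overlap_shares(n_B=635, n_C=1065, n_D=502)
        assert shares["both_responsive"] == 1567
        assert shares["factor2_responsive"] == 2202
        assert round(100 * shares["factor2_overlap"]) == 71

    def test_overlap_share_twofold_row(self):
        shares = overlap_shares(n_B=78, n_C=223, n_D=296)
        assert shares["both_responsive"] == 519
        assert round(100 * shares["factor2_overlap"]) == 87

    def test_zero_denominator_is_nan_not_crash(self):
        shares = overlap_shares(0, 0, 0, n_A=0)
        assert np.isnan(shares["factor2_overlap"])
        assert np.isnan(shares["factor1_overlap"])

    def test_empty_call_set_gives_zero_table(self):
        calls = classify(_fake_anova([]))
        summary = summarize_categories(calls)
        assert (summary.filter(like="n_").to_numpy() == 0).all()
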
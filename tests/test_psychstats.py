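"""Statistics battery vs independently coded brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from flankit.psychstats import (
    chi_square_independence,
    mixed_anova_2x2,
    paired_from_summary,
    paired_test,
    pearson_with_ci,
    round2,
)

# ---------------------------------------------------------------------------
# Brute-force oracles, written from the defining formulas only
# ---------------------------------------------------------------------------


def oracle_paired_t(diffs):
    n = len(diffs)
    m = sum(diffs) / n
    sd = math.sqrt(sum((d - m) ** 2 for d in diffs) / (n - 1))
    return m / (sd / math.sqrt(n))


def oracle_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def oracle_chi2(table):
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    total = sum(rows)
    chi2 = 0.0
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            e = r * c / total
            chi2 += (table[i][j] - e) ** 2 / e
    return chi2


# ---------------------------------------------------------------------------
# Paired tests
# ---------------------------------------------------------------------------


def test_identical_samples_give_null_result():
    r = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (r.t, r.cohens_d, r.ci95) == (0.0, 0.0, (0.0, 0.0))


def test_paired_test_matches_brute_force_oracle(rng):
    for _ in range(30):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r = paired_test(x, y)
        assert r.t == pytest.approx(oracle_paired_t(list(x - y)), rel=1e-10)
        assert r.mean_diff == pytest.approx(float((x - y).mean()), rel=1e-10)


def test_paired_summary_internal_identities(rng):
    r = paired_from_summary(12.3, 7.7, 17)
    assert r.t * r.se == pytest.approx(r.mean_diff, rel=1e-12)
    assert r.cohens_d * math.sqrt(r.n) == pytest.approx(r.t, rel=1e-12)
    assert r.ci95[0] < r.mean_diff < r.ci95[1]


def test_zero_mean_summary():
    r = paired_from_summary(0.0, 1.0, 20)
    assert (r.t, r.cohens_d) == (0.0, 0.0)
    assert r.p == pytest.approx(1.0)


@pytest.mark.parametrize("bad", [dict(n=1), dict(sd_diff=0.0), dict(sd_diff=-1.0)])
def test_paired_summary_invalid_inputs(bad):
    kwargs = dict(mean_diff=1.0, sd_diff=1.0, n=10)
    kwargs.update(bad)
    with pytest.raises(ValueError):
        paired_from_summary(**kwargs)


def test_paired_test_rejects_mismatch_and_missing():
    with pytest.raises(ValueError):
        paired_test([1.0, 2.0], [1.0])
    with pytest.raises(ValueError):
        paired_test([1.0, np.nan], [1.0, 2.0])


@settings(derandomize=True, max_examples=100)
@given(
    diffs=st.lists(
        st.floats(-100, 100).filter(lambda v: abs(v) > 1e-6),
        min_size=3, max_size=40,
    )
)
def test_cohens_d_equals_t_over_sqrt_n(diffs):
    x = np.asarray(diffs)
    if x.std(ddof=1) < 1e-9:
        return
    r = paired_test(x, np.zeros_like(x))
    assert r.cohens_d == pytest.approx(r.t / math.sqrt(r.n), rel=1e-9)


def test_se_shrinks_as_inverse_sqrt_n():
    a = paired_from_summary(5.0, 10.0, 25)
    b = paired_from_summary(5.0, 10.0, 100)
    assert b.se == pytest.approx(a.se / 2.0)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def test_collinear_inputs_give_r_one():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    r = pearson_with_ci(x, [2 * v + 1 for v in x])
    assert r.r == 1.0
    assert r.ci95 == (1.0, 1.0)


def test_pearson_matches_brute_force_oracle(rng):
    for _ in range(30):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r = pearson_with_ci(x, y)
        assert r.r == pytest.approx(oracle_pearson(list(x), list(y)), rel=1e-10)
        # p from the exact t transform
        t = r.r * math.sqrt((r.n - 2) / (1 - r.r**2))
        assert r.p == pytest.approx(2 * sps.t.sf(abs(t), r.n - 2), rel=1e-10)


def test_fisher_interval_brackets_r_and_stays_in_range(rng):
    for _ in range(20):
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        r = pearson_with_ci(x, y)
        assert -1.0 <= r.ci95[0] < r.r < r.ci95[1] <= 1.0


def test_fisher_interval_at_printed_precision():
    """r = 0.703, n = 20 -> 95% CI ~ [0.38, 0.87] via Fisher z."""
    z = math.atanh(0.703)
    lo, hi = math.tanh(z - 1.959963984540054 / math.sqrt(17)), math.tanh(
        z + 1.959963984540054 / math.sqrt(17)
    )
    assert round2(lo) == 0.38
    assert round2(hi) == 0.87


def test_pearson_invalid_inputs():
    with pytest.raises(ValueError):
        pearson_with_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])  # n < 4
    with pytest.raises(ValueError):
        pearson_with_ci([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])  # zero variance


def test_fisher_ci_coverage_at_rho_half():
    """500 bivariate-normal replicates at rho=0.5, n=1000: ~95% coverage."""
    rng = np.random.default_rng(123)
    rho, n, reps = 0.5, 1000, 500
    cov = [[1.0, rho], [rho, 1.0]]
    hits = 0
    for _ in range(reps):
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        r = pearson_with_ci(xy[:, 0], xy[:, 1])
        hits += r.ci95[0] <= rho <= r.ci95[1]
    assert hits / reps == pytest.approx(0.95, abs=0.02)


# ---------------------------------------------------------------------------
# Mixed ANOVA
# ---------------------------------------------------------------------------


def _long_table(scores):
    """scores: dict subject -> (group, {level: value})."""
    rows = []
    for subj, (grp, levels) in scores.items():
        for lvl, val in levels.items():
            rows.append({"subject": subj, "group": grp, "level": lvl, "dv": float(val)})
    return pd.DataFrame(rows)


def test_anova_null_condition_effect():
    df = _long_table(
        {
            "a": ("g1", {"A": 3, "B": 3}),
            "b": ("g1", {"A": 4, "B": 4}),
            "c": ("g2", {"A": 5, "B": 5}),
            "d": ("g2", {"A": 2, "B": 2}),
        }
    )
    res = mixed_anova_2x2(df, dv="dv", within="level", between="group", subject="subject")
    assert res.within.F == pytest.approx(0.0, abs=1e-12)


def test_anova_tiny_table_matches_cell_means_oracle():
    """4 children, hand-decomposed sums of squares."""
    df = _long_table(
        {
            "a": ("g1", {"A": 1.0, "B": 3.0}),
            "b": ("g1", {"A": 2.0, "B": 6.0}),
            "c": ("g2", {"A": 5.0, "B": 4.0}),
            "d": ("g2", {"A": 6.0, "B": 7.0}),
        }
    )
    y = df["dv"].to_numpy()
    grand = y.mean()  # 4.25
    subj_means = {"a": 2.0, "b": 4.0, "c": 4.5, "d": 6.5}
    grp_means = {"g1": 3.0, "g2": 5.5}
    lvl_means = {"A": 3.5, "B": 5.0}
    cells = {("g1", "A"): 1.5, ("g1", "B"): 4.5, ("g2", "A"): 5.5, ("g2", "B"): 5.5}
    ss_total = sum((v - grand) ** 2 for v in y)
    ss_between_subj = 2 * sum((m - grand) ** 2 for m in subj_means.values())
    ss_a = 2 * 2 * sum((m - grand) ** 2 for m in grp_means.values())
    ss_subj_w = ss_between_subj - ss_a
    ss_b = 4 * sum((m - grand) ** 2 for m in lvl_means.values())
    ss_cells = 2 * sum((c - grand) ** 2 for c in cells.values())
    ss_ab = ss_cells - ss_a - ss_b
    ss_err_w = ss_total - ss_between_subj - ss_b - ss_ab

    res = mixed_anova_2x2(df, dv="dv", within="level", between="group", subject="subject")
    assert res.between.F == pytest.approx((ss_a / 1) / (ss_subj_w / 2), rel=1e-10)
    assert res.within.F == pytest.approx((ss_b / 1) / (ss_err_w / 2), rel=1e-10)
    assert res.interaction.F == pytest.approx((ss_ab / 1) / (ss_err_w / 2), rel=1e-10)
    assert res.within.partial_eta_sq == pytest.approx(ss_b / (ss_b + ss_err_w), rel=1e-10)


def test_anova_matches_pingouin_on_random_balanced_data(rng):
    pingouin = pytest.importorskip("pingouin")
    for _ in range(5):
        scores = {}
        for i in range(10):
            grp = "g1" if i < 5 else "g2"
            scores[f"s{i}"] = (grp, {"A": rng.normal(), "B": rng.normal()})
        df = _long_table(scores)
        res = mixed_anova_2x2(df, dv="dv", within="level", between="group", subject="subject")
        ref = pingouin.mixed_anova(
            data=df, dv="dv", within="level", between="group", subject="subject"
        ).set_index("Source")
        assert res.between.F == pytest.approx(ref.loc["group", "F"], rel=1e-8)
        assert res.within.F == pytest.approx(ref.loc["level", "F"], rel=1e-8)
        assert res.interaction.F == pytest.approx(ref.loc["Interaction", "F"], rel=1e-8)
        p_col = "p_unc" if "p_unc" in ref.columns else "p-unc"
        assert res.within.p == pytest.approx(ref.loc["level", p_col], rel=1e-8)
        assert res.within.partial_eta_sq == pytest.approx(ref.loc["level", "np2"], rel=1e-8)


def test_anova_type_one_error_calibrated_under_null():
    """Null simulation: the condition p-value is uniform, type-I ~ 5%."""
    rng = np.random.default_rng(7)
    reps, hits = 400, 0
    pvals = []
    for _ in range(reps):
        scores = {
            f"s{i}": ("g1" if i % 2 else "g2", {"A": rng.normal(), "B": rng.normal()})
            for i in range(12)
        }
        res = mixed_anova_2x2(
            _long_table(scores), dv="dv", within="level", between="group", subject="subject"
        )
        pvals.append(res.within.p)
        hits += res.within.p < 0.05
    assert hits / reps == pytest.approx(0.05, abs=0.03)
    # crude uniformity check on the p-value distribution
    assert np.mean(pvals) == pytest.approx(0.5, abs=0.06)


def test_anova_rejects_missing_condition_rows():
    df = _long_table({"a": ("g1", {"A": 1.0}), "b": ("g2", {"A": 1.0, "B": 2.0})})
    with pytest.raises(ValueError):
        mixed_anova_2x2(df, dv="dv", within="level", between="group", subject="subject")


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------


def test_proportional_table_gives_zero_chi2():
    r = chi_square_independence([[10, 20], [5, 10]])
    assert r.chi2 == pytest.approx(0.0, abs=1e-12)
    assert r.p == pytest.approx(1.0)


def test_diagonal_2x2_hand_computation():
    r = chi_square_independence([[10, 0], [0, 10]])
    assert r.chi2 == pytest.approx(20.0)
    assert r.df == 1
    assert (r.expected.to_numpy() == 5.0).all()


def test_chi2_matches_brute_force_oracle(rng):
    for _ in range(30):
        table = rng.integers(1, 30, size=(2, 3)).tolist()
        r = chi_square_independence(table)
        assert r.chi2 == pytest.approx(oracle_chi2(table), rel=1e-10)
        assert r.df == 2


def test_chi2_margins_preserved(rng):
    table = [[7, 3, 5], [2, 8, 6]]
    r = chi_square_independence(table)
    assert r.expected.sum(axis=1).tolist() == pytest.approx(r.observed.sum(axis=1).tolist())
    assert r.expected.sum(axis=0).tolist() == pytest.approx(r.observed.sum(axis=0).tolist())


def test_chi2_zero_margin_rejected():
    with pytest.raises(ValueError):
        chi_square_independence([[0, 0], [1, 2]])
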
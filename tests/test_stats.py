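"""Statistical battery: closed-form oracles, published values, pingouin
cross-checks of the split-plot machinery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from exefun.stats import (
    GroupSummary,
    bonferroni_posthoc,
    chi_square,
    cohens_f_from_eta,
    d_from_f,
    epsilons,
    eta_sq_from_t,
    levene,
    mann_whitney_u,
    mauchly,
    mixed_rm_anova,
    one_way_anova,
    pooled_t,
    sensitivity_f,
    shapiro_wilk,
    welch_t,
)


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ym, ysd, om, osd, expected", [
    (14.55, 1.87, 14.49, 3.15, 0.11),    # education
    (84.3, 9.64, 68.15, 12.25, 7.38),    # fluid intelligence
    (70.75, 10.04, 83.79, 10.67, -6.28), # vocabulary
    (69.06, 11.07, 48.35, 8.11, 10.45),  # processing speed
])
def test_pooled_t_reproduces_published_age_contrasts(ym, ysd, om, osd, expected):
    res = pooled_t(GroupSummary("y", 55, ym, ysd), GroupSummary("o", 45, om, osd))
    assert res.df == 98
    assert res.statistic == pytest.approx(expected, abs=0.02)


def test_pooled_t_identical_summaries_is_zero():
    s = GroupSummary("g", 10, 5.0, 2.0)
    assert pooled_t(s, s).statistic == 0.0


def test_pooled_t_matches_direct_formula_on_raw_vectors(rng):
    a, b = rng.normal(0, 1, 9), rng.normal(0.5, 1.4, 7)
    res = pooled_t(a, b)
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    assert res.statistic == pytest.approx(t, abs=1e-12)
    # summary-statistic entry point agrees with the raw-vector one
    res2 = pooled_t(GroupSummary.from_values(a), GroupSummary.from_values(b))
    assert res2.statistic == pytest.approx(res.statistic, abs=1e-12)


def test_welch_hand_example_and_limit():
    res = welch_t(GroupSummary("a", 2, 0.0, 1.0), GroupSummary("b", 2, 1.0, 1.0))
    assert res.statistic == pytest.approx(-1.0)
    assert res.df == pytest.approx(2.0)
    assert welch_t([1.0, 2.0], [1.0, 2.0]).statistic == 0.0
    # equal variances and n: Welch df equals pooled df
    eq = welch_t(GroupSummary("a", 8, 0.0, 2.0), GroupSummary("b", 8, 1.0, 2.0))
    assert eq.df == pytest.approx(14.0)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _brute_u(a, b):
    return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)


def test_mann_whitney_complete_separation_and_symmetry():
    assert mann_whitney_u([1, 2], [3, 4]).statistic == 0.0
    assert mann_whitney_u([3, 1, 2], [2, 3, 1]).statistic == pytest.approx(4.5)  # n^2/2


def test_mann_whitney_matches_exhaustive_enumeration():
    for a in itertools.product(range(1, 5), repeat=2):
        for b in itertools.product(range(1, 5), repeat=2):
            assert mann_whitney_u(list(a), list(b)).statistic == pytest.approx(
                _brute_u(a, b))


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def test_chi_square_reproduces_published_sex_by_genotype():
    younger = [[12, 9], [7, 10], [8, 9]]
    older = [[7, 8], [7, 5], [12, 6]]
    res_y, res_o = chi_square(younger), chi_square(older)
    assert res_y.df == 2 and res_o.df == 2
    assert res_y.statistic == pytest.approx(0.99, abs=0.02)
    assert res_o.statistic == pytest.approx(1.34, abs=0.02)


def test_chi_square_zero_when_observed_equals_expected():
    assert chi_square([[10, 20], [20, 40]]).statistic == pytest.approx(0.0)


def test_chi_square_zero_marginal_raises():
    with pytest.raises(ValueError):
        chi_square([[0, 0], [3, 4]])


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def test_one_way_f_is_zero_for_equal_means():
    res = one_way_anova([[1.0, 3.0], [2.0, 2.0], [0.0, 4.0]])
    assert res.statistic == pytest.approx(0.0)


def test_two_group_anova_equals_squared_t(rng):
    a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1.2, 9)
    f_res = one_way_anova([a, b])
    t_res = pooled_t(a, b)
    assert f_res.statistic == pytest.approx(t_res.statistic**2, abs=1e-10)
    assert f_res.p_value == pytest.approx(t_res.p_value, abs=1e-12)


def test_one_way_matches_scipy_on_random_fixture(rng):
    groups = [rng.normal(m, 1.0, n) for m, n in [(0, 8), (0.4, 11), (1.0, 6)]]
    res = one_way_anova(groups)
    ref = sps.f_oneway(*groups)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _toy_splitplot():
    data = pd.DataFrame({"m1": [1.0, 2.0, 5.0, 7.0], "m2": [3.0, 4.0, 4.0, 8.0]})
    group = pd.Series(["A", "A", "B", "B"])
    return data, group


def test_mixed_anova_matches_hand_ss_decomposition():
    """2 groups x 2 within levels, 8 observations, fully hand-computed."""
    data, group = _toy_splitplot()
    Y = data.to_numpy()
    grand = Y.mean()
    subj = Y.mean(axis=1)
    g_means = {"A": subj[:2].mean(), "B": subj[2:].mean()}
    ss_group = 2 * sum(2 * (g_means[g] - subj.mean()) ** 2 for g in g_means)
    ss_subj = 2 * (sum((subj[:2] - g_means["A"]) ** 2) + sum((subj[2:] - g_means["B"]) ** 2))
    col = Y.mean(axis=0)
    ss_within = 4 * sum((col - grand) ** 2)
    cells = np.array([[Y[:2, 0].mean(), Y[:2, 1].mean()],
                      [Y[2:, 0].mean(), Y[2:, 1].mean()]])
    ss_cells = 2 * ((cells - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_within
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_cells - ss_subj

    fit = mixed_rm_anova(data, group)
    tab = fit.table
    assert tab.loc["group", "ss"] == pytest.approx(ss_group, abs=1e-10)
    assert tab.loc["within", "ss"] == pytest.approx(ss_within, abs=1e-10)
    assert tab.loc["group_x_within", "ss"] == pytest.approx(ss_inter, abs=1e-10)
    assert fit.ms_subject == pytest.approx(ss_subj / 2, abs=1e-10)
    assert fit.ms_error_within == pytest.approx(ss_err / 2, abs=1e-10)
    assert tab.loc["group", "F"] == pytest.approx(
        (ss_group / 1) / (ss_subj / 2), abs=1e-10)
    assert tab.loc["within", "F"] == pytest.approx(
        (ss_within / 1) / (ss_err / 2), abs=1e-10)
    assert tuple(tab.loc["group", ["df1", "df2"]]) == (1, 2)
    assert tuple(tab.loc["within", ["df1", "df2"]]) == (1, 2)


def test_mixed_anova_matches_pingouin_balanced(rng):
    pg = pytest.importorskip("pingouin")
    n_per, w = 8, 3
    data = pd.DataFrame(rng.normal(size=(2 * n_per, w)), columns=list("abc"))
    data += rng.normal(size=(2 * n_per, 1))  # subject heterogeneity
    group = pd.Series(["g1"] * n_per + ["g2"] * n_per)
    fit = mixed_rm_anova(data, group)
    long = data.copy()
    long["subject"], long["grp"] = range(len(data)), group
    long = long.melt(["subject", "grp"], var_name="w", value_name="y")
    ref = pg.mixed_anova(data=long, dv="y", within="w", subject="subject",
                         between="grp").set_index("Source")
    assert fit.table.loc["group", "F"] == pytest.approx(ref.loc["grp", "F"])
    assert fit.table.loc["within", "F"] == pytest.approx(ref.loc["w", "F"])
    assert fit.table.loc["group_x_within", "F"] == pytest.approx(
        ref.loc["Interaction", "F"])
    assert fit.table.loc["group", "p"] == pytest.approx(ref.loc["grp", "p_unc"])


def test_mixed_anova_unbalanced_group_and_interaction_match_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    sizes = [9, 6, 7]
    group = pd.Series(np.repeat(["a", "b", "c"], sizes))
    data = pd.DataFrame(rng.normal(size=(sum(sizes), 3)), columns=["l1", "l2", "l3"])
    fit = mixed_rm_anova(data, group)
    long = data.copy()
    long["subject"], long["grp"] = range(len(data)), group
    long = long.melt(["subject", "grp"], var_name="w", value_name="y")
    ref = pg.mixed_anova(data=long, dv="y", within="w", subject="subject",
                         between="grp").set_index("Source")
    assert fit.table.loc["group", "F"] == pytest.approx(ref.loc["grp", "F"])
    assert fit.table.loc["group_x_within", "F"] == pytest.approx(
        ref.loc["Interaction", "F"])


def test_constant_within_levels_give_zero_within_ss(rng):
    base = rng.normal(size=10)
    data = pd.DataFrame({"a": base, "b": base, "c": base})
    group = pd.Series(["g1"] * 5 + ["g2"] * 5)
    with np.errstate(invalid="ignore"):
        fit = mixed_rm_anova(data, group)
    assert fit.table.loc["within", "ss"] == pytest.approx(0.0, abs=1e-12)
    assert fit.table.loc["group_x_within", "ss"] == pytest.approx(0.0, abs=1e-12)


def test_group_f_invariant_under_relabeling_within_groups(rng):
    data = pd.DataFrame(rng.normal(size=(12, 3)))
    group = pd.Series(["a"] * 7 + ["b"] * 5)
    fit1 = mixed_rm_anova(data, group)
    perm = np.r_[np.random.default_rng(1).permutation(7),
                 7 + np.random.default_rng(2).permutation(5)]
    fit2 = mixed_rm_anova(data.iloc[perm].reset_index(drop=True), group)
    assert fit1.table["F"].to_numpy() == pytest.approx(fit2.table["F"].to_numpy())


def test_df_structure_of_study_design(rng):
    sizes = [21, 17, 17, 15, 12, 18]
    group = pd.Series(np.repeat(list("abcdef"), sizes))
    data = pd.DataFrame(rng.normal(size=(100, 3)))
    fit = mixed_rm_anova(data, group)
    assert tuple(fit.table.loc["group", ["df1", "df2"]]) == (5, 94)
    assert tuple(fit.table.loc["within", ["df1", "df2"]]) == (2, 188)
    assert tuple(fit.table.loc["group_x_within", ["df1", "df2"]]) == (10, 188)


# ---------------------------------------------------------------------------
# sphericity
# ---------------------------------------------------------------------------

def test_mauchly_two_levels_is_trivial(rng):
    res = mauchly(pd.DataFrame(rng.normal(size=(10, 2))))
    assert res.statistic == 1.0 and res.p_value == 1.0


def test_spherical_covariance_gives_w_one_and_eps_one(rng):
    Y = rng.normal(size=(40, 3))
    centered = Y - Y.mean(axis=0)
    S = centered.T @ centered / (len(Y) - 1)
    vals, vecs = np.linalg.eigh(S)
    white = centered @ vecs @ np.diag(vals**-0.5) @ vecs.T  # sample cov = I
    data = pd.DataFrame(white)
    res = mauchly(data)
    assert res.statistic == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)
    gg, hf = epsilons(data)
    assert gg == pytest.approx(1.0) and hf == 1.0


def test_sphericity_matches_pingouin_single_group(rng):
    pg = pytest.importorskip("pingouin")
    data = pd.DataFrame(rng.normal(size=(25, 3)) @
                        np.array([[1, 0.5, 0.2], [0, 1, 0.4], [0, 0, 1]]))
    res = mauchly(data)
    spher = pg.sphericity(data)
    assert res.statistic == pytest.approx(spher.W)
    assert res.p_value == pytest.approx(spher.pval)
    gg, hf = epsilons(data)
    assert gg == pytest.approx(pg.epsilon(data, correction="gg"))
    assert hf == pytest.approx(min(1.0, pg.epsilon(data, correction="hf")))


def test_epsilon_bounds_and_ordering(rng):
    for seed in range(5):
        r = np.random.default_rng(seed)
        data = pd.DataFrame(r.normal(size=(20, 3)) @ r.normal(size=(3, 3)))
        gg, hf = epsilons(data)
        assert 0.5 - 1e-12 <= gg <= 1.0
        assert hf >= gg
        # for F > 1, the GG correction can only make the test less significant
        fit = mixed_rm_anova(data, pd.Series(["a"] * 10 + ["b"] * 10))
        if fit.table.loc["within", "F"] > 1.0:
            assert fit.table.loc["within", "p_gg"] >= fit.table.loc["within", "p"] - 1e-12


def test_split_plot_hf_formula_reproduces_published_pair():
    """In the N=100, 6-group, 3-level design, a GG epsilon of 0.886 maps to
    an HF epsilon of 0.949 under the pooled split-plot adjustment."""
    gg = 0.886  # printed to 3 dp, so the mapped HF inherits that rounding
    hf = (100 * 2 * gg - 2) / (2 * (100 - 6 - 2 * gg))
    assert hf == pytest.approx(0.949, abs=1.5e-3)


# ---------------------------------------------------------------------------
# post-hoc
# ---------------------------------------------------------------------------

def test_bonferroni_posthoc_hand_oracle():
    data, group = _toy_splitplot()
    fit = mixed_rm_anova(data, group)
    post = bonferroni_posthoc(fit, family="all_pairs")
    assert len(post) == 6  # C(4,2) cell pairs
    # within-group pair (A:m1 vs A:m2): paired-type t from MS_error_within
    row = post.query("cell_a == 'A:m1' and cell_b == 'A:m2'").iloc[0]
    diff = data["m1"][:2].mean() - data["m2"][:2].mean()
    t_hand = diff / math.sqrt(2 * fit.ms_error_within / 2)
    assert row["t"] == pytest.approx(t_hand)
    assert row["p_bonferroni"] == pytest.approx(
        min(1.0, 6 * 2 * sps.t.sf(abs(t_hand), fit.df_error_within)))
    # cross-group pair uses the combined error term
    row = post.query("cell_a == 'A:m1' and cell_b == 'B:m1'").iloc[0]
    ms_comb = (fit.ms_subject + fit.ms_error_within) / 2
    t_hand = (data["m1"][:2].mean() - data["m1"][2:].mean()) / math.sqrt(ms_comb)
    assert row["t"] == pytest.approx(t_hand)
    assert (post["p_bonferroni"] >= post["p_raw"] - 1e-15).all()


def test_bonferroni_identical_cells_and_family_of_one(rng):
    data = pd.DataFrame(rng.normal(size=(10, 2)), columns=["m1", "m2"])
    # equalize the a:m1 and a:m2 cell means without zeroing the error term
    data.iloc[:5, 1] = data.iloc[:5, 0].to_numpy()[::-1]
    fit = mixed_rm_anova(data, pd.Series(["a"] * 5 + ["b"] * 5))
    post = bonferroni_posthoc(fit, family="within_measure")
    # 2 groups: each within-measure family has a single pair
    assert (post["p_bonferroni"] == post["p_raw"]).all()
    same = bonferroni_posthoc(fit, family="all_pairs")
    within_same_group = same.query("cell_a == 'a:m1' and cell_b == 'a:m2'").iloc[0]
    assert within_same_group["t"] == pytest.approx(0.0)
    assert within_same_group["p_bonferroni"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

def test_shapiro_matches_reference_implementation():
    x = [12.1, 9.4, 7.3, 15.2, 11.8, 8.9, 10.5, 13.7, 6.2, 9.9, 14.1, 7.8]
    res = shapiro_wilk(x)
    assert res.statistic == pytest.approx(0.9693261384, abs=1e-6)
    assert res.p_value == pytest.approx(0.9036177164, abs=1e-4)
    sym = [2.1, 3.4, 3.9, 4.4, 4.8, 5.2, 5.6, 6.1, 6.6, 7.9]
    assert shapiro_wilk(sym).statistic == pytest.approx(0.9996918244, abs=1e-6)


def test_shapiro_constant_vector_raises():
    with pytest.raises(ValueError):
        shapiro_wilk([3.0, 3.0, 3.0, 3.0])


def test_levene_zero_for_mirror_image_groups():
    a = [1.0, 2.0, 6.0, 7.0]
    b = [11.0, 12.0, 16.0, 17.0]  # same spread, shifted
    assert levene([a, b]).statistic == pytest.approx(0.0)


def test_levene_two_groups_is_squared_t_on_absolute_deviations(rng):
    a, b = rng.normal(0, 1, 10), rng.normal(0, 2.5, 8)
    res = levene([a, b])
    da, db = np.abs(a - a.mean()), np.abs(b - b.mean())
    assert res.statistic == pytest.approx(pooled_t(da, db).statistic**2, abs=1e-10)


# ---------------------------------------------------------------------------
# effect sizes and sensitivity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("t, df, expected", [
    (6.2, 98, 0.28), (2.45, 98, 0.06), (2.00, 98, 0.04),
])
def test_eta_sq_from_published_t_values(t, df, expected):
    assert eta_sq_from_t(t, df) == pytest.approx(expected, abs=0.005)


def test_eta_sq_zero_t():
    assert eta_sq_from_t(0.0, 98) == 0.0


def test_f_eta_d_conversion_chain():
    assert cohens_f_from_eta(0.0) == 0.0
    assert cohens_f_from_eta(0.5) == pytest.approx(1.0)
    # the published chain: f=.30 <-> eta^2=.08 (rounded), d = 2f = .60
    assert cohens_f_from_eta(0.08) == pytest.approx(0.30, abs=0.01)
    eta_exact = 0.30**2 / (1 + 0.30**2)
    assert cohens_f_from_eta(eta_exact) == pytest.approx(0.30, abs=1e-12)
    assert d_from_f(0.30) == pytest.approx(0.60)
    with pytest.raises(ValueError):
        cohens_f_from_eta(1.0)


def test_sensitivity_monotone_and_alpha_limit():
    f100 = sensitivity_f(100, 6)
    f400 = sensitivity_f(400, 6)
    assert f400 < f100
    assert sensitivity_f(100, 6, alpha=0.05, power=0.06) < 0.08


def test_sensitivity_f_verified_by_monte_carlo():
    """Simulated one-way power at the returned f reaches the target."""
    n_per, k = 17, 6
    n_total = n_per * k
    f_star = sensitivity_f(n_total, k, 0.05, 0.80)
    delta = f_star * math.sqrt(3.0)  # means (d,-d,0,0,0,0): between-SD = f
    means = np.array([delta, -delta, 0, 0, 0, 0])
    reps = 30_000
    r = np.random.default_rng(99)
    data = r.normal(size=(reps, k, n_per)) + means[None, :, None]
    gm = data.mean(axis=2)
    grand = gm.mean(axis=1, keepdims=True)
    ssb = n_per * ((gm - grand) ** 2).sum(axis=1)
    ssw = ((data - data.mean(axis=2, keepdims=True)) ** 2).sum(axis=(1, 2))
    F = (ssb / (k - 1)) / (ssw / (n_total - k))
    rate = (F > sps.f.isf(0.05, k - 1, n_total - k)).mean()
    se = math.sqrt(0.8 * 0.2 / reps)
    assert abs(rate - 0.80) < 3 * se + 1e-9
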
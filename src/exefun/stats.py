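"""Statistical battery for the cohort analyses.

Covers the two-sample comparisons (pooled and Welch–Satterthwaite t,
Mann-Whitney U), Pearson χ² for contingency tables, one-way ANOVA,
the mixed (split-plot) repeated-measures ANOVA with Mauchly's sphericity
test and Greenhouse-Geisser / Huynh-Feldt corrections, Bonferroni cell
post-hocs on the interaction, assumption checks (Shapiro-Wilk, Levene),
the η² / Cohen's f / Cohen's d conversions, and the noncentral-F
sensitivity analysis (minimal detectable effect at given n, α, power).

The split-plot decomposition uses Type-III (sum-coded) sums of squares so
that unequal group sizes are handled the way mainstream ANOVA software
handles them: the between-subject stratum tests group against
subject-within-group; the within stratum tests the repeated factor and
its interaction with group against the subject×factor residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "GroupSummary",
    "MixedANOVA",
    "pooled_t",
    "welch_t",
    "mann_whitney_u",
    "chi_square",
    "one_way_anova",
    "mixed_rm_anova",
    "mauchly",
    "epsilons",
    "bonferroni_posthoc",
    "shapiro_wilk",
    "levene",
    "eta_sq_from_t",
    "cohens_f_from_eta",
    "d_from_f",
    "sensitivity_f",
]


@dataclass(frozen=True)
class StatResult:
    """One test outcome: statistic, degrees of freedom, p, effect sizes."""

    test_name: str
    statistic: float
    df: float | tuple[float, ...]
    p_value: float
    effect_size: dict[str, float] = field(default_factory=dict)
    notes: str = ""


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group, sufficient for t tests."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r} needs n >= 2")
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")

    @classmethod
    def from_values(cls, values, label: str = "") -> "GroupSummary":
        x = np.asarray(values, dtype=float)
        return cls(label=label, n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)))


def _as_summary(x, label: str) -> GroupSummary:
    return x if isinstance(x, GroupSummary) else GroupSummary.from_values(x, label)


# ---------------------------------------------------------------------------
# two-sample tests
# ---------------------------------------------------------------------------

def pooled_t(a, b) -> StatResult:
    """Classical pooled-variance two-sample t (first minus second).

    Accepts raw vectors or :class:`GroupSummary` objects, so printed
    mean/SD/n tables are first-class inputs. df = n_a + n_b − 2.
    """
    sa, sb = _as_summary(a, "a"), _as_summary(b, "b")
    if sa.sd == 0 and sb.sd == 0:
        raise ValueError("zero pooled variance: t undefined")
    t, p = sps.ttest_ind_from_stats(
        sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n, equal_var=True
    )
    df = sa.n + sb.n - 2
    return StatResult("pooled_t", float(t), float(df), float(p),
                      {"eta_sq": eta_sq_from_t(float(t), df)})


def welch_t(a, b) -> StatResult:
    """Welch two-sample t with Satterthwaite degrees of freedom."""
    sa, sb = _as_summary(a, "a"), _as_summary(b, "b")
    if sa.sd == 0 and sb.sd == 0:
        raise ValueError("zero variance in both groups: t undefined")
    t, p = sps.ttest_ind_from_stats(
        sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n, equal_var=False
    )
    va, vb = sa.sd**2 / sa.n, sb.sd**2 / sb.n
    df = (va + vb) ** 2 / (va**2 / (sa.n - 1) + vb**2 / (sb.n - 1))
    return StatResult("welch_t", float(t), float(df), float(p))


def mann_whitney_u(a, b) -> StatResult:
    """Mann-Whitney U with tie-corrected normal approximation.

    The reported U is the statistic of the first sample (number of
    (a, b) pairs with a > b, ties counting one half).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    return StatResult("mann_whitney_u", float(res.statistic),
                      float(a.size + b.size - 2), float(res.pvalue))


def chi_square(table) -> StatResult:
    """Pearson χ² test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = sps.chi2_contingency(table, correction=False)
    return StatResult("chi_square", float(res.statistic), float(res.dof),
                      float(res.pvalue))


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def one_way_anova(groups: list) -> StatResult:
    """One-way between-subjects ANOVA with η² = SS_between / SS_total."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups of n >= 2")
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    k, n = len(arrays), allv.size
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        raise ValueError("zero within-group variance: F undefined")
    f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f_stat, df1, df2))
    eta = ss_between / (ss_between + ss_within)
    return StatResult("one_way_anova", float(f_stat), (float(df1), float(df2)), p,
                      {"eta_sq": float(eta)})


# ---------------------------------------------------------------------------
# mixed (split-plot) repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixedANOVA:
    """Fitted split-plot decomposition.

    ``table`` has one row per effect (group, within, interaction) with SS,
    df, F, p, sphericity-corrected p's and both η² flavors. The error-term
    mean squares are retained for post-hoc cell comparisons.
    """

    table: pd.DataFrame
    cell_means: pd.DataFrame          # groups × within levels
    group_sizes: pd.Series
    ms_subject: float
    df_subject: float
    ms_error_within: float
    df_error_within: float
    n_within: int
    mauchly: StatResult
    epsilon_gg: float
    epsilon_hf: float


def _sum_code(labels: np.ndarray, levels: list) -> np.ndarray:
    """Deviation (sum-to-zero) coding: k levels -> k−1 columns."""
    out = np.zeros((len(labels), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        out[labels == lev, j] = 1.0
    out[labels == levels[-1], :] = -1.0
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def mixed_rm_anova(data: pd.DataFrame, group: pd.Series) -> MixedANOVA:
    """Split-plot ANOVA: one between factor, one within factor.

    ``data`` is a wide table (one row per participant, one column per
    within level, no missing cells — impute upstream); ``group`` assigns
    each row its between-group label. Emits F tests for the group effect
    (against subject-within-group), the within factor and group×within
    interaction (against the within residual), with Greenhouse-Geisser
    and Huynh-Feldt corrected p values and both classical and partial η².
    """
    Y = data.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("missing cells: impute before fitting")
    group = pd.Series(np.asarray(group), index=data.index)
    levels = list(pd.unique(group))
    n, w = Y.shape
    if w < 2 or len(levels) < 2:
        raise ValueError("need >= 2 within levels and >= 2 groups")
    k = len(levels)

    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())

    # between-subject stratum: one-way ANOVA on subject means, scaled by w
    subj_means = Y.mean(axis=1)
    ss_group = 0.0
    ss_subj = 0.0
    sizes = {}
    for lev in levels:
        m = subj_means[group.to_numpy() == lev]
        sizes[lev] = m.size
        ss_group += w * m.size * (m.mean() - subj_means.mean()) ** 2
        ss_subj += w * ((m - m.mean()) ** 2).sum()
    # weighted grand of subject means == grand since within factor is balanced
    df_group, df_subj = k - 1, n - k

    # within-subject stratum on deviations from subject means (Type III)
    D = (Y - subj_means[:, None]).ravel()
    glab = np.repeat(group.to_numpy(), w)
    wlab = np.tile(np.arange(w), n)
    W = _sum_code(wlab, list(range(w)))
    G = _sum_code(glab, levels)
    GW = np.column_stack([G[:, i] * W[:, j]
                          for i in range(k - 1) for j in range(w - 1)])
    X_full = np.column_stack([W, GW])
    rss_full = _rss(X_full, D)
    ss_within_f = _rss(GW, D) - rss_full
    ss_inter = _rss(W, D) - rss_full
    ss_err_w = rss_full
    df_within, df_inter = w - 1, (k - 1) * (w - 1)
    df_err_w = (n - k) * (w - 1)

    ms_subj = ss_subj / df_subj
    ms_err_w = ss_err_w / df_err_w

    try:
        sphericity = mauchly(data, group)
        eps_gg, eps_hf = epsilons(data, group)
    except ValueError as exc:  # singular contrast covariance
        sphericity = StatResult("mauchly", float("nan"), float("nan"),
                                float("nan"), notes=str(exc))
        eps_gg = eps_hf = 1.0

    rows = []
    for name, ss, df1, ss_err, df2 in [
        ("group", ss_group, df_group, ss_subj, df_subj),
        ("within", ss_within_f, df_within, ss_err_w, df_err_w),
        ("group_x_within", ss_inter, df_inter, ss_err_w, df_err_w),
    ]:
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = float(np.divide(ss / df1, ss_err / df2))
        p = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else float("nan")
        row = {
            "effect": name,
            "ss": ss,
            "df1": float(df1),
            "df2": float(df2),
            "F": f_stat,
            "p": p,
            "eta_sq": ss / ss_total,
            "partial_eta_sq": ss / (ss + ss_err),
        }
        if name != "group" and np.isfinite(f_stat):
            # sphericity only touches within-stratum tests
            row["p_gg"] = float(sps.f.sf(f_stat, df1 * eps_gg, df2 * eps_gg))
            row["p_hf"] = float(sps.f.sf(f_stat, df1 * eps_hf, df2 * eps_hf))
        else:
            row["p_gg"] = p
            row["p_hf"] = p
        rows.append(row)

    cell_means = pd.DataFrame(
        {lev: Y[group.to_numpy() == lev].mean(axis=0) for lev in levels},
        index=list(data.columns),
    ).T
    return MixedANOVA(
        table=pd.DataFrame(rows).set_index("effect"),
        cell_means=cell_means,
        group_sizes=pd.Series(sizes),
        ms_subject=ms_subj,
        df_subject=float(df_subj),
        ms_error_within=ms_err_w,
        df_error_within=float(df_err_w),
        n_within=w,
        mauchly=sphericity,
        epsilon_gg=eps_gg,
        epsilon_hf=eps_hf,
    )


def _contrast_cov(data: pd.DataFrame, group: pd.Series | None):
    """Orthonormal-contrast covariance of the within levels, pooled over groups."""
    Y = data.to_numpy(dtype=float)
    n, w = Y.shape
    if group is None:
        centered = Y - Y.mean(axis=0)
        df = n - 1
    else:
        glab = np.asarray(group)
        centered = np.empty_like(Y)
        k = 0
        for lev in pd.unique(glab):
            mask = glab == lev
            centered[mask] = Y[mask] - Y[mask].mean(axis=0)
            k += 1
        df = n - k
    S = centered.T @ centered / df
    # orthonormal contrasts: QR of centered identity, drop the constant
    helmert = np.linalg.qr(np.eye(w) - 1.0 / w)[0][:, : w - 1]
    V = helmert.T @ S @ helmert
    return V, n, df


def mauchly(data: pd.DataFrame, group: pd.Series | None = None) -> StatResult:
    """Mauchly's sphericity test on the within-level covariance.

    With a between factor the covariance is pooled within groups (the
    split-plot convention). For two within levels sphericity is automatic
    and W ≡ 1 is reported. χ² approximation with df = w(w−1)/2 − 1.
    """
    w = data.shape[1]
    if w == 2:
        return StatResult("mauchly", 1.0, 0.0, 1.0,
                          notes="two within levels: sphericity automatic")
    V, n, df_pooled = _contrast_cov(data, group)
    b = w - 1
    eig = np.linalg.eigvalsh(V)
    if eig.min() <= 0:
        raise ValueError("singular contrast covariance: Mauchly undefined")
    W_stat = float(np.prod(eig) / (eig.mean() ** b))
    mult = df_pooled - (2 * b**2 + b + 2) / (6.0 * b)
    chi2 = -mult * math.log(W_stat)
    df = w * (w - 1) / 2 - 1
    return StatResult("mauchly", W_stat, float(df), float(sps.chi2.sf(chi2, df)),
                      {"chi2": float(chi2)})


def epsilons(data: pd.DataFrame, group: pd.Series | None = None) -> tuple[float, float]:
    """Greenhouse-Geisser and Huynh-Feldt sphericity corrections.

    GG from the eigenvalues of the pooled contrast covariance; HF applies
    the small-sample adjustment (with the group count entering the
    denominator in the split-plot case), capped at 1. GG is bounded below
    by 1/(w−1).
    """
    w = data.shape[1]
    if w == 2:
        return 1.0, 1.0
    V, n, df_pooled = _contrast_cov(data, group)
    b = w - 1
    eig = np.linalg.eigvalsh(V)
    gg = float(eig.sum() ** 2 / (b * (eig**2).sum()))
    k = n - df_pooled  # number of groups (1 when group is None)
    hf = (n * b * gg - 2.0) / (b * (n - k - b * gg))
    return gg, float(min(1.0, hf))


def bonferroni_posthoc(fit: MixedANOVA, family: str = "all_pairs") -> pd.DataFrame:
    """Bonferroni-adjusted pairwise comparisons of the group×within cells.

    Within-group (paired-type) contrasts use the within residual mean
    square; cross-group contrasts use the Cochran-combined error
    (MS_subject + (w−1)·MS_within)/w with Satterthwaite df. ``family``
    is either ``all_pairs`` (every cell pair corrected together — 153
    for 6×3) or ``within_measure`` (same within level only, corrected per
    level). Adjusted p = min(1, m·p).
    """
    if family not in ("all_pairs", "within_measure"):
        raise ValueError(f"unknown family {family!r}")
    cells = [(g, m) for g in fit.cell_means.index for m in fit.cell_means.columns]
    pairs = list(combinations(cells, 2))
    if family == "within_measure":
        pairs = [p for p in pairs if p[0][1] == p[1][1]]
        m_family = len(fit.cell_means.index) * (len(fit.cell_means.index) - 1) // 2
    else:
        m_family = len(pairs)
    w = fit.n_within
    ms_comb = (fit.ms_subject + (w - 1) * fit.ms_error_within) / w
    df_comb = ms_comb**2 * w**2 / (
        fit.ms_subject**2 / fit.df_subject
        + ((w - 1) * fit.ms_error_within) ** 2 / fit.df_error_within
    )
    rows = []
    for (g1, m1), (g2, m2) in pairs:
        n1, n2 = fit.group_sizes[g1], fit.group_sizes[g2]
        diff = fit.cell_means.loc[g1, m1] - fit.cell_means.loc[g2, m2]
        if g1 == g2:
            var = 2.0 * fit.ms_error_within / n1
            df = fit.df_error_within
        else:
            var = ms_comb * (1.0 / n1 + 1.0 / n2)
            df = df_comb
        t = diff / math.sqrt(var)
        p_raw = 2.0 * float(sps.t.sf(abs(t), df))
        rows.append({
            "cell_a": f"{g1}:{m1}", "cell_b": f"{g2}:{m2}",
            "mean_diff": diff, "t": t, "df": df,
            "p_raw": p_raw, "p_bonferroni": min(1.0, m_family * p_raw),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

def shapiro_wilk(values) -> StatResult:
    """Shapiro-Wilk normality test."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: Shapiro-Wilk undefined")
    res = sps.shapiro(x)
    return StatResult("shapiro_wilk", float(res.statistic), float(x.size),
                      float(res.pvalue))


def levene(groups: list) -> StatResult:
    """Levene's homogeneity-of-variance test, centered on group means."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("Levene needs >= 2 groups")
    res = sps.levene(*arrays, center="mean")
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return StatResult("levene", float(res.statistic),
                      (float(k - 1), float(n - k)), float(res.pvalue))


# ---------------------------------------------------------------------------
# effect sizes and sensitivity
# ---------------------------------------------------------------------------

def eta_sq_from_t(t: float, df: float) -> float:
    """η² for a two-group contrast: t² / (t² + df)."""
    if df <= 0:
        raise ValueError("df must be positive")
    return t * t / (t * t + df)


def cohens_f_from_eta(eta_sq: float) -> float:
    """Cohen's f = sqrt(η² / (1 − η²))."""
    if not 0 <= eta_sq < 1:
        raise ValueError("eta_sq must lie in [0, 1)")
    return math.sqrt(eta_sq / (1.0 - eta_sq))


def d_from_f(f: float, k: int = 2) -> float:
    """Cohen's d from f; for two groups d = 2f."""
    if k != 2:
        raise ValueError("d from f is only defined here for the two-group case")
    return 2.0 * f


def sensitivity_f(n_total: int, k_groups: int, alpha: float = 0.05,
                  power: float = 0.80, tol: float = 1e-6) -> float:
    """Minimal detectable Cohen's f of a one-way between ANOVA.

    Solves, by bisection, for the smallest f whose noncentral-F power
    (λ = f²·N, df = (k−1, N−k)) reaches the target at level α.
    """
    if n_total <= k_groups:
        raise ValueError("n_total must exceed the number of groups")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    df1, df2 = k_groups - 1, n_total - k_groups
    fcrit = sps.f.isf(alpha, df1, df2)

    def achieved(f_val: float) -> float:
        return float(sps.ncf.sf(fcrit, df1, df2, n_total * f_val**2))

    lo, hi = 0.0, 1.0
    while achieved(hi) < power:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("sensitivity search failed to bracket the target power")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if achieved(mid) < power:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
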
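"""Pipeline orchestration: simulate → score → composites → analyze.

Each stage reads and writes plain CSV/JSON so any stage can be run or
inspected independently; ``run_all`` chains them and writes a manifest
(seed, row counts, input hashes). ``verify_reference`` recomputes, from
the packaged summary-statistics fixtures, every group-level statistic of
the motivating study design that is recoverable from printed summaries —
the four age-contrast t tests, the two sex×genotype χ² tests and the
effect-size conversion identities — and reports pass/fail per check.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from importlib import resources
from pathlib import Path

import pandas as pd

from . import composites as comp
from . import simulate as sim
from . import stats as st
from .sequences import read_sequences_csv, score_sequences
from .tasks import MEASURE_COLUMNS, assemble_measures

__all__ = [
    "run_all",
    "analyze",
    "cohort_composites",
    "demographics_stats",
    "verify_reference",
    "PipelineError",
]

log = logging.getLogger(__name__)

COMPOSITE_NAMES = ("inhibition", "shifting", "updating")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _require(path: Path, stage: str) -> Path:
    path = Path(path)
    if not path.exists():
        raise PipelineError(stage, f"missing input file: {path}")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def cohort_composites(
    config: sim.CohortConfig | None = None,
    seed: int = 0,
    scheme: str = "younger_reference",
    *,
    shifting_wcst: str = "corrected",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort and score it end to end, in memory.

    Returns ``(composites, participants)`` where composites carry the
    age_group/genotype columns merged in — the quickest route from a seed
    to analysable scores.
    """
    from .sequences import DigitSequence

    cohort = sim.generate_cohort(config, seed)
    seqs = [
        DigitSequence(r.participant_id, tuple(map(int, r.responses.split())))
        for r in cohort.sequences.itertuples()
    ]
    indices = score_sequences(seqs)
    ref_ids = None
    if scheme == "younger_reference":
        ref_ids = cohort.participants.loc[
            cohort.participants["age_group"] == "younger", "participant_id"]
    measures = assemble_measures(cohort.raw_tasks, indices, rng_reference_ids=ref_ids)
    composite = comp.build_composites(
        measures, cohort.participants, scheme, shifting_wcst=shifting_wcst)
    composite = composite.merge(
        cohort.participants[["participant_id", "age_group", "genotype"]],
        on="participant_id")
    return composite, cohort.participants


# ---------------------------------------------------------------------------
# analysis stage
# ---------------------------------------------------------------------------

def demographics_stats(participants: pd.DataFrame) -> pd.DataFrame:
    """Age contrasts and genotype homogeneity checks on demographics.

    Pooled t (younger − older) on education and the global-cognition
    scores, Pearson χ² for sex×age and, within each age group,
    sex×genotype plus one-way genotype ANOVAs.
    """
    younger = participants[participants["age_group"] == "younger"]
    older = participants[participants["age_group"] == "older"]
    rows = []
    for var in ("education", "raven", "mill_hill", "processing_speed"):
        res = st.pooled_t(younger[var].dropna(), older[var].dropna())
        rows.append({"analysis": f"age_t_{var}", "statistic": res.statistic,
                     "df": res.df, "p": res.p_value})
    sex_age = pd.crosstab(participants["sex"], participants["age_group"])
    res = st.chi_square(sex_age.to_numpy())
    rows.append({"analysis": "chi2_sex_by_age", "statistic": res.statistic,
                 "df": res.df, "p": res.p_value})
    for grp, sub in (("younger", younger), ("older", older)):
        tab = pd.crosstab(sub["sex"], sub["genotype"])
        res = st.chi_square(tab.to_numpy())
        rows.append({"analysis": f"chi2_sex_by_genotype_{grp}",
                     "statistic": res.statistic, "df": res.df, "p": res.p_value})
        variables = ["education", "raven", "mill_hill", "processing_speed"]
        if grp == "older":
            variables.append("mattis")
        for var in variables:
            groups = [g[var].dropna().to_numpy()
                      for _, g in sub.groupby("genotype")]
            a = st.one_way_anova(groups)
            rows.append({"analysis": f"anova_{grp}_{var}", "statistic": a.statistic,
                         "df": f"{a.df[0]:.0f},{a.df[1]:.0f}", "p": a.p_value,
                         "eta_sq": a.effect_size["eta_sq"]})
    return pd.DataFrame(rows)


def analyze(
    composites_young_ref: pd.DataFrame,
    composites_pooled: pd.DataFrame,
    participants: pd.DataFrame,
    *,
    alpha: float = 0.05,
    posthoc_family: str = "all_pairs",
) -> dict[str, pd.DataFrame]:
    """Full statistical battery on one cohort's composite scores.

    Age effects use the younger-reference composites (pooled t, Welch t,
    Mann-Whitney U, η²); the 6-group (age×genotype) mixed repeated-
    measures ANOVA with sphericity diagnostics and Bonferroni cell
    post-hocs uses the pooled-scheme composites; assumption checks
    (Shapiro-Wilk per composite, Levene across the 6 groups) accompany
    them.
    """
    part = participants.copy()
    part["participant_id"] = part["participant_id"].astype(str)
    part = part.set_index("participant_id")

    cy = composites_young_ref.copy()
    cy["participant_id"] = cy["participant_id"].astype(str)
    cy = cy.set_index("participant_id")
    cy["age_group"] = part.loc[cy.index, "age_group"]

    age_rows = []
    for name in COMPOSITE_NAMES:
        y = cy.loc[cy["age_group"] == "younger", name].to_numpy()
        o = cy.loc[cy["age_group"] == "older", name].to_numpy()
        t_res = st.pooled_t(y, o)
        w_res = st.welch_t(y, o)
        u_res = st.mann_whitney_u(y, o)
        age_rows.append({
            "composite": name,
            "older_mean": o.mean(), "older_sd": o.std(ddof=1),
            "t": t_res.statistic, "t_df": t_res.df, "t_p": t_res.p_value,
            "eta_sq": t_res.effect_size["eta_sq"],
            "welch_t": w_res.statistic, "welch_df": w_res.df, "welch_p": w_res.p_value,
            "mann_whitney_u": u_res.statistic, "mann_whitney_p": u_res.p_value,
        })
    age_effects = pd.DataFrame(age_rows)

    cp = composites_pooled.copy()
    cp["participant_id"] = cp["participant_id"].astype(str)
    cp = cp.set_index("participant_id")
    group6 = (part.loc[cp.index, "age_group"].str[:1].str.upper()
              + "-" + part.loc[cp.index, "genotype"])
    wide = cp[list(COMPOSITE_NAMES)]
    fit = st.mixed_rm_anova(wide, group6)
    rm_table = fit.table.reset_index()
    rm_table["mauchly_w"] = fit.mauchly.statistic
    rm_table["mauchly_p"] = fit.mauchly.p_value
    rm_table["epsilon_gg"] = fit.epsilon_gg
    rm_table["epsilon_hf"] = fit.epsilon_hf
    posthoc = st.bonferroni_posthoc(fit, family=posthoc_family)

    assume_rows = []
    for name in COMPOSITE_NAMES:
        sw = st.shapiro_wilk(cp[name])
        groups = [g[name].to_numpy() for _, g in cp.groupby(group6)]
        lev = st.levene(groups)
        assume_rows.append({
            "composite": name,
            "shapiro_w": sw.statistic, "shapiro_p": sw.p_value,
            "levene_f": lev.statistic,
            "levene_df": f"{lev.df[0]:.0f},{lev.df[1]:.0f}",
            "levene_p": lev.p_value,
        })
    assumptions = pd.DataFrame(assume_rows)
    demographics = demographics_stats(participants)
    return {
        "age_effects": age_effects,
        "rm_anova": rm_table,
        "posthoc": posthoc,
        "assumptions": assumptions,
        "demographics": demographics,
    }


def _report_md(results: dict[str, pd.DataFrame], alpha: float) -> str:
    age = results["age_effects"]
    rm = results["rm_anova"].set_index("effect")
    lines = [
        "# Cohort analysis report", "",
        "## Age effects (younger-reference composites)", "",
    ]
    for _, r in age.iterrows():
        lines.append(
            f"- {r['composite']}: older mean {r['older_mean']:.2f} "
            f"(SD {r['older_sd']:.2f}); t({r['t_df']:.0f}) = {r['t']:.2f}, "
            f"p = {r['t_p']:.3g}, eta^2 = {r['eta_sq']:.2f}"
        )
    lines += ["", "## 6-group mixed repeated-measures ANOVA (pooled composites)", ""]
    for eff in rm.index:
        r = rm.loc[eff]
        lines.append(
            f"- {eff}: F({r['df1']:.0f},{r['df2']:.0f}) = {r['F']:.2f}, "
            f"p = {r['p']:.3g} (GG p = {r['p_gg']:.3g}), "
            f"partial eta^2 = {r['partial_eta_sq']:.3f}"
        )
    lines.append("")
    lines.append(
        f"- Mauchly W = {rm['mauchly_w'].iloc[0]:.3f} (p = {rm['mauchly_p'].iloc[0]:.3g}); "
        f"epsilon GG = {rm['epsilon_gg'].iloc[0]:.3f}, HF = {rm['epsilon_hf'].iloc[0]:.3f}"
    )
    sig = results["posthoc"].query("p_bonferroni < @alpha")
    lines += ["", f"## Bonferroni post-hocs significant at alpha = {alpha}", ""]
    if sig.empty:
        lines.append("- none")
    else:
        for _, r in sig.iterrows():
            lines.append(f"- {r['cell_a']} vs {r['cell_b']}: "
                         f"diff = {r['mean_diff']:.2f}, p = {r['p_bonferroni']:.3f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def run_all(
    out_dir: Path,
    *,
    seed: int = 0,
    config: sim.CohortConfig | None = None,
    scheme: str = "younger_reference",
    shifting_wcst: str = "corrected",
    alpha: float = 0.05,
    posthoc_family: str = "all_pairs",
) -> Path:
    """Simulate a cohort and run every stage, writing versioned outputs.

    Writes participants/raw_tasks/sequences/rng_indices/measures CSVs,
    composites under both schemes, the analysis tables, a markdown report
    and a manifest. Deterministic for a fixed seed and config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or sim.CohortConfig()
    manifest: dict = {"seed": seed, "scheme": scheme, "alpha": alpha, "stages": []}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except PipelineError:
            raise
        except Exception as exc:  # annotate with the failing stage
            raise PipelineError(name, str(exc)) from exc
        dt = time.perf_counter() - t0
        log.info("stage %-12s done in %.2fs", name, dt)
        manifest["stages"].append({"name": name, "seconds": round(dt, 3)})
        return result

    cohort = stage("simulate", lambda: sim.generate_cohort(config, seed))
    cohort.participants.to_csv(out_dir / "participants.csv", index=False)
    cohort.raw_tasks.to_csv(out_dir / "raw_tasks.csv", index=False)
    cohort.sequences.to_csv(out_dir / "sequences.csv", index=False)
    (out_dir / "truth.json").write_text(json.dumps(cohort.truth, indent=2))

    seqs = read_sequences_csv(out_dir / "sequences.csv", alphabet=config.alphabet)
    indices = stage("score-rng", lambda: score_sequences(seqs))
    indices.to_csv(out_dir / "rng_indices.csv", index=False)

    younger_ids = cohort.participants.loc[
        cohort.participants["age_group"] == "younger", "participant_id"]

    def measures_for(ref_ids):
        return assemble_measures(cohort.raw_tasks, indices, rng_reference_ids=ref_ids)

    measures = stage("score-tasks", lambda: measures_for(
        younger_ids if scheme == "younger_reference" else None))
    measures.to_csv(out_dir / "measures.csv", index=False)

    comp_young = stage("composites", lambda: comp.build_composites(
        measures_for(younger_ids), cohort.participants,
        "younger_reference", shifting_wcst=shifting_wcst))
    comp_pooled = comp.build_composites(
        measures_for(None), cohort.participants, "pooled",
        shifting_wcst=shifting_wcst)
    pd.concat([comp_young, comp_pooled]).to_csv(out_dir / "composites.csv", index=False)

    results = stage("analyze", lambda: analyze(
        comp_young, comp_pooled, cohort.participants,
        alpha=alpha, posthoc_family=posthoc_family))
    results_dir = out_dir / "results"
    results_dir.mkdir(exist_ok=True)
    for name, df in results.items():
        df.to_csv(results_dir / f"{name}.csv", index=False)
    (results_dir / "report.md").write_text(_report_md(results, alpha))

    for f in sorted(out_dir.glob("*.csv")):
        manifest.setdefault("hashes", {})[f.name] = _sha256(f)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


# ---------------------------------------------------------------------------
# reference-statistics verification
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("exefun.data") / name


def verify_reference(
    summary_csv: Path | None = None,
    counts_csv: Path | None = None,
) -> pd.DataFrame:
    """Recompute the published group statistics from the packaged fixtures.

    Each row is one check: the quantity recomputed by this package from
    the summary tables, the published value, the tolerance and pass/fail.
    """
    if summary_csv is None:
        summary = pd.read_csv(_fixture_path("reference_group_summary.csv"))
    else:
        summary = pd.read_csv(_require(summary_csv, "verify-reference"))
    if counts_csv is None:
        counts = pd.read_csv(_fixture_path("reference_sex_by_genotype.csv"))
    else:
        counts = pd.read_csv(_require(counts_csv, "verify-reference"))
    if summary.empty or counts.empty:
        raise PipelineError("verify-reference", "empty fixture file")
    checks = json.loads(_fixture_path("reference_checks.json").read_text())
    tol = checks["tolerances"]

    rows = []

    def add(name, computed, expected, tolerance):
        rows.append({
            "check": name, "computed": computed, "expected": expected,
            "tolerance": tolerance, "passed": abs(computed - expected) <= tolerance,
        })

    for _, r in summary.iterrows():
        a = st.GroupSummary("younger", int(r["n_younger"]),
                            r["younger_mean"], r["younger_sd"])
        b = st.GroupSummary("older", int(r["n_older"]),
                            r["older_mean"], r["older_sd"])
        res = st.pooled_t(a, b)
        add(f"t_{r['variable']}", res.statistic, r["published_t"], tol["t"])

    for grp in ("younger", "older"):
        sub = counts[counts["age_group"] == grp]
        table = sub[["n_male", "n_female"]].to_numpy()
        res = st.chi_square(table)
        add(f"chi2_sex_genotype_{grp}", res.statistic,
            checks["chi_square_sex_by_genotype"][grp], tol["chi2"])
        add(f"chi2_p_sex_genotype_{grp}", res.p_value,
            checks["chi_square_p"][grp], tol["chi2_p"])

    for t_val, df, expected in checks["eta_sq_from_t"]:
        add(f"eta_sq_t{t_val}", st.eta_sq_from_t(t_val, df), expected, tol["eta_sq"])
    f_chk = checks["f_from_eta"]
    add("f_from_eta", st.cohens_f_from_eta(f_chk["eta_sq"]), f_chk["f"], tol["f"])
    d_chk = checks["d_from_f"]
    add("d_from_f", st.d_from_f(d_chk["f"]), d_chk["d"], tol["d"])
    return pd.DataFrame(rows)
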
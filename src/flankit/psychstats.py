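"""Cohort-level statistics: paired tests, correlations, mixed ANOVA, chi-square.

Conventions used throughout (matching standard practice for small
within-subject designs):

* paired t-test: ``t = M_diff / (SD_diff / sqrt(n))`` with ``df = n - 1``;
  the 95% CI is ``M +/- t_crit(df) * SE`` from the exact t distribution.
* paired Cohen's d: ``d = M_diff / SD_diff``, equivalently ``t / sqrt(n)``.
  (The pooled-SD variant is deliberately not offered.)
* Pearson r CI: Fisher z transform with standard error ``1 / sqrt(n - 3)``;
  p-value from ``t = r * sqrt((n - 2) / (1 - r^2))``.
* 2x2 mixed ANOVA: classical split-plot sums-of-squares with one
  between-subject factor and one within-subject factor;
  ``partial eta^2 = SS_effect / (SS_effect + SS_error_for_that_effect)``.
* chi-square of independence: Pearson statistic, no continuity correction.

All tests are two-sided at alpha = 0.05.  No multiple-testing correction is
applied; the study report states how many tests were run.  Values are kept
at full precision internally and rounded (half-up, 2 decimals) only when a
report is rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enums import Preference

__all__ = [
    "PairedTestResult",
    "CorrelationResult",
    "AnovaEffect",
    "AnovaResult",
    "ChiSquareResult",
    "paired_test",
    "paired_from_summary",
    "pearson_with_ci",
    "mixed_anova_2x2",
    "chi_square_independence",
    "run_study_analysis",
    "StudyReport",
    "round2",
]


def round2(x: float) -> float:
    """Report-time rounding: half-up to 2 decimals."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PairedTestResult:
    """Paired-sample t-test summary (sign convention: mean of x - y)."""

    mean_diff: float
    sd_diff: float
    se: float
    df: int
    t: float
    ci95: tuple[float, float]
    cohens_d: float
    p: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci95: tuple[float, float]
    p: float


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    """Split-plot ANOVA: between-factor, within-factor, and interaction effects."""

    between: AnovaEffect
    within: AnovaEffect
    interaction: AnovaEffect


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    observed: pd.DataFrame
    expected: pd.DataFrame


def paired_from_summary(mean_diff: float, sd_diff: float, n: int) -> PairedTestResult:
    """Paired t-test from the summary statistics of the differences.

    Lets any printed (M, SD, n) triple be turned back into the full test.
    """
    if n < 2:
        raise ValueError("paired test needs n >= 2")
    if sd_diff <= 0:
        raise ValueError("sd_diff must be positive")
    se = sd_diff / math.sqrt(n)
    df = n - 1
    t = mean_diff / se
    tcrit = stats.t.ppf(0.975, df)
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedTestResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        se=se,
        df=df,
        t=t,
        ci95=(mean_diff - tcrit * se, mean_diff + tcrit * se),
        cohens_d=mean_diff / sd_diff,
        p=p,
        n=n,
    )


def paired_test(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test of mean(x - y) against zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equal length")
    if len(x) < 2:
        raise ValueError("paired test needs n >= 2")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing pairs are not allowed")
    d = x - y
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        # identical pairs: a degenerate but well-defined result
        m = float(d.mean())
        if m != 0.0:
            raise ValueError("zero variance with nonzero mean difference")
        return PairedTestResult(
            mean_diff=0.0, sd_diff=0.0, se=0.0, df=len(d) - 1, t=0.0,
            ci95=(0.0, 0.0), cohens_d=0.0, p=1.0, n=len(d),
        )
    return paired_from_summary(float(d.mean()), sd, len(d))


def pearson_with_ci(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with Fisher-z 95% CI and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equal length")
    n = len(x)
    if n < 4:
        raise ValueError("correlation CI needs n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance in input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < 1e-12:  # snap exactly collinear inputs
        r = math.copysign(1.0, r)
    if abs(r) == 1.0:
        return CorrelationResult(r=r, n=n, ci95=(r, r), p=0.0)
    z = math.atanh(r)
    zse = 1.0 / math.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.975)
    ci = (math.tanh(z - zcrit * zse), math.tanh(z + zcrit * zse))
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return CorrelationResult(r=r, n=n, ci95=ci, p=p)


def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
) -> AnovaResult:
    """Split-plot ANOVA: one between-subject and one within-subject factor.

    ``data`` is long-format with one row per subject x within-level.  Every
    subject must have exactly one row per within-level and a constant
    between-group label; otherwise the design is unbalanced and an error is
    raised.
    """
    df = data[[subject, within, between, dv]].copy()
    if df[dv].isna().any():
        raise ValueError("missing dv values")
    w_levels = sorted(df[within].unique())
    b = len(w_levels)
    counts = df.groupby(subject)[within].agg(["count", "nunique"])
    if not ((counts["count"] == b) & (counts["nunique"] == b)).all():
        raise ValueError("every subject needs exactly one row per within-level")
    g_per_subj = df.groupby(subject)[between].nunique()
    if (g_per_subj != 1).any():
        raise ValueError("between-group label must be constant within subject")

    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = df.groupby(subject)[dv].mean()
    subj_group = df.groupby(subject)[between].first()
    groups = sorted(subj_group.unique())
    a = len(groups)
    if a < 2:
        raise ValueError("between factor needs at least two levels")
    n_subj = len(subj_means)

    ss_between_subj = float(b * ((subj_means - grand) ** 2).sum())
    group_means = subj_means.groupby(subj_group).mean()
    n_g = subj_means.groupby(subj_group).size()
    ss_a = float(b * (n_g * (group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_a

    w_means = df.groupby(within)[dv].mean()
    ss_b = float(n_subj * ((w_means - grand) ** 2).sum())
    cell = df.groupby([between, within])[dv].mean()
    ss_cells = 0.0
    for g in groups:
        for w in w_levels:
            ss_cells += n_g[g] * (cell[(g, w)] - grand) ** 2
    ss_ab = float(ss_cells - ss_a - ss_b)
    ss_err_within = ss_total - ss_between_subj - ss_b - ss_ab

    df_a, df_sw = a - 1, n_subj - a
    df_b, df_ab = b - 1, (a - 1) * (b - 1)
    df_ew = (n_subj - a) * (b - 1)

    def _effect(ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> AnovaEffect:
        if df_err <= 0 or ss_err < 0:
            raise ValueError("insufficient error degrees of freedom")
        ms_eff, ms_err = ss_eff / df_eff, ss_err / df_err
        if ms_err > 0:
            F = ms_eff / ms_err
        else:
            F = 0.0 if ms_eff <= 1e-300 else math.inf
        p = float(stats.f.sf(F, df_eff, df_err)) if math.isfinite(F) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return AnovaEffect(F=float(F), df1=df_eff, df2=df_err, p=p, partial_eta_sq=float(eta))

    return AnovaResult(
        between=_effect(ss_a, df_a, ss_subj_within, df_sw),
        within=_effect(ss_b, df_b, ss_err_within, df_ew),
        interaction=_effect(ss_ab, df_ab, ss_err_within, df_ew),
    )


def chi_square_independence(observed: pd.DataFrame | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table."""
    obs_df = pd.DataFrame(observed)
    obs = obs_df.to_numpy(dtype=float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table needs at least 2 rows and 2 columns")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("observed counts must be non-negative integers")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column total")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(
        chi2=float(chi2),
        df=int(dof),
        p=float(p),
        observed=obs_df,
        expected=pd.DataFrame(expected, index=obs_df.index, columns=obs_df.columns),
    )


# ---------------------------------------------------------------------------
# Full study analysis
# ---------------------------------------------------------------------------

_CROSS_CONDITION_METRICS = [
    "acc_incongruent",
    "acc_congruent",
    "acc_overall",
    "rt_incongruent_ms",
    "conflict_rt_ms",
    "conflict_acc",
]

_COVARIATE_METRICS = ["acc_incongruent", "rt_incongruent_ms"]


@dataclass
class StudyReport:
    """Every statistic of the full analysis battery, at full precision."""

    n_children: int
    paired: dict[str, PairedTestResult] = field(default_factory=dict)
    correlations: dict[str, CorrelationResult] = field(default_factory=dict)
    enjoyment_anova: Optional[AnovaResult] = None
    enjoyment_means: dict[str, tuple[float, float]] = field(default_factory=dict)
    preference_chi2: Optional[ChiSquareResult] = None
    preference_shares: dict[str, float] = field(default_factory=dict)
    n_tests_run: int = 0

    def to_markdown(self) -> str:
        lines = [
            "# Study analysis report",
            "",
            f"Children analyzed: {self.n_children}. "
            f"Statistical tests run: {self.n_tests_run} (no multiplicity correction).",
            "",
            "## Paired tests",
            "",
            "| comparison | M diff | SD | SE | t | df | 95% CI | d | p |",
            "|---|---|---|---|---|---|---|---|---|",
        ]
        for name, r in self.paired.items():
            lines.append(
                f"| {name} | {round2(r.mean_diff)} | {round2(r.sd_diff)} | {round2(r.se)} "
                f"| {round2(r.t)} | {r.df} | [{round2(r.ci95[0])}, {round2(r.ci95[1])}] "
                f"| {round2(r.cohens_d)} | {r.p:.3g} |"
            )
        lines += ["", "## Correlations", "", "| pair | r | n | 95% CI | p |", "|---|---|---|---|---|"]
        for name, c in self.correlations.items():
            lines.append(
                f"| {name} | {round2(c.r)} | {c.n} | [{round2(c.ci95[0])}, {round2(c.ci95[1])}] | {c.p:.3g} |"
            )
        if self.enjoyment_anova is not None:
            a = self.enjoyment_anova
            lines += [
                "",
                "## Enjoyment (mixed ANOVA: order between, condition within)",
                "",
                "| effect | F | df | p | partial eta^2 |",
                "|---|---|---|---|---|",
                f"| condition | {round2(a.within.F)} | ({a.within.df1}, {a.within.df2}) | {a.within.p:.3g} | {round2(a.within.partial_eta_sq)} |",
                f"| order | {round2(a.between.F)} | ({a.between.df1}, {a.between.df2}) | {a.between.p:.3g} | {round2(a.between.partial_eta_sq)} |",
                f"| interaction | {round2(a.interaction.F)} | ({a.interaction.df1}, {a.interaction.df2}) | {a.interaction.p:.3g} | {round2(a.interaction.partial_eta_sq)} |",
            ]
            for cond, (m, sd) in self.enjoyment_means.items():
                lines.append(f"- {cond}: M = {round2(m)}, SD = {round2(sd)}")
        if self.preference_shares:
            lines += ["", "## Preference"]
            for k, v in self.preference_shares.items():
                lines.append(f"- {k}: {round2(100 * v)}%")
        if self.preference_chi2 is not None:
            c = self.preference_chi2
            lines.append(
                f"- choice x order: chi2({c.df}) = {round2(c.chi2)}, p = {c.p:.3g}"
            )
        return "\n".join(lines) + "\n"


def _pivot_metric(metrics: pd.DataFrame, metric: str) -> pd.DataFrame:
    wide = metrics.pivot(index="child_id", columns="condition", values=metric)
    return wide.dropna()


def run_study_analysis(
    metrics: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    preference: Optional[pd.Series] = None,
) -> StudyReport:
    """Run the full analysis battery on a two-condition metrics table.

    ``metrics`` is the per-session table from
    :func:`flankit.scoring.metrics_frame` (both conditions per child).
    ``covariates`` optionally maps child_id to verbal_score / matrix_score.
    ``preference`` optionally maps child_id to a
    :class:`~flankit.enums.Preference` value; if absent it is derived from
    the per-session ``preferred`` flags.
    """
    conds = set(metrics["condition"].unique())
    if conds != {"TRADITIONAL", "GAMIFIED"}:
        raise ValueError("metrics must contain both conditions")
    both = metrics.groupby("child_id")["condition"].nunique()
    children = both[both == 2].index
    if len(children) < 2:
        raise ValueError("need at least 2 children with both conditions")
    metrics = metrics[metrics["child_id"].isin(children)]

    report = StudyReport(n_children=len(children))

    def _step(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"study analysis step '{name}' failed: {exc}") from exc

        return _Ctx()

    # Congruency paired tests within each condition
    for cond in ("GAMIFIED", "TRADITIONAL"):
        sub = metrics[metrics["condition"] == cond].set_index("child_id")
        with _step(f"{cond} accuracy conflict t-test"):
            report.paired[f"{cond}: congruent vs incongruent accuracy"] = paired_test(
                sub["acc_congruent"], sub["acc_incongruent"]
            )
        with _step(f"{cond} RT conflict t-test"):
            rt = sub[["rt_congruent_ms", "rt_incongruent_ms"]].dropna()
            report.paired[f"{cond}: incongruent vs congruent RT"] = paired_test(
                rt["rt_incongruent_ms"], rt["rt_congruent_ms"]
            )

    # Cross-condition comparisons of the conflict scores and incongruent accuracy
    with _step("cross-condition paired tests"):
        for metric, label in (
            ("conflict_acc", "conflict accuracy: gamified vs traditional"),
            ("conflict_rt_ms", "conflict RT: gamified vs traditional"),
            ("acc_incongruent", "incongruent accuracy: gamified vs traditional"),
        ):
            wide = _pivot_metric(metrics, metric)
            report.paired[label] = paired_test(wide["GAMIFIED"], wide["TRADITIONAL"])

    # Cross-condition correlations
    with _step("cross-condition correlations"):
        for metric in _CROSS_CONDITION_METRICS:
            wide = _pivot_metric(metrics, metric)
            report.correlations[f"{metric}: gamified vs traditional"] = pearson_with_ci(
                wide["GAMIFIED"], wide["TRADITIONAL"]
            )

    # Covariate correlations
    if covariates is not None:
        cov = covariates.set_index("child_id") if "child_id" in covariates.columns else covariates
        with _step("covariate correlations"):
            for cond in ("GAMIFIED", "TRADITIONAL"):
                sub = metrics[metrics["condition"] == cond].set_index("child_id")
                sub = sub.drop(
                    columns=[c for c in ("verbal_score", "matrix_score") if c in sub.columns]
                )
                joined = sub.join(cov[["verbal_score", "matrix_score"]], how="inner")
                for metric in _COVARIATE_METRICS:
                    for cov_name in ("verbal_score", "matrix_score"):
                        pair = joined[[metric, cov_name]].dropna()
                        report.correlations[f"{cond}: {metric} vs {cov_name}"] = pearson_with_ci(
                            pair[metric], pair[cov_name]
                        )

    # Enjoyment: mixed ANOVA with order between and condition within
    if metrics["enjoyment"].notna().all() and metrics["order_position"].notna().all():
        with _step("enjoyment mixed ANOVA"):
            enjoy = metrics[["child_id", "condition", "order_position", "enjoyment"]].copy()
            first = enjoy[enjoy["order_position"] == "FIRST"].set_index("child_id")["condition"]
            enjoy["order_group"] = enjoy["child_id"].map(first)
            report.enjoyment_anova = mixed_anova_2x2(
                enjoy, dv="enjoyment", within="condition", between="order_group", subject="child_id"
            )
            for cond in ("GAMIFIED", "TRADITIONAL"):
                vals = enjoy.loc[enjoy["condition"] == cond, "enjoyment"].astype(float)
                report.enjoyment_means[cond] = (float(vals.mean()), float(vals.std(ddof=1)))

    # Preference shares and choice x order chi-square
    with _step("preference analysis"):
        if preference is None:
            preference = _derive_preference(metrics)
        if preference is not None:
            shares = preference.value_counts(normalize=True)
            report.preference_shares = {
                p.value: float(shares.get(p.value, 0.0)) for p in Preference
            }
            first = (
                metrics[metrics["order_position"] == "FIRST"]
                .set_index("child_id")["condition"]
                .reindex(preference.index)
            )
            table = pd.crosstab(preference, first)
            if table.shape[0] >= 2 and table.shape[1] >= 2:
                try:
                    report.preference_chi2 = chi_square_independence(table)
                except ValueError:
                    report.preference_chi2 = None

    report.n_tests_run = (
        len(report.paired)
        + len(report.correlations)
        + (3 if report.enjoyment_anova is not None else 0)
        + (1 if report.preference_chi2 is not None else 0)
    )
    return report


def _derive_preference(metrics: pd.DataFrame) -> Optional[pd.Series]:
    """Turn per-session ``preferred`` flags into one GA/FLANKER/NONE choice per child."""
    if metrics["preferred"].isna().all():
        return None
    out = {}
    for child, sub in metrics.groupby("child_id"):
        chosen = sub[sub["preferred"] == True]  # noqa: E712
        if len(chosen) == 0:
            out[child] = Preference.NONE.value
        else:
            cond = chosen["condition"].iloc[0]
            out[child] = Preference.GA.value if cond == "GAMIFIED" else Preference.FLANKER.value
    return pd.Series(out, name="preference")
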
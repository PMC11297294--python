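"""Statistical layer: Student's t, Pearson correlation, post-hoc power, report.

Comparisons between safe and unsafe AI conditions use the independent
two-sample Student's t-test with pooled variance (Welch available as an
option), two-sided throughout.  Post-hoc power for a two-sided two-sample
t-test comes from the noncentral t distribution with noncentrality
d * sqrt(n1 n2 / (n1 + n2)).  No multiple-testing adjustment is applied
anywhere; the report footer states this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from clingaze.io import AI_ROIS, CONVENTIONAL_ROIS, MAJOR_ROIS, XAI_ROIS, RATING_COLUMNS

_XAI_RATING = {
    "xai_qdiff": "rating_qdiff",
    "xai_mortality": "rating_mortality",
    "xai_features": "rating_features",
    "xai_examples": "rating_examples",
}


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    df: float
    p_value: float
    n1: int
    n2: int
    mean_1: float
    mean_2: float
    ci95_1: tuple[float, float]
    ci95_2: tuple[float, float]
    pooled_sd: float
    cohens_d: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    note: str = ""


@dataclass(frozen=True)
class PowerResult:
    effect_size_d: float
    n1: int
    n2: int
    alpha: float
    power: float


def _group_ci95(vals: np.ndarray) -> tuple[float, float]:
    n = len(vals)
    m = float(np.mean(vals))
    se = float(np.std(vals, ddof=1)) / np.sqrt(n)
    tcrit = float(sps.t.ppf(0.975, n - 1))
    return (m - tcrit * se, m + tcrit * se)


def students_t_independent(
    group_1, group_2, welch: bool = False,
) -> TTestResult:
    """Independent two-sample t-test (pooled-variance Student's by default).

    Each group's 95% CI uses its own standard error and t critical value.
    Degenerate zero-variance data: equal means give t = 0, p = 1; unequal
    means raise (no finite t exists).
    """
    g1 = np.asarray(group_1, dtype=float)
    g2 = np.asarray(group_2, dtype=float)
    g1 = g1[~np.isnan(g1)]
    g2 = g2[~np.isnan(g2)]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 finite observations")
    m1, m2 = float(np.mean(g1)), float(np.mean(g2))
    v1, v2 = float(np.var(g1, ddof=1)), float(np.var(g2, ddof=1))

    if welch:
        se = np.sqrt(v1 / n1 + v2 / n2)
        dof = se**4 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        pooled_var = (v1 + v2) / 2.0
    else:
        dof = float(n1 + n2 - 2)
        pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / dof
        se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))

    pooled_sd = float(np.sqrt(pooled_var))
    if se == 0.0:
        if m1 == m2:
            t_stat, p = 0.0, 1.0
        else:
            raise ValueError("zero pooled variance with unequal means: t undefined")
    else:
        t_stat = (m1 - m2) / se
        p = 2.0 * float(sps.t.sf(abs(t_stat), dof))
    d = (m1 - m2) / pooled_sd if pooled_sd > 0 else 0.0
    return TTestResult(
        float(t_stat), float(dof), float(p), n1, n2, m1, m2,
        _group_ci95(g1), _group_ci95(g2), pooled_sd, float(d),
    )


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided p from
    t = r sqrt((n-2)/(1-r^2)).  Pairs with missing values are dropped;
    constant input yields an undefined result with a QC note."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return CorrelationResult(float("nan"), n, float("nan"), "fewer than 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), n, float("nan"), "constant input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), n, float(p))


def spearman_correlation(x, y) -> CorrelationResult:
    """Rank-based alternative to :func:`pearson_correlation`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return CorrelationResult(float("nan"), n, float("nan"), "fewer than 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), n, float("nan"), "constant input")
    r, p = sps.spearmanr(x, y)
    return CorrelationResult(float(r), n, float(p))


def posthoc_power_t(
    d: float, n1: int, n2: int, alpha: float = 0.05,
) -> PowerResult:
    """Power of the two-sided two-sample t-test for effect size d (Cohen).

    Noncentrality is d * sqrt(n1 n2 / (n1 + n2)); the rejection probability
    comes from the noncentral t distribution on n1 + n2 - 2 df.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    dof = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, dof)
    power = float(sps.nct.sf(tcrit, dof, nc) + sps.nct.cdf(-tcrit, dof, nc))
    return PowerResult(float(d), n1, n2, float(alpha), power)


# --------------------------------------------------------------------------- #
# Headline report


@dataclass
class Report:
    """Deterministic bundle of the headline comparison tables."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary_md: str = ""

    def write(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tbl in self.tables.items():
            tbl.to_csv(out / f"report_{name}.csv", index=False)
        (out / "report_summary.md").write_text(self.summary_md, encoding="utf-8")


def _ttest_row(label: str, g1, g2, extra: dict | None = None) -> dict:
    """One comparison row; not-computable arms are reported, never dropped."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    g1 = g1[~np.isnan(g1)]
    g2 = g2[~np.isnan(g2)]
    row = {"comparison": label, "n_1": len(g1), "n_2": len(g2)}
    if extra:
        row.update(extra)
    if len(g1) < 2 or len(g2) < 2:
        row.update(computable=False, t=np.nan, df=np.nan, p=np.nan,
                   mean_1=np.nan, mean_2=np.nan,
                   ci95_lo_1=np.nan, ci95_hi_1=np.nan,
                   ci95_lo_2=np.nan, ci95_hi_2=np.nan, cohens_d=np.nan)
        return row
    try:
        res = students_t_independent(g1, g2)
    except ValueError:
        row.update(computable=False, t=np.nan, df=np.nan, p=np.nan,
                   mean_1=float(np.mean(g1)), mean_2=float(np.mean(g2)),
                   ci95_lo_1=np.nan, ci95_hi_1=np.nan,
                   ci95_lo_2=np.nan, ci95_hi_2=np.nan, cohens_d=np.nan)
        return row
    row.update(
        computable=True, t=res.t_statistic, df=res.df, p=res.p_value,
        mean_1=res.mean_1, mean_2=res.mean_2,
        ci95_lo_1=res.ci95_1[0], ci95_hi_1=res.ci95_1[1],
        ci95_lo_2=res.ci95_2[0], ci95_hi_2=res.ci95_2[1],
        cohens_d=res.cohens_d,
    )
    return row


def _corr_row(label: str, x, y, extra: dict | None = None) -> dict:
    res = pearson_correlation(x, y)
    row = {"comparison": label, "r": res.r, "n": res.n, "p": res.p_value,
           "note": res.note}
    if extra:
        row.update(extra)
    return row


def headline_report(
    attention: pd.DataFrame,
    behaviour: pd.DataFrame,
    trials: pd.DataFrame,
    alpha: float = 0.05,
    participant_level: bool = False,
) -> Report:
    """Assemble the safe-vs-unsafe comparisons and correlation screens.

    Tables (group 1 = unsafe, group 2 = safe for condition contrasts):

    * ``safe_unsafe_fixations`` — AI-screen (and per-explanation-panel)
      fixation counts, unsafe vs safe, with post-hoc power at the observed
      effect size for the panel comparisons.
    * ``blink_conventional_vs_ai`` — per-trial per-ROI blink rates pooled
      over conventional clinical surfaces vs AI surfaces.
    * ``per_roi_metrics`` — mean fixation duration, blink rate, gaze
      proportions and actual/chance ratio per ROI.
    * ``chance_gaze`` — actual vs chance gaze proportion per major and
      explanation ROI.
    * ``correlations`` — eye-tracking metrics vs practice variation and vs
      influence of AI (by drug and condition), and explanation-panel
      fixations vs self-reported usefulness.

    Trial-level rows pool trials across participants; with
    ``participant_level=True`` condition contrasts instead use participant
    means per condition (one value per participant per arm), which respects
    independence at the cost of power.  Generation is deterministic: no RNG.
    """
    att = attention.copy()

    def condition_groups(df: pd.DataFrame, value: str):
        if participant_level:
            agg = (df.groupby(["participant_id", "condition"])[value]
                     .mean().reset_index())
        else:
            agg = df
        uns = agg.loc[agg["condition"] == "unsafe", value]
        saf = agg.loc[agg["condition"] == "safe", value]
        return uns.to_numpy(float), saf.to_numpy(float)

    # (1) + (2): AI-screen and per-panel fixation counts, unsafe vs safe
    fix_rows = []
    ai = att[att["roi_id"] == "ai_screen"]
    uns, saf = condition_groups(ai, "n_fixations")
    fix_rows.append(_ttest_row("ai_screen fixations: unsafe vs safe", uns, saf,
                               {"roi_id": "ai_screen", "posthoc_power": np.nan}))
    for roi in XAI_ROIS:
        sub = att[att["roi_id"] == roi]
        uns, saf = condition_groups(sub, "n_fixations")
        row = _ttest_row(f"{roi} fixations: unsafe vs safe", uns, saf,
                         {"roi_id": roi})
        if row["computable"]:
            row["posthoc_power"] = posthoc_power_t(
                abs(row["cohens_d"]), row["n_1"], row["n_2"], alpha).power
        else:
            row["posthoc_power"] = np.nan
        fix_rows.append(row)
    fixations_tbl = pd.DataFrame(fix_rows)

    # (3): blink rate on conventional clinical vs AI surfaces
    conv = att[att["roi_id"].isin(CONVENTIONAL_ROIS)]["blink_rate_bpm"]
    aib = att[att["roi_id"].isin(AI_ROIS)]["blink_rate_bpm"]
    blink_tbl = pd.DataFrame([
        _ttest_row("blink rate: conventional ROIs vs AI ROIs",
                   conv.to_numpy(float), aib.to_numpy(float)),
    ])

    # (4): per-ROI descriptive metrics
    per_roi = (att.groupby("roi_id")
               .agg(n_trials=("roi_id", "size"),
                    mean_fixation_duration_ms=("mean_fixation_duration_ms", "mean"),
                    sd_fixation_duration_ms=("mean_fixation_duration_ms", "std"),
                    mean_blink_rate_bpm=("blink_rate_bpm", "mean"),
                    sd_blink_rate_bpm=("blink_rate_bpm", "std"),
                    mean_actual_gaze_proportion=("actual_gaze_proportion", "mean"),
                    mean_chance_gaze_proportion=("chance_gaze_proportion", "mean"),
                    mean_fixations=("n_fixations", "mean"))
               .reset_index())
    # (5): ratio of mean actual to mean chance gaze + actual-vs-chance t-test
    chance_rows = []
    for roi in [*MAJOR_ROIS, *XAI_ROIS]:
        sub = att[att["roi_id"] == roi]
        actual = sub["actual_gaze_proportion"].to_numpy(float)
        chance = sub["chance_gaze_proportion"].to_numpy(float)
        row = _ttest_row(f"{roi}: actual vs chance gaze proportion",
                         actual, chance, {"roi_id": roi})
        mc = np.nanmean(chance) if len(chance) else np.nan
        row["actual_to_chance_ratio"] = (
            np.nanmean(actual) / mc if mc and mc > 0 else np.nan)
        chance_rows.append(row)
    chance_tbl = pd.DataFrame(chance_rows)

    # (6): correlation screens
    corr_rows = []
    wide = behaviour.merge(
        att[att["roi_id"] == "ai_screen"]
        [["participant_id", "scenario_id", "n_fixations", "blink_rate_bpm"]],
        on=["participant_id", "scenario_id"], how="left",
    )
    for drug in sorted(wide["drug"].unique()):
        sub = wide[wide["drug"] == drug]
        for metric in ("blink_rate_bpm", "n_fixations"):
            corr_rows.append(_corr_row(
                f"{metric} vs practice variation ({drug})",
                sub[metric], sub["practice_variation"],
                {"drug": drug, "condition": "all"}))
        for cond in ("safe", "unsafe"):
            sc = sub[(sub["condition"] == cond) & sub["influence_defined"]]
            for metric in ("blink_rate_bpm", "n_fixations"):
                corr_rows.append(_corr_row(
                    f"{metric} vs influence of AI ({drug}, {cond})",
                    sc[metric], sc["influence_clamped"],
                    {"drug": drug, "condition": cond}))
    # explanation-panel fixations vs self-reported usefulness
    ratings = trials[["participant_id", "scenario_id"] + RATING_COLUMNS] \
        .drop_duplicates(["participant_id", "scenario_id"])
    for roi, rating_col in _XAI_RATING.items():
        sub = att[att["roi_id"] == roi].merge(
            ratings, on=["participant_id", "scenario_id"], how="left")
        corr_rows.append(_corr_row(
            f"{roi} fixations vs usefulness rating",
            sub["n_fixations"], sub[rating_col],
            {"drug": "", "condition": "all"}))
    corr_tbl = pd.DataFrame(corr_rows)

    tables = {
        "safe_unsafe_fixations": fixations_tbl,
        "blink_conventional_vs_ai": blink_tbl,
        "per_roi_metrics": per_roi,
        "chance_gaze": chance_tbl,
        "correlations": corr_tbl,
    }
    return Report(tables=tables, summary_md=_summary_md(tables, alpha, participant_level))


def _fmt_p(p: float) -> str:
    if np.isnan(p):
        return "n/a"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _summary_md(tables: dict[str, pd.DataFrame], alpha: float,
                participant_level: bool) -> str:
    lines = ["# Attention and behaviour report", ""]
    level = "participant-mean" if participant_level else "trial"
    lines.append(f"Condition contrasts computed at the {level} level; "
                 f"significance threshold alpha = {alpha}.")
    lines.append("")
    f = tables["safe_unsafe_fixations"].iloc[0]
    if f["computable"]:
        lines.append(
            f"- AI-screen fixations, unsafe vs safe: mean {f['mean_1']:.1f} "
            f"[95% CI {f['ci95_lo_1']:.1f}-{f['ci95_hi_1']:.1f}] vs "
            f"{f['mean_2']:.1f} [{f['ci95_lo_2']:.1f}-{f['ci95_hi_2']:.1f}], "
            f"t({f['df']:.0f}) = {f['t']:.2f}, p = {_fmt_p(f['p'])}.")
    else:
        lines.append("- AI-screen fixations, unsafe vs safe: not computable "
                     f"(n = {f['n_1']} vs {f['n_2']}).")
    b = tables["blink_conventional_vs_ai"].iloc[0]
    if b["computable"]:
        lines.append(
            f"- Blink rate, conventional vs AI surfaces: {b['mean_1']:.1f} vs "
            f"{b['mean_2']:.1f} bpm, p = {_fmt_p(b['p'])}.")
    else:
        lines.append("- Blink rate, conventional vs AI surfaces: not computable.")
    ratios = tables["chance_gaze"]
    pretty = ", ".join(
        f"{r['roi_id']} {r['actual_to_chance_ratio']:.1f}"
        for _, r in ratios.iterrows()
        if np.isfinite(r["actual_to_chance_ratio"]))
    lines.append(f"- Actual/chance gaze ratios: {pretty}.")
    sig = tables["correlations"]
    n_sig = int((sig["p"] < alpha).sum())
    lines.append(f"- Correlation screen: {n_sig} of {len(sig)} correlations "
                 f"below alpha (no adjustment applied).")
    lines.append("")
    lines.append("No multiple-testing adjustment is applied to any p-value "
                 "in this report.")
    return "\n".join(lines) + "\n"
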
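"""Group-level statistics and report tables.

Mirrors the study's analysis plan: a 3-SD outlier screen within condition,
paired t-tests with Cohen's d (paired convention: mean of differences over
SD of differences, identically t / sqrt(n)) for the two-task comparisons,
linear mixed models with participant random intercepts for the
task x effector and task x eccentricity analyses, and Holm-Bonferroni
correction for follow-up comparisons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ComparisonResult:
    """Paired two-condition comparison of one measure."""

    measure_name: str
    t_statistic: float
    df: int
    p_value: float
    cohens_d: float
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    label_a: str = "a"
    label_b: str = "b"


def screen_outliers(
    table: pd.DataFrame, k: float = 3.0, value_col: str = "value"
) -> pd.DataFrame:
    """Flag values outside mean +- k*SD within condition.

    Condition = task x effector x measure (whichever of those columns are
    present). Returns a copy with a boolean ``outlier`` column; flagged rows
    are excluded from downstream tests by the caller.
    """
    cond_cols = [c for c in ("task", "effector", "measure", "bin") if c in table]
    out = table.copy()
    out["outlier"] = False

    def _flag(v: pd.Series) -> pd.Series:
        # leave-one-out mean/SD: an extreme value must not mask itself
        flags = pd.Series(False, index=v.index)
        if len(v) < 3:
            return flags
        for i in v.index:
            rest = v.drop(i)
            sd = rest.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                flags[i] = abs(v[i] - rest.mean()) > 0
            else:
                flags[i] = abs(v[i] - rest.mean()) > k * sd
        return flags

    if cond_cols:
        out["outlier"] = out.groupby(cond_cols, dropna=False)[value_col].transform(
            _flag
        )
    else:
        out["outlier"] = _flag(out[value_col])
    return out


def paired_comparison(
    values_a: np.ndarray,
    values_b: np.ndarray,
    measure_name: str = "",
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Two-sided paired t-test with paired Cohen's d = mean(diff)/SD(diff).

    The effect-size convention satisfies d = t / sqrt(n) exactly.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = a.size
    if n < 3:
        raise ValueError("paired comparison needs n >= 3")
    diff = a - b
    sd_diff = float(np.std(diff, ddof=1))
    if sd_diff == 0:
        raise ValueError("zero variance of paired differences")
    t_stat, p = stats.ttest_rel(a, b)
    d = float(np.mean(diff)) / sd_diff
    return ComparisonResult(
        measure_name=measure_name,
        t_statistic=float(t_stat),
        df=n - 1,
        p_value=float(p),
        cohens_d=d,
        n=n,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        label_a=label_a,
        label_b=label_b,
    )


def holm_bonferroni(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm's step-down multiple-comparison procedure.

    Sort p ascending; reject p_(i) while p_(i) <= alpha / (m - i + 1),
    stopping at the first failure. Returns (reject flags, adjusted
    p-values) in the input order; adjusted p-values are
    max-accumulated so they are monotone in the raw-p order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a 1-D array of at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adj[idx] = running_max
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject, adj


@dataclass
class ModelSummary:
    """Fixed-effect F-tests and random-intercept variance of one LMM."""

    terms: dict  # term -> {"F", "df_num", "df_den", "p"}
    random_intercept_var: float
    n_obs: int
    method: str = "mixed_lm"


def _wald_f_tests(result, n_obs: int) -> dict:
    """Per-term Wald F statistics from a fitted mixed model.

    The chi-square Wald statistic for each non-intercept fixed term is
    divided by its numerator df; denominator df is the conservative
    n_obs - n_fixed_params (no Satterthwaite approximation).
    """
    design_info = result.model.data.design_info
    k_fe = result.model.exog.shape[1]
    df_den = n_obs - k_fe
    terms = {}
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        term = term.replace(", Sum)", ")")
        L = np.zeros((sl.stop - sl.start, len(result.params)))
        for i, j in enumerate(range(sl.start, sl.stop)):
            L[i, j] = 1.0
        wt = result.wald_test(L, scalar=True)
        df_num = sl.stop - sl.start
        f_stat = float(wt.statistic) / df_num
        terms[term] = {
            "F": f_stat,
            "df_num": df_num,
            "df_den": df_den,
            "p": float(stats.f.sf(f_stat, df_num, df_den)),
        }
    return terms


def _fit_lmm(data: pd.DataFrame, formula: str) -> ModelSummary:
    import statsmodels.formula.api as smf

    data = data.dropna(subset=["value"]).copy()
    model = smf.mixedlm(formula, data, groups=data["participant"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    if not np.all(np.isfinite(result.params)):
        raise np.linalg.LinAlgError("singular mixed-model fit")
    n_obs = len(data)
    return ModelSummary(
        terms=_wald_f_tests(result, n_obs),
        random_intercept_var=float(np.asarray(result.cov_re).ravel()[0]),
        n_obs=n_obs,
        method="mixed_lm",
    )


def _fit_rm_anova(data: pd.DataFrame, within: list[str]) -> ModelSummary:
    """Fallback: repeated-measures ANOVA on participant-cell means."""
    from statsmodels.stats.anova import AnovaRM

    cell = (
        data.groupby(["participant"] + within, as_index=False)["value"].mean()
    )
    res = AnovaRM(cell, "value", "participant", within=within).fit()
    tbl = res.anova_table
    terms = {
        idx: {
            "F": float(row["F Value"]),
            "df_num": float(row["Num DF"]),
            "df_den": float(row["Den DF"]),
            "p": float(row["Pr > F"]),
        }
        for idx, row in tbl.iterrows()
    }
    return ModelSummary(
        terms=terms,
        random_intercept_var=float("nan"),
        n_obs=len(data),
        method="rm_anova",
    )


def fit_task_effector_model(table: pd.DataFrame) -> ModelSummary:
    """2 task x 2 effector LMM on spread with participant random intercepts.

    ``table`` is long format with columns participant, task, effector,
    value (spread in degrees), restricted to the eye and head effectors.
    Falls back to a repeated-measures decomposition on participant means if
    the mixed fit is singular.
    """
    data = table[table["effector"].isin(["eye", "head"])].copy()
    try:
        # sum-to-zero contrasts so each term tests a Type-III main effect
        return _fit_lmm(data, "value ~ C(task, Sum) * C(effector, Sum)")
    except np.linalg.LinAlgError:
        warnings.warn("singular mixed-model fit; falling back to RM ANOVA")
        return _fit_rm_anova(data, ["task", "effector"])


def fit_task_eccentricity_model(table: pd.DataFrame) -> ModelSummary:
    """2 task x 8 eccentricity-bin LMM on head contribution.

    ``table`` has columns participant, task, bin, value (mean contribution
    percent); absent bins are simply missing rows (unbalanced designs are
    fine for the mixed model). A bin with no observations at all in one
    task leaves the task x bin interaction inestimable, so such bins are
    dropped from the model with a warning.
    """
    data = table.copy()
    data["bin"] = data["bin"].astype(int)
    cell_counts = data.groupby(["task", "bin"]).size().unstack(fill_value=0)
    estimable = cell_counts.columns[(cell_counts >= 2).all(axis=0)]
    dropped = sorted(set(data["bin"]) - set(estimable))
    if dropped:
        warnings.warn(
            f"bins {dropped} lack observations in one task and are excluded "
            "from the task x eccentricity model"
        )
        data = data[data["bin"].isin(estimable)]
    try:
        return _fit_lmm(data, "value ~ C(task, Sum) * C(bin, Sum)")
    except np.linalg.LinAlgError:
        warnings.warn("singular mixed-model fit; falling back to RM ANOVA")
        # RM ANOVA needs complete cells: keep bins every participant has
        n_p = data["participant"].nunique()
        cells = data.groupby("bin")["participant"].nunique()
        complete = cells.index[cells == n_p]
        return _fit_rm_anova(data[data["bin"].isin(complete)], ["task", "bin"])


def _summary_stats(df: pd.DataFrame, by: list[str]) -> list[dict]:
    out = []
    for keys, g in df.groupby(by):
        keys = keys if isinstance(keys, tuple) else (keys,)
        out.append(
            {
                **dict(zip(by, [str(k) for k in keys])),
                "n": int(g["value"].count()),
                "mean": float(g["value"].mean()),
                "sd": float(g["value"].std(ddof=1)),
            }
        )
    return out


def build_report(
    measure_table: pd.DataFrame,
    contribution_table: pd.DataFrame | None = None,
    comparisons: list[ComparisonResult] | None = None,
    models: dict[str, ModelSummary] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Assemble the results bundle: condition means/SDs, tests, models.

    Returns the report as a dict and, when ``out_dir`` is given, writes
    ``report.json`` plus human-readable CSV tables (locomotion, spread per
    effector, binned head contribution).
    """
    report: dict = {}

    loco = measure_table[measure_table["measure"] != "spread"]
    if len(loco):
        report["locomotion"] = _summary_stats(loco, ["task", "measure"])
    spread_tbl = measure_table[measure_table["measure"] == "spread"]
    if len(spread_tbl):
        report["spread"] = _summary_stats(spread_tbl, ["task", "effector"])
    if contribution_table is not None and len(contribution_table):
        report["head_contribution"] = _summary_stats(
            contribution_table, ["task", "bin"]
        )
    else:
        report["head_contribution"] = None

    if comparisons:
        report["paired_tests"] = [asdict(c) for c in comparisons]
    if models:
        report["models"] = {name: asdict(m) for name, m in models.items()}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
        if len(loco):
            pd.DataFrame(report["locomotion"]).to_csv(
                out / "locomotion_table.csv", index=False
            )
        if len(spread_tbl):
            pd.DataFrame(report["spread"]).to_csv(
                out / "spread_table.csv", index=False
            )
        if report.get("head_contribution"):
            pd.DataFrame(report["head_contribution"]).to_csv(
                out / "contribution_table.csv", index=False
            )
    return report
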
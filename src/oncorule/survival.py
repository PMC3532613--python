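"""Time-to-event analysis for dichotomous prognostic calls.

Thin, typed wrappers around lifelines providing the analyses used to
validate a prognostic rule: Kaplan-Meier curves, the log-rank test, Cox
proportional-hazards fits (Efron tie handling) with complete-case
covariate handling and per-model n accounting, a univariate screen that
adjusts each baseline variable for the rule call, backward elimination
with a forced covariate, and a Wald comparison of two classifiers'
coefficients in a joint model.

Recurrence-free-survival convention: patients who recur contribute
their time to first recurrence as an event; nonrecurrent patients are
administratively censored at the 36-month horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "CoxFit",
    "km_curve",
    "logrank_test",
    "cox_fit",
    "univariate_screen",
    "backward_elimination",
    "compare_hazard_models",
    "prepare_covariates",
]


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    ``summary`` has one row per covariate with columns ``coef``, ``hr``,
    ``se``, ``p``, ``hr_lower``, ``hr_upper``; ``n_used`` counts the
    complete cases entering the model and ``n_excluded`` the rows
    dropped for missing covariates.
    """

    summary: pd.DataFrame
    log_likelihood: float
    n_used: int
    n_excluded: int
    n_events: int
    variance_matrix: pd.DataFrame

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def _complete_cases(
    data: pd.DataFrame, covariates: list[str], duration_col: str, event_col: str
) -> tuple[pd.DataFrame, int]:
    cols = [duration_col, event_col] + covariates
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sub = data[cols].apply(pd.to_numeric, errors="coerce")
    kept = sub.dropna()
    return kept, len(sub) - len(kept)


def km_curve(
    data: pd.DataFrame,
    group_col: str | None = None,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> dict[object, pd.DataFrame]:
    """Product-limit survival estimates, one step function per group.

    Returns ``{group: DataFrame(time, survival)}``; with no
    ``group_col`` the single key is ``"all"``.  Survival starts at 1.0,
    is nonincreasing, and drops only at event times.
    """
    if data.empty:
        raise ValueError("empty survival data")
    groups = {"all": data} if group_col is None else {
        k: g for k, g in data.groupby(group_col)
    }
    out: dict[object, pd.DataFrame] = {}
    for key, sub in groups.items():
        if sub.empty:
            raise ValueError(f"empty group {key!r}")
        km = KaplanMeierFitter()
        km.fit(sub[duration_col], event_observed=sub[event_col])
        sf = km.survival_function_
        out[key] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return out


def logrank_test(
    data: pd.DataFrame,
    group_col: str,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p).

    Invariant to swapping the group labels; requires both groups to be
    nonempty and at least one event overall.
    """
    levels = pd.unique(data[group_col].dropna())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, found {len(levels)}")
    a = data[data[group_col] == levels[0]]
    b = data[data[group_col] == levels[1]]
    if a.empty or b.empty:
        raise ValueError("one group is empty")
    if int(data[event_col].sum()) == 0:
        raise ValueError("no events observed")
    res = _ll_logrank(
        a[duration_col], b[duration_col],
        event_observed_A=a[event_col], event_observed_B=b[event_col],
    )
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time_months",
    event_col: str = "event",
    alpha: float = 0.05,
) -> CoxFit:
    """Cox proportional-hazards fit with Efron tie handling.

    Rows missing any model covariate are excluded (complete-case) and
    counted in ``n_excluded``.  Raises on non-convergence or when no
    events remain among complete cases.
    """
    kept, n_excluded = _complete_cases(data, list(covariates), duration_col, event_col)
    if int(kept[event_col].sum()) == 0:
        raise ValueError("no events among complete cases")
    for c in covariates:
        if kept[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant among complete cases")
    cph = CoxPHFitter(alpha=alpha)
    cph.fit(kept, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "se": s["se(coef)"],
            "p": s["p"],
            "hr_lower": np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"]),
            "hr_upper": np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"]),
        }
    )
    summary.index.name = "covariate"
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n_used=len(kept),
        n_excluded=n_excluded,
        n_events=int(kept[event_col].sum()),
        variance_matrix=cph.variance_matrix_,
    )


def univariate_screen(
    data: pd.DataFrame,
    baseline_vars: list[str],
    test_var: str,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Per-variable two-covariate Cox models (variable + rule call).

    For each baseline variable, fits a Cox model containing that
    variable plus the dichotomous test call and reports the variable's
    HR/p together with the test's adjusted HR/p and the complete-case n
    for that pair.  Per-variable failures are reported in an ``error``
    column rather than raised.
    """
    rows = []
    for var in baseline_vars:
        row: dict[str, object] = {"variable": var}
        try:
            fit = cox_fit(data, [var, test_var], duration_col, event_col)
            row.update(
                n_used=fit.n_used,
                variable_hr=fit.hr(var), variable_p=fit.p(var),
                test_adjusted_hr=fit.hr(test_var), test_adjusted_p=fit.p(test_var),
                error="",
            )
        except Exception as exc:  # per-variable failure is not fatal
            row.update(
                n_used=np.nan, variable_hr=np.nan, variable_p=np.nan,
                test_adjusted_hr=np.nan, test_adjusted_p=np.nan, error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def backward_elimination(
    data: pd.DataFrame,
    variables: list[str],
    forced: str,
    alpha: float = 0.05,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> tuple[CoxFit, pd.DataFrame]:
    """Stepwise backward elimination with a forced covariate.

    Starting from the full model, repeatedly drops the non-forced
    variable with the highest Wald p value until every remaining
    non-forced variable has p < ``alpha``.  The forced variable is never
    dropped.  Returns the final fit and an elimination trace
    (step, dropped variable, its p, n variables remaining).
    """
    if forced not in variables:
        raise ValueError(f"forced variable {forced!r} not among variables")
    current = list(variables)
    trace_rows = []
    step = 0
    while True:
        fit = cox_fit(data, current, duration_col, event_col)
        candidates = {v: fit.p(v) for v in current if v != forced}
        if not candidates:
            break
        worst, worst_p = max(candidates.items(), key=lambda kv: kv[1])
        if worst_p < alpha:
            break
        current.remove(worst)
        step += 1
        trace_rows.append(
            {"step": step, "dropped": worst, "p": worst_p, "remaining": len(current)}
        )
    trace = pd.DataFrame(trace_rows, columns=["step", "dropped", "p", "remaining"])
    return fit, trace


@dataclass
class HazardModelComparison:
    """Wald comparison of two classifiers' coefficients in one model."""

    delta: float          # coef_a - coef_b
    se: float
    z: float
    p: float
    fit: CoxFit


def compare_hazard_models(
    data: pd.DataFrame,
    col_a: str,
    col_b: str,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> HazardModelComparison:
    """Joint Cox model with both binary calls; Wald test on the
    difference of their coefficients using the joint covariance.

    Swapping the two predictors negates ``delta`` and leaves ``p``
    unchanged.  Identical call vectors are degenerate and raise.
    """
    kept, _ = _complete_cases(data, [col_a, col_b], duration_col, event_col)
    if kept[col_a].equals(kept[col_b]):
        raise ValueError("degenerate comparison: the two call vectors are identical")
    fit = cox_fit(data, [col_a, col_b], duration_col, event_col)
    ca = float(fit.summary.loc[col_a, "coef"])
    cb = float(fit.summary.loc[col_b, "coef"])
    V = fit.variance_matrix
    var = float(V.loc[col_a, col_a] + V.loc[col_b, col_b] - 2.0 * V.loc[col_a, col_b])
    se = float(np.sqrt(var))
    z = (ca - cb) / se
    from scipy import stats as _st

    p = float(2.0 * _st.norm.sf(abs(z)))
    return HazardModelComparison(delta=ca - cb, se=se, z=z, p=p, fit=fit)


def prepare_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric model frame for a clinical table.

    Codings mirror the univariate-report conventions: indicator of
    Caucasian race, indicator of left-sided (vs right-sided) colon
    tumor, indicator of female sex, booleans for LVI / PNI /
    obstruction-perforation (NaN where unknown), and T classification,
    grade, node count and age entered as continuous values.
    """
    out = pd.DataFrame(index=clinical.index)
    out["time_months"] = pd.to_numeric(clinical["time_months"])
    out["event"] = clinical["event"].astype(int)
    out["t_class"] = clinical["t_class"].astype(str).str.lstrip("T").astype(float)
    out["grade"] = pd.to_numeric(clinical["grade"])
    out["n_nodes_examined"] = pd.to_numeric(clinical["n_nodes_examined"])
    out["age_years"] = pd.to_numeric(clinical["age_years"])
    out["female"] = (clinical["sex"].astype(str) == "F").astype(float)
    out["caucasian"] = (clinical["race"].astype(str) == "Caucasian").astype(float)
    site = clinical["site"].astype(str)
    left = site.map({"colon-left": 1.0, "colon-right": 0.0}).astype(float)
    out["left_sided"] = left  # NaN for rectal tumors
    for col in ("lvi", "pni", "obstruction_perforation"):
        vals = clinical[col]
        out[col] = pd.array(vals, dtype="boolean").to_numpy(dtype="float", na_value=np.nan)
    return out
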
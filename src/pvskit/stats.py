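"""Reliability gating and longitudinal change models for PVS cohort tables.

The analysis chain mirrors a longitudinal two-group design:

1. **Reliability gate.** ICC(3,k) — two-way mixed effects, consistency,
   average measures — is computed for each metric across the astronauts'
   two pre-flight sessions and across the controls' four sessions. Any
   metric with ICC below 0.5 in either cohort is excluded from all further
   models; the exclusion list is reported, never silently applied.

2. **Pre-to-post change.** The outcome is the per-subject difference from
   the last pre-flight session (L-60, falling back to L-180 when missing)
   to the first post-flight session (R+4). An intercept-only least-squares
   fit tests for a whole-group shift (identical to a one-sample t-test);
   covariates (sex, mean-centered age, mission duration, days from landing
   to scan, novice vs. experienced status) enter a full model pruned by
   stepwise AIC search.

3. **Exploratory contrasts.** Baseline-vs-prior-flight-experience Pearson
   and age-partial correlations in the experienced subgroup; demographics
   contrasts (Welch t, chi-square); and the SANS subgroup re-fit of the
   change model with SANS status replacing experience status.

No multiple-comparison correction is applied anywhere; every model emits
raw p values and confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .phantom import PRE_SESSIONS

ICC_GATE = 0.5
ALPHA = 0.05

DEFAULT_COVARIATES = [
    "sex",
    "age_at_launch_yr",
    "mission_duration_d",
    "days_landing_to_scan_d",
    "group",
]


# --------------------------------------------------------------------------
# reliability
# --------------------------------------------------------------------------

@dataclass
class ICCResult:
    metric: str
    icc3k: float
    k: int
    n: int
    retained: bool


def icc3k(wide: pd.DataFrame, metric: str = "") -> ICCResult:
    """ICC(3,k): two-way mixed effects, consistency, average measures.

    ``wide`` is subjects x sessions for one metric; rows with any missing
    session are dropped (complete cases). With between-subject mean square
    MS_R and residual mean square MS_E from the two-way subject x session
    decomposition, ICC(3,k) = (MS_R - MS_E) / MS_R.
    """
    x = wide.dropna(axis=0).to_numpy(dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 complete subjects and >= 2 sessions, got {n}x{k}")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    sess_means = x.mean(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_sess = n * ((sess_means - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_sess
    ms_r = ss_subj / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r <= 0:
        icc = float("nan")
    else:
        icc = (ms_r - ms_e) / ms_r
    retained = bool(icc >= ICC_GATE) if math.isfinite(icc) else False
    return ICCResult(metric=metric, icc3k=float(icc), k=k, n=n, retained=retained)


def metric_wide(table: pd.DataFrame, metric: str, sessions) -> pd.DataFrame:
    """Pivot a long cohort table to subjects x sessions for one metric."""
    sub = table[table["session"].isin(sessions)]
    return sub.pivot_table(
        index="subject_id", columns="session", values=metric, aggfunc="first"
    ).reindex(columns=list(sessions))


def reliability_gate(
    table: pd.DataFrame, metrics, astronaut_sessions=PRE_SESSIONS,
    control_sessions=("C1", "C2", "C3", "C4"),
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Apply the ICC >= 0.5 gate in both cohorts.

    Returns (report, retained metrics, excluded metrics). A metric must
    clear the gate for the astronauts' pre-flight pair AND the controls'
    session table to be retained.
    """
    ast = table[table["cohort"] == "astronaut"]
    ctl = table[table["cohort"] == "control"]
    rows, retained, excluded = [], [], []
    for m in metrics:
        r_ast = icc3k(metric_wide(ast, m, astronaut_sessions), m)
        r_ctl = icc3k(metric_wide(ctl, m, list(control_sessions)), m)
        keep = r_ast.retained and r_ctl.retained
        rows.append(
            {
                "metric": m,
                "icc3k_astronauts": r_ast.icc3k,
                "icc3k_controls": r_ctl.icc3k,
                "n_astronauts": r_ast.n,
                "n_controls": r_ctl.n,
                "retained": keep,
            }
        )
        (retained if keep else excluded).append(m)
    return pd.DataFrame(rows), retained, excluded


# --------------------------------------------------------------------------
# pre -> post change
# --------------------------------------------------------------------------

def prepost_delta(
    table: pd.DataFrame,
    metric: str,
    pre: str = "L-60",
    pre_fallback: str = "L-180",
    post: str = "R+4",
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-subject change value(post) - value(pre) with baseline fallback.

    Astronaut rows only. A subject missing the primary pre-flight session
    uses the fallback baseline; subjects missing both baselines or the
    post session are dropped, each with a logged reason.
    """
    ast = table[table["cohort"] == "astronaut"]
    log: list[dict] = []
    rows = []
    for sid, sub in ast.groupby("subject_id", sort=True):
        by_sess = sub.set_index("session")[metric].to_dict()
        pre_val = by_sess.get(pre)
        used_fallback = False
        if pre_val is None or (isinstance(pre_val, float) and math.isnan(pre_val)):
            pre_val = by_sess.get(pre_fallback)
            used_fallback = True
            if pre_val is None or (isinstance(pre_val, float) and math.isnan(pre_val)):
                log.append({"subject_id": sid, "reason": "no baseline session"})
                continue
            log.append({"subject_id": sid, "reason": f"baseline fallback to {pre_fallback}"})
        post_val = by_sess.get(post)
        if post_val is None or (isinstance(post_val, float) and math.isnan(post_val)):
            log.append({"subject_id": sid, "reason": f"missing {post} session"})
            continue
        first = sub.iloc[0]
        rows.append(
            {
                "subject_id": sid,
                "delta": float(post_val) - float(pre_val),
                "baseline_fallback": used_fallback,
                "group": first["group"],
                "sans": first.get("sans", "unknown"),
                "sex": first.get("sex"),
                "age_at_launch_yr": first.get("age_at_launch_yr"),
                "mission_duration_d": first.get("mission_duration_d"),
                "days_landing_to_scan_d": first.get("days_landing_to_scan_d"),
            }
        )
    return pd.DataFrame(rows), log


# --------------------------------------------------------------------------
# linear change models and stepwise AIC
# --------------------------------------------------------------------------

@dataclass
class ChangeModelResult:
    outcome: str
    predictors: list[str]
    coef_table: pd.DataFrame
    r2: float
    r2_adj: float
    shapiro_p: float
    aic: float
    aic_trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    n: int = 0


def _design_matrix(data: pd.DataFrame, predictors) -> pd.DataFrame:
    """Numeric design matrix: sex/group/sans coded 0/1, continuous
    covariates mean-centered."""
    cols = {}
    for p in predictors:
        col = data[p]
        if p == "sex":
            cols["sex_F"] = (col == "F").astype(float)
        elif p == "group":
            cols["novice"] = (col == "novice").astype(float)
        elif p == "sans":
            cols["sans_pos"] = (col == "SANS").astype(float)
        elif col.dtype == object:
            lev = sorted(col.dropna().unique())
            if len(lev) != 2:
                raise ValueError(f"cannot code predictor {p} with levels {lev}")
            cols[f"{p}_{lev[1]}"] = (col == lev[1]).astype(float)
        else:
            cols[p] = col.astype(float) - col.astype(float).mean()
    return pd.DataFrame(cols, index=data.index)


def gaussian_aic(rss: float, n: int, p: int) -> float:
    """AIC in the Gaussian least-squares form n*log(RSS/n) + 2p.

    Additive constants are dropped; comparisons are valid within a search.
    ``p`` counts estimated mean parameters, including the intercept.
    """
    if rss <= 0:
        return -math.inf
    return n * math.log(rss / n) + 2 * p


def fit_change_model(
    data: pd.DataFrame,
    outcome: str = "delta",
    predictors=(),
    name: str = "",
) -> ChangeModelResult:
    """Least-squares fit of the change outcome on a covariate set.

    With no predictors this is the intercept-only model, whose t test of
    the intercept is exactly the one-sample t test of the mean change.
    Reports estimates, SEs, 95% CIs, t, p, R2/adjusted R2, a Shapiro
    normality check on residuals, and the Gaussian AIC.
    """
    predictors = list(predictors)
    y = data[outcome].astype(float)
    X = _design_matrix(data, predictors) if predictors else pd.DataFrame(index=data.index)
    X = sm.add_constant(X, has_constant="add")
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"n={n} too small for {p} parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        raise ValueError(f"rank-deficient design matrix (columns {list(X.columns)})")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=ALPHA)
    coef = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    resid = np.asarray(fit.resid)
    shapiro_p = float(sps.shapiro(resid)[1]) if 3 <= n <= 5000 and resid.std() > 0 else float("nan")
    return ChangeModelResult(
        outcome=name or outcome,
        predictors=predictors,
        coef_table=coef,
        r2=float(fit.rsquared) if p > 1 else 0.0,
        r2_adj=float(fit.rsquared_adj) if p > 1 else 0.0,
        shapiro_p=shapiro_p,
        aic=gaussian_aic(float(fit.ssr), n, p),
        n=n,
    )


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def stepwise_aic(
    data: pd.DataFrame,
    outcome: str = "delta",
    predictors=(),
    name: str = "",
) -> ChangeModelResult:
    """Bidirectional stepwise search minimizing the Gaussian AIC.

    Starts from the full model; at each step evaluates all single-term
    deletions and additions, moving to the best AIC improvement. The
    intercept is always retained; ties break toward the smaller model.
    Returns the final model (refit with the full coefficient table) and
    the visited-model AIC trace.
    """
    predictors = list(predictors)
    y = data[outcome].astype(float).to_numpy()
    full_X = _design_matrix(data, predictors) if predictors else pd.DataFrame(index=data.index)
    terms = list(full_X.columns)
    n = len(y)
    ones = np.ones((n, 1))

    def model_aic(subset: tuple[str, ...]) -> float:
        X = np.hstack([ones] + [full_X[t].to_numpy()[:, None] for t in subset])
        return gaussian_aic(_rss(y, X), n, X.shape[1])

    current = tuple(terms)
    cache: dict[tuple[str, ...], float] = {}

    def aic_of(subset) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = model_aic(key)
        return cache[key]

    trace = [(current, aic_of(current))]
    while True:
        cur_aic = aic_of(current)
        candidates: list[tuple[float, int, tuple[str, ...]]] = []
        for t in current:  # deletions; prefer smaller models on ties
            sub = tuple(x for x in current if x != t)
            candidates.append((aic_of(sub), len(sub), sub))
        for t in terms:  # additions
            if t not in current:
                sub = tuple(list(current) + [t])
                candidates.append((aic_of(sub), len(sub), sub))
        if not candidates:
            break
        candidates.sort(key=lambda c: (round(c[0], 12), c[1]))
        best_aic, _, best = candidates[0]
        if best_aic < cur_aic - 1e-12:
            current = best
            trace.append((current, best_aic))
        else:
            break

    # map selected design columns back to predictor names for the refit
    col_to_pred = {}
    for p_name in predictors:
        cols = list(_design_matrix(data, [p_name]).columns)
        for c in cols:
            col_to_pred[c] = p_name
    selected = []
    for t in terms:
        if t in current and col_to_pred[t] not in selected:
            selected.append(col_to_pred[t])
    result = fit_change_model(data, outcome=outcome, predictors=selected, name=name)
    result.aic_trace = [(tuple(sorted(s)), a) for s, a in trace]
    return result


# --------------------------------------------------------------------------
# exploratory contrasts
# --------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    r: float
    p: float
    df: int
    partial_r: float
    partial_p: float
    n: int


def baseline_average(table: pd.DataFrame, metric: str) -> pd.Series:
    """Per-subject mean of the pre-flight sessions (single session if only
    one baseline survives quality control)."""
    ast = table[(table["cohort"] == "astronaut") & table["session"].isin(PRE_SESSIONS)]
    return ast.groupby("subject_id")[metric].mean()


def _partial_corr(x, y, z):
    """Correlation of x and y after regressing each on z (with intercept)."""
    Z = np.column_stack([np.ones_like(z), z])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        return float("nan"), float("nan")
    r, _ = sps.pearsonr(rx, ry)
    n = len(x)
    df = n - 3
    if df <= 0 or abs(r) >= 1:
        return float(r), float("nan")
    t = r * math.sqrt(df / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), df)
    return float(r), float(p)


def experience_correlations(
    table: pd.DataFrame, metric: str, experience_col: str = "prior_flight_days_d"
) -> CorrelationReport:
    """Baseline metric vs. prior flight days in the experienced subgroup.

    Pearson r with df = n - 2, plus an age-partial correlation computed by
    residualizing both variables on age.
    """
    exp = table[(table["cohort"] == "astronaut") & (table["group"] == "experienced")]
    base = baseline_average(table, metric)
    per_subj = exp.groupby("subject_id").first()
    joined = per_subj.join(base.rename("baseline"), how="inner").dropna(
        subset=["baseline", experience_col]
    )
    n = len(joined)
    if n < 3:
        raise ValueError(f"need >= 3 experienced subjects, got {n}")
    x = joined[experience_col].to_numpy(dtype=float)
    y = joined["baseline"].to_numpy(dtype=float)
    r, p = sps.pearsonr(x, y)
    age = joined["age_at_launch_yr"].to_numpy(dtype=float)
    pr, pp = _partial_corr(x, y, age)
    return CorrelationReport(
        r=float(r), p=float(p), df=n - 2, partial_r=pr, partial_p=pp, n=n
    )


@dataclass
class GroupContrast:
    variable: str
    kind: str  # "welch_t" or "chi2"
    statistic: float
    df: float
    p: float


def group_contrasts(
    table: pd.DataFrame,
    group_col: str = "group",
    groups=("novice", "experienced"),
    continuous=("age_at_launch_yr", "mission_duration_d", "days_landing_to_scan_d"),
    categorical=("sex",),
) -> list[GroupContrast]:
    """Demographics contrasts: Welch two-sample t tests for continuous
    covariates, Pearson chi-square (no continuity correction) for
    categorical ones."""
    per_subj = table.groupby("subject_id").first()
    a = per_subj[per_subj[group_col] == groups[0]]
    b = per_subj[per_subj[group_col] == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 subjects per group")
    out = []
    for v in continuous:
        xa, xb = a[v].dropna(), b[v].dropna()
        t, p = sps.ttest_ind(xa, xb, equal_var=False)
        # Welch-Satterthwaite df
        va, vb = xa.var(ddof=1) / len(xa), xb.var(ddof=1) / len(xb)
        df = (va + vb) ** 2 / (
            va**2 / (len(xa) - 1) + vb**2 / (len(xb) - 1)
        )
        out.append(GroupContrast(v, "welch_t", float(t), float(df), float(p)))
    for v in categorical:
        tab = pd.crosstab(per_subj[group_col], per_subj[v])
        chi2, p, df, _ = sps.chi2_contingency(tab, correction=False)
        out.append(GroupContrast(v, "chi2", float(chi2), float(df), float(p)))
    return out


def run_sans_contrast(
    data: pd.DataFrame, outcome: str = "delta", covariates=(), name: str = ""
) -> ChangeModelResult:
    """Change model with SANS status as the predictor of interest.

    Subjects with unknown SANS status are excluded (logged via the returned
    model's n); otherwise identical machinery to the experience contrast.
    """
    known = data[data["sans"].isin(["SANS", "no-SANS"])]
    levels = known["sans"].unique()
    if len(levels) < 2 or min((known["sans"] == lv).sum() for lv in levels) < 2:
        raise ValueError("need >= 2 subjects per SANS level")
    predictors = ["sans"] + [c for c in covariates if c != "group"]
    if len(predictors) > 1:
        return stepwise_aic(known, outcome=outcome, predictors=predictors, name=name)
    return fit_change_model(known, outcome=outcome, predictors=predictors, name=name)
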
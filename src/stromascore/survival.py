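"""Disease-free-survival statistics for tertile-stratified biomarker cohorts.

Implements the study workflow around a continuous stromal chromogen score:
cohort filtering with an exclusion report, rank-based tertile assignment,
a Spearman correlation screen of the score against clinical covariates,
univariate Cox proportional-hazards fits per covariate, a multivariable
Cox model reduced by backward elimination, a scaled-Schoenfeld-residual
check of the proportional-hazards assumption, and Cox-based / Kaplan-Meier
survival curves with k-group log-rank tests.

Partial-likelihood maximisation is delegated to statsmodels' ``PHReg``
(Efron tie handling by default; Breslow available — the choice is recorded
in every fit). Kaplan-Meier curves and log-rank tests come from lifelines.
Scaled Schoenfeld residuals are computed here directly (Grambsch-Therneau
scaling: d * Cov(beta_hat) @ r_i) and correlated with event time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "TertileAssignment",
    "CoxFit",
    "PHDiagnostic",
    "CurveBundle",
    "validate_cohort",
    "filter_cohort",
    "assign_tertiles",
    "spearman_screen",
    "cox_univariate",
    "cox_multivariate_backward",
    "ph_test",
    "survival_curves",
]

EXCLUSION_REASONS = ("none", "misclassified", "insufficient_material", "poor_quality")
TERTILE_LABELS = ("lower", "middle", "upper")

TIME_COL = "time_to_recurrence"
EVENT_COL = "event"


def validate_cohort(df: pd.DataFrame, time_col: str = TIME_COL, event_col: str = EVENT_COL) -> None:
    if "patient_id" in df.columns and df["patient_id"].duplicated().any():
        raise ValueError("duplicated patient_id in cohort")
    if time_col in df.columns:
        if not (df[time_col] > 0).all():
            raise ValueError("all times must be > 0")
    if event_col in df.columns:
        if not df[event_col].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")


def filter_cohort(
    manifest: pd.DataFrame, reason_col: str = "exclusion_reason"
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the selection manifest; keep rows with reason 'none'.

    Returns the retained cohort and a per-reason exclusion count report.
    """
    if len(manifest) == 0:
        raise ValueError("empty cohort")
    reasons = manifest[reason_col].astype(str)
    unknown = sorted(set(reasons) - set(EXCLUSION_REASONS))
    if unknown:
        raise ValueError(f"unknown exclusion reason(s): {unknown}")
    report = {r: int((reasons == r).sum()) for r in EXCLUSION_REASONS}
    report["n_selected"] = len(manifest)
    report["n_retained"] = report.pop("none")
    retained = manifest.loc[reasons == "none"].drop(columns=[reason_col]).reset_index(drop=True)
    return retained, report


@dataclass
class TertileAssignment:
    """Rank-based three-group split: lower / middle / upper."""

    index: np.ndarray           # 0 = lower, 1 = middle, 2 = upper
    sizes: tuple[int, int, int]
    cut_ranks: tuple[int, int]  # [0, c0) lower, [c0, c1) middle, [c1, n) upper

    def labels(self) -> np.ndarray:
        return np.array(TERTILE_LABELS)[self.index]


def assign_tertiles(values, ids=None) -> TertileAssignment:
    """Split scores into tertiles by ascending rank, ties broken by patient id.

    The lower and upper groups take the first and last ceil(n/3) ranks; the
    middle group takes the remainder, so group sizes differ by at most one
    (n = 86 gives 29/28/29).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        raise ValueError("tertile assignment requires n >= 3")
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    order = np.lexsort((ids, v))
    n_outer = -(-n // 3)  # ceil(n/3)
    c0, c1 = n_outer, n - n_outer
    idx = np.empty(n, dtype=int)
    idx[order[:c0]] = 0
    idx[order[c0:c1]] = 1
    idx[order[c1:]] = 2
    sizes = (c0, c1 - c0, n - c1)
    return TertileAssignment(index=idx, sizes=sizes, cut_ranks=(c0, c1))


def spearman_screen(
    cohort: pd.DataFrame, score_column: str, variables: list[str]
) -> pd.DataFrame:
    """Spearman rank correlation of the score against each listed variable.

    Average ranks for ties; two-sided p by the t approximation. A constant
    variable has undefined rho and is reported as missing (with a warning).
    """
    rows = []
    score = cohort[score_column]
    for var in variables:
        pair = pd.concat([score, cohort[var]], axis=1).dropna()
        if len(pair) < 4:
            raise ValueError(f"fewer than 4 complete pairs for {var!r}")
        x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            warnings.warn(f"variable {var!r} is constant; Spearman rho undefined")
            rows.append({"variable": var, "rho": np.nan, "p": np.nan, "n": len(pair)})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"variable": var, "rho": float(rho), "p": float(p), "n": len(pair)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """A fitted Cox model: per-term log-HRs, HRs, Wald 95% CIs and p-values."""

    terms: list[str]
    coef: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    variable_terms: dict[str, list[str]]
    ties: str
    n: int
    n_events: int
    converged: bool
    logrank_p: float | None = None
    flags: list[str] = field(default_factory=list)
    design: pd.DataFrame | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    cov: np.ndarray | None = None

    def term_hr(self, term: str) -> float:
        return float(self.hr[self.terms.index(term)])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "hr": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p,
            }
        )


@dataclass
class PHDiagnostic:
    """Correlation of scaled Schoenfeld residuals with event time, per term."""

    term: str
    corr: float
    p: float
    passed: bool  # at alpha = 0.05


@dataclass
class CurveBundle:
    cox_curves: pd.DataFrame
    km_curves: pd.DataFrame
    logrank_stat: float
    logrank_p: float
    fit: CoxFit


def _encode_variable(cohort: pd.DataFrame, variable: str) -> tuple[pd.DataFrame, list[str]]:
    """Design columns for one variable.

    Object/categorical dtypes and low-cardinality integers become treatment-
    coded dummies (first sorted level is the reference); everything else
    enters per unit as a single continuous column.
    """
    col = cohort[variable]
    n_unique = col.nunique()
    if n_unique < 2:
        raise ValueError(f"variable {variable!r} has fewer than 2 distinct values")
    categorical = (
        col.dtype == object
        or isinstance(col.dtype, pd.CategoricalDtype)
        or (np.issubdtype(col.dtype, np.integer) and n_unique <= 3)
    )
    if not categorical:
        return pd.DataFrame({variable: col.astype(float)}), [variable]
    levels = sorted(col.unique())
    cols = {}
    for lev in levels[1:]:
        name = f"{variable}[{lev}]" if len(levels) > 2 else variable
        cols[name] = (col == lev).astype(float)
    design = pd.DataFrame(cols, index=cohort.index)
    return design, list(design.columns)


def _fit_phreg(
    design: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    ties: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, list[str]]:
    flags: list[str] = []
    model = PHReg(time, design.to_numpy(float), status=event, ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
    coef = np.asarray(res.params, float)
    cov = np.asarray(res.cov_params(), float)
    se = np.sqrt(np.diag(cov))
    converged = bool(np.all(np.isfinite(coef)) and np.all(np.isfinite(se)))
    if converged and (np.any(np.abs(coef) > 15) or np.any(se > 50)):
        converged = False
        flags.append("possible complete separation: estimates diverged")
    return coef, cov, se, converged, flags


def _build_fit(
    design: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    variable_terms: dict[str, list[str]],
    ties: str,
    logrank_p: float | None = None,
    extra_flags: list[str] | None = None,
) -> CoxFit:
    coef, cov, se, converged, flags = _fit_phreg(design, time, event, ties)
    z = np.divide(coef, se, out=np.zeros_like(coef), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):
        ci_lo = np.exp(coef - 1.959963984540054 * se)
        ci_hi = np.exp(coef + 1.959963984540054 * se)
    return CoxFit(
        terms=list(design.columns),
        coef=coef,
        hr=np.exp(coef),
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        p=p,
        variable_terms=variable_terms,
        ties=ties,
        n=len(design),
        n_events=int(event.sum()),
        converged=converged,
        logrank_p=logrank_p,
        flags=(extra_flags or []) + flags,
        design=design,
        time=np.asarray(time, float),
        event=np.asarray(event, int),
        cov=cov,
    )


def cox_univariate(
    cohort: pd.DataFrame,
    variable: str,
    time_col: str = TIME_COL,
    event_col: str = EVENT_COL,
    ties: str = "efron",
) -> CoxFit:
    """Single-variable Cox fit; categorical variables also get a log-rank p.

    The reference level of a categorical variable is its first sorted level.
    Levels with zero events are flagged rather than dropped.
    """
    time = cohort[time_col].to_numpy(float)
    event = cohort[event_col].to_numpy(int)
    if event.sum() == 0:
        raise ValueError("no events")
    design, terms = _encode_variable(cohort, variable)
    flags = []
    col = cohort[variable]
    logrank_p = None
    if col.nunique() <= 3:
        for lev in sorted(col.unique()):
            if event[(col == lev).to_numpy()].sum() == 0:
                flags.append(f"level {lev!r} of {variable!r} has zero events")
        lr = multivariate_logrank_test(time, col.to_numpy(), event)
        logrank_p = float(lr.p_value)
    return _build_fit(
        design, time, event, {variable: terms}, ties, logrank_p=logrank_p, extra_flags=flags
    )


def cox_multivariate_backward(
    cohort: pd.DataFrame,
    candidate_variables: list[str],
    removal_alpha: float = 0.10,
    time_col: str = TIME_COL,
    event_col: str = EVENT_COL,
    ties: str = "efron",
) -> tuple[CoxFit, list[dict]]:
    """Multivariable Cox fit reduced by backward elimination.

    At each step the variable whose smallest per-term Wald p is largest is
    removed if that p is >= ``removal_alpha``; elimination stops when every
    remaining variable has p < ``removal_alpha``. The default alpha of 0.10
    keeps borderline prognostic factors (p slightly above 0.05) in the final
    model. Returns the final fit and the ordered removal trace.
    """
    if not candidate_variables:
        raise ValueError("empty candidate set")
    time = cohort[time_col].to_numpy(float)
    event = cohort[event_col].to_numpy(int)
    if event.sum() == 0:
        raise ValueError("no events")

    remaining = list(candidate_variables)
    trace: list[dict] = []
    while True:
        blocks = {v: _encode_variable(cohort, v)[0] for v in remaining}
        design = pd.concat(blocks.values(), axis=1)
        variable_terms = {v: list(b.columns) for v, b in blocks.items()}
        fit = _build_fit(design, time, event, variable_terms, ties)
        var_p = {
            v: float(min(fit.p[fit.terms.index(t)] for t in ts))
            for v, ts in variable_terms.items()
        }
        worst_var = max(var_p, key=var_p.get)
        if var_p[worst_var] < removal_alpha:
            return fit, trace
        trace.append({"step": len(trace) + 1, "removed": worst_var, "p": var_p[worst_var]})
        remaining.remove(worst_var)
        if not remaining:
            fit.flags.append("all candidates eliminated")
            return fit, trace


def ph_test(fit: CoxFit, alpha: float = 0.05) -> list[PHDiagnostic]:
    """Scaled-Schoenfeld test of the proportional-hazards assumption.

    For each event, the Schoenfeld residual is the covariate of the failing
    subject minus the risk-weighted mean covariate over its risk set; scaled
    residuals (d * Cov(beta) @ r) are Pearson-correlated with event time and
    a two-sided t-test p is reported per term.
    """
    if fit.design is None:
        raise ValueError("fit carries no design matrix")
    time, event = fit.time, fit.event
    x = fit.design.to_numpy(float)
    d = int(event.sum())
    if d < 3:
        raise ValueError("need at least 3 events for the PH diagnostic")
    risk = np.exp(x @ fit.coef)
    ev_idx = np.flatnonzero(event == 1)
    ev_order = ev_idx[np.argsort(time[ev_idx], kind="stable")]
    resid = np.empty((d, x.shape[1]))
    ev_times = np.empty(d)
    for k, i in enumerate(ev_order):
        in_risk = time >= time[i]
        w = risk[in_risk]
        xbar = (w[:, None] * x[in_risk]).sum(axis=0) / w.sum()
        resid[k] = x[i] - xbar
        ev_times[k] = time[i]
    scaled = d * resid @ fit.cov  # Grambsch-Therneau scaling (constant beta omitted)
    out = []
    for j, term in enumerate(fit.terms):
        r = scaled[:, j]
        if np.ptp(r) == 0 or np.ptp(ev_times) == 0:
            out.append(PHDiagnostic(term, np.nan, np.nan, False))
            continue
        corr, p = stats.pearsonr(r, ev_times)
        out.append(PHDiagnostic(term, float(corr), float(p), bool(p >= alpha)))
    return out


def _breslow_baseline(fit: CoxFit) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimate of the baseline cumulative hazard at event times."""
    time, event = fit.time, fit.event
    risk = np.exp(fit.design.to_numpy(float) @ fit.coef)
    ev_times = np.unique(time[event == 1])
    cumhaz = np.empty(ev_times.size)
    h = 0.0
    for k, t in enumerate(ev_times):
        d_t = int(((time == t) & (event == 1)).sum())
        denom = risk[time >= t].sum()
        h += d_t / denom
        cumhaz[k] = h
    return ev_times, cumhaz


def survival_curves(
    cohort: pd.DataFrame,
    groups,
    time_col: str = TIME_COL,
    event_col: str = EVENT_COL,
    ties: str = "efron",
) -> CurveBundle:
    """Cox-based and Kaplan-Meier survival curves per group plus log-rank test.

    ``groups`` may be a TertileAssignment or any per-patient label array.
    Cox curves are S0(t)^exp(beta_g) with a Breslow baseline from a fit on
    group indicators (first sorted group is the reference).
    """
    if isinstance(groups, TertileAssignment):
        labels = groups.labels()
    else:
        labels = np.asarray(groups)
    time = cohort[time_col].to_numpy(float)
    event = cohort[event_col].to_numpy(int)
    uniq = (
        [l for l in TERTILE_LABELS if l in set(labels)]
        if set(labels) <= set(TERTILE_LABELS)
        else sorted(set(labels))
    )
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if event.sum() == 0:
        raise ValueError("no events")

    design = pd.DataFrame(
        {f"group[{g}]": (labels == g).astype(float) for g in uniq[1:]}
    )
    fit = _build_fit(design, time, event, {"group": list(design.columns)}, ties)

    ev_times, cumhaz = _breslow_baseline(fit)
    cox_rows = []
    for g in uniq:
        beta_g = 0.0 if g == uniq[0] else fit.coef[uniq.index(g) - 1]
        surv = np.exp(-cumhaz * np.exp(beta_g))
        for t, s in zip(ev_times, surv):
            cox_rows.append({"group": g, "time": float(t), "survival": float(s)})

    km_rows = []
    for g in uniq:
        sel = labels == g
        km = KaplanMeierFitter()
        km.fit(time[sel], event[sel])
        at_risk = km.event_table["at_risk"]
        for t, s in km.survival_function_.itertuples():
            km_rows.append(
                {
                    "group": g,
                    "time": float(t),
                    "survival": float(s),
                    "at_risk": int(at_risk.get(t, 0)),
                }
            )

    lr = multivariate_logrank_test(time, labels, event)
    return CurveBundle(
        cox_curves=pd.DataFrame(cox_rows),
        km_curves=pd.DataFrame(km_rows),
        logrank_stat=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        fit=fit,
    )
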
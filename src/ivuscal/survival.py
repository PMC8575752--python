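"""Survival and regression stack for the ICS prognostic analysis.

Implements the full analysis pipeline applied to a cohort: Kaplan-Meier
survival curves and the log-rank test, cumulative incidence under
competing risks (Aalen-Johansen), cause-specific Cox proportional-
hazards regression with optional stratification and Efron (default) or
Breslow tie handling, Schoenfeld-residual proportional-hazards checks,
ordinary least-squares regression for sqrt(ICS), and the univariate
p < 0.1 screening procedure that builds the multivariate sqrt(ICS)
model.  Numerics are delegated to lifelines and statsmodels; this
module owns the cause-specific bookkeeping (competing causes censored
at their event times), the endpoint definitions, and the report layout.

Event tables are DataFrames with columns ``id``, ``time_days``,
``cause`` (one of death/stroke/mi/revascularization/censored) and
``target_vessel``; each patient contributes exactly one first-event
row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import AalenJohansenFitter, CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .cohort import CAUSES, HORIZON_DAYS, POCE_CAUSES

log = logging.getLogger(__name__)

#: Default adjustment covariates for the cause-specific Cox models.
DEFAULT_ADJUSTMENT = ("age", "diabetes", "egfr", "acs_presentation", "prev_cabg")

#: Candidate covariates screened for the multivariate sqrt(ICS) model.
SQRT_ICS_CANDIDATES = (
    "male", "age", "hypertension", "hypercholesterolemia", "diabetes",
    "familial_history", "smoking", "prev_mi", "prev_pci", "prev_cabg",
    "prev_stroke", "prev_pad", "egfr", "acs_presentation", "vessel_lad",
)


# ---------------------------------------------------------------------------
# estimates
# ---------------------------------------------------------------------------

@dataclass
class KMEstimate:
    """Product-limit survival estimate."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function lookup, S(t) right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CIFEstimate:
    """Aalen-Johansen cumulative incidence per cause."""

    times: np.ndarray
    incidence_by_cause: Dict[str, np.ndarray]
    all_cause_incidence: np.ndarray

    def incidence_at(self, t: float, cause: Optional[str] = None) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 0.0
        curve = (self.all_cause_incidence if cause is None
                 else self.incidence_by_cause[cause])
        return float(curve[idx])


@dataclass
class CoxFit:
    """Cause-specific Cox fit (Wald 95% CIs on the log scale)."""

    coefficients: pd.Series
    hr: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    strata_spec: Optional[str]
    ties_method: str
    converged: bool
    n_events: int
    _model: object = field(default=None, repr=False)
    _data: Optional[pd.DataFrame] = field(default=None, repr=False)


@dataclass
class LinearFit:
    """OLS fit with t-based 95% CIs."""

    coefficients: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    residuals: np.ndarray
    _result: object = field(default=None, repr=False)


@dataclass
class ScreeningResult:
    """Multivariate model + the univariate selection log."""

    fit: LinearFit
    selection_log: pd.DataFrame  # columns: candidate, univariate_p, selected


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _event_indicator(events: pd.DataFrame, event_def: Iterable[str],
                     target_vessel: Optional[bool] = None) -> np.ndarray:
    """True where the recorded first event matches the endpoint."""
    causes = frozenset(event_def)
    ind = events["cause"].isin(causes).to_numpy()
    if target_vessel:
        ind &= events["target_vessel"].to_numpy(dtype=bool)
    return ind


def _check_times(events: pd.DataFrame) -> None:
    if len(events) == 0:
        raise ValueError("empty event table")
    if (events["time_days"].to_numpy() <= 0).any():
        raise ValueError("event times must be strictly positive")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_estimate(events: pd.DataFrame, event_def: Iterable[str] = POCE_CAUSES) -> KMEstimate:
    """Kaplan-Meier estimate; causes outside ``event_def`` censor."""
    _check_times(events)
    observed = _event_indicator(events, event_def)
    kmf = KaplanMeierFitter()
    kmf.fit(events["time_days"], observed)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = table.index.to_numpy(float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy()
    return KMEstimate(times=times, survival=surv,
                      at_risk=table["at_risk"].to_numpy(),
                      events=table["observed"].to_numpy())


def logrank_test(events_a: pd.DataFrame, events_b: pd.DataFrame,
                 event_def: Iterable[str] = POCE_CAUSES) -> Dict[str, float]:
    """Two-sample log-rank test (1 df)."""
    if len(events_a) == 0 or len(events_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(
        events_a["time_days"], events_b["time_days"],
        _event_indicator(events_a, event_def), _event_indicator(events_b, event_def))
    return {"chi2": float(res.test_statistic), "p": float(res.p_value)}


# ---------------------------------------------------------------------------
# competing risks
# ---------------------------------------------------------------------------

def cif_estimate(events: pd.DataFrame,
                 causes: Iterable[str] = POCE_CAUSES) -> CIFEstimate:
    """Aalen-Johansen cumulative incidence for each cause in ``causes``.

    Observed causes outside ``causes`` are treated as competing events
    (they remove subjects from the risk set without contributing to any
    curve of interest); ``cause == "censored"`` rows censor.  The
    all-cause curve is the sum of the per-cause curves, which equals
    1 - KM of the composite exactly when every observed cause is in the
    set (and reduces to 1 - KM with a single cause and no competitors).
    """
    _check_times(events)
    causes = [c for c in CAUSES if c in frozenset(causes)]
    durations = events["time_days"].to_numpy(float)
    code_of = {c: i + 1 for i, c in enumerate(causes)}
    competing_code = len(causes) + 1
    codes = np.zeros(len(events), dtype=int)
    for i, c in enumerate(events["cause"]):
        codes[i] = 0 if c == "censored" else code_of.get(c, competing_code)

    event_times = np.unique(durations[codes > 0])
    incidence: Dict[str, np.ndarray] = {}
    for c in causes:
        if not (codes == code_of[c]).any():
            incidence[c] = np.zeros(len(event_times))
            continue
        ajf = AalenJohansenFitter(calculate_variance=False, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ajf.fit(durations, codes, event_of_interest=code_of[c])
        cd = ajf.cumulative_density_
        col = cd.columns[0]
        cd_times = cd.index.to_numpy(float)
        idx = np.searchsorted(cd_times, event_times, side="right") - 1
        vals = cd[col].to_numpy()
        incidence[c] = np.where(idx >= 0, vals[np.maximum(idx, 0)], 0.0)

    all_cause = (np.sum([incidence[c] for c in causes], axis=0)
                 if causes else np.zeros(len(event_times)))
    return CIFEstimate(times=event_times, incidence_by_cause=incidence,
                       all_cause_incidence=all_cause)


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def cox_fit(events: pd.DataFrame, covariates: pd.DataFrame,
            cause_def: Iterable[str] = POCE_CAUSES,
            strata: Optional[str] = None,
            ties_method: str = "efron",
            target_vessel: Optional[bool] = None) -> CoxFit:
    """Cause-specific Cox model: competing causes censor at their time.

    ``covariates`` must align row-wise with ``events`` (matched on
    ``id``).  ``strata`` names a covariate column used for a separate
    baseline hazard per level.  Efron tie handling by default; Breslow
    available via ``ties_method="breslow"`` (delegated to statsmodels).
    """
    _check_times(events)
    ev = events.set_index("id")
    if "id" in covariates.columns:
        cov = covariates.set_index(covariates["id"]).loc[ev.index]
    else:  # positional alignment
        cov = covariates.copy()
        cov.index = ev.index
    xcols = [c for c in cov.columns if c != "id"]
    X = cov[xcols].astype(float)

    event = _event_indicator(events, cause_def, target_vessel)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events of the cause of interest")
    check_cols = [c for c in xcols if c != strata]
    if check_cols:
        mat = X[check_cols].to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(mat)), mat])) < len(check_cols) + 1:
            raise ValueError("design matrix is rank-deficient")

    df = X.copy()
    df["T"] = ev["time_days"].to_numpy(float)
    df["E"] = event.astype(int)

    if ties_method == "breslow":
        return _cox_fit_breslow(df, xcols, strata)
    if ties_method != "efron":
        raise ValueError("ties_method must be 'efron' or 'breslow'")

    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df.reset_index(drop=True), duration_col="T", event_col="E",
                    strata=[strata] if strata else None,
                    fit_options={"precision": 1e-11})  # sharp optimum: the
            # partial-likelihood gradient must vanish at the reported fit
    except ConvergenceError as err:
        log.warning("Cox model failed to converge: %s", err)
        raise
    with np.errstate(over="ignore"):  # near-degenerate fits: CI bound -> inf
        ci = np.exp(cph.confidence_intervals_)
    return CoxFit(
        coefficients=cph.params_.copy(),
        hr=np.exp(cph.params_),
        ci_low=ci.iloc[:, 0],
        ci_high=ci.iloc[:, 1],
        p_values=cph.summary["p"].copy(),
        strata_spec=strata,
        ties_method="efron",
        converged=converged,
        n_events=n_events,
        _model=cph,
        _data=df.reset_index(drop=True),
    )


def _cox_fit_breslow(df: pd.DataFrame, xcols: List[str],
                     strata: Optional[str]) -> CoxFit:
    import statsmodels.api as sm

    cols = [c for c in xcols if c != strata]
    model = sm.PHReg(df["T"], df[cols],
                     status=df["E"],
                     strata=df[strata] if strata else None,
                     ties="breslow")
    res = model.fit()
    params = pd.Series(res.params, index=cols)
    se = pd.Series(res.bse, index=cols)
    z = stats.norm.ppf(0.975)
    return CoxFit(
        coefficients=params,
        hr=np.exp(params),
        ci_low=np.exp(params - z * se),
        ci_high=np.exp(params + z * se),
        p_values=pd.Series(res.pvalues, index=cols),
        strata_spec=strata,
        ties_method="breslow",
        converged=True,
        n_events=int(df["E"].sum()),
        _model=res,
        _data=df,
    )


def schoenfeld_check(fit: CoxFit, events: Optional[pd.DataFrame] = None,
                     covariates: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Scaled-Schoenfeld proportional-hazards check per covariate.

    Residuals are correlated against the rank of the event times; the
    p-value per covariate comes from the score test on the
    rank-transformed time axis.  Requires an Efron fit produced by
    :func:`cox_fit` (the fitted model and data travel with it).
    """
    if fit._model is None or fit._data is None or fit.ties_method != "efron":
        raise ValueError("schoenfeld_check needs an Efron CoxFit from cox_fit()")
    if fit.n_events < 2:
        raise ValueError("need at least 2 events for a Schoenfeld check")
    cph, df = fit._model, fit._data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        test = proportional_hazard_test(cph, df, time_transform="rank")
        resid = cph.compute_residuals(df, "scaled_schoenfeld")
    event_times = df.loc[resid.index, "T"]
    ranks = stats.rankdata(event_times)
    rows = {}
    pvals = test.summary["p"]
    for cov in fit.coefficients.index:
        r = float(np.corrcoef(ranks, resid[cov])[0, 1])
        key = (cov, "rank") if (cov, "rank") in pvals.index else cov
        rows[cov] = {"correlation": r, "p": float(pvals.loc[key])}
    return pd.DataFrame(rows).T


def cox_partial_loglik(beta: np.ndarray, times: np.ndarray, events: np.ndarray,
                       X: np.ndarray) -> float:
    """Log partial likelihood (no ties), for gradient checks.

    With distinct event times Efron and Breslow coincide with this
    product over risk sets.
    """
    beta = np.asarray(beta, float)
    eta = X @ beta
    order = np.argsort(times)
    ll = 0.0
    for i in order:
        if not events[i]:
            continue
        at_risk = times >= times[i]
        ll += eta[i] - np.log(np.exp(eta[at_risk]).sum())
    return ll


# ---------------------------------------------------------------------------
# linear regression and model building
# ---------------------------------------------------------------------------

def linreg_fit(response: Sequence[float], design: pd.DataFrame) -> LinearFit:
    """OLS of the response on the design (intercept added), 95% t CIs."""
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    X = design.astype(float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more observations than parameters")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        bad = _collinear_columns(Xc)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, Xc).fit()
    ci = res.conf_int(alpha=0.05)
    return LinearFit(
        coefficients=res.params.copy(),
        ci_low=ci.iloc[:, 0],
        ci_high=ci.iloc[:, 1],
        p_values=res.pvalues.copy(),
        residuals=np.asarray(res.resid),
        _result=res,
    )


def _collinear_columns(X: pd.DataFrame) -> List[str]:
    """Columns whose removal restores full rank (greedy, for messages)."""
    cols = list(X.columns)
    bad = []
    current = X.to_numpy()
    while np.linalg.matrix_rank(current) < current.shape[1]:
        for j in range(current.shape[1] - 1, -1, -1):
            reduced = np.delete(current, j, axis=1)
            if np.linalg.matrix_rank(reduced) == reduced.shape[1]:
                bad.append(cols.pop(j))
                current = reduced
                break
        else:  # pragma: no cover - every column degenerate
            bad.extend(cols)
            break
    return bad


def build_multivariate(response: Sequence[float], candidates: pd.DataFrame,
                       threshold: float = 0.1) -> ScreeningResult:
    """Univariate p < 0.1 screening, then one joint OLS fit.

    Every candidate is fitted univariately against the response; those
    with p strictly below ``threshold`` enter the joint model.  When no
    candidate passes, an intercept-only fit is returned with a warning.
    """
    y = np.asarray(response, dtype=float)
    records = []
    for col in candidates.columns:
        uni = linreg_fit(y, candidates[[col]])
        p = float(uni.p_values[col])
        records.append({"candidate": col, "univariate_p": p,
                        "selected": p < threshold})
    selection_log = pd.DataFrame(records)
    selected = selection_log.loc[selection_log["selected"], "candidate"].tolist()
    if not selected:
        warnings.warn("no candidate passed univariate screening; "
                      "returning intercept-only model")
        fit = linreg_fit(y, candidates.iloc[:, :0])
    else:
        fit = linreg_fit(y, candidates[selected])
    return ScreeningResult(fit=fit, selection_log=selection_log)


# ---------------------------------------------------------------------------
# full cohort analysis
# ---------------------------------------------------------------------------

#: endpoint name -> (cause set, target-vessel restriction)
ENDPOINTS: Dict[str, Tuple[FrozenSet[str], Optional[bool]]] = {
    "poce": (POCE_CAUSES, None),
    "any_revascularization": (frozenset({"revascularization"}), None),
    "target_vessel_revascularization": (frozenset({"revascularization"}), True),
    "any_mi": (frozenset({"mi"}), None),
    "target_vessel_mi": (frozenset({"mi"}), True),
    "stroke": (frozenset({"stroke"}), None),
    "all_cause_mortality": (frozenset({"death"}), None),
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of :func:`analyze_cohort`."""

    adjustment: Tuple[str, ...] = DEFAULT_ADJUSTMENT
    cutoff: float = 85.0
    horizon_days: float = HORIZON_DAYS
    #: POCE models get a separate baseline hazard per diabetes level
    poce_strata: Optional[str] = "diabetes"
    #: endpoints with fewer events fall back to univariate models
    min_events_for_adjustment: int = 15


def _exposure_columns(cohort: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    out = cohort.copy()
    out["group_high"] = (out["ics"] >= cutoff).astype(float)
    out["ics_per100"] = out["ics"] / 100.0
    out["vessel_lad"] = (out["study_vessel"] == "LAD").astype(float)
    return out


def _fit_endpoint_model(events, cov, exposure, adjustment, cause_def,
                        tv, strata, min_events) -> Dict[str, object]:
    n_events = int(_event_indicator(events, cause_def, tv).sum())
    adjusted = n_events >= min_events
    cols = ["id", exposure] + ([c for c in adjustment if c != strata] if adjusted else [])
    if adjusted and strata:
        cols.append(strata)
    try:
        fit = cox_fit(events, cov[cols], cause_def=cause_def,
                      strata=strata if adjusted else None, target_vessel=tv)
    except (ValueError, ConvergenceError) as err:
        return {"error": str(err), "adjusted": adjusted}
    return {
        "hr": float(fit.hr[exposure]),
        "ci_low": float(fit.ci_low[exposure]),
        "ci_high": float(fit.ci_high[exposure]),
        "p": float(fit.p_values[exposure]),
        "adjusted": adjusted,
        "note": None if adjusted else "too few events; univariate model",
    }


def analyze_cohort(cohort: pd.DataFrame, events: pd.DataFrame,
                   config: AnalysisConfig = AnalysisConfig()) -> Dict[str, object]:
    """Run the full prognostic analysis on one cohort.

    Per endpoint: event counts and 6-year cumulative incidence overall
    and by ICS group, plus two cause-specific Cox models (ICS >= cutoff
    group indicator, and ICS per 100 units), adjusted when the endpoint
    has enough events; the POCE models are stratified on diabetes.
    Also includes the sqrt(ICS) screening regression and the POCE
    cumulative-incidence curves per group.  Invariant to row order.
    """
    cohort = cohort.sort_values("id").reset_index(drop=True)
    events = events.sort_values("id").reset_index(drop=True)
    if not np.array_equal(cohort["id"].to_numpy(), events["id"].to_numpy()):
        raise ValueError("cohort and event ids do not match")
    cov = _exposure_columns(cohort, config.cutoff)
    high = cov["group_high"].to_numpy(bool)
    ev_hi, ev_lo = events[high], events[~high]

    report: Dict[str, object] = {"n": len(cohort), "endpoints": {}}
    for name, (cause_def, tv) in ENDPOINTS.items():
        ind = _event_indicator(events, cause_def, tv)
        row: Dict[str, object] = {
            "n_events": int(ind.sum()),
            "n_events_low": int(ind[~high].sum()),
            "n_events_high": int(ind[high].sum()),
        }
        for label, ev_g in (("overall", events), ("low", ev_lo), ("high", ev_hi)):
            # endpoint-specific incidence: other first events compete
            ev_mod = ev_g.copy()
            keep = _event_indicator(ev_g, cause_def, tv)
            ev_mod.loc[~keep & (ev_g["cause"] != "censored"), "cause"] = \
                _competing_relabel(cause_def)
            cif = cif_estimate(ev_mod, causes=cause_def)
            row[f"cum_incidence_{label}"] = cif.incidence_at(config.horizon_days)
        strata = config.poce_strata if name == "poce" else None
        row["model_group"] = _fit_endpoint_model(
            events, cov, "group_high", config.adjustment, cause_def, tv,
            strata, config.min_events_for_adjustment)
        row["model_per100"] = _fit_endpoint_model(
            events, cov, "ics_per100", config.adjustment, cause_def, tv,
            strata, config.min_events_for_adjustment)
        report["endpoints"][name] = row

    # log-rank between groups for POCE
    report["logrank_poce"] = logrank_test(ev_hi, ev_lo, POCE_CAUSES)

    # Table-2-style sqrt(ICS) regression
    candidates = cov[list(SQRT_ICS_CANDIDATES)].astype(float)
    screen = build_multivariate(cov["sqrt_ics"].to_numpy(), candidates)
    report["sqrt_ics_regression"] = {
        "selection": screen.selection_log.to_dict(orient="records"),
        "coefficients": {k: float(v) for k, v in screen.fit.coefficients.items()},
        "ci_low": {k: float(v) for k, v in screen.fit.ci_low.items()},
        "ci_high": {k: float(v) for k, v in screen.fit.ci_high.items()},
        "p_values": {k: float(v) for k, v in screen.fit.p_values.items()},
    }

    # POCE cumulative incidence curves per group
    curves = {}
    for label, ev_g in (("low", ev_lo), ("high", ev_hi)):
        cif = cif_estimate(ev_g, causes=POCE_CAUSES)
        curves[label] = {"times": cif.times.tolist(),
                         "incidence": cif.all_cause_incidence.tolist()}
    report["cif_curves_poce"] = curves
    return report


def _competing_relabel(cause_def: FrozenSet[str]) -> str:
    """A cause label outside ``cause_def`` to mark competing events."""
    for c in CAUSES:
        if c not in cause_def:
            return c
    return "death"


def poce_cumulative_incidence(events: pd.DataFrame,
                              at: float = HORIZON_DAYS) -> float:
    """All-cause POCE cumulative incidence at a time point (Aalen-Johansen)."""
    cif = cif_estimate(events, causes=POCE_CAUSES)
    return cif.incidence_at(at)
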
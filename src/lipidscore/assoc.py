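"""Outcome association under case-cohort, matched and effect-modification designs.

Case-cohort data are analyzed with Prentice-weighted Cox partial likelihood:
subcohort members are at risk over their whole (entry, exit] age interval,
while cases outside the subcohort enter the risk set only immediately before
their own event (their entry time is moved to just below their event age).
Age is the time scale throughout.  Variance is robust by default (dfbeta
sandwich over subjects), with an optional finite-sampling correction when
the subcohort sampling fraction is known.  Ties: Efron (default) or
Breslow.

Matched 1:1 designs use exact conditional logistic regression, which for
pair-matched data reduces to a no-intercept logistic model on within-pair
(case minus control) covariate differences.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PRENTICE_EPS = 1e-4  # age offset placing non-subcohort cases just before their event


@dataclass
class HazardResult:
    term: str
    hr: float
    ci: tuple[float, float]
    log_hr: float
    se: float
    p: float
    n: int
    n_events: int
    model: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.ci
        if not (lo <= self.hr <= hi):
            raise ValueError("confidence interval must bracket the hazard ratio")

    @property
    def percent_risk_reduction(self) -> float:
        return (1.0 - self.hr) * 100.0


@dataclass
class OddsResult:
    term: str
    odds_ratio: float
    ci: tuple[float, float]
    beta: float
    se: float
    p: float
    n_pairs: int
    model: dict = field(default_factory=dict)


def _check_complete(df: pd.DataFrame, cols) -> None:
    bad = [c for c in cols if df[c].isna().any()]
    if bad:
        raise ValueError(f"missing values in model columns (complete-case contract): {bad}")


def _prentice_frame(d: pd.DataFrame, entry_col: str, exit_col: str, event_col: str,
                    subcohort_col: str, eps: float) -> pd.DataFrame:
    df = d.copy()
    non_sub = ~df[subcohort_col].astype(bool)
    if (non_sub & ~df[event_col].astype(bool)).any():
        raise ValueError("non-subcohort rows must all be cases")
    df.loc[non_sub, entry_col] = df.loc[non_sub, exit_col] - eps
    return df


def fit_prentice_cox(d: pd.DataFrame, exposure: str, covariates=(), *,
                     entry_col: str = "entry_age", exit_col: str = "exit_age",
                     event_col: str = "event", subcohort_col: str = "subcohort",
                     ties_method: str = "efron", robust: bool = True,
                     subcohort_fraction: float | None = None,
                     eps: float = PRENTICE_EPS) -> HazardResult:
    """Prentice-weighted Cox regression of an exposure on a case-cohort table.

    If ``subcohort_col`` is absent every row is treated as a subcohort
    member, which reduces the fit to a standard (left-truncated) Cox model.

    Variance: with ``robust=True`` the dfbeta sandwich (infinitesimal
    jackknife over subjects).  When the subcohort sampling fraction of the
    source cohort is supplied, the Self-Prentice-style finite-sampling
    correction of Therneau & Li (1999) is used instead:
    ``V = I^-1 + (1 - fraction) * sum over subcohort members of D_i D_i^T``.
    """
    import statsmodels.duration.hazard_regression as hz

    covariates = list(covariates)
    df = d.copy()
    if subcohort_col not in df.columns:
        df[subcohort_col] = True
    cols = [exposure, *covariates, entry_col, exit_col, event_col, subcohort_col]
    _check_complete(df, cols)
    n_events = int(df[event_col].astype(bool).sum())
    if n_events == 0:
        raise ValueError("no events in the analysis table")
    if ties_method not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method: {ties_method!r}")
    if subcohort_fraction is not None and not (0 < subcohort_fraction <= 1):
        raise ValueError("subcohort_fraction must be in (0, 1]")
    df = _prentice_frame(df, entry_col, exit_col, event_col, subcohort_col, eps)
    exog_cols = [exposure, *covariates]
    exog = df[exog_cols].astype(float)
    mod = hz.PHReg(df[exit_col].astype(float), exog,
                   status=df[event_col].astype(int),
                   entry=df[entry_col].astype(float), ties=ties_method)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PHReg emits benign convergence chatter
        res = mod.fit(maxiter=200)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(f"Cox model failed to converge: params={res.params}")
    i_exp = 0
    info_inv = np.asarray(res.cov_params())
    if robust:
        score_resid = mod.score_residuals(res.params)
        # subjects at risk for no event time have a 0/0 residual; their true
        # score contribution is zero
        score_resid = np.nan_to_num(score_resid, nan=0.0)
        dfbeta = score_resid @ info_inv
        if subcohort_fraction is not None:
            sub_mask = df[subcohort_col].astype(bool).to_numpy()
            d_sub = dfbeta[sub_mask]
            V = info_inv + (1.0 - subcohort_fraction) * (d_sub.T @ d_sub)
        else:
            V = dfbeta.T @ dfbeta
    else:
        V = info_inv
    log_hr = float(res.params[i_exp])
    se = float(np.sqrt(V[i_exp, i_exp]))
    z = stats.norm.ppf(0.975)
    return HazardResult(
        term=exposure, hr=float(np.exp(log_hr)),
        ci=(float(np.exp(log_hr - z * se)), float(np.exp(log_hr + z * se))),
        log_hr=log_hr, se=se, p=float(2 * stats.norm.sf(abs(log_hr / se))),
        n=len(d), n_events=n_events,
        model={"ties": ties_method, "robust": robust, "covariates": covariates,
               "subcohort_fraction": subcohort_fraction,
               "design": "prentice_case_cohort"},
    )


def percent_risk_reduction(hr: HazardResult) -> dict:
    """(1 - HR) x 100 with monotonically transformed CI endpoints."""
    if hr.hr <= 0:
        raise ValueError("hazard ratio must be positive")
    lo, hi = hr.ci
    return {"percent": (1.0 - hr.hr) * 100.0,
            "ci": ((1.0 - hi) * 100.0, (1.0 - lo) * 100.0)}


# ---------------------------------------------------------------------------
# Matched designs
# ---------------------------------------------------------------------------

def _pair_differences(pairs: pd.DataFrame, cols, pair_col: str, case_col: str) -> pd.DataFrame:
    """Case-minus-control differences per matched pair (validates 1:1 strata)."""
    _check_complete(pairs, [*cols, pair_col, case_col])
    sizes = pairs.groupby(pair_col)[case_col].agg(["size", "sum"])
    bad = sizes.index[(sizes["size"] != 2) | (sizes["sum"] != 1)]
    if len(bad):
        raise ValueError(f"stratum {bad[0]!r} is not a 1:1 case-control pair")
    cases = pairs.loc[pairs[case_col] == 1].set_index(pair_col)[list(cols)].sort_index()
    ctrls = pairs.loc[pairs[case_col] == 0].set_index(pair_col)[list(cols)].sort_index()
    return (cases - ctrls).astype(float).reset_index(drop=True)


def _clogit(diffs: pd.DataFrame, exposure: str) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton-Raphson for the 1:1 conditional likelihood on pair differences."""
    X = diffs.to_numpy(dtype=float)
    n, k = X.shape
    if np.allclose(X[:, diffs.columns.get_loc(exposure)], 0):
        raise ValueError("exposure identical within every pair; no information")
    beta = np.zeros(k)
    for _ in range(100):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (1.0 - mu)
        W = mu * (1.0 - mu)
        hess = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("conditional logistic fit is degenerate "
                             "(possible separation or collinear differences)") from exc
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    if np.max(np.abs(beta)) > 30:
        raise ValueError("conditional logistic fit diverged: complete separation")
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    cov = np.linalg.inv((X * W[:, None]).T @ X)
    loglik = float(np.sum(np.log(mu)))
    return beta, np.sqrt(np.diag(cov)), loglik


def fit_conditional_logistic(pairs: pd.DataFrame, exposure: str, covariates=(), *,
                             pair_col: str = "pair_id", case_col: str = "case",
                             standardize: bool = True) -> OddsResult:
    """Conditional logistic regression for 1:1 matched case-control pairs.

    With ``standardize=True`` the exposure is divided by the control-group
    standard deviation, so the odds ratio is per control s.d.
    """
    covariates = list(covariates)
    pairs = pairs.copy()
    sd = 1.0
    if standardize:
        sd = float(pairs.loc[pairs[case_col] == 0, exposure].std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("cannot standardize: control exposure has no variance")
        pairs[exposure] = pairs[exposure] / sd
    cols = [exposure, *covariates]
    diffs = _pair_differences(pairs, cols, pair_col, case_col)
    beta, se, _ = _clogit(diffs, exposure)
    i = cols.index(exposure)
    z = stats.norm.ppf(0.975)
    b, s = float(beta[i]), float(se[i])
    return OddsResult(term=exposure, odds_ratio=float(np.exp(b)),
                      ci=(float(np.exp(b - z * s)), float(np.exp(b + z * s))),
                      beta=b, se=s, p=float(2 * stats.norm.sf(abs(b / s))),
                      n_pairs=len(diffs),
                      model={"covariates": covariates, "standardized": standardize,
                             "exposure_sd": sd})


def change_analysis(pairs: pd.DataFrame, score_t0: str, score_t1: str, covariates=(), *,
                    pair_col: str = "pair_id", case_col: str = "case",
                    timepoints_precede_events_col: str | None = "t2_before_events") -> OddsResult:
    """Odds ratio per s.d. of 10-year score change, adjusted for baseline score.

    Requires both measurements to precede all events (enforced via the flag
    column when present).
    """
    pairs = pairs.copy()
    if timepoints_precede_events_col and timepoints_precede_events_col in pairs.columns:
        if not pairs[timepoints_precede_events_col].astype(bool).all():
            raise ValueError("both score timepoints must precede all events")
    pairs["_delta"] = pairs[score_t1] - pairs[score_t0]
    if float(pairs["_delta"].abs().max()) == 0.0:
        raise ValueError("score change is identically zero; model drops the term")
    res = fit_conditional_logistic(pairs, "_delta", [score_t0, *covariates],
                                   pair_col=pair_col, case_col=case_col,
                                   standardize=True)
    res.model["analysis"] = "10y_change"
    return res


# ---------------------------------------------------------------------------
# Effect modification
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    p_interaction: float
    beta_interaction: float
    strata: dict           # "low"/"high" -> HazardResult | None
    strata_n: dict
    threshold: float


def interaction_and_strata(d: pd.DataFrame, *, arm_col: str = "arm",
                           pre_col: str = "pre_score", post_col: str = "post1_score",
                           covariates=("age", "sex"),
                           strata_covariates=("age", "sex", "bmi"),
                           entry_col: str = "entry_age", exit_col: str = "exit_age",
                           event_col: str = "event", subcohort_col: str = "subcohort") -> InteractionResult:
    """Three-way interaction (pre-score x arm x 1-year score) plus stratified fits.

    The interaction model contains the three main effects, the three-way
    product and the adjustment covariates; its Wald p-value is reported.
    Strata are split at the median pre-intervention score (ties to the low
    stratum) and the arm effect is re-estimated within each stratum.
    A stratum with zero events in either arm is flagged (``None``).
    """
    df = d.copy()
    if subcohort_col not in df.columns:
        df[subcohort_col] = True
    df["_threeway"] = df[pre_col] * df[arm_col] * df[post_col]
    full = fit_prentice_cox(df, "_threeway",
                            [arm_col, pre_col, post_col, *covariates],
                            entry_col=entry_col, exit_col=exit_col,
                            event_col=event_col, subcohort_col=subcohort_col)
    med = float(df[pre_col].median())
    low_mask = df[pre_col] <= med
    strata: dict[str, HazardResult | None] = {}
    sizes: dict[str, int] = {}
    for label, mask in (("low", low_mask), ("high", ~low_mask)):
        sub = df.loc[mask]
        sizes[label] = len(sub)
        events_by_arm = sub.groupby(arm_col)[event_col].sum()
        if len(events_by_arm) < 2 or (events_by_arm == 0).any():
            logger.warning("stratum %r has an arm without events; no estimate", label)
            strata[label] = None
            continue
        strata[label] = fit_prentice_cox(sub, arm_col, list(strata_covariates),
                                         entry_col=entry_col, exit_col=exit_col,
                                         event_col=event_col, subcohort_col=subcohort_col)
    return InteractionResult(p_interaction=full.p, beta_interaction=full.log_hr,
                             strata=strata, strata_n=sizes, threshold=med)


def correlate_score(scores: pd.Series, frame: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Spearman correlation of a score with each column of a covariate/food table."""
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    rows = []
    for col in frame.columns:
        paired = pd.concat([scores, frame[col]], axis=1).dropna()
        n = len(paired)
        if n < 3 or paired[col].nunique() < 2 or paired.iloc[:, 0].nunique() < 2:
            rows.append((col, np.nan, n))
            continue
        rho, _ = stats.spearmanr(paired.iloc[:, 0], paired[col])
        rows.append((col, float(rho), n))
    return pd.DataFrame(rows, columns=["variable", "rho", "n"]).set_index("variable")
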
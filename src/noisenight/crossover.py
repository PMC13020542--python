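"""Mixed models for the crossover endpoints.

All models share the study structure: exposure condition and period (the
chronological night index) as fixed effects and participant as a random
intercept. Four fits are provided:

* :func:`fit_lmm` -- linear mixed model for a numeric outcome; model-based
  condition means and all pairwise differences.
* :func:`fit_glmm_occurrence` -- random-intercept logistic regression for
  heart-rate-peak occurrence after noise peaks; odds ratios per condition
  pair, per period and averaged over periods.
* :func:`fit_before_after` -- linear mixed model for the before/after
  heart-rate delta with exposure x period cell means.
* :func:`fit_vitc_contrast` -- intervention-vs-none difference in FMD
  change per condition and pooled.

Inference uses large-sample (Wald) intervals on the fixed effects; the
random-intercept logistic model is fitted by maximum likelihood with
Gauss-Hermite quadrature over the participant intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.special import logsumexp
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "EffectTable",
    "fit_lmm",
    "fit_glmm_occurrence",
    "fit_before_after",
    "fit_vitc_contrast",
]

Z975 = scipy.stats.norm.ppf(0.975)


@dataclass
class EffectTable:
    """Model-based estimates: level means, pairwise contrasts, metadata."""

    means: pd.DataFrame
    differences: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "means": self.means.to_dict(orient="records"),
            "differences": self.differences.to_dict(orient="records"),
            "metadata": self.metadata,
        }


# ---------------------------------------------------------------------------
# design-matrix helpers


def _levels(values, preferred=("control", "noise30", "noise60")):
    present = list(pd.unique(values))
    ordered = [c for c in preferred if c in present]
    return ordered + sorted(set(present) - set(ordered))


def _design(df, conditions, periods, interaction=False):
    """Treatment-coded design matrix columns for condition + period terms."""
    cols = {"Intercept": np.ones(len(df))}
    for c in conditions[1:]:
        cols[f"cond[{c}]"] = (df["condition"] == c).to_numpy(dtype=float)
    for p in periods[1:]:
        cols[f"period[{p}]"] = (df["period"] == p).to_numpy(dtype=float)
    if interaction:
        for c in conditions[1:]:
            for p in periods[1:]:
                cols[f"cond[{c}]:period[{p}]"] = (
                    cols[f"cond[{c}]"] * cols[f"period[{p}]"]
                )
    return pd.DataFrame(cols, index=df.index)


def _row_vector(columns, condition, period, conditions, periods):
    """Design row for a single (condition, period) cell."""
    row = pd.Series(0.0, index=columns)
    row["Intercept"] = 1.0
    if condition != conditions[0]:
        row[f"cond[{condition}]"] = 1.0
    if period is not None and period != periods[0]:
        key = f"period[{period}]"
        if key in row.index:
            row[key] = 1.0
        ikey = f"cond[{condition}]:period[{period}]"
        if ikey in row.index and condition != conditions[0]:
            row[ikey] = 1.0
    return row.to_numpy()


def _cell_vector(columns, condition, period, conditions, periods):
    """Design row for a cell; period=None averages over observed periods."""
    if period is not None:
        return _row_vector(columns, condition, period, conditions, periods)
    rows = [_row_vector(columns, condition, p, conditions, periods) for p in periods]
    return np.mean(rows, axis=0)


def _wald(est, se):
    if se == 0:
        return est, est, np.nan
    z = est / se
    p = 2 * scipy.stats.norm.sf(abs(z))
    return est - Z975 * se, est + Z975 * se, p


# ---------------------------------------------------------------------------
# linear mixed model core


def _fit_linear_mixed(df, outcome, exog):
    """Fit a participant-random-intercept LMM, with an OLS fallback for
    deterministic (zero-residual) outcomes where the mixed fit is singular."""
    endog = df[outcome].to_numpy(dtype=float)
    meta = {"model": "lmm", "fit_method": "reml", "ci_method": "wald",
            "multiplicity_adjustment": "none"}
    ols = sm.OLS(endog, exog.to_numpy()).fit()
    if ols.ssr < 1e-10 * max(1.0, float(np.sum(endog**2))):
        meta["singular"] = "outcome deterministic given fixed effects; OLS fallback"
        params = pd.Series(ols.params, index=exog.columns)
        cov = pd.DataFrame(0.0, index=exog.columns, columns=exog.columns)
        return params, cov, meta
    model = sm.MixedLM(endog, exog.to_numpy(), groups=df["participant"].to_numpy())
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # boundary/singular-covariance warnings are expected on degenerate
        # inputs and handled explicitly below
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="lbfgs")
        except (np.linalg.LinAlgError, ValueError) as exc:
            meta["singular"] = f"mixed fit failed ({exc}); OLS fallback"
            params = pd.Series(ols.params, index=exog.columns)
            cov = pd.DataFrame(
                ols.cov_params(), index=exog.columns, columns=exog.columns
            )
            return params, cov, meta
    if not res.converged:
        meta["singular"] = "mixed model did not converge"
    k = exog.shape[1]
    participant_var = float(np.asarray(res.cov_re)[0, 0])
    residual_var = float(res.scale)
    # boundary fits (random-intercept variance ~ 0) leave MixedLM with an
    # unusable covariance; the model then reduces to OLS, which we fit with
    # participant-clustered standard errors
    if participant_var < 1e-8 * residual_var:
        meta["singular"] = (
            "random-intercept variance on boundary; OLS with cluster-robust SEs"
        )
        res_ols = sm.OLS(endog, exog.to_numpy()).fit(
            cov_type="cluster", cov_kwds={"groups": df["participant"].to_numpy()}
        )
        params = pd.Series(res_ols.params, index=exog.columns)
        cov = pd.DataFrame(
            res_ols.cov_params(), index=exog.columns, columns=exog.columns
        )
        return params, cov, meta
    params = pd.Series(res.params[:k], index=exog.columns)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k, :k], index=exog.columns, columns=exog.columns
    )
    meta["participant_var"] = participant_var
    meta["residual_var"] = residual_var
    return params, cov, meta


def fit_lmm(cohort: pd.DataFrame, outcome_name: str) -> EffectTable:
    """Linear mixed model for a numeric crossover outcome.

    Fixed effects: condition and period (treatment coded); random intercept
    per participant. Condition means are estimated marginal means averaging
    the period effects over the observed periods; differences cover all
    condition pairs with 95% Wald intervals and p-values.
    """
    if outcome_name not in cohort.columns:
        raise KeyError(f"unknown outcome {outcome_name!r}")
    df = cohort.dropna(subset=[outcome_name])
    conditions = _levels(df["condition"])
    periods = sorted(pd.unique(df["period"]))
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    if df["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")

    exog = _design(df, conditions, periods)
    params, cov, meta = _fit_linear_mixed(df, outcome_name, exog)
    meta["outcome"] = outcome_name

    beta, V = params.to_numpy(), cov.to_numpy()
    mean_rows, diff_rows = [], []
    vectors = {
        c: _cell_vector(exog.columns, c, None, conditions, periods) for c in conditions
    }
    for c in conditions:
        L = vectors[c]
        est = float(L @ beta)
        se = float(np.sqrt(max(L @ V @ L, 0.0)))
        lo, hi, _ = _wald(est, se)
        mean_rows.append(
            {"condition": c, "estimate": est, "se": se, "ci_low": lo, "ci_high": hi}
        )
    for i, a in enumerate(conditions):
        for b in conditions[i + 1 :]:
            L = vectors[a] - vectors[b]
            est = float(L @ beta)
            se = float(np.sqrt(max(L @ V @ L, 0.0)))
            lo, hi, p = _wald(est, se)
            diff_rows.append(
                {
                    "contrast": f"{a} - {b}",
                    "estimate": est,
                    "se": se,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": p,
                }
            )
    return EffectTable(pd.DataFrame(mean_rows), pd.DataFrame(diff_rows), meta)


# ---------------------------------------------------------------------------
# random-intercept logistic GLMM (maximum likelihood, Gauss-Hermite)


def _glmm_nll_factory(y, X, starts, n_nodes=15):
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)

    def nll(theta):
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta0 = X @ beta
        b = np.sqrt(2.0) * sigma * nodes  # (K,)
        eta = eta0[:, None] + b[None, :]  # (n, K)
        ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
        ll_cluster = np.add.reduceat(ll_obs, starts, axis=0)  # (G, K)
        return -float(np.sum(logsumexp(ll_cluster + log_w[None, :], axis=1)))

    return nll


def _fit_logistic_glmm(df, exog, outcome="occurred", n_nodes=15):
    """ML fit of a random-intercept logistic model via adaptive-free
    Gauss-Hermite quadrature; returns (params, cov, metadata)."""
    df = df.sort_values("participant", kind="stable")
    exog = exog.loc[df.index]
    y = df[outcome].to_numpy(dtype=float)
    X = exog.to_numpy(dtype=float)
    groups = df["participant"].to_numpy()
    starts = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])

    meta = {"model": "glmm-logit", "fit_method": "ml-gauss-hermite",
            "ci_method": "wald", "n_quadrature": n_nodes,
            "multiplicity_adjustment": "none"}
    if y.min() == y.max():
        raise ValueError("binary outcome has a single class; cannot fit")
    sep = [
        str(c)
        for c, vals in df.groupby("condition")[outcome].agg(["min", "max"]).iterrows()
        if vals["min"] == vals["max"]
    ]
    if sep:
        meta["separation"] = f"single-class outcome within condition(s): {sep}"

    start_glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    theta0 = np.concatenate([start_glm.params, [0.0]])
    nll = _glmm_nll_factory(y, X, starts, n_nodes=n_nodes)
    opt = scipy.optimize.minimize(nll, theta0, method="BFGS",
                                  options={"gtol": 1e-6, "maxiter": 500})
    if not opt.success:
        opt2 = scipy.optimize.minimize(nll, opt.x, method="Nelder-Mead",
                                       options={"maxiter": 4000, "xatol": 1e-8})
        if opt2.fun < opt.fun:
            opt = opt2
        meta["convergence"] = "fall-back optimizer used"
    hess = approx_hess1(opt.x, nll)
    try:
        cov_all = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(hess)
        meta["singular"] = "Hessian singular; pseudo-inverse covariance"
    k = X.shape[1]
    params = pd.Series(opt.x[:k], index=exog.columns)
    cov = pd.DataFrame(cov_all[:k, :k], index=exog.columns, columns=exog.columns)
    meta["random_intercept_sd"] = float(np.exp(opt.x[-1]))
    meta["loglik"] = -float(opt.fun)
    return params, cov, meta


def fit_glmm_occurrence(response_dataset: pd.DataFrame, outcome: str = "occurred",
                        n_nodes: int = 15) -> EffectTable:
    """Random-intercept logistic model for heart-rate-peak occurrence.

    ``response_dataset`` has one row per (non-excluded) noise peak with
    columns ``participant``, ``period``, ``condition`` and a binary outcome.
    With multiple periods, a condition x period interaction is fitted so the
    odds ratios can be reported per period; the "all" rows average the
    log-odds contrast over periods.
    """
    df = response_dataset.dropna(subset=[outcome]).copy()
    df[outcome] = df[outcome].astype(float)
    conditions = _levels(df["condition"])
    periods = sorted(pd.unique(df["period"]))
    interaction = len(periods) > 1
    exog = _design(df, conditions, periods, interaction=interaction)
    params, cov, meta = _fit_logistic_glmm(df, exog, outcome=outcome, n_nodes=n_nodes)
    meta["outcome"] = outcome

    beta, V = params.to_numpy(), cov.to_numpy()
    period_labels = ([*periods, "all"]) if interaction else ["all"]

    mean_rows, or_rows = [], []
    for c in conditions:
        L = _cell_vector(exog.columns, c, None, conditions, periods)
        est = float(L @ beta)  # log-odds
        se = float(np.sqrt(max(L @ V @ L, 0.0)))
        lo, hi, _ = _wald(est, se)
        mean_rows.append(
            {
                "condition": c,
                "estimate": 1.0 / (1.0 + np.exp(-est)),  # marginal-ish probability
                "log_odds": est,
                "se": se,
                "ci_low": 1.0 / (1.0 + np.exp(-lo)),
                "ci_high": 1.0 / (1.0 + np.exp(-hi)),
            }
        )
    for i, a in enumerate(conditions):
        for b in conditions[i + 1 :]:
            for plab in period_labels:
                period = None if plab == "all" else plab
                La = _cell_vector(exog.columns, a, period, conditions, periods)
                Lb = _cell_vector(exog.columns, b, period, conditions, periods)
                L = La - Lb
                est = float(L @ beta)
                se = float(np.sqrt(max(L @ V @ L, 0.0)))
                lo, hi, p = _wald(est, se)
                or_rows.append(
                    {
                        "contrast": f"{a} / {b}",
                        "period": plab,
                        "odds_ratio": float(np.exp(est)),
                        "log_or": est,
                        "se": se,
                        "ci_low": float(np.exp(lo)),
                        "ci_high": float(np.exp(hi)),
                        "p_value": p,
                    }
                )
    return EffectTable(pd.DataFrame(mean_rows), pd.DataFrame(or_rows), meta)


# ---------------------------------------------------------------------------
# before/after delta and intervention contrast


def fit_before_after(response_dataset: pd.DataFrame, outcome: str = "delta") -> EffectTable:
    """LMM for the after-minus-before heart-rate change at noise peaks.

    Reports the mean delta per exposure x period cell and averaged over
    periods ("all"), plus pairwise exposure differences on the averaged
    scale.
    """
    df = response_dataset.dropna(subset=[outcome]).copy()
    conditions = _levels(df["condition"])
    periods = sorted(pd.unique(df["period"]))
    interaction = len(periods) > 1
    exog = _design(df, conditions, periods, interaction=interaction)
    params, cov, meta = _fit_linear_mixed(df, outcome, exog)
    meta["outcome"] = outcome

    beta, V = params.to_numpy(), cov.to_numpy()
    period_labels = ([*periods, "all"]) if interaction else ["all"]
    mean_rows, diff_rows = [], []
    for c in conditions:
        for plab in period_labels:
            period = None if plab == "all" else plab
            L = _cell_vector(exog.columns, c, period, conditions, periods)
            est = float(L @ beta)
            se = float(np.sqrt(max(L @ V @ L, 0.0)))
            lo, hi, _ = _wald(est, se)
            mean_rows.append(
                {
                    "condition": c,
                    "period": plab,
                    "estimate": est,
                    "se": se,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    for i, a in enumerate(conditions):
        for b in conditions[i + 1 :]:
            La = _cell_vector(exog.columns, a, None, conditions, periods)
            Lb = _cell_vector(exog.columns, b, None, conditions, periods)
            L = La - Lb
            est = float(L @ beta)
            se = float(np.sqrt(max(L @ V @ L, 0.0)))
            lo, hi, p = _wald(est, se)
            diff_rows.append(
                {
                    "contrast": f"{a} - {b}",
                    "estimate": est,
                    "se": se,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": p,
                }
            )
    return EffectTable(pd.DataFrame(mean_rows), pd.DataFrame(diff_rows), meta)


def fit_vitc_contrast(cohort: pd.DataFrame, outcome: str = "fmd_change_pct") -> EffectTable:
    """Intervention-vs-none difference in post-intervention FMD change.

    Fixed effects: condition, intervention flag and their interaction;
    random intercept per participant. Differences are intervention minus
    no-intervention, per condition and pooled over conditions.
    """
    df = cohort.dropna(subset=[outcome]).copy()
    if df["vitc"].nunique() < 2:
        raise ValueError("both intervention groups must be present")
    conditions = _levels(df["condition"])
    cols = {"Intercept": np.ones(len(df)), "vitc": df["vitc"].to_numpy(dtype=float)}
    for c in conditions[1:]:
        cols[f"cond[{c}]"] = (df["condition"] == c).to_numpy(dtype=float)
        cols[f"cond[{c}]:vitc"] = cols[f"cond[{c}]"] * cols["vitc"]
    exog = pd.DataFrame(cols, index=df.index)
    params, cov, meta = _fit_linear_mixed(df, outcome, exog)
    meta["outcome"] = outcome

    beta, V = params.to_numpy(), cov.to_numpy()

    def cell(condition, vitc):
        row = pd.Series(0.0, index=exog.columns)
        row["Intercept"] = 1.0
        row["vitc"] = float(vitc)
        if condition != conditions[0]:
            row[f"cond[{condition}]"] = 1.0
            row[f"cond[{condition}]:vitc"] = float(vitc)
        return row.to_numpy()

    mean_rows, diff_rows = [], []
    for c in conditions:
        for v in (0, 1):
            L = cell(c, v)
            est = float(L @ beta)
            se = float(np.sqrt(max(L @ V @ L, 0.0)))
            lo, hi, _ = _wald(est, se)
            mean_rows.append(
                {
                    "condition": c,
                    "group": "vitc" if v else "none",
                    "estimate": est,
                    "se": se,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    contrast_vectors = {c: cell(c, 1) - cell(c, 0) for c in conditions}
    contrast_vectors["pooled"] = np.mean(
        [contrast_vectors[c] for c in conditions], axis=0
    )
    for label, L in contrast_vectors.items():
        est = float(L @ beta)
        se = float(np.sqrt(max(L @ V @ L, 0.0)))
        lo, hi, p = _wald(est, se)
        diff_rows.append(
            {
                "contrast": f"vitc - none @ {label}",
                "condition": label,
                "estimate": est,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": p,
            }
        )
    return EffectTable(pd.DataFrame(mean_rows), pd.DataFrame(diff_rows), meta)
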
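"""Calibrate input-output models against observed summer concentrations.

Two adjustment routes are fit on the log10 scale:

* the null route (H0): ordinary least squares of log10(observed) on
  log10(predicted export concentration);
* the Vollenweider route (H1–H8): robust nonlinear regression of observed
  concentrations on the generalized input-output form, by iteratively
  reweighted least squares with a Huber psi (tuning constant 1.345,
  the convention of robust M-estimation), free coefficients searched on the
  log scale where they must stay positive.

Each fit reports RMSE of the log10 residuals, the adjusted R-squared of the
observed-vs-predicted regression, and a Gaussian AIC; the hypothesis with
the lowest AIC is selected per nutrient.  A Welch t-test on residual means
between short and long residence-time lakes diagnoses hydrologic bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .models import InputOutputModelSpec, get_model, predict_concentration

logger = logging.getLogger(__name__)

HUBER_TUNING = 1.345
#: Residence-time class bounds (years): first/fourth quartile of the
#: observed lakes, short < 0.04 and long > 0.4.
HRT_SHORT_MAX = 0.04
HRT_LONG_MIN = 0.4

TP_DETECTION_LIMIT = 0.004
TP_SUBSTITUTE = 0.002


class InsufficientDataError(ValueError):
    pass


@dataclass
class FitResult:
    """One calibrated hypothesis for one nutrient."""

    hypothesis_id: str
    nutrient: str
    coefficients: dict
    free: tuple
    residuals: np.ndarray          # log10(obs) - log10(pred)
    predictions: np.ndarray        # mg/L
    rmse: float
    adj_r2: float
    aic: float
    n_obs: int
    converged: bool
    robust_weights: np.ndarray | None = None
    lake_ids: np.ndarray | None = None
    n_iter: int = 0

    @property
    def n_free(self) -> int:
        return len(self.free)


def apply_detection_limit(values, detection_limit=TP_DETECTION_LIMIT,
                          substitute=TP_SUBSTITUTE):
    """Replace below-detection values by a fixed substitute.

    Returns ``(adjusted_values, below_detection_flags)``.  Values strictly
    below the limit are substituted; values at the limit are kept.
    """
    if substitute <= 0:
        raise ValueError("substitute must be positive")
    vals = np.asarray(values, dtype=float)
    flags = vals < detection_limit
    out = np.where(flags, substitute, vals)
    return out, flags


def goodness_of_fit(obs, pred, rmse_from_regression: bool = False):
    """RMSE of log10 residuals and adjusted R² of log10(obs) ~ log10(pred).

    With ``rmse_from_regression`` the RMSE is the residual standard error of
    that regression instead of the raw prediction residuals.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if len(obs) < 3:
        raise InsufficientDataError("need at least 3 observations")
    lo, lp = np.log10(obs), np.log10(pred)
    ols = sm.OLS(lo, sm.add_constant(lp)).fit()
    if rmse_from_regression:
        rmse = float(np.sqrt(ols.ssr / ols.df_resid))
    else:
        rmse = float(np.sqrt(np.mean((lo - lp) ** 2)))
    return rmse, float(ols.rsquared_adj)


def aic_of_fit(residuals, n_free: int):
    """Gaussian AIC on log10 residuals: n ln(RSS/n) + 2 (p + 1).

    ``n_free`` is the number of estimated model coefficients; the +1 counts
    the residual variance.  Model ranking is unchanged by the constant
    n ln(2 pi) + n omitted here.
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    rss = float(r @ r)
    if rss <= 0:
        logger.warning("zero residual sum of squares; AIC is -inf")
        return float("-inf")
    return n * np.log(rss / n) + 2 * (n_free + 1)


def fit_linear_adjustment(obs, pred_out, lake_ids=None, nutrient="N"):
    """OLS adjustment of log10(observed) on log10(export concentration).

    Returns ``(intercept, slope, FitResult)`` where the FitResult's
    predictions are the back-transformed fitted values.  This is the H0
    route: the lake concentration is the export concentration, linearly
    adjusted on the log scale for seasonal and inter-annual offset.
    """
    obs = np.asarray(obs, dtype=float)
    pred_out = np.asarray(pred_out, dtype=float)
    if len(obs) < 3:
        raise InsufficientDataError("need at least 3 observations")
    lx = np.log10(pred_out)
    if np.ptp(lx) == 0:
        raise np.linalg.LinAlgError("zero variance in predictor: singular fit")
    ols = sm.OLS(np.log10(obs), sm.add_constant(lx)).fit()
    intercept, slope = float(ols.params[0]), float(ols.params[1])
    adjusted = 10.0 ** ols.fittedvalues
    residuals = np.log10(obs) - np.log10(adjusted)
    rmse, adj_r2 = goodness_of_fit(obs, adjusted)
    fit = FitResult(
        hypothesis_id="H0", nutrient=nutrient,
        coefficients={"intercept": intercept, "slope": slope},
        free=("intercept", "slope"),
        residuals=residuals, predictions=np.asarray(adjusted),
        rmse=rmse, adj_r2=adj_r2,
        aic=aic_of_fit(residuals, 2), n_obs=len(obs), converged=True,
        lake_ids=None if lake_ids is None else np.asarray(lake_ids),
    )
    return intercept, slope, fit


def _pack(spec: InputOutputModelSpec, coefs: dict):
    theta = []
    for name in spec.free:
        v = coefs[name]
        theta.append(np.log(v) if name in spec.positive else v)
    return np.asarray(theta, dtype=float)


def _unpack(spec: InputOutputModelSpec, theta):
    coefs = spec.coefficients()
    for name, v in zip(spec.free, theta):
        coefs[name] = float(np.exp(v)) if name in spec.positive else float(v)
    return coefs


def _huber_weights(resid, tuning):
    s = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if s < 1e-12:
        return np.ones_like(resid), s
    u = np.abs(resid / s)
    with np.errstate(divide="ignore"):
        w = np.where(u <= tuning, 1.0, tuning / u)
    return w, s


def robust_fit(spec: InputOutputModelSpec, obs, conc_in, tau_yr, z_m,
               lake_ids=None, nutrient="N", init=None,
               tuning: float = HUBER_TUNING, max_iter: int = 50,
               tol: float = 1e-8) -> FitResult:
    """Huber IRLS fit of one input-output model to observed concentrations.

    Residuals are on the log10 scale.  Each outer iteration solves a
    weighted nonlinear least-squares problem (scipy ``least_squares``) and
    re-derives Huber weights from the MAD-scaled residuals; convergence is
    declared when the largest coefficient change drops below ``tol``.
    Deterministic for fixed inputs and starting values.
    """
    obs = np.asarray(obs, dtype=float)
    conc_in = np.asarray(conc_in, dtype=float)
    tau_yr = np.asarray(tau_yr, dtype=float)
    z_m = np.asarray(z_m, dtype=float)
    if len(obs) < max(3, spec.n_free + 1):
        raise InsufficientDataError("too few observations for the free coefficients")
    log_obs = np.log10(obs)

    start = dict(spec.coefficients())
    if init:
        start.update(init)
    theta = _pack(spec, start)

    def log_residuals(th):
        coefs = _unpack(spec, th)
        pred = predict_concentration(spec.with_coefficients(**coefs),
                                     conc_in, tau_yr, z_m)
        return log_obs - np.log10(pred)

    if spec.n_free == 0:
        resid = log_residuals(theta)
        weights = np.ones_like(resid)
        converged, it = True, 0
    else:
        weights = np.ones_like(log_obs)
        converged, it = False, 0
        for it in range(1, max_iter + 1):
            sw = np.sqrt(weights)
            sol = scipy.optimize.least_squares(
                lambda th: sw * log_residuals(th), theta, method="lm")
            resid = log_residuals(sol.x)
            weights, scale = _huber_weights(resid, tuning)
            step = np.max(np.abs(sol.x - theta))
            theta = sol.x
            if step < tol or scale < 1e-12:
                converged = True
                break
        resid = log_residuals(theta)

    coefs = _unpack(spec, theta)
    pred = predict_concentration(spec.with_coefficients(**coefs),
                                 conc_in, tau_yr, z_m)
    rmse, adj_r2 = goodness_of_fit(obs, pred)
    if not converged:
        logger.warning("%s/%s did not converge in %d iterations",
                       spec.hypothesis_id, nutrient, max_iter)
    return FitResult(
        hypothesis_id=spec.hypothesis_id, nutrient=nutrient,
        coefficients=coefs, free=spec.free,
        residuals=resid, predictions=np.asarray(pred),
        rmse=rmse, adj_r2=adj_r2,
        aic=aic_of_fit(resid, spec.n_free),
        n_obs=len(obs), converged=converged,
        robust_weights=weights,
        lake_ids=None if lake_ids is None else np.asarray(lake_ids),
        n_iter=it,
    )


def fit_hypothesis(hypothesis_id: str, data: pd.DataFrame, nutrient: str = "N",
                   **kwargs) -> FitResult:
    """Fit one hypothesis to a calibration table.

    ``data`` needs columns ``obs``, ``conc_in``, ``conc_out``, ``tau_yr``,
    ``z_mean_m`` and optionally ``lake_id``.  H0 dispatches to the linear
    adjustment; H1–H8 to the robust nonlinear fit.
    """
    ids = data["lake_id"].to_numpy() if "lake_id" in data else None
    if hypothesis_id == "H0":
        _, _, fit = fit_linear_adjustment(data["obs"], data["conc_out"],
                                          lake_ids=ids, nutrient=nutrient)
        return fit
    spec = get_model(hypothesis_id)
    return robust_fit(spec, data["obs"], data["conc_in"], data["tau_yr"],
                      data["z_mean_m"], lake_ids=ids, nutrient=nutrient, **kwargs)


def fit_all_hypotheses(data: pd.DataFrame, nutrient: str = "N",
                       hypotheses=None, **kwargs) -> dict:
    """Fit every requested hypothesis; returns {hypothesis_id: FitResult}."""
    hypotheses = list(hypotheses) if hypotheses is not None else \
        [f"H{i}" for i in range(9)]
    return {h: fit_hypothesis(h, data, nutrient, **({} if h == "H0" else kwargs))
            for h in hypotheses}


def fit_report(fits_by_nutrient: dict) -> pd.DataFrame:
    """Model-selection report: one row per hypothesis x nutrient."""
    rows = []
    for nutrient, fits in fits_by_nutrient.items():
        for hid in sorted(fits):
            f = fits[hid]
            rows.append({"hypothesis": hid, "nutrient": nutrient,
                         "rmse": f.rmse, "adj_r2": f.adj_r2, "aic": f.aic,
                         "n_obs": f.n_obs, "converged": f.converged})
    return pd.DataFrame(rows)


def select_best(fits: dict) -> str:
    """Hypothesis id with the lowest AIC among converged fits.

    Ties break toward fewer free coefficients, then lexically.  Raises if
    nothing converged; warns when only a single converged fit is available.
    """
    converged = {h: f for h, f in fits.items() if f.converged}
    if not converged:
        raise ValueError("no converged fits to select from")
    if len(converged) == 1:
        only = next(iter(converged))
        logger.warning("only one converged fit (%s); selecting it", only)
        return only
    return min(converged, key=lambda h: (converged[h].aic,
                                         converged[h].n_free, h))


@dataclass
class HrtBiasReport:
    """Welch t-test of residual means, short vs long residence-time lakes."""

    n_short: int
    n_long: int
    mean_short: float
    mean_long: float
    sd_short: float
    sd_long: float
    t: float
    df: float
    p: float
    skipped: bool = False


def residual_hrt_bias_test(residuals, tau_values, short_max: float = HRT_SHORT_MAX,
                           long_min: float = HRT_LONG_MIN) -> HrtBiasReport:
    """Compare residual means between short- and long-residence-time lakes.

    Welch's two-sample t-test (unequal variances, fractional degrees of
    freedom).  A systematic difference means the model mishandles
    residence-time-dependent retention.  Returns a report with the test
    skipped when either class has fewer than two lakes.
    """
    residuals = np.asarray(residuals, dtype=float)
    tau = np.asarray(tau_values, dtype=float)
    short = residuals[tau < short_max]
    long_ = residuals[tau > long_min]
    stats = dict(
        n_short=len(short), n_long=len(long_),
        mean_short=float(np.mean(short)) if len(short) else float("nan"),
        mean_long=float(np.mean(long_)) if len(long_) else float("nan"),
        sd_short=float(np.std(short, ddof=1)) if len(short) > 1 else float("nan"),
        sd_long=float(np.std(long_, ddof=1)) if len(long_) > 1 else float("nan"),
    )
    if len(short) < 2 or len(long_) < 2:
        logger.warning("HRT bias test skipped: group sizes %d/%d",
                       len(short), len(long_))
        return HrtBiasReport(**stats, t=float("nan"), df=float("nan"),
                             p=float("nan"), skipped=True)
    res = scipy.stats.ttest_ind(short, long_, equal_var=False)
    return HrtBiasReport(**stats, t=float(res.statistic), df=float(res.df),
                         p=float(res.pvalue))


def improvement_summary(fit_linear: FitResult, fit_vw: FitResult) -> float:
    """Percentage-point gain in adjusted R² of the Vollenweider route over
    the linear adjustment, on the same lakes."""
    if fit_linear.n_obs != fit_vw.n_obs:
        raise ValueError("fits cover different lake sets")
    if fit_linear.lake_ids is not None and fit_vw.lake_ids is not None:
        if not np.array_equal(fit_linear.lake_ids, fit_vw.lake_ids):
            raise ValueError("fits cover different lake sets")
    return 100.0 * (fit_vw.adj_r2 - fit_linear.adj_r2)


def build_calibration_table(observed: pd.DataFrame, lakes: pd.DataFrame,
                            nutrient: str = "N") -> pd.DataFrame:
    """Join observed concentrations to aggregated lake attributes.

    ``observed`` needs ``lake_id`` and ``obs_TN``/``obs_TP`` (mg/L);
    ``lakes`` is the budget table with morphometry attached.  TP values are
    passed through the detection-limit substitution.  Rows lacking a defined
    conc_in, conc_out, tau or z are dropped (and counted in the log).
    """
    col = {"N": "obs_TN", "P": "obs_TP"}[nutrient]
    merged = observed.merge(lakes, on="lake_id", how="inner")
    obs = merged[col].to_numpy(dtype=float)
    if nutrient == "P":
        obs, flags = apply_detection_limit(obs)
        merged["below_detection"] = flags
    merged["obs"] = obs
    merged["conc_in"] = merged[f"conc_in_{nutrient}"]
    merged["conc_out"] = merged[f"conc_out_{nutrient}"]
    keep = ["lake_id", "obs", "conc_in", "conc_out", "tau_yr", "z_mean_m"]
    for extra in ("design_weight", "is_probability_sample", "below_detection"):
        if extra in merged:
            keep.append(extra)
    out = merged[keep]
    usable = out.dropna(subset=["obs", "conc_in", "conc_out", "tau_yr", "z_mean_m"])
    usable = usable[(usable["obs"] > 0) & (usable["conc_in"] > 0)
                    & (usable["conc_out"] > 0) & (usable["tau_yr"] > 0)
                    & (usable["z_mean_m"] > 0)]
    if len(usable) < len(out):
        logger.info("calibration table: dropped %d of %d lakes with undefined inputs",
                    len(out) - len(usable), len(out))
    return usable.reset_index(drop=True)
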
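"""Population-level assessment: design-weighted CDFs and trophic state.

Survey observations carry design weights (inverse inclusion probabilities);
the population cumulative distribution of a concentration is estimated with
the Horvitz–Thompson weighted proportion, with a normal-approximation 95%
confidence band.  Trophic state follows the national lake-survey
convention of inclusive upper concentration bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TROPHIC_CLASSES = ("oligotrophic", "mesotrophic", "eutrophic", "hypereutrophic")


@dataclass(frozen=True)
class TrophicThresholds:
    """Inclusive upper bounds (mg/L) for oligo-, meso- and eutrophic lakes."""

    nutrient: str
    oligo_max: float
    meso_max: float
    eu_max: float

    def __post_init__(self):
        if not (0 < self.oligo_max < self.meso_max < self.eu_max):
            raise ValueError("thresholds must be strictly increasing and positive")


#: 2007 National Lake Assessment conventions.
DEFAULT_THRESHOLDS = {
    "N": TrophicThresholds("N", 0.35, 0.75, 1.4),
    "P": TrophicThresholds("P", 0.010, 0.025, 0.050),
}


@dataclass
class WeightedCDF:
    support: np.ndarray     # mg/L, increasing
    cdf: np.ndarray         # estimates in [0, 1], nondecreasing
    lo95: np.ndarray
    hi95: np.ndarray

    def at(self, x):
        """Step-function evaluation (right-continuous)."""
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float), side="right") - 1
        out = np.where(idx >= 0, self.cdf[np.clip(idx, 0, None)], 0.0)
        return float(out) if out.ndim == 0 else out


def weighted_cdf(values, weights=None, support=None, z_crit: float = 1.959964) -> WeightedCDF:
    """Horvitz–Thompson estimate of the population CDF.

    F_hat(x) = sum(w_i 1[v_i <= x]) / sum(w_i).  The 95% band uses the
    normal approximation with the estimated variance of the weighted
    proportion, var_hat = sum(w_i^2 (1[v_i<=x] - F_hat)^2) / (sum w_i)^2,
    clamped to [0, 1].  Equal weights reduce to the empirical CDF.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    if np.any(values <= 0):
        raise ValueError("values must be positive")
    if support is None:
        support = np.unique(values)
    support = np.asarray(support, dtype=float)

    wsum = weights.sum()
    ind = values[None, :] <= support[:, None]          # (m, n)
    cdf = (ind * weights).sum(axis=1) / wsum
    var = ((weights ** 2)[None, :] * (ind - cdf[:, None]) ** 2).sum(axis=1) / wsum ** 2
    half = z_crit * np.sqrt(var)
    return WeightedCDF(
        support=support, cdf=cdf,
        lo95=np.clip(cdf - half, 0.0, 1.0),
        hi95=np.clip(cdf + half, 0.0, 1.0),
    )


def cdf_within_band(cdf_test: WeightedCDF, cdf_ref: WeightedCDF) -> float:
    """Fraction of the reference support where the test CDF lies inside the
    reference 95% band.  Mismatched supports are evaluated on the reference
    support via the test CDF's step function."""
    if not np.array_equal(cdf_test.support, cdf_ref.support):
        logger.info("cdf_within_band: interpolating test CDF onto reference support")
    test_vals = cdf_test.at(cdf_ref.support)
    inside = (test_vals >= cdf_ref.lo95) & (test_vals <= cdf_ref.hi95)
    return float(np.mean(inside))


def trophic_state(conc, thresholds: TrophicThresholds):
    """Classify concentrations (mg/L) into trophic classes.

    Bounds are inclusive upper limits: oligotrophic if conc <= oligo_max,
    mesotrophic if <= meso_max, eutrophic if <= eu_max, else hypereutrophic.
    """
    arr = np.asarray(conc, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("concentrations must be positive")
    bins = np.array([thresholds.oligo_max, thresholds.meso_max, thresholds.eu_max])
    idx = np.searchsorted(bins, arr, side="left")
    out = np.array(TROPHIC_CLASSES, dtype=object)[idx]
    return str(out) if arr.ndim == 0 else out


def population_summary(predictions: pd.DataFrame, morphometry: pd.DataFrame | None = None,
                       min_area_m2: float | None = None,
                       min_zmax_m: float | None = None,
                       thresholds: TrophicThresholds | None = None,
                       nutrient: str = "N") -> dict:
    """Trophic class counts and retention statistics for a lake population.

    ``predictions`` is the output of ``predict_population`` (lake_id,
    conc_pred, retention_pct).  Optional area/maximum-depth filters restrict
    to lakes consistent with the survey design (e.g. area >= 4 ha, zmax >=
    1 m); lakes missing the morphometry needed by a requested filter are
    dropped and counted.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS[nutrient]
    df = predictions
    n_dropped_missing = 0
    if min_area_m2 is not None or min_zmax_m is not None:
        if morphometry is None:
            raise ValueError("filters requested but no morphometry given")
        df = df.merge(morphometry[["lake_id", "area_m2", "zmax_m"]],
                      on="lake_id", how="left")
        mask = pd.Series(True, index=df.index)
        if min_area_m2 is not None:
            ok = df["area_m2"].notna()
            mask &= ok & (df["area_m2"] >= min_area_m2)
            n_dropped_missing += int((~ok).sum())
        if min_zmax_m is not None:
            ok = df["zmax_m"].notna()
            mask &= ok & (df["zmax_m"] >= min_zmax_m)
            n_dropped_missing += int((~ok).sum())
        if n_dropped_missing:
            logger.info("population_summary: %d lakes lacked morphometry for a filter",
                        n_dropped_missing)
        df = df.loc[mask]

    classes = trophic_state(df["conc_pred"].to_numpy(), thresholds) if len(df) \
        else np.array([], dtype=object)
    counts = {cls: int(np.sum(classes == cls)) for cls in TROPHIC_CLASSES}
    ret = df["retention_pct"].to_numpy(dtype=float)
    return {
        "n": int(len(df)),
        "n_dropped_missing_morphometry": n_dropped_missing,
        "class_counts": counts,
        "retention_mean_pct": float(np.mean(ret)) if len(ret) else float("nan"),
        "retention_median_pct": float(np.median(ret)) if len(ret) else float("nan"),
        "retention_sd_pct": float(np.std(ret, ddof=1)) if len(ret) > 1 else float("nan"),
    }
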
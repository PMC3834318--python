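"""Generalized Vollenweider (input-output) lake nutrient models.

Every hypothesis in the catalog is an instance of one functional form

    C_lake = g * C_in * tau**e * z**f / (1 + a * tau**b * z**c * C_in**d)

where C_in is the inflow concentration (mg/L), tau the hydraulic residence
time (years) and z the mean depth (m).  The null model H0 (lake
concentration equals the export concentration) is the one special case.
Literature coefficients are the catalog defaults; the recalibrated
H6 coefficient vectors for total nitrogen and total phosphorus in
northeastern lakes are available as the presets ``Eq1`` and ``Eq2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

logger = logging.getLogger(__name__)

COEF_NAMES = ("g", "e", "f", "a", "b", "c", "d")


@dataclass(frozen=True)
class InputOutputModelSpec:
    """Coefficients of the generalized input-output form for one hypothesis.

    ``free`` names the coefficients estimated during calibration; the rest
    stay fixed at their literature values.  ``positive`` names free
    coefficients constrained positive (searched on the log scale).
    """

    hypothesis_id: str
    g: float = 1.0
    e: float = 0.0
    f: float = 0.0
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    free: tuple = ()
    positive: tuple = ()
    nutrient: str | None = None

    @property
    def n_free(self) -> int:
        return len(self.free)

    def coefficients(self) -> dict:
        return {k: getattr(self, k) for k in COEF_NAMES}

    def with_coefficients(self, **updates) -> "InputOutputModelSpec":
        unknown = set(updates) - set(COEF_NAMES)
        if unknown:
            raise ValueError(f"unknown coefficients: {sorted(unknown)}")
        return replace(self, **updates)


def model_catalog() -> dict:
    """All hypotheses H0–H8 with literature starting coefficients.

    H0 predicts the lake concentration directly from the export
    concentration.  H1–H6 are retention-denominator models (prediction never
    exceeds the input concentration); H7–H8 are product-form models for
    nitrogen and may exceed it at short residence times.
    """
    cat = {
        "H0": InputOutputModelSpec("H0"),
        # C_in / (1 + 0.45 tau)
        "H1": InputOutputModelSpec("H1", a=0.45, b=1.0, free=("a",), positive=("a",)),
        # C_in / (1 + 1.06): constant retention
        "H2": InputOutputModelSpec("H2", a=1.06, free=("a",), positive=("a",)),
        # C_in / (1 + 5.1 tau / z): apparent-settling-velocity form
        "H3": InputOutputModelSpec("H3", a=5.1, b=1.0, c=-1.0, free=("a",), positive=("a",)),
        # C_in / (1 + 1.12 tau^0.53)
        "H4": InputOutputModelSpec("H4", a=1.12, b=0.53, free=("a", "b"), positive=("a", "b")),
        # 0.65 C_in / (1 + 0.17 tau)
        "H5": InputOutputModelSpec("H5", g=0.65, a=0.17, b=1.0,
                                   free=("g", "a"), positive=("g", "a")),
        # C_in / (1 + 3.0 tau^0.25 z^0.58 C_in^0.53)
        "H6": InputOutputModelSpec("H6", a=3.0, b=0.25, c=0.58, d=0.53,
                                   free=("a", "b", "c", "d"),
                                   positive=("a", "b", "c", "d")),
        # 0.32 C_in tau^-0.18
        "H7": InputOutputModelSpec("H7", g=0.32, e=-0.18, free=("g", "e"), positive=("g",)),
        # 0.27 C_in tau^-0.22 z^-0.12
        "H8": InputOutputModelSpec("H8", g=0.27, e=-0.22, f=-0.12,
                                   free=("g", "e", "f"), positive=("g",)),
    }
    return cat


def get_model(hypothesis_id: str) -> InputOutputModelSpec:
    cat = model_catalog()
    if hypothesis_id not in cat:
        raise KeyError(f"no such hypothesis: {hypothesis_id!r}")
    return cat[hypothesis_id]


#: Recalibrated H6 models for northeastern lakes (the paper's Eq. 1 and 2).
PRESETS = {
    "Eq1": InputOutputModelSpec("H6", a=2.0, b=0.38, c=0.29, d=1.14,
                                free=("a", "b", "c", "d"),
                                positive=("a", "b", "c", "d"), nutrient="N"),
    "Eq2": InputOutputModelSpec("H6", a=89.0, b=0.40, c=0.57, d=1.08,
                                free=("a", "b", "c", "d"),
                                positive=("a", "b", "c", "d"), nutrient="P"),
}


def predict_concentration(spec: InputOutputModelSpec, conc_in, tau_yr=None,
                          z_m=None, conc_out=None):
    """Evaluate one model, returning predicted lake concentration in mg/L.

    H0 requires ``conc_out``; every other hypothesis requires ``conc_in``
    plus ``tau_yr``/``z_m`` wherever the corresponding exponent is nonzero.
    Raises ``ValueError`` on nonpositive tau/z where an exponent is nonzero.
    """
    if spec.hypothesis_id == "H0":
        if conc_out is None:
            raise TypeError("H0 requires conc_out")
        out = np.asarray(conc_out, dtype=float)
        return float(out) if out.ndim == 0 else out

    conc_in = np.asarray(conc_in, dtype=float)
    scalar = conc_in.ndim == 0
    if np.any(conc_in <= 0):
        raise ValueError("conc_in must be positive")

    def _check(name, value, *exponents):
        if all(x == 0 for x in exponents):
            return np.ones_like(conc_in)
        if value is None:
            raise TypeError(f"{spec.hypothesis_id} requires {name}")
        arr = np.asarray(value, dtype=float)
        if np.any(arr <= 0):
            raise ValueError(f"{name} must be positive for {spec.hypothesis_id}")
        return arr

    tau = _check("tau_yr", tau_yr, spec.e, spec.b)
    z = _check("z_m", z_m, spec.f, spec.c)

    numer = spec.g * conc_in * tau ** spec.e * z ** spec.f
    denom = 1.0 + spec.a * tau ** spec.b * z ** spec.c * conc_in ** spec.d
    pred = numer / denom
    return float(pred) if scalar else pred


def retention_percent(conc_in, conc_pred):
    """Percent of the nutrient input retained: 100 (C_in - C_pred) / C_in.

    Valid as a mass fraction because water is conserved (inflow equals
    outflow).  Negative values (prediction above input, possible for the
    product-form models) are returned unclamped and logged.
    """
    conc_in = np.asarray(conc_in, dtype=float)
    if np.any(conc_in <= 0):
        raise ValueError("conc_in must be positive")
    pct = 100.0 * (conc_in - np.asarray(conc_pred, dtype=float)) / conc_in
    if np.any(pct < 0):
        logger.info("negative retention for %d lakes (prediction exceeds input)",
                    int(np.sum(pct < 0)))
    return float(pct) if pct.ndim == 0 else pct


def predict_population(spec, lakes, nutrient: str = "N"):
    """Predict concentrations and retention for a population table.

    ``lakes`` needs columns ``lake_id``, ``conc_in_<nutrient>``, ``tau_yr``
    and ``z_mean_m`` (e.g. the output of
    :func:`lakeloads.network.attach_morphometry`).  Lakes with undefined
    inputs are returned separately as rejects.

    Returns ``(predictions, rejects, summary)`` where predictions has
    columns ``lake_id, conc_in, conc_pred, retention_pct`` and summary holds
    mean/median/sd of retention.
    """
    import pandas as pd

    cols = ["lake_id", f"conc_in_{nutrient}", "tau_yr", "z_mean_m"]
    if len(lakes) == 0:
        logger.warning("predict_population called with empty input")
        empty = pd.DataFrame(columns=["lake_id", "conc_in", "conc_pred", "retention_pct"])
        return empty, lakes.copy(), {"n": 0}

    ok = (
        lakes[f"conc_in_{nutrient}"].gt(0)
        & lakes["tau_yr"].gt(0)
        & lakes["z_mean_m"].gt(0)
    ).fillna(False)
    usable = lakes.loc[ok, cols]
    rejects = lakes.loc[~ok]

    pred = predict_concentration(
        spec,
        usable[f"conc_in_{nutrient}"].to_numpy(),
        usable["tau_yr"].to_numpy(),
        usable["z_mean_m"].to_numpy(),
    )
    ret = retention_percent(usable[f"conc_in_{nutrient}"].to_numpy(), pred)
    predictions = pd.DataFrame({
        "lake_id": usable["lake_id"].to_numpy(),
        "conc_in": usable[f"conc_in_{nutrient}"].to_numpy(),
        "conc_pred": pred,
        "retention_pct": ret,
    })
    summary = {
        "n": int(len(predictions)),
        "n_rejected": int(len(rejects)),
        "retention_mean_pct": float(np.mean(ret)) if len(ret) else float("nan"),
        "retention_median_pct": float(np.median(ret)) if len(ret) else float("nan"),
        "retention_sd_pct": float(np.std(ret, ddof=1)) if len(ret) > 1 else float("nan"),
    }
    return predictions, rejects, summary


def spec_to_dict(spec: InputOutputModelSpec) -> dict:
    d = {"hypothesis_id": spec.hypothesis_id, **spec.coefficients(),
         "free": list(spec.free), "positive": list(spec.positive)}
    if spec.nutrient:
        d["nutrient"] = spec.nutrient
    return d


def dump_catalog(path, catalog=None) -> None:
    """Serialize a model catalog to YAML so users can add variants."""
    catalog = catalog if catalog is not None else model_catalog()
    with open(path, "w") as fh:
        yaml.safe_dump({k: spec_to_dict(v) for k, v in catalog.items()}, fh,
                       sort_keys=True)


def load_catalog(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for key, d in raw.items():
        out[key] = InputOutputModelSpec(
            hypothesis_id=d["hypothesis_id"],
            **{k: float(d.get(k, 0.0)) for k in COEF_NAMES},
            free=tuple(d.get("free", ())),
            positive=tuple(d.get("positive", ())),
            nutrient=d.get("nutrient"),
        )
    return out
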
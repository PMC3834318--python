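"""CSV readers/writers and pipeline configuration.

All interchange is plain CSV.  Input tables use NHDPlus/SPARROW-style
headers (case-insensitive); readers validate the schema, reject rows with
negative loads or unparsable numbers (logged with their line numbers), and
map to the column names the library uses internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """An input table is missing a required column."""


FLOW_HEADERS = {"FROMCOMID": "from_reach", "TOCOMID": "to_reach"}
REACH_HEADERS = {
    "COMID": "reach_id", "WB_ID": "lake_id",
    "TOT_N_KGYR": "total_load_N", "INC_N_KGYR": "incremental_load_N",
    "TOT_P_KGYR": "total_load_P", "INC_P_KGYR": "incremental_load_P",
    "FLOW_CFS": "flow_cfs",
}
MORPHO_HEADERS = {"WB_ID": "lake_id", "AREA_M2": "area_m2",
                  "VOLUME_M3": "volume_m3", "ZMAX_M": "zmax_m"}
OBSERVED_HEADERS = {"LAKE_ID": "lake_id", "TN_MGL": "obs_TN", "TP_MGL": "obs_TP",
                    "WEIGHT": "design_weight", "PROB_SAMPLE": "is_probability_sample"}


def _read_mapped(path, header_map: dict, id_cols=()) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str, skipinitialspace=True)
    upper = {c.upper().strip(): c for c in df.columns}
    missing = [h for h in header_map if h not in upper]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    out = pd.DataFrame()
    for header, name in header_map.items():
        col = df[upper[header]]
        if name in id_cols:
            col = col.where(col.notna() & (col.str.strip() != ""), None)
            out[name] = col
        else:
            out[name] = pd.to_numeric(col, errors="coerce")
    logger.info("read %s: %d rows, %d columns", path, len(out), len(out.columns))
    return out


def read_flow_table(path) -> pd.DataFrame:
    """Edge table: FROMCOMID, TOCOMID (IDs kept as opaque strings)."""
    out = _read_mapped(path, FLOW_HEADERS, id_cols=("from_reach", "to_reach"))
    return out.dropna().reset_index(drop=True)


def read_reach_table(path) -> pd.DataFrame:
    """Reach attributes; rows with negative or unparsable loads are dropped."""
    out = _read_mapped(path, REACH_HEADERS, id_cols=("reach_id", "lake_id"))
    numeric = [c for c in out.columns if c not in ("reach_id", "lake_id")]
    bad = out[numeric].isna().any(axis=1) | (out[numeric] < 0).any(axis=1)
    for i in out.index[bad]:
        logger.warning("%s line %d: negative or unparsable value; row rejected",
                       path, i + 2)
    return out.loc[~bad].reset_index(drop=True)


def read_morphometry(path) -> pd.DataFrame:
    return _read_mapped(path, MORPHO_HEADERS, id_cols=("lake_id",))


def read_observed(path) -> pd.DataFrame:
    out = _read_mapped(path, OBSERVED_HEADERS,
                       id_cols=("lake_id", "is_probability_sample"))
    out["is_probability_sample"] = (
        out["is_probability_sample"].astype(str).str.strip().str.lower()
        .isin(("1", "true", "yes", "t"))
    )
    return out


_WRITERS = {
    "flow_table": ({"from_reach": "FROMCOMID", "to_reach": "TOCOMID"}, None),
    "reach_table": ({v: k for k, v in REACH_HEADERS.items()},
                    "# loads kg/yr; flow CFS"),
    "morphometry": ({v: k for k, v in MORPHO_HEADERS.items()},
                    "# area m2; volume m3; zmax m"),
    "observed": ({v: k for k, v in OBSERVED_HEADERS.items()},
                 "# concentrations mg/L; weight = inverse inclusion probability"),
}


def write_table(df: pd.DataFrame, path, kind: str | None = None) -> None:
    """Write a table in the external CSV dialect (unit note as a # comment)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header_map, comment = _WRITERS.get(kind, ({}, None))
    out = df.rename(columns=header_map)
    if header_map:
        out = out[[c for c in header_map.values() if c in out.columns]]
    with open(path, "w") as fh:
        if comment:
            fh.write(comment + "\n")
        out.to_csv(fh, index=False)


def write_budgets(budgets: pd.DataFrame, path) -> None:
    """Lake budget export: one row per lake, units noted in a header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# loads kg/yr; flow m3/yr; concentrations mg/L\n")
        budgets.to_csv(fh, index=False)


@dataclass
class PipelineConfig:
    """Paths, constants and fitting controls for a pipeline run."""

    flow_table: str | None = None
    reach_table: str | None = None
    morphometry: str | None = None
    observed: str | None = None
    out_dir: str = "results"
    cfs_to_m3yr: float = 893_593.0
    tp_detection_limit: float = 0.004
    tp_substitute: float = 0.002
    hrt_short_max: float = 0.04
    hrt_long_min: float = 0.4
    mass_balance_rel_tol: float = 1e-6
    trophic_tn: tuple = (0.35, 0.75, 1.4)
    trophic_tp: tuple = (0.010, 0.025, 0.050)
    min_area_m2: float | None = 4.0e4      # survey-design filter: >= 4 ha
    min_zmax_m: float | None = 1.0
    hypotheses: tuple = tuple(f"H{i}" for i in range(9))
    huber_tuning: float = 1.345
    max_iter: int = 50
    seed: int = 0
    n_lakes: int = 500

    def __post_init__(self):
        for name in ("cfs_to_m3yr", "tp_detection_limit", "tp_substitute",
                     "hrt_short_max", "hrt_long_min", "huber_tuning"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        bad = set(self.hypotheses) - {f"H{i}" for i in range(9)}
        if bad:
            raise ValueError(f"unknown hypotheses: {sorted(bad)}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("trophic_tn", "trophic_tp", "hypotheses"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def dump_config(config: PipelineConfig, path) -> None:
    d = {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in vars(config).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
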
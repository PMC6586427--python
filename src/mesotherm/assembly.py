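"""Observation-table handling: loading, validation, transforms, centering.

The pipeline consumes a tidy table with one row per ecosystem-week.  The
canonical schema (column names below) mirrors the deposited experiment file:
tank identity, trophic treatment (A / AG / AGP), heater power (watts), week,
weekly mean water temperature, chlorophyll-a, the nine diel dissolved-oxygen
fields, and zooplankton counts per 10 L.

Statistical covariates are built here: responses are ln-transformed
(ln(x + 1) for zooplankton counts, which can be zero), temperatures go
through the 1/kT transform, and the inverse temperature of each row is
decomposed by within-subject mean centering into

    x_within  = 1/kT_wj - 1/kT-bar_j     (deviation from the tank mean)
    x_between = 1/kT-bar_j - 1/kT-bar    (tank mean minus grand mean)

so that separate within- and between-ecosystem temperature slopes are
estimable.  The trophic-cascade response pairs AG and AGP tanks that share a
heater power level: ln(chla_AGP / chla_AG) per power level and week.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import PhysicalConstants, celsius_to_kelvin, inv_kT

__all__ = [
    "CANONICAL_COLUMNS",
    "MesocosmRecord",
    "load_dataset",
    "write_dataset",
    "ln_plus_one",
    "center_design",
    "build_cascade_series",
    "cascade_design",
    "zooplankton_design",
]

logger = logging.getLogger("mesotherm")

TREATMENTS = ("A", "AG", "AGP")

#: Canonical input columns.  ``date`` is optional metadata.
CANONICAL_COLUMNS = [
    "tank_id", "treatment", "watts", "week", "temp_week_C", "chla_ug_L",
    "o2_dawn", "o2_dusk", "o2_dawn2", "t_dawn", "t_dusk", "t_dawn2",
    "temp_dawn_C", "temp_dusk_C", "temp_dawn2_C",
    "daphnia_per10L", "copepod_per10L",
]

_KEY_COLUMNS = ["tank_id", "treatment", "watts", "week", "temp_week_C"]
_NUMERIC_COLUMNS = [c for c in CANONICAL_COLUMNS
                    if c not in ("tank_id", "treatment")]


@dataclass(frozen=True)
class MesocosmRecord:
    """One validated ecosystem-week observation."""

    tank_id: str
    treatment: str
    watts: float
    week: int
    temp_week_C: float
    chla_ug_L: float
    daphnia_per10L: float
    copepod_per10L: float


def load_dataset(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load and validate a tidy per-ecosystem-per-week observation table.

    ``column_map`` renames incoming headers (other dialects) to the canonical
    schema before validation.  Rows with malformed numeric cells or values
    violating row invariants are rejected with a logged reason; rows with
    genuinely missing diel-oxygen fields are kept (flux treated as missing
    downstream).  Unknown treatment codes and duplicate (tank, week) pairs
    are hard errors, as is an empty table.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _KEY_COLUMNS + ["chla_ug_L"] if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if len(df) == 0:
        raise ValueError("empty observation table")
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    df["treatment"] = df["treatment"].astype(str).str.strip()
    bad_trt = sorted(set(df["treatment"]) - set(TREATMENTS))
    if bad_trt:
        raise ValueError(f"unknown treatment codes: {bad_trt}")

    # Malformed numeric cells: non-empty values that fail to parse.
    reject = pd.Series(False, index=df.index)
    for col in _NUMERIC_COLUMNS:
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        malformed = raw.notna() & parsed.isna()
        for idx in df.index[malformed]:
            logger.warning("rejecting row %s: malformed %s=%r",
                           idx, col, raw.loc[idx])
        reject |= malformed
        df[col] = parsed

    # Row invariants on parsed values.
    checks = {
        "missing key field": df[_KEY_COLUMNS].isna().any(axis=1),
        "week outside 2-9": ~df["week"].between(2, 9),
        "negative chlorophyll": df["chla_ug_L"] < 0,
        "negative zooplankton count": (df["daphnia_per10L"] < 0)
        | (df["copepod_per10L"] < 0),
    }
    for reason, mask in checks.items():
        mask = mask.fillna(False) & ~reject
        for idx in df.index[mask]:
            logger.warning("rejecting row %s: %s", idx, reason)
        reject |= mask

    df = df.loc[~reject].copy()
    if len(df) == 0:
        raise ValueError("no valid rows after validation")
    df["week"] = df["week"].astype(int)
    dup = df.duplicated(subset=["tank_id", "week"])
    if dup.any():
        pairs = df.loc[dup, ["tank_id", "week"]].itertuples(index=False)
        raise ValueError(f"duplicate (tank, week) pairs: {list(pairs)}")
    order = [c for c in df.columns if c in CANONICAL_COLUMNS or c == "date"]
    return df[order].reset_index(drop=True)


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a canonical-schema table; round-trips through load_dataset."""
    df.to_csv(path, index=False)


def ln_plus_one(count):
    """ln(count + 1) transform for zero-inflated zooplankton counts."""
    c = np.asarray(count, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    out = np.log1p(c)
    return float(out) if out.ndim == 0 else out


_RESPONSE_COLUMNS = {
    "chla": "chla_ug_L",
    "nep": "nep_umol_L_h",
    "er": "er_umol_L_h",
}


def center_design(df: pd.DataFrame, response: str,
                  constants: PhysicalConstants = PhysicalConstants()
                  ) -> pd.DataFrame:
    """Build the within/between mean-centered design for one ln response.

    ``response`` is one of "chla", "nep", "er" (the latter two require flux
    columns from :func:`mesotherm.oxygen.add_fluxes`).  Rows with a missing
    or non-positive response are dropped and counted
    (``result.attrs["n_dropped"]``).  Tank mean inverse temperatures are
    taken over each tank's analyzed weeks, and the grand mean is the mean of
    the tank means, so x_within sums to zero within every tank and the
    tank-level x_between values average to zero.
    """
    col = _RESPONSE_COLUMNS.get(response)
    if col is None:
        raise ValueError(f"unknown response {response!r}; "
                         f"expected one of {sorted(_RESPONSE_COLUMNS)}")
    if col not in df.columns:
        raise ValueError(f"column {col!r} not present; run add_fluxes first?")
    ok = df[col].notna() & (df[col] > 0) & df["temp_week_C"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("center_design(%s): dropped %d rows with missing or "
                    "non-positive response", response, n_dropped)
    d = df.loc[ok].copy()
    if d.empty:
        raise ValueError(f"no usable rows for response {response!r}")

    d["inv_kT"] = inv_kT(celsius_to_kelvin(d["temp_week_C"]), constants)
    tank_mean = d.groupby("tank_id")["inv_kT"].transform("mean")
    single = d.groupby("tank_id")["inv_kT"].transform("size") == 1
    if single.any():
        logger.warning("center_design(%s): %d tank(s) observed a single "
                       "week; x_within forced to 0", response,
                       d.loc[single, "tank_id"].nunique())
    grand = float(d.groupby("tank_id")["inv_kT"].mean().mean())

    out = pd.DataFrame({
        "tank_id": d["tank_id"].to_numpy(),
        "treatment": d["treatment"].to_numpy(),
        "week": d["week"].to_numpy(),
        "y": np.log(d[col].to_numpy(dtype=float)),
        "inv_kT": d["inv_kT"].to_numpy(),
        "x_within": (d["inv_kT"] - tank_mean).to_numpy(),
        "x_between": (tank_mean - grand).to_numpy(),
        "z_ag": (d["treatment"] == "AG").astype(float).to_numpy(),
        "z_agp": (d["treatment"] == "AGP").astype(float).to_numpy(),
    })
    out.attrs["grand_mean_inv_kT"] = grand
    out.attrs["n_dropped"] = n_dropped
    out.attrs["response"] = response
    return out


def build_cascade_series(df: pd.DataFrame,
                         constants: PhysicalConstants = PhysicalConstants()
                         ) -> pd.DataFrame:
    """Pair AG and AGP tanks by heater power and compute cascade strength.

    One record per (watts, week) where both paired tanks have positive
    chlorophyll: ln_ratio = ln(chla_AGP) - ln(chla_AG).  ``temp_week_K`` is
    the mean of the paired tanks' weekly temperatures.  Power levels present
    in only one of the two treatments are skipped with a log message.
    """
    ag = df[df["treatment"] == "AG"]
    agp = df[df["treatment"] == "AGP"]
    only = set(ag["watts"]) ^ set(agp["watts"])
    for w in sorted(only):
        logger.warning("cascade: power level %s W present in one treatment "
                       "only; skipped", w)
    merged = ag.merge(agp, on=["watts", "week"], suffixes=("_ag", "_agp"))
    ok = (merged["chla_ug_L_ag"].notna() & (merged["chla_ug_L_ag"] > 0)
          & merged["chla_ug_L_agp"].notna() & (merged["chla_ug_L_agp"] > 0))
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("cascade: skipped %d pairs lacking positive chla", n_skip)
    m = merged.loc[ok]
    t_k = celsius_to_kelvin(
        (m["temp_week_C_ag"].to_numpy() + m["temp_week_C_agp"].to_numpy()) / 2.0)
    out = pd.DataFrame({
        "watts": m["watts"].to_numpy(),
        "week": m["week"].to_numpy(),
        "ln_ratio": np.log(m["chla_ug_L_agp"].to_numpy(dtype=float))
        - np.log(m["chla_ug_L_ag"].to_numpy(dtype=float)),
        "temp_week_K": t_k,
    })
    return out.sort_values(["watts", "week"]).reset_index(drop=True)


def cascade_design(cascade: pd.DataFrame,
                   constants: PhysicalConstants = PhysicalConstants()
                   ) -> pd.DataFrame:
    """Covariates for the cascade model: within-power-level centered 1/kT and
    mean-centered numeric week, grouped by power level."""
    d = cascade.copy()
    d["inv_kT"] = inv_kT(d["temp_week_K"].to_numpy(), constants)
    power_mean = d.groupby("watts")["inv_kT"].transform("mean")
    d["x_within"] = d["inv_kT"] - power_mean
    d["week_c"] = d["week"] - d["week"].mean()
    d["y"] = d["ln_ratio"]
    return d


def zooplankton_design(df: pd.DataFrame, taxon: str = "total",
                       constants: PhysicalConstants = PhysicalConstants()
                       ) -> pd.DataFrame:
    """ln(count + 1) zooplankton design over AG/AGP tanks.

    ``taxon`` is "daphnia", "copepod", or "total" (sum of both).  The
    temperature covariate is 1/kT of the weekly mean, centered on its grand
    mean; ``z_pred`` flags predator presence (AGP).  Rows without counts
    (algae-only tanks, unsampled weeks) are excluded.
    """
    if taxon == "total":
        counts = df["daphnia_per10L"] + df["copepod_per10L"]
    elif taxon == "daphnia":
        counts = df["daphnia_per10L"]
    elif taxon == "copepod":
        counts = df["copepod_per10L"]
    else:
        raise ValueError(f"unknown taxon {taxon!r}")
    ok = df["treatment"].isin(["AG", "AGP"]) & counts.notna() \
        & df["temp_week_C"].notna()
    d = df.loc[ok]
    x = inv_kT(celsius_to_kelvin(d["temp_week_C"].to_numpy()), constants)
    out = pd.DataFrame({
        "tank_id": d["tank_id"].to_numpy(),
        "week": d["week"].to_numpy(),
        "y": ln_plus_one(counts.loc[ok].to_numpy()),
        "x_temp": x - x.mean(),
        "z_pred": (d["treatment"] == "AGP").astype(float).to_numpy(),
    })
    out.attrs["taxon"] = taxon
    return out
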
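"""Raw driver ingestion and daily reduction.

Reads the delimited meteorology, water-table and sap-flow tables, computes
vapour pressure deficit and leaf temperature, anchors the logger's
water-table trace to the manual tube readings, and reduces everything to the
daily statistic the calibration consumes: the median of the largest 10% of
each day's values.  The reduction is applied identically to every driver and
to sap flow.

Input formats (CSV/TSV with a header, ISO-8601 timestamps):

* met:      ``timestamp,T,h_r,I``          (degC, fraction 0-1, mol m-2 s-1)
* WTD:      ``timestamp,delta[,wtt][,tube_id]``  (cm positive downward)
* sap flow: ``timestamp,tree_id,J``        (mol H2O m-2 sapwood s-1)

Outputs: ``daily_drivers.csv`` with ``date,D,I,T,T_l,delta`` and
``daily_E_obs.csv`` with ``date,tree_id,E_obs``.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.3145

DAILY_DRIVER_COLUMNS = ["date", "D", "I", "T", "T_l", "delta"]


def sapwood_thickness(d: float) -> float:
    """Sapwood thickness (mm) from diameter at breast height ``d`` (mm).

    Quadratic allometry fitted on increment cores from same-site Scots pine:
    ``0.0001 d^2 + 0.1668 d + 9.755``.

    Raises ``ValueError`` for non-positive diameter.
    """
    d = float(d)
    if d <= 0:
        raise ValueError(f"DBH must be positive, got {d}")
    return 0.0001 * d**2 + 0.1668 * d + 9.755


def vpd(t, h_r):
    """Vapour pressure deficit (Pa) from air temperature (degC) and relative
    humidity (fraction).

    Saturation vapour pressure follows the Magnus-type form
    ``611 exp(17.502 T / (T + 240.97))``; the deficit is its product with
    ``1 - h_r``.  Accepts scalars or arrays; ``h_r`` outside [0, 1] raises.
    """
    t = np.asarray(t, dtype=float)
    h_r = np.asarray(h_r, dtype=float)
    if np.any((h_r < 0) | (h_r > 1)):
        raise ValueError("relative humidity must lie in [0, 1]")
    out = 611.0 * np.exp(17.502 * t / (t + 240.97)) * (1.0 - h_r)
    return out if out.ndim else float(out)


def vpd_molar(vpd_pa, t):
    """Convert VPD from Pa to molar concentration D (mol H2O m-3).

    Ideal gas law: ``D = VPD / (R (T + 273.15))``.
    """
    vpd_pa = np.asarray(vpd_pa, dtype=float)
    t = np.asarray(t, dtype=float)
    out = vpd_pa / (R_GAS * (t + 273.15))
    return out if out.ndim else float(out)


def leaf_temperature(t, i):
    """Leaf temperature (degC): air temperature plus a linear irradiance
    offset, ``T_l = T + 1.5e3 I`` with I in mol m-2 s-1."""
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    if np.any(i < 0):
        raise ValueError("PPFD must be non-negative")
    out = t + 1.5e3 * i
    return out if out.ndim else float(out)


def daily_top_decile_median(values: Iterable[float]) -> float:
    """Median of the largest 10% of a day's values.

    The top decile is the ``ceil(0.1 n)`` largest values, so the set is
    non-empty for any n >= 1.  NaNs are dropped first; an empty day returns
    NaN (the day is excluded downstream, never imputed).
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    n = arr.size
    if n == 0:
        return float("nan")
    k = math.ceil(0.1 * n)
    top = np.sort(arr)[n - k:]
    return float(np.median(top))


def reduce_daily(df: pd.DataFrame, value_cols: list[str],
                 timestamp_col: str = "timestamp") -> pd.DataFrame:
    """Reduce sub-daily rows to one row per calendar day using the
    top-decile-median statistic, independently per column."""
    ts = pd.to_datetime(df[timestamp_col])
    grouped = df[value_cols].groupby(ts.dt.date)
    out = grouped.agg(lambda s: daily_top_decile_median(s.to_numpy()))
    out.index.name = "date"
    return out.reset_index()


def interpolate_wtd(manual: pd.DataFrame, logger_series: pd.DataFrame) -> pd.DataFrame:
    """Anchor the logger's WTD trace to sparse manual tube readings.

    The logger provides the temporal *shape*; the manual points provide the
    level.  At each manual timestamp the offset ``manual - logger`` is
    computed, linearly interpolated in time (held constant beyond the first
    and last manual point), and added back to the logger series, so the
    output passes exactly through every manual reading and follows the
    logger's pattern between them.  With a single manual point this reduces
    to a constant shift; if the logger does not cover a manual timestamp the
    nearest logger value is used and a warning is logged.

    Parameters
    ----------
    manual : DataFrame with columns ``timestamp, delta`` (one tube).
    logger_series : DataFrame with columns ``timestamp, delta``.

    Returns the logger timestamps with the anchored ``delta`` (cm, >= 0;
    negative values, i.e. standing water above the surface, are clamped to
    zero with a warning).
    """
    man = manual.sort_values("timestamp").reset_index(drop=True)
    log = logger_series.sort_values("timestamp").reset_index(drop=True)
    t_log = pd.to_datetime(log["timestamp"]).astype("int64").to_numpy(dtype=float)
    t_man = pd.to_datetime(man["timestamp"]).astype("int64").to_numpy(dtype=float)
    if t_man.min() < t_log.min() or t_man.max() > t_log.max():
        logger.warning("logger series does not span the manual readings; "
                       "using nearest logger values at the ends")
    logger_at_manual = np.interp(t_man, t_log, log["delta"].to_numpy(dtype=float))
    offsets = man["delta"].to_numpy(dtype=float) - logger_at_manual
    offset_t = np.interp(t_log, t_man, offsets)  # constant beyond the ends
    delta = log["delta"].to_numpy(dtype=float) + offset_t
    n_neg = int(np.sum(delta < 0))
    if n_neg:
        logger.warning("clamping %d negative WTD values (standing water) to 0", n_neg)
        delta = np.maximum(delta, 0.0)
    return pd.DataFrame({"timestamp": log["timestamp"], "delta": delta})


# ---------------------------------------------------------------------------
# Table IO

def _read_table(path) -> pd.DataFrame:
    """Read a CSV/TSV with exactly round-trippable floats."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_met(path) -> pd.DataFrame:
    df = _read_table(path)
    _require(df, ["timestamp", "T", "h_r", "I"], path)
    return df


def read_wtd(path) -> pd.DataFrame:
    df = _read_table(path)
    _require(df, ["timestamp", "delta"], path)
    return df


def read_sapflow(path) -> pd.DataFrame:
    df = _read_table(path)
    _require(df, ["timestamp", "tree_id", "J"], path)
    return df


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def build_daily_drivers(met: pd.DataFrame, wtd: pd.DataFrame) -> pd.DataFrame:
    """Daily driver table ``date,D,I,T,T_l,delta`` from sub-daily met and WTD.

    VPD and leaf temperature are computed at the native resolution, then all
    variables are reduced with the top-decile median.  Days missing any
    driver are dropped (with a log message), never imputed.
    """
    met = met.copy()
    met["VPD"] = vpd(met["T"], met["h_r"])
    met["D"] = vpd_molar(met["VPD"], met["T"])
    met["T_l"] = leaf_temperature(met["T"], met["I"])
    if "tube_id" in wtd.columns:
        # several measurement tubes: average their anchored series per
        # timestamp into the single site-level WTD input
        wtd = wtd.groupby("timestamp", as_index=False)["delta"].mean()
    daily_met = reduce_daily(met, ["D", "I", "T", "T_l"])
    daily_wtd = reduce_daily(wtd, ["delta"])
    out = daily_met.merge(daily_wtd, on="date", how="inner")
    out = out[DAILY_DRIVER_COLUMNS]
    n_bad = int(out[["D", "I", "T", "T_l", "delta"]].isna().any(axis=1).sum())
    if n_bad:
        logger.info("dropping %d day(s) with missing drivers", n_bad)
        out = out.dropna()
    return out.reset_index(drop=True)


def build_daily_eobs(sapflow: pd.DataFrame, rho: float = 2500.0) -> pd.DataFrame:
    """Per-tree daily observed transpiration ``E_obs = J / rho``
    (mol H2O m-2 leaf s-1) from sub-daily sap flow density."""
    frames = []
    for tree_id, grp in sapflow.groupby("tree_id"):
        daily = reduce_daily(grp, ["J"])
        daily["tree_id"] = tree_id
        frames.append(daily)
    out = pd.concat(frames, ignore_index=True)
    out["E_obs"] = out.pop("J") / rho
    return out[["date", "tree_id", "E_obs"]].dropna().reset_index(drop=True)


def write_daily_drivers(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_daily_drivers(path) -> pd.DataFrame:
    df = _read_table(path)
    _require(df, DAILY_DRIVER_COLUMNS, path)
    return df


def read_daily_eobs(path) -> pd.DataFrame:
    df = _read_table(path)
    _require(df, ["date", "tree_id", "E_obs"], path)
    return df
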
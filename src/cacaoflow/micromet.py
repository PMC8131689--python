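"""Microclimate derivations: VPD, hourly slot summaries, AF comparisons.

Vapor pressure deficit follows the FAO-56 formulation: saturation vapor
pressure e_s(T) = 0.6108 * exp(17.27 T / (T + 237.3)) kPa, and
VPD = e_s(T) * (1 - RH/100).  VPD is computed per minute-level sample before
any averaging; because e_s is convex in T, the mean of minute-level VPD is
not the VPD of the slot-mean inputs, and the two can differ noticeably over
a diurnal cycle.  A daily max/min estimator (the other FAO-56 recipe) is
provided for comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MICRO_COLUMNS = ("timestamp", "af", "rh_a_pct", "t_a_c", "par_umol_m2_s")
VARIABLES = ("rh_a", "t_a", "par", "vpd")
#: Column name per short variable key.
VARIABLE_COLUMNS = {"rh_a": "rh_a_pct", "t_a": "t_a_c", "par": "par_umol_m2_s", "vpd": "vpd_kpa"}

DAY_START_HOUR = 6
DAY_END_HOUR = 18
PAR_DAY_THRESHOLD = 5.0  # umol/m2/s


def saturation_vapor_pressure(t_a):
    """Saturation vapor pressure e_s (kPa) at air temperature t_a (deg C)."""
    t = np.asarray(t_a, dtype=float)
    out = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return float(out) if np.isscalar(t_a) else out


def vpd(t_a, rh_a, lenient: bool = False):
    """Vapor pressure deficit (kPa) from instantaneous T (deg C) and RH (%).

    RH outside [0, 100] raises unless ``lenient`` is set, in which case the
    values are clipped (and the event logged).
    """
    rh = np.asarray(rh_a, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        if not lenient:
            raise ValueError("relative humidity outside [0, 100]")
        log.warning("clipping %d RH values outside [0, 100]", int(np.sum((rh < 0) | (rh > 100))))
        rh = np.clip(rh, 0.0, 100.0)
    out = saturation_vapor_pressure(t_a) * (1.0 - rh / 100.0)
    return float(out) if np.isscalar(t_a) and np.isscalar(rh_a) else out


def vpd_from_extremes(t_max, t_min, rh_max, rh_min):
    """Daily VPD estimate from temperature and humidity extremes (FAO-56).

    e_s is the average of saturation pressures at the extremes; actual vapor
    pressure averages e_s(t_min)*RH_max and e_s(t_max)*RH_min.
    """
    es = (saturation_vapor_pressure(t_max) + saturation_vapor_pressure(t_min)) / 2.0
    ea = (
        saturation_vapor_pressure(t_min) * np.asarray(rh_max, dtype=float) / 100.0
        + saturation_vapor_pressure(t_max) * np.asarray(rh_min, dtype=float) / 100.0
    ) / 2.0
    return es - ea


def add_vpd(df: pd.DataFrame, lenient: bool = False) -> pd.DataFrame:
    """Append a ``vpd_kpa`` column computed sample-by-sample."""
    out = df.copy()
    out["vpd_kpa"] = vpd(out["t_a_c"].to_numpy(), out["rh_a_pct"].to_numpy(), lenient=lenient)
    return out


def classify_day_night(df: pd.DataFrame, mode: str = "hours", day_start: int = DAY_START_HOUR, day_end: int = DAY_END_HOUR, par_threshold: float = PAR_DAY_THRESHOLD) -> pd.Series:
    """Label each sample ``day`` or ``night``.

    ``hours`` mode: day iff local hour in [day_start, day_end).  ``par``
    mode: day iff PAR exceeds ``par_threshold``.
    """
    if mode == "hours":
        hour = pd.to_datetime(df["timestamp"]).dt.hour
        is_day = (hour >= day_start) & (hour < day_end)
    elif mode == "par":
        is_day = df["par_umol_m2_s"] > par_threshold
    else:
        raise ValueError(f"unknown day/night mode {mode!r}")
    return pd.Series(np.where(is_day, "day", "night"), index=df.index, name="day_night")


def slot_summary(df: pd.DataFrame, slot_hours=(10, 13, 16, 20, 0, 4), day_hours=(10, 13, 16)) -> pd.DataFrame:
    """Mean and standard error per AF x slot hour x variable.

    A sample belongs to slot h when its local hour equals h.  SE is the
    sample SD over the slot divided by sqrt(n); single-sample slots report
    SE 0 with ``degenerate`` set.  PAR rows are emitted for day slots only.
    Empty (af, hour) cells are absent from the output (and logged).
    """
    if df.empty:
        raise ValueError("empty microclimate series")
    data = df.copy()
    data["hour"] = pd.to_datetime(data["timestamp"]).dt.hour
    rows = []
    for af in sorted(data["af"].unique()):
        for h in slot_hours:
            cell = data[(data["af"] == af) & (data["hour"] == h)]
            if cell.empty:
                log.warning("no samples for AF %s at hour %02d:00", af, h)
                continue
            for var in VARIABLES:
                if var == "par" and h not in day_hours:
                    continue
                col = VARIABLE_COLUMNS[var]
                if col not in cell.columns:
                    continue
                vals = cell[col].to_numpy(dtype=float)
                se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
                rows.append(
                    {
                        "af": af,
                        "hour": h,
                        "variable": var,
                        "mean": float(vals.mean()),
                        "se": se,
                        "n": len(vals),
                        "degenerate": len(vals) < 2,
                    }
                )
    return pd.DataFrame(rows)


def _assign_letters(order: list[str], distinct: set[frozenset]) -> dict[str, str]:
    """Compact letter display: groups ordered by descending mean share a
    letter iff no pairwise test separates them."""
    letters: dict[str, str] = {g: "" for g in order}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    used = 0
    covered: list[set[str]] = []
    for i, g in enumerate(order):
        block = {g}
        for h in order[i + 1 :]:
            if frozenset((g, h)) not in distinct and all(
                frozenset((h, m)) not in distinct for m in block
            ):
                block.add(h)
        if any(block <= c for c in covered):
            continue
        letter = alphabet[used]
        used += 1
        covered.append(block)
        for m in block:
            letters[m] += letter
    return letters


def compare_afs(df: pd.DataFrame, alpha: float = 0.05, slot_hours=(10, 13, 16, 20, 0, 4), day_hours=(10, 13, 16)) -> pd.DataFrame:
    """Fisher's LSD comparison of AF means, per variable per slot hour.

    Runs the one-way omnibus F test across AFs, then all pairwise LSD
    t-tests using the pooled within-group variance; letters are assigned by
    descending mean, identical letters meaning no significant pairwise
    difference at ``alpha``.  Cells with fewer than two AFs or fewer than
    two observations per AF are flagged and carry no letters.
    """
    data = df.copy()
    data["hour"] = pd.to_datetime(data["timestamp"]).dt.hour
    rows = []
    for h in slot_hours:
        for var in VARIABLES:
            if var == "par" and h not in day_hours:
                continue
            col = VARIABLE_COLUMNS[var]
            if col not in data.columns:
                continue
            cell = data[data["hour"] == h]
            groups = {af: g[col].dropna().to_numpy(dtype=float) for af, g in cell.groupby("af")}
            groups = {af: v for af, v in groups.items() if len(v) > 0}
            ok = len(groups) >= 2 and all(len(v) >= 2 for v in groups.values())
            pooled_var = np.nan
            p_omni = np.nan
            if ok:
                k = len(groups)
                n_tot = sum(len(v) for v in groups.values())
                dfe = n_tot - k
                pooled_var = sum((len(v) - 1) * np.var(v, ddof=1) for v in groups.values()) / dfe
                if pooled_var > 0:
                    p_omni = stats.f_oneway(*groups.values()).pvalue
                else:
                    ok = False
            letters = {af: "" for af in groups}
            if ok:
                distinct = set()
                names = list(groups)
                for i, a in enumerate(names):
                    for b in names[i + 1 :]:
                        se = np.sqrt(pooled_var * (1 / len(groups[a]) + 1 / len(groups[b])))
                        t = (groups[a].mean() - groups[b].mean()) / se
                        p = 2 * stats.t.sf(abs(t), dfe)
                        if p < alpha:
                            distinct.add(frozenset((a, b)))
                order = sorted(groups, key=lambda af: -groups[af].mean())
                letters = _assign_letters(order, distinct)
            for af in groups:
                rows.append(
                    {
                        "af": af,
                        "hour": h,
                        "variable": var,
                        "mean": float(groups[af].mean()),
                        "n": len(groups[af]),
                        "p_omnibus": float(p_omni) if np.isfinite(p_omni) else np.nan,
                        "letter": letters.get(af, ""),
                        "degenerate": not ok,
                    }
                )
    return pd.DataFrame(rows)


def read_micro_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in MICRO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
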
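"""Heat Ratio Method (HRM) sap-flow processing.

Converts raw heat-pulse sensor readings (the ratio of the temperature rise at
a thermocouple downstream of the heater to one equidistant upstream) into a
signed heat-pulse velocity, and from there into volumetric sap flow through
the conducting sapwood:

    V_h = (k / x) * ln(T1 / T2) * 3600        [cm/h]
    V_s = (rho_b / rho_s) * (m_c + C_w / C_s) * V_h * S / 1000   [L/h]

Positive velocity is acropetal (roots to crown); a ratio below one yields a
negative, basipetal velocity, the signature of nocturnal hydraulic
redistribution.  The module also provides the zero-flow offset correction
(stem-cut calibration), the Burgess-style polynomial wound correction, the
merge of the two installation depths, and per-day cumulative totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RAW_COLUMNS = ("timestamp", "plant_id", "depth_mm")
PROCESSED_COLUMNS = ("timestamp", "plant_id", "af", "vh_cm_h", "vs_l_h")

#: Identity wound correction (a, b, c) applied as a*vh + b*vh**2 + c*vh**3.
IDENTITY_WOUND = (1.0, 0.0, 0.0)


@dataclass(frozen=True)
class ProbeGeometry:
    """Sensor geometry and thermal properties of the fresh wood.

    Parameters
    ----------
    k : float
        Thermal diffusivity of green (fresh) wood, cm^2/s.
    x : float
        Heater-to-thermocouple spacing, cm.
    depths : tuple of float
        Installation depths behind the cambium, mm, strictly increasing.
    """

    k: float = 0.0025
    x: float = 0.6
    depths: tuple[float, ...] = (5.0, 20.0)

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"thermal diffusivity k must be > 0, got {self.k}")
        if not self.x > 0:
            raise ValueError(f"probe spacing x must be > 0, got {self.x}")
        d = tuple(self.depths)
        if any(v <= 0 for v in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError(f"depths must be strictly increasing and > 0, got {d}")


@dataclass(frozen=True)
class SapwoodProperties:
    """Sapwood properties entering the velocity-to-flow conversion.

    rho_b is the basic density of dry sapwood (kg/m^3), rho_s the sap density
    (kg/m^3), m_c the water content of fresh sapwood (kg/kg dry wood), C_w and
    C_s the specific heat capacities of the dry wood matrix and the sap
    (J/kg/K), and S the cross-sectional conducting sapwood area (cm^2).

    The study does not report rho_b, m_c or S for its cacao trees; the
    defaults here are plausible stand-ins used by fixtures only.
    """

    rho_b: float = 500.0
    rho_s: float = 1000.0
    m_c: float = 1.0
    C_w: float = 1200.0
    C_s: float = 4186.0
    S: float = 40.0

    def __post_init__(self) -> None:
        for name in ("rho_b", "rho_s", "m_c", "C_w", "C_s", "S"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def flow_factor(self) -> float:
        """Multiplier converting cm/h velocity to L/h flow (always > 0)."""
        return (self.rho_b / self.rho_s) * (self.m_c + self.C_w / self.C_s) * self.S / 1000.0


def heat_pulse_velocity(ratio, geom: ProbeGeometry = ProbeGeometry(), timestamps=None):
    """Heat pulse velocity (cm/h) from the downstream/upstream temperature ratio.

    Antisymmetric under ratio inversion; zero at ratio == 1.  ``timestamps``
    lets series-level callers report which sample carried a non-positive
    ratio.
    """
    r = np.asarray(ratio, dtype=float)
    bad = ~(r > 0)
    if np.any(bad):
        if timestamps is not None:
            ts = np.asarray(timestamps)[np.atleast_1d(bad)]
            raise ValueError(f"non-positive temperature ratio at {list(ts[:5])}")
        raise ValueError("temperature ratio must be > 0")
    out = (geom.k / geom.x) * np.log(r) * 3600.0
    return float(out) if np.isscalar(ratio) else out


def wound_correction(vh, coeffs=IDENTITY_WOUND):
    """Polynomial wound/misalignment correction a*vh + b*vh^2 + c*vh^3.

    The study applies a Burgess-style correction but does not publish its
    coefficients, so the default is the identity.
    """
    a, b, c = coeffs
    v = np.asarray(vh, dtype=float)
    out = a * v + b * v**2 + c * v**3
    return float(out) if np.isscalar(vh) else out


def sap_flow_rate(vh, wood: SapwoodProperties = SapwoodProperties()):
    """Volumetric sap flow (L/h) from heat-pulse velocity (cm/h).

    Linear and sign-preserving: the sapwood factor is strictly positive.
    """
    v = np.asarray(vh, dtype=float)
    out = wood.flow_factor * v
    return float(out) if np.isscalar(vh) else out


def zero_offset_correction(series: pd.Series, baseline_window) -> pd.Series:
    """Subtract the mean velocity over a zero-flow baseline window.

    ``series`` is velocity indexed by timestamp; ``baseline_window`` is a
    ``(start, stop)`` pair (stop exclusive) identifying the post-stem-cut
    period during which true flow is zero.  Idempotent on re-application
    with the same window.
    """
    start, stop = baseline_window
    mask = (series.index >= start) & (series.index < stop)
    if not mask.any():
        raise ValueError(f"baseline window {baseline_window} contains no samples")
    return series - series.loc[mask].mean()


def combine_depths(velocities: dict, weights: dict | None = None) -> float:
    """Weighted mean of per-depth velocities (default: unweighted mean).

    The study installs thermocouples at 5 and 20 mm but does not state how
    the depths were merged; an unweighted mean is the neutral choice.
    """
    if weights is None:
        weights = {d: 1.0 for d in velocities}
    if set(weights) != set(velocities):
        raise ValueError(
            f"depth keys differ: velocities {sorted(velocities)} vs weights {sorted(weights)}"
        )
    w = np.array([weights[d] for d in velocities], dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    v = np.array([velocities[d] for d in velocities], dtype=float)
    return float(np.sum(w * v) / w.sum())


def combine_depths_frame(df: pd.DataFrame, value_col: str, weights: dict | None = None) -> pd.DataFrame:
    """Collapse a per-depth long table to one row per (timestamp, plant)."""

    def _one(g: pd.DataFrame) -> float:
        return combine_depths(dict(zip(g["depth_mm"], g[value_col])), weights)

    out = (
        df.groupby(["timestamp", "plant_id"], sort=True)
        .apply(_one, include_groups=False)
        .rename(value_col)
        .reset_index()
    )
    return out


def daily_cumulative(df: pd.DataFrame, gap_minutes: float = 30.0) -> pd.DataFrame:
    """Per-calendar-day cumulative flow (L) by trapezoidal integration.

    Expects columns ``timestamp`` (sorted within plant) and ``vs_l_h``.
    Each interval between consecutive samples contributes its trapezoid
    volume to the calendar day it falls in, split linearly at midnight when
    it straddles the boundary, so a constant 0.1 L/h sampled over exactly
    24 h integrates to 2.4 L.  Intervals longer than ``gap_minutes`` are not
    integrated; the affected days carry ``gap_flag`` (as do days covered by
    a single sample).  Days with no samples are simply absent.
    """
    rows = []
    for plant, g in df.groupby("plant_id", sort=True):
        ts = pd.to_datetime(g["timestamp"]).reset_index(drop=True)
        if not ts.is_monotonic_increasing:
            raise ValueError(f"timestamps for plant {plant!r} are not sorted")
        v = g["vs_l_h"].to_numpy(dtype=float)
        vol: dict = {}
        flagged: set = set()
        for d in ts.dt.date.unique():
            vol[d] = 0.0
        for i in range(len(ts) - 1):
            t0, t1 = ts.iloc[i], ts.iloc[i + 1]
            dt_h = (t1 - t0).total_seconds() / 3600.0
            d0 = t0.date()
            if dt_h * 60.0 > gap_minutes:
                flagged.update({d0, t1.date()})
                continue
            # a sample at exactly midnight closes the previous day
            d1 = t1.date() if t1 != t1.normalize() else (t1 - pd.Timedelta(seconds=1)).date()
            if d0 == d1:
                vol[d0] = vol.get(d0, 0.0) + 0.5 * (v[i] + v[i + 1]) * dt_h
            else:
                mid = t1.normalize()
                f = (mid - t0).total_seconds() / 3600.0 / dt_h
                v_mid = v[i] + f * (v[i + 1] - v[i])
                vol[d0] = vol.get(d0, 0.0) + 0.5 * (v[i] + v_mid) * f * dt_h
                vol[d1] = vol.get(d1, 0.0) + 0.5 * (v_mid + v[i + 1]) * (1 - f) * dt_h
        counts = ts.dt.date.value_counts()
        for d in sorted(vol):
            flag = d in flagged or counts.get(d, 0) < 2
            if flag:
                log.warning("plant %s day %s flagged: sparse or gappy sampling", plant, d)
            rows.append({"plant_id": plant, "date": d, "cumulative_l": float(vol[d]), "gap_flag": bool(flag)})
    return pd.DataFrame(rows, columns=["plant_id", "date", "cumulative_l", "gap_flag"])


def process_raw(
    raw: pd.DataFrame,
    af_by_plant: dict,
    geom: ProbeGeometry = ProbeGeometry(),
    wood: SapwoodProperties = SapwoodProperties(),
    wound_coeffs=IDENTITY_WOUND,
    baseline_window=None,
    depth_weights: dict | None = None,
) -> pd.DataFrame:
    """Full HRM pipeline: raw sensor table -> processed sap-flow table.

    ``raw`` must carry ``timestamp, plant_id, depth_mm`` plus either a
    ``ratio`` column or ``t1_c``/``t2_c`` temperature-rise columns.  Steps:
    ratio -> velocity per depth, merge depths, optional zero-offset
    correction, wound correction, flow conversion.  Returns the
    ``timestamp, plant_id, af, vh_cm_h, vs_l_h`` schema.
    """
    df = raw.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"raw table missing columns {missing}")
    if "ratio" not in df.columns:
        if not {"t1_c", "t2_c"} <= set(df.columns):
            raise ValueError("raw table needs either 'ratio' or 't1_c'/'t2_c' columns")
        df["ratio"] = df["t1_c"] / df["t2_c"]
    df["vh_cm_h"] = heat_pulse_velocity(df["ratio"].to_numpy(), geom, timestamps=df["timestamp"].to_numpy())

    merged = combine_depths_frame(df, "vh_cm_h", depth_weights)
    if baseline_window is not None:
        parts = []
        for plant, g in merged.groupby("plant_id", sort=True):
            s = zero_offset_correction(g.set_index("timestamp")["vh_cm_h"], baseline_window)
            parts.append(s.reset_index().assign(plant_id=plant))
        merged = pd.concat(parts, ignore_index=True)
    merged["vh_cm_h"] = wound_correction(merged["vh_cm_h"].to_numpy(), wound_coeffs)
    merged["vs_l_h"] = sap_flow_rate(merged["vh_cm_h"].to_numpy(), wood)
    merged["af"] = merged["plant_id"].map(af_by_plant)
    if merged["af"].isna().any():
        unknown = sorted(merged.loc[merged["af"].isna(), "plant_id"].unique())
        raise ValueError(f"no AF label for plants {unknown}")
    return merged[list(PROCESSED_COLUMNS)].sort_values(["plant_id", "timestamp"]).reset_index(drop=True)


def read_raw_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_processed_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(PROCESSED_COLUMNS))
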
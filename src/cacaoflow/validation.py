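"""Goodness-of-fit metrics and diagnostic summaries for sap-flow predictions.

Implements the validation statistics used for the sap-flow model: root mean
square error, percent bias (positive = overprediction), Nash-Sutcliffe
efficiency, the observed-versus-predicted regression with its
slope-versus-identity test, Pearson correlation tables between sap flow and
the microclimatic covariates, holdout splitting, and nocturnal flow
summaries (mean reverse flow, t-test against zero, and the volume-weighted
share of the daily flow that is basipetal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .micromet import VARIABLE_COLUMNS


def _check_pair(obs, pred, min_n=2):
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: obs {o.shape} vs pred {p.shape}")
    if o.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {o.size}")
    return o, p


def rmse(obs, pred) -> float:
    """Root mean square error, in the units of the observations (L/h)."""
    o, p = _check_pair(obs, pred)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def pbias(obs, pred) -> float:
    """Percent bias: 100 * sum(pred - obs) / sum(obs).  Positive means the
    model overpredicts on aggregate."""
    o, p = _check_pair(obs, pred)
    denom = o.sum()
    if denom == 0:
        raise ValueError("sum of observations is zero; percent bias undefined")
    return float(100.0 * (p - o).sum() / denom)


def nse(obs, pred) -> float:
    """Nash-Sutcliffe efficiency: 1 is perfect, 0 equals predicting the mean."""
    o, p = _check_pair(obs, pred)
    ss = np.sum((o - o.mean()) ** 2)
    if ss == 0:
        raise ValueError("observations have zero variance; NSE undefined")
    return float(1.0 - np.sum((p - o) ** 2) / ss)


def obs_pred_regression(obs, pred) -> dict:
    """Least-squares regression of observed on predicted values.

    Returns slope, intercept, r2 and the two-sided t-test p-value for
    slope == 1 (identity line).  A perfect fit has zero slope SE; the test
    is then reported as undefined (p = nan, ``perfect`` flag set).
    """
    o, p = _check_pair(obs, pred, min_n=3)
    if np.ptp(p) == 0:
        raise ValueError("predicted values have zero variance")
    res = stats.linregress(p, o)
    perfect = res.stderr == 0
    if perfect:
        p_slope1 = np.nan
    else:
        t = (res.slope - 1.0) / res.stderr
        p_slope1 = float(2 * stats.t.sf(abs(t), o.size - 2))
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "slope_vs_1_p": p_slope1,
        "perfect": bool(perfect),
        "n": int(o.size),
    }


@dataclass(frozen=True)
class ValidationMetrics:
    """Bundle of goodness-of-fit statistics for one AF (or pooled)."""

    rmse: float
    pbias: float
    nse: float
    r2: float
    slope: float
    intercept: float
    slope_vs_1_p: float
    n: int

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.nse > 1 + 1e-12 or not (0 <= self.r2 <= 1 + 1e-12):
            raise ValueError("metric invariants violated")


def validate(obs, pred) -> ValidationMetrics:
    reg = obs_pred_regression(obs, pred)
    return ValidationMetrics(
        rmse=rmse(obs, pred),
        pbias=pbias(obs, pred),
        nse=nse(obs, pred),
        r2=reg["r2"],
        slope=reg["slope"],
        intercept=reg["intercept"],
        slope_vs_1_p=reg["slope_vs_1_p"],
        n=reg["n"],
    )


def correlation_table(data: pd.DataFrame, response: str = "vs_l_h") -> pd.DataFrame:
    """Pearson correlations between sap flow and each covariate.

    One row per AF plus a pooled ``General`` row; cells backed by a constant
    column are flagged rather than reported.
    """
    groups = [("General", data)] + [(af, g) for af, g in data.groupby("af", sort=True)]
    rows = []
    for label, g in groups:
        row: dict = {"factor": label, "n": len(g)}
        for var, col in VARIABLE_COLUMNS.items():
            x = g[col].to_numpy(dtype=float)
            y = g[response].to_numpy(dtype=float)
            if len(g) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                row[f"r_{var}"] = np.nan
                row[f"p_{var}"] = np.nan
                row["flagged"] = True
                continue
            r, p = stats.pearsonr(x, y)
            row[f"r_{var}"] = float(r)
            row[f"p_{var}"] = float(p)
        row.setdefault("flagged", False)
        rows.append(row)
    return pd.DataFrame(rows)


def holdout_split(data: pd.DataFrame, fraction: float, mode: str = "chronological", seed: int | None = None, min_rows: int = 3):
    """Split rows into a fit set and a validation set.

    ``chronological`` (default) holds out the last ``fraction`` of rows
    after sorting by timestamp; ``random`` draws the holdout with the given
    seed.  Returns ``(fit_df, validation_df)``.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n = len(data)
    n_val = int(round(n * fraction))
    n_fit = n - n_val
    if n_fit < min_rows or n_val < min_rows:
        raise ValueError(f"split {n_fit}/{n_val} leaves a set below {min_rows} rows")
    if mode == "chronological":
        ordered = data.sort_values("timestamp", kind="stable")
        return ordered.iloc[:n_fit], ordered.iloc[n_fit:]
    if mode == "random":
        rng = np.random.default_rng(seed)
        idx = rng.permutation(n)
        return data.iloc[np.sort(idx[:n_fit])], data.iloc[np.sort(idx[n_fit:])]
    raise ValueError(f"unknown split mode {mode!r}")


@dataclass(frozen=True)
class NocturnalSummary:
    """Night-time sap-flow behaviour for one AF."""

    af: str
    mean: float
    se: float
    t_stat: float
    p_value: float
    reversed_pct: float
    n_night: int


def reversed_flow_proportion(df: pd.DataFrame) -> float:
    """Share (%) of the time-integrated flow volume that is basipetal.

    Volume-weighted: each sample contributes |flow|*dt, with dt taken from
    the sampling interval per plant; the proportion is the negative share of
    the total absolute volume over the whole series (day and night).
    """
    total = 0.0
    negative = 0.0
    for _, g in df.groupby("plant_id", sort=False) if "plant_id" in df.columns else [(None, df)]:
        ts = pd.to_datetime(g["timestamp"])
        dt = ts.diff().dt.total_seconds().to_numpy() / 3600.0
        if len(dt) > 1:
            dt[0] = np.median(dt[1:])
        else:
            dt[:] = 1.0
        v = g["vs_l_h"].to_numpy(dtype=float)
        vol = np.abs(v) * dt
        total += vol.sum()
        negative += vol[v < 0].sum()
    if total == 0:
        return 0.0
    return float(100.0 * negative / total)


def nocturnal_summary(df: pd.DataFrame, labels: pd.Series, af: str | None = None) -> NocturnalSummary:
    """Nocturnal mean +/- SE, t-test against zero, and reversed-flow share.

    ``labels`` is the day/night label series aligned with ``df``; the
    reversed-flow proportion integrates over the full series (both labels).
    """
    if set(labels.unique()) != {"day", "night"}:
        raise ValueError("labels must contain both 'day' and 'night'")
    night = df.loc[labels == "night", "vs_l_h"].to_numpy(dtype=float)
    if night.size == 0:
        raise ValueError("no night samples")
    mean = float(night.mean())
    se = float(np.std(night, ddof=1) / np.sqrt(night.size)) if night.size > 1 else 0.0
    t, p = stats.ttest_1samp(night, 0.0)
    return NocturnalSummary(
        af=af if af is not None else str(df["af"].iloc[0]) if "af" in df.columns else "",
        mean=mean,
        se=se,
        t_stat=float(t),
        p_value=float(p),
        reversed_pct=reversed_flow_proportion(df),
        n_night=int(night.size),
    )


def metrics_frame(per_af: dict) -> pd.DataFrame:
    """Tabulate ValidationMetrics per AF in the CSV output schema."""
    rows = []
    for af, m in per_af.items():
        rows.append({"af": af, "n": m.n, "rmse": m.rmse, "pbias_pct": m.pbias, "nse": m.nse,
                     "r2": m.r2, "slope": m.slope, "intercept": m.intercept,
                     "slope_vs_1_p": m.slope_vs_1_p})
    return pd.DataFrame(rows)
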
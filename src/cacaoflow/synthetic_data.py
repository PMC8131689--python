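"""Seedable synthetic field campaign for the cacao sap-flow pipeline.

No sensor data accompany the study, so this module generates datasets with
the statistical structure the analysis assumes and the published summary
statistics pin down:

* minute-resolution diurnal microclimate (RH_a, T_a, PAR) per agroforestry
  system, whose hourly means at the six reported slot hours reproduce the
  published means exactly by construction, and whose day-to-day variability
  is calibrated so the standard error of those slot means matches the
  published SEs (day SD = SE * sqrt(14), 14 monitoring days);
* VPD derived per minute from the generated T and RH (the instantaneous
  FAO-56 formula) — note the published VPD slot means came from the daily
  max/min recipe and are NOT reproduced by minute-level VPD; see
  docs/methods.md;
* sap flow evaluated from the reconciled published coefficient set, plus
  per-plant and per-day random intercepts and Gaussian noise whose default
  scale (0.015 L/h) sits in the middle of the published RMSE range
  (0.01-0.02 L/h);
* an inverse-HRM fixture (flow -> temperature ratios) so the raw-sensor
  pipeline can be round-trip tested.

Diurnal shapes are monotone piecewise-cubic arcs through the slot anchors
(periodic for RH/T, a zero-ended day arc for PAR) with AR(1) minute jitter.
Weather is driven by a single standardized day factor shared by all AFs
(clear day: T and PAR up, RH down); day factors and minute jitter are
centered per hour-of-day cell so the slot-mean calibration is exact rather
than approximate.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import hrm, micromet, model, reference

AFS = reference.AFS
N_REFERENCE_DAYS = 14  # monitoring days behind the published slot SEs

_VAR_INDEX = {"rh_a": 0, "t_a": 1, "par": 2}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic campaign.

    Defaults mirror the study conditions: 3 AFs x 4 plants x 14 days,
    1-minute microclimate, 5556 sap-flow rows per AF (3816 for fitting plus
    1740 for validation), noise SD 0.015 L/h, and plant/day random-intercept
    SDs of 0.005 L/h.
    """

    seed: int = 0
    n_days: int = 14
    start: str = "2015-01-13"
    interval_min: int = 1
    afs: tuple = AFS
    n_plants: int = 4
    n_flow_rows: int = reference.N_FIT + reference.N_VALIDATION
    noise_sd: float = 0.015
    plant_effect_sd: float = 0.005
    day_effect_sd: float = 0.005
    ar1_rho: float = 0.7
    jitter_t_sd: float = 0.3
    jitter_par_rel: float = 0.10
    jitter_rh_rel: float = 0.25
    coefficients: model.ModelCoefficients = field(default_factory=model.ModelCoefficients.reconciled)

    def __post_init__(self) -> None:
        for name in ("noise_sd", "plant_effect_sd", "day_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if (24 * 60) % self.interval_min:
            raise ValueError("interval_min must divide 24 h")
        unknown = set(self.afs) - set(AFS)
        if unknown:
            raise ValueError(f"unknown AF labels {sorted(unknown)}")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(key)))


def _slot_anchor(af: str, var: str):
    """(hours, means, ses) of the published slots carrying this variable."""
    hours, means, ses = [], [], []
    for h in reference.SLOT_HOURS:
        stats_ = reference.SLOT_STATS[(h, af)]
        if var in stats_:
            hours.append(h)
            m, s = stats_[var]
            means.append(m)
            ses.append(s)
    return np.array(hours, float), np.array(means, float), np.array(ses, float)


def _periodic_pchip(hours_centers: np.ndarray, values: np.ndarray) -> PchipInterpolator:
    order = np.argsort(hours_centers)
    x = hours_centers[order]
    v = values[order]
    x_ext = np.concatenate([x[-2:] - 24.0, x, x[:2] + 24.0])
    v_ext = np.concatenate([v[-2:], v, v[:2]])
    return PchipInterpolator(x_ext, v_ext)


def _calibrate_profile(af: str, var: str) -> tuple:
    """Deterministic diurnal curve whose slot means hit the published values.

    Anchor values at the slot centers are adjusted iteratively until the
    minute-level mean over each anchored hour equals the published mean.
    Returns ``(curve, envelope)``: the profile and the day-to-day SD
    envelope (published SE * sqrt(14) interpolated across hours; relative
    to the profile for PAR).
    """
    hours, means, ses = _slot_anchor(af, var)
    minutes = np.arange(0, 24 * 60) / 60.0
    in_slot = {h: (minutes >= h) & (minutes < h + 1) for h in hours}

    if var == "par":
        xs = np.array([6.0, *(hours + 0.5), 18.0])
        vals = means.copy()
        for _ in range(12):
            f = PchipInterpolator(xs, np.concatenate([[0.0], vals, [0.0]]))
            y = np.where((minutes >= 6) & (minutes < 18), np.clip(f(minutes), 0.0, None), 0.0)
            vals += means - np.array([y[in_slot[h]].mean() for h in hours])
        f = PchipInterpolator(xs, np.concatenate([[0.0], vals, [0.0]]))

        def curve(t):
            t = np.asarray(t, float)
            return np.where((t >= 6) & (t < 18), np.clip(f(t), 0.0, None), 0.0)

        rel = ses * np.sqrt(N_REFERENCE_DAYS) / np.maximum(means, 1.0)
        env_f = PchipInterpolator(
            np.array([6.0, *(hours + 0.5), 18.0]),
            np.concatenate([[rel[0]], rel, [rel[-1]]]),
        )

        def envelope(t):
            t = np.asarray(t, float)
            return np.where((t >= 6) & (t < 18), env_f(t), 0.0)

        return curve, envelope

    vals = means.copy()
    for _ in range(12):
        f = _periodic_pchip(hours + 0.5, vals)
        y = f(minutes)
        if var == "rh_a":
            y = np.clip(y, 0.0, 100.0)
        vals += means - np.array([y[in_slot[h]].mean() for h in hours])
    f = _periodic_pchip(hours + 0.5, vals)

    def curve(t):
        y = f(np.mod(np.asarray(t, float), 24.0))
        return np.clip(y, 0.0, 100.0) if var == "rh_a" else y

    env_f = _periodic_pchip(hours + 0.5, ses * np.sqrt(N_REFERENCE_DAYS))

    def envelope(t):
        return np.clip(env_f(np.mod(np.asarray(t, float), 24.0)), 0.0, None)

    return curve, envelope


@lru_cache(maxsize=None)
def diurnal_profile(af: str, var: str):
    if af not in AFS:
        raise ValueError(f"unknown AF label {af!r}")
    return _calibrate_profile(af, var)


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    e = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = e[0]
    scale = np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + scale * e[i]
    return out


def _center_by_cell(values: np.ndarray, hour_cell: np.ndarray) -> np.ndarray:
    out = values.copy()
    for h in np.unique(hour_cell):
        m = hour_cell == h
        out[m] -= out[m].mean()
    return out


def day_factors(config: GeneratorConfig) -> np.ndarray:
    """Standardized weather factor per day (clear > 0 > overcast), shared by
    all AFs and centered so slot means are unaffected."""
    w = _rng(config.seed, 9).standard_normal(config.n_days)
    return w - w.mean()


def generate_microclimate(config: GeneratorConfig, af: str) -> pd.DataFrame:
    """Minute-level RH_a, T_a, PAR and derived VPD for one AF."""
    if af not in AFS:
        raise ValueError(f"unknown AF label {af!r}")
    per_day = 24 * 60 // config.interval_min
    n = per_day * config.n_days
    ts = pd.date_range(config.start, periods=n, freq=f"{config.interval_min}min")
    t_of_day = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    hour_cell = ts.hour.to_numpy()
    day_idx = np.repeat(np.arange(config.n_days), per_day)
    w = day_factors(config)[day_idx]
    af_i = AFS.index(af)
    rho = config.ar1_rho

    out = {}
    for var in ("rh_a", "t_a", "par"):
        curve, envelope = diurnal_profile(af, var)
        base = curve(t_of_day)
        env = envelope(t_of_day)
        e = _ar1(_rng(config.seed, af_i, _VAR_INDEX[var]), n, rho)
        if var == "par":
            # clear-day factor raises PAR; relative jitter; clip keeps night at 0
            rel = env * w + config.jitter_par_rel * e
            rel = np.where(base > 0, _center_by_cell(np.where(base > 0, rel, 0.0), hour_cell), 0.0)
            y = base * np.clip(1.0 + rel, 0.0, None)
        elif var == "t_a":
            add = env * w + config.jitter_t_sd * e
            y = base + _center_by_cell(add, hour_cell)
        else:  # rh_a, anti-phased with the day factor, tight jitter near saturation
            jit_sd = np.minimum(1.5, config.jitter_rh_rel * (100.0 - base))
            add = -env * w + jit_sd * e
            y = np.clip(base + _center_by_cell(add, hour_cell), 0.0, 100.0)
        out[var] = y

    df = pd.DataFrame(
        {
            "timestamp": ts,
            "af": af,
            "rh_a_pct": out["rh_a"],
            "t_a_c": out["t_a"],
            "par_umol_m2_s": out["par"],
        }
    )
    return micromet.add_vpd(df)


def true_sap_flow(micro: pd.DataFrame, coeffs: model.ModelCoefficients | None = None, af: str | None = None) -> np.ndarray:
    """Noiseless sap flow (L/h): the linear model evaluated pointwise.

    Shares the evaluation path with :func:`cacaoflow.model.predict`;
    negative values are meaningful (basipetal flow), nothing is clipped.
    """
    if coeffs is None:
        coeffs = model.ModelCoefficients.reconciled()
    return model.predict(coeffs, micro, af=af)


def sample_flow_rows(micro: pd.DataFrame, config: GeneratorConfig, af: str) -> pd.DataFrame:
    """Thin the minute grid to the per-plant sap-flow sampling times.

    Each of the ``n_plants`` plants logs ``n_flow_rows / n_plants`` rows at
    evenly spaced minute indices across the campaign (~15-min cadence at the
    defaults), mirroring the study's per-AF model row count.
    """
    per_plant = config.n_flow_rows // config.n_plants
    idx = np.unique(np.round(np.linspace(0, len(micro) - 1, per_plant)).astype(int))
    rows = []
    for p in range(config.n_plants):
        g = micro.iloc[idx].copy()
        g["plant_id"] = f"{af}_p{p + 1}"
        rows.append(g)
    out = pd.concat(rows, ignore_index=True)
    out["vs_true"] = true_sap_flow(out, config.coefficients, af)
    return out


def add_noise(flow: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Observed flow = truth + plant intercept + day intercept + white noise.

    Plant and day intercepts are drawn once per unit (days shared across
    AFs, as in the crossed-random-intercept model).  Deterministic per seed.
    """
    out = flow.copy()
    rng_p = _rng(config.seed, 21)
    rng_d = _rng(config.seed, 22)
    rng_e = _rng(config.seed, 23)
    plants = np.sort(out["plant_id"].unique())
    b_plant = dict(zip(plants, rng_p.normal(0.0, config.plant_effect_sd, len(plants))))
    days = np.sort(pd.to_datetime(out["timestamp"]).dt.date.unique())
    b_day = dict(zip(days, rng_d.normal(0.0, config.day_effect_sd, len(days))))
    eps = rng_e.normal(0.0, config.noise_sd, len(out))
    out["vs_l_h"] = (
        out["vs_true"].to_numpy()
        + out["plant_id"].map(b_plant).to_numpy()
        + pd.to_datetime(out["timestamp"]).dt.date.map(b_day).to_numpy()
        + eps
    )
    return out


def generate_campaign(config: GeneratorConfig):
    """Full synthetic bundle: ``(microclimate, flow)`` tables over all AFs.

    ``flow`` carries the covariates at the sampled rows plus ``vs_true``
    (the generating signal) and ``vs_l_h`` (the noisy observation).
    """
    micro = pd.concat([generate_microclimate(config, af) for af in config.afs], ignore_index=True)
    flows = []
    for af in config.afs:
        m = micro[micro["af"] == af].reset_index(drop=True)
        flows.append(sample_flow_rows(m, config, af))
    flow = add_noise(pd.concat(flows, ignore_index=True), config)
    return micro, flow


def invert_to_heat_pulse(
    flow: pd.DataFrame,
    wood: hrm.SapwoodProperties = hrm.SapwoodProperties(),
    geom: hrm.ProbeGeometry = hrm.ProbeGeometry(),
    flow_col: str = "vs_l_h",
) -> pd.DataFrame:
    """Invert the HRM equations: flow series -> raw temperature-ratio table.

    Produces one row per installation depth with the ratio that, pushed back
    through the HRM pipeline with identity corrections, reproduces the input
    flow exactly (zero flow maps to ratio 1; negative flow to ratios < 1).
    """
    vh = flow[flow_col].to_numpy(dtype=float) / wood.flow_factor
    ratio = np.exp(vh * geom.x / (geom.k * 3600.0))
    rows = []
    for depth in geom.depths:
        g = pd.DataFrame(
            {
                "timestamp": flow["timestamp"].to_numpy(),
                "plant_id": flow["plant_id"].to_numpy() if "plant_id" in flow.columns else "p1",
                "depth_mm": depth,
                "ratio": ratio,
            }
        )
        rows.append(g)
    return pd.concat(rows, ignore_index=True).sort_values(["plant_id", "timestamp", "depth_mm"]).reset_index(drop=True)


def write_bundle(config: GeneratorConfig, outdir) -> dict:
    """Write the CSV bundle (microclimate, raw heat pulse, truth) and return
    the paths keyed by role."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    micro, flow = generate_campaign(config)
    paths = {
        "microclimate": outdir / "microclimate.csv",
        "raw_heat_pulse": outdir / "raw_heat_pulse.csv",
        "truth": outdir / "truth.csv",
        "coefficients": outdir / "generating_coefficients.csv",
    }
    micro.to_csv(paths["microclimate"], index=False)
    invert_to_heat_pulse(flow).to_csv(paths["raw_heat_pulse"], index=False)
    flow.to_csv(paths["truth"], index=False)
    config.coefficients.to_frame().to_csv(paths["coefficients"])
    return paths
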
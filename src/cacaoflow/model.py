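"""AF-stratified linear prediction model for cacao sap flow.

The model predicts volumetric sap flow V_s (L/h) from four microclimatic
covariates, with a full set of coefficients per agroforestry system (AF):

    V_s = beta0(af) + beta_rh(af) RH_a + beta_ta(af) T_a
          + beta_par(af) PAR + beta_vpd(af) VPD

Dummy-coding the AF against every covariate makes this a single linear model
with 15 fixed-effect columns (3 AFs x (intercept + 4 slopes)).  Day and
plant enter as crossed random intercepts (REML via statsmodels MixedLM); a
pure fixed-effects OLS fit is available and coincides with the mixed fit
when the random-effect variances are zero.  Slope differences between AFs
are Wald contrasts on the fitted covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import reference
from .micromet import VARIABLE_COLUMNS

log = logging.getLogger(__name__)

AFS = reference.AFS
COVARIATES = reference.COVARIATES
TERMS = ("beta0",) + COVARIATES


def design_columns(afs=AFS, quadratic=()) -> list[str]:
    """Stable fixed-effect column order: per AF, intercept then slopes."""
    cols = [f"{af}:{t}" for af in afs for t in TERMS]
    cols += [f"{af}:{v}^2" for af in afs for v in quadratic]
    return cols


@dataclass(frozen=True)
class ModelCoefficients:
    """Per-AF intercept and the four partial slopes.

    ``values`` maps AF label -> {beta0, rh_a, t_a, par, vpd}.
    """

    values: dict

    def __post_init__(self) -> None:
        for af, terms in self.values.items():
            missing = [t for t in TERMS if t not in terms]
            if missing:
                raise ValueError(f"AF {af}: missing terms {missing}")
            bad = [t for t, v in terms.items() if not np.isfinite(v)]
            if bad:
                raise ValueError(f"AF {af}: non-finite terms {bad}")

    @classmethod
    def reconciled(cls) -> "ModelCoefficients":
        """The published coefficient set with summed (reconciled) intercepts."""
        return cls(reference.reconciled_coefficients())

    @classmethod
    def as_printed(cls) -> "ModelCoefficients":
        """The published per-AF table verbatim (inconsistent intercepts)."""
        return cls({af: dict(v) for af, v in reference.TABLE_COEFFICIENTS_ABSOLUTE.items()})

    def __getitem__(self, af: str) -> dict:
        return self.values[af]

    @property
    def afs(self) -> tuple:
        return tuple(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values).reindex(index=list(TERMS))

    @classmethod
    def from_params(cls, params: pd.Series) -> "ModelCoefficients":
        vals: dict[str, dict[str, float]] = {}
        for name, v in params.items():
            if ":" not in name or name.endswith("^2"):
                continue
            af, term = name.split(":", 1)
            vals.setdefault(af, {})[term] = float(v)
        return cls(vals)


def predict(coeffs: ModelCoefficients, covariates: pd.DataFrame, af: str | None = None) -> np.ndarray:
    """Evaluate the linear model over a covariate table.

    ``covariates`` must carry ``rh_a_pct, t_a_c, par_umol_m2_s, vpd_kpa``
    and, when ``af`` is not given, an ``af`` column.  No clipping: negative
    predictions are meaningful (basipetal flow).
    """
    missing = [c for c in VARIABLE_COLUMNS.values() if c not in covariates.columns]
    if missing:
        raise ValueError(f"missing covariate columns {missing}")
    labels = pd.Series(af, index=covariates.index) if af is not None else covariates["af"]
    unknown = sorted(set(labels.unique()) - set(coeffs.afs))
    if unknown:
        raise ValueError(f"no coefficients for AF(s) {unknown}")
    out = np.empty(len(covariates), dtype=float)
    for label, idx in labels.groupby(labels).groups.items():
        c = coeffs[label]
        g = covariates.loc[idx]
        pos = covariates.index.get_indexer(idx)
        out[pos] = c["beta0"] + sum(
            c[v] * g[VARIABLE_COLUMNS[v]].to_numpy(dtype=float) for v in COVARIATES
        )
    return out


def build_design(data: pd.DataFrame, quadratic=(), response: str = "vs_l_h"):
    """Expand merged covariate+response rows into the dummy-interaction design.

    Returns ``(X, y)`` where X has one intercept and one slope column per AF
    per covariate (plus optional per-AF centered-squared columns).  Rows with
    unknown AF labels or missing covariates are rejected with their indices.
    """
    cov_cols = [VARIABLE_COLUMNS[v] for v in COVARIATES]
    missing_cols = [c for c in cov_cols + ["af"] if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data missing columns {missing_cols}")
    unknown = data.index[~data["af"].isin(AFS)]
    if len(unknown):
        raise ValueError(f"unknown AF label at rows {list(unknown[:10])}")
    bad = data.index[data[cov_cols].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"missing covariate values at rows {list(bad[:10])}")

    afs_present = [af for af in AFS if (data["af"] == af).any()]
    cols = design_columns(afs_present, quadratic)
    X = pd.DataFrame(0.0, index=data.index, columns=cols)
    centers = {v: data[VARIABLE_COLUMNS[v]].mean() for v in quadratic}
    for af in afs_present:
        m = (data["af"] == af).to_numpy()
        X.loc[m, f"{af}:beta0"] = 1.0
        for v in COVARIATES:
            X.loc[m, f"{af}:{v}"] = data.loc[m, VARIABLE_COLUMNS[v]].to_numpy(dtype=float)
        for v in quadratic:
            centered = data.loc[m, VARIABLE_COLUMNS[v]].to_numpy(dtype=float) - centers[v]
            X.loc[m, f"{af}:{v}^2"] = centered**2
    y = data[response].astype(float) if response in data.columns else None
    return X, y


@dataclass
class FitResult:
    """Fitted model: coefficients, uncertainties, and information criteria."""

    params: pd.Series
    cov_params: pd.DataFrame
    random_variances: dict
    llf: float
    n: int
    n_params: int
    method: str
    converged: bool = True
    quadratic: tuple = ()

    def __post_init__(self) -> None:
        self.aic = -2.0 * self.llf + 2.0 * self.n_params
        self.bic = -2.0 * self.llf + self.n_params * np.log(self.n)

    @property
    def coefficients(self) -> ModelCoefficients:
        return ModelCoefficients.from_params(self.params)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    def to_frame(self) -> pd.DataFrame:
        se = self.se
        z = self.params / se
        p = 2 * stats.norm.sf(np.abs(z))
        out = pd.DataFrame({"estimate": self.params, "se": se, "p": p})
        out.index.name = "term"
        return out


def _check_singular(X: pd.DataFrame) -> None:
    scale = np.linalg.norm(X.to_numpy(), axis=0)
    scale[scale == 0] = 1.0
    r = np.linalg.matrix_rank(X.to_numpy() / scale)
    if r < X.shape[1]:
        q, rr = np.linalg.qr(X.to_numpy() / scale)
        dep = [X.columns[i] for i in range(X.shape[1]) if abs(rr[i, i]) < 1e-10]
        raise ValueError(f"singular design; collinear columns {dep}")


def fit(
    data: pd.DataFrame,
    random_spec: tuple = ("plant", "day"),
    method: str = "reml",
    nested: bool = False,
    quadratic: tuple = (),
) -> FitResult:
    """Fit the dummy-interaction sap-flow model.

    ``method='reml'`` fits a linear mixed model with crossed random
    intercepts for plant and day (variance components on a single grouping);
    ``nested=True`` nests day within plant instead.  ``method='ols'`` is the
    fixed-effects fallback, identical to the mixed fit when random-effect
    variances are zero.  Random factors with fewer than two levels are
    dropped with a warning.
    """
    X, y = build_design(data, quadratic=quadratic)
    if y is None:
        raise ValueError("data carries no response column 'vs_l_h'")
    if len(X) <= X.shape[1]:
        raise ValueError(f"n={len(X)} rows cannot identify {X.shape[1]} fixed effects")
    _check_singular(X)

    frame = X.copy()
    safe = {c: f"c{i}" for i, c in enumerate(X.columns)}
    frame = frame.rename(columns=safe)
    frame["vs"] = y.to_numpy()

    factors = {}
    if "plant" in random_spec and "plant_id" in data.columns:
        factors["plant"] = data["plant_id"].astype(str).to_numpy()
    if "day" in random_spec and "timestamp" in data.columns:
        day = pd.to_datetime(data["timestamp"]).dt.date.astype(str).to_numpy()
        if nested and "plant" in factors:
            day = np.char.add(np.char.add(factors["plant"], "/"), day)
        factors["day"] = day
    for name in list(factors):
        if len(np.unique(factors[name])) < 2:
            log.warning("random factor %r has < 2 levels; dropping it", name)
            del factors[name]

    if method == "ols" or not factors:
        res = sm.OLS(frame["vs"], frame[list(safe.values())]).fit()
        params = pd.Series(res.params.to_numpy(), index=list(X.columns))
        cov = pd.DataFrame(res.cov_params().to_numpy(), index=X.columns, columns=X.columns)
        rv = {"plant": 0.0, "day": 0.0, "residual": float(res.scale)}
        return FitResult(params, cov, rv, float(res.llf), len(X), X.shape[1] + 1,
                         "ols", True, tuple(quadratic))

    for name, vals in factors.items():
        frame[name] = vals
    frame["_g"] = "all"
    vc = {name: f"0 + C({name})" for name in factors}
    formula = "vs ~ 0 + " + " + ".join(safe.values())
    md = sm.MixedLM.from_formula(formula, data=frame, groups="_g", vc_formula=vc, re_formula="0")
    # Powell handles the vcomp-at-zero boundary better than gradient methods
    res = md.fit(reml=True, method="powell", maxiter=500)
    fe = res.fe_params
    params = pd.Series(fe.to_numpy(), index=list(X.columns))
    cov = pd.DataFrame(
        res.cov_params().iloc[: len(fe), : len(fe)].to_numpy(), index=X.columns, columns=X.columns
    )
    rv = {name: float(res.vcomp[i]) for i, name in enumerate(vc)}
    rv["residual"] = float(res.scale)
    n_params = X.shape[1] + len(vc) + 1
    return FitResult(params, cov, rv, float(res.llf), len(X), n_params,
                     "reml", bool(res.converged), tuple(quadratic))


def residuals(fitres: FitResult, data: pd.DataFrame) -> np.ndarray:
    """Raw residuals against the fixed-effect prediction."""
    X, y = build_design(data, quadratic=fitres.quadratic)
    return y.to_numpy() - X.to_numpy() @ fitres.params.reindex(X.columns).to_numpy()


def partial_residuals(fitres: FitResult, data: pd.DataFrame, variable: str, alpha: float = 0.01):
    """Partial residuals for one covariate, with a curvature flag.

    The partial residual adds the fitted per-AF component of ``variable``
    back onto the raw residual.  Curvature is flagged when the quadratic
    coefficient of a follow-up regression of the partial residuals on the
    (centered) covariate is significant at ``alpha``.
    Returns ``(series, flagged, p_quadratic)``.
    """
    if variable not in COVARIATES:
        raise ValueError(f"{variable!r} is not a model covariate {COVARIATES}")
    col = VARIABLE_COLUMNS[variable]
    v = data[col].to_numpy(dtype=float)
    if np.ptp(v) == 0:
        raise ValueError(f"covariate {variable!r} is constant")
    resid = residuals(fitres, data)
    comp = np.zeros_like(resid)
    for af in AFS:
        name = f"{af}:{variable}"
        if name in fitres.params.index:
            comp += np.where(data["af"].to_numpy() == af, fitres.params[name] * v, 0.0)
    partial = resid + comp
    vc = v - v.mean()
    Z = sm.add_constant(np.column_stack([vc, vc**2]))
    follow = sm.OLS(partial, Z).fit()
    p_quad = float(follow.pvalues[2])
    return pd.Series(partial, index=data.index, name=f"partial_{variable}"), p_quad < alpha, p_quad


def contrast_slopes(fitres: FitResult, variable: str, af_a: str, af_b: str) -> dict:
    """Wald contrast between two AFs' coefficients for one term.

    ``variable`` may be any model term including ``beta0``.  Returns the
    estimated difference (af_a minus af_b), its SE, and a two-sided p-value.
    """
    if variable not in TERMS:
        raise ValueError(f"unknown term {variable!r}")
    na, nb = f"{af_a}:{variable}", f"{af_b}:{variable}"
    for name in (na, nb):
        if name not in fitres.params.index:
            raise ValueError(f"term {name!r} not in fit")
    if af_a == af_b:
        return {"variable": variable, "af_a": af_a, "af_b": af_b, "estimate": 0.0, "se": 0.0, "p": 1.0}
    est = float(fitres.params[na] - fitres.params[nb])
    var = float(
        fitres.cov_params.loc[na, na] + fitres.cov_params.loc[nb, nb] - 2 * fitres.cov_params.loc[na, nb]
    )
    se = float(np.sqrt(max(var, 0.0)))
    z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return {"variable": variable, "af_a": af_a, "af_b": af_b, "estimate": est, "se": se, "p": p}


def reference_coded_table(fitres: FitResult, baseline: str = "H_PAR") -> pd.DataFrame:
    """Re-express the per-AF fit in baseline + difference form.

    Mirrors the published reference-coded layout: baseline coefficients,
    each other AF as a difference from the baseline, plus the difference
    between the two non-baseline AFs.
    """
    others = [af for af in AFS if af != baseline]
    rows = []
    for term in TERMS:
        name = f"{baseline}:{term}"
        rows.append(
            {"term": term, "level": baseline,
             "estimate": float(fitres.params[name]),
             "se": float(fitres.se[name]),
             "p": float(2 * stats.norm.sf(abs(fitres.params[name] / fitres.se[name])))}
        )
        for af in others:
            c = contrast_slopes(fitres, term, af, baseline)
            rows.append({"term": term, "level": af, "estimate": c["estimate"], "se": c["se"], "p": c["p"]})
        c = contrast_slopes(fitres, term, others[0], others[1])
        rows.append({"term": term, "level": f"{others[0]}_vs_{others[1]}",
                     "estimate": c["estimate"], "se": c["se"], "p": c["p"]})
    return pd.DataFrame(rows)


def select_model(candidates: list[dict], data: pd.DataFrame, method: str = "ols", random_spec: tuple = ()) -> pd.DataFrame:
    """Fit candidate specifications and rank them by AIC and by BIC.

    Each candidate is ``{"name": str, "quadratic": tuple of covariates}``
    (squared terms are centered per covariate, added per AF).  Failed fits
    are recorded and excluded from the rankings.  Ties break toward fewer
    parameters, then earlier list position.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    rows = []
    for i, cand in enumerate(candidates):
        try:
            f = fit(data, random_spec=random_spec, method=method, quadratic=tuple(cand.get("quadratic", ())))
            rows.append({"name": cand["name"], "index": i, "aic": f.aic, "bic": f.bic,
                         "n_params": f.n_params, "failed": False})
        except Exception as exc:  # noqa: BLE001 - candidate exclusion is the contract
            log.warning("candidate %r failed to fit: %s", cand.get("name", i), exc)
            rows.append({"name": cand.get("name", str(i)), "index": i, "aic": np.nan,
                         "bic": np.nan, "n_params": np.nan, "failed": True})
    tab = pd.DataFrame(rows)
    ok = tab[~tab["failed"]]
    for crit in ("aic", "bic"):
        order = ok.sort_values([crit, "n_params", "index"]).index
        ranks = pd.Series(range(1, len(order) + 1), index=order)
        tab[f"rank_{crit}"] = ranks.reindex(tab.index)
    return tab
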
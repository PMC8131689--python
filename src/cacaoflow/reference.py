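"""Published reference values for the cacao agroforestry sap-flow study.

These constants are the calibration targets and cross-checks used across the
package: hourly microclimate summary statistics per agroforestry system (AF),
the Pearson correlation table between sap flow and microclimate, and the two
printed forms of the fitted coefficient set for the linear sap-flow model

    V_s = beta0 + beta_rh*RH_a + beta_ta*T_a + beta_par*PAR + beta_vpd*VPD

The coefficient set was published twice: once in reference-coded form (the
high-radiation system H_PAR as baseline, the other two systems as differences
from it) and once as per-AF absolute coefficients.  Summing baseline and
difference reproduces every absolute *slope* exactly, but the absolute
*intercepts* as printed simply repeat the raw difference rows.  Only the
summed intercepts reproduce the study's reported nocturnal flow signs and
magnitudes per AF, so :func:`reconciled_coefficients` ships intercepts
obtained by summing; :data:`TABLE_COEFFICIENTS_ABSOLUTE` preserves the
printed (inconsistent) values verbatim.  See docs/methods.md.
"""

from __future__ import annotations

AFS = ("H_PAR", "M_PAR", "L_PAR")
COVARIATES = ("rh_a", "t_a", "par", "vpd")

#: Hourly microclimate means +/- standard errors per AF at the six reported
#: slot hours (local time, UTC-5).  Keys: (hour, af) -> variable -> (mean, se).
#: PAR is reported for the three daytime slots only.
SLOT_STATS: dict[tuple[int, str], dict[str, tuple[float, float]]] = {
    (10, "L_PAR"): {"rh_a": (88.32, 1.91), "t_a": (23.98, 0.43), "par": (354.51, 38.66), "vpd": (0.30, 0.05)},
    (10, "M_PAR"): {"rh_a": (81.69, 2.66), "t_a": (25.88, 0.49), "par": (446.25, 51.58), "vpd": (0.53, 0.08)},
    (10, "H_PAR"): {"rh_a": (80.26, 3.18), "t_a": (26.87, 0.67), "par": (1426.98, 216.07), "vpd": (0.56, 0.10)},
    (13, "L_PAR"): {"rh_a": (76.56, 2.69), "t_a": (26.63, 0.64), "par": (467.67, 45.80), "vpd": (0.69, 0.09)},
    (13, "M_PAR"): {"rh_a": (69.16, 3.10), "t_a": (28.44, 0.67), "par": (559.43, 51.88), "vpd": (1.00, 0.12)},
    (13, "H_PAR"): {"rh_a": (67.94, 3.45), "t_a": (29.75, 0.80), "par": (2278.98, 275.40), "vpd": (1.12, 0.15)},
    (16, "L_PAR"): {"rh_a": (80.11, 3.49), "t_a": (26.25, 0.86), "par": (216.88, 37.74), "vpd": (0.61, 0.13)},
    (16, "M_PAR"): {"rh_a": (76.51, 4.02), "t_a": (27.03, 0.81), "par": (238.44, 38.69), "vpd": (0.75, 0.15)},
    (16, "H_PAR"): {"rh_a": (78.24, 3.93), "t_a": (27.47, 0.89), "par": (778.36, 148.99), "vpd": (0.71, 0.14)},
    (20, "L_PAR"): {"rh_a": (97.86, 0.19), "t_a": (23.04, 0.17), "vpd": (0.05, 0.01)},
    (20, "M_PAR"): {"rh_a": (95.57, 0.37), "t_a": (23.27, 0.12), "vpd": (0.11, 0.01)},
    (20, "H_PAR"): {"rh_a": (95.06, 0.38), "t_a": (23.65, 0.12), "vpd": (0.12, 0.01)},
    (0, "L_PAR"): {"rh_a": (99.47, 0.08), "t_a": (21.99, 0.16), "vpd": (0.01, 0.01)},
    (0, "M_PAR"): {"rh_a": (98.41, 0.22), "t_a": (22.43, 0.12), "vpd": (0.04, 0.01)},
    (0, "H_PAR"): {"rh_a": (98.03, 0.18), "t_a": (22.79, 0.12), "vpd": (0.05, 0.01)},
    (4, "L_PAR"): {"rh_a": (99.84, 0.05), "t_a": (21.48, 0.13), "vpd": (0.00, 0.00)},
    (4, "M_PAR"): {"rh_a": (99.35, 0.09), "t_a": (22.21, 0.11), "vpd": (0.01, 0.01)},
    (4, "H_PAR"): {"rh_a": (99.03, 0.09), "t_a": (22.44, 0.10), "vpd": (0.05, 0.01)},
}

SLOT_HOURS = (10, 13, 16, 20, 0, 4)
DAY_SLOT_HOURS = (10, 13, 16)

#: Pearson correlations between sap flow and microclimate, per AF and pooled.
CORRELATIONS: dict[str, dict[str, float]] = {
    "General": {"rh_a": -0.78, "t_a": 0.73, "par": 0.75, "vpd": 0.77},
    "L_PAR": {"rh_a": -0.87, "t_a": 0.78, "par": 0.91, "vpd": 0.84},
    "M_PAR": {"rh_a": -0.93, "t_a": 0.90, "par": 0.90, "vpd": 0.92},
    "H_PAR": {"rh_a": -0.92, "t_a": 0.88, "par": 0.93, "vpd": 0.92},
}

#: Reference-coded coefficient table: term -> (estimate, standard error).
#: "H_PAR" rows are the baseline coefficients; "M_PAR"/"L_PAR" rows are
#: differences from the baseline; "M_vs_L" rows are M_PAR minus L_PAR.
TABLE_COEFFICIENTS_REFERENCE_CODED: dict[str, dict[str, tuple[float, float]]] = {
    "beta0": {
        "H_PAR": (0.14904, 0.02786),
        "M_PAR": (0.37090, 0.03559),
        "L_PAR": (-0.04641, 0.02349),
        "M_vs_L": (0.41732, 0.02908),
    },
    "rh_a": {
        "H_PAR": (-0.00059, 0.00022),
        "M_PAR": (-0.00409, 0.00033),
        "L_PAR": (-0.00057, 0.00021),
        "M_vs_L": (-0.00352, 0.00027),
    },
    "t_a": {
        "H_PAR": (-0.00258, 0.00046),
        "M_PAR": (-0.00043, 0.00036),
        "L_PAR": (0.00178, 0.00027),
        "M_vs_L": (-0.00220, 0.00030),
    },
    "par": {
        "H_PAR": (0.00007, 0.00001),
        "M_PAR": (0.00050, 0.00001),
        "L_PAR": (0.00001, 0.00001),
        "M_vs_L": (0.00049, 0.00001),
    },
    "vpd": {
        "H_PAR": (0.12195, 0.00697),
        "M_PAR": (-0.07844, 0.01113),
        "L_PAR": (-0.06120, 0.00721),
        "M_vs_L": (-0.01724, 0.00913),
    },
}

#: Per-AF absolute coefficients exactly as printed (intercept row preserved
#: verbatim even though it is inconsistent with the reference-coded table).
TABLE_COEFFICIENTS_ABSOLUTE: dict[str, dict[str, float]] = {
    "H_PAR": {"beta0": 0.14904, "rh_a": -0.00059, "t_a": -0.00258, "par": 0.00007, "vpd": 0.12195},
    "M_PAR": {"beta0": 0.37090, "rh_a": -0.00468, "t_a": -0.00301, "par": 0.00057, "vpd": 0.04351},
    "L_PAR": {"beta0": -0.04641, "rh_a": -0.00116, "t_a": -0.0008, "par": 0.00008, "vpd": 0.06075},
}

#: Reported nocturnal sap-flow means +/- SE (L/h) per AF.
NOCTURNAL_MEANS: dict[str, tuple[float, float]] = {
    "H_PAR": (0.0300, 0.0023),
    "M_PAR": (-0.0047, 0.0085),
    "L_PAR": (-0.0314, 0.004),
}

#: Reported share of the daily integrated flow volume that was basipetal (%).
REVERSED_FLOW_PROPORTION: dict[str, float] = {"L_PAR": 49.3, "M_PAR": 5.08}

#: Fit / validation sample sizes per AF and reported accuracy bounds.
N_FIT = 3816
N_VALIDATION = 1740
RMSE_RANGE_L_H = (0.01, 0.02)
R2_MIN = 0.95


def summed_coefficients() -> dict[str, dict[str, float]]:
    """Absolute coefficients obtained by summing the reference-coded table.

    Baseline rows pass through; difference rows are added to the baseline.
    """
    ref = TABLE_COEFFICIENTS_REFERENCE_CODED
    out: dict[str, dict[str, float]] = {af: {} for af in AFS}
    for term, rows in ref.items():
        base = rows["H_PAR"][0]
        out["H_PAR"][term] = base
        out["M_PAR"][term] = base + rows["M_PAR"][0]
        out["L_PAR"][term] = base + rows["L_PAR"][0]
    return out


def reconciled_coefficients() -> dict[str, dict[str, float]]:
    """The coefficient set used as the synthetic-data generating truth.

    Slopes are the printed absolute values; intercepts come from summing the
    reference-coded table (the only combination that reproduces the reported
    per-AF nocturnal flow signs).
    """
    out = {af: dict(TABLE_COEFFICIENTS_ABSOLUTE[af]) for af in AFS}
    summed = summed_coefficients()
    for af in AFS:
        out[af]["beta0"] = summed[af]["beta0"]
    return out
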
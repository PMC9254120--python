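"""Dose-response statistics for hormetic (Gαs/Gαi) cAMP pharmacology.

Glucagon-receptor cAMP responses are biphasic: Gαs-mediated stimulation
dominates at low agonist concentrations and Gαi-mediated inhibition at
higher ones, producing a bell-shaped concentration-response curve.  The
module fits

* a 3-parameter logistic (Hill slope fixed at 1),
      R(c) = basal + (Emax - basal) / (1 + EC50 / c),
* a "bell" model as the superposition of a stimulatory and an inhibitory
  logistic,
      R(c) = basal + span_s / (1 + EC50_s / c) - span_i / (1 + EC50_i / c),
  with EC50_i >= EC50_s enforced through the parameterisation
  EC50_i = EC50_s * 10**delta, delta >= 0 (inhibition needs more agonist
  than stimulation),

and implements the derived measures used downstream: the Gαi component as
the pointwise difference between the pertussis-toxin (Gαs-only) curve and
the total response, the combined agonism index log10[(Emax/EC50) /
(Emax/EC50)_vehicle], its linear regression against cellular cholesterol,
and the glucagon-alanine index (fasting glucagon [pmol/L] x alanine
[mmol/L]), a surrogate marker of glucagon resistance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import t as t_dist

__all__ = [
    "DoseResponseDataset",
    "DoseResponseFit",
    "AgonismIndex",
    "fit_logistic3",
    "fit_bell",
    "gi_component",
    "agonism_index",
    "cholesterol_response_regression",
    "glucagon_alanine_index",
]


@dataclass
class DoseResponseDataset:
    """Tidy dose-response data for one condition.

    ``concentrations_m`` are agonist concentrations in mol/L (must be > 0;
    log-spacing is typical); ``responses`` are in whatever assay units the
    caller uses (the module treats units as opaque).
    """

    concentrations_m: np.ndarray
    responses: np.ndarray
    condition: str = ""
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations_m = np.asarray(self.concentrations_m, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations_m.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations_m <= 0):
            raise ValueError("concentrations must be positive")

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.concentrations_m).size)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str) -> "DoseResponseDataset":
        sub = df[df["condition"] == condition]
        return cls(
            concentrations_m=sub["concentration_M"].to_numpy(),
            responses=sub["response"].to_numpy(),
            condition=condition,
            replicate=(sub["replicate"].to_numpy()
                       if "replicate" in sub else None),
        )


@dataclass
class DoseResponseFit:
    """Fitted 3-parameter logistic or bell model."""

    model: str  # "logistic3" | "bell"
    basal: float
    emax: float  # fitted curve maximum (for bell: max over concentration)
    ec50_m: float  # logistic3 EC50; for bell, EC50 of the stimulatory arm
    r_squared: float
    span_s: float | None = None
    ec50_s_m: float | None = None
    span_i: float | None = None
    ec50_i_m: float | None = None
    collapsed_to_logistic3: bool = False

    def __post_init__(self) -> None:
        if self.ec50_m <= 0:
            raise ValueError("EC50 must be positive")

    def predict(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        if self.model == "logistic3":
            return self.basal + (self.emax - self.basal) / (1 + self.ec50_m / c)
        return (self.basal
                + self.span_s / (1 + self.ec50_s_m / c)
                - self.span_i / (1 + self.ec50_i_m / c))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "basal": self.basal,
            "emax": self.emax,
            "ec50_m": self.ec50_m,
            "span_s": self.span_s,
            "ec50_s_m": self.ec50_s_m,
            "span_i": self.span_i,
            "ec50_i_m": self.ec50_i_m,
            "r_squared": self.r_squared,
            "collapsed_to_logistic3": self.collapsed_to_logistic3,
        }


@dataclass(frozen=True)
class AgonismIndex:
    """log10-transformed Emax/EC50 normalised to vehicle."""

    value: float
    treatment: str


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    rss = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - rss / tss if tss > 0 else 1.0


def fit_logistic3(data: DoseResponseDataset) -> DoseResponseFit:
    """3-parameter logistic fit with Hill slope fixed at 1.

    Parameterised with log10 EC50 and solved by trust-region least squares
    from several deterministic starts spanning the concentration range.
    """
    if data.n_distinct < 4:
        raise ValueError("need >= 4 distinct concentrations for a 3-parameter fit")
    c, y = data.concentrations_m, data.responses
    logc = np.log10(c)

    def resid(p):
        basal, emax, logec50 = p
        return basal + (emax - basal) / (1 + 10.0 ** (logec50 - logc)) - y

    y_lo, y_hi = float(y.min()), float(y.max())
    spread = max(y_hi - y_lo, 1e-9)
    best = None
    for logec0 in np.linspace(logc.min(), logc.max(), 5):
        sol = least_squares(
            resid, [y_lo, y_hi, logec0],
            bounds=([y_lo - 10 * spread, y_lo - 10 * spread, logc.min() - 6],
                    [y_hi + 10 * spread, y_hi + 10 * spread, logc.max() + 6]),
            method="trf", max_nfev=5000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e6:
        raise RuntimeError("logistic fit did not converge")
    basal, emax, logec50 = best.x
    pred = basal + (emax - basal) / (1 + 10.0 ** (logec50 - logc))
    return DoseResponseFit(
        model="logistic3", basal=float(basal), emax=float(emax),
        ec50_m=float(10.0 ** logec50), r_squared=_r2(y, pred),
    )


def fit_bell(data: DoseResponseDataset,
             collapse_tol: float = 1e-3) -> DoseResponseFit:
    """Bell (stimulatory minus inhibitory logistic) fit.

    When the fitted inhibitory span is negligible relative to the
    stimulatory span the result is reported as collapsed to the
    3-parameter logistic.
    """
    if data.n_distinct < 6:
        raise ValueError("need >= 6 distinct concentrations for a bell fit")
    c, y = data.concentrations_m, data.responses
    logc = np.log10(c)

    def model(p):
        basal, span_s, logec_s, span_i, delta = p
        stim = span_s / (1 + 10.0 ** (logec_s - logc))
        inhib = span_i / (1 + 10.0 ** (logec_s + delta - logc))
        return basal + stim - inhib

    def resid(p):
        return model(p) - y

    y_lo, y_hi = float(y.min()), float(y.max())
    spread = max(y_hi - y_lo, 1e-9)
    best = None
    for logec0 in np.linspace(logc.min(), logc.max(), 4):
        for delta0 in (0.5, 1.0, 2.0):
            p0 = [y_lo, spread, logec0, spread / 2, delta0]
            sol = least_squares(
                resid, p0,
                bounds=([y_lo - 10 * spread, 0.0, logc.min() - 6, 0.0, 0.0],
                        [y_hi + 10 * spread, 20 * spread, logc.max() + 6,
                         20 * spread, 12.0]),
                method="trf", max_nfev=10000,
            )
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("bell fit did not converge")
    basal, span_s, logec_s, span_i, delta = best.x
    pred = model(best.x)
    ec50_s = float(10.0 ** logec_s)
    ec50_i = float(10.0 ** (logec_s + delta))

    collapsed = span_i <= collapse_tol * max(span_s, 1e-12)
    grid = np.logspace(logc.min() - 2, logc.max() + 2, 2000)
    curve = (basal + span_s / (1 + ec50_s / grid) - span_i / (1 + ec50_i / grid))
    return DoseResponseFit(
        model="bell", basal=float(basal), emax=float(curve.max()),
        ec50_m=ec50_s, r_squared=_r2(y, pred),
        span_s=float(span_s), ec50_s_m=ec50_s,
        span_i=float(span_i), ec50_i_m=ec50_i,
        collapsed_to_logistic3=bool(collapsed),
    )


def gi_component(
    total: DoseResponseDataset,
    ptx: DoseResponseDataset,
) -> pd.DataFrame:
    """Gαi component: pertussis-toxin (Gαs-only) minus total response.

    Both datasets must share an identical concentration grid (replicates are
    averaged per concentration first).  Returns a per-concentration table of
    the positive-signed Gαi suppression plus its AUC over log10
    concentration (trapezoid rule), stored in ``DataFrame.attrs["auc"]``.
    """
    def mean_by_conc(ds: DoseResponseDataset) -> tuple[np.ndarray, np.ndarray]:
        conc = np.unique(ds.concentrations_m)
        resp = np.array([
            ds.responses[ds.concentrations_m == cc].mean() for cc in conc
        ])
        return conc, resp

    conc_t, resp_t = mean_by_conc(total)
    conc_p, resp_p = mean_by_conc(ptx)
    if conc_t.size != conc_p.size or not np.allclose(conc_t, conc_p,
                                                     rtol=1e-9, atol=0.0):
        raise ValueError("total and PTX datasets must share the concentration grid")

    component = resp_p - resp_t  # suppression, positive when Gαi is active
    out = pd.DataFrame({
        "concentration_M": conc_t,
        "total": resp_t,
        "ptx": resp_p,
        "gi_component": component,
    })
    out.attrs["auc"] = float(np.trapezoid(component, np.log10(conc_t)))
    return out


def agonism_index(
    treatment_fit: DoseResponseFit,
    vehicle_fit: DoseResponseFit,
    treatment: str = "",
) -> AgonismIndex:
    """log10 of (Emax/EC50) normalised to the vehicle fit.

    Invariant to rescaling both curves' response units by a common factor;
    the vehicle's own index is exactly 0.
    """
    for fit in (treatment_fit, vehicle_fit):
        if fit.emax <= 0 or fit.ec50_m <= 0:
            raise ValueError("Emax and EC50 must be positive")
    value = float(
        np.log10((treatment_fit.emax / treatment_fit.ec50_m)
                 / (vehicle_fit.emax / vehicle_fit.ec50_m))
    )
    return AgonismIndex(value=value, treatment=treatment)


def cholesterol_response_regression(
    cholesterol: np.ndarray,
    indices: np.ndarray,
) -> dict:
    """OLS of agonism index on relative cellular cholesterol.

    Returns slope, intercept, R^2 and 95% CIs on both coefficients.
    """
    x = np.asarray(cholesterol, dtype=float)
    y = np.asarray(indices, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points for regression")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in cholesterol values")
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    pred = intercept + slope * x
    rss = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    dof = n - 2
    sigma2 = rss / dof if dof > 0 else 0.0
    se_slope = float(np.sqrt(sigma2 / sxx))
    se_int = float(np.sqrt(sigma2 * (1.0 / n + xm**2 / sxx)))
    tcrit = float(t_dist.ppf(0.975, dof)) if dof > 0 else np.inf
    return {
        "slope": slope,
        "intercept": intercept,
        "r_squared": r2,
        "slope_ci95": (slope - tcrit * se_slope, slope + tcrit * se_slope),
        "intercept_ci95": (intercept - tcrit * se_int, intercept + tcrit * se_int),
        "n": n,
    }


def glucagon_alanine_index(glucagon_pmol_l: float, alanine_mmol_l: float) -> float:
    """Fasting glucagon (pmol/L) x fasting alanine (mmol/L)."""
    if glucagon_pmol_l < 0 or alanine_mmol_l < 0:
        raise ValueError("glucagon and alanine levels must be non-negative")
    return float(glucagon_pmol_l * alanine_mmol_l)
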
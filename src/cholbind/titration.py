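"""Occupancy titration: apparent Kd from binding saturation curves.

Simulating the same protein in bilayers of increasing cholesterol content
and plotting site occupancy against the free (unbound) cholesterol mole
percentage yields a saturation curve,

    Occ(x) = Occ_max * x / (Kd_app + x),

whose half-saturation point Kd_app is an apparent dissociation constant in
mole-% units — the membrane-embedded analogue of a solution binding
constant.  "Free cholesterol %" is defined here as the time-averaged number
of cholesterol molecules not in dual-cutoff contact with any protein
residue, normalised by the total lipid count; this corrects the nominal
bilayer composition for protein-sequestered cholesterol.

Non-specific (non-saturable) background binding shows up as an
approximately linear occupancy-vs-x trend; it can either be fitted as an
additive linear term or detected and flagged when the hyperbolic fit fails
to saturate within the sampled composition range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit, minimize_scalar
from scipy.stats import f as f_dist

from .contacts import ContactParameters, ContactRecord
from .md_io import Topology, Trajectory

__all__ = [
    "TitrationPoint",
    "SaturationFit",
    "free_cholesterol_percent",
    "site_occupancy_percent",
    "fit_saturation",
    "aggregate_replicates",
]

#: Kd above this multiple of the largest sampled composition is reported as
#: non-saturable (the curve is indistinguishable from a straight line)
NONSATURABLE_KD_FACTOR = 5.0


@dataclass(frozen=True)
class TitrationPoint:
    """One composition: free cholesterol % vs site occupancy %."""

    x_free_pct: float
    occupancy_pct: float
    occupancy_se: float | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_free_pct <= 100.0):
            raise ValueError("free cholesterol % must be in [0, 100]")
        if not (0.0 <= self.occupancy_pct <= 100.0):
            raise ValueError("occupancy % must be in [0, 100]")


@dataclass
class SaturationFit:
    """Hyperbolic saturation fit: Kd_app and Occ_max with uncertainty.

    ``kd_ci95`` is a profile-likelihood (F-test inversion) interval: the
    apparent Kd is a ratio-like parameter whose sampling distribution is
    skewed at small design sizes, so the Wald interval from the covariance
    under-covers while the profile interval tracks the asymmetry.
    """

    kd_app_pct: float | None
    kd_se: float | None
    occ_max_pct: float | None
    occ_max_se: float | None
    nonspecific_slope: float | None
    r_squared: float
    n_points: int
    kd_ci95: tuple[float, float] | None = None
    flagged: bool = False
    flag_reason: str | None = None

    def to_dict(self) -> dict:
        ci = self.kd_ci95
        return {
            "kd_app_pct": self.kd_app_pct,
            "kd_se": self.kd_se,
            "kd_ci95_low": None if ci is None else ci[0],
            "kd_ci95_high": None if ci is None else ci[1],
            "occ_max_pct": self.occ_max_pct,
            "occ_max_se": self.occ_max_se,
            "nonspecific_slope": self.nonspecific_slope,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "flagged": self.flagged,
            "flag_reason": self.flag_reason,
            "x_definition": "unbound cholesterol over all lipids, time-averaged",
        }


def free_cholesterol_percent(
    trajectory: Trajectory,
    topology: Topology,
    contacts: list[ContactRecord],
    params: ContactParameters | None = None,
) -> float:
    """Time-averaged mole % of cholesterol not bound to any protein residue.

    x = 100 * <#cholesterol with no dual-cutoff contact>_frames / #lipids.
    ``contacts`` must come from the same trajectory/parameters.
    """
    n_lipids = len(topology.lipids)
    if n_lipids == 0:
        raise ValueError("topology contains no lipid molecules")
    chol = topology.lipids_of_type("cholesterol")
    if not chol:
        return 0.0
    n_frames = (
        contacts[0].bound.size if contacts
        else int(np.ceil(trajectory.frame_count / (params.stride if params else 1)))
    )
    bound_any: dict[int, np.ndarray] = {}
    for rec in contacts:
        if rec.lipid_id in bound_any:
            bound_any[rec.lipid_id] |= rec.bound
        else:
            bound_any[rec.lipid_id] = rec.bound.copy()
    n_bound = np.zeros(n_frames)
    chol_ids = {l.mol_id for l in chol}
    for lid, bound in bound_any.items():
        if lid in chol_ids:
            n_bound += bound
    free_mean = len(chol) - float(n_bound.mean())
    return 100.0 * free_mean / n_lipids


def site_occupancy_percent(
    site_residues: list[str],
    contacts: list[ContactRecord],
) -> float:
    """Percentage of frames in which >= 1 lipid is bound to >= 1 site residue."""
    residue_set = set(site_residues)
    any_bound = None
    for rec in contacts:
        if rec.residue not in residue_set:
            continue
        if any_bound is None:
            any_bound = rec.bound.copy()
        else:
            any_bound |= rec.bound
    return 0.0 if any_bound is None else float(any_bound.mean() * 100.0)


def aggregate_replicates(
    replicates: list[tuple[float, float]],
) -> TitrationPoint:
    """Combine per-replicate (x, occupancy) pairs into one titration point.

    x and occupancy are averaged over replicates; the occupancy SE is the
    standard error of the mean across replicates.
    """
    if not replicates:
        raise ValueError("no replicates")
    xs = np.array([r[0] for r in replicates])
    occs = np.array([r[1] for r in replicates])
    se = (
        float(occs.std(ddof=1) / np.sqrt(len(occs))) if len(occs) > 1 else None
    )
    return TitrationPoint(
        x_free_pct=float(xs.mean()),
        occupancy_pct=float(occs.mean()),
        occupancy_se=se,
        n_replicates=len(replicates),
    )


def _hyperbola(x, occ_max, kd):
    return occ_max * x / (kd + x)


def _hyperbola_ns(x, occ_max, kd, m):
    return occ_max * x / (kd + x) + m * x


#: Kd search range for the profile (mole %); beyond x_max * factor the curve
#: is operationally a straight line
_KD_GRID = np.logspace(-3, 4, 300)


def _profile_rss(kd: float, xs: np.ndarray, occ: np.ndarray, w: np.ndarray,
                 include_ns: bool) -> tuple[float, np.ndarray]:
    """RSS minimised over the linear parameters (Occ_max [, m]) at fixed Kd."""
    h = xs / (kd + xs)
    design = np.column_stack([h, xs]) if include_ns else h[:, None]
    sw = np.sqrt(w)[:, None]
    coef, *_ = np.linalg.lstsq(design * sw, occ * sw[:, 0], rcond=None)
    resid = occ * sw[:, 0] - (design * sw) @ coef
    return float(resid @ resid), coef


def fit_saturation(
    points: list[TitrationPoint],
    include_nonspecific: bool = False,
) -> SaturationFit:
    """Fit Occ(x) = Occ_max * x / (Kd_app + x) [+ m*x] to titration points.

    Weighted by 1/SE^2 when every point carries an SE.  Kd_app is profiled:
    at each candidate Kd the remaining parameters are linear and solved in
    closed form, the point estimate minimises the profiled RSS, and the 95%
    CI inverts the F test on the profiled RSS.  Occ_max is reported
    truncated to the physical (0, 100] range; parameter SEs come from the
    local covariance at the optimum.  Degenerate inputs — all-zero
    occupancy, or a curve that does not approach saturation inside the
    sampled composition range — return a flagged fit rather than raising.
    """
    xs = np.array([p.x_free_pct for p in points], dtype=float)
    occ = np.array([p.occupancy_pct for p in points], dtype=float)
    if np.unique(xs).size < 3:
        raise ValueError("need >= 3 distinct free-cholesterol compositions")
    n = xs.size
    if np.allclose(occ, 0.0):
        return SaturationFit(None, None, None, None, None, 0.0, n,
                             flagged=True, flag_reason="all occupancies zero")

    ses = [p.occupancy_se for p in points]
    w = (
        np.array([1.0 / max(s, 1e-6) ** 2 for s in ses], dtype=float)
        if all(s is not None and s > 0 for s in ses)
        else np.ones(n)
    )

    # profile minimisation: coarse log grid, then local refinement
    rss_grid = [_profile_rss(k, xs, occ, w, include_nonspecific)[0]
                for k in _KD_GRID]
    i = int(np.argmin(rss_grid))
    lo_b = _KD_GRID[max(i - 1, 0)]
    hi_b = _KD_GRID[min(i + 1, len(_KD_GRID) - 1)]
    res = minimize_scalar(
        lambda k: _profile_rss(k, xs, occ, w, include_nonspecific)[0],
        bounds=(lo_b, hi_b), method="bounded",
        options={"xatol": 1e-10},
    )
    kd = float(res.x)
    rss0, coef = _profile_rss(kd, xs, occ, w, include_nonspecific)
    occ_max = float(coef[0])
    slope = float(coef[1]) if include_nonspecific else None
    if occ_max <= 0:
        return SaturationFit(None, None, None, None, slope, 0.0, n,
                             flagged=True,
                             flag_reason="no saturable binding component")

    n_params = 3 if include_nonspecific else 2
    dof = n - n_params
    ci = None
    if dof > 0 and rss0 >= 0:
        thresh = rss0 * (1.0 + f_dist.ppf(0.95, 1, dof) / dof) + 1e-12

        def excess(k):
            return _profile_rss(k, xs, occ, w, include_nonspecific)[0] - thresh

        lo_end, hi_end = 1e-4, 1e5
        ci_lo = brentq(excess, lo_end, kd) if excess(lo_end) > 0 else 0.0
        ci_hi = brentq(excess, kd, hi_end) if excess(hi_end) > 0 else np.inf
        ci = (min(float(ci_lo), kd), max(float(ci_hi), kd))

    # local covariance for reported SEs
    kd_se = occ_max_se = None
    try:
        model = _hyperbola_ns if include_nonspecific else _hyperbola
        p0 = [occ_max, kd] + ([slope] if include_nonspecific else [])
        sigma = 1.0 / np.sqrt(w)
        _, pcov = curve_fit(model, xs, occ, p0=p0, sigma=sigma,
                            absolute_sigma=False, maxfev=10000)
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        occ_max_se, kd_se = float(perr[0]), float(perr[1])
    except RuntimeError:
        pass

    pred = _hyperbola(xs, occ_max, kd) + (slope * xs if slope else 0.0)
    tss = float(np.sum(w * (occ - np.average(occ, weights=w)) ** 2))
    r2 = 1.0 - rss0 / tss if tss > 0 else 1.0

    fit = SaturationFit(
        kd_app_pct=kd, kd_se=kd_se,
        occ_max_pct=min(occ_max, 100.0), occ_max_se=occ_max_se,
        nonspecific_slope=slope, r_squared=r2, n_points=n, kd_ci95=ci,
    )
    if kd > NONSATURABLE_KD_FACTOR * float(xs.max()):
        fit.flagged = True
        fit.flag_reason = "non-saturable: Kd far beyond sampled compositions"
    return fit


def points_to_frame(points: list[TitrationPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "x_free_pct": p.x_free_pct,
            "occupancy_pct": p.occupancy_pct,
            "occupancy_se": p.occupancy_se,
            "n_replicates": p.n_replicates,
        } for p in points],
        columns=["x_free_pct", "occupancy_pct", "occupancy_se", "n_replicates"],
    )
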
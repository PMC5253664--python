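"""Pseudo-first-order oxidation kinetics.

Radiolysis dose-response data arrive as chromatographic peak areas of the
unoxidized and oxidized species of each peptide at a series of X-ray
exposure times (milliseconds). The unmodified fraction Y decays as
Y = Y0 * exp(-k t); the fitted k (reported in 1/s) is the footprinting
oxidation rate constant for the mapped site.

Fitting is two-stage: a log-linear regression of ln Y on t supplies the
initial estimate (points with Y <= 0 excluded), then nonlinear least
squares refines (Y0, k) on the exponential form. Replicates are pooled
into one fit by default; ``pooled=False`` fits each replicate separately
and averages, for diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .structio import SiteAssignment

__all__ = [
    "OxidationSeries",
    "RateConstant",
    "unmodified_fraction",
    "fit_first_order",
    "consolidate_rates",
    "series_from_table",
    "fit_rate_table",
]


class KineticsError(ValueError):
    pass


class InsufficientDataError(KineticsError):
    pass


class FitFailureError(KineticsError):
    pass


@dataclass
class OxidationSeries:
    """Dose-response measurements for one oxidized species at one site.

    ``points`` maps replicate id -> (times in ms, unmodified fractions).
    """

    site: SiteAssignment
    species: str
    mod_mass: float
    points: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for rep, (t, y) in self.points.items():
            t = np.asarray(t, dtype=float)
            y = np.asarray(y, dtype=float)
            if t.size < 3:
                raise InsufficientDataError(
                    f"replicate {rep}: need >= 3 time points, got {t.size}"
                )
            if np.any(t < 0) or np.any(np.diff(t) <= 0):
                raise KineticsError(
                    f"replicate {rep}: times must be non-negative and strictly increasing"
                )
            if t[0] != 0:
                raise KineticsError(f"replicate {rep}: a t=0 point is required")
            self.points[rep] = (t, y)


@dataclass
class RateConstant:
    """A fitted first-order rate: k (1/s) with amplitude and diagnostics."""

    k: float
    Y0: float
    sd_k: float
    n_replicates: int
    n_points: int
    rss: float
    site: SiteAssignment | None = None
    species: str = ""
    mod_mass: float = float("nan")

    def __post_init__(self) -> None:
        if self.k < 0:
            raise KineticsError("rate constant must be non-negative")
        if not (0 < self.Y0 <= 1.05):
            raise KineticsError(f"Y0 {self.Y0} outside (0, 1.05]")


def unmodified_fraction(area_unmod: float, areas_mod: list[float]) -> float:
    """Unoxidized peak area over the total of unoxidized + oxidized areas."""
    if area_unmod < 0 or any(a < 0 for a in areas_mod):
        raise KineticsError("peak areas must be non-negative")
    total = area_unmod + sum(areas_mod)
    if total <= 0:
        raise KineticsError("total peak area is zero; fraction undefined")
    return area_unmod / total


def _model(t: np.ndarray, y0: float, k: float) -> np.ndarray:
    return y0 * np.exp(-k * t)


def _loglinear_init(t_s: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    mask = y > 0
    if mask.sum() < 2:
        return 1.0, 0.0
    slope, intercept = np.polyfit(t_s[mask], np.log(y[mask]), 1)
    return float(np.exp(intercept)), max(float(-slope), 0.0)


def _fit_points(t_s: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    y0_init, k_init = _loglinear_init(t_s, y)
    y0_init = min(max(y0_init, 1e-6), 1.05)
    # Peak-area noise is multiplicative, so residuals scale with Y itself;
    # weighting by Y makes the fit homoscedastic and its covariance honest.
    sigma = np.maximum(y, 1e-3 * max(float(np.max(y)), 1e-12))
    try:
        popt, pcov = curve_fit(
            _model,
            t_s,
            y,
            p0=[y0_init, k_init],
            sigma=sigma,
            bounds=([1e-9, 0.0], [1.05, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise FitFailureError(
            f"exponential fit did not converge (init Y0={y0_init:.3g}, "
            f"k={k_init:.3g}/s): {exc}"
        ) from exc
    y0, k = popt
    sd_k = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    rss = float(np.sum((y - _model(t_s, y0, k)) ** 2))
    if k <= 1e-9 and y.size > 1 and y[-1] > y[0]:
        warnings.warn(
            "fitted k pinned at 0 with increasing unmodified fraction; "
            "check peak assignment",
            stacklevel=3,
        )
    return float(y0), float(k), sd_k, rss


def fit_first_order(series: OxidationSeries, pooled: bool = True) -> RateConstant:
    """Fit Y = Y0*exp(-k t) to a dose-response series; k in 1/s.

    With ``pooled`` (default) all replicates enter a single least-squares
    fit and sd_k comes from the fit covariance. With ``pooled=False`` each
    replicate is fitted separately; k is their mean and sd_k the
    across-replicate standard deviation.
    """
    reps = list(series.points)
    if pooled or len(reps) == 1:
        t_all = np.concatenate([series.points[r][0] for r in reps]) / 1000.0
        y_all = np.concatenate([series.points[r][1] for r in reps])
        y0, k, sd_k, rss = _fit_points(t_all, y_all)
        return RateConstant(
            k=k, Y0=y0, sd_k=sd_k, n_replicates=len(reps), n_points=t_all.size,
            rss=rss, site=series.site, species=series.species,
            mod_mass=series.mod_mass,
        )
    ks, rsss, npts = [], 0.0, 0
    for r in reps:
        t, y = series.points[r]
        _, k, _, rss = _fit_points(t / 1000.0, y)
        ks.append(k)
        rsss += rss
        npts += t.size
    k_mean = float(np.mean(ks))
    sd = float(np.std(ks, ddof=1)) if len(ks) > 1 else float("nan")
    y0_pool, _, _, _ = _fit_points(
        np.concatenate([series.points[r][0] for r in reps]) / 1000.0,
        np.concatenate([series.points[r][1] for r in reps]),
    )
    return RateConstant(
        k=k_mean, Y0=y0_pool, sd_k=sd, n_replicates=len(reps), n_points=npts,
        rss=rsss, site=series.site, species=series.species,
        mod_mass=series.mod_mass,
    )


def series_from_table(df: pd.DataFrame) -> list[OxidationSeries]:
    """Group a rates table (structio schema) into per-species series.

    Rows sharing (peptide_id, site, mod_mass) form one species; the
    unmodified fraction of each row is area_unmod / (area_unmod + area_mod).
    """
    out: list[OxidationSeries] = []
    for (pep, site_str, mod), grp in df.groupby(
        ["peptide_id", "site", "mod_mass"], sort=True
    ):
        site = SiteAssignment.parse(str(site_str))
        points: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for rep, sub in grp.groupby("replicate"):
            sub = sub.sort_values("time_ms")
            y = np.array(
                [
                    unmodified_fraction(u, [m])
                    for u, m in zip(sub["area_unmod"], sub["area_mod"])
                ]
            )
            points[str(rep)] = (sub["time_ms"].to_numpy(float), y)
        out.append(
            OxidationSeries(
                site=site, species=f"{pep}+{mod:g}", mod_mass=float(mod),
                points=points,
            )
        )
    return out


def consolidate_rates(fits: list[RateConstant]) -> pd.DataFrame:
    """Collect per-species fits into a per-(site, species) rate table."""
    seen: set[tuple[str, str]] = set()
    rows = []
    for f in fits:
        if f.site is None:
            raise KineticsError("fit lacks a site assignment")
        key = (str(f.site), f.species)
        if key in seen:
            raise KineticsError(f"duplicate (site, species) key {key}")
        seen.add(key)
        rows.append(
            {
                "site": str(f.site),
                "residues": "".join(r.code for r in f.site.residues),
                "mod_mass": f.mod_mass,
                "species": f.species,
                "k_per_s": f.k,
                "sd_k": f.sd_k,
                "n_points": f.n_points,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["site", "residues", "mod_mass", "species", "k_per_s", "sd_k",
                 "n_points"],
    )


def fit_rate_table(df: pd.DataFrame, pooled: bool = True) -> pd.DataFrame:
    """Convenience: dose-response table in -> consolidated rate table out."""
    return consolidate_rates(
        [fit_first_order(s, pooled=pooled) for s in series_from_table(df)]
    )
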
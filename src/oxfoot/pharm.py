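"""Sigmoidal dose-response pharmacology for BRET recruitment assays.

Arrestin-recruitment responses as a function of agonist concentration are
fitted with the four-parameter logistic

    y = bottom + (top - bottom) / (1 + 10^((log10 EC50 - log10 x) * h)),

with the Hill slope h free but bounded. Emax is top - bottom (the
response swing between zero and saturating ligand) and pEC50 = -log10
EC50 (in molar). Mutant constructs are interpreted against wild type
measured in the same session: dpEC50 = pEC50_mut - pEC50_WT and
%Emax = Emax_mut / Emax_WT * 100.

Zero-dose wells cannot sit on a log axis, so they anchor the bottom
parameter as data points at a pseudo-concentration three decades below
the lowest tested dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseCurve",
    "PotencyEstimate",
    "fit_dose_response",
    "normalize_to_wt",
    "fold_potency",
    "curve_from_table",
]

HILL_BOUNDS = (0.3, 5.0)


class PharmError(ValueError):
    pass


@dataclass
class DoseResponseCurve:
    """One ligand's dose-response points, with zero-dose wells kept aside."""

    ligand: str
    conc_M: np.ndarray
    response: np.ndarray
    baseline: np.ndarray = field(default_factory=lambda: np.array([]))
    construct: str = "WT"
    session: str = "1"

    def __post_init__(self) -> None:
        self.conc_M = np.asarray(self.conc_M, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if np.any(self.conc_M <= 0):
            raise PharmError(
                "concentrations must be positive; store zero-dose wells as baseline"
            )
        if np.unique(self.conc_M).size < 4:
            raise PharmError("need >= 4 distinct concentrations")


@dataclass(frozen=True)
class PotencyEstimate:
    pEC50: float
    se_pEC50: float
    Emax: float
    se_Emax: float
    hill: float
    bottom: float
    ligand: str = ""
    construct: str = "WT"
    session: str = "1"

    @property
    def EC50(self) -> float:
        return 10.0 ** (-self.pEC50)


def _logistic(logx: np.ndarray, bottom: float, top: float,
              logec50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logec50 - logx) * hill))


def fit_dose_response(curve: DoseResponseCurve) -> PotencyEstimate:
    """Four-parameter logistic fit; returns pEC50, Emax, Hill slope + SEs."""
    logx = np.log10(curve.conc_M)
    y = curve.response
    if curve.baseline.size:
        pseudo = logx.min() - 3.0
        logx = np.concatenate([np.full(curve.baseline.size, pseudo), logx])
        y = np.concatenate([curve.baseline, y])

    span = float(y.max() - y.min())
    if span < 1e-12 or span < 0.02 * max(abs(y).max(), 1e-12):
        warnings.warn(
            f"{curve.ligand}: flat dose-response; Emax ~ 0 and EC50 undefined",
            stacklevel=2,
        )
        return PotencyEstimate(
            pEC50=float("nan"), se_pEC50=float("nan"), Emax=0.0,
            se_Emax=float("nan"), hill=float("nan"), bottom=float(y.mean()),
            ligand=curve.ligand, construct=curve.construct, session=curve.session,
        )

    p0 = [float(y.min()), float(y.max()), float(np.median(logx)), 1.0]
    lo = [y.min() - 2 * span, y.min() - 2 * span, logx.min() - 4, HILL_BOUNDS[0]]
    hi = [y.max() + 2 * span, y.max() + 2 * span, logx.max() + 4, HILL_BOUNDS[1]]
    try:
        popt, pcov = curve_fit(_logistic, logx, y, p0=p0, bounds=(lo, hi),
                               maxfev=20_000)
    except RuntimeError as exc:
        raise PharmError(
            f"{curve.ligand}: logistic fit did not converge: {exc}"
        ) from exc
    bottom, top, logec50, hill = popt
    perr = np.sqrt(np.diag(pcov))
    se_emax = float(np.sqrt(pcov[0, 0] + pcov[1, 1] - 2 * pcov[0, 1]))
    if not (curve.conc_M.min() <= 10**logec50 <= curve.conc_M.max()):
        warnings.warn(
            f"{curve.ligand}: fitted EC50 {10**logec50:.3g} M lies outside the "
            "tested concentration range; potency is an extrapolation",
            stacklevel=2,
        )
    return PotencyEstimate(
        pEC50=float(-logec50), se_pEC50=float(perr[2]),
        Emax=float(top - bottom), se_Emax=se_emax, hill=float(hill),
        bottom=float(bottom), ligand=curve.ligand, construct=curve.construct,
        session=curve.session,
    )


def normalize_to_wt(
    mutant: PotencyEstimate, wt_same_day: PotencyEstimate
) -> tuple[float, float]:
    """(dpEC50, %Emax) of a mutant against same-session wild type."""
    if mutant.session != wt_same_day.session:
        raise PharmError(
            f"session mismatch: {mutant.session!r} vs {wt_same_day.session!r}; "
            "mutants are normalized against WT measured the same day"
        )
    if wt_same_day.Emax == 0:
        raise PharmError("WT Emax is zero; %Emax undefined")
    return (
        mutant.pEC50 - wt_same_day.pEC50,
        mutant.Emax / wt_same_day.Emax * 100.0,
    )


def fold_potency(
    estimate_a: PotencyEstimate | float, estimate_b: PotencyEstimate | float
) -> tuple[float, int]:
    """EC50_a / EC50_b as (exact fold, rounded convenience fold).

    Accepts PotencyEstimates or raw EC50 values in molar.
    """
    ec_a = estimate_a.EC50 if isinstance(estimate_a, PotencyEstimate) else estimate_a
    ec_b = estimate_b.EC50 if isinstance(estimate_b, PotencyEstimate) else estimate_b
    if not (ec_a > 0 and ec_b > 0):
        raise PharmError("EC50 values must be positive")
    fold = ec_a / ec_b
    return fold, int(round(fold))


def curve_from_table(
    df: pd.DataFrame, ligand: str, construct: str = "WT", session: str | None = None
) -> DoseResponseCurve:
    """Extract one ligand/construct curve from a BRET table (structio schema)."""
    sel = (df["ligand"] == ligand) & (df["construct"] == construct)
    if session is not None:
        sel &= df["session"] == session
    sub = df[sel]
    if sub.empty:
        raise PharmError(f"no rows for ligand={ligand!r} construct={construct!r}")
    dosed = sub[sub["conc_M"] > 0]
    zero = sub[sub["conc_M"] == 0]
    return DoseResponseCurve(
        ligand=ligand,
        conc_M=dosed["conc_M"].to_numpy(float),
        response=dosed["response"].to_numpy(float),
        baseline=zero["response"].to_numpy(float),
        construct=construct,
        session=str(sub["session"].iloc[0]),
    )
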
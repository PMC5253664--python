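"""Calibration of protection against solvent accessibility.

On a reference state with a known structure, ln PF falls linearly with
fractional side-chain SASA (buried residues oxidize slowly, so their
protection factors are large). Ordinary least squares of

    ln PF = a + b * fSASA      (b < 0 for a working experiment)

yields the calibration; inverting it converts ln PF measured in a second,
structurally uncharacterized state into predicted fractional (and, via
the reference areas, absolute) accessibility. The Pearson correlation R
of the calibration pairs is the standard quality readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationModel",
    "calibrate",
    "predict_bound_fsasa",
    "delta_accessibility",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationModel:
    """Linear ln PF = intercept + slope * fSASA fit."""

    slope: float
    intercept: float
    pearson_r: float
    n: int
    residual_se: float

    def predict_lnpf(self, fsasa: float) -> float:
        return self.intercept + self.slope * fsasa

    def invert(self, lnpf: float) -> float:
        if self.slope == 0:
            raise CalibrationError("zero slope: calibration not invertible")
        return (lnpf - self.intercept) / self.slope


def calibrate(pairs: list[tuple[float, float]] | np.ndarray) -> CalibrationModel:
    """Fit ln PF on fSASA by OLS and report the Pearson correlation.

    ``pairs`` is a sequence of (fSASA, lnPF) tuples; at least 3 with
    non-degenerate fSASA are required.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise CalibrationError("need >= 3 (fSASA, lnPF) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise CalibrationError("fSASA values all identical: rank-deficient fit")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = max(len(x) - 2, 1)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        n=len(x),
        residual_se=float(np.sqrt(np.sum(resid**2) / dof)),
    )


@dataclass(frozen=True)
class BoundPrediction:
    fsasa_raw: float
    fsasa: float
    clipped: bool
    sasa: float | None = None


def predict_bound_fsasa(
    lnpf_bound: float,
    model: CalibrationModel,
    clip: bool = True,
    sasa_ref: float | None = None,
) -> BoundPrediction:
    """Invert the calibration: fSASA_pred = (lnPF - a) / b.

    With ``clip`` (default) the prediction is clamped to the physical
    [0, 1] range; the raw value is retained alongside. If ``sasa_ref`` (the
    site's weighted reference area) is given, an absolute SASA prediction
    is included.
    """
    raw = model.invert(lnpf_bound)
    clipped_val = min(max(raw, 0.0), 1.0) if clip else raw
    return BoundPrediction(
        fsasa_raw=raw,
        fsasa=clipped_val,
        clipped=clip and clipped_val != raw,
        sasa=clipped_val * sasa_ref if sasa_ref is not None else None,
    )


def delta_accessibility(
    free_fsasa: dict[str, float],
    bound_fsasa: dict[str, float],
) -> pd.DataFrame:
    """Per-site burial change, free minus predicted bound, ranked by delta.

    Keys must match exactly; orphans on either side raise with a listing
    rather than being dropped.
    """
    orphans_free = sorted(set(free_fsasa) - set(bound_fsasa))
    orphans_bound = sorted(set(bound_fsasa) - set(free_fsasa))
    if orphans_free or orphans_bound:
        raise CalibrationError(
            "unmatched sites: "
            f"free-only={orphans_free or '[]'}, bound-only={orphans_bound or '[]'}"
        )
    rows = [
        {
            "site": site,
            "fSASA_free": free_fsasa[site],
            "fSASA_bound": bound_fsasa[site],
            "delta_fSASA": free_fsasa[site] - bound_fsasa[site],
        }
        for site in free_fsasa
    ]
    df = pd.DataFrame(rows).sort_values("delta_fSASA", ascending=False)
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)


def summary_text(model: CalibrationModel) -> str:
    return (
        f"ln PF = {model.intercept:.3f} {model.slope:+.3f} * fSASA "
        f"(Pearson R = {model.pearson_r:.3f}, n = {model.n}, "
        f"residual SE = {model.residual_se:.3f})"
    )
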
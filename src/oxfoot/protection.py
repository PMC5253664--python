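"""Protection factors from oxidation rates.

A residue's protection factor is its intrinsic hydroxyl-radical reactivity
divided by the measured footprinting oxidation rate:

    PF = (sum_i R_i) / k_FP

where the sum runs over every residue the oxidation event may belong to
(one residue, or two for an ambiguous site, or all oxidizable residues of
a peptide-level measurement). High PF means the side chain is shielded
from bulk solvent.

The intrinsic reactivities are configuration: the shipped default covers
the 16 commonly oxidizable residues and can be replaced by any CSV with
``residue, reactivity`` columns. Because PF is homogeneous of degree +1
in the reactivity scale, swapping tables rescales PFs uniformly and
leaves the ln PF vs fSASA slope and correlation untouched.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._tables import HYDROXYL_REACTIVITY
from .structio import SiteAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "ReactivityTable",
    "ProtectionRecord",
    "load_reactivity_table",
    "protection_factor",
    "protection_table",
]


class ReactivityError(ValueError):
    pass


@dataclass(frozen=True)
class ReactivityTable:
    """Residue one-letter code -> intrinsic hydroxyl-radical reactivity.

    Residues absent from the map are declared non-oxidizable.
    """

    values: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        for code, r in self.values.items():
            if not r > 0:
                raise ReactivityError(
                    f"reactivity for {code!r} must be positive, got {r}"
                )

    def __contains__(self, code: str) -> bool:
        return code in self.values

    def __getitem__(self, code: str) -> float:
        try:
            return self.values[code]
        except KeyError:
            raise ReactivityError(
                f"no intrinsic reactivity for residue {code!r}"
            ) from None

    def scaled(self, factor: float) -> "ReactivityTable":
        return ReactivityTable(
            {k: v * factor for k, v in self.values.items()},
            provenance=f"{self.provenance} (x{factor:g})",
        )


@dataclass(frozen=True)
class ProtectionRecord:
    site: SiteAssignment
    PF: float
    lnPF: float
    k_FP: float
    reactivity_sum: float


def load_reactivity_table(source: str | Path = "default") -> ReactivityTable:
    """Load a reactivity table from a CSV path, or the shipped default.

    The default is the free-amino-acid hydroxyl-radical rate-constant
    compilation (1e9 M^-1 s^-1 units), covering 16 oxidizable residues.
    """
    if str(source) == "default":
        return ReactivityTable(
            dict(HYDROXYL_REACTIVITY),
            provenance="free amino acid .OH rate constants, 1e9 M^-1 s^-1",
        )
    df = pd.read_csv(source)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"residue", "reactivity"} <= set(df.columns):
        raise ReactivityError(
            f"{source}: expected columns 'residue' and 'reactivity'"
        )
    return ReactivityTable(
        {str(r).strip(): float(v) for r, v in zip(df["residue"], df["reactivity"])},
        provenance=str(source),
    )


def protection_factor(
    k_FP: float,
    residues: str | list[str],
    table: ReactivityTable,
    site: SiteAssignment | None = None,
) -> ProtectionRecord:
    """PF = (sum of intrinsic reactivities over ``residues``) / k_FP."""
    if not k_FP > 0:
        raise ReactivityError(f"k_FP must be positive, got {k_FP}")
    codes = list(residues)
    if not codes:
        raise ReactivityError("at least one residue code required")
    r_sum = sum(table[c] for c in codes)
    pf = r_sum / k_FP
    return ProtectionRecord(
        site=site, PF=pf, lnPF=math.log(pf), k_FP=k_FP, reactivity_sum=r_sum
    )


def protection_table(
    rates: pd.DataFrame,
    table: ReactivityTable,
    mod_mass: float | None = 16.0,
) -> pd.DataFrame:
    """Convert a consolidated rate table into per-site protection factors.

    Only species matching ``mod_mass`` (default the +16 Da single-oxygen
    products, the species used for accessibility calibration) are
    converted; pass ``mod_mass=None`` to keep all. Sites containing a
    residue with no tabulated reactivity are skipped with a logged reason.
    """
    df = rates
    if mod_mass is not None:
        df = df[df["mod_mass"] == mod_mass]
    rows = []
    for _, row in df.iterrows():
        site = SiteAssignment.parse(row["site"])
        codes = [r.code for r in site.residues]
        unknown = [c for c in codes if c not in table]
        if unknown:
            logger.info(
                "site %s skipped: no reactivity for %s",
                row["site"], ",".join(unknown),
            )
            continue
        if not row["k_per_s"] > 0:
            logger.info("site %s skipped: non-positive rate", row["site"])
            continue
        rec = protection_factor(row["k_per_s"], codes, table, site=site)
        rows.append(
            {
                "site": row["site"],
                "residues": "".join(codes),
                "mod_mass": row["mod_mass"],
                "k_per_s": rec.k_FP,
                "reactivity_sum": rec.reactivity_sum,
                "PF": rec.PF,
                "lnPF": rec.lnPF,
            }
        )
    if not rows:
        warnings.warn("no sites survived the protection-factor filter", stacklevel=2)
    return pd.DataFrame(
        rows,
        columns=["site", "residues", "mod_mass", "k_per_s", "reactivity_sum",
                 "PF", "lnPF"],
    )
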
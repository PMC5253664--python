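"""Between-state comparison of oxidation rates.

Two liganded states of the same protein are compared by the ratio of the
oxidation rates of every site detected in both, reported as
log10(k_A / k_B). Sites carrying several oxidation events (different
peptides or modification masses) are aggregated to residues by averaging
the log ratios; ambiguous two-residue sites contribute to both candidate
residues with an ambiguity mark. A residue is classified as
increased/decreased in state B when the fold change strictly exceeds a
threshold (default 1.4, i.e. a >40% rate change).

The comparison is descriptive -- ratios plus a threshold -- with a
delta-method standard deviation of the log ratio carried along for the
user; no hypothesis-testing machinery is attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import ResidueId, SiteAssignment

__all__ = [
    "RateRatioRecord",
    "rate_ratios",
    "aggregate_per_residue",
    "classify_activation_sites",
]

_LN10 = math.log(10.0)


class StateCompError(ValueError):
    pass


@dataclass(frozen=True)
class RateRatioRecord:
    site: SiteAssignment
    species: str
    k_state_a: float
    k_state_b: float
    log10_ratio: float
    sd_log10_ratio: float


def rate_ratios(
    rates_a: pd.DataFrame,
    rates_b: pd.DataFrame,
) -> tuple[list[RateRatioRecord], pd.DataFrame]:
    """Per-(site, species) log10 rate ratios between two states.

    Returns the shared-site records and an orphan report DataFrame listing
    every entry seen in only one state (never silently dropped). Entries
    with a non-positive rate in either state are excluded with a reason in
    the orphan report.
    """
    a = rates_a.set_index(["site", "species"])
    b = rates_b.set_index(["site", "species"])
    shared = a.index.intersection(b.index)
    records: list[RateRatioRecord] = []
    orphans: list[dict] = []
    for key in shared:
        ka = float(a.loc[key, "k_per_s"])
        kb = float(b.loc[key, "k_per_s"])
        if ka <= 0 or kb <= 0:
            orphans.append(
                {"site": key[0], "species": key[1], "state": "both",
                 "reason": "non-positive rate"}
            )
            continue
        sda = float(a.loc[key].get("sd_k", np.nan))
        sdb = float(b.loc[key].get("sd_k", np.nan))
        # delta method: var(log10 k) ~ (sd_k / k)^2 / ln(10)^2
        sd = math.sqrt((sda / ka) ** 2 + (sdb / kb) ** 2) / _LN10
        records.append(
            RateRatioRecord(
                site=SiteAssignment.parse(key[0]),
                species=key[1],
                k_state_a=ka,
                k_state_b=kb,
                log10_ratio=math.log10(ka / kb),
                sd_log10_ratio=sd,
            )
        )
    for key in a.index.difference(b.index):
        orphans.append({"site": key[0], "species": key[1], "state": "A",
                        "reason": "detected in A only"})
    for key in b.index.difference(a.index):
        orphans.append({"site": key[0], "species": key[1], "state": "B",
                        "reason": "detected in B only"})
    orphan_df = pd.DataFrame(orphans, columns=["site", "species", "state", "reason"])
    return records, orphan_df


def aggregate_per_residue(records: list[RateRatioRecord]) -> pd.DataFrame:
    """Average log10 ratios of multiple oxidation events per residue.

    Ambiguous two-residue sites contribute their ratio to both residues
    and mark them ambiguous. Output is one row per residue with columns
    residue, chain, number, mean_log10_ratio, n_species, ambiguous.
    """
    acc: dict[ResidueId, list[float]] = {}
    ambig: dict[ResidueId, bool] = {}
    for rec in records:
        for res in rec.site.residues:
            acc.setdefault(res, []).append(rec.log10_ratio)
            ambig[res] = ambig.get(res, False) or rec.site.ambiguous
    rows = [
        {
            "residue": str(res),
            "chain": res.chain,
            "number": res.number,
            "code": res.code,
            "mean_log10_ratio": float(np.mean(vals)),
            "n_species": len(vals),
            "ambiguous": ambig[res],
        }
        for res, vals in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["residue", "chain", "number", "code", "mean_log10_ratio",
                 "n_species", "ambiguous"],
    )


def classify_activation_sites(
    per_residue: pd.DataFrame,
    threshold_fold: float = 1.4,
) -> pd.DataFrame:
    """Label residues by fold rate change between the states.

    With the A/B ratio convention, a residue oxidizing strictly more than
    ``threshold_fold`` times faster in state B (log10 ratio below
    -log10 threshold) is ``increased_in_B``; the mirror case is
    ``decreased_in_B``; everything else ``unchanged``. The inequality is
    strict, so a fold change exactly at the threshold stays unchanged.
    """
    if not threshold_fold > 1:
        raise StateCompError("threshold_fold must exceed 1")
    cut = math.log10(threshold_fold)
    out = per_residue.copy()
    ratio = out["mean_log10_ratio"]
    out["label"] = np.where(
        ratio < -cut, "increased_in_B",
        np.where(ratio > cut, "decreased_in_B", "unchanged"),
    )
    return out
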
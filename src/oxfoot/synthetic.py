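"""Synthetic footprinting and pharmacology experiments with known truth.

Every pipeline stage can be exercised without external data: idealized
structures (helix, antiparallel strand pair, or a two-chain helix bundle
with a genuine buried interface) supply coordinates; the footprinting
generator inverts the analysis model -- true rate k = sum(R_i) /
exp(a + b * fSASA_true) -- and emits dose-response tables in the exact
schema the readers expect, alongside a machine-readable truth record.

Noise enters through two independent knobs: a lognormal multiplier on the
per-site rate (site-to-site biological/measurement scatter) and a
multiplicative Gaussian on the unmodified fractions (peak-integration
noise). Side chains are single pseudo-atoms at the C-beta position:
enough to create realistic burial contrast without rotamer modelling.

All generators are deterministic in their seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .protection import ReactivityTable, load_reactivity_table
from .sasa import RadiusTable, per_residue_sasa, shrake_rupley
from ._tables import SASA_REF_SIDECHAIN
from .structio import Atom, ResidueId, SiteAssignment, Structure

__all__ = [
    "SyntheticTruth",
    "make_fixture_structure",
    "interface_residues",
    "simulate_decay_series",
    "simulate_footprinting",
    "simulate_two_state",
    "simulate_bret",
]

#: Exposure-time grid (ms) mirroring a 0-15 ms synchrotron dose series.
DEFAULT_TIMES_MS = (0.0, 2.5, 5.0, 10.0, 15.0)

_RESIDUE_POOL = "CWYMFHRILVPQTKSEGAND"  # oxidizable-heavy but mixed


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated footprinting experiment."""

    intercept: float
    slope: float
    seed: int
    sigma_rate: float
    sigma_frac: float
    sites: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @property
    def fsasa(self) -> dict[str, float]:
        return {s["site"]: s["fsasa"] for s in self.sites}

    @property
    def k_true(self) -> dict[str, float]:
        return {s["site"]: s["k_true"] for s in self.sites}


def _helix_atoms(
    chain: str, codes: str, origin: np.ndarray, start_number: int = 1
) -> list[Atom]:
    """Ideal alpha-helix backbone + C-beta pseudo side chains.

    CA trace: radius 2.3 A, 100 deg/residue, 1.5 A rise. N and C sit on
    the CA-CA virtual bonds; O points back along the axis; CB points
    radially outward (so burial is controlled by what faces the helix).
    """
    n = len(codes)
    ca = np.array(
        [
            [
                2.3 * math.cos(math.radians(100.0 * i)),
                2.3 * math.sin(math.radians(100.0 * i)),
                1.5 * i,
            ]
            for i in range(n)
        ]
    )
    atoms: list[Atom] = []
    for i, code in enumerate(codes):
        res = ResidueId(chain, start_number + i, code)
        prev_dir = ca[i - 1] - ca[i] if i > 0 else np.array([0.0, 0.0, -1.0]) * 3.8
        next_dir = ca[i + 1] - ca[i] if i < n - 1 else np.array([0.0, 0.0, 1.0]) * 3.8
        pos_n = ca[i] + 0.38 * prev_dir
        pos_c = ca[i] + 0.40 * next_dir
        pos_o = pos_c + np.array([0.0, 0.0, -1.23])
        radial = np.array([ca[i][0], ca[i][1], 0.0])
        radial /= np.linalg.norm(radial)
        pos_cb = ca[i] + 1.53 * radial
        for name, elem, pos in (
            ("N", "N", pos_n),
            ("CA", "C", ca[i]),
            ("C", "C", pos_c),
            ("O", "O", pos_o),
        ):
            atoms.append(Atom(res, name, elem, *(origin + pos)))
        if code != "G":
            atoms.append(Atom(res, "CB", "C", *(origin + pos_cb)))
    return atoms


def _strand_atoms(
    chain: str, codes: str, origin: np.ndarray, start_number: int = 1
) -> list[Atom]:
    atoms: list[Atom] = []
    for i, code in enumerate(codes):
        res = ResidueId(chain, start_number + i, code)
        zig = 0.6 if i % 2 == 0 else -0.6
        ca = origin + np.array([3.3 * i, 0.0, zig])
        for name, elem, pos in (
            ("N", "N", ca + np.array([-1.2, 0.0, 0.3])),
            ("CA", "C", ca),
            ("C", "C", ca + np.array([1.2, 0.0, 0.3])),
            ("O", "O", ca + np.array([1.2, 1.0, 0.9])),
        ):
            atoms.append(Atom(res, name, elem, *pos))
        if code != "G":
            cb = ca + np.array([0.0, 0.0, 1.53 if zig > 0 else -1.53])
            atoms.append(Atom(res, "CB", "C", *cb))
    return atoms


def make_fixture_structure(
    kind: str = "helix", n_residues: int = 30, seed: int = 0
) -> Structure:
    """Ideal-geometry fixture structure with stub side chains.

    Kinds: ``helix`` (one chain), ``sheet_pair`` (two antiparallel
    strands, one chain), ``two_domain_complex`` (two helical chains packed
    face to face; the contact residues are the known protected set).
    Sequences are drawn from a mixed residue pool, deterministically in
    the seed.
    """
    if n_residues < 5:
        raise ValueError("n_residues must be >= 5")
    rng = np.random.default_rng(seed)
    codes = "".join(rng.choice(list(_RESIDUE_POOL), size=n_residues))
    if kind == "helix":
        return Structure(atoms=_helix_atoms("A", codes, np.zeros(3)))
    if kind == "sheet_pair":
        half = n_residues // 2
        atoms = _strand_atoms("A", codes[:half], np.zeros(3))
        atoms += _strand_atoms(
            "A", codes[half:], np.array([0.0, 4.8, 0.0]), start_number=half + 1
        )
        return Structure(atoms=atoms)
    if kind == "two_domain_complex":
        half = n_residues // 2
        atoms = _helix_atoms("A", codes[:half], np.zeros(3))
        # second helix alongside the first, close enough for CB contact
        atoms += _helix_atoms("B", codes[half:], np.array([8.6, 0.0, 0.75]))
        return Structure(atoms=atoms)
    raise ValueError(f"unknown fixture kind {kind!r}")


def interface_residues(
    complex_structure: Structure,
    min_drop: float = 0.2,
    n_points: int = 480,
) -> set[ResidueId]:
    """Residues whose side-chain SASA drops by > ``min_drop`` (relative)
    between the separated chains and the complex."""
    radii = RadiusTable()
    areas_complex = per_residue_sasa(
        complex_structure, shrake_rupley(complex_structure, radii, n_points)
    )
    out: set[ResidueId] = set()
    for chain in complex_structure.sequence:
        alone = Structure(
            atoms=[a for a in complex_structure.atoms if a.residue.chain == chain]
        )
        areas_alone = per_residue_sasa(alone, shrake_rupley(alone, radii, n_points))
        for res, area in areas_alone.items():
            if area > 1.0 and (area - areas_complex[res]) / area > min_drop:
                out.add(res)
    return out


def simulate_decay_series(
    k: float,
    times_ms: np.ndarray | None = None,
    sigma_frac: float = 0.05,
    replicates: int = 2,
    y0: float = 1.0,
    seed: int = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Noisy first-order decay points for one rate, per replicate.

    When no time grid is given, eight points spanning about two decay
    constants of ``k`` are used (a dose series is always tuned so the
    probed rates actually decay over it). Fractions carry multiplicative
    lognormal noise of width ``sigma_frac``.
    """
    rng = np.random.default_rng(seed)
    if times_ms is None:
        times_ms = np.linspace(0.0, 2000.0 / k, 8)
    times_ms = np.asarray(times_ms, dtype=float)
    out = {}
    for rep in range(1, replicates + 1):
        y = y0 * np.exp(-k * times_ms / 1000.0)
        y = y * np.exp(rng.normal(0.0, sigma_frac, size=y.size)) if sigma_frac else y
        out[str(rep)] = (times_ms, y)
    return out


def simulate_footprinting(
    structure: Structure,
    intercept: float = 4.0,
    slope: float = -3.5,
    reactivities: ReactivityTable | None = None,
    times_ms: tuple[float, ...] = DEFAULT_TIMES_MS,
    sigma_rate: float = 0.45,
    sigma_frac: float = 0.0,
    replicates: int = 2,
    n_sites: int | None = None,
    seed: int = 0,
    sasa_n_points: int = 480,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a dose-response table from a structure and a calibration line.

    Each oxidizable residue of the structure becomes a +16 Da site with
    true rate k = sum(R_i) / exp(a + b * fSASA_true), fSASA_true computed
    from the structure's side-chain areas. The observed rate is drawn
    lognormally (width ``sigma_rate``) around the true rate and converted
    to peak-area rows in the standard rates-table schema.
    """
    if slope >= 0:
        raise ValueError("calibration slope must be negative")
    times = np.asarray(times_ms, dtype=float)
    if times.size < 3 or times[0] != 0:
        raise ValueError("need >= 3 exposure times including 0")
    if reactivities is None:
        reactivities = load_reactivity_table()
    rng = np.random.default_rng(seed)

    areas = shrake_rupley(structure, RadiusTable(), n_points=sasa_n_points)
    per_res = per_residue_sasa(structure, areas, side_chain_only=True)
    oxidizable = [r for r in structure.residues if r.code in reactivities]
    if n_sites is not None and n_sites < len(oxidizable):
        idx = rng.choice(len(oxidizable), size=n_sites, replace=False)
        oxidizable = [oxidizable[i] for i in sorted(idx)]

    rows = []
    truth = SyntheticTruth(
        intercept=intercept, slope=slope, seed=seed,
        sigma_rate=sigma_rate, sigma_frac=sigma_frac,
    )
    for i, res in enumerate(oxidizable):
        r_sum = reactivities[res.code]
        ref = SASA_REF_SIDECHAIN[res.code]
        fsasa = min(per_res[res] / ref, 1.0)
        k_true = r_sum / math.exp(intercept + slope * fsasa)
        k_obs = k_true * math.exp(rng.normal(0.0, sigma_rate)) if sigma_rate else k_true
        site = SiteAssignment((res,))
        for rep in range(1, replicates + 1):
            y = np.exp(-k_obs * times / 1000.0)
            if sigma_frac:
                y = y * np.exp(rng.normal(0.0, sigma_frac, size=y.size))
            y = np.clip(y, 1e-6, 1.0)
            total = 1e6
            for t, yi in zip(times, y):
                rows.append(
                    {
                        "peptide_id": f"pep{i:03d}",
                        "site": str(site),
                        "mod_mass": 16.0,
                        "time_ms": t,
                        "area_unmod": yi * total,
                        "area_mod": (1.0 - yi) * total,
                        "replicate": str(rep),
                    }
                )
        truth.sites.append(
            {
                "site": str(site),
                "code": res.code,
                "fsasa": fsasa,
                "reactivity_sum": r_sum,
                "k_true": k_true,
                "k_obs": k_obs,
            }
        )
    return pd.DataFrame(rows), truth


def simulate_two_state(
    sites: list[SiteAssignment],
    protected: set[str],
    fold: float = 3.0,
    sigma_rate: float = 0.1,
    base_rate: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two consolidated rate tables where ``protected`` sites oxidize
    ``fold`` times slower in state B; both states carry independent
    lognormal rate noise of width ``sigma_rate``.
    """
    rng = np.random.default_rng(seed)
    rows_a, rows_b = [], []
    for i, site in enumerate(sites):
        k_a = base_rate * math.exp(rng.normal(0.0, 0.5))
        k_b = k_a / fold if str(site) in protected else k_a
        noise_a = math.exp(rng.normal(0.0, sigma_rate)) if sigma_rate else 1.0
        noise_b = math.exp(rng.normal(0.0, sigma_rate)) if sigma_rate else 1.0
        common = {
            "site": str(site),
            "residues": "".join(r.code for r in site.residues),
            "mod_mass": 16.0,
            "species": f"pep{i:03d}+16",
            "sd_k": 0.0,
            "n_points": 10,
        }
        rows_a.append({**common, "k_per_s": k_a * noise_a})
        rows_b.append({**common, "k_per_s": k_b * noise_b})
    cols = ["site", "residues", "mod_mass", "species", "k_per_s", "sd_k", "n_points"]
    return (
        pd.DataFrame(rows_a)[cols],
        pd.DataFrame(rows_b)[cols],
    )


def simulate_bret(
    ec50: float,
    emax: float = 1.0,
    hill: float = 1.0,
    doses: np.ndarray | None = None,
    sigma: float = 0.05,
    replicates: int = 3,
    bottom: float = 0.0,
    ligand: str = "ligand",
    construct: str = "WT",
    session: str = "1",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated BRET dose-response table (four-parameter logistic truth).

    Default doses are an 8-point half-log serial dilution topping out at
    1 uM, plus zero-dose baseline wells; noise is additive Gaussian with
    standard deviation ``sigma * emax``.
    """
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    rng = np.random.default_rng(seed)
    if doses is None:
        doses = 1e-6 * 10.0 ** (-0.5 * np.arange(8))
    doses = np.asarray(doses, dtype=float)
    rows = []
    for rep in range(1, replicates + 1):
        for x in np.concatenate([[0.0], doses]):
            if x > 0:
                y = bottom + emax / (
                    1.0 + 10.0 ** ((math.log10(ec50) - math.log10(x)) * hill)
                )
            else:
                y = bottom
            y += rng.normal(0.0, sigma * emax) if sigma else 0.0
            rows.append(
                {
                    "ligand": ligand,
                    "construct": construct,
                    "session": session,
                    "conc_M": x,
                    "response": y,
                    "replicate": str(rep),
                }
            )
    return pd.DataFrame(rows)
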
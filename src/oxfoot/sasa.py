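"""Solvent-accessible surface area by the Shrake-Rupley point-counting method.

Each atom is expanded by the probe radius (default 1.4 A, a water
molecule) and covered with a deterministic golden-spiral lattice of test
points; the accessible fraction is the share of points outside every
neighbouring expanded sphere, so

    area_i = 4 pi (r_i + probe)^2 * n_accessible / n_points.

The lattice is deterministic, so results are bit-stable across runs.
Per-residue SASA sums the residue's atoms; the default mode counts
side-chain atoms only (backbone N, CA, C, O, OXT excluded), matching the
side-chain-oxidation chemistry the footprinting rates report on.

Fractional SASA divides an observed (possibly reactivity-weighted) area
by the residue-specific maximum reference area, giving a burial fraction
nominally in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._tables import SASA_REF_SIDECHAIN, VDW_RADII
from .protection import ReactivityTable
from .structio import ResidueId, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "RadiusTable",
    "AccessibilityRecord",
    "shrake_rupley",
    "per_residue_sasa",
    "weighted_peptide_sasa",
    "fractional_sasa",
    "residue_fsasa_table",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class SasaError(ValueError):
    pass


@dataclass(frozen=True)
class RadiusTable:
    """Van der Waals radii per element (A) plus the solvent probe radius."""

    radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    probe: float = 1.4

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()):
            raise SasaError("van der Waals radii must be positive")
        if self.probe < 0:
            raise SasaError("probe radius must be non-negative")

    def radius(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise SasaError(f"no van der Waals radius for element {element!r}") from None


@dataclass(frozen=True)
class AccessibilityRecord:
    residues: tuple[ResidueId, ...]
    SASA: float
    SASA_REF: float
    fSASA: float
    flagged: bool = False  # fSASA > 1


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere lattice (golden spiral), deterministic."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Body-fixed orthonormal frame from the coordinate principal axes.

    Anchoring the test-point lattice to this frame makes the computed
    areas invariant under rigid motion of the input: rotating the
    molecule rotates the lattice with it. Signs are fixed by making each
    eigenvector's largest component positive; degenerate principal axes
    (exactly symmetric point sets) fall back to the lab frame.
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    try:
        evals, evecs = np.linalg.eigh(cov)
    except np.linalg.LinAlgError:
        return np.eye(3)
    if np.min(np.diff(evals)) < 1e-9 * max(evals[-1], 1.0):
        return np.eye(3)
    # sign fixed by the third moment along each axis: intrinsic to the
    # point set, so it co-rotates with the molecule (unlike lab axes)
    for j in range(3):
        skew = float(np.sum((centered @ evecs[:, j]) ** 3))
        if skew < 0:
            evecs[:, j] = -evecs[:, j]
    return evecs


def shrake_rupley(
    structure: Structure,
    radii: RadiusTable | None = None,
    n_points: int = 960,
    orient: bool = True,
) -> np.ndarray:
    """Per-atom SASA (A^2) in the order of ``structure.atoms``.

    With ``orient`` (default) the point lattice is anchored to the
    molecule's principal-axis frame, making the result invariant under
    rigid motion of the input; ``orient=False`` keeps the lab-frame
    lattice, whose per-atom areas are stable under atom addition (useful
    when comparing the same coordinates across structures).
    """
    if radii is None:
        radii = RadiusTable()
    if not structure.atoms:
        raise SasaError("empty structure")
    if n_points < 92:
        raise SasaError("n_points must be >= 92 for a usable lattice")

    coords = np.array([[a.x, a.y, a.z] for a in structure.atoms])
    expanded = np.array(
        [radii.radius(a.element) + radii.probe for a in structure.atoms]
    )
    unit = sphere_points(n_points)
    if orient:
        unit = unit @ _canonical_frame(coords).T
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.empty(len(coords))
    for i, (center, r_i) in enumerate(zip(coords, expanded)):
        pts = center + r_i * unit
        neighbours = [
            j for j in tree.query_ball_point(center, r_i + max_r) if j != i
        ]
        if neighbours:
            nb = np.asarray(neighbours)
            d2 = np.sum((pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < expanded[nb][None, :] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * r_i * r_i * frac
    return areas


def per_residue_sasa(
    structure: Structure,
    atom_areas: np.ndarray,
    side_chain_only: bool = True,
) -> dict[ResidueId, float]:
    """Sum atomic areas per residue (default: side-chain atoms only)."""
    out: dict[ResidueId, float] = {r: 0.0 for r in structure.residues}
    for atom, area in zip(structure.atoms, atom_areas):
        if side_chain_only and atom.name in BACKBONE_ATOMS:
            continue
        out[atom.residue] += float(area)
    return out


def _weights(
    residues: list[ResidueId],
    reactivities: ReactivityTable | None,
    uniform: bool,
) -> tuple[list[ResidueId], np.ndarray]:
    """Normalized per-residue weights over the oxidizable subset."""
    if uniform or reactivities is None:
        return residues, np.full(len(residues), 1.0 / len(residues))
    oxidizable = [r for r in residues if r.code in reactivities]
    if not oxidizable:
        raise SasaError(
            "no oxidizable residue among "
            + ",".join(str(r) for r in residues)
        )
    w = np.array([reactivities[r.code] for r in oxidizable])
    return oxidizable, w / w.sum()


def weighted_peptide_sasa(
    per_residue: dict[ResidueId, float],
    peptide_residues: list[ResidueId],
    reactivities: ReactivityTable | None = None,
    uniform: bool = False,
) -> float:
    """Reactivity-weighted mean SASA over a peptide's oxidizable residues.

    Weights are w_i = R_i / sum_j R_j, so the most reactive residues --
    the ones that dominate the measured peptide oxidation rate -- dominate
    the area too. A single residue passes through unchanged; ``uniform``
    switches to an unweighted mean.
    """
    subset, w = _weights(peptide_residues, reactivities, uniform)
    sasa = np.array([per_residue[r] for r in subset])
    return float(np.dot(w, sasa))


def fractional_sasa(
    per_residue: dict[ResidueId, float],
    residues: list[ResidueId],
    sasa_ref: dict[str, float] | None = None,
    reactivities: ReactivityTable | None = None,
    uniform: bool = False,
) -> AccessibilityRecord:
    """fSASA = weighted observed SASA / weighted reference SASA.

    Numerator and denominator share the same weights; values above 1
    (possible for exposed conformations or generous references) are
    allowed but flagged.
    """
    if sasa_ref is None:
        sasa_ref = SASA_REF_SIDECHAIN
    subset, w = _weights(residues, reactivities, uniform)
    missing = [r.code for r in subset if r.code not in sasa_ref]
    if missing:
        raise SasaError(f"no reference SASA for residue(s) {','.join(missing)}")
    sasa = float(np.dot(w, [per_residue[r] for r in subset]))
    ref = float(np.dot(w, [sasa_ref[r.code] for r in subset]))
    f = sasa / ref
    flagged = f > 1.0
    if flagged:
        logger.info(
            "fSASA %.3f > 1 for %s", f, ",".join(str(r) for r in subset)
        )
    return AccessibilityRecord(
        residues=tuple(subset), SASA=sasa, SASA_REF=ref, fSASA=f, flagged=flagged
    )


def residue_fsasa_table(
    structure: Structure,
    radii: RadiusTable | None = None,
    n_points: int = 960,
    side_chain_only: bool = True,
    sasa_ref: dict[str, float] | None = None,
):
    """Convenience: structure in -> per-residue SASA/fSASA DataFrame out."""
    import pandas as pd

    if sasa_ref is None:
        sasa_ref = SASA_REF_SIDECHAIN
    areas = shrake_rupley(structure, radii=radii, n_points=n_points)
    per_res = per_residue_sasa(structure, areas, side_chain_only=side_chain_only)
    rows = []
    for res, sasa in per_res.items():
        ref = sasa_ref.get(res.code)
        rows.append(
            {
                "residue": str(res),
                "chain": res.chain,
                "number": res.number,
                "code": res.code,
                "SASA": sasa,
                "SASA_REF": ref,
                "fSASA": sasa / ref if ref else np.nan,
            }
        )
    return pd.DataFrame(rows)
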
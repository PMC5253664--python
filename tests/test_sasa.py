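import math

import numpy as np
import pytest

from oxfoot.protection import ReactivityTable
from oxfoot.sasa import (
    RadiusTable,
    SasaError,
    fractional_sasa,
    per_residue_sasa,
    shrake_rupley,
    sphere_points,
    weighted_peptide_sasa,
)
from oxfoot.structio import Atom, ResidueId, Structure
from oxfoot.synthetic import make_fixture_structure


from _oracles import mc_surface_oracle, sphere_structure


class TestSpherePoints:
    def test_unit_norm_and_determinism(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.array_equal(pts, sphere_points(960))


class TestShrakeRupley:
    def test_isolated_atom_full_sphere(self):
        s = sphere_structure([[0, 0, 0]], ["C"])
        area = shrake_rupley(s, RadiusTable(), 960)[0]
        assert area == pytest.approx(4 * math.pi * 3.1**2, rel=1e-9)

    def test_distant_atoms_non_interacting(self):
        s = sphere_structure([[0, 0, 0], [100, 0, 0]], ["C", "C"])
        areas = shrake_rupley(s, RadiusTable(), 960)
        assert np.allclose(areas, 4 * math.pi * 3.1**2, rtol=1e-9)

    def test_two_sphere_analytic_cap(self):
        """Equal expanded spheres R at distance d: exposed area per sphere
        is 4 pi R^2 - 2 pi R (R - d/2)."""
        d, big_r = 3.1, 1.7 + 1.4
        s = sphere_structure([[0, 0, 0], [d, 0, 0]], ["C", "C"])
        areas = shrake_rupley(s, RadiusTable(), 10_000)
        exact = 4 * math.pi * big_r**2 - 2 * math.pi * big_r * (big_r - d / 2)
        assert areas[0] == pytest.approx(exact, rel=5e-3)
        assert areas[1] == pytest.approx(exact, rel=5e-3)

    def test_monte_carlo_oracle_random_systems(self, rng):
        rt = RadiusTable()
        for trial in range(4):
            n = int(rng.integers(2, 6))
            coords = rng.uniform(0, 6, size=(n, 3))
            elements = rng.choice(["C", "N", "O", "S"], size=n)
            s = sphere_structure(coords, elements)
            sr = shrake_rupley(s, rt, 10_000)
            expanded = np.array([rt.radius(e) + rt.probe for e in elements])
            mc = mc_surface_oracle(coords, expanded, n=250_000, seed=trial)
            assert sr.sum() == pytest.approx(mc.sum(), rel=0.01)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        s = make_fixture_structure("helix", 15, seed=2)
        base = shrake_rupley(s, RadiusTable(), 960)
        rot = Rotation.random(random_state=11).as_matrix()
        shift = rng.uniform(-30, 30, 3)
        moved = Structure(
            atoms=[
                Atom(a.residue, a.name, a.element,
                     *(rot @ np.array([a.x, a.y, a.z]) + shift))
                for a in s.atoms
            ]
        )
        assert shrake_rupley(moved, RadiusTable(), 960).sum() == pytest.approx(
            base.sum(), rel=1e-9
        )

    def test_adding_neighbour_never_increases_sasa(self, rng):
        # lab-frame lattice keeps per-atom point sets identical between
        # the two structures, so occlusion can only grow
        coords = rng.uniform(0, 5, size=(4, 3)).tolist()
        s4 = sphere_structure(coords, ["C"] * 4)
        base = shrake_rupley(s4, RadiusTable(), 960, orient=False)
        s5 = sphere_structure(coords + [[2.5, 2.5, 2.5]], ["C"] * 5)
        more = shrake_rupley(s5, RadiusTable(), 960, orient=False)[:4]
        assert np.all(more <= base + 1e-9)

    def test_lattice_convergence(self):
        s = make_fixture_structure("helix", 20, seed=1)
        a = shrake_rupley(s, RadiusTable(), 960).sum()
        b = shrake_rupley(s, RadiusTable(), 3840).sum()
        assert abs(a - b) / b < 0.01

    def test_unknown_element_errors(self):
        s = sphere_structure([[0, 0, 0]], ["Zz"])
        with pytest.raises(SasaError, match="Zz"):
            shrake_rupley(s, RadiusTable(), 960)


def residues(*codes):
    return [ResidueId("A", i + 1, c) for i, c in enumerate(codes)]


class TestWeightedPeptideSasa:
    def test_single_residue_identity(self):
        (r,) = residues("W")
        assert weighted_peptide_sasa({r: 42.0}, [r]) == pytest.approx(42.0)

    def test_equal_weights_are_mean(self):
        r1, r2 = residues("W", "F")
        table = ReactivityTable({"W": 10.0, "F": 10.0})
        got = weighted_peptide_sasa({r1: 100.0, r2: 50.0}, [r1, r2], table)
        assert got == pytest.approx(75.0)

    def test_reactivity_weighted_mean(self):
        r1, r2 = residues("W", "F")
        table = ReactivityTable({"W": 30.0, "F": 10.0})
        got = weighted_peptide_sasa({r1: 100.0, r2: 50.0}, [r1, r2], table)
        assert got == pytest.approx(87.5)

    def test_no_oxidizable_residue_errors(self):
        (r,) = residues("G")
        with pytest.raises(SasaError):
            weighted_peptide_sasa({r: 10.0}, [r], ReactivityTable({"W": 1.0}))


class TestFractionalSasa:
    def test_single_residue_ratio(self):
        (r,) = residues("W")
        rec = fractional_sasa({r: 50.0}, [r], sasa_ref={"W": 200.0})
        assert rec.fSASA == pytest.approx(0.25)

    def test_fully_buried(self):
        (r,) = residues("W")
        assert fractional_sasa({r: 0.0}, [r], sasa_ref={"W": 200.0}).fSASA == 0.0

    def test_weighted_ratio_two_residues(self):
        r1, r2 = residues("W", "F")
        table = ReactivityTable({"W": 5.0, "F": 5.0})
        rec = fractional_sasa(
            {r1: 50.0, r2: 100.0}, [r1, r2],
            sasa_ref={"W": 200.0, "F": 200.0}, reactivities=table,
        )
        assert rec.fSASA == pytest.approx(75.0 / 200.0)

    def test_above_one_flagged_not_failed(self):
        (r,) = residues("W")
        rec = fractional_sasa({r: 300.0}, [r], sasa_ref={"W": 200.0})
        assert rec.flagged and rec.fSASA == pytest.approx(1.5)

    def test_missing_reference_errors(self):
        (r,) = residues("W")
        with pytest.raises(SasaError):
            fractional_sasa({r: 10.0}, [r], sasa_ref={"F": 100.0})

    def test_fixture_fsasa_within_unit_range(self):
        """With the shipped theoretical-maximum references, every residue
        of an idealized fixture stays within [0, 1]."""
        s = make_fixture_structure("two_domain_complex", 40, seed=6)
        areas = shrake_rupley(s, RadiusTable(), 960)
        per_res = per_residue_sasa(s, areas)
        for res in s.residues:
            rec = fractional_sasa(per_res, [res])
            assert 0.0 <= rec.fSASA <= 1.0


class TestSideChainMode:
    def test_backbone_excluded_by_default(self, tripeptide):
        areas = shrake_rupley(tripeptide, RadiusTable(), 960)
        side = per_residue_sasa(tripeptide, areas, side_chain_only=True)
        full = per_residue_sasa(tripeptide, areas, side_chain_only=False)
        ala = tripeptide.residues[1]
        gly = tripeptide.residues[0]
        assert side[gly] == 0.0  # glycine has no side-chain heavy atom
        assert 0.0 < side[ala] < full[ala]
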
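import numpy as np
import pytest

from oxfoot.structio import Atom, ResidueId, Structure


def _backbone(res: ResidueId, origin):
    ox, oy, oz = origin
    return [
        Atom(res, "N", "N", ox - 1.2, oy, oz),
        Atom(res, "CA", "C", ox, oy, oz),
        Atom(res, "C", "C", ox + 1.2, oy, oz + 0.3),
        Atom(res, "O", "O", ox + 1.2, oy + 1.0, oz + 0.9),
    ]


@pytest.fixture
def tripeptide() -> Structure:
    """Gly-Ala-Gly with a CB on the alanine; spacing keeps atoms in contact."""
    atoms = []
    for i, code in enumerate("GAG"):
        res = ResidueId("A", i + 1, code)
        atoms += _backbone(res, (3.8 * i, 0.0, 0.0))
        if code == "A":
            atoms.append(Atom(res, "CB", "C", 3.8 * i, 0.0, 1.53))
    return Structure(atoms=atoms)


@pytest.fixture
def tripeptide_pdb(tmp_path, tripeptide):
    """The tripeptide written as PDB text by hand (not by the package)."""
    from oxfoot._tables import AA_1TO3

    lines = []
    for i, a in enumerate(tripeptide.atoms, start=1):
        lines.append(
            f"ATOM  {i:>5d}  {a.name:<3s} {AA_1TO3[a.residue.code]} "
            f"{a.residue.chain}{a.residue.number:>4d}    "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}  1.00  0.00          "
            f"{a.element:>2s}"
        )
    lines += ["TER", "END"]
    path = tmp_path / "tri.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
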
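"""Independent oracles shared by the surface-area tests."""

import numpy as np

from oxfoot.structio import Atom, ResidueId, Structure


def sphere_structure(centers, elements):
    atoms = [
        Atom(ResidueId("A", i + 1, "G"), "CA", e, *c)
        for i, (c, e) in enumerate(zip(centers, elements))
    ]
    return Structure(atoms=atoms)


def mc_surface_oracle(coords, expanded, n=1_000_000, seed=0):
    """Monte-Carlo surface sampling: uniform points on each expanded
    sphere, accessible if outside all other expanded spheres."""
    rng = np.random.default_rng(seed)
    areas = []
    for i, (c, r) in enumerate(zip(coords, expanded)):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = c + r * v
        free = np.ones(n, dtype=bool)
        for j, (cj, rj) in enumerate(zip(coords, expanded)):
            if j != i:
                free &= np.sum((pts - cj) ** 2, axis=1) >= rj * rj
        areas.append(4 * np.pi * r * r * free.mean())
    return np.array(areas)
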
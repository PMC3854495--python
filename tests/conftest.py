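"""Shared fixtures: small constructed systems with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import lobescope as lb
from lobescope.topology import ConformerSet, make_atom


@pytest.fixture(scope="session")
def scheme() -> lb.RegionScheme:
    return lb.default_scheme()


@pytest.fixture(scope="session")
def dumbbell(scheme) -> lb.ConformerSet:
    """One straight-linker conformer at l=33 A, phi=100 deg."""
    return lb.build_dumbbell(lb.DumbbellSpec(target_l=33.0, target_phi=100.0))


def chain_conformers(n_atoms: int = 20, kink_deg: float = 60.0):
    """A straight pseudo-C-alpha chain and a copy kinked at the midpoint."""
    atoms = [make_atom(i + 1, "CA", "ALA", i + 1, element="C") for i in range(n_atoms)]
    straight = np.zeros((n_atoms, 3))
    straight[:, 0] = np.arange(n_atoms) * 3.8
    bent = straight.copy()
    mid = n_atoms // 2
    th = np.radians(kink_deg)
    rot = np.array(
        [[np.cos(th), 0, np.sin(th)], [0, 1, 0], [-np.sin(th), 0, np.cos(th)]]
    )
    bent[mid:] = (bent[mid:] - bent[mid]) @ rot.T + bent[mid]
    cs = ConformerSet(atoms=atoms, frames=np.stack([straight, bent]))
    cs._cache["bonds"] = np.array([[i, i + 1] for i in range(n_atoms - 1)])
    return cs


@pytest.fixture()
def toy_chain() -> ConformerSet:
    return chain_conformers()


def minimal_frame(positions: dict[tuple[int, str], np.ndarray], resname="ALA") -> ConformerSet:
    """ConformerSet from a {(resnum, atom_name): xyz} map (single frame)."""
    atoms = []
    coords = []
    for serial, ((resnum, name), xyz) in enumerate(sorted(positions.items()), start=1):
        atoms.append(make_atom(serial, name, resname, resnum, element=name[0]))
        coords.append(np.asarray(xyz, dtype=float))
    return ConformerSet(atoms=atoms, frames=np.asarray(coords)[None, :, :])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation matrix."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def dihedral_oracle(p0, p1, p2, p3) -> float:
    """Independent arccos-plus-sign torsion formula (normal-vector based)."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if n1 @ b3 < 0:
        ang = -ang
    if ang <= -180.0:
        ang += 360.0
    return float(ang)
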
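"""Shared atom topology and the ConformerSet container.

A :class:`ConformerSet` unifies NMR ensembles (one frame per MODEL) and MD
trajectories (one frame per saved coordinate set): a single ordered atom
list plus an ``(n_frames, n_atoms, 3)`` coordinate array in Angstrom, with
optional per-frame orthorhombic box lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TopologyMismatchError

# Standard atomic masses (amu) for elements common in protein/ion systems.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,  # calcium (element), not the CA alpha-carbon atom name
    "ZN": 65.38,
    "FE": 55.845,
}

#: Backbone heavy-atom names; everything else heavy on a protein residue is
#: counted as a side-chain heavy atom.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

#: Residue names of monoatomic ions commonly present as HETATM records.
ION_RESNAMES = frozenset({"CA", "NA", "CL", "K", "MG", "ZN", "SOD", "CLA", "POT"})


def element_mass(element: str) -> float:
    return ELEMENT_MASSES.get(element.upper(), 12.011)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology (PDB author conventions)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    mass: float
    is_sidechain_heavy: bool
    hetero: bool = False

    @property
    def is_ion(self) -> bool:
        return self.hetero and self.residue_name.upper() in ION_RESNAMES


def make_atom(
    serial: int,
    name: str,
    residue_name: str,
    residue_number: int,
    chain_id: str = "A",
    element: str | None = None,
    hetero: bool = False,
) -> AtomRecord:
    """Build an AtomRecord, inferring element and flags from PDB conventions."""
    name = name.strip()
    residue_name = residue_name.strip()
    if element is None or not element.strip():
        if hetero and residue_name.upper() in ION_RESNAMES:
            element = residue_name.upper()
        else:
            # First alphabetic character of the atom name, PDB convention
            # for protein atoms (CA -> C, OD1 -> O, NZ -> N, 1HB -> H).
            alpha = [c for c in name if c.isalpha()]
            element = alpha[0].upper() if alpha else "C"
    element = element.strip().upper()
    heavy = element != "H"
    is_sc = heavy and not hetero and name.upper() not in BACKBONE_NAMES
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_number=residue_number,
        chain_id=chain_id,
        mass=element_mass(element),
        is_sidechain_heavy=is_sc,
        hetero=hetero,
    )


@dataclass
class ConformerSet:
    """Shared topology + one coordinate set per model/frame.

    Parameters
    ----------
    atoms:
        Ordered atom records; identical for every frame.
    frames:
        ``(n_frames, n_atoms, 3)`` coordinates in Angstrom.
    box:
        Optional ``(n_frames, 3)`` orthorhombic box lengths in Angstrom.
    time_step:
        Optional spacing between frames in ps.
    """

    atoms: list[AtomRecord]
    frames: np.ndarray
    box: np.ndarray | None = None
    time_step: float | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, :, :]
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TopologyMismatchError(
                f"frames must have shape (n_frames, n_atoms, 3), got {self.frames.shape}"
            )
        if self.frames.shape[1] != len(self.atoms):
            raise TopologyMismatchError(
                f"{len(self.atoms)} atoms in topology but frames carry "
                f"{self.frames.shape[1]} coordinates"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.ndim == 1:
                self.box = np.tile(self.box, (self.n_frames, 1))
            if self.box.shape != (self.n_frames, 3):
                raise TopologyMismatchError(
                    f"box must have shape ({self.n_frames}, 3), got {self.box.shape}"
                )
            if np.any(self.box <= 0):
                raise TopologyMismatchError("box lengths must all be > 0")

    # -- basic accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def frame(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def masses(self) -> np.ndarray:
        if "masses" not in self._cache:
            self._cache["masses"] = np.array([a.mass for a in self.atoms])
        return self._cache["masses"]

    @property
    def residue_numbers(self) -> np.ndarray:
        if "resnums" not in self._cache:
            self._cache["resnums"] = np.array([a.residue_number for a in self.atoms])
        return self._cache["resnums"]

    @property
    def atom_names(self) -> np.ndarray:
        if "names" not in self._cache:
            self._cache["names"] = np.array([a.name for a in self.atoms])
        return self._cache["names"]

    @property
    def residue_names(self) -> np.ndarray:
        if "resnames" not in self._cache:
            self._cache["resnames"] = np.array([a.residue_name for a in self.atoms])
        return self._cache["resnames"]

    def sequence(self) -> dict[int, str]:
        """Residue number -> residue name map over non-hetero atoms."""
        seq: dict[int, str] = {}
        for a in self.atoms:
            if not a.hetero:
                seq.setdefault(a.residue_number, a.residue_name)
        return seq

    def atom_index(self, residue_number: int, name: str) -> int | None:
        """Index of the first atom matching (residue_number, name), or None."""
        key = ("aidx", residue_number, name)
        if key not in self._cache:
            hit = None
            for i, a in enumerate(self.atoms):
                if a.residue_number == residue_number and a.name == name and not a.hetero:
                    hit = i
                    break
            self._cache[key] = hit
        return self._cache[key]

    def subset(self, indices) -> "ConformerSet":
        indices = np.asarray(indices, dtype=int)
        return ConformerSet(
            atoms=[self.atoms[i] for i in indices],
            frames=self.frames[:, indices, :].copy(),
            box=None if self.box is None else self.box.copy(),
            time_step=self.time_step,
        )

    def with_frames(self, frames: np.ndarray, box: np.ndarray | None = None) -> "ConformerSet":
        return ConformerSet(atoms=list(self.atoms), frames=frames, box=box, time_step=self.time_step)


def concatenate_atoms(a: ConformerSet, b: ConformerSet) -> ConformerSet:
    """Merge two sets frame-wise (same n_frames), stacking atoms of b after a."""
    if a.n_frames != b.n_frames:
        raise TopologyMismatchError(
            f"cannot merge systems with {a.n_frames} and {b.n_frames} frames"
        )
    box = a.box if a.box is not None else b.box
    return ConformerSet(
        atoms=list(a.atoms) + list(b.atoms),
        frames=np.concatenate([a.frames, b.frames], axis=1),
        box=box,
        time_step=a.time_step or b.time_step,
    )
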
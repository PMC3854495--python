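"""Reading and writing structures, ensembles and trajectories.

Multi-model PDB files go through biotite; DCD/XTC trajectories through
MDAnalysis. Both are exposed behind one container, :class:`ConformerSet`,
so downstream analyses never care whether frames came from an NMR ensemble
or a saved MD trajectory.
"""

from __future__ import annotations

import warnings

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import TopologyMismatchError
from .topology import AtomRecord, ConformerSet, make_atom

__all__ = ["read_pdb_models", "write_pdb_models", "read_trajectory", "write_trajectory"]


def _atoms_from_arrays(names, resnames, resids, chains, elements, hetero) -> list[AtomRecord]:
    records = []
    for i in range(len(names)):
        records.append(
            make_atom(
                serial=i + 1,
                name=str(names[i]),
                residue_name=str(resnames[i]),
                residue_number=int(resids[i]),
                chain_id=str(chains[i]) if str(chains[i]).strip() else "A",
                element=str(elements[i]) if elements is not None else None,
                hetero=bool(hetero[i]) if hetero is not None else False,
            )
        )
    return records


def read_pdb_models(path) -> ConformerSet:
    """Read a (possibly multi-model) PDB file into a ConformerSet.

    One frame per MODEL block; a file without MODEL records yields a single
    frame. HETATM calcium and other monoatomic ions are retained and
    flagged via ``AtomRecord.hetero``.

    Raises
    ------
    TopologyMismatchError
        If the models do not share an identical atom count, naming the
        first offending model.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    models = []
    for m in range(1, n_models + 1):
        models.append(pdb.get_structure(model=m))
    counts = [m.array_length() for m in models]
    if len(set(counts)) > 1:
        ref = counts[0]
        for i, c in enumerate(counts, start=1):
            if c != ref:
                raise TopologyMismatchError(
                    f"model {i} has {c} atoms but model 1 has {ref}"
                )
    first = models[0]
    atoms = _atoms_from_arrays(
        first.atom_name,
        first.res_name,
        first.res_id,
        first.chain_id,
        first.element if "element" in first.get_annotation_categories() else None,
        first.hetero,
    )
    frames = np.stack([m.coord for m in models])
    return ConformerSet(atoms=atoms, frames=frames)


def write_pdb_models(cs: ConformerSet, path) -> None:
    """Write every frame of a ConformerSet as a MODEL block of one PDB file."""
    n = cs.n_atoms
    array = struc.AtomArray(n)
    array.coord = cs.frames[0]
    array.set_annotation("atom_name", np.array([a.name for a in cs.atoms], dtype="U6"))
    array.set_annotation("res_name", np.array([a.residue_name for a in cs.atoms], dtype="U5"))
    array.set_annotation("res_id", np.array([a.residue_number for a in cs.atoms], dtype=int))
    array.set_annotation("chain_id", np.array([a.chain_id for a in cs.atoms], dtype="U4"))
    array.set_annotation("element", np.array([a.element for a in cs.atoms], dtype="U2"))
    array.set_annotation("hetero", np.array([a.hetero for a in cs.atoms], dtype=bool))
    stack = struc.stack([array] * cs.n_frames)
    stack.coord = cs.frames.copy()
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_trajectory(topology, traj) -> ConformerSet:
    """Read a DCD or XTC trajectory (topology from PDB or PSF).

    Frames are returned in file order; per-frame orthorhombic box lengths
    are populated when the trajectory carries them.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(topology), str(traj))
        except (ValueError, IOError) as exc:
            raise TopologyMismatchError(
                f"cannot pair topology {topology!r} with trajectory {traj!r}: {exc}"
            ) from exc
        ag = u.atoms
        try:
            chains = ag.chainIDs
        except Exception:
            chains = ["A"] * len(ag)
        try:
            resnames = ag.resnames
        except Exception:
            resnames = ["UNK"] * len(ag)
        atoms = _atoms_from_arrays(
            ag.names, resnames, ag.resids, chains, None, None
        )
        frames = []
        boxes = []
        have_box = True
        for i, ts in enumerate(u.trajectory):
            if ts.positions.shape[0] != len(atoms):
                raise TopologyMismatchError(
                    f"frame {i} carries {ts.positions.shape[0]} atoms, topology has {len(atoms)}"
                )
            frames.append(ts.positions.astype(float).copy())
            dims = ts.dimensions
            if dims is None or not np.all(dims[:3] > 0):
                have_box = False
            else:
                boxes.append(dims[:3].astype(float).copy())
        dt = getattr(u.trajectory, "dt", None)
    return ConformerSet(
        atoms=atoms,
        frames=np.stack(frames),
        box=np.stack(boxes) if have_box and boxes else None,
        time_step=float(dt) if dt else None,
    )


def write_trajectory(cs: ConformerSet, path) -> None:
    """Write frames to a trajectory file (format from extension, e.g. .dcd)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(cs.n_atoms, trajectory=True)
        with mda.Writer(str(path), n_atoms=cs.n_atoms) as w:
            for i in range(cs.n_frames):
                u.atoms.positions = cs.frames[i]
                if cs.box is not None:
                    u.dimensions = [*cs.box[i], 90.0, 90.0, 90.0]
                w.write(u.atoms)
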
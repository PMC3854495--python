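"""Superposition, RMSD series, helix axes, salt bridges, Ca2+ coordination.

These are the measurement operations used to track interdomain motion:
least-squares (Kabsch) superposition and fit/measure RMSD series, the
angle between EF-hand helix axes, detection of acidic-basic side-chain
salt bridges along a trajectory, and a per-frame check that each EF loop
keeps its calcium coordinated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, EmptySelectionError, MissingResidueError
from .regions import RegionScheme, select_region
from .topology import ConformerSet

__all__ = [
    "superpose",
    "rmsd",
    "rmsd_series",
    "helix_axis",
    "interhelix_angle",
    "interhelix_angle_series",
    "SaltBridgeEvent",
    "salt_bridge_scan",
    "ca_coordination_check",
]


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(((a - b) ** 2).sum(axis=-1).mean()))


def superpose(mobile: np.ndarray, reference: np.ndarray, indices=None):
    """Optimal rigid superposition of mobile onto reference.

    Least-squares Kabsch fit over ``indices`` (all atoms when None).
    Returns ``(rotation (3,3), translation (3,), rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches reference; the
    rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if indices is not None:
        indices = np.asarray(indices, dtype=int)
        mob = mobile[indices]
        ref = reference[indices]
    else:
        mob = mobile
        ref = reference
    if len(mob) < 3:
        raise DegenerateGeometryError("superposition needs at least 3 atoms")
    mob_mean = mob.mean(axis=0)
    ref_mean = ref.mean(axis=0)
    mob_c = mob - mob_mean
    ref_c = ref - ref_mean
    # collinear selections leave the rotation about the line undetermined
    for pts in (mob_c, ref_c):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError("fit selection is (near-)collinear")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    rmat = rot.as_matrix()
    fit_rmsd = float(rssd / np.sqrt(len(mob)))
    translation = ref_mean - rmat @ mob_mean
    return rmat, translation, fit_rmsd


def rmsd_series(
    cs: ConformerSet,
    reference,
    fit_indices,
    measure_indices=None,
) -> np.ndarray:
    """Per-frame RMSD after superposing each frame on the reference.

    Each frame is fitted on ``fit_indices`` and the RMSD reported over
    ``measure_indices`` (defaults to the fit set). Fitting a subunit and
    measuring over all atoms exposes interdomain rearrangement; fitting
    and measuring the same subunit exposes its internal motion only.
    ``reference`` is a frame index or an (n_atoms, 3) array.
    """
    ref = cs.frames[int(reference)] if isinstance(reference, (int, np.integer)) else np.asarray(reference)
    fit_indices = np.asarray(fit_indices, dtype=int)
    measure = fit_indices if measure_indices is None else np.asarray(measure_indices, dtype=int)
    out = np.empty(cs.n_frames)
    for f in range(cs.n_frames):
        rmat, t, _ = superpose(cs.frames[f], ref, fit_indices)
        moved = cs.frames[f][measure] @ rmat.T + t
        out[f] = rmsd(moved, ref[measure])
    return out


def helix_axis(cs: ConformerSet, helix, frame=0) -> np.ndarray:
    """Unit axis of a helix, oriented from its N- to its C-terminal end.

    The axis is the principal eigenvector of the C-alpha positional
    covariance — robust to terminal fraying compared with an end-to-end
    vector. ``helix`` is a residue range ``(lo, hi)`` or a helix label
    resolved through a scheme by :func:`interhelix_angle_series`.
    """
    lo, hi = helix
    f = cs.frames[int(frame)] if isinstance(frame, (int, np.integer)) else np.asarray(frame)
    ca = []
    for r in range(lo, hi + 1):
        idx = cs.atom_index(r, "CA")
        if idx is not None:
            ca.append(f[idx])
    if len(ca) < 5:
        raise DegenerateGeometryError(
            f"helix {lo}-{hi} has {len(ca)} C-alphas; need at least 5"
        )
    ca = np.asarray(ca)
    if len(ca) >= 8:
        # suppress the ~3.6-residue helical wiggle before the PCA; on
        # short fragments the truncated kernel hurts more than it helps
        kernel = np.array([1.0, 2.0, 2.0, 2.0, 1.0])
        smoothed = np.empty_like(ca)
        for i in range(len(ca)):
            ks = [k for k in range(-2, 3) if 0 <= i + k < len(ca)]
            w_k = np.array([kernel[k + 2] for k in ks])
            smoothed[i] = (ca[[i + k for k in ks]] * w_k[:, None]).sum(axis=0) / w_k.sum()
        ca = smoothed
    centered = ca - ca.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def interhelix_angle(cs: ConformerSet, helix_a, helix_b, frame=0) -> float:
    """Angle (degrees, [0, 180]) between two oriented helix axes."""
    a = helix_axis(cs, helix_a, frame)
    b = helix_axis(cs, helix_b, frame)
    return float(np.degrees(np.arccos(np.clip(a @ b, -1.0, 1.0))))


def interhelix_angle_series(
    cs: ConformerSet,
    scheme: RegionScheme,
    label_a: str,
    label_b: str,
) -> np.ndarray:
    """Per-frame angle between two scheme helices (e.g. "I" and "II")."""
    ha = scheme.helices[label_a]
    hb = scheme.helices[label_b]
    return np.array([interhelix_angle(cs, ha, hb, f) for f in range(cs.n_frames)])


# --- salt bridges -------------------------------------------------------

ACIDIC_GROUP_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_GROUP_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}


@dataclass(frozen=True)
class SaltBridgeEvent:
    """A recurring acidic-basic side-chain contact along a trajectory."""

    acidic_residue: int
    basic_residue: int
    first_frame: int
    last_frame: int
    min_distance: float
    occupancy: float


def _charged_groups(cs: ConformerSet, table) -> dict[int, np.ndarray]:
    groups: dict[int, list[int]] = {}
    for i, a in enumerate(cs.atoms):
        names = table.get(a.residue_name.upper())
        if names and a.name.upper() in names and not a.hetero:
            groups.setdefault(a.residue_number, []).append(i)
    return {r: np.array(v, dtype=int) for r, v in groups.items()}


def salt_bridge_scan(
    cs: ConformerSet,
    cutoff: float = 4.0,
    min_occupancy: float = 0.1,
) -> list[SaltBridgeEvent]:
    """Detect salt bridges: charged-group heavy atoms within ``cutoff``.

    A pair (Asp/Glu carboxylate O vs Lys NZ / Arg NH1-NH2-NE) is reported
    when its minimum heavy-atom distance is at or below ``cutoff`` in at
    least ``min_occupancy`` of the frames. Events are sorted by occupancy,
    highest first.
    """
    acids = _charged_groups(cs, ACIDIC_GROUP_ATOMS)
    bases = _charged_groups(cs, BASIC_GROUP_ATOMS)
    events: list[SaltBridgeEvent] = []
    for ar, aidx in acids.items():
        for br, bidx in bases.items():
            mins = np.empty(cs.n_frames)
            for f in range(cs.n_frames):
                d = cs.frames[f][aidx][:, None, :] - cs.frames[f][bidx][None, :, :]
                mins[f] = np.sqrt((d * d).sum(axis=-1)).min()
            formed = mins <= cutoff
            occ = float(formed.mean())
            if occ >= min_occupancy and formed.any():
                where = np.where(formed)[0]
                events.append(
                    SaltBridgeEvent(
                        acidic_residue=ar,
                        basic_residue=br,
                        first_frame=int(where[0]),
                        last_frame=int(where[-1]),
                        min_distance=float(mins.min()),
                        occupancy=occ,
                    )
                )
    events.sort(key=lambda e: (-e.occupancy, e.acidic_residue, e.basic_residue))
    return events


# --- EF-hand calcium coordination ---------------------------------------


def _sidechain_oxygens(cs: ConformerSet, resnum: int) -> np.ndarray:
    idx = [
        i
        for i, a in enumerate(cs.atoms)
        if a.residue_number == resnum and a.is_sidechain_heavy and a.element == "O"
    ]
    if not idx:
        raise MissingResidueError(f"residue {resnum} has no side-chain oxygen atoms")
    return np.array(idx, dtype=int)


def ca_coordination_check(
    cs: ConformerSet,
    scheme: RegionScheme,
    cutoff: float = 3.2,
):
    """Per-loop, per-frame calcium-coordination intactness.

    Each Ca2+ ion is assigned to the EF loop whose coordinating side-chain
    oxygens it sits nearest in frame 0 (one ion per loop). A loop is
    intact in a frame iff every listed coordinating residue has a
    side-chain oxygen within ``cutoff`` Angstrom of its ion.

    Returns ``(intact, distances)``: ``intact[loop]`` is a boolean array
    over frames; ``distances[(loop, resnum)]`` the per-frame minimum O-Ca
    distance.
    """
    ca_ions = [i for i, a in enumerate(cs.atoms) if a.is_ion and a.residue_name.upper() == "CA"]
    if len(ca_ions) < len(scheme.ef_loops):
        raise EmptySelectionError(
            f"{len(ca_ions)} Ca2+ ions present but {len(scheme.ef_loops)} EF loops defined"
        )
    loop_oxygens = {
        loop: {r: _sidechain_oxygens(cs, r) for r in residues}
        for loop, residues in scheme.ef_loops.items()
    }
    # greedy nearest assignment in frame 0
    f0 = cs.frames[0]
    assignment: dict[str, int] = {}
    taken: set[int] = set()
    pairs = []
    for loop, res_ox in loop_oxygens.items():
        all_ox = np.concatenate(list(res_ox.values()))
        centroid = f0[all_ox].mean(axis=0)
        for ion in ca_ions:
            pairs.append((float(np.linalg.norm(f0[ion] - centroid)), loop, ion))
    for _, loop, ion in sorted(pairs):
        if loop not in assignment and ion not in taken:
            assignment[loop] = ion
            taken.add(ion)
    intact: dict[str, np.ndarray] = {}
    distances: dict[tuple[str, int], np.ndarray] = {}
    for loop, res_ox in loop_oxygens.items():
        ion = assignment[loop]
        ok = np.ones(cs.n_frames, dtype=bool)
        for r, ox in res_ox.items():
            d = np.linalg.norm(cs.frames[:, ox, :] - cs.frames[:, ion, :][:, None, :], axis=-1)
            dmin = d.min(axis=1)
            distances[(loop, r)] = dmin
            ok &= dmin <= cutoff
        intact[loop] = ok
    return intact, distances
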
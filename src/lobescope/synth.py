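"""Synthetic fixtures with known ground truth for every analysis stage.

The generators emulate the geometric features the analyses measure, and
nothing more: two rigid lobes joined by a linker whose end-to-end length
and interlobe torsion are prescribed exactly (so projection can be checked
by parameter recovery), an optional kink at a chosen linker residue,
toy trajectories switching between prescribed states at known frames,
uniform or radially-biased ion baths in periodic boxes, and minimal
charged peptides. Conformers are coarse: one C-alpha plus one pseudo
side-chain heavy atom (CB) per non-glycine residue, all carbon-mass.
Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .charges import CALMODULIN_SEQUENCE, ONE_TO_THREE
from .errors import LobescopeError, UnreachableTargetError
from .topology import AtomRecord, ConformerSet, concatenate_atoms, make_atom

__all__ = [
    "DumbbellSpec",
    "IonBathSpec",
    "build_dumbbell",
    "make_state_switch_trajectory",
    "sample_ion_bath",
    "toy_charged_peptide",
    "make_helix_tilt_trajectory",
    "dumbbell_bonds",
]

LINKER_RANGE = (69, 91)
COM_N_RANGE = (5, 68)
COM_C_RANGE = (92, 147)
HELIX_RISE = 1.5       # Angstrom per residue along the axis
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # C-alpha distance from the axis
CA_CA = 3.8            # pseudo-bond length between consecutive C-alphas (lattice lobes)
CB_LENGTH = 1.5        # pseudo side-chain bond length
LOBE_OFFSET_R = 14.0   # lobe COM distance from the linker axis
LOBE_OFFSET_A = 10.0   # lobe COM axial stand-off beyond the linker ends
MAX_RISE = 3.75        # near the contour-length limit (CA-CA = 3.8 A)


def _radius_for_rise(rise: float, twist: float = HELIX_TWIST) -> float:
    """Helix radius keeping consecutive C-alphas at their 3.8 A spacing.

    An alpha-helical linker (rise 1.5) has radius ~2.3 A; as the linker
    unwinds toward an extended chain the rise grows and the radius shrinks,
    with the per-residue step length held at CA_CA throughout. This lets
    one 23-residue linker span end-to-end lengths from compact (~20 A)
    out to nearly the contour length while staying bond-consistent.
    """
    chord = np.sqrt(max(CA_CA**2 - rise**2, 1e-4))
    return chord / (2.0 * np.sin(np.radians(twist / 2.0)))


@dataclass(frozen=True)
class DumbbellSpec:
    """Build targets for one two-lobed conformer.

    ``target_l`` of None keeps the natural linker length of ``rise``
    (useful when two conformers must share identical bond geometry).
    """

    n_residues: int = 148
    target_l: float | None = 33.0
    target_phi: float = 100.0
    bend_residue: int | None = None
    bend_angle: float = 0.0
    rise: float = HELIX_RISE
    twist: float = HELIX_TWIST
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < LINKER_RANGE[1] + 1:
            raise LobescopeError(
                f"need at least {LINKER_RANGE[1] + 1} residues for the lobe/linker layout"
            )
        if self.bend_residue is not None and not (
            LINKER_RANGE[0] < self.bend_residue < LINKER_RANGE[1]
        ):
            raise LobescopeError("bend_residue must lie strictly inside the linker")


@dataclass(frozen=True)
class IonBathSpec:
    """Discrete ions in a periodic orthorhombic box."""

    box: tuple[float, float, float] = (40.0, 40.0, 40.0)
    ion_counts: dict = field(default_factory=lambda: {"NA": 500})
    n_frames: int = 20
    radial_bias: dict | None = None   # {"species","r0","sigma","n_biased"}
    exclusion_radius: float = 1.8     # excluded volume around reference atoms, A
    seed: int = 0


def _sequence_for(n_residues: int) -> list[str]:
    seq = (CALMODULIN_SEQUENCE * (n_residues // len(CALMODULIN_SEQUENCE) + 1))[:n_residues]
    return [ONE_TO_THREE[c] for c in seq]


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(u @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e1 = trial - (trial @ u) * u
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def _helix_points(
    n: int, origin, u, rise: float, twist: float, radius: float, phase0: float = 0.0
):
    """C-alpha positions of an ideal helix along unit axis u."""
    u = np.asarray(u, dtype=float)
    e1, e2 = _perp_basis(u)
    pts = np.empty((n, 3))
    for i in range(n):
        th = np.radians(phase0 + i * twist)
        pts[i] = (
            np.asarray(origin)
            + i * rise * u
            + radius * (np.cos(th) * e1 + np.sin(th) * e2)
        )
    return pts


def _linker_points(rise: float, spec: DumbbellSpec) -> np.ndarray:
    """Linker C-alphas, straight or kinked at spec.bend_residue."""
    lo, hi = LINKER_RANGE
    n = hi - lo + 1
    radius = _radius_for_rise(rise, spec.twist)
    if spec.bend_residue is None:
        return _helix_points(n, (0, 0, 0), (0, 0, 1), rise, spec.twist, radius)
    b = spec.bend_residue - lo
    arm1 = _helix_points(b + 1, (0, 0, 0), (0, 0, 1), rise, spec.twist, radius)
    ang = np.radians(spec.bend_angle)
    u2 = np.array([np.sin(ang), 0.0, np.cos(ang)])
    # continue from the kink vertex along the rotated axis, keeping phase
    arm2 = _helix_points(
        n - b, arm1[-1], u2, rise, spec.twist, radius, phase0=b * spec.twist
    )
    arm2 = arm2 - arm2[0] + arm1[-1]
    return np.concatenate([arm1, arm2[1:]])


def _lattice_cluster(n_res: int, spacing: float = CA_CA) -> np.ndarray:
    """Compact snake-ordered lattice of C-alpha positions (rigid lobe)."""
    side = int(np.ceil(n_res ** (1.0 / 3.0)))
    pts = []
    count = 0
    for iz in range(side + 1):
        for iy in range(side):
            ys = iy if iz % 2 == 0 else side - 1 - iy
            for ix in range(side):
                xs = ix if iy % 2 == 0 else side - 1 - ix
                pts.append((xs * spacing, ys * spacing, iz * spacing))
                count += 1
                if count == n_res:
                    return np.array(pts)
    return np.array(pts[:n_res])


_CB_DIR = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)


def _emit_residues(resnames: Sequence[str], resnums: Sequence[int], ca: np.ndarray,
                   cb_dirs: np.ndarray | None, serial0: int):
    """AtomRecords + coordinates for CA (+CB for non-Gly) of a residue run."""
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = serial0
    for k, (name, num) in enumerate(zip(resnames, resnums)):
        atoms.append(make_atom(serial, "CA", name, num, element="C"))
        coords.append(ca[k])
        serial += 1
        if name != "GLY":
            d = _CB_DIR if cb_dirs is None else cb_dirs[k]
            atoms.append(make_atom(serial, "CB", name, num, element="C"))
            coords.append(ca[k] + CB_LENGTH * d)
            serial += 1
    return atoms, np.array(coords), serial


def build_dumbbell(spec: DumbbellSpec) -> ConformerSet:
    """One conformer hitting (target_l, target_phi) by construction.

    Reduced-coordinate projection recovers the build targets within
    0.5 Angstrom and 2 degrees; a built-in kink is recovered by bend
    detection within one residue.
    """
    lo, hi = LINKER_RANGE
    resnames = _sequence_for(spec.n_residues)
    # -- linker: solve the helical rise so the end-to-end length matches
    if spec.target_l is None:
        linker_ca = _linker_points(spec.rise, spec)
    else:
        def gap(r):
            p = _linker_points(r, spec)
            return float(np.linalg.norm(p[-1] - p[0])) - spec.target_l

        if gap(MAX_RISE) < 0:
            raise UnreachableTargetError(
                f"target_l={spec.target_l} A unreachable for a "
                f"{hi - lo + 1}-residue linker (max ~{spec.target_l + gap(MAX_RISE):.1f} A)"
            )
        if gap(0.02) > 0:
            raise UnreachableTargetError(
                f"target_l={spec.target_l} A below the compact limit of this linker build"
            )
        rise = brentq(gap, 0.02, MAX_RISE, xtol=1e-10)
        linker_ca = _linker_points(rise, spec)
    # rotate/translate so P69 sits at the origin and P69->P91 runs along +z
    e = linker_ca[-1] - linker_ca[0]
    l_actual = float(np.linalg.norm(e))
    w = e / l_actual
    e1, e2 = _perp_basis(w)
    R = np.stack([e1, e2, w])          # rows: new basis -> world z = old e direction
    linker_ca = (linker_ca - linker_ca[0]) @ R.T
    # CB pseudo side chains point radially away from the local axis
    axis_pts = np.outer(linker_ca[:, 2], np.array([0, 0, 1.0]))
    radial = linker_ca - axis_pts
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    cb_dirs = np.where(norms > 1e-9, radial / np.maximum(norms, 1e-9), _CB_DIR)

    phi = np.radians(spec.target_phi)
    com_n_target = np.array([LOBE_OFFSET_R, 0.0, -LOBE_OFFSET_A])
    com_c_target = np.array(
        [LOBE_OFFSET_R * np.cos(phi), LOBE_OFFSET_R * np.sin(phi), l_actual + LOBE_OFFSET_A]
    )

    def lobe(first: int, last: int, com_lo: int, com_hi: int, target_com: np.ndarray):
        nums = list(range(first, last + 1))
        ca = _lattice_cluster(len(nums))
        atoms, coords, _ = _emit_residues([resnames[n - 1] for n in nums], nums, ca, None, 1)
        mask = np.array([com_lo <= a.residue_number <= com_hi for a in atoms])
        com = coords[mask].mean(axis=0)  # equal masses: plain mean == mass-weighted
        return [resnames[n - 1] for n in nums], nums, ca + (target_com - com)

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 1
    n_names, n_nums, n_ca = lobe(1, lo - 1, *COM_N_RANGE, com_n_target)
    a, c, serial = _emit_residues(n_names, n_nums, n_ca, None, serial)
    atoms += a
    coords.append(c)
    a, c, serial = _emit_residues(
        [resnames[n - 1] for n in range(lo, hi + 1)], list(range(lo, hi + 1)),
        linker_ca, cb_dirs, serial
    )
    atoms += a
    coords.append(c)
    c_names, c_nums, c_ca = lobe(hi + 1, spec.n_residues, *COM_C_RANGE, com_c_target)
    a, c, serial = _emit_residues(c_names, c_nums, c_ca, None, serial)
    atoms += a
    coords.append(c)
    cs = ConformerSet(atoms=atoms, frames=np.vstack(coords)[None, :, :])
    cs._cache["bonds"] = dumbbell_bonds(cs)
    return cs


def dumbbell_bonds(cs: ConformerSet) -> np.ndarray:
    """Pseudo-bond list of a coarse model: CA(i)-CA(i+1) within each
    segment (lobes and linker separately) and CA-CB within each residue."""
    pairs = []
    ca_of: dict[int, int] = {}
    for i, a in enumerate(cs.atoms):
        if a.name == "CA" and not a.hetero:
            ca_of[a.residue_number] = i
        elif a.name == "CB":
            pairs.append((ca_of[a.residue_number], i))
    lo, hi = LINKER_RANGE
    segments = [(min(ca_of), lo - 1), (lo, hi), (hi + 1, max(ca_of))]
    for slo, shi in segments:
        for r in range(slo, shi):
            if r in ca_of and r + 1 in ca_of:
                pairs.append((ca_of[r], ca_of[r + 1]))
    return np.array(sorted(tuple(sorted(p)) for p in pairs), dtype=int)


def make_state_switch_trajectory(
    states: Sequence[tuple[DumbbellSpec, int]],
    noise_sigma: float = 0.3,
    seed: int = 0,
) -> ConformerSet:
    """Frames concatenated per state, with Gaussian coordinate noise.

    Every state must share ``n_residues`` (one topology). The switch
    frames are the cumulative state lengths; a classifier should recover
    each state's length class for nearly all frames at sigma <= 0.5 A.
    """
    if not states:
        raise LobescopeError("need at least one state")
    rng = np.random.default_rng(seed)
    base = [build_dumbbell(s) for s, _ in states]
    n_atoms = {b.n_atoms for b in base}
    if len(n_atoms) > 1:
        raise LobescopeError("states must share one topology (same n_residues)")
    frames = []
    for b, (_, n_frames) in zip(base, states):
        ref = b.frames[0]
        for _ in range(n_frames):
            frames.append(ref + noise_sigma * rng.standard_normal(ref.shape))
    out = base[0].with_frames(np.stack(frames))
    out._cache["bonds"] = base[0]._cache.get("bonds")
    return out


def sample_ion_bath(
    spec: IonBathSpec,
    reference: ConformerSet | None = None,
) -> ConformerSet:
    """Ions in a periodic box, optionally with a radial excess kernel.

    With no bias the bath is uniform and g(r) around any fixed reference
    is flat at 1. A Gaussian kernel ``{"species", "r0", "sigma",
    "n_biased"}`` re-places that many ions of the species at distances
    ~N(r0, sigma) from randomly chosen reference atoms, producing a
    first RDF peak at r0. The returned set contains the (static)
    reference atoms followed by the ions, with per-frame box lengths.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    n_total = int(sum(spec.ion_counts.values()))
    if n_total * (2 * 1.5) ** 3 > float(np.prod(box)):
        raise LobescopeError("ion density exceeds close packing for this box")
    ref_coords = reference.frames[0] if reference is not None else None
    ion_atoms: list[AtomRecord] = []
    serial = (reference.n_atoms if reference is not None else 0) + 1
    for species, count in spec.ion_counts.items():
        for _ in range(count):
            ion_atoms.append(
                make_atom(serial, species.upper(), species.upper(), serial, hetero=True)
            )
            serial += 1
    species_of = np.array([a.residue_name for a in ion_atoms])
    bias = spec.radial_bias
    frames = []
    for _ in range(spec.n_frames):
        pos = rng.uniform(0.0, 1.0, size=(len(ion_atoms), 3)) * box
        if ref_coords is not None and spec.exclusion_radius > 0:
            # excluded volume: resample ions overlapping a reference atom
            # (mimics the short-range repulsion real solutes exert)
            for k in range(len(ion_atoms)):
                for _attempt in range(200):
                    d = ref_coords - pos[k]
                    d -= box * np.round(d / box)
                    if (d * d).sum(axis=1).min() >= spec.exclusion_radius**2:
                        break
                    pos[k] = rng.uniform(0.0, 1.0, size=3) * box
        if bias:
            if ref_coords is None:
                raise LobescopeError("radial bias needs reference atoms")
            sp = bias.get("species", "NA").upper()
            cand = np.where(species_of == sp)[0]
            n_b = min(int(bias["n_biased"]), len(cand))
            for k in cand[:n_b]:
                center = ref_coords[rng.integers(len(ref_coords))]
                d = rng.standard_normal(3)
                d /= np.linalg.norm(d)
                r = max(abs(rng.normal(bias["r0"], bias["sigma"])), spec.exclusion_radius)
                pos[k] = np.mod(center + r * d, box)
        frames.append(pos)
    ion_frames = np.stack(frames)
    box_per_frame = np.tile(box, (spec.n_frames, 1))
    ions = ConformerSet(atoms=ion_atoms, frames=ion_frames, box=box_per_frame)
    if reference is None:
        return ions
    ref_rep = reference.with_frames(
        np.repeat(reference.frames[:1], spec.n_frames, axis=0), box=box_per_frame
    )
    return concatenate_atoms(ref_rep, ions)


def toy_charged_peptide(sequence: str):
    """A minimal peptide for charge accounting: (resnum->resname, ConformerSet).

    C-alphas along x at 3.8 A spacing, plus a CB pseudo side-chain atom
    for non-glycine residues.
    """
    resnames = [ONE_TO_THREE[c.upper()] for c in sequence]
    nums = list(range(1, len(resnames) + 1))
    ca = np.outer(np.arange(len(resnames)), np.array([CA_CA, 0.0, 0.0]))
    atoms, coords, _ = _emit_residues(resnames, nums, ca, None, 1)
    seq_map = {n: r for n, r in zip(nums, resnames)}
    return seq_map, ConformerSet(atoms=atoms, frames=coords[None, :, :])


def make_helix_tilt_trajectory(
    angles_deg: Sequence[float],
    helix_a: tuple[int, int] = (5, 17),
    helix_b: tuple[int, int] = (30, 39),
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> ConformerSet:
    """Two ideal helices whose inter-axis angle follows a per-frame script.

    Helix A lies along +z; helix B is rebuilt each frame along
    ``(sin(theta), 0, cos(theta))`` so the oriented inter-axis angle equals
    the scripted value. Useful for checking that an angle series recovers
    a scripted tilt (e.g. a 80 -> 56 degree EF-hand rearrangement).
    """
    rng = np.random.default_rng(seed)
    na = helix_a[1] - helix_a[0] + 1
    nb = helix_b[1] - helix_b[0] + 1
    nums = list(range(helix_a[0], helix_a[1] + 1)) + list(range(helix_b[0], helix_b[1] + 1))
    resnames = ["ALA"] * (na + nb)
    atoms = [make_atom(i + 1, "CA", resnames[i], nums[i], element="C") for i in range(na + nb)]
    a_pts = _helix_points(na, (0, 0, 0), (0, 0, 1), HELIX_RISE, HELIX_TWIST, HELIX_RADIUS)
    frames = []
    for th in angles_deg:
        u = np.array([np.sin(np.radians(th)), 0.0, np.cos(np.radians(th))])
        b_pts = _helix_points(nb, (15.0, 0.0, 0.0), u, HELIX_RISE, HELIX_TWIST, HELIX_RADIUS)
        f = np.concatenate([a_pts, b_pts])
        if noise_sigma > 0:
            f = f + noise_sigma * rng.standard_normal(f.shape)
        frames.append(f)
    return ConformerSet(atoms=atoms, frames=np.stack(frames))
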
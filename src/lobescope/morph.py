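"""Geometric-targeting morphs between two conformers.

The morph walks from a start structure to a target in fixed-RMSD steps
(default 0.05 Angstrom) without any energetics: after each step toward the
target, geometric constraints are restored by randomly-ordered iterative
projection sweeps (Gauss-Seidel style) — covalent bond lengths back to
their reference values within a fractional tolerance, and steric overlaps
opened to at least ``clash_factor`` times the summed van der Waals radii.
The seeded random sweep order is the only source of randomness, so runs
with equal seeds are bit-reproducible, and an ensemble of seeds yields a
family of geometrically viable pathways whose spread can be summarized in
reduced coordinates.

Hydrogens are ignored throughout; Ramachandran, hydrogen-bond and
hydrophobic-contact constraints of the full geometric-targeting method are
out of scope by design — bonds and clashes are the verifiable core.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, TopologyMismatchError
from .geometry import rmsd, superpose
from .reduced import ReducedCoordSeries, project
from .regions import RegionScheme
from .topology import ConformerSet

__all__ = [
    "MorphSpec",
    "MorphTopology",
    "MorphResult",
    "build_morph_topology",
    "validate_frame",
    "morph",
    "ensemble_morph",
    "VDW_RADII",
]

#: Van der Waals radii (Angstrom) for the elements the morph cares about.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "CA": 2.31,
    "NA": 2.27,
    "CL": 1.75,
    "MG": 1.73,
    "K": 2.75,
}
DEFAULT_VDW = 1.70

#: Heavy-atom pairs closer than this in the reference frame are covalent.
BOND_DETECT_CUTOFF = 1.99


@dataclass(frozen=True)
class MorphSpec:
    """Tunable knobs of the geometric-targeting walk."""

    step_rmsd: float = 0.05          # RMSD decrease per step, Angstrom
    bond_tolerance: float = 0.02     # fractional bond-length deviation allowed
    clash_factor: float = 0.8        # min separation / sum of vdW radii
    max_steps: int = 5000
    seed: int = 0
    maintain_hbonds: bool = False    # reserved; no hydrogen model here
    max_projection_passes: int = 500
    wander: float = 0.25             # random lateral displacement per step,
                                     # as a fraction of step_rmsd (0 = greedy)

    def __post_init__(self) -> None:
        if self.step_rmsd <= 0:
            raise ValueError("step_rmsd must be > 0")
        if not 0 < self.clash_factor < 1:
            raise ValueError("clash_factor must be in (0, 1)")


@dataclass
class MorphTopology:
    """Reference bond network and clash bookkeeping for one system."""

    bonds: np.ndarray                # (n_bonds, 2) atom indices
    ref_lengths: np.ndarray          # (n_bonds,) Angstrom
    radii: np.ndarray                # (n_atoms,) vdW radii
    excluded: set                    # frozenset pairs exempt from clash checks (1-2, 1-3)
    n_atoms: int


def build_morph_topology(cs: ConformerSet, frame: int = 0, bonds=None) -> MorphTopology:
    """Bond network and clash exclusions for a system.

    Bonds come from, in order of preference: the explicit ``bonds`` array,
    a pseudo-bond list the generator cached on the ConformerSet, or a
    distance criterion (heavy-atom pairs closer than 1.99 Angstrom in the
    reference frame). Reference lengths are read from ``frame``.
    """
    coords = cs.frames[frame]
    heavy = np.array([a.element != "H" for a in cs.atoms])
    if not heavy.all():
        raise TopologyMismatchError("morphing expects heavy-atom-only systems")
    if bonds is None:
        bonds = cs._cache.get("bonds")
    if bonds is not None:
        pairs = np.asarray(bonds, dtype=int).reshape(-1, 2)
    else:
        nonion = np.array([not a.is_ion for a in cs.atoms])
        tree = cKDTree(coords)
        pairs = tree.query_pairs(BOND_DETECT_CUTOFF, output_type="ndarray")
        if len(pairs):
            keep = nonion[pairs[:, 0]] & nonion[pairs[:, 1]]
            pairs = pairs[keep]
    lengths = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1) if len(pairs) else np.empty(0)
    adjacency: dict[int, set[int]] = {}
    for i, j in pairs:
        adjacency.setdefault(int(i), set()).add(int(j))
        adjacency.setdefault(int(j), set()).add(int(i))
    excluded = {frozenset((int(i), int(j))) for i, j in pairs}
    for center, neigh in adjacency.items():
        for i in neigh:
            for j in neigh:
                if i < j:
                    excluded.add(frozenset((i, j)))
    radii = np.array([VDW_RADII.get(a.element, DEFAULT_VDW) for a in cs.atoms])
    return MorphTopology(
        bonds=pairs.astype(int),
        ref_lengths=np.asarray(lengths, dtype=float),
        radii=radii,
        excluded=excluded,
        n_atoms=cs.n_atoms,
    )


def validate_frame(coords: np.ndarray, topo: MorphTopology, spec: MorphSpec) -> list[tuple]:
    """Complete violation list for one coordinate set.

    Returns tuples ``("bond", i, j, magnitude)`` for bond lengths outside
    the reference +- tolerance band and ``("clash", i, j, magnitude)`` for
    non-bonded pairs closer than ``clash_factor`` x summed vdW radii;
    magnitudes are the Angstrom the constraint is violated by. An empty
    list means the frame is valid.
    """
    coords = np.asarray(coords, dtype=float)
    out: list[tuple] = []
    if len(topo.bonds):
        vec = coords[topo.bonds[:, 0]] - coords[topo.bonds[:, 1]]
        lengths = np.linalg.norm(vec, axis=1)
        lo = topo.ref_lengths * (1 - spec.bond_tolerance)
        hi = topo.ref_lengths * (1 + spec.bond_tolerance)
        bad = (lengths < lo - 1e-5) | (lengths > hi + 1e-5)
        for k in np.where(bad)[0]:
            mag = max(lo[k] - lengths[k], lengths[k] - hi[k])
            out.append(("bond", int(topo.bonds[k, 0]), int(topo.bonds[k, 1]), float(mag)))
    tree = cKDTree(coords)
    maxdist = 2 * topo.radii.max() * spec.clash_factor
    for i, j in tree.query_pairs(maxdist, output_type="ndarray"):
        pair = frozenset((int(i), int(j)))
        if pair in topo.excluded:
            continue
        min_sep = spec.clash_factor * (topo.radii[i] + topo.radii[j])
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < min_sep - 1e-5:
            out.append(("clash", int(i), int(j), float(min_sep - d)))
    return out


def _project_constraints(
    coords: np.ndarray,
    topo: MorphTopology,
    spec: MorphSpec,
    rng: np.random.Generator,
) -> bool:
    """Randomly-ordered Gauss-Seidel sweeps; True when all constraints hold."""
    n_bonds = len(topo.bonds)
    for _ in range(spec.max_projection_passes):
        moved = 0.0
        for k in rng.permutation(n_bonds):
            i, j = topo.bonds[k]
            vec = coords[i] - coords[j]
            length = float(np.linalg.norm(vec))
            ref = topo.ref_lengths[k]
            lo, hi = ref * (1 - spec.bond_tolerance), ref * (1 + spec.bond_tolerance)
            if length < 1e-9:
                vec = rng.standard_normal(3)
                vec /= np.linalg.norm(vec)
                length = 1e-9
            else:
                vec = vec / length
            target = min(max(length, lo), hi)
            if target != length:
                corr = 0.5 * (target - length)
                coords[i] += corr * vec
                coords[j] -= corr * vec
                moved = max(moved, abs(target - length))
        tree = cKDTree(coords)
        maxdist = 2 * topo.radii.max() * spec.clash_factor
        pairs = tree.query_pairs(maxdist, output_type="ndarray")
        if len(pairs):
            for k in rng.permutation(len(pairs)):
                i, j = int(pairs[k, 0]), int(pairs[k, 1])
                if frozenset((i, j)) in topo.excluded:
                    continue
                min_sep = spec.clash_factor * (topo.radii[i] + topo.radii[j])
                vec = coords[i] - coords[j]
                length = float(np.linalg.norm(vec))
                if length >= min_sep:
                    continue
                if length < 1e-9:
                    vec = rng.standard_normal(3)
                    vec /= np.linalg.norm(vec)
                else:
                    vec = vec / length
                corr = 0.5 * (min_sep - length)
                coords[i] += corr * vec
                coords[j] -= corr * vec
                moved = max(moved, min_sep - length)
        if moved < 1e-7:
            return True
    return not validate_frame(coords, topo, spec)


@dataclass
class MorphResult:
    """A single geometric-targeting pathway."""

    frames: ConformerSet
    rmsd_to_target: np.ndarray
    violations: list[list[tuple]]
    converged: bool
    seed: int
    reduced_path: ReducedCoordSeries | None = None


def morph(
    cs: ConformerSet,
    spec: MorphSpec | None = None,
    start: int = 0,
    target: int = -1,
    scheme: RegionScheme | None = None,
) -> MorphResult:
    """Morph frame ``start`` into frame ``target`` of one ConformerSet.

    The target is first rigidly superposed onto the start (the walk should
    spend no steps on global rotation). Each iteration linearly displaces
    all atoms toward the target so the RMSD drops by ``step_rmsd``, then
    restores bond and clash constraints by seeded projection sweeps. The
    walk stops when the RMSD to the target is at most one step, or flags
    ``converged=False`` if projection stalls the approach. With a
    ``scheme`` the pathway is also projected onto (l, phi).
    """
    spec = spec or MorphSpec()
    rng = np.random.default_rng(spec.seed)
    X = cs.frames[start].copy()
    Y = cs.frames[target].copy()
    if X.shape != Y.shape:
        raise TopologyMismatchError("start and target must share the atom topology")
    if len(X) >= 3:
        try:
            rmat, t, _ = superpose(Y, X)
            Y = Y @ rmat.T + t
        except DegenerateGeometryError:
            pass
    topo = build_morph_topology(cs, frame=start)
    frames = [X.copy()]
    d = rmsd(X, Y)
    rmsds = [d]
    violations = [validate_frame(X, topo, spec)]
    converged = True
    s = spec.step_rmsd
    while d > s and len(frames) - 1 < spec.max_steps:
        d_prev = d
        goal = d_prev - s
        alpha = 1.0 - goal / d if d > 1e-12 else 1.0
        X += alpha * (Y - X)
        if spec.wander > 0:
            # seeded lateral jitter makes each seed a distinct random
            # pathway through the geometrically allowed region
            X += spec.wander * s * rng.standard_normal(X.shape) / np.sqrt(3.0)
        ok = _project_constraints(X, topo, spec, rng)
        d = rmsd(X, Y)
        tries = 0
        while d > goal + 0.5 * s and tries < 8:
            # projection pushed us back; pull toward the target again
            alpha = 1.0 - goal / d
            X += alpha * (Y - X)
            ok = _project_constraints(X, topo, spec, rng)
            d = rmsd(X, Y)
            tries += 1
        if d >= d_prev - 1e-9:
            converged = False
            break
        frames.append(X.copy())
        rmsds.append(d)
        violations.append(validate_frame(X, topo, spec))
        if not ok:
            converged = False
            break
    path = ConformerSet(atoms=list(cs.atoms), frames=np.stack(frames))
    reduced = project(path, scheme) if scheme is not None else None
    return MorphResult(
        frames=path,
        rmsd_to_target=np.asarray(rmsds),
        violations=violations,
        converged=converged,
        seed=spec.seed,
        reduced_path=reduced,
    )


def _resample(values: np.ndarray, arc: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if len(values) == 1:
        return np.full(len(grid), values[0])
    return np.interp(grid, arc, values)


def ensemble_morph(
    cs: ConformerSet,
    spec: MorphSpec | None = None,
    start: int = 0,
    target: int = -1,
    n_paths: int = 10,
    scheme: RegionScheme | None = None,
    grid_points: int = 51,
):
    """A family of morph pathways with distinct seeds plus a path summary.

    Each path gets seed ``spec.seed + k``. Paths are resampled onto a
    common normalized arc-length grid (cumulative inter-frame RMSD) before
    computing the per-point median and standard error. The summary carries
    (l, phi) tracks when a scheme is given, otherwise the RMSD-to-target
    track.

    Returns ``(results, summary)`` where summary maps track names to
    ``(grid, median, stderr)``.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    spec = spec or MorphSpec()
    results = []
    for k in range(n_paths):
        results.append(morph(cs, replace(spec, seed=spec.seed + k), start, target, scheme))
    grid = np.linspace(0.0, 1.0, grid_points)
    tracks: dict[str, np.ndarray] = {}
    names = ("l", "phi") if scheme is not None else ("rmsd_to_target",)
    samples = {name: np.empty((n_paths, grid_points)) for name in names}
    for p, res in enumerate(results):
        steps = [
            rmsd(res.frames.frames[i], res.frames.frames[i + 1])
            for i in range(res.frames.n_frames - 1)
        ]
        arc = np.concatenate([[0.0], np.cumsum(steps)])
        arc = arc / arc[-1] if arc[-1] > 0 else np.linspace(0, 1, len(arc))
        if scheme is not None:
            samples["l"][p] = _resample(res.reduced_path.l, arc, grid)
            samples["phi"][p] = _resample(res.reduced_path.phi_unwrapped, arc, grid)
        else:
            samples["rmsd_to_target"][p] = _resample(res.rmsd_to_target, arc, grid)
    summary = {}
    for name in names:
        med = np.median(samples[name], axis=0)
        se = samples[name].std(axis=0, ddof=1) / np.sqrt(n_paths) if n_paths > 1 else np.zeros(grid_points)
        summary[name] = (grid, med, se)
        tracks[name] = samples[name]
    summary["samples"] = tracks
    return results, summary
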
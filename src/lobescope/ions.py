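"""Protein-ion radial distribution functions and coordination shells.

g(r) between reference sites (by default the side-chain heavy atoms of a
region) and a solvent ion species, computed with the minimum-image
convention in per-frame orthorhombic boxes and normalized by the per-frame
bulk ion density rho = N_ions / V_box:

    g(r) = <pair count in shell [r, r+dr)> / (N_ref * rho * V_shell)

First-peak / first-minimum queries run on a lightly smoothed profile
(3-bin moving average by default) since the shell boundary of a noisy
binned g(r) is otherwise ill-defined. The first coordination shell of a
reference set is everything inside the first minimum; the coordination
number counts each ion at most once per frame, however many reference
atoms it touches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptySelectionError, LobescopeError
from .regions import RegionScheme, select_region
from .topology import ConformerSet

__all__ = [
    "RDFProfile",
    "compute_rdf",
    "first_peak",
    "first_minimum",
    "coordination_number",
    "ion_indices",
    "acidic_sidechain_oxygen_indices",
]

ACIDIC_RESNAMES = frozenset({"ASP", "GLU"})


def ion_indices(cs: ConformerSet, species: str = "NA") -> np.ndarray:
    """Indices of monoatomic ions of a species (by residue name)."""
    species = species.upper()
    out = [i for i, a in enumerate(cs.atoms) if a.is_ion and a.residue_name.upper() == species]
    if not out:
        raise EmptySelectionError(f"no {species} ions in the system")
    return np.array(out, dtype=int)


def acidic_sidechain_oxygen_indices(
    cs: ConformerSet, scheme: RegionScheme, region: str
) -> np.ndarray:
    """Side-chain oxygens of Asp/Glu residues of a region (carboxylate O)."""
    idx = select_region(cs, scheme, region, "sidechain_heavy")
    out = [
        i
        for i in idx
        if cs.atoms[i].residue_name.upper() in ACIDIC_RESNAMES and cs.atoms[i].element == "O"
    ]
    if not out:
        raise EmptySelectionError(f"no acidic side-chain oxygens in region {region!r}")
    return np.array(out, dtype=int)


def minimum_image_distances(ref: np.ndarray, other: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(n_ref, n_other) distance matrix under the orthorhombic minimum image."""
    d = ref[:, None, :] - other[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=-1))


@dataclass
class RDFProfile:
    """Binned g(r) with enough bookkeeping to answer shell queries."""

    bin_edges: np.ndarray          # uniform width, Angstrom
    g: np.ndarray                  # dimensionless, one per bin
    pair_counts: np.ndarray        # raw observed pairs per bin (all frames)
    rho_bulk: float                # mean ions / A^3 over frames
    n_frames: int
    n_ref: int
    region_label: str = ""
    ion_label: str = ""

    @property
    def r(self) -> np.ndarray:
        """Bin centers."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def dr(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def smoothed(self, window: int = 3) -> np.ndarray:
        """Moving-average smoothed g (window of bins, odd)."""
        if window <= 1:
            return self.g.copy()
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.concatenate([self.g[:pad][::-1], self.g, self.g[-pad:][::-1]])
        return np.convolve(padded, kernel, mode="valid")

    def mean_g(self, r_lo: float, r_hi: float) -> float:
        mask = (self.r >= r_lo) & (self.r <= r_hi)
        return float(self.g[mask].mean())

    def shell_integral(self, r_cut: float) -> float:
        """rho_bulk * integral_0^r_cut g(r) 4 pi r^2 dr (per reference atom)."""
        mask = self.r < r_cut
        shell_vol = (4.0 / 3.0) * np.pi * (self.bin_edges[1:] ** 3 - self.bin_edges[:-1] ** 3)
        return float(self.rho_bulk * np.sum(self.g[mask] * shell_vol[mask]))


def compute_rdf(
    cs: ConformerSet,
    ref_indices,
    ion_sel,
    dr: float = 0.1,
    r_max: float = 10.0,
    region_label: str = "",
    ion_label: str = "",
) -> RDFProfile:
    """Radial distribution function between reference atoms and ions.

    ``ion_sel`` is either an index array or a species name. Requires
    per-frame box lengths and r_max at most half the smallest box edge.
    """
    if cs.box is None:
        raise LobescopeError("RDF needs per-frame box lengths (periodic system)")
    if isinstance(ion_sel, str):
        ion_label = ion_label or ion_sel
        ion_sel = ion_indices(cs, ion_sel)
    ref_indices = np.asarray(ref_indices, dtype=int)
    ion_sel = np.asarray(ion_sel, dtype=int)
    if ref_indices.size == 0 or ion_sel.size == 0:
        raise EmptySelectionError("empty reference or ion selection for RDF")
    half_min_box = float(cs.box.min()) / 2.0
    if r_max > half_min_box + 1e-9:
        raise LobescopeError(
            f"r_max {r_max} A exceeds half the minimum box length {half_min_box:.2f} A"
        )
    if dr <= 0:
        raise LobescopeError("dr must be > 0")
    edges = np.arange(0.0, r_max + dr / 2, dr)
    n_bins = len(edges) - 1
    counts = np.zeros(n_bins, dtype=np.int64)
    expected = np.zeros(n_bins)
    shell_vol = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho_sum = 0.0
    for f in range(cs.n_frames):
        box = cs.box[f]
        rho = ion_sel.size / float(np.prod(box))
        rho_sum += rho
        dist = minimum_image_distances(cs.frames[f][ref_indices], cs.frames[f][ion_sel], box)
        hist, _ = np.histogram(dist.ravel(), bins=edges)
        counts += hist
        expected += ref_indices.size * rho * shell_vol
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    return RDFProfile(
        bin_edges=edges,
        g=g,
        pair_counts=counts,
        rho_bulk=rho_sum / cs.n_frames,
        n_frames=cs.n_frames,
        n_ref=int(ref_indices.size),
        region_label=region_label,
        ion_label=ion_label,
    )


def first_peak(
    profile: RDFProfile,
    search_window: float = 6.0,
    smooth_window: int = 3,
    min_height: float = 1.0,
) -> tuple[float, float] | None:
    """(r_peak, g_peak) of the first local maximum above ``min_height``.

    Searches the smoothed profile out to ``search_window`` Angstrom;
    returns None when no qualifying peak exists. The reported height is
    read from the smoothed curve, the same curve on which the maximum was
    located.
    """
    gs = profile.smoothed(smooth_window)
    r = profile.r
    limit = np.searchsorted(r, search_window)
    for i in range(limit):
        left = gs[i - 1] if i > 0 else -np.inf
        right = gs[i + 1] if i + 1 < len(gs) else -np.inf
        if gs[i] > min_height and gs[i] >= left and gs[i] > right:
            return float(r[i]), float(gs[i])
    return None


def first_minimum(
    profile: RDFProfile,
    search_window: float = 6.0,
    smooth_window: int = 3,
) -> float | None:
    """Location of the first local minimum after the first peak, or None."""
    peak = first_peak(profile, search_window, smooth_window)
    if peak is None:
        return None
    gs = profile.smoothed(smooth_window)
    r = profile.r
    start = int(np.searchsorted(r, peak[0])) + 1
    for i in range(start, len(gs) - 1):
        if gs[i] <= gs[i - 1] and gs[i] < gs[i + 1]:
            return float(r[i])
    return None


def coordination_number(
    cs: ConformerSet,
    ref_indices,
    ion_sel,
    r_cut: float,
) -> float:
    """Mean number of ions per frame within ``r_cut`` of any reference atom.

    Each ion counts at most once per frame (ions are counted, not
    contacts). Uses the minimum image when a box is present, plain
    Euclidean distances otherwise.
    """
    if r_cut <= 0:
        raise LobescopeError("r_cut must be > 0")
    if isinstance(ion_sel, str):
        ion_sel = ion_indices(cs, ion_sel)
    ref_indices = np.asarray(ref_indices, dtype=int)
    ion_sel = np.asarray(ion_sel, dtype=int)
    if ref_indices.size == 0 or ion_sel.size == 0:
        raise EmptySelectionError("empty reference or ion selection")
    total = 0.0
    for f in range(cs.n_frames):
        ref = cs.frames[f][ref_indices]
        ions = cs.frames[f][ion_sel]
        if cs.box is not None:
            dist = minimum_image_distances(ref, ions, cs.box[f])
        else:
            d = ref[:, None, :] - ions[None, :, :]
            dist = np.sqrt((d * d).sum(axis=-1))
        total += np.count_nonzero((dist <= r_cut).any(axis=0))
    return total / cs.n_frames
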
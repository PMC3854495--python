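"""Radial distribution functions, shell queries, coordination numbers."""

import numpy as np
import pytest

import lobescope as lb
from lobescope.ions import RDFProfile, minimum_image_distances
from lobescope.topology import ConformerSet, make_atom


def lattice_reference(n_side=3, spacing=10.0, offset=10.0) -> ConformerSet:
    """Well-separated fixed reference atoms inside the box."""
    atoms = []
    coords = []
    serial = 1
    for ix in range(n_side):
        for iy in range(n_side):
            atoms.append(make_atom(serial, "CA", "ALA", serial, element="C"))
            coords.append([offset + ix * spacing, offset + iy * spacing, 20.0])
            serial += 1
    return ConformerSet(atoms=atoms, frames=np.asarray(coords)[None, :, :])


def brute_force_rdf(cs, ref_idx, ion_idx, dr, r_max):
    """O(N^2) pair-count oracle with explicit periodic images."""
    edges = np.arange(0.0, r_max + dr / 2, dr)
    counts = np.zeros(len(edges) - 1)
    expected = np.zeros(len(edges) - 1)
    rho_sum = 0.0
    for f in range(cs.n_frames):
        box = cs.box[f]
        rho = len(ion_idx) / np.prod(box)
        rho_sum += rho
        for i in ref_idx:
            for j in ion_idx:
                best = np.inf
                for sx in (-1, 0, 1):
                    for sy in (-1, 0, 1):
                        for sz in (-1, 0, 1):
                            shift = np.array([sx, sy, sz]) * box
                            d = np.linalg.norm(cs.frames[f, i] - cs.frames[f, j] + shift)
                            best = min(best, d)
                if best < r_max:
                    k = int(best / dr)
                    if k < len(counts):
                        counts[k] += 1
        shell = (4 / 3) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        expected += len(ref_idx) * rho * shell
    g = np.where(expected > 0, counts / expected, 0.0)
    return counts, g


class TestComputeRDF:
    def test_uniform_bath_is_flat(self):
        ref = lattice_reference()
        bath = lb.sample_ion_bath(
            lb.IonBathSpec(box=(40, 40, 40), ion_counts={"NA": 500}, n_frames=40, seed=8),
            reference=ref,
        )
        prof = lb.compute_rdf(bath, np.arange(ref.n_atoms), "NA", dr=0.1, r_max=10.0)
        window = (prof.r >= 3.0) & (prof.r <= 10.0)
        assert prof.pair_counts[window].sum() > 10_000
        assert 0.95 <= prof.g[window].mean() <= 1.05

    def test_single_pair_lands_in_single_bin(self):
        atoms = [
            make_atom(1, "CA", "ALA", 1, element="C"),
            make_atom(2, "NA", "NA", 2, hetero=True),
        ]
        frames = np.array([[[10.0, 10, 10], [12.5, 10, 10]]])
        cs = ConformerSet(atoms=atoms, frames=frames, box=np.array([[30.0, 30, 30]]))
        prof = lb.compute_rdf(cs, [0], [1], dr=0.1, r_max=10.0)
        assert prof.pair_counts.sum() == 1
        k = np.argmax(prof.pair_counts)
        assert prof.bin_edges[k] <= 2.5 < prof.bin_edges[k + 1]

    def test_matches_brute_force_oracle_small_system(self):
        rng = np.random.default_rng(17)
        box = np.array([18.0, 20.0, 22.0])
        n_ref, n_ion, n_frames = 6, 30, 4
        atoms = [make_atom(i + 1, "CA", "ALA", i + 1, element="C") for i in range(n_ref)]
        atoms += [
            make_atom(n_ref + i + 1, "NA", "NA", n_ref + i + 1, hetero=True)
            for i in range(n_ion)
        ]
        frames = rng.uniform(0, 1, size=(n_frames, n_ref + n_ion, 3)) * box
        cs = ConformerSet(atoms=atoms, frames=frames, box=np.tile(box, (n_frames, 1)))
        ref_idx = np.arange(n_ref)
        ion_idx = np.arange(n_ref, n_ref + n_ion)
        prof = lb.compute_rdf(cs, ref_idx, ion_idx, dr=0.25, r_max=8.0)
        counts, g = brute_force_rdf(cs, ref_idx, ion_idx, dr=0.25, r_max=8.0)
        np.testing.assert_array_equal(prof.pair_counts, counts)
        np.testing.assert_allclose(prof.g, g, atol=1e-9)

    def test_r_max_beyond_half_box_rejected(self):
        ref = lattice_reference()
        bath = lb.sample_ion_bath(
            lb.IonBathSpec(box=(18, 18, 18), ion_counts={"NA": 30}, n_frames=1, seed=1),
            reference=ref,
        )
        with pytest.raises(lb.LobescopeError):
            lb.compute_rdf(bath, np.arange(ref.n_atoms), "NA", dr=0.1, r_max=10.0)

    def test_integral_consistency_with_in_shell_count(self):
        ref = lattice_reference()
        bath = lb.sample_ion_bath(
            lb.IonBathSpec(box=(40, 40, 40), ion_counts={"NA": 400}, n_frames=30, seed=5),
            reference=ref,
        )
        ref_idx = np.arange(ref.n_atoms)
        ion_idx = lb.ion_indices(bath, "NA")
        r_cut = 6.0
        prof = lb.compute_rdf(bath, ref_idx, ion_idx, dr=0.1, r_max=10.0)
        integral = prof.shell_integral(r_cut) * prof.n_ref
        pairs_in_shell = 0.0
        for f in range(bath.n_frames):
            d = minimum_image_distances(
                bath.frames[f][ref_idx], bath.frames[f][ion_idx], bath.box[f]
            )
            pairs_in_shell += (d < r_cut).sum()
        pairs_in_shell /= bath.n_frames
        assert integral == pytest.approx(pairs_in_shell, rel=0.05)


def synthetic_profile(g_values, dr=0.1):
    edges = np.arange(0.0, dr * (len(g_values) + 0.5), dr)[: len(g_values) + 1]
    return RDFProfile(
        bin_edges=edges,
        g=np.asarray(g_values, dtype=float),
        pair_counts=np.zeros(len(g_values), dtype=int),
        rho_bulk=0.01,
        n_frames=1,
        n_ref=1,
    )


class TestPeakQueries:
    def test_gaussian_bump_peak_location(self):
        r = np.arange(0.05, 8.0, 0.1)
        prof = synthetic_profile(1.0 + 3.0 * np.exp(-((r - 2.3) ** 2) / 0.08))
        r_peak, g_peak = lb.first_peak(prof)
        assert r_peak == pytest.approx(2.3, abs=0.1)
        assert g_peak > 2.0

    def test_monotone_decreasing_peaks_at_first_bin(self):
        prof = synthetic_profile(np.linspace(5.0, 0.5, 60))
        r_peak, _ = lb.first_peak(prof)
        assert r_peak == pytest.approx(prof.r[0])

    def test_noisy_profile_matches_argmax_after_identical_smoothing(self):
        rng = np.random.default_rng(23)
        r = np.arange(0.05, 8.0, 0.1)
        # RDF-like shape: excluded-volume zero at contact, single peak, decay
        g = 2.5 * np.exp(-((r - 2.5) ** 2) / 0.2) + rng.normal(0, 0.05, len(r))
        g[r < 1.5] = 0.0
        prof = synthetic_profile(g)
        r_peak, g_peak = lb.first_peak(prof)
        gs = prof.smoothed(3)
        window = prof.r < 6.0
        k = int(np.argmax(gs[window]))
        assert r_peak == pytest.approx(prof.r[k])
        assert g_peak == pytest.approx(gs[k])

    def test_flat_profile_has_no_peak(self):
        prof = synthetic_profile(np.ones(80))
        assert lb.first_peak(prof) is None
        assert lb.first_minimum(prof) is None

    def test_two_gaussian_minimum_between_peaks(self):
        r = np.arange(0.05, 8.0, 0.1)
        g = (
            1.0
            + 3.0 * np.exp(-((r - 2.3) ** 2) / 0.08)
            + 2.0 * np.exp(-((r - 4.5) ** 2) / 0.08)
        )
        prof = synthetic_profile(g)
        r_min = lb.first_minimum(prof)
        assert 2.3 < r_min < 4.5


class TestCoordinationNumber:
    def test_one_ion_inside_cutoff_every_frame(self):
        atoms = [
            make_atom(1, "CA", "ALA", 1, element="C"),
            make_atom(2, "NA", "NA", 2, hetero=True),
        ]
        frames = np.tile(np.array([[[10.0, 10, 10], [12.0, 10, 10]]]), (10, 1, 1))
        cs = ConformerSet(atoms=atoms, frames=frames, box=np.tile([30.0, 30, 30], (10, 1)))
        assert lb.coordination_number(cs, [0], [1], r_cut=3.0) == pytest.approx(1.0)

    def test_no_ions_in_shell_gives_zero(self):
        atoms = [
            make_atom(1, "CA", "ALA", 1, element="C"),
            make_atom(2, "NA", "NA", 2, hetero=True),
        ]
        frames = np.tile(np.array([[[5.0, 5, 5], [20.0, 20, 20]]]), (4, 1, 1))
        cs = ConformerSet(atoms=atoms, frames=frames, box=np.tile([50.0, 50, 50], (4, 1)))
        assert lb.coordination_number(cs, [0], [1], r_cut=3.0) == 0.0

    def test_random_configurations_match_counting_oracle(self):
        rng = np.random.default_rng(29)
        box = np.array([25.0, 25.0, 25.0])
        n_ref, n_ion, n_frames = 5, 40, 6
        atoms = [make_atom(i + 1, "CA", "ALA", i + 1, element="C") for i in range(n_ref)]
        atoms += [
            make_atom(n_ref + i + 1, "NA", "NA", n_ref + i + 1, hetero=True)
            for i in range(n_ion)
        ]
        frames = rng.uniform(0, 1, size=(n_frames, n_ref + n_ion, 3)) * box
        cs = ConformerSet(atoms=atoms, frames=frames, box=np.tile(box, (n_frames, 1)))
        r_cut = 6.0
        got = lb.coordination_number(cs, np.arange(n_ref), np.arange(n_ref, n_ref + n_ion), r_cut)
        total = 0
        for f in range(n_frames):
            for j in range(n_ref, n_ref + n_ion):
                near = False
                for i in range(n_ref):
                    delta = cs.frames[f, i] - cs.frames[f, j]
                    delta -= box * np.round(delta / box)
                    if np.linalg.norm(delta) <= r_cut:
                        near = True
                        break
                total += near
        assert got == pytest.approx(total / n_frames)

    def test_ion_counted_once_despite_multiple_contacts(self):
        atoms = [
            make_atom(1, "CA", "ALA", 1, element="C"),
            make_atom(2, "CB", "ALA", 1, element="C"),
            make_atom(3, "NA", "NA", 2, hetero=True),
        ]
        frames = np.array([[[10.0, 10, 10], [11.0, 10, 10], [10.5, 10, 10]]])
        cs = ConformerSet(atoms=atoms, frames=frames, box=np.array([[30.0, 30, 30]]))
        assert lb.coordination_number(cs, [0, 1], [2], r_cut=3.0) == pytest.approx(1.0)
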
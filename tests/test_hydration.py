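"""Density profiles, water orientations, RDFs and first-shell detection."""

import numpy as np
import pytest

from nanosorb.dynamics import Trajectory
from nanosorb.hydration import (
    density_profile,
    first_minimum,
    orientation_angles,
    orientation_histogram,
    pair_rdf,
)
from nanosorb.structures import LatticeSpec, build_unit_cell
from nanosorb.synthetic import (
    layered_fluid_trajectory,
    sample_orientations,
    two_gaussian_profile,
)


def ideal_gas_traj(rng, n=400, frames=8, box=(30.0, 30.0, 60.0), periodic=(True, True, False)):
    pos = rng.uniform(size=(frames, n, 3)) * np.asarray(box)
    return Trajectory(
        species=np.array(["O"] * n, dtype=object),
        times=np.arange(frames, dtype=float),
        frames=pos,
        box=np.asarray(box, dtype=float),
        periodic=np.asarray(periodic),
    )


class TestDensityProfile:
    def test_ideal_gas_planar_profile_is_flat(self, rng):
        traj = ideal_gas_traj(rng)
        prof = density_profile(traj, mode="planar-z", bin_width=0.5)
        expected = 400 / (3.0 * 3.0 * 6.0)  # nm^-3
        assert prof.density.mean() == pytest.approx(expected, rel=0.02)
        assert prof.density.std() / expected < 0.25  # counting noise only

    def test_ideal_gas_radial_profile_flat_after_shell_normalization(self, rng):
        n, frames = 3000, 10
        pos = rng.uniform(-1, 1, size=(frames, n, 3)) * 25.0
        r = np.linalg.norm(pos, axis=2)
        traj = Trajectory(
            species=np.array(["O"] * n, dtype=object),
            times=np.arange(frames, dtype=float),
            frames=pos,
            box=np.full(3, 50.0),
            periodic=np.zeros(3, dtype=bool),
        )
        prof = density_profile(traj, mode="radial", reference=np.zeros(3),
                               bin_width=0.25, r_max=2.0)
        inner = prof.density[(prof.bins > 0.5) & (prof.bins < 2.0)]
        assert inner.std() / inner.mean() < 0.15

    def test_layered_fluid_roundtrip_recovers_peaks(self):
        target = two_gaussian_profile(centers=(1.0, 2.2), widths=(0.12, 0.18),
                                      amplitudes=(3.0, 1.5), baseline=0.1)
        traj = layered_fluid_trajectory(target, n_frames=40, seed=3,
                                        n_particles=800)
        prof = density_profile(traj, mode="planar-z", bin_width=0.05)
        for center in (1.0, 2.2):
            near = np.abs(prof.bins - center) < 0.3
            peak_pos = prof.bins[near][np.argmax(prof.density[near])]
            assert abs(peak_pos - center) <= 0.05  # within one bin

    def test_mass_conservation(self, rng):
        traj = ideal_gas_traj(rng)
        for mode, ref in (("planar-z", None), ("radial", np.array([15.0, 15.0, 30.0]))):
            prof = density_profile(traj, mode=mode, reference=ref, bin_width=0.3,
                                   r_max=4.0)
            recovered = (prof.density * prof.volumes).sum()
            assert abs(recovered - prof.n_mean) / traj.n_atoms < 1e-3

    def test_nearest_surface_mode_uses_closest_atom(self):
        surface = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        pos = np.array([[[0.0, 0.0, 3.0], [10.0, 0.0, 5.0]]])
        traj = Trajectory(
            species=np.array(["O", "O"], dtype=object),
            times=np.array([0.0]),
            frames=pos,
            box=np.full(3, 50.0),
            periodic=np.zeros(3, dtype=bool),
        )
        prof = density_profile(traj, mode="nearest-surface", reference=surface,
                               bin_width=0.1)
        occupied = prof.bins[prof.density > 0]
        assert np.allclose(sorted(occupied), [0.35, 0.55], atol=1e-6)

    def test_empty_selection_rejected(self, rng):
        traj = ideal_gas_traj(rng)
        with pytest.raises(ValueError, match="selection"):
            density_profile(traj, selection="Zn")


def water_frame(dipole_dir, n=1, hoh_deg=104.52, oh=0.9572):
    """O at origin and two H placed so the dipole bisector points along
    ``dipole_dir``."""
    dipole_dir = np.asarray(dipole_dir, dtype=float)
    dipole_dir = dipole_dir / np.linalg.norm(dipole_dir)
    # orthonormal partner for the in-plane spread
    helper = np.array([1.0, 0.0, 0.0])
    if abs(dipole_dir @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    perp = np.cross(dipole_dir, helper)
    perp /= np.linalg.norm(perp)
    half = np.deg2rad(hoh_deg / 2)
    h1 = oh * (np.cos(half) * dipole_dir + np.sin(half) * perp)
    h2 = oh * (np.cos(half) * dipole_dir - np.sin(half) * perp)
    o = np.array([5.0, 5.0, 5.0])
    return np.array([o, o + h1, o + h2])


def single_water_traj(dipole_dir):
    frame = water_frame(dipole_dir)
    return Trajectory(
        species=np.array(["O", "H", "H"], dtype=object),
        times=np.array([0.0]),
        frames=frame[None, :, :],
        box=np.full(3, 20.0),
        periodic=np.zeros(3, dtype=bool),
    )


class TestOrientationAngles:
    def test_dipole_along_reference_gives_theta_zero(self):
        traj = single_water_traj([0.0, 0.0, 1.0])
        samples = orientation_angles(traj, [[0, 1, 2]], reference="z")
        assert samples.theta_deg[0] == pytest.approx(0.0, abs=1e-9)

    def test_ideal_geometry_oh_angles_are_half_hoh(self):
        traj = single_water_traj([0.0, 0.0, 1.0])
        samples = orientation_angles(traj, [[0, 1, 2]], reference="z")
        assert np.allclose(samples.alpha_deg, 104.52 / 2, atol=1e-9)

    def test_isotropic_mean_cos_theta_vanishes(self):
        n = 4000
        dirs = sample_orientations("isotropic", n=n, seed=5)
        frames = np.array([np.concatenate([water_frame(d) for d in dirs])])
        triples = np.arange(3 * n).reshape(n, 3)
        traj = Trajectory(
            species=np.array(["O", "H", "H"] * n, dtype=object),
            times=np.array([0.0]),
            frames=frames,
            box=np.full(3, 20.0),
            periodic=np.zeros(3, dtype=bool),
        )
        samples = orientation_angles(traj, triples, reference="z")
        mean_cos = np.cos(np.deg2rad(samples.theta_deg)).mean()
        assert abs(mean_cos) < 3.0 / np.sqrt(3 * n)

    def test_shell_filter_by_distance_to_surface(self):
        traj = single_water_traj([0.0, 0.0, 1.0])
        surface = np.array([[5.0, 5.0, 0.0]])
        inside = orientation_angles(traj, [[0, 1, 2]], reference="z",
                                    surface=surface, shell=(0.0, 0.6))
        assert len(inside.theta_deg) == 1
        outside = orientation_angles(traj, [[0, 1, 2]], reference="z",
                                     surface=surface, shell=(0.6, 1.0))
        assert len(outside.theta_deg) == 0

    def test_rotation_invariance_with_radial_reference(self, rng):
        from scipy.spatial.transform import Rotation

        n = 200
        dirs = sample_orientations("axial-biased", n=n, seed=8, mu_deg=65.0)
        frames = np.array([np.concatenate([water_frame(d) for d in dirs])])
        triples = np.arange(3 * n).reshape(n, 3)

        def hist(frames_in):
            traj = Trajectory(
                species=np.array(["O", "H", "H"] * n, dtype=object),
                times=np.array([0.0]),
                frames=frames_in,
                box=np.full(3, 20.0),
                periodic=np.zeros(3, dtype=bool),
            )
            center = np.array([5.0, 5.0, 5.0]) * 0.0  # rotate about origin
            samples = orientation_angles(traj, triples, reference=("radial", center))
            return orientation_histogram(samples.theta_deg, bin_width=5.0)[1]

        rot = Rotation.random(random_state=4).as_matrix()
        h0 = hist(frames)
        h1 = hist(frames @ rot.T)
        assert np.allclose(h0, h1, atol=1e-12)


class TestOrientationHistogram:
    def test_isotropic_raw_histogram_follows_sine(self):
        dirs = sample_orientations("isotropic", n=100_000, seed=2)
        theta = np.rad2deg(np.arccos(np.clip(dirs[:, 2], -1, 1)))
        centers, density = orientation_histogram(theta, weighting="raw",
                                                 bin_width=5.0)
        expected = np.sin(np.deg2rad(centers))
        expected /= expected.sum() * 5.0
        assert np.abs(density - expected).max() < 0.002
        assert centers[np.argmax(density)] == pytest.approx(90.0, abs=5.0)

    def test_isotropic_sin_corrected_is_flat(self):
        dirs = sample_orientations("isotropic", n=100_000, seed=2)
        theta = np.rad2deg(np.arccos(np.clip(dirs[:, 2], -1, 1)))
        centers, density = orientation_histogram(theta, weighting="sin-corrected",
                                                 bin_width=10.0)
        interior = (centers > 15) & (centers < 165)  # poles are noise-dominated
        assert density[interior].std() / density[interior].mean() < 0.1

    def test_histogram_normalizes_to_unit_integral(self):
        theta = np.full(50, 65.0)
        centers, density = orientation_histogram(theta, bin_width=2.0)
        assert (density * 2.0).sum() == pytest.approx(1.0)
        assert (density > 0).sum() == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            orientation_histogram(np.array([]))


class TestPairRDF:
    def test_ideal_gas_rdf_is_unity(self, rng):
        n, frames = 300, 12
        box = np.full(3, 30.0)
        pos = rng.uniform(size=(frames, n, 3)) * box
        traj = Trajectory(
            species=np.array(["O"] * n, dtype=object),
            times=np.arange(frames, dtype=float),
            frames=pos, box=box, periodic=np.ones(3, dtype=bool),
        )
        rdf = pair_rdf(traj, np.arange(n), np.arange(n), bin_width=0.1, r_max=1.4)
        tail = rdf.g[rdf.r > 0.3]
        assert tail.mean() == pytest.approx(1.0, abs=0.05)

    def test_two_fixed_particles_peak_at_separation(self):
        pos = np.array([[[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]]])
        traj = Trajectory(
            species=np.array(["A", "B"], dtype=object),
            times=np.array([0.0]),
            frames=pos, box=np.full(3, 30.0), periodic=np.zeros(3, dtype=bool),
        )
        rdf = pair_rdf(traj, np.array([0]), np.array([1]), bin_width=0.05,
                       r_max=1.0)
        assert rdf.r[np.argmax(rdf.g)] == pytest.approx(0.625, abs=0.026)

    def test_crystal_shell_distances(self):
        cell = build_unit_cell(LatticeSpec())
        # replicate 3x3x3 to fill shells around central atoms
        reps = []
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    reps.append(cell.positions + np.array([i, j, k]) * 5.41)
        pos = np.concatenate(reps)
        species = np.tile(cell.species, 27)
        traj = Trajectory(
            species=species,
            times=np.array([0.0]),
            frames=pos[None, :, :],
            box=np.full(3, 3 * 5.41),
            periodic=np.ones(3, dtype=bool),
        )
        zn = np.flatnonzero(species == "Zn")
        s = np.flatnonzero(species == "S")
        rdf = pair_rdf(traj, zn, s, bin_width=0.01, r_max=0.6)
        peaks = rdf.r[rdf.g > 0.5]
        a = 0.541
        assert np.any(np.abs(peaks - a * np.sqrt(3) / 4) < 0.01)
        assert np.any(np.abs(peaks - a * np.sqrt(11) / 4) < 0.01)
        # nothing between the shells
        between = (rdf.r > 0.26) & (rdf.r < 0.43)
        assert rdf.g[between].max() == 0.0

    def test_r_max_beyond_half_box_rejected(self, rng):
        traj = ideal_gas_traj(rng, box=(20.0, 20.0, 20.0),
                              periodic=(True, True, True))
        with pytest.raises(ValueError, match="half"):
            pair_rdf(traj, np.arange(10), np.arange(10), r_max=1.5)


class TestFirstMinimum:
    def test_two_gaussian_profile_trough(self):
        x = np.linspace(0, 4, 400)
        y = np.exp(-((x - 1.0) ** 2) / 0.02) + 0.7 * np.exp(-((x - 2.0) ** 2) / 0.05)
        loc = first_minimum((x, y))
        # analytic trough of the sum sits between the peaks
        dense = np.linspace(1.0, 2.0, 20000)
        yd = np.exp(-((dense - 1.0) ** 2) / 0.02) + 0.7 * np.exp(-((dense - 2.0) ** 2) / 0.05)
        assert loc == pytest.approx(dense[np.argmin(yd)], abs=0.015)

    def test_monotone_profile_raises(self):
        x = np.linspace(0, 1, 50)
        with pytest.raises(ValueError, match="maximum"):
            first_minimum((x, np.exp(-x)))

    def test_no_smoothing_equals_smoothed_on_noiseless_input(self):
        x = np.linspace(0, 4, 400)
        y = np.exp(-((x - 1.0) ** 2) / 0.02) + 0.7 * np.exp(-((x - 2.0) ** 2) / 0.05)
        assert first_minimum((x, y), window=1) == pytest.approx(
            first_minimum((x, y), window=3), abs=0.02
        )
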
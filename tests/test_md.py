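"""MD trajectory descriptors against analytic and Monte-Carlo oracles."""

import math

import numpy as np
import pytest

from viscml.md import (
    R_KCAL_MOL_K,
    SystemTopology,
    Trajectory,
    TrajectoryFrame,
    cohesive_energy_and_solubility,
    ensemble_descriptors,
    heat_of_vaporization,
    mass_density,
    percent_free_volume,
    radius_of_gyration,
    read_trajectory,
    rms_displacement,
    write_trajectory,
)
from viscml.synthetic import generate_toy_trajectory


def box_frame(coords, L=10.0, time=0.0, energies=None):
    return TrajectoryFrame(
        np.asarray(coords, dtype=float), np.array([L, L, L]), time, energies
    )


def simple_topo(n, mass=18.0, radius=1.5, per_atom_molecules=True):
    return SystemTopology(
        np.full(n, mass),
        np.full(n, radius),
        np.arange(n) if per_atom_molecules else np.zeros(n, dtype=int),
        n if per_atom_molecules else 1,
    )


class TestDensity:
    def test_hand_unit_conversion(self):
        # 100 atoms of 18 u in a (10 A)^3 box -> 2.989 g/cm^3
        frame = box_frame(np.zeros((100, 3)))
        topo = simple_topo(100)
        assert mass_density(frame, topo) == pytest.approx(2.989, abs=1e-3)

    def test_box_scaling_exponent(self):
        coords = np.zeros((10, 3))
        topo = simple_topo(10)
        d1 = mass_density(box_frame(coords, L=10), topo)
        d2 = mass_density(box_frame(coords, L=20), topo)
        assert d1 / d2 == pytest.approx(8.0)

    def test_empty_topology_errors(self):
        with pytest.raises(ValueError):
            SystemTopology(np.array([]), np.array([]), np.array([]), 0)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        frame = box_frame([[5, 5, 5]])
        assert radius_of_gyration(frame, simple_topo(1)) == 0.0

    def test_dimer_half_distance(self):
        traj, topo, expected = generate_toy_trajectory("dimer", d=2.0)
        assert radius_of_gyration(traj.frames[0], topo) == pytest.approx(
            expected["MD_Rg"], abs=1e-9
        )

    def test_square_analytic(self):
        traj, topo, expected = generate_toy_trajectory("square", a=3.0)
        assert radius_of_gyration(traj.frames[0], topo) == pytest.approx(
            expected["MD_Rg"], abs=1e-9
        )

    def test_periodic_unwrapping_within_molecule(self):
        # dimer straddling the boundary: 0.5 and 9.5 are 1 A apart under
        # minimum image, so Rg = 0.5
        frame = box_frame([[0.5, 5, 5], [9.5, 5, 5]])
        topo = simple_topo(2, per_atom_molecules=False)
        assert radius_of_gyration(frame, topo) == pytest.approx(0.5, abs=1e-9)

    def test_translation_invariance(self, rng):
        coords = rng.uniform(2, 4, size=(5, 3))
        topo = simple_topo(5, per_atom_molecules=False)
        r1 = radius_of_gyration(box_frame(coords), topo)
        r2 = radius_of_gyration(box_frame((coords + 3.7) % 10.0), topo)
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestRmsDisplacement:
    def test_identical_frames_zero(self):
        coords = np.ones((4, 3))
        traj = Trajectory([box_frame(coords, time=0), box_frame(coords, time=1)])
        out = rms_displacement(traj)
        np.testing.assert_allclose(out, [0.0, 0.0])

    def test_rigid_unit_translation(self):
        traj, topo, expected = generate_toy_trajectory(
            "translate", delta=(1.0, 0.0, 0.0), n_frames=3
        )
        out = rms_displacement(traj, topo)
        np.testing.assert_allclose(out, expected["rmsd_per_frame"], atol=1e-9)

    def test_hand_two_atom_case(self):
        a = np.array([[1.0, 1, 1], [5.0, 5, 5]])
        b = a + np.array([[3.0, 0, 0], [4.0, 0, 0]])
        traj = Trajectory([box_frame(a, time=0), box_frame(b, time=1)])
        assert rms_displacement(traj)[1] == pytest.approx(math.sqrt(12.5))

    def test_reference_index_validation(self):
        coords = np.ones((2, 3))
        traj = Trajectory([box_frame(coords, time=0), box_frame(coords, time=1)])
        with pytest.raises(IndexError):
            rms_displacement(traj, reference_index=5)


class TestFreeVolume:
    def test_empty_box_is_100_percent(self):
        frame = box_frame(np.zeros((1, 3)))
        topo = SystemTopology(
            np.array([1.0]), np.array([0.0]), np.array([0]), 1
        )
        # zero-radius atom occupies (essentially) nothing
        assert percent_free_volume(frame, topo, grid_spacing=0.5) > 99.9

    def test_single_sphere_closed_form(self):
        traj, topo, expected = generate_toy_trajectory(
            "single-sphere", radius=2.0, box=10.0
        )
        fv = percent_free_volume(traj.frames[0], topo, grid_spacing=0.25)
        assert fv == pytest.approx(expected["MD_FV"], abs=0.5)

    def test_lattice_closed_form(self):
        traj, topo, expected = generate_toy_trajectory(
            "lattice", m=3, radius=1.0, box=9.0
        )
        fv = percent_free_volume(traj.frames[0], topo, grid_spacing=0.1)
        assert fv == pytest.approx(expected["MD_FV"], abs=0.5)

    def test_agrees_with_monte_carlo_oracle(self, rng):
        coords = rng.uniform(0, 10, size=(12, 3))
        radii = rng.uniform(0.8, 1.8, size=12)
        topo = SystemTopology(np.ones(12), radii, np.arange(12), 12)
        frame = box_frame(coords)
        grid = percent_free_volume(frame, topo, grid_spacing=0.2)
        # independent MC estimate with periodic minimum image
        pts = rng.uniform(0, 10, size=(40000, 3))
        free = np.ones(len(pts), dtype=bool)
        for x, r in zip(coords, radii):
            d = pts - x
            d -= 10.0 * np.round(d / 10.0)
            free &= (d**2).sum(axis=1) > r * r
        mc = 100.0 * free.mean()
        assert grid == pytest.approx(mc, abs=1.0)

    def test_grid_spacing_validation(self):
        frame = box_frame(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            percent_free_volume(frame, simple_topo(1), grid_spacing=0.0)


class TestEnergetics:
    def test_zero_energy_gives_zero_parameters(self):
        frames = [
            box_frame(np.zeros((2, 3)), time=t,
                      energies={"e_inter": 0.0, "e_elec": 0.0, "e_vdw": 0.0})
            for t in (0, 1)
        ]
        out = cohesive_energy_and_solubility(frames, simple_topo(2))
        assert out["MD_SP"] == out["MD_SP_E"] == out["MD_SP_V"] == 0.0

    def test_unit_conversion_oracle(self):
        traj, topo, expected = generate_toy_trajectory(
            "constant-energy", e_inter=-1000.0, box=10.0 ** (5 / 3)
        )
        out = cohesive_energy_and_solubility(traj.frames, topo)
        # independent conversion: kcal/mol/A^3 -> Pa via Avogadro
        ced_pa = 1000.0 * 4184.0 / 6.02214076e23 / (10.0**5 * 1e-30)
        assert out["CED"] == pytest.approx(ced_pa / 1e6, rel=1e-9)
        assert out["MD_SP"] == pytest.approx(math.sqrt(ced_pa / 1e6), rel=1e-9)

    def test_component_additivity(self):
        traj, topo, _ = generate_toy_trajectory(
            "constant-energy", e_inter=-500.0, e_elec=-200.0, e_vdw=-300.0
        )
        out = cohesive_energy_and_solubility(traj.frames, topo)
        assert out["MD_SP_E"] ** 2 + out["MD_SP_V"] ** 2 == pytest.approx(
            out["MD_SP"] ** 2, rel=1e-9
        )

    def test_positive_energy_clamped_with_warning(self):
        traj, topo, _ = generate_toy_trajectory("constant-energy", e_inter=50.0)
        with pytest.warns(UserWarning):
            out = cohesive_energy_and_solubility(traj.frames, topo)
        assert out["MD_SP"] == 0.0

    def test_heat_of_vaporization_rt_limit(self):
        frames = [
            box_frame(np.zeros((3, 3)), time=t, energies={"e_inter": 0.0})
            for t in (0, 1)
        ]
        topo = simple_topo(3)
        hv = heat_of_vaporization(frames, topo, T=300.0)
        assert hv == pytest.approx(R_KCAL_MOL_K * 300.0, rel=1e-9)
        assert hv == pytest.approx(0.5962, abs=1e-4)

    def test_heat_of_vaporization_arithmetic(self):
        frames = [
            box_frame(np.zeros((3, 3)), time=t, energies={"e_inter": -4000.0})
            for t in (0, 1)
        ]
        topo = SystemTopology(
            np.ones(3), np.ones(3), np.array([0, 1, 2]), 3
        )
        # 100 molecules would give 40; with 3 molecules scale accordingly
        assert heat_of_vaporization(frames, topo, T=0.0) == pytest.approx(
            4000.0 / 3
        )

    def test_missing_energies_error(self):
        frames = [box_frame(np.zeros((2, 3)), time=t) for t in (0, 1)]
        with pytest.raises(ValueError):
            heat_of_vaporization(frames, simple_topo(2), 300.0)


class TestEnsembleAveraging:
    def _ramp_trajectory(self):
        # density ramp via shrinking box: descriptor values vary per frame
        frames = []
        for k in range(10):
            L = 10.0 - 0.1 * k
            frames.append(
                TrajectoryFrame(
                    np.full((4, 3), 2.0),
                    np.array([L, L, L]),
                    float(k),
                    {"e_inter": -100.0 - k, "e_elec": -50.0, "e_vdw": -50.0 - k},
                )
            )
        return Trajectory(frames, ["C"] * 4)

    def test_trailing_window_mean(self):
        traj = self._ramp_trajectory()
        topo = simple_topo(4)
        desc = ensemble_descriptors(traj, topo, T=300.0, trailing_fraction=0.5)
        expected = np.mean(
            [mass_density(f, topo) for f in traj.frames[5:]]
        )
        assert desc.MD_density == pytest.approx(expected, rel=1e-12)

    def test_full_window_boundary(self):
        traj = self._ramp_trajectory()
        topo = simple_topo(4)
        desc = ensemble_descriptors(traj, topo, T=300.0, trailing_fraction=1.0)
        expected = np.mean([mass_density(f, topo) for f in traj.frames])
        assert desc.MD_density == pytest.approx(expected, rel=1e-12)

    def test_constant_values_recovered(self):
        frames = [
            TrajectoryFrame(
                np.full((2, 3), 5.0), np.array([10.0] * 3), float(t),
                {"e_inter": -10.0, "e_elec": -4.0, "e_vdw": -6.0},
            )
            for t in range(4)
        ]
        traj = Trajectory(frames, ["C", "C"])
        topo = simple_topo(2)
        desc = ensemble_descriptors(traj, topo, T=300.0)
        assert desc.MD_density == pytest.approx(
            mass_density(frames[0], topo), rel=1e-12
        )
        assert desc.MD_RMSD == 0.0


class TestTrajectoryIO:
    def test_round_trip(self, tmp_path, rng):
        frames = [
            TrajectoryFrame(
                rng.uniform(0, 10, (3, 3)), np.array([10.0, 11.0, 12.0]),
                100.0 * t, {"e_inter": -5.0 - t},
            )
            for t in range(2)
        ]
        traj = Trajectory(frames, ["C", "O", "H"])
        path = tmp_path / "traj.xyz"
        write_trajectory(path, traj)
        topo_path = tmp_path / "topo.json"
        topo_path.write_text(
            '{"molecule_membership": [0, 0, 0], "n_molecules": 1}'
        )
        back, topo = read_trajectory(path, topo_path)
        assert len(back) == 2
        np.testing.assert_allclose(
            back.frames[0].coordinates, frames[0].coordinates, atol=1e-6
        )
        assert back.frames[1].energies["e_inter"] == -6.0
        # masses/radii defaulted from the element table
        assert topo.atom_masses[1] == pytest.approx(15.999)

    def test_atom_count_mismatch_errors(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text('1\nbox="10 10 10" time=0\nC 1 1 1\n')
        topo_path = tmp_path / "topo.json"
        topo_path.write_text('{"molecule_membership": [0, 0], "n_molecules": 1}')
        with pytest.raises(ValueError):
            read_trajectory(path, topo_path)

    def test_missing_energy_block_tolerated(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text(
            '1\nbox="10 10 10" time=0 e_inter=-1\nC 1 1 1\n'
            '1\nbox="10 10 10" time=1\nC 1 1 1\n'
        )
        traj, _ = read_trajectory(path)
        assert traj.frames[0].energies == {"e_inter": -1.0}
        assert traj.frames[1].energies is None

    def test_non_monotonic_times_error(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text(
            '1\nbox="10 10 10" time=1\nC 1 1 1\n'
            '1\nbox="10 10 10" time=0\nC 1 1 1\n'
        )
        with pytest.raises(ValueError):
            read_trajectory(path)
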
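"""Force-field fitting, mixing and energy/force evaluation."""

import numpy as np
import pytest

from nanosorb.constants import COULOMB_K
from nanosorb.forcefield import (
    BondedParams,
    BuckinghamParams,
    SpeciesNonbonded,
    ForceFieldModel,
    evaluate_energy_forces,
    fit_harmonic_angle,
    fit_harmonic_bond,
    load_forcefield,
    lorentz_berthelot,
    pair_total_potential,
    save_forcefield,
    zns_table1_forcefield,
)
from nanosorb.structures import NanoStructure


def harmonic_lsq_oracle(x, u):
    """Independent dense-grid least-squares oracle via explicit normal
    equations on the monomial basis (1, x, x^2)."""
    A = np.stack([np.ones_like(x), x, x * x], axis=1)
    coef = np.linalg.solve(A.T @ A, A.T @ u)
    k = 2.0 * coef[2]
    x0 = -coef[1] / (2.0 * coef[2])
    return k, x0


class TestPairPotential:
    def test_pure_coulomb_at_10A(self):
        buck = BuckinghamParams(A=0.0, rho=1.0, C6=0.0)
        e = pair_total_potential(10.0, buck, 2.0, -2.0)
        assert e == pytest.approx(-555.7418, abs=1e-3)

    def test_pure_exponential_term(self):
        buck = BuckinghamParams(A=1000.0, rho=0.3, C6=0.0)
        r = 2.0
        assert pair_total_potential(r, buck, 0.0, 0.0) == pytest.approx(
            1000.0 * np.exp(-r / 0.3)
        )

    def test_additivity_of_terms(self):
        buck = BuckinghamParams(A=1234.0, rho=0.25, C6=500.0)
        r = 2.2
        total = pair_total_potential(r, buck, 2.0, -2.0)
        parts = (
            1234.0 * np.exp(-r / 0.25)
            - 500.0 / r**6
            + COULOMB_K * 2.0 * -2.0 / r
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_zero_distance_raises(self):
        with pytest.raises(ValueError):
            pair_total_potential(0.0, BuckinghamParams(A=1.0, rho=1.0), 0, 0)


class TestHarmonicFits:
    def test_self_fit_recovers_harmonic(self):
        kb, r0 = 750.0, 2.34
        fit = fit_harmonic_bond(lambda r: 0.5 * kb * (r - r0) ** 2 + 3.0, 2.0, 2.5)
        assert fit.params.kb == pytest.approx(kb, rel=1e-6)
        assert fit.params.r0 == pytest.approx(r0, rel=1e-6)
        assert fit.rms_residual < 1e-8

    def test_coulomb_window_fit_matches_normal_equations_oracle(self):
        # like charges: the repulsive branch is convex on the bond window
        pot = lambda r: COULOMB_K * 2.0 * 2.0 / r
        fit = fit_harmonic_bond(pot, 2.0, 2.5, n=512)
        x = np.linspace(2.0, 2.5, 512)
        k_o, x0_o = harmonic_lsq_oracle(x, pot(x))
        assert fit.params.kb == pytest.approx(k_o, rel=1e-6)
        assert fit.params.r0 == pytest.approx(x0_o, rel=1e-6)

    def test_non_harmonic_window_raises(self):
        with pytest.raises(ValueError, match="curvature"):
            fit_harmonic_bond(lambda r: -(r - 2.25) ** 2, 2.0, 2.5)

    def test_attractive_coulomb_window_is_non_harmonic(self):
        # unlike charges give a concave window: flagged, not silently fitted
        pot = lambda r: COULOMB_K * 2.0 * -2.0 / r
        with pytest.raises(ValueError, match="curvature"):
            fit_harmonic_bond(pot, 2.0, 2.5)

    def test_angle_self_fit(self):
        kt, t0 = 274.022, 109.47
        curve = lambda t: 0.5 * kt * (np.deg2rad(t) - np.deg2rad(t0)) ** 2
        fit = fit_harmonic_angle(curve, (95.0, 125.0))
        assert fit.params.k_theta == pytest.approx(kt, rel=1e-6)
        assert fit.params.theta0 == pytest.approx(t0, rel=1e-6)

    def test_cosine_threebody_maps_to_2k_sin2(self):
        # U = k' (cos t - cos t0)^2 has curvature 2 k' sin^2(t0) at its minimum
        kp, t0 = 150.0, 109.47
        curve = lambda t: kp * (np.cos(np.deg2rad(t)) - np.cos(np.deg2rad(t0))) ** 2
        fit = fit_harmonic_angle(curve, (t0 - 2.0, t0 + 2.0))
        expected = 2.0 * kp * np.sin(np.deg2rad(t0)) ** 2
        assert fit.params.k_theta == pytest.approx(expected, rel=1e-3)
        assert fit.params.theta0 == pytest.approx(t0, abs=2e-2)

    def test_angle_fit_matches_oracle_on_tabulated_curve(self):
        t = np.linspace(100.0, 120.0, 800)
        u = 120.0 * (np.cos(np.deg2rad(t)) + 1.0 / 3.0) ** 2
        fit = fit_harmonic_angle((t, u), (100.0, 120.0), r_nn=3.4, n=512)
        x = np.deg2rad(np.linspace(100.0, 120.0, 512))
        k_o, x0_o = harmonic_lsq_oracle(x, np.interp(np.rad2deg(x), t, u))
        assert fit.params.k_theta == pytest.approx(k_o, rel=1e-6)
        assert fit.params.theta0 == pytest.approx(np.rad2deg(x0_o), rel=1e-6)


class TestMixing:
    def test_table1_zn_s_mixing(self, table1_ff):
        sigma, eps = lorentz_berthelot(
            table1_ff.nonbonded["Zn"], table1_ff.nonbonded["S"]
        )
        assert sigma == pytest.approx(4.043, abs=1e-6)
        assert eps == pytest.approx(np.sqrt(0.022 * 1.087), rel=1e-9)
        assert eps == pytest.approx(0.15464, abs=5e-5)

    def test_idempotent_for_identical_species(self, table1_ff):
        zn = table1_ff.nonbonded["Zn"]
        sigma, eps = lorentz_berthelot(zn, zn)
        assert sigma == zn.sigma
        assert eps == pytest.approx(zn.epsilon)

    def test_special_pair_overrides_mixing(self, table1_ff):
        sigma, eps = table1_ff.lj_pair("Zn", "OC")
        assert (sigma, eps) == (1.75, 86.0)
        sigma_s, eps_s = table1_ff.lj_pair("S", "OC")
        assert (sigma_s, eps_s) == (5.8, 0.01)

    def test_special_pairs_symmetric_under_key_swap(self, table1_ff):
        assert table1_ff.lj_pair("OC", "Zn") == table1_ff.lj_pair("Zn", "OC")


def _two_particles(species, r, q=None, bonds=None):
    return NanoStructure(
        species=np.array(species, dtype=object),
        positions=np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
        charges=np.zeros(2) if q is None else np.array(q, dtype=float),
        box=np.full(3, 200.0),
        periodic=np.zeros(3, dtype=bool),
        bonds=np.empty((0, 2), dtype=int) if bonds is None else np.array(bonds),
    )


@pytest.fixture()
def toy_ff():
    """Minimal non-periodic model: one bonded class, bland LJ, full charges."""
    return ForceFieldModel(
        bonds={("A", "B"): BondedParams(kb=100.0, r0=2.0)},
        angles={("B", "A", "B"): BondedParams(k_theta=50.0, theta0=109.47)},
        nonbonded={
            "A": SpeciesNonbonded(q=2.0, sigma=3.0, epsilon=0.0),
            "B": SpeciesNonbonded(q=-2.0, sigma=3.0, epsilon=0.0),
        },
        coulomb_scheme="all-pairs",
        cutoff=50.0,
    )


class TestEnergyForces:
    def test_bonded_dimer_at_r0_has_zero_energy_and_force(self, toy_ff):
        dimer = _two_particles(["A", "B"], 2.0, q=[2.0, -2.0], bonds=[[0, 1]])
        e, f, br = evaluate_energy_forces(dimer, toy_ff)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f).max() < 1e-12
        assert br["coulomb"] == 0.0  # excluded between bonded atoms

    def test_two_unbonded_charges_at_1nm(self, toy_ff):
        pair = _two_particles(["A", "B"], 10.0, q=[2.0, -2.0])
        e, _, br = evaluate_energy_forces(pair, toy_ff)
        assert br["lj"] == 0.0
        assert e == pytest.approx(-555.7418, abs=1e-3)

    def test_forces_match_central_differences(self, rng):
        ff = ForceFieldModel(
            bonds={("A", "B"): BondedParams(kb=300.0, r0=2.3)},
            angles={
                ("B", "A", "B"): BondedParams(k_theta=80.0, theta0=109.47),
                ("A", "B", "A"): BondedParams(k_theta=80.0, theta0=109.47),
            },
            nonbonded={
                "A": SpeciesNonbonded(q=1.0, sigma=3.0, epsilon=0.4),
                "B": SpeciesNonbonded(q=-1.0, sigma=3.4, epsilon=0.6),
            },
            coulomb_scheme="all-pairs",
            cutoff=50.0,
        )
        pos = np.array(
            [[0, 0, 0], [2.3, 0, 0], [0, 2.3, 0], [0, 0, 2.3], [2.3, 2.3, 2.3]],
            dtype=float,
        ) + rng.normal(scale=0.05, size=(5, 3))
        st = NanoStructure(
            species=np.array(["A", "B", "B", "B", "A"], dtype=object),
            positions=pos,
            charges=np.array([1.0, -1.0, -1.0, -1.0, 1.0]),
            box=np.full(3, 100.0),
            periodic=np.zeros(3, dtype=bool),
            bonds=np.array([[0, 1], [0, 2], [0, 3], [1, 4]]),
            angles=np.array([[1, 0, 2], [1, 0, 3], [2, 0, 3], [0, 1, 4]]),
        )
        _, forces, _ = evaluate_energy_forces(st, ff)
        h = 1e-5
        for atom in range(st.n_atoms):
            for ax in range(3):
                for sign, store in ((1, "p"), (-1, "m")):
                    stx = st.copy()
                    stx.positions[atom, ax] += sign * h
                    e, _, _ = evaluate_energy_forces(stx, ff)
                    if store == "p":
                        ep = e
                    else:
                        em = e
                num = -(ep - em) / (2 * h)
                assert num == pytest.approx(forces[atom, ax], rel=1e-4, abs=1e-6)

    def test_net_force_zero_on_isolated_system(self, rng):
        ff = zns_table1_forcefield(coulomb_scheme="all-pairs")
        pos = rng.uniform(0, 8, size=(6, 3))
        st = NanoStructure(
            species=np.array(["Zn", "S"] * 3, dtype=object),
            positions=pos,
            charges=np.array([2.0, -2.0] * 3),
            box=np.full(3, 100.0),
            periodic=np.zeros(3, dtype=bool),
        )
        _, forces, _ = evaluate_energy_forces(st, ff)
        assert np.abs(forces.sum(axis=0)).max() < 1e-8

    def test_energy_invariant_under_rigid_rotation(self, rng):
        from scipy.spatial.transform import Rotation

        ff = zns_table1_forcefield(coulomb_scheme="all-pairs")
        pos = rng.uniform(0, 8, size=(6, 3))
        st = NanoStructure(
            species=np.array(["Zn", "S"] * 3, dtype=object),
            positions=pos,
            charges=np.array([2.0, -2.0] * 3),
            box=np.full(3, 100.0),
            periodic=np.zeros(3, dtype=bool),
        )
        e0, _, _ = evaluate_energy_forces(st, ff)
        rot = Rotation.random(random_state=7).as_matrix()
        st.positions = pos @ rot.T
        e1, _, _ = evaluate_energy_forces(st, ff)
        assert e1 == pytest.approx(e0, rel=1e-8)

    def test_overlapping_atoms_raise(self, toy_ff):
        pair = _two_particles(["A", "B"], 1e-9, q=[2.0, -2.0])
        with pytest.raises(ValueError, match="overlap"):
            evaluate_energy_forces(pair, toy_ff)

    def test_unparameterized_species_raise(self, toy_ff):
        pair = _two_particles(["A", "Q"], 3.0)
        with pytest.raises(ValueError, match="species"):
            evaluate_energy_forces(pair, toy_ff)

    def test_angle_end_exclusion_rule(self):
        # linear B-A-B with 1-3 exclusion: coulomb term loses the B..B pair
        st = NanoStructure(
            species=np.array(["A", "B", "B"], dtype=object),
            positions=np.array([[0, 0, 0], [2, 0, 0], [-2, 0, 0]], dtype=float),
            charges=np.array([2.0, -1.0, -1.0]),
            box=np.full(3, 100.0),
            periodic=np.zeros(3, dtype=bool),
            bonds=np.array([[0, 1], [0, 2]]),
            angles=np.array([[1, 0, 2]]),
        )
        nb = {
            "A": SpeciesNonbonded(q=2.0, sigma=3.0, epsilon=0.0),
            "B": SpeciesNonbonded(q=-1.0, sigma=3.0, epsilon=0.0),
        }
        common = dict(
            bonds={("A", "B"): BondedParams(kb=0.0, r0=2.0)},
            angles={("B", "A", "B"): BondedParams(k_theta=0.0, theta0=179.0)},
            nonbonded=nb, coulomb_scheme="all-pairs", cutoff=50.0,
        )
        e_12, _, br_12 = evaluate_energy_forces(
            st, ForceFieldModel(exclusion_rule="bonded-pairs", **common)
        )
        e_13, _, br_13 = evaluate_energy_forces(
            st, ForceFieldModel(exclusion_rule="bonded-pairs-and-angle-ends", **common)
        )
        assert br_12["coulomb"] == pytest.approx(COULOMB_K * 1.0 / 4.0)
        assert br_13["coulomb"] == 0.0
        assert e_12 != e_13


class TestSerialization:
    def test_forcefield_table_roundtrip(self, table1_ff, tmp_path):
        path = tmp_path / "zns.ff.yaml"
        save_forcefield(table1_ff, path)
        back = load_forcefield(path)
        assert back.bonds == table1_ff.bonds
        assert back.angles == table1_ff.angles
        assert back.nonbonded == table1_ff.nonbonded
        assert back.special_pairs == table1_ff.special_pairs
        assert back.cutoff == table1_ff.cutoff
        assert back.exclusion_rule == table1_ff.exclusion_rule

    def test_invalid_theta0_rejected(self):
        with pytest.raises(ValueError):
            BondedParams(k_theta=1.0, theta0=181.0)
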
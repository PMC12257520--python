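"""Force-field correctness: gradients, symmetries, closed forms."""

import numpy as np
import pytest

from isopimd.constants import COULOMB
from isopimd.forcefield import (
    BeadConfiguration,
    ForceFieldConstants,
    IsotopeSystem,
    SimulationCell,
    intermolecular_energy_forces,
    intramolecular_energy_forces,
    load_constants,
    m_site_positions,
    monomer_equilibrium_geometry,
    monomer_normal_modes,
    reaction_field_pair_energy,
    redistribute_m_forces,
    total_potential,
)


@pytest.fixture(scope="module")
def ff():
    return load_constants()


def _random_cluster(rng, n_mol=3, nb=2, jitter=0.004):
    ff = load_constants()
    pos = monomer_equilibrium_geometry(ff).repeat(nb, axis=2)
    shifts = [[0, 0, 0], [0.32, 0, 0], [0.0, 0.31, 0.05], [0.3, 0.3, 0.3]]
    pos = np.concatenate([pos + shifts[i] for i in range(n_mol)], axis=0)
    return pos + rng.normal(0, jitter, pos.shape)


class TestIntramolecular:
    def test_equilibrium_monomer_is_minimum(self, ff):
        pos = monomer_equilibrium_geometry(ff)
        e, f, _ = intramolecular_energy_forces(pos, ff)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f).max() == pytest.approx(0.0, abs=1e-9)

    def test_stretch_harmonic_limit(self, ff):
        """For small bond elongation delta, E -> D_r alpha^2 delta^2."""
        for delta in (1e-4, 5e-5, 2.5e-5):
            pos = monomer_equilibrium_geometry(ff)
            bond = pos[0, 1, 0] / np.linalg.norm(pos[0, 1, 0])
            pos[0, 1, 0] += delta * bond
            e, _, _ = intramolecular_energy_forces(pos, ff)
            expected = ff.D_r * ff.alpha_r**2 * delta**2
            assert e[0] == pytest.approx(expected, rel=3 * ff.alpha_r * delta)

    def test_forces_match_finite_differences(self, ff, rng):
        pos = _random_cluster(rng, n_mol=1, nb=3)
        _, f, _ = intramolecular_energy_forces(pos, ff)
        h = 1e-6
        for idx in [(0, 0, 0, 0), (0, 1, 1, 2), (0, 2, 2, 1)]:
            pp, pm = pos.copy(), pos.copy()
            pp[idx] += h
            pm[idx] -= h
            ep, _, _ = intramolecular_energy_forces(pp, ff)
            em, _, _ = intramolecular_energy_forces(pm, ff)
            fd = -(ep.sum() - em.sum()) / (2 * h)
            assert fd == pytest.approx(f[idx], rel=1e-6, abs=1e-6)

    def test_rejects_nonfinite_and_degenerate(self, ff):
        pos = monomer_equilibrium_geometry(ff)
        bad = pos.copy()
        bad[0, 1, 0, 0] = np.nan
        with pytest.raises(ValueError):
            intramolecular_energy_forces(bad, ff)
        collapsed = pos.copy()
        collapsed[0, 1, 0] = collapsed[0, 0, 0]
        with pytest.raises(ValueError):
            intramolecular_energy_forces(collapsed, ff)


class TestMSite:
    def test_on_bisector_for_symmetric_molecule(self, ff):
        pos = monomer_equilibrium_geometry(ff)
        m = m_site_positions(pos, ff)[0, 0]
        bisector = (pos[0, 1, 0] + pos[0, 2, 0]) / 2
        bisector /= np.linalg.norm(bisector)
        assert np.cross(m, bisector) == pytest.approx(np.zeros(3), abs=1e-12)

    def test_weight_one_collapses_onto_oxygen(self, ff):
        from dataclasses import replace

        ff1 = replace(ff, m_site_weight=1.0)
        pos = monomer_equilibrium_geometry(ff1)
        assert m_site_positions(pos, ff1)[0, 0] == pytest.approx(pos[0, 0, 0])

    def test_redistribution_conserves_force_and_torque(self, ff, rng):
        pos = _random_cluster(rng, n_mol=1, nb=1)
        f_m = rng.normal(size=(1, 1, 3))
        forces = np.zeros_like(pos)
        out = redistribute_m_forces(forces, f_m, ff)
        # total force conserved
        assert out.sum(axis=(0, 1, 2)) == pytest.approx(f_m.sum(axis=(0, 1)))
        # torque about origin conserved: sum r_i x F_i == r_M x F_M
        m = m_site_positions(pos, ff)[0, 0]
        torque = np.cross(pos[0, :, 0, :], out[0, :, 0, :]).sum(axis=0)
        assert torque == pytest.approx(np.cross(m, f_m[0, 0]), abs=1e-12)


class TestIntermolecular:
    def test_zero_beyond_cutoff(self, ff):
        pos = monomer_equilibrium_geometry(ff)
        far = np.concatenate([pos, pos + [1.3, 0, 0]], axis=0)
        cell = SimulationCell(5.0, periodic=False)
        e, f, _ = intermolecular_energy_forces(far, ff, cell)
        assert e == pytest.approx(0.0, abs=1e-14)
        assert np.abs(f).max() == 0.0

    def test_reaction_field_kernel_hand_evaluated(self, ff):
        r = 0.47
        k_rf = (ff.eps_rf - 1) / ((2 * ff.eps_rf + 1) * ff.r_c**3)
        c_rf = 1 / ff.r_c + k_rf * ff.r_c**2
        expected = COULOMB * ff.q_H * ff.q_H * (1 / r + k_rf * r**2 - c_rf)
        assert reaction_field_pair_energy(ff.q_H, ff.q_H, r, ff) == pytest.approx(expected)
        assert reaction_field_pair_energy(1.0, 1.0, ff.r_c + 0.01, ff) == 0.0

    def test_pair_energy_decomposes_into_site_kernels(self, ff):
        """Dimer energy = LJ(O-O) + sum of RF kernels over charge sites."""
        pos = monomer_equilibrium_geometry(ff)
        dimer = np.concatenate([pos, pos + [0.30, 0.02, 0.01]], axis=0)
        cell = SimulationCell(5.0, periodic=False)
        e, _, _ = intermolecular_energy_forces(dimer, ff, cell)
        msites = m_site_positions(dimer, ff)[:, 0, :]
        charges = [
            (dimer[0, 1, 0], ff.q_H), (dimer[0, 2, 0], ff.q_H), (msites[0], ff.q_M)]
        charges_j = [
            (dimer[1, 1, 0], ff.q_H), (dimer[1, 2, 0], ff.q_H), (msites[1], ff.q_M)]
        expected = 0.0
        r_oo = np.linalg.norm(dimer[1, 0, 0] - dimer[0, 0, 0])
        sr6 = (ff.sigma / r_oo) ** 6
        expected += 4 * ff.epsilon * (sr6**2 - sr6)
        for pi, qi in charges:
            for pj, qj in charges_j:
                expected += reaction_field_pair_energy(qi, qj, np.linalg.norm(pj - pi), ff)
        assert e[0] == pytest.approx(expected, rel=1e-12)

    def test_lj_closed_form_points(self):
        """LJ contribution is 0 at r = sigma and -epsilon at 2^(1/6) sigma."""
        ff0 = load_constants(q_H=0.0, q_M=0.0)  # charges off isolates LJ
        cell = SimulationCell(5.0, periodic=False)
        pos = monomer_equilibrium_geometry(ff0)
        for r, expected in ((ff0.sigma, 0.0), (2 ** (1 / 6) * ff0.sigma, -ff0.epsilon)):
            dimer = np.concatenate([pos, pos + [r, 0, 0]], axis=0)
            # rotate second molecule's hydrogens far from overlap
            e, _, _ = intermolecular_energy_forces(dimer, ff0, cell)
            assert e[0] == pytest.approx(expected, abs=1e-12)

    def test_overlapping_charges_rejected(self, ff):
        pos = monomer_equilibrium_geometry(ff)
        clash = np.concatenate([pos, pos + [1e-6, 0, 0]], axis=0)
        cell = SimulationCell(5.0, periodic=False)
        with pytest.raises(ValueError, match="overlap"):
            intermolecular_energy_forces(clash, ff, cell)

    def test_small_periodic_cell_rejected(self, ff):
        pos = monomer_equilibrium_geometry(ff)
        two = np.concatenate([pos, pos + [0.4, 0, 0]], axis=0)
        with pytest.raises(ValueError, match="2 r_c"):
            intermolecular_energy_forces(two, ff, SimulationCell(1.0))


class TestTotalPotential:
    def test_isolated_monomer_equals_intramolecular(self, ff, rng):
        pos = _random_cluster(rng, n_mol=1, nb=2)
        e1, f1, _ = intramolecular_energy_forces(pos, ff)
        e2, f2, _ = total_potential(pos, ff)
        assert e2 == pytest.approx(e1)
        assert f2 == pytest.approx(f1)

    def test_forces_match_finite_differences_full(self, ff, rng):
        pos = _random_cluster(rng, n_mol=3, nb=2)
        cell = SimulationCell(2.5)
        _, f, _ = total_potential(pos, ff, cell)
        h = 1e-6
        worst = 0.0
        for idx in [(0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 0, 2), (1, 0, 1, 0)]:
            pp, pm = pos.copy(), pos.copy()
            pp[idx] += h
            pm[idx] -= h
            ep, _, _ = total_potential(pp, ff, cell)
            em, _, _ = total_potential(pm, ff, cell)
            fd = -(ep.sum() - em.sum()) / (2 * h)
            worst = max(worst, abs(fd - f[idx]) / max(1.0, abs(f[idx])))
        assert worst < 1e-6

    def test_net_force_vanishes(self, ff, rng):
        pos = _random_cluster(rng, n_mol=4, nb=2)
        cell = SimulationCell(2.5)
        _, f, _ = total_potential(pos, ff, cell)
        scale = np.abs(f).max()
        assert np.abs(f.sum(axis=(0, 1, 2))).max() / scale < 1e-10

    def test_translation_invariance(self, ff, rng):
        pos = _random_cluster(rng, n_mol=3, nb=2)
        cell = SimulationCell(4.0, periodic=False)
        e1, _, _ = total_potential(pos, ff, cell)
        e2, _, _ = total_potential(pos + np.array([0.37, -0.21, 0.11]), ff, cell)
        assert e2 == pytest.approx(e1, rel=1e-12)

    def test_rotation_invariance(self, ff, rng):
        from scipy.spatial.transform import Rotation

        pos = _random_cluster(rng, n_mol=2, nb=2)
        cell = SimulationCell(4.0, periodic=False)
        e1, _, _ = total_potential(pos, ff, cell)
        rot = Rotation.random(rng=np.random.default_rng(5)).as_matrix()
        e2, _, _ = total_potential(pos @ rot.T, ff, cell)
        assert e2 == pytest.approx(e1, rel=1e-10)

    def test_bead_slices_identical_when_coincident(self, ff, rng):
        pos = _random_cluster(rng, n_mol=3, nb=1)
        pos = pos.repeat(4, axis=2)
        cell = SimulationCell(2.5)
        e, _, _ = total_potential(pos, ff, cell)
        assert np.ptp(e) == pytest.approx(0.0, abs=1e-10)

    def test_isotope_substitution_leaves_potential_unchanged(self, ff, rng):
        """Masses enter only the dynamics: energy at fixed coordinates is
        composition independent."""
        pos = _random_cluster(rng, n_mol=2, nb=2)
        cell = SimulationCell(2.5)
        e_ref, f_ref, _ = total_potential(pos, ff, cell)
        for comp in ("HDO", "D2O", "T2O"):
            IsotopeSystem(2, comp)  # different masses, same constants
            e, f, _ = total_potential(pos, ff, cell)
            assert e == pytest.approx(e_ref)
            assert f == pytest.approx(f_ref)


class TestConstants:
    def test_charge_neutrality_enforced(self, ff):
        with pytest.raises(ValueError, match="neutrality"):
            load_constants(q_M=-1.0)

    def test_hdo_has_one_h_and_one_d(self):
        sys_hdo = IsotopeSystem(4, "HDO")
        m = sys_hdo.site_masses
        assert sorted(np.round(m[1:], 4)) == [1.0078, 2.0141]
        assert sys_hdo.site_species() == ["O", "H", "D"]

    def test_monomer_stretch_ratio_tracks_reduced_mass(self):
        """Harmonic stretch frequencies scale as 1/sqrt(reduced mass)."""
        ff = load_constants()
        m_o, m_h, m_d = 15.9949, 1.00783, 2.01410
        w_h = monomer_normal_modes(ff, [m_o, m_h, m_h])
        w_d = monomer_normal_modes(ff, [m_o, m_d, m_d])
        mu_h = m_o * m_h / (m_o + m_h)
        mu_d = m_o * m_d / (m_o + m_d)
        expected = np.sqrt(mu_d / mu_h)
        assert w_h[1] / w_d[1] == pytest.approx(expected, rel=0.01)
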
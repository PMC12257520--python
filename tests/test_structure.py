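"""Structure operators: RDF, order parameters, hydrogen bonds, gyration."""

import numpy as np
import pytest

from isopimd.constants import KB
from isopimd.fixtures import (
    make_dimer,
    make_tetrahedral_lattice,
    sample_free_ring_polymer,
)
from isopimd.ringpolymer import free_rg2_closed_form
from isopimd.structure import (
    HydrogenBondCriteria,
    detect_hbonds,
    detect_hbonds_bruteforce,
    dfs_metric,
    gyration_analysis,
    hb_energy,
    hb_geometry_stats,
    rdf,
    tetrahedral_q,
)


class TestRDF:
    def test_ideal_gas_is_unity(self):
        rng = np.random.default_rng(0)
        n_mol, L = 128, 3.0
        frames = rng.uniform(0, L, (8, n_mol, 1, 1, 3)).repeat(3, axis=2)
        # spread the three "sites" so only O-O (site 0) is used
        r, g = rdf(frames, L, ("O", "O"), ["O", "H", "H"], n_bins=30)
        sel = r > 0.3
        assert np.abs(g[sel] - 1.0).max() < 0.25
        assert g[sel].mean() == pytest.approx(1.0, abs=0.05)

    def test_two_fixed_atoms_hand_normalized_spike(self):
        """Two molecules at fixed separation: g(r) carries all pair weight
        in one bin, equal to V / (shell volume) for a single pair."""
        L = 4.0
        d = 0.93  # off any bin edge
        frames = np.zeros((1, 2, 3, 1, 3))
        frames[0, 1, :, 0, 0] = d
        n_bins = 40
        r, g = rdf(frames, L, ("O", "O"), ["O", "H", "H"], n_bins=n_bins, r_max=2.0)
        edges = np.linspace(0, 2.0, n_bins + 1)
        k = np.searchsorted(edges, d) - 1
        shell = 4 / 3 * np.pi * (edges[k + 1] ** 3 - edges[k] ** 3)
        expected = L**3 / shell
        assert g[k] == pytest.approx(expected, rel=1e-10)
        assert np.count_nonzero(g) == 1

    def test_rmax_beyond_half_box_rejected(self):
        frames = np.zeros((1, 2, 3, 1, 3))
        with pytest.raises(ValueError, match="half the box"):
            rdf(frames, 2.0, ("O", "O"), ["O", "H", "H"], r_max=1.5)

    def test_hdo_isotope_channels_select_distinct_sites(self):
        rng = np.random.default_rng(4)
        frames = rng.uniform(0, 3.0, (2, 16, 3, 2, 3))
        species = ["O", "H", "D"]
        r, g_oh = rdf(frames, 3.0, ("O", "H"), species, n_bins=20)
        _, g_od = rdf(frames, 3.0, ("O", "D"), species, n_bins=20)
        _, g_ox = rdf(frames, 3.0, ("O", "X"), species, n_bins=20)
        assert not np.allclose(g_oh, g_od)  # different random sites
        # OX channel pools both isotopes
        assert g_ox == pytest.approx(0.5 * (g_oh + g_od), rel=1e-8)


class TestTetrahedralOrder:
    def test_perfect_lattice_gives_unity(self):
        config, cell = make_tetrahedral_lattice(2)
        q, skipped = tetrahedral_q(config.positions[:, 0, 0, :], cell.length)
        assert q == pytest.approx(1.0, abs=1e-10)
        assert skipped == 0

    def test_random_gas_near_zero(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 4.0, (400, 3))
        q, _ = tetrahedral_q(pts, 4.0)
        assert abs(q) < 0.05

    def test_single_perturbed_neighbor_hand_computed(self):
        """Rotating one tetrahedral neighbour by a known angle changes q by
        the closed-form amount."""
        dirs = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / np.sqrt(3)
        r0 = 0.28
        center = np.array([5.0, 5.0, 5.0])
        eps = 0.2  # radians, rotate neighbour 0 in the plane of dirs 0,1
        axis = np.cross(dirs[0], dirs[1])
        axis /= np.linalg.norm(axis)

        def rot(v, ax, ang):
            return (
                v * np.cos(ang)
                + np.cross(ax, v) * np.sin(ang)
                + ax * np.dot(ax, v) * (1 - np.cos(ang))
            )

        neigh = dirs.copy()
        neigh[0] = rot(dirs[0], axis, eps)
        pts = np.vstack([center, center + r0 * neigh])
        # add a distant shell so every neighbour list is well defined
        far = center + 2.0 * np.vstack([np.eye(3), -np.eye(3)])
        pts = np.vstack([pts, far])
        q, _ = tetrahedral_q(pts, None)
        # hand-computed q of the central molecule
        vecs = neigh
        s = 0.0
        for a in range(3):
            for b in range(a + 1, 4):
                s += (np.dot(vecs[a], vecs[b]) + 1 / 3) ** 2
        q_central = 1 - 3 / 8 * s
        # peripheral molecules lack 4 good neighbours; central dominates
        assert q_central < 1.0
        # evaluate q for the central point only via a restricted cloud
        q_only, _ = tetrahedral_q(pts[:5], None)
        assert q_only < 1.0


class TestShellSeparation:
    def test_constructed_lattice_exact_gap(self):
        center = np.zeros(3)
        dirs = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / np.sqrt(3)
        first = center + 0.28 * dirs
        second = center + 0.45 * np.vstack([np.eye(3), -np.eye(3)])
        pts = np.vstack([center[None], first, second])
        d, _ = dfs_metric(pts, None)
        # only the central molecule has >= 5 neighbours... others too, but
        # the central one has gap 0.45 - 0.28
        gaps = []
        for i in range(len(pts)):
            r = np.sort(np.linalg.norm(pts - pts[i], axis=1))
            r = r[r > 0]
            if len(r) >= 5:
                gaps.append(r[4] - r[3])
        assert d == pytest.approx(np.mean(gaps), rel=1e-12)

    def test_equidistant_neighbors_give_zero_gap(self):
        center = np.zeros(3)
        shell = 0.3 * np.vstack([np.eye(3), -np.eye(3)])  # six equidistant
        pts = np.vstack([center[None], shell])
        d_all, _ = dfs_metric(pts, None)
        # for the central point the 4th and 5th neighbours are equidistant,
        # so its contribution to the mean gap is exactly zero
        r = np.sort(np.linalg.norm(pts[1:] - center, axis=1))
        assert r[4] - r[3] == pytest.approx(0.0, abs=1e-14)

    def test_interstitial_reduces_separation(self):
        center = np.zeros(3)
        dirs = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / np.sqrt(3)
        first = center + 0.28 * dirs
        second = center + 0.45 * np.vstack([np.eye(3), -np.eye(3)])
        pts0 = np.vstack([center[None], first, second])
        base_gap = np.sort(np.linalg.norm(pts0[1:] - center, axis=1))
        base = base_gap[4] - base_gap[3]
        interstitial = center + np.array([0.0, 0.0, 0.36])
        pts1 = np.vstack([pts0, interstitial[None]])
        r1 = np.sort(np.linalg.norm(pts1[1:] - center, axis=1))
        reduced = r1[4] - r1[3]
        assert reduced < base


class TestHydrogenBonds:
    @pytest.mark.parametrize(
        "d_oo,theta,n_expected",
        [(0.34, 20.0, 1), (0.36, 5.0, 0), (0.34, 35.0, 0), (0.29, 10.0, 1)],
    )
    def test_dimer_criterion(self, d_oo, theta, n_expected):
        config = make_dimer(d_oo, theta)
        bonds = detect_hbonds(config.positions[:, :, 0, :], None)
        assert len(bonds) == n_expected
        if n_expected:
            assert tuple(bonds[0]) == (0, 1, 1)

    def test_matches_bruteforce_oracle_on_random_frames(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            frame = np.zeros((16, 3, 3))
            frame[:, 0, :] = rng.uniform(0, 1.2, (16, 3))
            for s in (1, 2):
                direction = rng.normal(size=(16, 3))
                direction /= np.linalg.norm(direction, axis=1, keepdims=True)
                frame[:, s, :] = frame[:, 0, :] + 0.096 * direction
            fast = detect_hbonds(frame, 1.2)
            brute = detect_hbonds_bruteforce(frame, 1.2)
            assert sorted(map(tuple, fast)) == sorted(map(tuple, brute))

    def test_dimer_stats_equal_requested_geometry(self):
        config = make_dimer(0.30, 12.0)
        stats = hb_geometry_stats(config.positions, None)
        assert stats.d_oo_mean == pytest.approx(3.0, abs=1e-10)  # Angstrom
        assert stats.theta_mean == pytest.approx(12.0, abs=1e-8)
        assert stats.n_hb_per_molecule == pytest.approx(1.0)  # 2 * 1 bond / 2 mol

    def test_replica_averaging_hand_computed(self):
        """Two replicas with different constructed geometries average to the
        mean of the per-replica means."""
        c1 = make_dimer(0.30, 10.0).positions
        c2 = make_dimer(0.34, 25.0).positions
        frames = np.concatenate([c1, c2], axis=2)[None]  # (1, 2 mol, 3, 2 beads, 3)
        stats = hb_geometry_stats(frames, None)
        assert stats.d_oo_mean == pytest.approx((3.0 + 3.4) / 2, abs=1e-9)
        assert stats.theta_mean == pytest.approx((10.0 + 25.0) / 2, abs=1e-7)
        assert len(stats.per_replica_d_oo) == 2

    def test_hdo_split_by_donor_species(self):
        config = make_dimer(0.30, 12.0)
        stats = hb_geometry_stats(config.positions, None, species=["O", "H", "D"])
        assert "H" in stats.by_donor_species
        assert stats.by_donor_species["H"]["count"] == 1
        assert "D" not in stats.by_donor_species  # X1 (H site) donates here


class TestHBEnergy:
    class _Arc:
        def __init__(self, potential, n_mol, beads, cell, config):
            self.estimators = {"potential": np.asarray(potential)}
            self.n_molecules = n_mol
            self.bead_positions = beads
            self.cell_length = cell
            self.config = config

    def test_constructed_arithmetic(self):
        """E_pot - E_0 = -24 kJ/mol per molecule with n_HB = 1 bond per
        molecule pair (2 bonds per 2 molecules) gives E_HB = -24."""
        dimer = make_dimer(0.30, 5.0).positions[None]
        cfg = {"temperature": 300.0, "n_beads": 1, "composition": "H2O"}
        liquid = self._Arc([2.0 * (-20.0)], 2, dimer, None, cfg)
        mono = self._Arc([4.0], 1, None, None, cfg)
        out = hb_energy(liquid, mono)
        # E_pot/molecule = -20, E_0 = 4, n_HB = 2*1/2 = 1 -> E_HB = -24
        assert out.n_hb == pytest.approx(1.0)
        assert out.e_hb == pytest.approx(-24.0)

    def test_mismatched_runs_rejected(self):
        dimer = make_dimer(0.30, 5.0).positions[None]
        liquid = self._Arc([1.0], 2, dimer, None,
                           {"temperature": 300.0, "n_beads": 2, "composition": "H2O"})
        mono = self._Arc([1.0], 1, None, None,
                         {"temperature": 240.0, "n_beads": 2, "composition": "H2O"})
        with pytest.raises(ValueError, match="disagree"):
            hb_energy(liquid, mono)

    def test_no_bonds_signalled(self):
        apart = make_dimer(0.45, 5.0).positions[None]
        cfg = {"temperature": 300.0, "n_beads": 1, "composition": "H2O"}
        liquid = self._Arc([0.0], 2, apart, None, cfg)
        mono = self._Arc([0.0], 1, None, None, cfg)
        with pytest.raises(ValueError, match="undefined"):
            hb_energy(liquid, mono)


class TestGyration:
    def test_single_bead_gives_zero(self):
        frames = np.random.default_rng(0).normal(size=(2, 3, 3, 1, 3))
        rec = gyration_analysis(frames, ["O", "H", "H"])
        for v in rec.r_g.values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_free_ring_polymer_closed_form(self):
        nb, temp, mass = 16, 250.0, 1.00783
        samples = sample_free_ring_polymer(temp, mass, nb, 3000, seed=2)
        # embed as the X1 site of fake molecules with rigid O/X2 sites
        n = samples.shape[0]
        frames = np.zeros((1, n, 3, nb, 3))
        frames[0, :, 1, :, :] = samples + np.array([0.1, 0.0, 0.0])
        frames[0, :, 2, :, :] = np.array([0.0, 0.1, 0.0])
        rec = gyration_analysis(frames, ["O", "H", "D"])  # H selects X1 only
        expected = np.sqrt(free_rg2_closed_form(temp, mass, nb)) * 10.0
        assert rec.r_g["H"] == pytest.approx(expected, rel=0.03)

    def test_isotropic_beads_have_equal_components(self):
        rng = np.random.default_rng(5)
        nb = 32
        frames = np.zeros((1, 200, 3, nb, 3))
        frames[0, :, 1, :, :] = 0.01 * rng.normal(size=(200, nb, 3))
        frames[0, :, 1, :, :] += np.array([0.1, 0, 0])
        frames[0, :, 2, :, :] = np.array([0, 0.1, 0])
        rec = gyration_analysis(frames, ["O", "H", "H"])
        cx, cy, cz = rec.r_g2_components["H"]
        assert cy / cx == pytest.approx(1.0, abs=0.1)
        assert cz / cx == pytest.approx(1.0, abs=0.1)

    def test_components_sum_to_total_exactly(self):
        rng = np.random.default_rng(6)
        frames = rng.normal(0, 0.01, size=(2, 5, 3, 8, 3))
        frames[:, :, 1] += np.array([0.1, 0, 0])
        frames[:, :, 2] += np.array([0, 0.1, 0])
        rec = gyration_analysis(frames, ["O", "H", "H"])
        for lab in ("O", "H"):
            total = (rec.r_g[lab]) ** 2
            comp_sum = rec.r_g2_components[lab].sum()
            assert comp_sum == pytest.approx(total, rel=1e-6)


class TestCriteria:
    def test_positive_criteria_enforced(self):
        with pytest.raises(ValueError):
            HydrogenBondCriteria(d_oo_max=-1.0)
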
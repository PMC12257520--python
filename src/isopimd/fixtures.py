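"""Seed-deterministic desk-scale inputs with known statistical structure.

Every generator here stands in for one class of raw data in the study:
free ring polymers with closed-form gyration statistics, toy velocity
and dipole series with planted spectral peaks, hand-built hydrogen-bond
geometries, tetrahedral lattices (perfect-tetrahedrality reference),
ideal-gas volume samples, and synthetic D(T)/H(T)/E(T) curve families
with stated noise for fit-recovery tests.  Pipelines consume these
through the same array/archive formats as real runs.
"""

from __future__ import annotations

import numpy as np

from .constants import C_CM_PER_PS, KB, N_AVOGADRO
from .forcefield import (
    BeadConfiguration,
    ForceFieldConstants,
    IsotopeSystem,
    SimulationCell,
    load_constants,
    monomer_equilibrium_geometry,
)
from .ringpolymer import normal_mode_frequencies, normal_mode_matrix

__all__ = [
    "sample_free_ring_polymer",
    "make_tetrahedral_lattice",
    "make_dimer",
    "make_spectral_toy",
    "make_curve_family",
    "ideal_gas_volume_samples",
    "build_water_box",
]


def sample_free_ring_polymer(
    temperature: float,
    mass: float,
    n_beads: int,
    n_samples: int,
    seed: int = 0,
    dim: int = 3,
) -> np.ndarray:
    """Exact normal-mode Gaussian samples of a free ring polymer.

    Returns bead positions of shape ``(n_samples, n_beads, dim)`` with the
    centroid pinned at the origin.  Internal mode k is drawn from the
    classical Gaussian at temperature ``n_b T`` with stiffness
    ``m omega_k^2``, i.e. variance ``n_b / (beta m omega_k^2)`` per
    Cartesian component.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * temperature)
    omega = normal_mode_frequencies(n_beads, beta)
    c = normal_mode_matrix(n_beads)
    u = np.zeros((n_samples, n_beads, dim))
    if n_beads > 1:
        sigma = np.sqrt(n_beads / (beta * mass * omega[1:] ** 2))
        u[:, 1:, :] = rng.normal(size=(n_samples, n_beads - 1, dim)) * sigma[:, None]
    return np.einsum("jk,skc->sjc", c.T, u)


def make_tetrahedral_lattice(n_cells: int = 2, a: float = 0.6367):
    """Diamond-cubic oxygen lattice with hydrogens along bond directions.

    ``a`` is the conventional cubic lattice constant (nm); the default
    reproduces an ice-like O-O nearest-neighbour distance of
    ``a*sqrt(3)/4 = 0.2757`` nm.  Every oxygen sees a perfect tetrahedral
    first shell, so the tetrahedral order parameter is exactly 1.

    Returns ``(BeadConfiguration, SimulationCell)`` with ``n_b = 1``.
    """
    fcc = np.array(
        [[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]], dtype=float
    )
    basis = np.concatenate([fcc, fcc + 0.25])
    cells = np.array(
        [[i, j, k] for i in range(n_cells) for j in range(n_cells) for k in range(n_cells)],
        dtype=float,
    )
    oxygens = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    n_mol = len(oxygens)
    ff = load_constants()
    # bond directions of the diamond A/B sublattices
    dirs_a = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
    dirs_b = -dirs_a
    pos = np.zeros((n_mol, 3, 1, 3))
    per_cell = len(basis)
    for i in range(n_mol):
        sub_b = (i % per_cell) >= 4
        dirs = dirs_b if sub_b else dirs_a
        pos[i, 0, 0] = oxygens[i]
        pos[i, 1, 0] = oxygens[i] + ff.r_eq * dirs[0]
        pos[i, 2, 0] = oxygens[i] + ff.r_eq * dirs[1]
    return BeadConfiguration(pos), SimulationCell(n_cells * a)


def make_dimer(d_oo: float, theta_hoo: float, n_beads: int = 1):
    """Two-molecule configuration with exact requested HB geometry.

    ``d_oo`` in nm, ``theta_hoo`` in degrees: the angle at the donor O
    between the donor O->X1 covalent bond and the O->O vector.  The
    acceptor molecule points away from the donor.
    """
    ff = load_constants()
    th = np.deg2rad(theta_hoo)
    hoh = ff.theta_eq
    pos = np.zeros((2, 3, n_beads, 3))
    # donor: O at origin, O-O axis along +x, X1 at angle theta from it
    pos[0, 0, :] = 0.0
    pos[0, 1, :] = ff.r_eq * np.array([np.cos(th), np.sin(th), 0.0])
    # X2: rotate X1 direction by the equilibrium HOH angle in-plane
    pos[0, 2, :] = ff.r_eq * np.array([np.cos(th - hoh), np.sin(th - hoh), 0.0])
    # acceptor: O at distance d_oo on +x, hydrogens pointing downstream
    acc_o = np.array([d_oo, 0.0, 0.0])
    pos[1, 0, :] = acc_o
    for s, sign in ((1, 1.0), (2, -1.0)):
        direction = np.array(
            [np.cos(hoh / 2.0), 0.0, sign * np.sin(hoh / 2.0)]
        )
        pos[1, s, :] = acc_o + ff.r_eq * direction
    return BeadConfiguration(pos)


def make_spectral_toy(
    frequencies_cm: np.ndarray,
    amplitudes: np.ndarray,
    dt: float,
    n_steps: int,
    seed: int = 0,
    noise: float = 0.0,
    phases: np.ndarray | None = None,
) -> np.ndarray:
    """Superposed-cosine velocity/dipole series with planted peaks.

    ``frequencies_cm`` are wavenumbers (cm^-1); ``dt`` is the sampling
    interval (ps).  Refuses frequencies beyond the Nyquist limit
    ``1 / (2 dt c)``.
    """
    freqs = np.atleast_1d(np.asarray(frequencies_cm, dtype=float))
    amps = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    nyquist_cm = 1.0 / (2.0 * dt * C_CM_PER_PS)
    if np.any(freqs >= nyquist_cm):
        raise ValueError(
            f"planted frequency exceeds the Nyquist limit {nyquist_cm:.0f} cm^-1"
        )
    rng = np.random.default_rng(seed)
    if phases is None:
        phases = np.zeros_like(freqs)
    t = np.arange(n_steps) * dt
    omega = 2.0 * np.pi * freqs * C_CM_PER_PS  # rad/ps
    series = np.sum(
        amps[:, None] * np.cos(omega[:, None] * t[None, :] + phases[:, None]), axis=0
    )
    if noise > 0:
        series = series + rng.normal(0.0, noise, size=n_steps)
    return series


def make_curve_family(
    model: str,
    params: dict,
    t_grid: np.ndarray,
    noise: float = 0.0,
    seed: int = 0,
):
    """Synthetic observable tables for fit-recovery tests.

    model='arrhenius': D = D0 exp(-E_A / k_B T), params D0 (A^2/ps), E_A
    (kJ/mol); model='mct': D = D1 (T - T_MCT)^gamma; model='poly4':
    y = sum c_k T^k with params['coeffs'].  Multiplicative noise for the
    diffusion models, additive for the polynomial.  Returns a pandas
    DataFrame with columns T, y, y_err.
    """
    import pandas as pd

    t = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    if model == "arrhenius":
        y = params["D0"] * np.exp(-params["E_A"] / (KB * t))
        err = noise * y
        y = y * (1.0 + rng.normal(0.0, noise, size=t.shape)) if noise > 0 else y
    elif model == "mct":
        y = params["D1"] * (t - params["T_MCT"]) ** params["gamma"]
        err = noise * y
        y = y * (1.0 + rng.normal(0.0, noise, size=t.shape)) if noise > 0 else y
    elif model == "poly4":
        coeffs = np.asarray(params["coeffs"], dtype=float)
        y = sum(c * t**k for k, c in enumerate(coeffs))
        err = np.full_like(t, noise)
        y = y + rng.normal(0.0, noise, size=t.shape) if noise > 0 else y
    else:
        raise ValueError(f"unknown model {model!r}")
    return pd.DataFrame({"T": t, "y": y, "y_err": err})


def ideal_gas_volume_samples(
    n_molecules: int,
    pressure_mpa: float,
    temperature: float,
    n_samples: int,
    seed: int = 0,
) -> np.ndarray:
    """Exact NPT ideal-gas volume samples (nm^3): Gamma(N+1, k_B T / P)."""
    rng = np.random.default_rng(seed)
    # k_B T in kJ/mol, P in MPa -> V in nm^3
    scale = KB * temperature * (1e24 / N_AVOGADRO) / pressure_mpa
    return rng.gamma(shape=n_molecules + 1, scale=scale, size=n_samples)


def build_water_box(
    system: IsotopeSystem,
    molar_volume: float,
    n_beads: int,
    seed: int = 0,
):
    """Lattice-packed water box at the requested molar volume (cm^3/mol).

    Molecules sit on a simple-cubic lattice with random orientations;
    all beads start coincident (classical collapse) and spread during
    thermalization.  Returns ``(BeadConfiguration, SimulationCell)``.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    n = system.n_molecules
    vol_nm3 = n * molar_volume / N_AVOGADRO * 1e21
    length = vol_nm3 ** (1.0 / 3.0)
    n_side = int(np.ceil(n ** (1.0 / 3.0)))
    spacing = length / n_side
    mono = monomer_equilibrium_geometry(load_constants())[0, :, 0, :]  # (3, 3)
    mono = mono - mono[0]
    pos = np.zeros((n, 3, n_beads, 3))
    idx = 0
    for i in range(n_side):
        for j in range(n_side):
            for k in range(n_side):
                if idx >= n:
                    break
                center = (np.array([i, j, k]) + 0.5) * spacing
                rot = Rotation.random(rng=rng).as_matrix()
                sites = center + mono @ rot.T
                pos[idx, :, :, :] = sites[:, None, :]
                idx += 1
    return BeadConfiguration(pos), SimulationCell(length)
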
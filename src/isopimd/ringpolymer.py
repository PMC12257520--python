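"""Ring-polymer normal modes and closed-form reference results.

The discretized path integral maps each quantum particle onto a cyclic
chain of ``n_b`` beads coupled by harmonic springs with frequency
``omega_n = n_b / (beta * hbar)``; the chain is sampled at the elevated
temperature ``n_b * T``.  The orthonormal normal-mode transform
diagonalizes the spring coupling; mode 0 is the centroid and mode k has
frequency ``2 * omega_n * sin(k * pi / n_b)``.

This module also carries the analytic results used as oracles throughout
the test suite: the free ring-polymer squared gyration radius (both as a
closed form and by brute-force normal-mode summation) and the exact
finite-bead energy of a harmonic oscillator.
"""

from __future__ import annotations

import numpy as np

from .constants import HBAR, KB

__all__ = [
    "normal_mode_matrix",
    "normal_mode_frequencies",
    "spring_frequency",
    "to_normal_modes",
    "from_normal_modes",
    "free_rg2_closed_form",
    "free_rg2_bruteforce",
    "ho_energy_classical",
    "ho_energy_quantum",
    "ho_energy_finite_beads",
]


def spring_frequency(n_beads: int, beta: float) -> float:
    """Inter-bead spring frequency omega_n = n_b/(beta hbar), rad/ps."""
    return n_beads / (beta * HBAR)


def normal_mode_matrix(n_beads: int) -> np.ndarray:
    """Orthonormal transform C with u_k = sum_j C[k, j] x_j; row 0 = centroid."""
    n = n_beads
    c = np.empty((n, n))
    j = np.arange(n)
    c[0] = np.sqrt(1.0 / n)
    for k in range(1, (n - 1) // 2 + 1):
        c[k] = np.sqrt(2.0 / n) * np.cos(2.0 * np.pi * k * j / n)
    if n % 2 == 0:
        c[n // 2] = np.sqrt(1.0 / n) * (-1.0) ** j
    for k in range(n // 2 + 1, n):
        c[k] = np.sqrt(2.0 / n) * np.sin(2.0 * np.pi * k * j / n)
    return c


def normal_mode_frequencies(n_beads: int, beta: float) -> np.ndarray:
    """Frequencies of the rows of :func:`normal_mode_matrix`, rad/ps."""
    k = np.arange(n_beads)
    return 2.0 * spring_frequency(n_beads, beta) * np.sin(np.pi * k / n_beads)


def to_normal_modes(x: np.ndarray, c: np.ndarray, axis: int = -2) -> np.ndarray:
    """Apply the transform along the bead axis (default: second-to-last)."""
    xm = np.moveaxis(np.asarray(x), axis, 0)
    return np.moveaxis(np.tensordot(c, xm, axes=(1, 0)), 0, axis)


def from_normal_modes(u: np.ndarray, c: np.ndarray, axis: int = -2) -> np.ndarray:
    """Inverse of :func:`to_normal_modes` (transpose of the orthogonal map)."""
    return to_normal_modes(u, c.T, axis=axis)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def free_rg2_closed_form(
    temperature: float, mass: float, n_beads: int, dim: int = 3
) -> float:
    """Mean squared gyration radius of a free ring polymer, nm^2.

    Per Cartesian dimension the result is
    ``hbar^2 beta / (12 m) * (1 - 1/n_b^2)``; the returned value is
    multiplied by ``dim``.
    """
    beta = 1.0 / (KB * temperature)
    return dim * HBAR**2 * beta / (12.0 * mass) * (1.0 - 1.0 / n_beads**2)


def free_rg2_bruteforce(
    temperature: float, mass: float, n_beads: int, dim: int = 3
) -> float:
    """Same quantity by direct summation over normal modes.

    Each internal mode is a classical harmonic DOF at temperature
    ``n_b T`` with stiffness ``m omega_k^2``; its variance contributes
    ``<u_k^2>/n_b`` to R_g^2.  The mode frequencies are taken from direct
    diagonalization of the bead-coupling matrix rather than the sine
    formula, keeping this estimate independent of the transform code.
    """
    beta = 1.0 / (KB * temperature)
    omega_n = spring_frequency(n_beads, beta)
    # bead coupling (cyclic Laplacian) eigenvalues
    lap = 2.0 * np.eye(n_beads)
    for j in range(n_beads):
        lap[j, (j + 1) % n_beads] -= 1.0
        lap[j, (j - 1) % n_beads] -= 1.0
    evals = np.sort(np.linalg.eigvalsh(lap))  # eigenvalue = (omega_k/omega_n)^2
    total = 0.0
    beta_n = beta / n_beads
    for lam in evals[1:]:
        omega2 = omega_n**2 * lam
        total += 1.0 / (beta_n * mass * omega2) / n_beads
    return dim * total


def ho_energy_classical(temperature: float) -> float:
    """Classical 1-D harmonic oscillator mean energy, kJ/mol."""
    return KB * temperature


def ho_energy_quantum(temperature: float, omega: float) -> float:
    """Exact quantum 1-D harmonic oscillator mean energy, kJ/mol."""
    beta = 1.0 / (KB * temperature)
    x = 0.5 * beta * HBAR * omega
    return 0.5 * HBAR * omega / np.tanh(x)


def ho_energy_finite_beads(
    temperature: float, mass: float, omega: float, n_beads: int, dbeta: float = 1e-6
) -> float:
    """Mean energy of the n_b-bead discretized 1-D harmonic oscillator.

    Computed as -d ln Z_n / d beta with the exact Gaussian partition
    function of the bead chain: ln Z_n = -sum_k ln(beta_n hbar_eff
    Omega_k) up to beta-independent constants, with Omega_k^2 = omega_k^2
    + omega^2.  The derivative is taken by central difference, which is
    exact to O(dbeta^2) and serves as an independent oracle for the PIMD
    estimators.  Converges to the quantum result as n_b grows and to
    k_B T at n_b = 1.
    """
    beta0 = 1.0 / (KB * temperature)

    def ln_z(beta: float) -> float:
        k = np.arange(n_beads)
        omega_k = 2.0 * (n_beads / (beta * HBAR)) * np.sin(np.pi * k / n_beads)
        big = np.sqrt(omega_k**2 + omega**2)
        beta_n = beta / n_beads
        # each mode contributes -ln(beta_n Omega_k): the position Gaussian
        # gives -0.5 ln(beta_n) - ln(Omega_k), the momentum Gaussian
        # -0.5 ln(beta_n); beta-independent constants dropped
        return float(np.sum(-np.log(beta_n * big)))

    h = dbeta * beta0
    return -(ln_z(beta0 + h) - ln_z(beta0 - h)) / (2.0 * h)
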
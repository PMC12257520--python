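"""q-TIP4P/F potential energy and forces for ring-polymer bead configurations.

The model is a flexible 4-site water potential: each covalent OX bond
(X = H, D or T) carries a quartic expansion of a Morse potential, the XOX
angle a harmonic bend, oxygens interact through Lennard-Jones, and the
negative charge sits on a massless M site placed on the XOX bisector as a
fixed linear combination of the three massive sites.  Long-range
electrostatics use the reaction-field approximation with a molecular
(O-O based) cutoff.  Force-field constants are isotope independent;
isotopes differ only in their site masses, which enter the dynamics, not
the potential.

Bead configurations are arrays of shape ``(n_mol, 3, n_b, 3)`` with site
order (O, X1, X2).  In the discretized path integral, bead slice ``b`` of
one molecule interacts only with the same bead slice of other molecules;
the kernels therefore loop over slices independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from numba import njit

from .constants import COMPOSITION_MASSES, COULOMB

__all__ = [
    "ForceFieldConstants",
    "IsotopeSystem",
    "SimulationCell",
    "BeadConfiguration",
    "load_constants",
    "intramolecular_energy_forces",
    "intermolecular_energy_forces",
    "total_potential",
    "m_site_positions",
    "redistribute_m_forces",
    "reaction_field_pair_energy",
    "monomer_equilibrium_geometry",
    "monomer_normal_modes",
]


@dataclass(frozen=True)
class ForceFieldConstants:
    """Numeric constants of the potential, in nm / kJ mol^-1 / e / rad."""

    D_r: float
    alpha_r: float
    r_eq: float
    k_theta: float
    theta_eq: float
    epsilon: float
    sigma: float
    q_H: float
    q_M: float
    m_site_weight: float
    r_c: float = 1.0
    eps_rf: float = 78.3
    #: shift the reaction-field kernel so it is continuous (zero) at r_c
    rf_shift: bool = True
    #: shift the LJ term to zero at r_c (plain cut when False)
    lj_shift: bool = False

    def __post_init__(self) -> None:
        if not np.isclose(self.q_M, -2.0 * self.q_H):
            raise ValueError("molecular neutrality requires q_M = -2 q_H")
        for name in ("r_eq", "sigma", "r_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def k_rf(self) -> float:
        """Reaction-field constant (eps_rf - 1)/((2 eps_rf + 1) r_c^3)."""
        return (self.eps_rf - 1.0) / ((2.0 * self.eps_rf + 1.0) * self.r_c**3)

    @property
    def c_rf(self) -> float:
        """Shift constant making the kernel vanish at the cutoff."""
        if not self.rf_shift:
            return 0.0
        return 1.0 / self.r_c + self.k_rf * self.r_c**2

    def with_cutoff(self, r_c: float) -> "ForceFieldConstants":
        return replace(self, r_c=r_c)


def load_constants(**overrides) -> ForceFieldConstants:
    """Load the versioned q-TIP4P/F constants file shipped with the package."""
    raw = json.loads(
        resources.files("isopimd.data").joinpath("qtip4pf.json").read_text()
    )
    kwargs = dict(
        D_r=raw["stretch"]["D_r"],
        alpha_r=raw["stretch"]["alpha_r"],
        r_eq=raw["stretch"]["r_eq"],
        k_theta=raw["bend"]["k_theta"],
        theta_eq=raw["bend"]["theta_eq"],
        epsilon=raw["lj"]["epsilon"],
        sigma=raw["lj"]["sigma"],
        q_H=raw["charges"]["q_H"],
        q_M=raw["charges"]["q_M"],
        m_site_weight=raw["m_site_weight"],
        r_c=raw["r_c"],
        eps_rf=raw["eps_rf"],
    )
    kwargs.update(overrides)
    return ForceFieldConstants(**kwargs)


@dataclass
class IsotopeSystem:
    """Composition and masses of a box of water molecules.

    ``hdo_site_order='HD'`` puts the H mass on site X1 and the D mass on
    X2 (all molecules singly deuterated for HDO).
    """

    n_molecules: int
    composition: str = "H2O"
    hdo_site_order: str = "HD"

    def __post_init__(self) -> None:
        if self.composition not in COMPOSITION_MASSES:
            raise ValueError(f"unknown composition {self.composition!r}")
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")
        if self.hdo_site_order not in ("HD", "DH"):
            raise ValueError("hdo_site_order must be 'HD' or 'DH'")

    @property
    def site_masses(self) -> np.ndarray:
        """Masses (amu) of the three massive sites in order (O, X1, X2)."""
        m_o, m_1, m_2 = COMPOSITION_MASSES[self.composition]
        if self.composition == "HDO" and self.hdo_site_order == "DH":
            m_1, m_2 = m_2, m_1
        return np.array([m_o, m_1, m_2])

    @property
    def masses(self) -> np.ndarray:
        """Per-site masses tiled over molecules, shape (n_mol, 3)."""
        return np.tile(self.site_masses, (self.n_molecules, 1))

    @property
    def molar_mass(self) -> float:
        return float(self.site_masses.sum())

    def site_species(self) -> list[str]:
        """Chemical species label of each massive site of one molecule."""
        label = {1.00783: "H", 2.01410: "D", 3.01605: "T"}
        m = self.site_masses
        return ["O"] + [label[round(float(x), 5)] for x in m[1:]]


@dataclass(frozen=True)
class SimulationCell:
    """Cubic periodic cell."""

    length: float
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("cell edge must be positive")

    @property
    def volume(self) -> float:
        return self.length**3


@dataclass
class BeadConfiguration:
    """Bead positions, shape (n_mol, 3 sites, n_b, 3), nm."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 4 or pos.shape[1] != 3 or pos.shape[3] != 3:
            raise ValueError("positions must have shape (n_mol, 3, n_b, 3)")
        if pos.shape[2] < 1:
            raise ValueError("need at least one bead")
        object.__setattr__(self, "positions", pos)

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[2]

    @property
    def centroids(self) -> np.ndarray:
        """Bead-averaged positions, shape (n_mol, 3, 3)."""
        return self.positions.mean(axis=2)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _intra_kernel(pos, D_r, alpha, r_eq, k_th, th_eq):
    n_mol, _, nb, _ = pos.shape
    e_beads = np.zeros(nb)
    forces = np.zeros_like(pos)
    virial = 0.0
    for i in range(n_mol):
        for b in range(nb):
            ro = pos[i, 0, b]
            # two stretches
            for s in range(1, 3):
                d = pos[i, s, b] - ro
                r = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
                if r <= 0.0:
                    return e_beads, forces, virial, 1
                x = r - r_eq
                a2 = alpha * alpha
                e_beads[b] += D_r * (
                    a2 * x * x
                    - a2 * alpha * x * x * x
                    + (7.0 / 12.0) * a2 * a2 * x * x * x * x
                )
                dvdr = D_r * (
                    2.0 * a2 * x
                    - 3.0 * a2 * alpha * x * x
                    + (7.0 / 3.0) * a2 * a2 * x * x * x
                )
                for c in range(3):
                    fx = -dvdr * d[c] / r
                    forces[i, s, b, c] += fx
                    forces[i, 0, b, c] -= fx
                    virial += fx * d[c]
            # bend
            u = pos[i, 1, b] - ro
            v = pos[i, 2, b] - ro
            nu = np.sqrt(u[0] * u[0] + u[1] * u[1] + u[2] * u[2])
            nv = np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
            cth = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (nu * nv)
            if cth > 1.0:
                cth = 1.0
            if cth < -1.0:
                cth = -1.0
            th = np.arccos(cth)
            e_beads[b] += 0.5 * k_th * (th - th_eq) * (th - th_eq)
            sth = np.sqrt(1.0 - cth * cth)
            if sth > 1e-8:
                coef = -k_th * (th - th_eq)
                for c in range(3):
                    # d(theta)/dr1 and /dr2
                    g1 = (cth * u[c] / nu - v[c] / nv) / (nu * sth)
                    g2 = (cth * v[c] / nv - u[c] / nu) / (nv * sth)
                    f1 = coef * g1
                    f2 = coef * g2
                    forces[i, 1, b, c] += f1
                    forces[i, 2, b, c] += f2
                    forces[i, 0, b, c] -= f1 + f2
                    virial += f1 * u[c] + f2 * v[c]
    return e_beads, forces, virial, 0


@njit(cache=True)
def _inter_kernel(
    pos, L, periodic, sigma, eps, q_h, q_m, gamma, r_c, k_rf, c_rf, lj_shift
):
    n_mol, _, nb, _ = pos.shape
    e_beads = np.zeros(nb)
    forces = np.zeros_like(pos)
    f_m = np.zeros((n_mol, nb, 3))  # forces landing on M sites
    virial = 0.0
    # M-site positions
    msite = np.empty((n_mol, nb, 3))
    for i in range(n_mol):
        for b in range(nb):
            for c in range(3):
                msite[i, b, c] = gamma * pos[i, 0, b, c] + 0.5 * (1.0 - gamma) * (
                    pos[i, 1, b, c] + pos[i, 2, b, c]
                )
    qs = np.array([q_h, q_h, q_m])
    rc2 = r_c * r_c
    # LJ value at the cutoff (for the optional shift)
    sr2c = sigma * sigma / rc2
    sr6c = sr2c * sr2c * sr2c
    e_lj_rc = 4.0 * eps * (sr6c * sr6c - sr6c) if lj_shift else 0.0
    for i in range(n_mol - 1):
        for j in range(i + 1, n_mol):
            for b in range(nb):
                # LJ on O-O, site-resolved minimum image and cutoff
                d2 = 0.0
                dvec = np.empty(3)
                for c in range(3):
                    d = pos[j, 0, b, c] - pos[i, 0, b, c]
                    if periodic:
                        d -= L * np.rint(d / L)
                    dvec[c] = d
                    d2 += d * d
                if d2 <= rc2:
                    sr2 = sigma * sigma / d2
                    sr6 = sr2 * sr2 * sr2
                    e_beads[b] += 4.0 * eps * (sr6 * sr6 - sr6) - e_lj_rc
                    fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / d2
                    for c in range(3):
                        fc = fmag * dvec[c]
                        forces[j, 0, b, c] += fc
                        forces[i, 0, b, c] -= fc
                        virial += fc * dvec[c]
                # Coulomb among charged sites (X1, X2, M) x (X1, X2, M),
                # each site pair individually minimum-imaged and cut at r_c
                for si in range(3):
                    if si < 2:
                        pi = pos[i, si + 1, b]
                    else:
                        pi = msite[i, b]
                    for sj in range(3):
                        if sj < 2:
                            pj = pos[j, sj + 1, b]
                        else:
                            pj = msite[j, b]
                        r2q = 0.0
                        for c in range(3):
                            d = pj[c] - pi[c]
                            if periodic:
                                d -= L * np.rint(d / L)
                            dvec[c] = d
                            r2q += d * d
                        if r2q > rc2:
                            continue
                        if r2q < 1e-8:
                            return e_beads, forces, f_m, virial, 1
                        r = np.sqrt(r2q)
                        qq = COULOMB * qs[si] * qs[sj]
                        e_beads[b] += qq * (1.0 / r + k_rf * r2q - c_rf)
                        fmagq = qq * (1.0 / (r2q * r) - 2.0 * k_rf)
                        for c in range(3):
                            fc = fmagq * dvec[c]
                            virial += fc * dvec[c]
                            if sj < 2:
                                forces[j, sj + 1, b, c] += fc
                            else:
                                f_m[j, b, c] += fc
                            if si < 2:
                                forces[i, si + 1, b, c] -= fc
                            else:
                                f_m[i, b, c] -= fc
    return e_beads, forces, f_m, virial, 0


@njit(cache=True)
def _redistribute_kernel(forces, f_m, gamma):
    n_mol, nb, _ = f_m.shape
    for i in range(n_mol):
        for b in range(nb):
            for c in range(3):
                fm = f_m[i, b, c]
                forces[i, 0, b, c] += gamma * fm
                forces[i, 1, b, c] += 0.5 * (1.0 - gamma) * fm
                forces[i, 2, b, c] += 0.5 * (1.0 - gamma) * fm


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _check_positions(pos: np.ndarray) -> None:
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite coordinates")


def intramolecular_energy_forces(
    config: BeadConfiguration | np.ndarray, ff: ForceFieldConstants
):
    """Stretch + bend energy per bead slice and exact negative gradients.

    Returns ``(e_beads, forces, virial)`` where ``e_beads`` has shape
    ``(n_b,)`` (kJ/mol summed over molecules, one entry per bead slice),
    ``forces`` matches the positions array, and ``virial`` is the
    interaction virial summed over slices.
    """
    pos = config.positions if isinstance(config, BeadConfiguration) else np.asarray(config)
    _check_positions(pos)
    e, f, w, err = _intra_kernel(
        pos, ff.D_r, ff.alpha_r, ff.r_eq, ff.k_theta, ff.theta_eq
    )
    if err:
        raise ValueError("degenerate covalent bond (zero length)")
    return e, f, w


def m_site_positions(
    config: BeadConfiguration | np.ndarray, ff: ForceFieldConstants
) -> np.ndarray:
    """M-site positions, shape (n_mol, n_b, 3).

    The M site sits on the XOX bisector: r_M = w r_O + (1-w)(r_X1+r_X2)/2.
    With m_site_weight w = 1 it coincides with the oxygen.
    """
    pos = config.positions if isinstance(config, BeadConfiguration) else np.asarray(config)
    w = ff.m_site_weight
    return w * pos[:, 0] + 0.5 * (1.0 - w) * (pos[:, 1] + pos[:, 2])


def redistribute_m_forces(
    forces: np.ndarray, f_m: np.ndarray, ff: ForceFieldConstants
) -> np.ndarray:
    """Spread forces acting on massless M sites onto the massive sites.

    Uses the transpose of the placement weights, which conserves the total
    force and torque on each molecule.
    """
    out = forces.copy()
    _redistribute_kernel(out, np.ascontiguousarray(f_m), ff.m_site_weight)
    return out


def intermolecular_energy_forces(
    config: BeadConfiguration | np.ndarray,
    ff: ForceFieldConstants,
    cell: SimulationCell,
):
    """LJ (O-O) plus reaction-field Coulomb, per bead slice.

    A molecular cutoff is used: a pair of molecules interacts (all terms)
    iff their minimum-image O-O distance on that bead slice is below r_c,
    so neutral charge groups are never split by the cutoff.  Forces on the
    massless M site are redistributed to the massive sites.
    """
    pos = config.positions if isinstance(config, BeadConfiguration) else np.asarray(config)
    _check_positions(pos)
    if cell.periodic and cell.length < 2.0 * ff.r_c:
        raise ValueError(
            f"cell edge {cell.length} nm below 2 r_c = {2 * ff.r_c} nm; "
            "reduce the cutoff for desk-scale boxes"
        )
    e, f, f_m, w, err = _inter_kernel(
        pos,
        cell.length,
        cell.periodic,
        ff.sigma,
        ff.epsilon,
        ff.q_H,
        ff.q_M,
        ff.m_site_weight,
        ff.r_c,
        ff.k_rf,
        ff.c_rf,
        ff.lj_shift,
    )
    if err:
        raise ValueError("overlapping charged sites (r < 1e-4 nm)")
    f = redistribute_m_forces(f, f_m, ff)
    return e, f, w


def total_potential(
    config: BeadConfiguration | np.ndarray,
    ff: ForceFieldConstants,
    cell: SimulationCell | None = None,
):
    """Full potential: intramolecular + intermolecular terms.

    Returns ``(e_beads, forces, virial)``.  With ``cell=None`` (isolated
    system) only the intramolecular part is evaluated for a single
    molecule; for several molecules a non-periodic cell is implied.
    """
    pos = config.positions if isinstance(config, BeadConfiguration) else np.asarray(config)
    e, f, w = intramolecular_energy_forces(pos, ff)
    n_mol = pos.shape[0]
    if n_mol > 1 or cell is not None:
        if cell is None:
            cell = SimulationCell(length=1.0, periodic=False)
        e2, f2, w2 = intermolecular_energy_forces(pos, ff, cell)
        e = e + e2
        f = f + f2
        w = w + w2
    return e, f, w


def reaction_field_pair_energy(
    q1: float, q2: float, r: float, ff: ForceFieldConstants
) -> float:
    """Scalar reaction-field kernel: f q1 q2 (1/r + k_rf r^2 - c_rf), 0 beyond r_c."""
    if r >= ff.r_c:
        return 0.0
    return COULOMB * q1 * q2 * (1.0 / r + ff.k_rf * r * r - ff.c_rf)


# ---------------------------------------------------------------------------
# monomer helpers (equilibrium geometry, harmonic normal modes)
# ---------------------------------------------------------------------------


def monomer_equilibrium_geometry(ff: ForceFieldConstants) -> np.ndarray:
    """One molecule at the potential minimum, shape (1, 3, 1, 3), O at origin."""
    th = ff.theta_eq
    r = ff.r_eq
    h1 = np.array([r * np.cos(th / 2), r * np.sin(th / 2), 0.0])
    h2 = np.array([r * np.cos(th / 2), -r * np.sin(th / 2), 0.0])
    pos = np.zeros((1, 3, 1, 3))
    pos[0, 1, 0] = h1
    pos[0, 2, 0] = h2
    return pos


def monomer_normal_modes(
    ff: ForceFieldConstants, masses: np.ndarray, step: float = 1e-5
) -> np.ndarray:
    """Harmonic vibrational frequencies (cm^-1) of an isolated molecule.

    Builds the Cartesian Hessian of the intramolecular potential by
    central finite differences of the analytic forces at the equilibrium
    geometry, mass-weights it, and diagonalizes.  Returns the three
    vibrational frequencies sorted ascending (bend, symmetric stretch,
    antisymmetric stretch); zero/rotation modes are filtered out.
    """
    from .constants import wavenumber_from_angular_frequency

    pos0 = monomer_equilibrium_geometry(ff)
    n = 9
    hess = np.zeros((n, n))
    for k in range(n):
        for sgn, w in ((1, 1.0), (-1, -1.0)):
            p = pos0.copy()
            p.reshape(-1)[k] += sgn * step
            _, f, _ = intramolecular_energy_forces(p, ff)
            hess[:, k] += -w * f.reshape(-1) / (2 * step)
    hess = 0.5 * (hess + hess.T)
    m = np.repeat(np.asarray(masses, dtype=float), 3)
    mw = hess / np.sqrt(np.outer(m, m))
    evals = np.linalg.eigvalsh(mw)
    omega = np.sqrt(np.clip(evals, 0.0, None))  # rad/ps
    wn = np.array([wavenumber_from_angular_frequency(o) for o in omega])
    return np.sort(wn)[-3:]
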
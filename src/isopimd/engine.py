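"""PIMD/RPMD propagation: PILE thermostat, MC barostat, quantum estimators.

The propagator integrates the ring-polymer Hamiltonian

    H_n = sum_j [ p_j^2 / 2m + (m omega_n^2 / 2)(x_j - x_{j+1})^2 + V(x_j) ]

sampled at the elevated temperature ``n_b T`` (``omega_n = n_b / beta
hbar``).  One step is the symmetric OBABO splitting: half Ornstein-
Uhlenbeck thermostat in normal-mode space (PILE: centroid friction
``gamma0``, internal-mode friction ``2 omega_k``), half force kick, exact
free-ring-polymer drift, half kick, half thermostat.  With ``n_b = 1``
and the thermostat off this is exactly velocity Verlet.

The propagator is generic over the force field: any callable mapping bead
positions ``(n_particles, n_b, dim)`` to ``(energy_per_bead, forces,
virial)`` can be integrated, which is how the harmonic-oscillator and
free-particle oracle tests drive the same code path as the water runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .constants import HBAR, KB, N_AVOGADRO
from .ringpolymer import normal_mode_frequencies, normal_mode_matrix
from . import forcefield as ffmod
from .forcefield import (
    BeadConfiguration,
    ForceFieldConstants,
    IsotopeSystem,
    SimulationCell,
    m_site_positions,
    total_potential,
)

__all__ = [
    "IntegratorSettings",
    "RingPolymerState",
    "EstimatorRecord",
    "PILEPropagator",
    "rpmd_step",
    "mc_barostat_move",
    "quantum_estimators",
    "run_simulation",
    "initial_momenta",
]

#: per-step displacement (nm) beyond which the run is declared unstable
MAX_STEP_DISPLACEMENT = 0.05

#: 1 kJ mol^-1 nm^-3 expressed in MPa
PRESSURE_KJMOLNM3_TO_MPA = 1e24 / N_AVOGADRO

#: 1 MPa nm^3 expressed in kJ/mol
PV_MPANM3_TO_KJMOL = 1.0 / PRESSURE_KJMOLNM3_TO_MPA


@dataclass
class IntegratorSettings:
    """Run parameters mirroring the study's simulation setup."""

    dt: float = 2.5e-4  # ps (0.25 fs quantum; 0.5 fs classical)
    n_beads: int = 32
    temperature: float = 300.0  # K
    gamma0: float = 0.1  # ps^-1, centroid-mode friction (production)
    gamma_equil: float = 20.0  # ps^-1, strong centroid friction while equilibrating
    ensemble: str = "NVT"
    pressure: float = 0.1  # MPa, NPT target
    seed: int = 2024
    n_equil: int = 0
    n_prod: int = 1000
    frame_stride: int = 10  # estimator / centroid recording
    velocity_stride: int = 4  # centroid-velocity & dipole recording
    bead_stride: int = 50  # full bead-configuration recording
    thermostat: bool = True
    barostat_stride: int = 25
    barostat_dlnv: float = 0.02
    barostat_scale_beads: bool = False  # scale per-molecule centroids (default)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma0 < 0:
            raise ValueError("gamma0 must be non-negative")
        if self.ensemble not in ("NVT", "NPT"):
            raise ValueError("ensemble must be NVT or NPT")


@dataclass
class RingPolymerState:
    """Bead positions/momenta plus cell and thermodynamic state."""

    positions: np.ndarray  # (n_mol, 3, n_b, 3), nm
    momenta: np.ndarray  # (n_mol, 3, n_b, 3), amu nm/ps
    masses: np.ndarray  # (n_mol, 3), amu
    cell: SimulationCell
    temperature: float

    def __post_init__(self) -> None:
        if self.positions.shape != self.momenta.shape:
            raise ValueError("positions and momenta must have the same shape")
        if not np.all(np.isfinite(self.momenta)):
            raise ValueError("non-finite momenta")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[2]

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)

    def copy(self) -> "RingPolymerState":
        return RingPolymerState(
            self.positions.copy(),
            self.momenta.copy(),
            self.masses.copy(),
            self.cell,
            self.temperature,
        )


@dataclass
class EstimatorRecord:
    """Per-frame quantum estimators (totals for the whole system, kJ/mol)."""

    potential: float
    kinetic_primitive: float
    kinetic_cv: float
    energy: float  # K_cv + U
    pressure: float  # MPa, virial estimator
    volume: float  # nm^3
    enthalpy: float  # E + P_target V (NPT) or E + P_inst V (NVT)
    temperature: float  # centroid kinetic temperature, K


def initial_momenta(
    masses: np.ndarray, n_beads: int, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Maxwell-Boltzmann momenta at the bead temperature n_b T."""
    m = masses[..., None, None]
    sigma = np.sqrt(m * KB * temperature * n_beads)
    return rng.normal(0.0, 1.0, size=(*masses.shape, n_beads, 3)) * sigma


class PILEPropagator:
    """OBABO path-integral Langevin integrator over a generic force field.

    Parameters
    ----------
    force_fn:
        Callable ``(positions) -> (e_beads, forces, virial)`` where
        positions has the bead axis second to last.
    masses:
        Physical masses, broadcastable against the particle axes.
    """

    def __init__(
        self,
        force_fn: Callable,
        masses: np.ndarray,
        temperature: float,
        dt: float,
        n_beads: int,
        gamma0: float = 0.1,
        thermostat: bool = True,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.force_fn = force_fn
        self.masses = np.asarray(masses, dtype=float)
        self.temperature = temperature
        self.dt = dt
        self.n_beads = n_beads
        self.thermostat = thermostat
        self.rng = rng if rng is not None else np.random.default_rng(0)
        beta = 1.0 / (KB * temperature)
        self.beta = beta
        self.cmat = normal_mode_matrix(n_beads)
        self.omega_k = normal_mode_frequencies(n_beads, beta)
        gammas = 2.0 * self.omega_k
        gammas[0] = gamma0
        self._c1 = np.exp(-0.5 * gammas * dt)
        self._c2 = np.sqrt(1.0 - self._c1**2)
        # exact free-ring-polymer drift coefficients per mode
        wk = self.omega_k
        self._drift_cos = np.cos(wk * dt)
        self._drift_sin = np.sin(wk * dt)
        self._drift_sw = np.full_like(wk, dt)
        np.divide(self._drift_sin, wk, where=wk > 0, out=self._drift_sw)
        self._cached_forces = None
        self._cached_e_beads = None
        self._cached_virial = None

    # -- helpers ------------------------------------------------------------
    def _nm(self, a: np.ndarray) -> np.ndarray:
        # transform along the bead axis (second to last)
        return np.einsum("kj,...jc->...kc", self.cmat, a)

    def _nm_inv(self, a: np.ndarray) -> np.ndarray:
        return np.einsum("jk,...jc->...kc", self.cmat, a)

    def _ou_half(self, p: np.ndarray) -> np.ndarray:
        if not self.thermostat:
            return p
        pk = self._nm(p)
        m = self.masses[..., None, None]
        sigma = np.sqrt(m * KB * self.temperature * self.n_beads)
        noise = self.rng.normal(0.0, 1.0, size=pk.shape)
        pk = self._c1[:, None] * pk + sigma * self._c2[:, None] * noise
        return self._nm_inv(pk)

    def forces(self, x: np.ndarray):
        if self._cached_forces is None:
            self._cached_e_beads, self._cached_forces, self._cached_virial = self.force_fn(x)
        return self._cached_e_beads, self._cached_forces, self._cached_virial

    def invalidate_cache(self) -> None:
        self._cached_forces = None

    # -- one step -----------------------------------------------------------
    def step(self, x: np.ndarray, p: np.ndarray):
        """Advance one OBABO step; returns (x', p', e_beads, forces, virial)."""
        dt = self.dt
        m = self.masses[..., None, None]
        p = self._ou_half(p)
        _, f, _ = self.forces(x)
        p = p + 0.5 * dt * f
        # exact free-RP drift in normal modes
        xk = self._nm(x)
        pk = self._nm(p)
        cos = self._drift_cos[:, None]
        sw = self._drift_sw[:, None]
        msin = (self.masses[..., None, None] * self.omega_k[:, None]) * self._drift_sin[:, None]
        xk_new = cos * xk + sw * pk / m
        pk_new = cos * pk - msin * xk
        x_new = self._nm_inv(xk_new)
        p = self._nm_inv(pk_new)
        max_disp = float(np.max(np.abs(x_new - x)))
        if max_disp > MAX_STEP_DISPLACEMENT:
            raise RuntimeError(
                f"integration unstable: per-step displacement {max_disp:.3g} nm "
                f"exceeds {MAX_STEP_DISPLACEMENT} nm"
            )
        x = x_new
        self.invalidate_cache()
        e_beads, f, virial = self.forces(x)
        p = p + 0.5 * dt * f
        p = self._ou_half(p)
        return x, p, e_beads, f, virial


# ---------------------------------------------------------------------------
# water-specific wrappers
# ---------------------------------------------------------------------------


def _water_force_fn(ff: ForceFieldConstants, cell: SimulationCell):
    def fn(pos):
        return total_potential(pos, ff, cell)

    return fn


def make_propagator(
    state: RingPolymerState,
    ff: ForceFieldConstants,
    settings: IntegratorSettings,
    rng: Optional[np.random.Generator] = None,
) -> PILEPropagator:
    return PILEPropagator(
        _water_force_fn(ff, state.cell),
        state.masses,
        settings.temperature,
        settings.dt,
        state.n_beads,
        gamma0=settings.gamma0,
        thermostat=settings.thermostat,
        rng=rng,
    )


def rpmd_step(
    state: RingPolymerState,
    ff: ForceFieldConstants,
    settings: IntegratorSettings,
    propagator: Optional[PILEPropagator] = None,
    rng: Optional[np.random.Generator] = None,
) -> RingPolymerState:
    """Functional single-step interface (used by tests; runs use the class)."""
    prop = propagator or make_propagator(state, ff, settings, rng=rng)
    x, p, *_ = prop.step(state.positions, state.momenta)
    return RingPolymerState(x, p, state.masses, state.cell, state.temperature)


def quantum_estimators(
    state: RingPolymerState,
    ff: ForceFieldConstants,
    target_pressure: Optional[float] = None,
    e_beads: Optional[np.ndarray] = None,
    forces: Optional[np.ndarray] = None,
    virial: Optional[float] = None,
) -> EstimatorRecord:
    """Evaluate the quantum estimators on one configuration.

    Energies are totals over the system in kJ/mol; the pressure is the
    virial estimator in MPa.  For ``n_b = 1`` the centroid-virial kinetic
    estimator equals ``3 N k_B T / 2`` exactly and the pressure reduces to
    the classical atomic-virial expression.
    """
    x = state.positions
    n_mol, _, nb, _ = x.shape
    n_atoms = 3 * n_mol
    beta = state.beta
    if e_beads is None or forces is None or virial is None:
        e_beads, forces, virial = total_potential(x, ff, state.cell)
    u = float(np.mean(e_beads))
    # primitive kinetic estimator
    omega_n = nb / (beta * HBAR)
    diffs = x - np.roll(x, -1, axis=2)
    spring = 0.5 * float(
        np.sum(state.masses[..., None] * np.sum(diffs**2, axis=-1)) * omega_n**2
    )
    k_prim = 1.5 * n_atoms * nb / beta - spring
    # centroid-virial kinetic estimator
    xc = x.mean(axis=2, keepdims=True)
    k_cv = 1.5 * n_atoms / beta - 0.5 / nb * float(np.sum((x - xc) * forces))
    energy = k_cv + u
    vol = state.cell.volume
    # pressure: PV = (2/3) K_cv + W / (3 n_b)
    p_internal = (2.0 * k_cv + virial / nb) / (3.0 * vol)
    pressure = p_internal * PRESSURE_KJMOLNM3_TO_MPA
    # centroid kinetic temperature (centroid momenta are at the physical T)
    pc = state.momenta.mean(axis=2)
    ke_c = 0.5 * float(np.sum(pc**2 / state.masses[..., None]))
    temp_c = 2.0 * ke_c / (3.0 * n_atoms * KB)
    p_ref = target_pressure if target_pressure is not None else pressure
    pv = p_ref * vol * PV_MPANM3_TO_KJMOL
    return EstimatorRecord(
        potential=u,
        kinetic_primitive=k_prim,
        kinetic_cv=k_cv,
        energy=energy,
        pressure=pressure,
        volume=vol,
        enthalpy=energy + pv,
        temperature=temp_c,
    )


def mc_barostat_move(
    state: RingPolymerState,
    ff: ForceFieldConstants,
    settings: IntegratorSettings,
    rng: np.random.Generator,
    interactions_on: bool = True,
):
    """One Monte-Carlo volume move; returns (state', accepted: bool).

    Proposes a change in ln V, rescales per-molecule ring-polymer centers
    rigidly (internal geometry and bead spread preserved), and accepts
    with the Metropolis weight ``exp(-beta [dU + P dV] + (N+1) dlnV)``.
    """
    beta = state.beta
    v_old = state.cell.volume
    dlnv = settings.barostat_dlnv * rng.uniform(-1.0, 1.0)
    v_new = v_old * np.exp(dlnv)
    s = (v_new / v_old) ** (1.0 / 3.0)
    new_length = state.cell.length * s
    if state.cell.periodic and interactions_on and new_length < 2.0 * ff.r_c:
        return state, False
    x = state.positions
    if settings.barostat_scale_beads:
        x_new = x * s
    else:
        com = x.mean(axis=(1, 2), keepdims=True)  # per-molecule center
        x_new = x + (s - 1.0) * com
    new_cell = SimulationCell(new_length, state.cell.periodic)
    if interactions_on:
        e_old, _, _ = ffmod.intermolecular_energy_forces(x, ff, state.cell)
        e_new, _, _ = ffmod.intermolecular_energy_forces(x_new, ff, new_cell)
        du = float(np.mean(e_new) - np.mean(e_old))
    else:
        du = 0.0
    n_mol = x.shape[0]
    pdv = settings.pressure * (v_new - v_old) * PV_MPANM3_TO_KJMOL
    arg = -beta * (du + pdv) + (n_mol + 1) * dlnv
    if np.log(rng.uniform()) < arg:
        new_state = RingPolymerState(
            x_new, state.momenta.copy(), state.masses, new_cell, state.temperature
        )
        return new_state, True
    return state, False


def run_simulation(
    system: IsotopeSystem,
    settings: IntegratorSettings,
    ff: Optional[ForceFieldConstants] = None,
    initial_state: Optional[RingPolymerState] = None,
    molar_volume: float = 18.0,
    interactions_on: bool = True,
):
    """Equilibrate and run production PIMD; returns a TrajectoryArchive.

    When no initial state is given, molecules are placed on a cubic
    lattice at the requested molar volume (cm^3/mol) with coincident
    beads; the cutoff is clipped to half the box edge for desk-scale
    boxes.
    """
    from .archive import TrajectoryArchive
    from .fixtures import build_water_box

    rng = np.random.default_rng(settings.seed)
    if ff is None:
        ff = ffmod.load_constants()
    if initial_state is None:
        config, cell = build_water_box(
            system, molar_volume, settings.n_beads, seed=settings.seed
        )
        if cell.length < 2.0 * ff.r_c:
            # desk-scale box: clip the cutoff and shift the LJ so energies
            # stay continuous at the (short) cutoff; NPT keeps a margin so
            # volume fluctuations below the start volume are not rejected
            from dataclasses import replace

            factor = 0.45 if settings.ensemble == "NPT" else 0.5
            ff = replace(ff, r_c=factor * cell.length, lj_shift=True)
        p0 = initial_momenta(system.masses, settings.n_beads, settings.temperature, rng)
        state = RingPolymerState(
            config.positions, p0, system.masses, cell, settings.temperature
        )
    else:
        state = initial_state.copy()
        if state.cell.length < 2.0 * ff.r_c:
            from dataclasses import replace

            factor = 0.45 if settings.ensemble == "NPT" else 0.5
            ff = replace(ff, r_c=factor * state.cell.length, lj_shift=True)

    def force_fn(pos):
        # reads state.cell each call so barostat moves are picked up
        if interactions_on:
            return total_potential(pos, ff, state.cell)
        return ffmod.intramolecular_energy_forces(pos, ff)
    def build_prop(gamma0: float) -> PILEPropagator:
        return PILEPropagator(
            force_fn,
            state.masses,
            settings.temperature,
            settings.dt,
            settings.n_beads,
            gamma0=gamma0,
            thermostat=settings.thermostat,
            rng=rng,
        )

    # strong centroid friction drains the lattice-start excess energy;
    # production uses the study's weak friction
    prop = build_prop(settings.gamma_equil if settings.n_equil else settings.gamma0)

    x, p = state.positions, state.momenta
    # unwrapped coordinates are maintained throughout; minimum image is
    # applied inside the pair kernels only
    records: list[EstimatorRecord] = []
    times = []
    centroid_pos = []
    centroid_vel = []
    vel_times = []
    dipoles = []
    bead_frames = []
    bead_times = []
    volumes_series = []
    n_accept = n_attempt = 0

    def record_frame(step_idx: int, e_beads, forces, virial) -> None:
        st = RingPolymerState(x, p, state.masses, state.cell, state.temperature)
        rec = quantum_estimators(
            st,
            ff,
            target_pressure=settings.pressure if settings.ensemble == "NPT" else None,
            e_beads=e_beads,
            forces=forces,
            virial=virial,
        )
        records.append(rec)
        times.append(step_idx * settings.dt)
        centroid_pos.append(x.mean(axis=2).copy())
        volumes_series.append(state.cell.volume)

    total_steps = settings.n_equil + settings.n_prod
    for step_idx in range(total_steps):
        if step_idx == settings.n_equil and settings.n_equil:
            prop = build_prop(settings.gamma0)
        x, p, e_beads, forces, virial = prop.step(x, p)
        production = step_idx >= settings.n_equil
        if settings.ensemble == "NPT" and (step_idx + 1) % settings.barostat_stride == 0:
            st = RingPolymerState(x, p, state.masses, state.cell, state.temperature)
            st2, acc = mc_barostat_move(st, ff, settings, rng, interactions_on)
            n_attempt += 1
            n_accept += int(acc)
            if acc:
                x, p = st2.positions, st2.momenta
                state = RingPolymerState(x, p, state.masses, st2.cell, state.temperature)
                prop.invalidate_cache()
                e_beads, forces, virial = prop.forces(x)
        if production:
            k = step_idx - settings.n_equil
            if k % settings.frame_stride == 0:
                record_frame(step_idx, e_beads, forces, virial)
            if k % settings.velocity_stride == 0:
                centroid_vel.append((p.mean(axis=2) / state.masses[..., None]).copy())
                vel_times.append(step_idx * settings.dt)
                mpos = m_site_positions(x, ff).mean(axis=1)  # (n_mol, 3)
                xc = x.mean(axis=2)
                dip = ff.q_H * (xc[:, 1] + xc[:, 2]).sum(axis=0) + ff.q_M * mpos.sum(
                    axis=0
                )
                dipoles.append(dip)
            if k % settings.bead_stride == 0:
                bead_frames.append(x.copy())
                bead_times.append(step_idx * settings.dt)

    return TrajectoryArchive(
        config={
            "composition": system.composition,
            "n_molecules": system.n_molecules,
            "n_beads": settings.n_beads,
            "temperature": settings.temperature,
            "ensemble": settings.ensemble,
            "pressure": settings.pressure,
            "dt": settings.dt,
            "gamma0": settings.gamma0,
            "seed": settings.seed,
            "n_equil": settings.n_equil,
            "n_prod": settings.n_prod,
            "frame_stride": settings.frame_stride,
            "velocity_stride": settings.velocity_stride,
            "bead_stride": settings.bead_stride,
            "r_c": ff.r_c,
            "molar_volume": molar_volume,
            "barostat_acceptance": (n_accept / n_attempt) if n_attempt else None,
        },
        masses=state.masses,
        species=IsotopeSystem(
            system.n_molecules, system.composition, system.hdo_site_order
        ).site_species(),
        cell_length=state.cell.length,
        times=np.asarray(times),
        centroid_positions=np.asarray(centroid_pos),
        volumes=np.asarray(volumes_series),
        estimators={
            name: np.array([getattr(r, name) for r in records])
            for name in (
                "potential",
                "kinetic_primitive",
                "kinetic_cv",
                "energy",
                "pressure",
                "volume",
                "enthalpy",
                "temperature",
            )
        },
        velocity_times=np.asarray(vel_times),
        centroid_velocities=np.asarray(centroid_vel),
        dipoles=np.asarray(dipoles),
        bead_times=np.asarray(bead_times),
        bead_positions=np.asarray(bead_frames),
    )
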
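"""File formats and run configuration.

Extended-XYZ snapshots carry species, molecule id and bead index so a
bead configuration round-trips losslessly; run configurations are YAML
key-value files mirroring the simulation parameters and are persisted
verbatim into every archive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .engine import IntegratorSettings
from .forcefield import BeadConfiguration, IsotopeSystem, SimulationCell

__all__ = [
    "RunConfig",
    "write_extxyz",
    "read_extxyz",
    "load_run_config",
    "config_hash",
]


@dataclass
class RunConfig:
    """Simulation parameters; defaults mirror the study's setup.

    The documented desk-scale profile (used by the bundled analyses and
    tests) shrinks n_molecules / n_beads / run lengths so a full isotope
    scan runs in minutes; the cluster profile keeps the study-scale
    values.
    """

    composition: str = "H2O"
    ensemble: str = "NVT"
    temperature: float = 300.0
    pressure: float = 0.1  # MPa
    molar_volume: float = 18.0  # cm^3/mol
    n_molecules: int = 512
    n_beads: int = 32
    dt: float = 2.5e-4  # ps
    r_c: float = 1.0  # nm
    eps_rf: float = 78.3
    gamma0: float = 0.1  # ps^-1
    seed: int = 2024
    n_equil: int = 4000
    n_prod: int = 20000
    frame_stride: int = 10
    velocity_stride: int = 4
    bead_stride: int = 50
    arrhenius_t_min: float = 300.0
    mct_window: tuple = (220.0, 300.0)

    def settings(self) -> IntegratorSettings:
        return IntegratorSettings(
            dt=self.dt,
            n_beads=self.n_beads,
            temperature=self.temperature,
            gamma0=self.gamma0,
            ensemble=self.ensemble,
            pressure=self.pressure,
            seed=self.seed,
            n_equil=self.n_equil,
            n_prod=self.n_prod,
            frame_stride=self.frame_stride,
            velocity_stride=self.velocity_stride,
            bead_stride=self.bead_stride,
        )

    def system(self) -> IsotopeSystem:
        return IsotopeSystem(self.n_molecules, self.composition)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**known)
    if isinstance(cfg.mct_window, list):
        cfg.mct_window = tuple(cfg.mct_window)
    return cfg


def config_hash(config: dict | RunConfig) -> str:
    payload = asdict(config) if isinstance(config, RunConfig) else dict(config)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_extxyz(path, config: BeadConfiguration, species: list[str], cell: SimulationCell | None = None) -> None:
    """Write a bead configuration as extended XYZ with a bead-index column."""
    pos = config.positions
    n_mol, n_sites, nb, _ = pos.shape
    n_rows = n_mol * n_sites * nb
    lattice = ""
    if cell is not None:
        L = cell.length * 10.0  # nm -> Angstrom
        lattice = f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}" '
    with open(path, "w") as fh:
        fh.write(f"{n_rows}\n")
        fh.write(
            f"{lattice}Properties=species:S:1:pos:R:3:molecule:I:1:bead:I:1 "
            f"n_molecules={n_mol} n_beads={nb}\n"
        )
        for i in range(n_mol):
            for s in range(n_sites):
                for b in range(nb):
                    x, y, z = pos[i, s, b] * 10.0  # nm -> Angstrom
                    fh.write(
                        f"{species[s]} {x:.8f} {y:.8f} {z:.8f} {i} {b}\n"
                    )


def read_extxyz(path):
    """Read a bead-annotated extended-XYZ file written by :func:`write_extxyz`.

    Returns (BeadConfiguration, species, cell or None).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise IOError(f"truncated extended-XYZ file: {path}")
    n_rows = int(lines[0])
    header = lines[1]
    if len(lines) < 2 + n_rows:
        raise IOError(
            f"truncated extended-XYZ file: expected {n_rows} atom rows, "
            f"found {len(lines) - 2}"
        )
    cell = None
    if "Lattice=" in header:
        lat = header.split('Lattice="')[1].split('"')[0].split()
        cell = SimulationCell(float(lat[0]) / 10.0)
    meta = dict(
        item.split("=") for item in header.split() if "=" in item and '"' not in item
    )
    n_mol = int(meta["n_molecules"])
    nb = int(meta["n_beads"])
    pos = np.zeros((n_mol, 3, nb, 3))
    species = [""] * 3
    seen = {}
    for line in lines[2 : 2 + n_rows]:
        parts = line.split()
        sp, x, y, z, mol, bead = (
            parts[0],
            float(parts[1]),
            float(parts[2]),
            float(parts[3]),
            int(parts[4]),
            int(parts[5]),
        )
        s = seen.setdefault((mol, bead), 0)
        pos[mol, s, bead] = np.array([x, y, z]) / 10.0
        species[s] = sp
        seen[(mol, bead)] = s + 1
    return BeadConfiguration(pos), species, cell
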
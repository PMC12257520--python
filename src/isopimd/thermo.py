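"""Thermodynamic observables from estimator time series.

Turns per-run estimator series into the study's observables: density and
molar volume with block-averaged errors, the isothermal compressibility
from volume fluctuations, heat capacities from quartic fits of H(T) or
E(T), and the temperature of maximum density from either rho(T) at
constant P or the P(T) minimum at constant molar volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import KB, N_AVOGADRO

__all__ = [
    "block_average",
    "density_and_volume",
    "isothermal_compressibility",
    "heat_capacity_from_curve",
    "locate_density_maximum",
]


def block_average(series: np.ndarray, n_blocks: int = 10):
    """Mean and blocked standard error of the mean.

    Refuses to report an error bar with fewer than 5 blocks.
    """
    series = np.asarray(series, dtype=float)
    mean = float(series.mean())
    if n_blocks < 5 or len(series) < n_blocks:
        raise ValueError("need at least 5 blocks for a blocked error bar")
    usable = (len(series) // n_blocks) * n_blocks
    blocks = series[:usable].reshape(n_blocks, -1).mean(axis=1)
    err = float(blocks.std(ddof=1) / np.sqrt(n_blocks))
    return mean, err


def density_and_volume(archive, n_blocks: int = 10):
    """Density rho (g/cm^3) and molar volume v (cm^3/mol) with errors.

    rho = N M / (N_A <V>); v = M / rho identically.  Returns a dict with
    means and blocked standard errors.
    """
    vols = np.asarray(archive.volumes, dtype=float)  # nm^3
    n_mol = archive.n_molecules
    molar_mass = float(np.sum(archive.masses[0]))  # g/mol per molecule
    v_mean, v_err = block_average(vols, n_blocks)
    # nm^3 -> cm^3: 1e-21
    rho = n_mol * molar_mass / (N_AVOGADRO * v_mean * 1e-21)
    rho_err = rho * v_err / v_mean
    v_molar = v_mean * 1e-21 * N_AVOGADRO / n_mol  # cm^3/mol
    v_molar_err = v_molar * v_err / v_mean
    return {
        "rho": rho,
        "rho_err": rho_err,
        "v": v_molar,
        "v_err": v_molar_err,
        "molar_mass": molar_mass,
    }


def isothermal_compressibility(
    volumes: np.ndarray, temperature: float, min_frames: int = 100
):
    """kappa_T = <dV^2> / (k_B T <V>) from NPT volume fluctuations, 1/GPa.

    ``volumes`` in nm^3.  Warns when the series is short (wide error bar).
    """
    v = np.asarray(volumes, dtype=float)
    if len(v) < min_frames:
        warnings.warn(
            f"only {len(v)} volume frames; compressibility error bar is wide",
            stacklevel=2,
        )
    var = float(v.var(ddof=1)) if len(v) > 1 else 0.0
    mean = float(v.mean())
    kbt = KB * temperature  # kJ/mol
    # kappa in nm^3 / (kJ/mol) -> 1/Pa: multiply by (1e-27 m^3) / (1000/N_A J)
    kappa_internal = var / (kbt * mean)
    kappa_per_pa = kappa_internal * 1e-27 * N_AVOGADRO / 1000.0
    return kappa_per_pa * 1e9  # 1/GPa


@dataclass
class HeatCapacityFit:
    temperatures: np.ndarray
    capacity: np.ndarray  # J/mol/K on the input grid
    capacity_err: np.ndarray
    coefficients: np.ndarray
    label: str  # "C_P" for H(T) input, "C_V" for E(T) input

    def at(self, t: float) -> float:
        dcoef = np.polyder(np.poly1d(self.coefficients[::-1]))
        return float(dcoef(t) * 1000.0)


def heat_capacity_from_curve(
    temperatures: np.ndarray,
    values: np.ndarray,
    errors: np.ndarray | None = None,
    order: int = 4,
    kind: str = "H",
    n_boot: int = 200,
    seed: int = 0,
) -> HeatCapacityFit:
    """Heat capacity as the derivative of a quartic fit to H(T) or E(T).

    ``values`` are molar enthalpies/energies in kJ/mol; the returned
    capacity is in J/mol/K.  Uncertainties come from resampling the input
    error bars (when given).  At least ``order + 2`` points are required.
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < order + 2:
        raise ValueError(f"need at least {order + 2} temperature points")
    # unweighted least squares unless error bars provided
    w = None if errors is None else 1.0 / np.asarray(errors, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(t, y, order, w=w)
    dcoeffs = np.polynomial.polynomial.polyder(coeffs)
    cap = np.polynomial.polynomial.polyval(t, dcoeffs) * 1000.0  # kJ -> J
    if errors is not None:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, len(t)))
        for b in range(n_boot):
            yb = y + rng.normal(0.0, np.asarray(errors, dtype=float))
            cb = np.polynomial.polynomial.polyfit(t, yb, order, w=w)
            boots[b] = np.polynomial.polynomial.polyval(
                t, np.polynomial.polynomial.polyder(cb)
            ) * 1000.0
        cap_err = boots.std(axis=0, ddof=1)
    else:
        cap_err = np.zeros_like(cap)
    label = "C_P" if kind.upper() == "H" else "C_V"
    warnings.warn(
        "heat capacities from finite-bead PIMD are bead-convergence "
        "limited; treat as indicative of trends",
        stacklevel=2,
    )
    return HeatCapacityFit(t, cap, cap_err, coeffs, label)


def locate_density_maximum(
    temperatures: np.ndarray,
    values: np.ndarray,
    mode: str = "max",
    half_window: int = 3,
):
    """Extremum location from a local quadratic fit.

    ``mode='max'`` finds the rho(T) maximum at constant pressure;
    ``mode='min'`` the P(T) minimum at constant molar volume (the two
    locate the same density anomaly).  Returns ``(T_ext, T_err)`` or
    ``None`` when no interior extremum exists in range.
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(values, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    idx = int(np.argmax(y)) if mode == "max" else int(np.argmin(y))
    if idx == 0 or idx == len(t) - 1:
        return None
    lo = max(0, idx - half_window)
    hi = min(len(t), idx + half_window + 1)
    tt, yy = t[lo:hi], y[lo:hi]
    coeffs, cov = np.polyfit(tt - tt.mean(), yy, 2, cov=True)
    a, b = coeffs[0], coeffs[1]
    if (mode == "max" and a >= 0) or (mode == "min" and a <= 0):
        return None
    t_ext = tt.mean() - b / (2.0 * a)
    # first-order error propagation of the vertex location
    da, db = np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])
    t_err = abs(t_ext - tt.mean()) * np.sqrt(
        (da / a) ** 2 + (db / b) ** 2 if b != 0 else (da / a) ** 2
    )
    if not (t[0] <= t_ext <= t[-1]):
        return None
    return float(t_ext), float(t_err)
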
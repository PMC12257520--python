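#!/usr/bin/env python
"""Constant-pressure thermodynamics over a small temperature grid.

Desk-scale NPT runs of H2O (0.1 MPa) on a 6-point grid: density and
molar volume with blocked errors, compressibility from volume
fluctuations, C_P from a quartic fit of H(T), and the location of the
density maximum from a local quadratic fit (when an interior extremum
exists at this scale).  Writes results/thermo_h2o.csv.
"""

import os
import sys
import warnings

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from isopimd.engine import IntegratorSettings, run_simulation
from isopimd.forcefield import IsotopeSystem
from isopimd.thermo import (
    density_and_volume,
    heat_capacity_from_curve,
    isothermal_compressibility,
    locate_density_maximum,
)

ROOT = os.path.join(os.path.dirname(__file__), "..")
OUT = os.path.join(ROOT, "results")

T_GRID = (240.0, 260.0, 280.0, 300.0, 320.0, 340.0)
N_MOL, N_BEADS, SEED = 32, 8, 20240917


def main():
    os.makedirs(OUT, exist_ok=True)
    rows = []
    for temp in T_GRID:
        settings = IntegratorSettings(
            n_beads=N_BEADS, temperature=temp, ensemble="NPT", pressure=0.1,
            n_equil=8000, n_prod=12000, seed=SEED,
        )
        arc = run_simulation(IsotopeSystem(N_MOL, "H2O"), settings)
        dens = density_and_volume(arc)
        est = arc.estimator_frame()
        rows.append(
            {
                "T_K": temp,
                "rho_g_cm3": dens["rho"],
                "rho_err": dens["rho_err"],
                "v_cm3_mol": dens["v"],
                "kappa_T_per_GPa": isothermal_compressibility(arc.volumes, temp),
                "H_kJ_mol": est["enthalpy"].mean() / N_MOL,
                "H_err": est["enthalpy"].std(ddof=1)
                / np.sqrt(len(est) / 20)
                / N_MOL,
            }
        )
        print(f"T={temp:.0f} K  rho={dens['rho']:.3f} g/cm^3")
    table = pd.DataFrame(rows)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = heat_capacity_from_curve(
            table["T_K"], table["H_kJ_mol"], errors=table["H_err"], kind="H"
        )
    table["C_P_J_mol_K"] = fit.capacity
    table["C_P_err"] = fit.capacity_err

    tmax = locate_density_maximum(table["T_K"], table["rho_g_cm3"], mode="max")
    path = os.path.join(OUT, "thermo_h2o.csv")
    table.to_csv(path, index=False)
    print(table.to_string(index=False))
    if tmax is None:
        print("no interior density maximum resolved at desk scale")
    else:
        print(f"density maximum near T = {tmax[0]:.0f} +- {tmax[1]:.0f} K")
    print(
        "C_P from the quartic-H(T) route is bead-convergence limited at "
        "n_b = 8: treat values as trend indicators."
    )
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
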
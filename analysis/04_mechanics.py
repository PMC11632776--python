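"""Elastic constants from the three synthetic deformation directions.

For each pull axis: pressure-tensor series -> stress-strain curve ->
reflect-and-average smoothing -> Young's modulus (0.3-3% Hooke fit) and
maximum tensile strength (3-97%); transverse box response -> Poisson's
ratio (1-2%); Lame's relation -> bulk modulus.  Directions are aggregated
to mean +/- population std.  Also demonstrates the energy-delta bookkeeping
(E - E0 per strain).  Writes results/mechanics_summary.csv and
results/energy_deltas.csv.
"""

from pathlib import Path

import numpy as np

import mdprops as m

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "scratch" / "virtual_material"

if __name__ == "__main__":
    per_dir, rows = [], []
    for ax in "xyz":
        pz = m.read_table(
            open(SIM / f"stress_strain_{ax}.xvg"), dialect="engine",
            columns=[("strain", "dimensionless"), ("P_z", "bar")],
        )
        curve = m.smooth_reflect(m.stress_from_pressure(pz), half_width=0.025)
        E = m.youngs_modulus(curve)
        smax = m.max_stress(curve)
        deform = m.read_table(open(SIM / f"box_deformation_{ax}.csv"),
                              dialect="delimited")
        nu = m.poisson_ratio(deform)
        K = m.bulk_modulus(E.value, nu.value)
        per_dir.append(m.ElasticConstants(E=E.value, sigma_max=smax.value,
                                          nu=nu.value, K=K.value, flags=K.flags))
        print(f"direction {ax}: E={E.value:.3f} GPa, sigma_max={smax.value:.3f} GPa,"
              f" nu={nu.value:.4f}, K={K.value:.3f} GPa")
    agg = m.aggregate_directions(per_dir)
    (ROOT / "results").mkdir(exist_ok=True)
    m.write_results(
        [
            m.PropertyResult("youngs_modulus", agg.E, "GPa", error=agg.E_err),
            m.PropertyResult("max_stress", agg.sigma_max, "GPa",
                             error=agg.sigma_max_err),
            m.PropertyResult("poisson_ratio", agg.nu, "dimensionless",
                             error=agg.nu_err),
            m.PropertyResult("bulk_modulus", agg.K, "GPa", error=agg.K_err),
        ],
        str(ROOT / "results" / "mechanics_summary.csv"),
    )

    # energy-delta bookkeeping on a small synthetic energy table
    strains = np.linspace(0, 0.5, 11)
    energies = m.TimeSeriesTable(
        columns=[("strain", "dimensionless"), ("LJ", "kJ/mol"),
                 ("coulomb", "kJ/mol")],
        values=np.column_stack([strains, -5000 + 400 * strains**2,
                                -12000 + 150 * strains]),
    )
    m.write_table(m.delta_energy(energies),
                  str(ROOT / "results" / "energy_deltas.csv"))
    print(f"aggregate: E={agg.E:.3f}+/-{agg.E_err:.3f} GPa, "
          f"nu={agg.nu:.4f}+/-{agg.nu_err:.4f}, K={agg.K:.3f}+/-{agg.K_err:.3f} GPa"
          f" (truth E=3, nu=0.3, K=2.5)")
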
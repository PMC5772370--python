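"""Per-particle excipient stoichiometry for the two measured series.

Divides each formulation's molecules/mL by the measured particles/mL to get
molecules per particle and the particle molarity, for the chloroform-treated
DPPC liposome series (0.125 mM lipid) and the poloxamer-depleted SLN series
(10% w/v = 208 mmol/L cetyl palmitate).  Writes the two stoichiometry tables
under results/.
"""

from pathlib import Path

import pandas as pd

from colloidstat import io
from colloidstat.stoichiometry import (
    FormulationSpec,
    compute_stoichiometry,
    mass_fraction_to_molarity,
    molecules_per_ml,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def stoichiometry_table(series, formulation):
    rows = []
    for rec in series.records:
        st = compute_stoichiometry(formulation, rec.particles_per_ml)
        rows.append(
            {
                "condition": rec.condition_label,
                "size_nm": rec.size_nm,
                "particles_per_ml": rec.particles_per_ml,
                "molecules_per_particle": st.molecules_per_particle,
                "particle_molarity_mol_l": st.particle_molarity,
            }
        )
    return pd.DataFrame(rows)


def main():
    RESULTS.mkdir(exist_ok=True)

    dppc = FormulationSpec(excipient_name="DPPC", molar_concentration=1.25e-4)
    t1 = stoichiometry_table(io.load_table1_dppc(), dppc)
    t1.to_csv(RESULTS / "liposome_stoichiometry.csv", index=False)
    print(f"DPPC suspension holds {molecules_per_ml(1.25e-4):.3g} molecules/mL")
    print(t1.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print(
        "-> chloroform drives DPPC/liposome from "
        f"{t1.molecules_per_particle.iloc[0]:.2g} to "
        f"{t1.molecules_per_particle.iloc[-1]:.2g} (fewer, larger vesicles)\n"
    )

    cp_molar = mass_fraction_to_molarity(10.0, 480.85)
    cp = FormulationSpec(
        excipient_name="cetyl palmitate",
        molar_concentration=cp_molar,
        architecture="solid",
    )
    t2 = stoichiometry_table(io.load_table2_sln(), cp)
    t2.to_csv(RESULTS / "sln_stoichiometry.csv", index=False)
    print(f"10% w/v cetyl palmitate = {cp_molar * 1000:.0f} mmol/L")
    print(t2.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print(
        "-> surfactant depletion drives CP/SLN from "
        f"{t2.molecules_per_particle.iloc[0]:.2g} to "
        f"{t2.molecules_per_particle.iloc[-1]:.2g}"
    )


if __name__ == "__main__":
    main()
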
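#!/usr/bin/env python
"""Electrical characterization of the funnel pore.

Computes (i) the open-pore conductance of the C8 funnel geometry for a
range of electrolyte conductivities and diameter pairings, (ii) the GHK
cation/anion permeability ratio of the three pore stoichiometries from
their measured reversal potentials, and (iii) the single-ion currents
implied by MD-scale ion crossing rates.

Writes results/pore_characterization.csv and prints the headline numbers.
"""

from pathlib import Path

import pandas as pd

from nanofp.pore import (
    Diameter,
    IonConditions,
    YAXAB_C8,
    flux_to_current,
    funnel_conductance,
    ghk_selectivity,
)

OUT = Path("results")
OUT.mkdir(exist_ok=True)

rows = []

# conductance: cis entry x constriction is the default pairing
for sigma_s in (5.0, 10.5, 15.0):
    for d_in, d_out in [
        (Diameter.CIS_ENTRY, Diameter.CONSTRICTION),
        (Diameter.CIS_ENTRY, Diameter.TRANS_EXIT),
    ]:
        g = funnel_conductance(YAXAB_C8, sigma_s, d_in, d_out)
        rows.append(
            {
                "quantity": "conductance_nS",
                "detail": f"sigma_s={sigma_s} S/m, {d_in.value}x{d_out.value}",
                "value": round(g, 2),
            }
        )

# ion selectivity from the measured reversal potentials of the three pores
asym = IonConditions(
    cis_molarity=0.5,
    trans_molarity=2.0,
    cis_activity_coeff=0.649,
    trans_activity_coeff=0.573,
)
for label, vr in [("C8", 11.7), ("C9", 7.7), ("C10", 5.5)]:
    sel = ghk_selectivity(asym, vr)
    rows.append(
        {
            "quantity": "PK_over_PCl",
            "detail": f"{label}, Vr={vr} mV",
            "value": round(sel.permeability_ratio_PK_over_PCl, 2),
        }
    )

# flux -> current for the simulated ion crossing rates (open pore and with
# the protein trapped at the deep / shallow residence sites)
for detail, rate in [
    ("K+ open pore", 1.03),
    ("Cl- open pore", 0.52),
    ("K+ protein at deep site", 0.70),
    ("Cl- protein at deep site", 0.35),
    ("K+ protein at shallow site", 0.96),
    ("Cl- protein at shallow site", 0.42),
]:
    rows.append(
        {
            "quantity": "current_pA",
            "detail": detail,
            "value": round(flux_to_current(rate, 1)),
        }
    )

df = pd.DataFrame(rows)
df.to_csv(OUT / "pore_characterization.csv", index=False)
print(df.to_string(index=False))
print(
    "\nHeadline: C8 funnel conductance "
    f"{funnel_conductance(YAXAB_C8, 10.5):.2f} nS (cis entry x constriction, 10.5 S/m); "
    f"C8 selectivity P_K/P_Cl = "
    f"{ghk_selectivity(asym, 11.7).permeability_ratio_PK_over_PCl:.2f} — a strongly "
    "cation-selective pore, the prerequisite for electro-osmotic protein trapping."
)
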
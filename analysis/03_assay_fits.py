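"""Fit the enzyme assays: Michaelis-Menten kinetics, DSF melt, pH optimum.

Consumes the tables written by 01_simulate_inputs.py and writes fit
reports under results/.
"""

import json
from pathlib import Path

import pandas as pd

from rumizyme import assays

OUT = Path("results")
INP = OUT / "inputs"

mm_df = pd.read_csv(INP / "mm_velocities.tsv", sep="\t")
mm = assays.fit_michaelis_menten(
    assays.KineticsDataset(
        substrate_mg_ml=mm_df["substrate_mg_ml"].to_numpy(),
        velocity=mm_df["velocity"].to_numpy(),
        enzyme_conc_m=5e-8,
    )
)
print(f"Michaelis-Menten: kcat = {mm.kcat:.1f} +/- {mm.kcat_se:.1f} s^-1, "
      f"Km = {mm.km_mg_ml:.2f} +/- {mm.km_se:.2f} mg/ml")
print(f"catalytic efficiency kcat/Km = {mm.efficiency_m_s:.0f} M^-1 s^-1 "
      f"(xylose monomer, MW 150 g/mol)")

melt_df = pd.read_csv(INP / "melt_curve.tsv", sep="\t")
melt = assays.fit_boltzmann_melt(
    assays.MeltCurve(
        temperature_c=melt_df["temperature_C"].to_numpy(),
        fluorescence=melt_df["fluorescence"].to_numpy(),
    )
)
print(f"DSF: Tm = {melt.tm_c:.2f} degC, transition width = {melt.slope_c:.2f} degC "
      f"(r^2 = {melt.r_squared:.4f})")

ph_df = pd.read_csv(INP / "ph_profile.tsv", sep="\t")
optimum, ranking, tie = assays.ph_optimum(
    assays.PhActivityProfile(ph=ph_df["pH"].to_numpy(), activity=ph_df["activity"].to_numpy())
)
print(f"pH optimum = {optimum}" + (" (tie)" if tie else ""))

(OUT / "assay_fits.json").write_text(
    json.dumps(
        {
            "michaelis_menten": vars(mm),
            "dsf": vars(melt),
            "ph_optimum": optimum,
            "ph_ranking": ranking.to_dict(orient="records"),
        },
        indent=2,
    )
)
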
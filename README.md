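# rumizyme

Analysis pipeline for characterizing glycoside hydrolases recovered from
rumen microbial communities — the kind of enzymes (GH11 xylanases, GH45
endoglucanases) mined from metatranscriptomes and then characterized at
the bench. The package implements the full desk-side computational chain
of such a study:

- **Thermal-inactivation kinetics and thermodynamics** (`rumizyme.thermo`):
  first-order decay fits per temperature, Arrhenius analysis, half-life,
  decimal-reduction time, and the transition-state activation parameters.
- **Assay fitting** (`rumizyme.assays`): Michaelis–Menten kinetics, DSF
  (thermal-shift) Boltzmann melt curves, pH–activity optima.
- **Marker-peptide functional profiling** (`rumizyme.profiling`): greedy
  85%-identity clustering of protein families, extraction of cluster-unique
  marker peptides, abundance quantification in read sets, and the standard
  annotation-hit threshold filter (e ≤ 1e-5, identity ≥ 60, alignment ≥ 30).
- **Coulomb electrostatics** (`rumizyme.electrostatics`): the point-charge
  potential φ = Σ qᵢ/(ε·dᵢ) over partial-charge sets (TSV or PQR).
- **Synthetic data** (`rumizyme.simulate`): seeded generators for every
  input the pipeline consumes, so all stages run with no external data.

## The model at the core

Enzyme inactivation at a fixed temperature is treated as a first-order
process, ln(A/A₀) = −kt, with k obtained by linear regression of the log
residual activity on incubation time. Across temperatures the rate
constants follow the Arrhenius law ln k = −Eₐ/RT + c, and the activation
parameters of the inactivation step come from transition-state theory:

    t₁/₂ = ln 2 / k           D = ln 10 / k
    ΔH° = Eₐ − RT             ΔG° = −RT·ln(k·h / k_B·T)
    ΔS° = (ΔH° − ΔG°) / T

so D/t₁/₂ = ln 10 / ln 2 ≈ 3.3219 always holds, and ΔG° falling with T
signals progressive destabilization. Initial velocities follow
v₀ = k_cat[E]₀[S]₀/([S]₀ + K_M), and DSF melt curves follow the Boltzmann
sigmoid F(T) = F_min + (F_max − F_min)/(1 + exp((T_m − T)/slope)).

## Worked example

Run the numbered analyses (each is a thin driver over the library):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_inactivation_table.py
```

The second step prints the fitted thermodynamic table:

```
 temperature_C  k_per_min  t_half_min  d_value_min  dH_kJ_mol  dG_kJ_mol  dS_kJ_mol_K
          25.0     0.0017      407.73      1354.46     150.60      78.68         0.24
          40.0     0.0180       38.51       127.92     150.47      76.62         0.24
          50.0     0.2400        2.89         9.59     150.39      72.19         0.24
          60.0     0.9200        0.75         2.50     150.30      70.79         0.24

Arrhenius Ea = 153.07 kJ/mol (r^2 = 0.9859)
after 1 h: 9.7% lost at 25 degC, 34.0% remaining at 40 degC
```

Reading: the enzyme is very stable at 25 °C (half-life ~408 min, losing
under 10% activity in an hour) but k rises roughly ten-fold per 10 °C, so
at 60 °C activity decays within minutes. The near-constant ΔH° (~150
kJ/mol) and positive ΔS° mark an endothermic, disorder-increasing
unfolding as the rate-limiting step. `analysis/03`–`05` fit the kinetic
and melt assays (k_cat = 480 s⁻¹, K_M = 8.7 mg/ml, T_m = 55 °C recovered
from the simulated assays), run the marker-profiling chain (20 sequences
→ 5 clusters, planted marker counts recovered exactly over 500 reads),
and map the Coulomb potential of a toy charge set.

The same stages are available as a CLI: `rumizyme demo --seed 7`,
`rumizyme thermo-table --input courses.tsv --output table1.tsv`,
`rumizyme mm-fit`, `rumizyme dsf-fit`, `rumizyme cluster`,
`rumizyme quantify`, `rumizyme filter-hits`, `rumizyme coulomb`, …

Two unit conventions are deliberately explicit rather than silent: the
Eyring ΔG° uses rate constants expressed per hour by default (selectable;
see `docs/methods.md`), and catalytic efficiency is computed transparently
from k_cat, K_M and the monomer molecular weight.

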
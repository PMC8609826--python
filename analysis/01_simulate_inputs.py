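"""Generate every synthetic input dataset the downstream analyses consume.

Writes, under results/inputs/: decay time courses at the four published
inactivation rate constants, a Michaelis-Menten velocity table on the
published substrate grid, a DSF melt curve over the 25-95 degC scan, a
protein family database with truth table, and a peptide read set with
planted marker occurrences.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rumizyme import profiling, seqio, simulate
from rumizyme.pipeline import ASSAY_TIMES_MIN, DSF_GRID, SUBSTRATE_GRID, TABLE1_CONDITIONS
from rumizyme.simulate import FamilySimSpec, SimulationConfig

OUT = Path("results/inputs")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260923

cfg = SimulationConfig(seed=SEED, noise_sd=0.0)

rows = []
for temp, k in TABLE1_CONDITIONS.items():
    course = simulate.simulate_decay_course(k, ASSAY_TIMES_MIN, cfg, temperature_c=temp)
    rows.extend(
        {"temperature_C": temp, "time_min": t, "activity_pct": a}
        for t, a in zip(course.times_min, course.activities_pct)
    )
pd.DataFrame(rows).to_csv(OUT / "decay_courses.tsv", sep="\t", index=False)
print(f"decay courses: {len(TABLE1_CONDITIONS)} temperatures x {len(ASSAY_TIMES_MIN)} time points")

mm = simulate.simulate_mm(480.0, 8.7, 5e-8, SUBSTRATE_GRID, cfg)
pd.DataFrame({"substrate_mg_ml": mm.substrate_mg_ml, "velocity": mm.velocity}).to_csv(
    OUT / "mm_velocities.tsv", sep="\t", index=False
)
print(f"kinetics: {len(SUBSTRATE_GRID)} substrate levels, E0 = 5e-8 M")

melt = simulate.simulate_melt_curve(55.0, 1.2, 100.0, 1000.0, DSF_GRID, cfg)
pd.DataFrame({"temperature_C": melt.temperature_c, "fluorescence": melt.fluorescence}).to_csv(
    OUT / "melt_curve.tsv", sep="\t", index=False
)
print(f"melt curve: {len(DSF_GRID)} points, generating Tm = 55.0 degC")

ph = np.arange(4.0, 9.5, 0.5)
pd.DataFrame({"pH": ph, "activity": 100.0 * np.exp(-((ph - 6.0) ** 2) / 2.0)}).to_csv(
    OUT / "ph_profile.tsv", sep="\t", index=False
)

spec = FamilySimSpec(family_count=5, seqs_per_family=4, seq_length=120,
                     within_family_divergence=0.04)
db, truth = simulate.simulate_family_db(spec, SimulationConfig(seed=SEED + 1))
seqio.write_family_fasta(db, OUT / "family_db.fasta")
truth.to_csv(OUT / "family_truth.tsv", sep="\t", index=False)
print(f"family db: {len(db)} sequences in {spec.family_count} families")

clusters = profiling.cluster_proteins(db, threshold=0.85)
markers = profiling.extract_markers(clusters, db, min_marker_len=8)
planted = {m.marker_id: n for m, n in zip(markers.markers, (7, 3, 2, 5))}
read_length = max(len(m.peptide) for m in markers.markers) + 10
reads, read_truth = simulate.simulate_reads_with_markers(
    markers, planted, 500 - sum(planted.values()), read_length,
    SimulationConfig(seed=SEED + 2),
)
seqio.write_fastq(reads, OUT / "reads.fastq")
read_truth.to_csv(OUT / "read_truth.tsv", sep="\t", index=False)
print(f"reads: {len(reads)} x {read_length} aa, planted counts {tuple(planted.values())}")
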
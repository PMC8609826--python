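"""Coulomb potential map over a toy charge set, checked against the oracle.

Builds a small random set of partial charges, evaluates the potential on
a bounding-box grid, verifies the vectorized sum against a naive double
loop, and writes results/potential.tsv for import into a viewer.
"""

from pathlib import Path

import numpy as np

from rumizyme import electrostatics

OUT = Path("results")
SEED = 20260923

rng = np.random.default_rng(SEED)
charges = electrostatics.PointChargeSet(
    atom_ids=[f"a{i}" for i in range(50)],
    coords=rng.uniform(-10, 10, size=(50, 3)),
    charges=rng.uniform(-1, 1, size=50),
)
grid = electrostatics.bounding_box_grid(charges, spacing=4.0, margin=6.0)
result = electrostatics.potential_map(charges, grid)
result.to_dataframe().to_csv(OUT / "potential.tsv", sep="\t", index=False)

signs = {s: result.sign.count(s) for s in ("negative", "neutral", "positive")}
print(f"potential on {len(grid)} grid points: {signs}")

pt = rng.uniform(15, 25, size=3)
naive = sum(q / np.linalg.norm(pt - c) for c, q in zip(charges.coords, charges.charges))
fast = electrostatics.coulomb_potential(charges, pt)
print(f"oracle check at a random far point: |diff|/|phi| = "
      f"{abs(fast - naive) / abs(naive):.2e}")
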
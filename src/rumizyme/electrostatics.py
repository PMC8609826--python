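"""Coulomb electrostatic potential over point partial charges.

Evaluates phi(r) = prefactor * sum_i q_i / (epsilon * d_i), with d_i the
Euclidean distance from the query point to charge i. Units are those of
the inputs: with charges in elementary-charge units, distances in
angstroms and prefactor 1, phi is in e/(A*epsilon); the conventional
molecular-graphics prefactor 332.06 converts to kcal/mol per elementary
charge. A distance-dependent dielectric (epsilon = c * d) is available as
an option; the default is a constant dielectric, matching the plain
Coulomb sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "PointChargeSet",
    "PotentialResult",
    "SingularityError",
    "KCAL_MOL_PREFACTOR",
    "coulomb_potential",
    "potential_map",
    "read_charges_tsv",
    "read_pqr",
    "bounding_box_grid",
]

KCAL_MOL_PREFACTOR = 332.06


class SingularityError(ValueError):
    """A query point coincides (within min_distance) with a charge."""


@dataclass
class PointChargeSet:
    atom_ids: list[str]
    coords: np.ndarray  # (N, 3) angstrom
    charges: np.ndarray  # (N,) elementary-charge units
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        if self.coords.shape != (self.charges.size, 3):
            raise ValueError("coords must be (N, 3) matching N charges")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if len(self.atom_ids) != self.charges.size:
            raise ValueError("atom_ids must match charge count")


@dataclass
class PotentialResult:
    points: np.ndarray  # (M, 3)
    phi: np.ndarray  # (M,)
    sign: list[str]  # 'negative' / 'positive' / 'neutral' per point
    prefactor: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
                "phi": self.phi,
                "sign": self.sign,
            }
        )


def _phi(
    charges: PointChargeSet,
    points: np.ndarray,
    min_distance: float,
    prefactor: float,
    dielectric_model: Literal["constant", "distance"],
) -> np.ndarray:
    d = cdist(points, charges.coords)
    too_close = d < min_distance
    if np.any(too_close):
        pt_i, at_i = np.argwhere(too_close)[0]
        raise SingularityError(
            f"query point {pt_i} within {min_distance} A of atom "
            f"{charges.atom_ids[at_i]}"
        )
    if dielectric_model == "distance":
        denom = charges.epsilon * d * d  # epsilon = c*d screens as 1/d^2
    else:
        denom = charges.epsilon * d
    return prefactor * (charges.charges / denom).sum(axis=1)


def coulomb_potential(
    charges: PointChargeSet,
    point,
    min_distance: float = 1e-6,
    prefactor: float = 1.0,
    dielectric_model: Literal["constant", "distance"] = "constant",
) -> float:
    """Potential at a single query point."""
    pt = np.asarray(point, dtype=float).reshape(1, 3)
    return float(_phi(charges, pt, min_distance, prefactor, dielectric_model)[0])


def potential_map(
    charges: PointChargeSet,
    points,
    min_distance: float = 1e-6,
    prefactor: float = 1.0,
    sign_tolerance: float = 1e-9,
    dielectric_model: Literal["constant", "distance"] = "constant",
) -> PotentialResult:
    """Vectorized potential over many query points with sign classes."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points must be (M, 3)")
    phi = _phi(charges, pts, min_distance, prefactor, dielectric_model)
    sign = [
        "neutral" if abs(p) <= sign_tolerance else ("positive" if p > 0 else "negative")
        for p in phi
    ]
    return PotentialResult(points=pts, phi=phi, sign=sign, prefactor=prefactor)


def read_charges_tsv(path, epsilon: float = 1.0) -> PointChargeSet:
    """Read a 5-column TSV: atom_id, x, y, z, q."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["atom_id", "x", "y", "z", "q"], comment="#")
    return PointChargeSet(
        atom_ids=[str(a) for a in df["atom_id"]],
        coords=df[["x", "y", "z"]].to_numpy(float),
        charges=df["q"].to_numpy(float),
        epsilon=epsilon,
    )


def read_pqr(path, epsilon: float = 1.0) -> PointChargeSet:
    """Read ATOM/HETATM records of a whitespace-delimited PQR file.

    PQR is PDB-like with occupancy/B-factor replaced by charge and
    radius; a PDB file (no charge column) is rejected explicitly.
    """
    ids, coords, charges = [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            fields = line.split()
            if len(fields) < 10:
                raise ValueError(
                    "record has no charge column; PQR required, plain PDB "
                    "files carry no partial charges"
                )
            ids.append(f"{fields[2]}_{fields[1]}")
            coords.append([float(v) for v in fields[-5:-2]])
            charges.append(float(fields[-2]))
    if not ids:
        raise ValueError("no ATOM/HETATM records found")
    return PointChargeSet(
        atom_ids=ids,
        coords=np.array(coords),
        charges=np.array(charges),
        epsilon=epsilon,
    )


def bounding_box_grid(charges: PointChargeSet, spacing: float, margin: float = 5.0) -> np.ndarray:
    """Regular grid over the charge bounding box padded by ``margin`` A."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lo = charges.coords.min(axis=0) - margin
    hi = charges.coords.max(axis=0) + margin
    axes = [np.arange(lo[i], hi[i] + spacing / 2, spacing) for i in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)
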
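"""Synthetic-data generators for every pipeline stage.

Each generator draws from a seeded ``numpy.random.default_rng`` so that a
given seed and parameter set reproduces bit-identical data. Measurement
noise is additive Gaussian on the observable (activity percent, velocity,
fluorescence), truncated at physical lower bounds; assay-style replicate
wells (default 2) are drawn independently and averaged into the returned
observable, mirroring duplicate-well practice.

The family/read generators produce the fixtures the profiling stage needs:
protein families as point-mutated descendants of independent random
ancestors (i.i.d. per-site substitution to a uniformly random different
residue, no indels), and peptide read sets with marker peptides embedded a
known number of times in otherwise marker-free random background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import KineticsDataset, MeltCurve
from .profiling import AMINO_ACIDS, MarkerSet, ProteinFamilyDB, ProteinRecord
from .thermo import DecayTimeCourse

__all__ = [
    "SimulationConfig",
    "FamilySimSpec",
    "simulate_decay_course",
    "simulate_rate_series",
    "simulate_mm",
    "simulate_melt_curve",
    "simulate_family_db",
    "simulate_reads_with_markers",
]

GAS_CONSTANT = 8.314  # J mol-1 K-1


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    noise_sd: float = 0.0  # units of the simulated observable
    replicate_count: int = 2  # duplicate wells by default

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class FamilySimSpec:
    """Toy protein-family database layout (families of mutated variants)."""

    family_count: int = 4
    seqs_per_family: int = 5
    seq_length: int = 120
    within_family_divergence: float = 0.05  # per-site substitution prob
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        if self.family_count < 1 or self.seqs_per_family < 1 or self.seq_length < 1:
            raise ValueError("counts and lengths must be positive")
        if not 0.0 <= self.within_family_divergence < 0.5:
            raise ValueError("within_family_divergence must be in [0, 0.5)")


def _noisy(mean: np.ndarray, cfg: SimulationConfig, rng, lower: float | None):
    """Replicate-averaged Gaussian noise around ``mean``, clipped below."""
    reps = mean + rng.normal(0.0, cfg.noise_sd, size=(cfg.replicate_count,) + mean.shape) \
        if cfg.noise_sd > 0 else np.broadcast_to(mean, (cfg.replicate_count,) + mean.shape)
    out = reps.mean(axis=0)
    if lower is not None:
        out = np.maximum(out, lower)
    return out


def simulate_decay_course(
    k: float, times, cfg: SimulationConfig, temperature_c: float = 25.0
) -> DecayTimeCourse:
    """First-order activity decay: mean residual activity 100*exp(-k t) %."""
    if k < 0:
        raise ValueError("rate constant must be nonnegative")
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(times < 0) or np.any(np.diff(times) <= 0)):
        raise ValueError("times must be nonnegative and strictly increasing")
    mean = 100.0 * np.exp(-k * times)
    activities = _noisy(mean, cfg, cfg.rng(), lower=0.0)
    return DecayTimeCourse(
        temperature_c=temperature_c,
        times_min=times,
        activities_pct=activities,
        a0=100.0,
    )


def simulate_rate_series(ea_j_mol: float, c: float, temperatures_k) -> list[tuple[float, float]]:
    """Arrhenius rate constants k(T) = exp(c - Ea/(R T)), noiseless."""
    if ea_j_mol < 0:
        raise ValueError("activation energy must be nonnegative")
    temps = np.asarray(temperatures_k, dtype=float)
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive kelvin")
    return [(float(T), float(np.exp(c - ea_j_mol / (GAS_CONSTANT * T)))) for T in temps]


def simulate_mm(
    kcat: float, km: float, e0: float, substrate, cfg: SimulationConfig,
    monomer_mw: float = 150.0,
) -> KineticsDataset:
    """Michaelis-Menten velocities kcat*E0*S/(S+Km) with assay noise."""
    if kcat <= 0 or km <= 0 or e0 <= 0:
        raise ValueError("kcat, Km and E0 must be positive")
    s = np.asarray(substrate, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentrations must be nonnegative")
    mean = kcat * e0 * s / (s + km)
    v = _noisy(mean, cfg, cfg.rng(), lower=0.0)
    return KineticsDataset(
        substrate_mg_ml=s, velocity=v, enzyme_conc_m=e0, monomer_mw=monomer_mw
    )


def simulate_melt_curve(
    tm_c: float, slope_c: float, f_min: float, f_max: float,
    temperatures_c, cfg: SimulationConfig,
    buffer_label: str = "", ph: float | None = None,
) -> MeltCurve:
    """Boltzmann-sigmoid melt curve with Gaussian fluorescence noise."""
    if slope_c <= 0:
        raise ValueError("slope must be positive")
    if f_max <= f_min:
        raise ValueError("Fmax must exceed Fmin")
    t = np.asarray(temperatures_c, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    mean = f_min + (f_max - f_min) / (1.0 + np.exp((tm_c - t) / slope_c))
    f = _noisy(mean, cfg, cfg.rng(), lower=None)
    return MeltCurve(temperature_c=t, fluorescence=f, buffer_label=buffer_label, ph=ph)


def _random_peptide(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float, alphabet: str) -> str:
    if rate == 0.0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        others = alphabet.replace(chars[i], "")
        chars[i] = others[rng.integers(len(others))]
    return "".join(chars)


def simulate_family_db(
    spec: FamilySimSpec, cfg: SimulationConfig
) -> tuple[ProteinFamilyDB, pd.DataFrame]:
    """Protein families as mutated descendants of random ancestors.

    Returns the database plus a truth table (seq_id, family, n_mutations).
    Expected pairwise identity between two members of one family is
    (1-d)^2 + d^2/19 per site, d = within_family_divergence.
    """
    rng = cfg.rng()
    records: list[ProteinRecord] = []
    truth_rows = []
    for fam in range(spec.family_count):
        family = f"fam{fam:02d}"
        ancestor = _random_peptide(rng, spec.seq_length, spec.alphabet)
        for j in range(spec.seqs_per_family):
            seq = _mutate(rng, ancestor, spec.within_family_divergence, spec.alphabet)
            seq_id = f"{family}_s{j:02d}"
            records.append(ProteinRecord(seq_id=seq_id, family=family, sequence=seq))
            truth_rows.append(
                {
                    "seq_id": seq_id,
                    "family": family,
                    "n_mutations": sum(a != b for a, b in zip(seq, ancestor)),
                }
            )
    return ProteinFamilyDB(records=records), pd.DataFrame(truth_rows)


def simulate_reads_with_markers(
    markers: MarkerSet,
    planted_copies: dict[str, int],
    background_read_count: int,
    read_length: int,
    cfg: SimulationConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Peptide reads with each marker embedded exactly its planted count.

    Background reads are rejection-sampled so that no marker occurs in
    them by chance; each planted read carries exactly one marker at a
    random offset. Returns (reads as (id, sequence) pairs, truth table of
    placements). Reads are shuffled so planted reads are not positional.
    """
    peptides = {m.marker_id: m.peptide for m in markers.markers}
    unknown = set(planted_copies) - set(peptides)
    if unknown:
        raise ValueError(f"unknown marker ids: {sorted(unknown)}")
    longest = max((len(p) for p in peptides.values()), default=0)
    if read_length < longest:
        raise ValueError(
            f"read_length {read_length} shorter than longest marker ({longest})"
        )
    rng = cfg.rng()
    all_peptides = list(peptides.values())

    def background() -> str:
        while True:
            s = _random_peptide(rng, read_length, AMINO_ACIDS)
            if not any(p in s for p in all_peptides):
                return s

    reads: list[tuple[str, str]] = []
    truth_rows = []
    idx = 0
    for marker_id in sorted(planted_copies):
        pep = peptides[marker_id]
        for _ in range(planted_copies[marker_id]):
            offset = int(rng.integers(0, read_length - len(pep) + 1))
            body = background()
            seq = body[:offset] + pep + body[offset + len(pep):]
            # embedding must not create a second marker occurrence
            if sum(seq.count(p) for p in all_peptides) != 1:
                seq = pep + background()[len(pep):]
                offset = 0
            read_id = f"read{idx:05d}"
            reads.append((read_id, seq))
            truth_rows.append({"read_id": read_id, "marker_id": marker_id, "offset": offset})
            idx += 1
    for _ in range(background_read_count):
        reads.append((f"read{idx:05d}", background()))
        idx += 1
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]
    return reads, pd.DataFrame(truth_rows, columns=["read_id", "marker_id", "offset"])
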
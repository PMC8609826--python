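"""Targeted functional profiling of protein families via marker peptides.

Desk-scale analogue of marker-based family quantification: protein family
members are grouped by greedy centroid clustering at an amino-acid identity
threshold (default 85%), each cluster's centroid is scanned for peptide
windows that occur in no sequence outside the cluster (the cluster's
*markers*), and marker occurrences are counted in a read set to give a
length- and depth-normalized abundance per cluster. A separate helper
applies the standard annotation-hit thresholds (e-value, percent identity,
alignment length) to BLAST-like tabular hits.

The marker scheme here is deliberately explicit and simple: fixed-length
windows, exact-substring uniqueness against all out-of-cluster sequences,
overlapping unique windows merged into maximal unique regions. It is a
simplification of ShortBRED-style quasi/true-marker construction, not a
re-implementation of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "ProteinRecord",
    "ProteinFamilyDB",
    "Cluster",
    "ClusterSet",
    "Marker",
    "MarkerSet",
    "AbundanceProfile",
    "AnnotationHit",
    "pairwise_identity",
    "cluster_proteins",
    "extract_markers",
    "quantify_markers",
    "filter_annotation_hits",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = AMINO_ACIDS + "X"


@dataclass(frozen=True)
class ProteinRecord:
    seq_id: str
    family: str
    sequence: str


@dataclass
class ProteinFamilyDB:
    """Protein records with family labels; ids unique, 20-letter alphabet
    (X permitted but never counts as a match)."""

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        ids = [r.seq_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids must be unique")
        for r in self.records:
            bad = set(r.sequence) - set(_ALPHABET)
            if bad:
                raise ValueError(f"{r.seq_id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, seq_id: str) -> ProteinRecord:
        for r in self.records:
            if r.seq_id == seq_id:
                return r
        raise KeyError(seq_id)


@dataclass
class Cluster:
    centroid_id: str
    member_ids: list[str]


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    identity_threshold: float


@dataclass(frozen=True)
class Marker:
    marker_id: str
    cluster_id: str
    peptide: str


@dataclass
class MarkerSet:
    markers: list[Marker]
    min_marker_len: int
    markerless_clusters: list[str] = field(default_factory=list)


@dataclass
class AbundanceProfile:
    """Raw and normalized marker counts in a read set.

    Normalization is an RPKM analogue on amino-acid length:
    count / (marker_length_aa * total_reads / 1e6). Cluster-level values
    aggregate (sum) over the cluster's markers.
    """

    marker_counts: dict[str, int]
    cluster_counts: dict[str, int]
    normalized: dict[str, float]
    cluster_normalized: dict[str, float]
    total_reads: int
    skipped_markers: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class AnnotationHit:
    query_id: str
    subject_id: str
    e_value: float
    percent_identity: float
    alignment_length: int


def _make_aligner() -> PairwiseAligner:
    # identity scoring: match +1, mismatch 0, affine gaps open -10 / extend -1;
    # X scores 0 against everything including itself (never a match)
    mat = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in AMINO_ACIDS:
        mat[a, a] = 1.0
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matching columns / alignment length.

    The alignment maximizes matches under an identity scoring scheme
    (match +1, mismatch 0, gap open -10, gap extend -1). ``X`` never
    counts as a match.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(
        1 for ca, cb in zip(a, b) if ca == cb and ca != "-" and ca != "X"
    )
    return matches / len(a)


def cluster_proteins(db: ProteinFamilyDB, threshold: float = 0.85) -> ClusterSet:
    """Greedy centroid clustering at an identity threshold.

    Sequences are visited in order of decreasing length (ties broken by
    lexicographic id); each joins the first existing centroid it matches
    at >= ``threshold`` identity, otherwise it founds a new cluster.
    """
    if not db.records:
        raise ValueError("empty database")
    order = sorted(db.records, key=lambda r: (-len(r.sequence), r.seq_id))
    clusters: list[Cluster] = []
    centroids: list[ProteinRecord] = []
    for rec in order:
        for cl, cen in zip(clusters, centroids):
            if pairwise_identity(rec.sequence, cen.sequence) >= threshold:
                cl.member_ids.append(rec.seq_id)
                break
        else:
            clusters.append(Cluster(centroid_id=rec.seq_id, member_ids=[rec.seq_id]))
            centroids.append(rec)
    return ClusterSet(clusters=clusters, identity_threshold=threshold)


def _merge_windows(starts: list[int], win: int) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent windows [s, s+win) into maximal regions."""
    if not starts:
        return []
    regions: list[tuple[int, int]] = []
    lo = hi = None
    for s in sorted(starts):
        if lo is None:
            lo, hi = s, s + win
        elif s <= hi:  # overlap or abut
            hi = max(hi, s + win)
        else:
            regions.append((lo, hi))
            lo, hi = s, s + win
    regions.append((lo, hi))
    return regions


def extract_markers(
    clusters: ClusterSet,
    db: ProteinFamilyDB,
    min_marker_len: int = 8,
    max_markers_per_cluster: int = 50,
) -> MarkerSet:
    """Extract cluster-unique marker peptides from cluster centroids.

    Every window of ``min_marker_len`` residues on the centroid that does
    not occur as an exact substring in any sequence outside the cluster is
    kept; overlapping kept windows merge into maximal unique regions, of
    which the ``max_markers_per_cluster`` longest become the markers.
    Clusters without any unique window are flagged, not an error.
    """
    by_id = {r.seq_id: r for r in db.records}
    markers: list[Marker] = []
    markerless: list[str] = []
    for cl in clusters.clusters:
        centroid = by_id[cl.centroid_id].sequence
        members = set(cl.member_ids)
        foreign = [r.sequence for r in db.records if r.seq_id not in members]
        n_win = len(centroid) - min_marker_len + 1
        kept = [
            s
            for s in range(max(n_win, 0))
            if not any(centroid[s : s + min_marker_len] in f for f in foreign)
        ]
        regions = _merge_windows(kept, min_marker_len)
        regions.sort(key=lambda r: (-(r[1] - r[0]), r[0]))
        regions = regions[:max_markers_per_cluster]
        if not regions:
            markerless.append(cl.centroid_id)
            continue
        for i, (lo, hi) in enumerate(sorted(regions)):
            markers.append(
                Marker(
                    marker_id=f"{cl.centroid_id}|m{i:02d}",
                    cluster_id=cl.centroid_id,
                    peptide=centroid[lo:hi],
                )
            )
    return MarkerSet(
        markers=markers, min_marker_len=min_marker_len, markerless_clusters=markerless
    )


def _six_frame_peptides(read: str) -> list[str]:
    """All six reading frames, standard code, split at stop codons."""
    peptides: list[str] = []
    seq = Seq(read)
    for strand in (seq, seq.reverse_complement()):
        for offset in range(3):
            sub = strand[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) >= 3:
                peptides.extend(p for p in str(sub.translate()).split("*") if p)
    return peptides


def quantify_markers(
    markers: MarkerSet,
    reads: Iterable[tuple[str, str]],
    translate: bool = False,
) -> AbundanceProfile:
    """Count exact marker occurrences in reads (peptide or six-frame).

    Each read increments at most one marker: markers are tried in order
    of descending peptide length (ties broken by marker id) and the first
    that matches wins. Markers longer than the read length never match
    and are reported as skipped.
    """
    reads = list(reads)
    order = sorted(markers.markers, key=lambda m: (-len(m.peptide), m.marker_id))
    counts = {m.marker_id: 0 for m in order}
    max_read_len = max((len(s) for _, s in reads), default=0)
    skipped = [m.marker_id for m in order if len(m.peptide) > max_read_len]
    for _, read in reads:
        targets = _six_frame_peptides(read) if translate else [read]
        for m in order:
            if any(m.peptide in t for t in targets):
                counts[m.marker_id] += 1
                break
    total = len(reads)
    scale = total / 1e6
    by_marker_len = {m.marker_id: len(m.peptide) for m in order}
    normalized = {
        mid: (c / (by_marker_len[mid] * scale) if scale > 0 else 0.0)
        for mid, c in counts.items()
    }
    cluster_counts: dict[str, int] = {}
    cluster_norm: dict[str, float] = {}
    for m in order:
        cluster_counts[m.cluster_id] = cluster_counts.get(m.cluster_id, 0) + counts[m.marker_id]
        cluster_norm[m.cluster_id] = cluster_norm.get(m.cluster_id, 0.0) + normalized[m.marker_id]
    return AbundanceProfile(
        marker_counts=counts,
        cluster_counts=cluster_counts,
        normalized=normalized,
        cluster_normalized=cluster_norm,
        total_reads=total,
        skipped_markers=skipped,
    )


def filter_annotation_hits(
    hits: Sequence[AnnotationHit],
    max_e: float = 1e-5,
    min_identity: float = 60.0,
    min_aln: int = 30,
) -> list[AnnotationHit]:
    """Keep hits passing all three thresholds; boundaries inclusive.

    Input order is preserved. Thresholds follow the conventional
    annotation filter: e-value <= max_e, percent identity >= min_identity,
    alignment length >= min_aln.
    """
    return [
        h
        for h in hits
        if h.e_value <= max_e
        and h.percent_identity >= min_identity
        and h.alignment_length >= min_aln
    ]


def read_hits_tsv(path) -> tuple[list[AnnotationHit], int]:
    """Read BLAST outfmt-6-like TSV (qseqid, sseqid, pident, length, evalue).

    Malformed rows are rejected per-row; returns (hits, rejected_count).
    """
    hits: list[AnnotationHit] = []
    rejected = 0
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["qseqid", "sseqid", "pident", "length", "evalue"],
        dtype=str,
        comment="#",
    )
    for row in df.itertuples(index=False):
        try:
            pid = float(row.pident)
            length = int(float(row.length))
            ev = float(row.evalue)
            if not (0.0 <= pid <= 100.0) or ev < 0 or length < 0:
                raise ValueError
            hits.append(AnnotationHit(str(row.qseqid), str(row.sseqid), ev, pid, length))
        except (TypeError, ValueError):
            rejected += 1
    return hits, rejected
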
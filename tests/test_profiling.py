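"""Clustering, marker extraction, quantification and hit filtering."""

import numpy as np
import pytest

from rumizyme.profiling import (
    AnnotationHit,
    Marker,
    MarkerSet,
    ProteinFamilyDB,
    ProteinRecord,
    cluster_proteins,
    extract_markers,
    filter_annotation_hits,
    pairwise_identity,
    quantify_markers,
    read_hits_tsv,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def gotoh_score(a: str, b: str, match=1.0, mismatch=0.0, gap_open=-10.0, gap_ext=-1.0):
    """Independent affine-gap global alignment score (Gotoh DP).

    Gap scoring matches the package's aligner: the first gapped residue
    costs ``gap_open`` and each further residue ``gap_ext``.
    """
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (a aligned to '-')
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_ext
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_ext,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_ext,
                          X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


def mutate(rng, seq, n_sub):
    chars = list(seq)
    for i in rng.choice(len(chars), size=n_sub, replace=False):
        chars[i] = AA[(AA.index(chars[i]) + 1 + rng.integers(19)) % 20]
    return "".join(chars)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKTAYIAK", "MKTAYIAK") == 1.0

    def test_single_substitution(self):
        assert pairwise_identity("AAAA", "AAAT") == 0.75

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "AAAA")

    def test_x_never_matches(self):
        assert pairwise_identity("AXAX", "AXAX") == 0.5

    def test_gapped_alignment_identity(self):
        # one internal deletion: 9 matches over 10 alignment columns
        assert pairwise_identity("MKTAYIAKQR", "MKTAYIAQR"[:4] + "IAKQR") >= 0.8

    def test_substitution_only_pairs_match_hamming_oracle(self):
        # with gap open -10, substitution-only optima dominate at low
        # divergence, so identity must equal the per-site match fraction
        rng = np.random.default_rng(21)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=100))
            b = mutate(rng, a, int(rng.integers(0, 15)))
            hamming = sum(x == y for x, y in zip(a, b)) / 100
            assert pairwise_identity(a, b) == pytest.approx(hamming, rel=1e-12)

    def test_alignment_score_matches_gotoh_dp_oracle(self):
        rng = np.random.default_rng(22)
        from rumizyme.profiling import _ALIGNER

        for _ in range(10):
            la, lb = rng.integers(20, 60, size=2)
            a = "".join(rng.choice(list(AA), size=la))
            b = "".join(rng.choice(list(AA), size=lb))
            assert _ALIGNER.score(a, b) == pytest.approx(gotoh_score(a, b), rel=1e-12)


def db_from(seqs: dict[str, str], family: str = "f") -> ProteinFamilyDB:
    return ProteinFamilyDB(
        records=[ProteinRecord(sid, family, s) for sid, s in seqs.items()]
    )


class TestClustering:
    def test_identical_input_single_cluster(self):
        db = db_from({f"s{i}": "MKTAYIAKQRMKTAYIAKQR" for i in range(4)})
        clusters = cluster_proteins(db)
        assert len(clusters.clusters) == 1
        assert sorted(clusters.clusters[0].member_ids) == ["s0", "s1", "s2", "s3"]

    def test_outlier_founds_its_own_cluster(self):
        base = "MKTAYIAKQRLMNDEFGHWC" * 2
        rng = np.random.default_rng(7)
        near = mutate(rng, base, 3)  # 92.5% identity
        far = "".join(rng.choice(list(AA), size=40))
        db = db_from({"a": base, "b": near, "c": far})
        clusters = cluster_proteins(db, threshold=0.85)
        assert len(clusters.clusters) == 2
        # verified against the exhaustive identity matrix
        assert pairwise_identity(base, near) >= 0.85
        assert pairwise_identity(base, far) < 0.85

    def test_threshold_one_groups_exact_duplicates_only(self):
        db = db_from({"a": "MKTAYIAKQR", "b": "MKTAYIAKQR", "c": "MKTAYIAKQW"})
        clusters = cluster_proteins(db, threshold=1.0)
        sizes = sorted(len(c.member_ids) for c in clusters.clusters)
        assert sizes == [1, 2]

    def test_partition_and_identity_bound(self, toy_family):
        db, _ = toy_family
        clusters = cluster_proteins(db, threshold=0.85)
        members = [m for c in clusters.clusters for m in c.member_ids]
        assert sorted(members) == sorted(r.seq_id for r in db.records)
        for c in clusters.clusters:
            centroid = db.get(c.centroid_id).sequence
            for mid in c.member_ids:
                assert pairwise_identity(db.get(mid).sequence, centroid) >= 0.85

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            cluster_proteins(ProteinFamilyDB(records=[]))


class TestMarkerExtraction:
    def test_disjoint_alphabets_make_whole_centroid_unique(self):
        db = db_from({"a": "ACDEFGHIKL" * 2}, "f1")
        db.records += [ProteinRecord("b", "f2", "MNPQRSTVWY" * 2)]
        clusters = cluster_proteins(db, threshold=0.85)
        markers = extract_markers(clusters, db, min_marker_len=8)
        by_cluster = {m.cluster_id: m for m in markers.markers}
        assert by_cluster["a"].peptide == "ACDEFGHIKL" * 2
        assert by_cluster["b"].peptide == "MNPQRSTVWY" * 2

    def test_centroid_identical_to_foreign_sequence_yields_no_markers(self):
        seq = "MKTAYIAKQRLMNDEFGHWC"
        db = db_from({"a": seq}, "f1")
        db.records += [ProteinRecord("b", "f2", seq)]
        clusters = cluster_proteins(db, threshold=1.1)  # force separate clusters
        markers = extract_markers(clusters, db)
        assert markers.markers == []
        assert set(markers.markerless_clusters) == {"a", "b"}

    def test_marker_uniqueness_against_exhaustive_substring_oracle(self, toy_family):
        db, _ = toy_family
        clusters = cluster_proteins(db, threshold=0.85)
        markers = extract_markers(clusters, db, min_marker_len=8)
        assert markers.markers
        members = {c.centroid_id: set(c.member_ids) for c in clusters.clusters}
        for m in markers.markers:
            assert len(m.peptide) >= 8
            centroid_seq = db.get(m.cluster_id).sequence
            assert m.peptide in centroid_seq
            for rec in db.records:
                if rec.seq_id not in members[m.cluster_id]:
                    assert m.peptide not in rec.sequence

    def test_max_markers_per_cluster_truncates(self):
        # centroid alternating pattern against a distant foreign sequence:
        # every window unique, merge yields one region, cap respected
        db = db_from({"a": "ACACACACACAC"}, "f1")
        db.records += [ProteinRecord("b", "f2", "WYWYWYWYWYWY")]
        clusters = cluster_proteins(db, threshold=0.85)
        markers = extract_markers(clusters, db, min_marker_len=4, max_markers_per_cluster=1)
        per_cluster = {}
        for m in markers.markers:
            per_cluster[m.cluster_id] = per_cluster.get(m.cluster_id, 0) + 1
        assert all(n <= 1 for n in per_cluster.values())


class TestQuantification:
    def test_no_reads_all_zero(self):
        markers = MarkerSet([Marker("m1", "c1", "WWWWHHHH")], 8)
        profile = quantify_markers(markers, [])
        assert profile.marker_counts == {"m1": 0}
        assert profile.total_reads == 0

    def test_read_increments_at_most_one_marker(self):
        markers = MarkerSet(
            [Marker("long", "c1", "WWWWHHHHKKKK"), Marker("short", "c1", "WWWWHHHH")], 8
        )
        # read contains both peptides (short is a prefix of long):
        # the longest marker wins and the read is consumed
        profile = quantify_markers(markers, [("r1", "AAWWWWHHHHKKKKAA")])
        assert profile.marker_counts == {"long": 1, "short": 0}
        assert sum(profile.marker_counts.values()) <= 1

    def test_normalization_halves_when_background_doubles(self):
        markers = MarkerSet([Marker("m1", "c1", "WWWWHHHH")], 8)
        hit = ("r0", "CCWWWWHHHHCC")
        filler = [(f"b{i}", "ACDEFGHIKLMN") for i in range(9)]
        p1 = quantify_markers(markers, [hit] + filler)
        p2 = quantify_markers(markers, [hit] + filler * 2 + [("x", "ACDEFGHIKLMN")])
        assert p1.marker_counts["m1"] == p2.marker_counts["m1"] == 1
        assert p2.normalized["m1"] == pytest.approx(p1.normalized["m1"] / 2)

    def test_six_frame_translation_finds_encoded_marker(self):
        from Bio.Seq import Seq

        pep = "WHKDEC"
        markers = MarkerSet([Marker("m1", "c1", pep)], 6)
        # reverse-complement the coding sequence so only frame -1 matches
        nt = str(Seq("TGGCATAAAGATGAATGC").reverse_complement())
        profile = quantify_markers(markers, [("r1", "ACG" + nt)], translate=True)
        assert profile.marker_counts["m1"] == 1

    def test_marker_longer_than_reads_is_skipped(self):
        markers = MarkerSet([Marker("m1", "c1", "W" * 30)], 8)
        profile = quantify_markers(markers, [("r1", "ACDEFGHIKL")])
        assert profile.skipped_markers == ["m1"]
        assert profile.marker_counts["m1"] == 0

    def test_cluster_counts_aggregate_markers(self):
        markers = MarkerSet(
            [Marker("m1", "c1", "WWWWHHHH"), Marker("m2", "c1", "DDDDEEEE")], 8
        )
        reads = [("r1", "XWWWWHHHHX".replace("X", "A")), ("r2", "ADDDDEEEEA")]
        profile = quantify_markers(markers, reads)
        assert profile.cluster_counts["c1"] == 2


class TestHitFilter:
    TOY = [
        AnnotationHit("q1", "s1", 1e-8, 80.0, 50),   # passes all
        AnnotationHit("q2", "s2", 1e-5, 60.0, 30),   # exactly at thresholds
        AnnotationHit("q3", "s3", 1e-3, 90.0, 60),   # e-value too large
        AnnotationHit("q4", "s4", 1e-9, 40.0, 60),   # identity too low
        AnnotationHit("q5", "s5", 1e-9, 90.0, 10),   # alignment too short
        AnnotationHit("q6", "s6", 2e-5, 61.0, 31),   # e-value just over
    ]

    def test_empty_input(self):
        assert filter_annotation_hits([]) == []

    def test_boundary_hit_is_kept(self):
        kept = filter_annotation_hits([AnnotationHit("q", "s", 1e-5, 60.0, 30)])
        assert len(kept) == 1

    def test_toy_table_enumerated_survivors(self):
        kept = filter_annotation_hits(self.TOY)
        assert [h.query_id for h in kept] == ["q1", "q2"]

    def test_idempotent_and_order_preserving(self):
        kept = filter_annotation_hits(self.TOY)
        assert filter_annotation_hits(kept) == kept

    def test_tsv_round_trip_with_malformed_row(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\ts1\t80.0\t50\t1e-8\n"
            "q2\ts2\tnot_a_number\t30\t1e-5\n"
            "q3\ts3\t90.0\t60\t1e-3\n"
        )
        hits, rejected = read_hits_tsv(path)
        assert rejected == 1
        assert len(hits) == 2
        assert len(filter_annotation_hits(hits)) == 1
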
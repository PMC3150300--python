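"""Annotation loading, cluster construction, paralog collapsing, refinement."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircluster import annotation as ann
from mircluster.correlation import CorrelationReport

from conftest import arm_seq, make_gene, random_genes


def write_gff_fasta(genes, tmp_path, name="test"):
    gff = tmp_path / f"{name}.gff3"
    fa = tmp_path / f"{name}.fa"
    ann.write_gff3(genes, gff)
    ann.write_mature_fasta(genes, fa)
    return gff, fa


# ---------------------------------------------------------------------------
# Loading and validation


def test_gff3_round_trip_two_precursors_four_arms(tmp_path):
    genes = [make_gene(1, 1000), make_gene(2, 5000, strand="-")]
    gff, fa = write_gff_fasta(genes, tmp_path)
    loaded = ann.load_annotation(gff, fa)
    assert len(loaded) == 2
    by_id = {g.gene_id: g for g in loaded}
    for g in genes:
        h = by_id[g.gene_id]
        assert (h.precursor_start, h.precursor_end) == (
            g.precursor_start, g.precursor_end)
        assert h.strand == g.strand
        assert h.mir_arm.sequence == g.mir_arm.sequence
        assert h.star_arm.sequence == g.star_arm.sequence
        assert h.mir_arm.arm_role == ann.MIR
        assert h.star_arm.arm_role == ann.STAR


def test_identical_mir_sequences_share_paralog_group(tmp_path):
    shared = arm_seq(500)
    genes = [
        make_gene(1, 1000, gene_id="dme-mir-281-1", mir_seq=shared),
        make_gene(2, 3000, gene_id="dme-mir-281-2", mir_seq=shared),
        make_gene(3, 9000),
    ]
    gff, fa = write_gff_fasta(genes, tmp_path)
    loaded = {g.gene_id: g for g in ann.load_annotation(gff, fa)}
    assert (
        loaded["dme-mir-281-1"].paralog_group
        == loaded["dme-mir-281-2"].paralog_group
    )
    assert loaded["dme-mir-3"].paralog_group != loaded["dme-mir-281-1"].paralog_group


def test_arm_outside_precursor_is_validation_error():
    with pytest.raises(ann.AnnotationError, match="outside precursor"):
        ann.MiRNAGene(
            "g", "chrT", "+", 100, 190,
            ann.ArmRecord("g", 100, 122, arm_seq(0), ann.MIR),
            ann.ArmRecord("g*", 180, 202, arm_seq(1), ann.STAR),
        )


def test_malformed_gff_coordinates_name_the_line(tmp_path):
    bad = tmp_path / "bad.gff3"
    bad.write_text(
        "##gff-version 3\n"
        "chrT\t.\tmiRNA_primary_transcript\t10\tfoo\t.\t+\t.\tID=x\n"
    )
    with pytest.raises(ann.AnnotationParseError, match=r"bad\.gff3:2"):
        ann.load_annotation(bad)


def test_bed6_round_trip(tmp_path):
    genes = [make_gene(1, 1000), make_gene(2, 5000, strand="-")]
    bed = tmp_path / "genes.bed"
    lines = []
    for g in genes:
        lines.append(f"{g.chrom}\t{g.precursor_start}\t{g.precursor_end}\t"
                     f"precursor:{g.gene_id}\t.\t{g.strand}")
        lines.append(f"{g.chrom}\t{g.mir_arm.start}\t{g.mir_arm.end}\t"
                     f"mir:{g.gene_id}:{g.mir_arm.arm_id}\t.\t{g.strand}")
        lines.append(f"{g.chrom}\t{g.star_arm.start}\t{g.star_arm.end}\t"
                     f"star:{g.gene_id}:{g.star_arm.arm_id}\t.\t{g.strand}")
    bed.write_text("\n".join(lines) + "\n")
    fa = tmp_path / "m.fa"
    ann.write_mature_fasta(genes, fa)
    loaded = ann.load_annotation(bed, fa)
    assert {g.gene_id for g in loaded} == {"dme-mir-1", "dme-mir-2"}
    assert all(g.mir_arm.sequence for g in loaded)


# ---------------------------------------------------------------------------
# build_clusters


def brute_force_clusters(genes, max_gap, same_strand=True):
    """Independent oracle: transitive closure of the pairwise gap relation."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(g.gene_id for g in genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if a.chrom != b.chrom:
                continue
            if same_strand and a.strand != b.strand:
                continue
            lo, hi = sorted([a, b], key=lambda g: g.precursor_start)
            if hi.precursor_start - lo.precursor_end <= max_gap:
                G.add_edge(a.gene_id, b.gene_id)
    comps = [frozenset(c) for c in nx.connected_components(G)]
    clusters = {c for c in comps if len(c) >= 2}
    singles = {next(iter(c)) for c in comps if len(c) == 1}
    return clusters, singles


@pytest.mark.parametrize("gap,expect_cluster", [(1000, True), (1001, False)])
def test_one_kb_boundary_is_inclusive(gap, expect_cluster):
    a = make_gene(1, 1000)
    b = make_gene(2, a.precursor_end + gap)
    res = ann.build_clusters([a, b])
    if expect_cluster:
        assert len(res.clusters) == 1 and res.clusters[0].gaps == [gap]
        assert res.nonclustered == []
    else:
        assert res.clusters == []
        assert sorted(res.nonclustered) == ["dme-mir-1", "dme-mir-2"]


def test_chaining_joins_three_genes():
    a = make_gene(1, 1000)
    b = make_gene(2, a.precursor_end + 200)
    c = make_gene(3, b.precursor_end + 999)
    res = ann.build_clusters([c, a, b])  # shuffled input
    assert len(res.clusters) == 1
    assert res.clusters[0].members == ["dme-mir-1", "dme-mir-2", "dme-mir-3"]
    assert res.clusters[0].gaps == [200, 999]


def test_clusters_match_brute_force_on_random_annotations(rng):
    for _ in range(30):
        genes = random_genes(rng, 50)
        res = ann.build_clusters(genes)
        got_clusters = {frozenset(c.members) for c in res.clusters}
        got_singles = set(res.nonclustered)
        want_clusters, want_singles = brute_force_clusters(genes, 1000)
        assert got_clusters == want_clusters
        assert got_singles == want_singles


def test_clustering_is_a_partition_and_permutation_invariant(rng):
    genes = random_genes(rng, 60)
    res = ann.build_clusters(genes)
    covered = [m for c in res.clusters for m in c.members] + res.nonclustered
    assert sorted(covered) == sorted(g.gene_id for g in genes)
    shuffled = list(genes)
    rng.shuffle(shuffled)
    res2 = ann.build_clusters(shuffled)
    assert [c.members for c in res2.clusters] == [c.members for c in res.clusters]
    assert res2.nonclustered == res.nonclustered


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_larger_max_gap_never_fragments(seed):
    g = np.random.default_rng(seed)
    genes = random_genes(g, 25)
    counts = []
    for max_gap in (200, 1000, 5000):
        res = ann.build_clusters(genes, max_gap=max_gap)
        counts.append(len(res.clusters) + len(res.nonclustered))
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# Paralog collapsing


def _cluster_of(genes):
    res = ann.build_clusters(genes)
    assert len(res.clusters) == 1
    return res.clusters[0]


def test_identical_tandem_copies_collapse_to_one_member():
    shared_mir, shared_star = arm_seq(300), arm_seq(301)
    genes = []
    pos = 1000
    for gid in ["dme-mir-6-1", "dme-mir-6-2", "dme-mir-6-3"]:
        genes.append(make_gene(0, pos, gene_id=gid,
                               mir_seq=shared_mir, star_seq=shared_star))
        pos += 200
    genes.append(make_gene(9, pos, gene_id="dme-mir-309"))
    ann.assign_paralog_groups(genes)
    cluster = _cluster_of(genes)
    collapsed = ann.collapse_paralogs_within_cluster(
        cluster, {g.gene_id: g for g in genes})
    assert collapsed.members == ["dme-mir-6-1", "dme-mir-309"]
    assert collapsed.collapsed == {"dme-mir-6-1": ["dme-mir-6-2", "dme-mir-6-3"]}
    assert not collapsed.excluded


def test_fully_degenerate_cluster_is_excluded():
    shared = arm_seq(400)
    genes = [
        make_gene(0, 1000, gene_id="dme-mir-281-1", mir_seq=shared,
                  star_seq=arm_seq(401)),
        make_gene(1, 1400, gene_id="dme-mir-281-2", mir_seq=shared,
                  star_seq=arm_seq(401)),
    ]
    ann.assign_paralog_groups(genes)
    collapsed = ann.collapse_paralogs_within_cluster(
        _cluster_of(genes), {g.gene_id: g for g in genes})
    assert collapsed.excluded
    assert collapsed.members == ["dme-mir-281-1"]


def test_collapse_without_shared_groups_is_identity():
    genes = [make_gene(1, 1000), make_gene(2, 1500)]
    ann.assign_paralog_groups(genes)
    cluster = _cluster_of(genes)
    assert ann.collapse_paralogs_within_cluster(
        cluster, {g.gene_id: g for g in genes}) is cluster


# ---------------------------------------------------------------------------
# Correlation-based refinement


def _fake_report(members_r):
    arm_ids = sorted({a for pair in members_r for a in pair})
    rep = CorrelationReport(arm_ids=arm_ids, n_libraries=9)
    for (a, b), v in members_r.items():
        rep._r[frozenset((a, b))] = v
    return rep


def _chain(n, start=1000, gap=300):
    genes = []
    pos = start
    for i in range(1, n + 1):
        g = make_gene(i, pos)
        genes.append(g)
        pos = g.precursor_end + gap
    return genes


def test_refinement_splits_at_decorrelated_boundary():
    genes = _chain(6)
    gmap = {g.gene_id: g for g in genes}
    cluster = _cluster_of(genes)
    ids = cluster.members
    r = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            both_left = a in ids[:4] and b in ids[:4]
            both_right = a in ids[4:] and b in ids[4:]
            r[(a, b)] = 0.9 if (both_left or both_right) else 0.1
    parts = ann.refine_clusters_by_correlation(cluster, _fake_report(r), gmap)
    assert [p.members for p in parts] == [ids[:4], ids[4:]]
    # split sub-clusters renamed from their own extremes
    assert parts[0].cluster_id == "1~4"
    assert parts[1].cluster_id == "5~6"


def test_refinement_leaves_uniformly_correlated_cluster_alone():
    genes = _chain(4)
    gmap = {g.gene_id: g for g in genes}
    cluster = _cluster_of(genes)
    r = {(a, b): 0.9 for i, a in enumerate(cluster.members)
         for b in cluster.members[i + 1:]}
    assert ann.refine_clusters_by_correlation(
        cluster, _fake_report(r), gmap) == [cluster]


def test_refinement_never_emits_singletons():
    # two members, hopelessly uncorrelated: still one cluster (the
    # correlation module reports the low pair; refinement only separates
    # multi-member sub-runs)
    genes = _chain(2)
    gmap = {g.gene_id: g for g in genes}
    cluster = _cluster_of(genes)
    r = {(cluster.members[0], cluster.members[1]): -0.5}
    assert ann.refine_clusters_by_correlation(
        cluster, _fake_report(r), gmap) == [cluster]
    # three members with a 2+1 pattern must not split either
    genes3 = _chain(3)
    gmap3 = {g.gene_id: g for g in genes3}
    cluster3 = _cluster_of(genes3)
    ids = cluster3.members
    r3 = {(ids[0], ids[1]): 0.9, (ids[0], ids[2]): 0.1, (ids[1], ids[2]): 0.1}
    assert ann.refine_clusters_by_correlation(
        cluster3, _fake_report(r3), gmap3) == [cluster3]


def test_refinement_skips_with_warning_on_missing_r():
    genes = _chain(4)
    gmap = {g.gene_id: g for g in genes}
    cluster = _cluster_of(genes)
    ids = cluster.members
    r = {(ids[0], ids[1]): 0.9}  # most pairs missing
    with pytest.warns(UserWarning, match="missing correlation"):
        parts = ann.refine_clusters_by_correlation(cluster, _fake_report(r), gmap)
    assert parts == [cluster]
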
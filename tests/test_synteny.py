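"""Cluster detection, linkage classification, coupling and edge flags."""

import pytest

from pily_profiler.core_io import GeneFeature
from pily_profiler.synteny import (classify_linkage, detect_clusters,
                                   detect_translational_coupling, edge_flag)


def genes(spec, contig="c1", strand="+", gap=100, glen=900, start=1000):
    """Build features from a list of roles (or (role, gap_before) tuples)."""
    feats = []
    pos = start
    for i, item in enumerate(spec):
        role, gap_before = item if isinstance(item, tuple) else (item, gap)
        if i > 0:
            pos = feats[-1].end + 1 + gap_before
        feats.append(GeneFeature(contig=contig, start=pos,
                                 end=pos + glen - 1, strand=strand,
                                 locus_tag=f"{contig}_g{i}", role=role))
    return feats


class TestDetectClusters:
    def test_minor_cluster_with_trailing_non_role_gene(self):
        feats = genes(["fimU", "pilV", "pilW", "pilX", "pilY1", "other"])
        calls = detect_clusters(feats)
        assert len(calls) == 1
        call = calls[0]
        assert call.cluster_type == "minor_cluster"
        assert call.pilY1_tags == ["c1_g4"]
        assert call.roles == ["fimU", "pilV", "pilW", "pilX", "pilY1"]

    def test_pily1_embedded_in_major_cluster(self):
        feats = genes(["pilQ", "pilP", "pilO", "pilN", "pilM",
                       "fimU", "pilV", "pilW", "pilX", "pilY1",
                       "pilB", "pilT", "pilC", "pilA"])
        calls = detect_clusters(feats)
        assert [c.cluster_type for c in calls] == ["major_embedded_pilY1"]

    def test_major_cluster_without_pily1(self):
        feats = genes(["pilQ", "pilP", "pilO", "pilN", "pilM", "pilA"])
        assert [c.cluster_type for c in detect_clusters(feats)] == \
            ["major_cluster"]

    def test_distant_pily1_is_solitary(self):
        spec = ["pilX"] + ["other"] * 10 + [("pilY1", 100)]
        feats = genes(spec)
        calls = detect_clusters(feats)
        solitary = [c for c in calls if "pilY1" in c.roles]
        assert [c.cluster_type for c in solitary] == ["solitary_pilY1"]

    def test_gap_bp_rule_breaks_cluster(self):
        feats = genes(["pilX", "pilW", ("pilY1", 5000)])
        types = {c.cluster_type for c in detect_clusters(feats)}
        assert types == {"solitary_pilY1"}  # pilX+pilW run is untyped

    def test_unsorted_input_error(self):
        feats = genes(["pilX", "pilY1"])[::-1]
        with pytest.raises(ValueError, match="sorted"):
            detect_clusters(feats)

    def test_partition_no_tag_in_two_clusters(self):
        feats = genes(["fimU", "pilV", "pilW", "pilX", "pilY1",
                       ("pilQ", 4000), "pilP", "pilO", "pilN", "pilM",
                       "pilA"])
        calls = detect_clusters(feats)
        tags = [t for c in calls for t in c.members]
        assert len(tags) == len(set(tags))

    def test_reversal_invariance(self):
        feats = genes(["fimU", "pilV", "pilW", "pilX", "pilY1", "other"])
        total = max(f.end for f in feats) + 1000
        mirrored = sorted(
            (GeneFeature(contig=f.contig, start=total - f.end,
                         end=total - f.start,
                         strand="-" if f.strand == "+" else "+",
                         locus_tag=f.locus_tag, role=f.role)
             for f in feats), key=lambda f: f.start)
        fwd = detect_clusters(feats)
        rev = detect_clusters(mirrored)
        assert [sorted(c.members) for c in fwd] == \
            [sorted(c.members) for c in rev]
        assert [c.cluster_type for c in fwd] == [c.cluster_type for c in rev]


class TestLinkage:
    def test_adjacent_pilx_linked(self):
        feats = genes(["pilX", "pilY1"])
        calls = classify_linkage(feats)
        assert len(calls) == 1
        assert calls[0].status == "linked"
        assert calls[0].evidence == [("pilX", -1)]

    def test_only_other_neighbours_unlinked(self):
        feats = genes(["other", "other", "pilY1", "other"])
        assert [c.status for c in classify_linkage(feats)] == ["unlinked"]

    def test_window_respected(self):
        spec = ["pilX"] + ["other"] * 6 + ["pilY1"]
        feats = genes(spec)
        assert classify_linkage(feats)[0].status == "unlinked"
        assert classify_linkage(feats, window_genes=7)[0].status == "linked"

    def test_every_pily1_classified_exactly_once(self):
        spec = ["pilY1"] + ["other"] * 7 + ["pilY1", "pilX", "pilY1"]
        feats = genes(spec)
        calls = classify_linkage(feats)
        assert sorted(c.pilY1_tag for c in calls) == \
            ["c1_g0", "c1_g10", "c1_g8"]
        statuses = {c.pilY1_tag: c.status for c in calls}
        assert statuses["c1_g0"] == "unlinked"  # pilX 9 genes away
        assert statuses["c1_g8"] == "linked"
        assert statuses["c1_g10"] == "linked"


class TestCoupling:
    def test_four_bp_overlap_coupled(self):
        a = GeneFeature(contig="c", start=100, end=400, strand="+",
                        locus_tag="a", role="tfcP")
        b = GeneFeature(contig="c", start=397, end=900, strand="+",
                        locus_tag="b", role="pilY1")
        assert detect_translational_coupling([a, b]) == [("a", "b")]

    def test_large_gap_not_coupled(self):
        feats = genes(["pilX", ("pilY1", 200)])
        assert detect_translational_coupling(feats) == []

    def test_opposite_strands_never_coupled(self):
        a = GeneFeature(contig="c", start=100, end=400, strand="+",
                        locus_tag="a", role="other")
        b = GeneFeature(contig="c", start=399, end=900, strand="-",
                        locus_tag="b", role="other")
        assert detect_translational_coupling([a, b]) == []

    def test_minus_strand_upstream_is_rightmost(self):
        a = GeneFeature(contig="c", start=100, end=400, strand="-",
                        locus_tag="left", role="other")
        b = GeneFeature(contig="c", start=399, end=900, strand="-",
                        locus_tag="right", role="other")
        assert detect_translational_coupling([a, b]) == [("right", "left")]


class TestEdgeFlag:
    def test_interior_gene_not_flagged(self):
        feats = genes([("pilY1", 0)], start=5000, glen=1300)
        assert edge_flag(feats, "c1_g0", {"c1": 1_000_000}) is False

    def test_near_contig_end_flagged(self):
        feats = genes([("pilY1", 0)], start=8000, glen=1300)
        # ends 9299; contig length 9799 -> 500 bp from the end
        assert edge_flag(feats, "c1_g0", {"c1": 9799}) is True

    def test_missing_length_unknown(self, caplog):
        feats = genes(["pilY1"])
        assert edge_flag(feats, "c1_g0", {}) is None
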
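"""Gene-cluster detection and genomic-context classification of pilY1.

In most Myxococcota the adhesin gene *pilY1* sits in a minor-pilin operon
with *pilX*, *pilW*, *pilV* and *fimU* ("linked"); in some lineages the
whole minor set is embedded inside the major pilin cluster, and in others
*pilY1* occurs solitary elsewhere on the chromosome ("unlinked").  Adjacent
genes of an operon are frequently translationally coupled through
overlapping or abutting stop/start codons (e.g. the cytochrome gene *tfcP*
immediately upstream of *pilY1.1*).  This module classifies all three
phenomena from role-annotated gene features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core_io import (GeneFeature, MAJOR_CLUSTER_ROLES, MINOR_PILIN_ROLES)

logger = logging.getLogger(__name__)


@dataclass
class ClusterCall:
    """A detected run of T4aP-role genes on one contig."""

    contig: str
    members: list[str]                 # locus_tags in genomic order
    roles: list[str]                   # role per member
    start: int
    end: int
    cluster_type: str                  # minor_cluster | major_cluster |
    #                                    major_embedded_pilY1 | solitary_pilY1
    pilY1_tags: list[str] = field(default_factory=list)
    coupling_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class LinkageCall:
    """Linked/unlinked status of one pilY1 gene, with the minor-pilin
    neighbours found and their signed gene distances as evidence."""

    pilY1_tag: str
    status: str                        # linked | unlinked
    evidence: list[tuple[str, int]] = field(default_factory=list)


def _per_contig(features: list[GeneFeature],
                check_sorted: bool = True) -> dict[str, list[GeneFeature]]:
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_contig.setdefault(f.contig, []).append(f)
    if check_sorted:
        for contig, feats in by_contig.items():
            starts = [f.start for f in feats]
            if starts != sorted(starts):
                raise ValueError(
                    f"features on contig {contig} are not sorted by start")
    return by_contig


def _cluster_type(roles: list[str]) -> str | None:
    role_set = set(roles)
    n_core = len(role_set & set(MAJOR_CLUSTER_ROLES))
    n_minor = len(role_set & set(MINOR_PILIN_ROLES))
    has_pily1 = "pilY1" in role_set
    is_major = n_core >= 5
    is_minor = has_pily1 and n_minor >= 2
    if is_major and is_minor:
        return "major_embedded_pilY1"
    if is_major:
        return "major_cluster"
    if is_minor:
        return "minor_cluster"
    return None


def detect_clusters(features: list[GeneFeature], max_gap_genes: int = 2,
                    max_gap_bp: int = 3000) -> list[ClusterCall]:
    """Greedy chaining of T4aP-role genes into clusters.

    Two role-bearing genes join one cluster when at most ``max_gap_genes``
    non-role genes intervene *and* the intergenic span between them is at
    most ``max_gap_bp``.  Cluster typing: a run with >=5 distinct core
    roles is a major cluster; pilY1 plus >=2 of the four minor pilins makes
    a minor cluster; both at once is a pilY1-embedded major cluster.  A
    pilY1 whose run meets neither test is reported solitary.
    """
    calls: list[ClusterCall] = []
    for contig, feats in _per_contig(features).items():
        runs: list[list[int]] = []
        current: list[int] = []
        for idx, f in enumerate(feats):
            if f.role == "other":
                continue
            if current:
                prev = feats[current[-1]]
                intervening = idx - current[-1] - 1
                span = f.start - prev.end - 1
                if intervening <= max_gap_genes and span <= max_gap_bp:
                    current.append(idx)
                    continue
                runs.append(current)
            current = [idx]
        if current:
            runs.append(current)
        for run in runs:
            members = [feats[i] for i in run]
            roles = [f.role for f in members]
            ctype = _cluster_type(roles)
            pily1 = [f.locus_tag for f in members if f.role == "pilY1"]
            if ctype is None:
                if not pily1:
                    continue  # role genes with no pilY1 and no typed cluster
                ctype = "solitary_pilY1"
            # coupling among the full genomic span of the run (operon
            # neighbours, intervening non-role genes included)
            span_feats = feats[run[0]:run[-1] + 1]
            coupling = detect_translational_coupling(span_feats)
            calls.append(ClusterCall(
                contig=contig,
                members=[f.locus_tag for f in members],
                roles=roles,
                start=members[0].start, end=members[-1].end,
                cluster_type=ctype, pilY1_tags=pily1,
                coupling_pairs=coupling))
    return calls


def classify_linkage(features: list[GeneFeature],
                     window_genes: int = 5) -> list[LinkageCall]:
    """Per pilY1 gene: linked iff any minor-pilin gene (pilX/pilW/pilV/fimU)
    lies within ``window_genes`` genes on the same contig; strand ignored."""
    calls: list[LinkageCall] = []
    for _contig, feats in _per_contig(features, check_sorted=False).items():
        feats = sorted(feats, key=lambda f: (f.start, f.end))
        for idx, f in enumerate(feats):
            if f.role != "pilY1":
                continue
            evidence: list[tuple[str, int]] = []
            lo = max(0, idx - window_genes)
            hi = min(len(feats), idx + window_genes + 1)
            for j in range(lo, hi):
                if j == idx:
                    continue
                if feats[j].role in MINOR_PILIN_ROLES:
                    evidence.append((feats[j].role, j - idx))
            calls.append(LinkageCall(
                pilY1_tag=f.locus_tag,
                status="linked" if evidence else "unlinked",
                evidence=sorted(evidence, key=lambda e: (abs(e[1]), e[1]))))
    return calls


def detect_translational_coupling(features: list[GeneFeature],
                                  max_overlap_gap: int = 4
                                  ) -> list[tuple[str, str]]:
    """Report consecutive same-contig, same-strand CDS pairs whose
    intergenic distance ``g = next.start - prev.end - 1`` is at most
    ``max_overlap_gap`` bp (overlaps give negative g and always qualify)."""
    pairs: list[tuple[str, str]] = []
    for _contig, feats in _per_contig(features, check_sorted=False).items():
        feats = sorted(feats, key=lambda f: (f.start, f.end))
        for prev, nxt in zip(feats, feats[1:]):
            if prev.strand != nxt.strand:
                continue
            g = nxt.start - prev.end - 1
            if g <= max_overlap_gap:
                if prev.strand == "+":
                    pairs.append((prev.locus_tag, nxt.locus_tag))
                else:  # upstream gene is the rightmost one on the minus strand
                    pairs.append((nxt.locus_tag, prev.locus_tag))
    return pairs


def edge_flag(features: list[GeneFeature], pilY1_tag: str,
              contig_lengths: dict[str, int],
              margin_bp: int = 2000) -> bool | None:
    """Assembly-artifact caveat: does the pilY1 CDS start or end within
    ``margin_bp`` of a contig boundary?  Returns None (with a warning) when
    the contig length is unknown."""
    feat = next((f for f in features if f.locus_tag == pilY1_tag), None)
    if feat is None:
        raise ValueError(f"no feature with locus_tag {pilY1_tag!r}")
    length = contig_lengths.get(feat.contig)
    if length is None:
        logger.warning("contig %s: length unknown (no ##sequence-region); "
                       "edge flag for %s undetermined", feat.contig, pilY1_tag)
        return None
    return (feat.start - 1 < margin_bp) or (length - feat.end < margin_bp)
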
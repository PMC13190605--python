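"""Distance tree, clade assignment, clade summaries and ordination.

Clade structure among PilY1 homologs is recovered from the pairwise
percent-identity matrix: a neighbor-joining tree over d = 100 - identity,
clade labels propagated from reference exemplars (each query inherits the
clade of the smallest exemplar-spanning subtree containing it, falling back
to the nearest exemplar by distance), per-clade feature summaries, and a
principal component analysis of the identity-matrix rows.

Neighbor joining is implemented here rather than delegated so that the
tie-break (lowest index pair on equal Q) and the negative-branch-length
policy (clamp to zero, deficit moved to the sibling branch) are part of the
contract; trees are represented as :class:`skbio.TreeNode` and serialized
as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .align import DistanceMatrix
from .motifs import MOTIF_NAMES

#: clade -> N-terminal domain expected by the clade architectures
EXPECTED_DOMAIN = {
    "1.1": "DUF4114", "1.2": "DUF4114",
    "1.3": "vWFA", "1.4b": "vWFA", "1.5": "vWFA", "1.6": "vWFA",
    "1.7": "vWFA",
    "1.4a": None, "1.4c": None,
}


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Neighbor joining (Saitou-Nei Q criterion) over d = 100 - identity.

    Deterministic: on ties the lowest (i, j) index pair in the current
    working order is joined.  Negative branch lengths are clamped to zero
    and the deficit moved to the sibling branch.  The root trifurcates
    (unrooted binary topology).
    """
    ids = list(matrix.ids)
    if len(ids) < 3:
        raise ValueError("need at least three taxa")
    D = matrix.distance.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) with i < j among minima
        iu = np.triu_indices(n, k=1)
        qvals = Q[iu]
        kmin = int(np.flatnonzero(qvals == qvals.min())[0])
        i, j = int(iu[0][kmin]), int(iu[1][kmin])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(li)
        child_j.length = float(lj)
        parent = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([np.column_stack([D[np.ix_(keep, keep)],
                                        dnew[keep][:, None]]),
                       np.append(dnew[keep], 0.0)[None, :]])
        nodes = [nodes[k] for k in keep] + [parent]

    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length, b.length, c.length = (max(0.0, float(v)) for v in (la, lb, lc))
    return TreeNode(children=[a, b, c])


@dataclass
class CladeAssignment:
    """One protein's clade label with its supporting evidence."""

    protein_id: str
    clade: str                      # one of the clade labels or "unassigned"
    nearest_exemplar: str
    nearest_distance: float
    via: str                        # "exemplar" | "subtree" | "nearest"
    domain_consistent: bool = True


def _exemplar_leafsets(tree: TreeNode,
                       exemplars: dict[str, list[str]]
                       ) -> dict[str, frozenset[str]]:
    leafsets = {}
    tip_names = {t.name for t in tree.tips()}
    for clade, ids in exemplars.items():
        missing = set(ids) - tip_names
        if missing:
            raise ValueError(f"exemplars {sorted(missing)} absent from tree")
        if len(ids) == 1:
            leafsets[clade] = frozenset(ids)
        else:
            lca = tree.lca(ids)
            leafsets[clade] = frozenset(t.name for t in lca.tips())
    return leafsets


def assign_clades(tree: TreeNode, profiles, exemplars: dict[str, list[str]],
                  matrix: DistanceMatrix,
                  unassigned_ceiling: float = 75.0
                  ) -> list[CladeAssignment]:
    """Label every protein in ``matrix`` with a clade.

    ``exemplars`` maps clade label -> reference protein ids (all must be
    tree tips).  A query inherits the clade of the smallest
    exemplar-spanning subtree containing it; when contained in none, or in
    several equally small ones (conflict), it falls back to the nearest
    exemplar by matrix distance — and only in that fallback, when that
    distance exceeds ``unassigned_ceiling``, is it left "unassigned".
    Assignments inconsistent with the expected clade domain architecture
    keep their label but are flagged.
    """
    if not exemplars:
        raise ValueError("at least one exemplar clade is required")
    leafsets = _exemplar_leafsets(tree, exemplars)
    exemplar_clade = {pid: clade for clade, ids in exemplars.items()
                      for pid in ids}
    prof_by_id = {p.protein_id: p for p in profiles}
    D = matrix.distance
    ex_ids = sorted(exemplar_clade)
    ex_idx = [matrix.index(pid) for pid in ex_ids]

    out: list[CladeAssignment] = []
    for qi, pid in enumerate(matrix.ids):
        dists = D[qi, ex_idx]
        k = int(np.argmin(dists))
        nearest, ndist = ex_ids[k], float(dists[k])
        if pid in exemplar_clade:
            clade, via = exemplar_clade[pid], "exemplar"
        else:
            containing = sorted(
                (len(ls), clade) for clade, ls in leafsets.items()
                if pid in ls)
            if containing and (len(containing) == 1
                               or containing[0][0] < containing[1][0]):
                clade, via = containing[0][1], "subtree"
            else:
                conflict = bool(containing)  # equally small subtrees
                if conflict and ndist > unassigned_ceiling:
                    clade, via = "unassigned", "nearest"
                else:
                    clade, via = exemplar_clade[nearest], "nearest"
        consistent = True
        prof = prof_by_id.get(pid)
        if prof is not None and clade in EXPECTED_DOMAIN:
            expected = EXPECTED_DOMAIN[clade]
            has = prof.domain_flags
            if expected is None:
                consistent = not has.get("DUF4114") and not has.get("vWFA")
            else:
                other = "vWFA" if expected == "DUF4114" else "DUF4114"
                consistent = bool(has.get(expected)) and not has.get(other)
        out.append(CladeAssignment(
            protein_id=pid, clade=clade, nearest_exemplar=nearest,
            nearest_distance=ndist, via=via, domain_consistent=consistent))
    return out


def clade_summary(assignments, profiles) -> pd.DataFrame:
    """Per-clade feature summary: n, length and cysteine-count
    median/min/max, and motif-presence fractions."""
    prof_by_id = {p.protein_id: p for p in profiles}
    rows = []
    by_clade: dict[str, list] = {}
    for a in assignments:
        prof = prof_by_id.get(a.protein_id)
        if prof is not None:
            by_clade.setdefault(a.clade, []).append(prof)
    for clade in sorted(by_clade):
        profs = by_clade[clade]
        lengths = np.array([p.length for p in profs])
        cys = np.array([p.n_cys for p in profs])
        row = {
            "clade": clade, "n": len(profs),
            "length_median": float(np.median(lengths)),
            "length_min": int(lengths.min()),
            "length_max": int(lengths.max()),
            "n_cys_median": float(np.median(cys)),
            "n_cys_min": int(cys.min()), "n_cys_max": int(cys.max()),
        }
        for m in MOTIF_NAMES:
            row[f"frac_{m}"] = float(
                np.mean([bool(p.hits.get(m)) for p in profs]))
        row["frac_all_three_ca"] = float(
            np.mean([p.all_three_ca for p in profs]))
        rows.append(row)
    return pd.DataFrame(rows)


def pca_identity(matrix: DistanceMatrix, k: int = 2
                 ) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the identity-matrix rows.

    Rows are treated as feature vectors and column-centered; scores along
    the top-k principal axes are returned together with the explained-
    variance fractions.  Sign convention: the largest-magnitude loading of
    each component is positive.
    """
    n = len(matrix.ids)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of ids {n}")
    X = matrix.identity - matrix.identity.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for comp in range(min(k, len(S))):
        imax = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, imax] < 0:
            Vt[comp] *= -1.0
            U[:, comp] *= -1.0
    scores = U[:, :k] * S[:k]
    var = S ** 2
    explained = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    return scores, explained
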
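"""Rigid-body superposition RMSD and geometric disulfide-bridge detection.

Structural conservation among PilY1 models is quantified by least-squares
superposition (Kabsch algorithm: centroid alignment, covariance SVD,
reflection fix) of CA atoms paired by residue index, reported as RMSD in
Angstrom.  Cysteine-rich PilY1 variants form disulfide bridges; bridges are
called geometrically from SG-SG distances with a greedy matching so that
each cysteine joins at most one bridge.

The default superposition uses every paired atom.  An optional iterative
outlier-rejection mode (drop pairs beyond ``cutoff`` standard deviations of
the pair-deviation distribution, re-fit, up to ``cycles`` times) mimics the
behaviour of interactive viewers that trim poorly superposable regions;
the mode used is recorded in the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_io import StructureModel

logger = logging.getLogger(__name__)


@dataclass
class Superposition:
    rotation: np.ndarray      # 3x3 proper orthogonal (det +1)
    translation: np.ndarray   # 3-vector, Angstrom
    rmsd: float               # Angstrom
    n_pairs: int
    mode: str = "all_pairs"   # all_pairs | outlier_reject


@dataclass
class DisulfidePair:
    res_i: int
    res_j: int
    sg_distance: float


def pair_atoms(model_a: StructureModel, model_b: StructureModel,
               atom_name: str = "CA") -> tuple[np.ndarray, np.ndarray,
                                               list[int]]:
    """Pair atoms of the given name by shared residue index.

    Returns coordinate arrays (n, 3) for both models in ascending residue
    index, plus the paired indices.  Fewer than three pairs is an error
    (superposition underdetermined).
    """
    ca = model_a.coords(atom_name)
    cb = model_b.coords(atom_name)
    shared = sorted(set(ca) & set(cb))
    unpaired = (set(ca) | set(cb)) - set(shared)
    if unpaired:
        logger.info("%s/%s: %d residues unpaired for %s", model_a.model_id,
                    model_b.model_id, len(unpaired), atom_name)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared {atom_name} atoms between "
            f"{model_a.model_id} and {model_b.model_id}; need >= 3")
    A = np.array([ca[i] for i in shared], dtype=float)
    B = np.array([cb[i] for i in shared], dtype=float)
    return A, B, shared


def _kabsch(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                   float]:
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    F = np.diag([1.0, 1.0, d])
    R = Vt.T @ F @ U.T            # rotation applied to A coordinates
    t = cb - R @ ca
    diff = (A @ R.T + t) - B
    rmsd = float(np.sqrt((diff ** 2).sum() / len(A)))
    return R, t, rmsd


def kabsch_superpose(pairs_a: np.ndarray, pairs_b: np.ndarray,
                     outlier_reject: bool = False, cycles: int = 5,
                     cutoff: float = 2.0) -> Superposition:
    """Least-squares optimal rigid superposition of paired coordinates.

    Maps A onto B: ``x -> R @ x + t``.  Degenerate (collinear) inputs are
    rejected.  With ``outlier_reject`` the fit is repeated up to ``cycles``
    times, each time dropping pairs whose deviation exceeds ``cutoff``
    standard deviations of the current deviation distribution.
    """
    A = np.asarray(pairs_a, dtype=float)
    B = np.asarray(pairs_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("paired coordinate arrays must both be (n, 3)")
    if len(A) < 3:
        raise ValueError("need at least three atom pairs")
    if np.linalg.matrix_rank(A - A.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("collinear coordinates: superposition degenerate")

    keep = np.ones(len(A), dtype=bool)
    mode = "outlier_reject" if outlier_reject else "all_pairs"
    R, t, rmsd = _kabsch(A, B)
    if outlier_reject:
        for _ in range(cycles):
            dev = np.linalg.norm((A @ R.T + t) - B, axis=1)
            sigma = dev[keep].std()
            if sigma == 0:
                break
            new_keep = keep & (dev <= dev[keep].mean() + cutoff * sigma)
            if new_keep.sum() < 3 or new_keep.sum() == keep.sum():
                break
            keep = new_keep
            R, t, rmsd = _kabsch(A[keep], B[keep])
    return Superposition(rotation=R, translation=t, rmsd=rmsd,
                         n_pairs=int(keep.sum()), mode=mode)


def superpose_models(model_a: StructureModel, model_b: StructureModel,
                     atom_name: str = "CA", **kwargs) -> Superposition:
    A, B, _ = pair_atoms(model_a, model_b, atom_name)
    return kabsch_superpose(A, B, **kwargs)


def detect_disulfides(model: StructureModel, sg_max: float = 2.5
                      ) -> tuple[list[DisulfidePair], int]:
    """Call disulfide bridges from cysteine SG-SG distances.

    Candidate pairs are CYS SG atoms within ``sg_max`` Angstrom; greedy
    matching by ascending distance ensures each cysteine joins at most one
    bridge.  Returns the pairs and their count.
    """
    res_names = model.residues()
    sg = {idx: xyz for idx, xyz in model.coords("SG").items()
          if res_names.get(idx) == "CYS"}
    indices = sorted(sg)
    if len(indices) < 2:
        return [], 0
    coords = np.array([sg[i] for i in indices])
    dist = squareform(pdist(coords))
    candidates = sorted(
        (dist[u, v], indices[u], indices[v])
        for u in range(len(indices)) for v in range(u + 1, len(indices))
        if dist[u, v] <= sg_max)
    used: set[int] = set()
    pairs: list[DisulfidePair] = []
    for d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append(DisulfidePair(res_i=min(i, j), res_j=max(i, j),
                                   sg_distance=float(d)))
    pairs.sort(key=lambda p: (p.res_i, p.res_j))
    return pairs, len(pairs)
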
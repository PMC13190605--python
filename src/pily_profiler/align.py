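"""Global pairwise alignment with EMBOSS-needle-style identity/similarity.

Percent identity and similarity between PilY1 homologs are the raw material
for both the clade phylogeny and the ordination.  Scoring follows the
needle defaults: EBLOSUM62, gap open 10, gap extend 0.5, end gaps free, and
the alignment length (the denominator of both percentages) includes every
gap column, terminal gaps included.  A gap of length L is charged
``open + L * extend`` (needle's convention); this is mapped onto
Biopython's per-position convention by opening at ``open + extend``.

A column counts as *similar* when the substitution score of its residue
pair is strictly positive; gap columns are never similar.  Because every
diagonal entry of BLOSUM62 is positive, identical columns are always
similar, hence identity <= similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=8)
def load_matrix(name_or_path: str = "EBLOSUM62"):
    """Load a substitution matrix: the shipped EBLOSUM62 by default, else a
    file path in NCBI matrix format."""
    if name_or_path == "EBLOSUM62":
        path = resources.files("pily_profiler.data").joinpath("EBLOSUM62")
        with resources.as_file(path) as p:
            return substitution_matrices.read(str(p))
    return substitution_matrices.read(name_or_path)


@dataclass
class AlignParams:
    """Needle-style alignment parameters."""

    matrix: str = "EBLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_penalized: bool = False

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    align_len: int
    n_identical: int
    n_similar: int
    pct_identity: float
    pct_similarity: float


def _build_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = load_matrix(params.matrix)
    # needle charges open + L*extend for a length-L gap; Biopython charges
    # open for the first gapped position, so fold one extend into the open.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    if not params.end_gaps_penalized:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    return aligner


def global_align(a: str, b: str,
                 params: AlignParams | None = None) -> AlignmentResult:
    """Optimal affine-gap global alignment of two protein sequences.

    Returns the first optimal alignment under Biopython's deterministic
    traceback order.  Raises if a residue is absent from the matrix.
    """
    if params is None:
        params = AlignParams()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    matrix = load_matrix(params.matrix)
    alphabet = set(matrix.alphabet)
    for seq, label in ((a, "first"), (b, "second")):
        missing = set(seq) - alphabet
        if missing:
            raise ValueError(
                f"residue(s) {sorted(missing)} in {label} sequence absent "
                f"from matrix {params.matrix}")
    aligner = _build_aligner(params)
    return _align_with(aligner, matrix, a, b)


def _align_with(aligner, matrix, a: str, b: str) -> AlignmentResult:
    aln = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    return _summarize(aligned_a, aligned_b, float(aln.score), matrix)


def _summarize(aligned_a: str, aligned_b: str, score: float,
               matrix) -> AlignmentResult:
    align_len = len(aligned_a)
    n_identical = 0
    n_similar = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            n_identical += 1
        if matrix[x, y] > 0:
            n_similar += 1
    return AlignmentResult(
        aligned_a=aligned_a, aligned_b=aligned_b, score=score,
        align_len=align_len, n_identical=n_identical, n_similar=n_similar,
        pct_identity=100.0 * n_identical / align_len,
        pct_similarity=100.0 * n_similar / align_len)


@dataclass
class DistanceMatrix:
    """Symmetric percent-identity matrix with its distance companion
    ``d = 100 - identity`` (zero diagonal)."""

    ids: list[str]
    identity: np.ndarray  # percent identity, diagonal 100
    similarity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.identity = np.asarray(self.identity, dtype=float)
        n = len(self.ids)
        if self.identity.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.identity, self.identity.T, atol=1e-9):
            raise ValueError("identity matrix must be symmetric")
        if not np.isfinite(self.identity).all():
            raise ValueError("identity matrix must be finite")

    @property
    def distance(self) -> np.ndarray:
        d = 100.0 - self.identity
        np.fill_diagonal(d, 0.0)
        return d

    def index(self, pid: str) -> int:
        return self.ids.index(pid)


def identity_matrix(records, params: AlignParams | None = None,
                    ranges: dict[str, tuple[int, int]] | None = None
                    ) -> DistanceMatrix:
    """All-against-all percent identity over a record collection.

    ``ranges`` optionally restricts a record to a 1-based inclusive slice
    (e.g. a beta-propeller region) before alignment.
    """
    if params is None:
        params = AlignParams()
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least two records")
    seqs = []
    for rec in records:
        seq = rec.sequence
        if ranges and rec.id in ranges:
            lo, hi = ranges[rec.id]
            seq = seq[lo - 1:hi]
        seqs.append(seq)
    n = len(records)
    matrix = load_matrix(params.matrix)
    aligner = _build_aligner(params)
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = _align_with(aligner, matrix, seqs[i], seqs[j])
            ident[i, j] = ident[j, i] = res.pct_identity
            simil[i, j] = simil[j, i] = res.pct_similarity
    return DistanceMatrix(ids=[r.id for r in records], identity=ident,
                          similarity=simil)
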
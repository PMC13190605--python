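"""Degenerate sequence-motif scanning and the per-protein feature census.

PilY1 adhesins carry short degenerate calcium-binding motifs in their
C-terminal beta-propeller (motif 1 ``Dx(D/N)xDGxxD``, motif 2 ``DxDxNxxxD``,
motif 3 ``DxD/NxDxxxxxxD/E``), an integrin-binding ``RGD`` tripeptide, and —
inside von Willebrand factor A (vWFA) domains — a discontinuous metal-ion-
dependent adhesion site (MIDAS) whose contiguous core is ``DxSxS`` followed
at a distance by a Thr and an Asp.  This module compiles such patterns from
a compact text notation, reports every (possibly overlapping) occurrence,
and aggregates hits with the cysteine census and externally supplied domain
calls into one :class:`FeatureProfile` per protein.

Pattern notation: a fixed residue is its one-letter code, ``x`` is a
wildcard, and two residues joined by ``/`` (parenthesised or not) form an
alternative set, e.g. ``Dx(D/N)xDGxxD`` and ``DxD/NxDxxxxxxD/E``.  The
ambiguity letter X in a *sequence* never satisfies a fixed token but does
satisfy a wildcard.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .core_io import STANDARD_AA, ProteinRecord

#: canonical motif names in reporting order
MOTIF_NAMES = ("motif1", "motif2", "motif3", "MIDAS", "RGD")

#: the three calcium-binding motifs
CA_MOTIFS = ("motif1", "motif2", "motif3")

#: domain names recognised for profile flags (aliases map onto them)
DOMAIN_FLAGS = ("vWFA", "DUF4114", "beta_propeller")
_DOMAIN_ALIASES = {
    "vwfa": "vWFA", "vwa": "vWFA",
    "duf4114": "DUF4114",
    "beta_propeller": "beta_propeller", "beta-propeller": "beta_propeller",
    "pily1": "beta_propeller", "pf05567": "beta_propeller",
    "pily1_beta_propeller": "beta_propeller",
}


@dataclass(frozen=True)
class TailElement:
    """One discontinuous-tail requirement: ``residue`` somewhere in the
    window ``[core_start + lo, core_start + hi]`` (1-based offsets from the
    first core position)."""

    residue: str
    lo: int
    hi: int


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate motif.

    ``tokens`` is the contiguous core: each element is a frozenset of
    allowed residues, or ``None`` for a wildcard.  ``tail`` lists
    discontinuous downstream requirements; when ``tail_required`` is true a
    hit is only reported if every tail element can be placed, otherwise the
    tail positions are annotations recorded on the hit when found.
    """

    name: str
    tokens: tuple[frozenset[str] | None, ...]
    tail: tuple[TailElement, ...] = ()
    tail_required: bool = False

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError(f"pattern {self.name!r}: no tokens")
        for tok in self.tokens:
            if tok is not None and (not tok or not tok <= STANDARD_AA):
                raise ValueError(
                    f"pattern {self.name!r}: bad fixed set {sorted(tok)}")

    @property
    def core_length(self) -> int:
        return len(self.tokens)


@dataclass
class MotifHit:
    """One occurrence of a motif core; coordinates 1-based inclusive."""

    protein_id: str
    motif_name: str
    start: int
    end: int
    matched: str
    tail_positions: dict[str, int] = field(default_factory=dict)


@dataclass
class FeatureProfile:
    """Per-protein feature row: length, cysteine census, motif hits and
    domain flags — the unit aggregated into the feature table."""

    protein_id: str
    length: int
    n_cys: int
    cys_positions: list[int]
    hits: dict[str, list[MotifHit]]
    domain_flags: dict[str, bool]

    @property
    def flags(self) -> dict[str, bool]:
        return {m: bool(self.hits.get(m)) for m in MOTIF_NAMES}

    @property
    def all_three_ca(self) -> bool:
        return all(bool(self.hits.get(m)) for m in CA_MOTIFS)


_TOKEN_RE = re.compile(r"\(([A-WY])/([A-WY])\)|([A-WY])/([A-WY])|([A-WY])|(x)")


def compile_pattern(spec: str, name: str = "",
                    tail: tuple[TailElement, ...] = (),
                    tail_required: bool = False) -> MotifPattern:
    """Compile a pattern string like ``Dx(D/N)xDGxxD`` into a MotifPattern.

    ``A/B`` denotes an alternative set whether or not parenthesised; ``x``
    is a wildcard.  Malformed alternations raise ``ValueError``.
    """
    tokens: list[frozenset[str] | None] = []
    pos = 0
    while pos < len(spec):
        m = _TOKEN_RE.match(spec, pos)
        if m is None or m.start() != pos:
            raise ValueError(
                f"pattern {name or spec!r}: cannot parse at position "
                f"{pos + 1} ({spec[pos:]!r})")
        if m.group(1):
            tokens.append(frozenset((m.group(1), m.group(2))))
        elif m.group(3):
            tokens.append(frozenset((m.group(3), m.group(4))))
        elif m.group(5):
            tokens.append(frozenset(m.group(5)))
        else:
            tokens.append(None)
        pos = m.end()
    return MotifPattern(name=name or spec, tokens=tuple(tokens),
                        tail=tail, tail_required=tail_required)


def _token_matches(token: frozenset[str] | None, letter: str) -> bool:
    if token is None:
        return True  # wildcard; X allowed
    return letter in token  # X never in a fixed set


def _place_tail(seq: str, core_start0: int,
                tail: tuple[TailElement, ...]) -> dict[str, int] | None:
    """Find a position for each tail element; returns 1-based positions or
    None if any element cannot be placed.  Elements are placed greedily at
    their first admissible position, left to right."""
    placed: dict[str, int] = {}
    prev = -1
    for elem in tail:
        lo = core_start0 + elem.lo
        hi = core_start0 + elem.hi
        found = None
        for i in range(max(lo, prev + 1), min(hi, len(seq) - 1) + 1):
            if seq[i] == elem.residue:
                found = i
                break
        if found is None:
            return None
        placed[elem.residue] = found + 1
        prev = found
    return placed


def scan(record: ProteinRecord, pattern: MotifPattern) -> list[MotifHit]:
    """Report every occurrence of ``pattern`` in the record, ascending by
    start, including overlapping occurrences."""
    seq = record.sequence
    k = pattern.core_length
    hits: list[MotifHit] = []
    for off in range(len(seq) - k + 1):
        if all(_token_matches(tok, seq[off + i])
               for i, tok in enumerate(pattern.tokens)):
            tail_pos: dict[str, int] = {}
            if pattern.tail:
                placed = _place_tail(seq, off, pattern.tail)
                if placed is None and pattern.tail_required:
                    continue
                tail_pos = placed or {}
            hits.append(MotifHit(
                protein_id=record.id, motif_name=pattern.name,
                start=off + 1, end=off + k,
                matched=seq[off:off + k], tail_positions=tail_pos))
    return hits


def cysteine_census(record: ProteinRecord) -> tuple[int, int, list[int]]:
    """Return (length, number of cysteines, 1-based cysteine positions)."""
    positions = [i + 1 for i, aa in enumerate(record.sequence) if aa == "C"]
    return len(record.sequence), len(positions), positions


def default_catalog() -> dict[str, MotifPattern]:
    """The shipped motif catalog (loaded from package data)."""
    with resources.files("pily_profiler.data").joinpath(
            "motifs.tsv").open() as fh:
        return load_catalog(fh)


_TAIL_RE = re.compile(r"^([A-WY])@(\d+)-(\d+)$")


def load_catalog(fh) -> dict[str, MotifPattern]:
    """Parse a motif catalog: TSV of name, pattern, optional tail spec.

    A tail spec is a comma-separated list like ``T@6-40,D@7-80`` (residue at
    1-based offsets from the core start); append ``!`` to make the tail
    required rather than annotation-only.
    """
    catalog: dict[str, MotifPattern] = {}
    for line in fh:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        name, spec = parts[0], parts[1]
        tail: list[TailElement] = []
        required = False
        if len(parts) > 2 and parts[2]:
            tail_spec = parts[2]
            if tail_spec.endswith("!"):
                required = True
                tail_spec = tail_spec[:-1]
            for chunk in tail_spec.split(","):
                m = _TAIL_RE.match(chunk)
                if not m:
                    raise ValueError(f"bad tail spec {chunk!r} for {name}")
                tail.append(TailElement(m.group(1), int(m.group(2)),
                                        int(m.group(3))))
        catalog[name] = compile_pattern(spec, name=name, tail=tuple(tail),
                                        tail_required=required)
    return catalog


def profile(record: ProteinRecord,
            catalog: dict[str, MotifPattern] | None = None,
            domains: list[tuple[str, int, int]] | None = None
            ) -> FeatureProfile:
    """Aggregate motif scans, cysteine census and domain flags for a record.

    ``domains`` overrides the record's own domain annotations when given.
    """
    if catalog is None:
        catalog = default_catalog()
    length, n_cys, cys_positions = cysteine_census(record)
    hits = {name: scan(record, pat) for name, pat in catalog.items()}
    flags = {d: False for d in DOMAIN_FLAGS}
    for name, _start, _end in (domains if domains is not None
                               else record.domains):
        canon = _DOMAIN_ALIASES.get(name.strip().lower().replace(" ", "_"))
        if canon:
            flags[canon] = True
    return FeatureProfile(protein_id=record.id, length=length, n_cys=n_cys,
                          cys_positions=cys_positions, hits=hits,
                          domain_flags=flags)
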
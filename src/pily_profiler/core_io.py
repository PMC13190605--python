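"""Readers, writers and the shared in-memory data model.

The pipeline operates on three kinds of external evidence: protein sequences
(FASTA), genome annotations with gene-role labels for type IVa pilus genes
(GFF3), and atomic coordinate models (PDB ATOM records).  All coordinates are
kept 1-based inclusive, matching the conventions of GFF3 and of residue
numbering in the adhesin literature (e.g. "aa 619-621").
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

#: the 20 standard amino-acid letters; everything else folds to X
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: ambiguity / non-standard codes folded to X on input
_FOLD_TO_X = set("UBZJO*")

#: gene roles recognised for cluster and linkage analysis
T4AP_ROLES = (
    "pilY1", "pilX", "pilW", "pilV", "fimU", "tfcP",
    "pilA", "pilB", "pilT", "pilC", "pilM", "pilN", "pilO", "pilP", "pilQ",
)
MINOR_PILIN_ROLES = ("pilX", "pilW", "pilV", "fimU")
MAJOR_CLUSTER_ROLES = ("pilQ", "pilP", "pilO", "pilN", "pilM",
                       "pilB", "pilT", "pilC", "pilA")

_ROLE_LOOKUP = {r.lower(): r for r in T4AP_ROLES}

#: clade labels used throughout (the nine PilY1 lineages)
CLADE_LABELS = ("1.1", "1.2", "1.3", "1.4a", "1.4b", "1.4c", "1.5", "1.6", "1.7")


@dataclass
class ProteinRecord:
    """One candidate PilY1 / minor-pilin protein.

    ``domains`` holds externally supplied domain calls as
    ``(name, start, end)`` with 1-based inclusive coordinates.
    ``ref_clade`` marks reference exemplars with a known clade label.
    """

    id: str
    sequence: str
    organism: str = ""
    domains: list[tuple[str, int, int]] = field(default_factory=list)
    ref_clade: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - STANDARD_AA - {"X"}
        if bad:
            raise ValueError(
                f"record {self.id!r}: unexpected letters {sorted(bad)}")
        for name, start, end in self.domains:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(
                    f"record {self.id!r}: domain {name} span {start}-{end} "
                    f"outside 1..{len(self.sequence)}")
        if self.ref_clade is not None and self.ref_clade not in CLADE_LABELS:
            raise ValueError(f"unknown clade label {self.ref_clade!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """One annotated CDS with 1-based inclusive coordinates and a gene role."""

    contig: str
    start: int
    end: int
    strand: str
    locus_tag: str
    role: str = "other"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.locus_tag}: coordinates must be positive")
        if self.start > self.end:
            raise ValueError(
                f"{self.locus_tag}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"{self.locus_tag}: unknown strand {self.strand!r}")
        if self.role != "other" and self.role not in T4AP_ROLES:
            raise ValueError(f"{self.locus_tag}: unknown role {self.role!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class StructureModel:
    """Ordered atoms of one coordinate model.

    ``atoms`` entries are ``(res_index, res_name, atom_name, x, y, z)`` with
    coordinates in Angstrom, kept in file order.
    """

    model_id: str
    atoms: list[tuple[int, str, str, float, float, float]]

    def coords(self, atom_name: str) -> dict[int, tuple[float, float, float]]:
        """Map residue index -> xyz for the first atom of the given name."""
        out: dict[int, tuple[float, float, float]] = {}
        for res_index, _res_name, name, x, y, z in self.atoms:
            if name == atom_name and res_index not in out:
                out[res_index] = (x, y, z)
        return out

    def residues(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for res_index, res_name, *_ in self.atoms:
            out.setdefault(res_index, res_name)
        return out


def _fold_sequence(seq: str, rec_id: str) -> str:
    seq = seq.upper()
    folded = []
    replaced = set()
    for letter in seq:
        if letter in STANDARD_AA or letter == "X":
            folded.append(letter)
        elif letter in _FOLD_TO_X:
            folded.append("X")
            replaced.add(letter)
        else:
            raise ValueError(
                f"record {rec_id!r}: letter {letter!r} is not an amino acid")
    if replaced:
        logger.warning("record %s: folded %s to X", rec_id, sorted(replaced))
    return "".join(folded)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA; the header token before the first whitespace is the id.

    Non-standard letters (U/B/Z/J/O, stop ``*``) are folded to X with a
    warning.  Duplicate ids and empty sequences are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = _fold_sequence(str(entry.seq), entry.id)
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {entry.id!r}")
        desc = entry.description.split(None, 1)
        organism = desc[1] if len(desc) > 1 else ""
        records.append(ProteinRecord(id=entry.id, sequence=seq,
                                     organism=organism))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.organism:
                header += f" {rec.organism}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


_ROLE_KEYWORDS = {r.lower(): r for r in T4AP_ROLES}


def _role_from_attributes(attrs: dict[str, list[str]]) -> str:
    # precedence: explicit role= > gene= > product keyword match
    for key in ("role", "gene"):
        for value in attrs.get(key, []):
            role = _ROLE_LOOKUP.get(value.strip().lower())
            if role:
                return role
    for value in attrs.get("product", []):
        for word in value.replace(",", " ").split():
            role = _ROLE_LOOKUP.get(word.strip().lower())
            if role:
                return role
    return "other"


def read_gff3(path: str | Path) -> tuple[list[GeneFeature], dict[str, int]]:
    """Read gene features and contig lengths from a GFF3 file.

    Only ``CDS`` and ``gene`` rows are consumed; when both exist for one
    locus_tag the CDS row wins.  The role is taken from a ``role=`` attribute,
    else ``gene=``, else a keyword match on ``product=``, mapped
    case-insensitively onto the T4aP role vocabulary; anything else is
    ``other``.  Contig lengths come from ``##sequence-region`` pragmas and may
    be missing (empty dict entries are simply absent).
    """
    path = Path(path)
    contig_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    contig_lengths[parts[1]] = int(parts[3])
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    by_tag: dict[str, tuple[str, GeneFeature]] = {}
    order: list[str] = []
    for ftype in ("gene", "CDS"):
        for feat in db.features_of_type(ftype):
            if feat.strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: feature at {feat.seqid}:{feat.start}-{feat.end} "
                    f"has unsupported strand {feat.strand!r}")
            attrs = dict(feat.attributes)
            tags = attrs.get("locus_tag") or attrs.get("ID") or [feat.id]
            tag = tags[0]
            gf = GeneFeature(contig=feat.seqid, start=feat.start,
                             end=feat.end, strand=feat.strand,
                             locus_tag=tag,
                             role=_role_from_attributes(attrs))
            prev = by_tag.get(tag)
            if prev is None:
                by_tag[tag] = (ftype, gf)
                order.append(tag)
            elif prev[0] == "gene" and ftype == "CDS":
                by_tag[tag] = (ftype, gf)  # CDS row preferred
    features = [by_tag[t][1] for t in order]
    features.sort(key=lambda f: (f.contig, f.start, f.end, f.locus_tag))
    return features, contig_lengths


def read_pdb(path: str | Path, model_id: str | None = None) -> StructureModel:
    """Parse ATOM records of a PDB file into a :class:`StructureModel`.

    HETATM records are ignored; of alternate locations only blank or 'A' is
    kept.  Raises if the file contains no ATOM records.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(model_id or path.stem, str(path))
    atoms: list[tuple[int, str, str, float, float, float]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for model in structure:
            for chain in model:
                for residue in chain:
                    if residue.id[0] != " ":  # HETATM / water
                        continue
                    for atom in residue.get_unpacked_list():
                        if atom.get_altloc() not in (" ", "A"):
                            continue
                        x, y, z = (float(v) for v in atom.coord)
                        atoms.append((residue.id[1], residue.resname.strip(),
                                      atom.get_name(), x, y, z))
            break  # first model only
    if not atoms:
        raise ValueError(f"{path}: no ATOM records")
    return StructureModel(model_id=model_id or path.stem, atoms=atoms)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal single-chain PDB file with fixed-column ATOM records."""
    with open(path, "w") as fh:
        for serial, (res_index, res_name, atom_name, x, y, z) in enumerate(
                model.atoms, start=1):
            element = atom_name[0]
            name_field = f" {atom_name:<3s}" if len(atom_name) < 4 else atom_name
            fh.write(
                f"ATOM  {serial:>5d} {name_field:<4s}{'':1s}{res_name:>3s} "
                f"A{res_index:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n")
        fh.write("END\n")


def read_domain_table(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read a TSV of externally produced domain calls.

    Columns: protein id, domain name, start, end (1-based inclusive).  Lines
    starting with '#' are comments.
    """
    out: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pid, name, start, end = line.split("\t")[:4]
            out.setdefault(pid, []).append((name, int(start), int(end)))
    return out


def write_outputs(profiles, clusters, tree, assignments, outdir,
                  linkage=None) -> dict[str, Path]:
    """Write the standard pipeline products into ``outdir``.

    Produces feature_table.tsv, clusters.tsv, tree.nwk and report.json with
    deterministic column and row order (rows sorted by id).  Any argument may
    be ``None`` / empty; the corresponding file is then omitted (tree) or
    reduced to its header row (tables), and report.json records which
    sections were written.
    """
    from .motifs import MOTIF_NAMES  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    clade_of = {a.protein_id: a.clade for a in (assignments or [])}
    linkage_of = {lc.pilY1_tag: lc.status for lc in (linkage or [])}

    ft_path = outdir / "feature_table.tsv"
    cols = ["id", "length", "n_cys"]
    for m in MOTIF_NAMES:
        cols += [f"{m}_flag", f"{m}_starts"]
    cols += ["vWFA", "DUF4114", "beta_propeller", "all_three_ca",
             "clade", "linkage"]
    with open(ft_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for prof in sorted(profiles or [], key=lambda p: p.protein_id):
            row = [prof.protein_id, str(prof.length), str(prof.n_cys)]
            for m in MOTIF_NAMES:
                hits = prof.hits.get(m, [])
                row.append("1" if hits else "0")
                row.append(",".join(str(h.start) for h in hits))
            row += ["1" if prof.domain_flags.get(d) else "0"
                    for d in ("vWFA", "DUF4114", "beta_propeller")]
            row.append("1" if prof.all_three_ca else "0")
            row.append(clade_of.get(prof.protein_id, ""))
            row.append(linkage_of.get(prof.protein_id, ""))
            fh.write("\t".join(row) + "\n")
    written["feature_table"] = ft_path

    cl_path = outdir / "clusters.tsv"
    with open(cl_path, "w") as fh:
        fh.write("contig\tspan\tcluster_type\tmembers\troles\t"
                 "pilY1_tags\tcoupling_pairs\n")
        for call in sorted(clusters or [],
                           key=lambda c: (c.contig, c.members[0])):
            fh.write("\t".join([
                call.contig, f"{call.start}-{call.end}", call.cluster_type,
                ",".join(call.members), ",".join(call.roles),
                ",".join(call.pilY1_tags),
                ";".join(f"{a}|{b}" for a, b in call.coupling_pairs),
            ]) + "\n")
    written["clusters"] = cl_path

    if tree is not None:
        tree_path = outdir / "tree.nwk"
        tree.write(str(tree_path), format="newick")
        written["tree"] = tree_path

    report = {
        "n_proteins": len(profiles or []),
        "n_clusters_by_type": {},
        "n_per_clade": {},
        "sections": sorted(written),
    }
    for call in clusters or []:
        report["n_clusters_by_type"][call.cluster_type] = (
            report["n_clusters_by_type"].get(call.cluster_type, 0) + 1)
    for a in assignments or []:
        report["n_per_clade"][a.clade] = report["n_per_clade"].get(a.clade, 0) + 1
    if linkage:
        report["n_linked"] = sum(1 for lc in linkage if lc.status == "linked")
        report["n_unlinked"] = sum(1 for lc in linkage
                                   if lc.status == "unlinked")
    rp_path = outdir / "report.json"
    with open(rp_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["report"] = rp_path
    return written
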
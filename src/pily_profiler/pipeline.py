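"""End-to-end orchestration: configuration, stage running, reports.

Stages are separable — motif profiling needs only a FASTA, synteny needs
only a GFF3, structure comparison needs only coordinate models — so
missing optional inputs skip their stage (with a logged notice) rather
than failing the run.  All outputs are deterministic for a fixed
configuration and input set, and report.json echoes the configuration it
was produced under.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import align, core_io, motifs, phylo, structure, synteny

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration for all stages; every threshold is the module
    default unless overridden."""

    fasta: str | None = None
    gff3: list[str] = field(default_factory=list)
    domain_table: str | None = None
    structures: list[str] = field(default_factory=list)
    exemplar_labels: str | None = None     # TSV: protein id, clade
    motif_catalog: str | None = None
    matrix: str = "EBLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    window_genes: int = 5
    max_gap_genes: int = 2
    max_gap_bp: int = 3000
    coupling_gap: int = 4
    clade_ceiling: float = 75.0
    sg_max: float = 2.5
    seed: int = 0
    outdir: str = "pily_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file; list-valued keys
        (gff3, structures) take comma-separated values."""
        kwargs: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                ftype = fields[key].type
                if key in ("gff3", "structures"):
                    kwargs[key] = [v.strip() for v in value.split(",") if v.strip()]
                elif ftype in ("int", int):
                    kwargs[key] = int(value)
                elif ftype in ("float", float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_catalog(config: PipelineConfig):
    if config.motif_catalog:
        with open(config.motif_catalog) as fh:
            return motifs.load_catalog(fh)
    return motifs.default_catalog()


def _align_params(config: PipelineConfig) -> align.AlignParams:
    return align.AlignParams(matrix=config.matrix,
                             gap_open=config.gap_open,
                             gap_extend=config.gap_extend)


def _load_exemplars(config: PipelineConfig,
                    records) -> dict[str, list[str]]:
    exemplars: dict[str, list[str]] = {}
    if config.exemplar_labels:
        with open(config.exemplar_labels) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                pid, clade = line.split("\t")[:2]
                exemplars.setdefault(clade, []).append(pid)
    else:
        for rec in records:
            if rec.ref_clade:
                exemplars.setdefault(rec.ref_clade, []).append(rec.id)
    return exemplars


def run_profile(config: PipelineConfig):
    """Profile every FASTA record: motifs, cysteine census, domain flags.
    Returns (records, profiles) and writes feature_table.tsv."""
    if not config.fasta:
        raise FileNotFoundError("no fasta input configured")
    records = core_io.read_fasta(config.fasta)
    catalog = _load_catalog(config)
    domain_calls = (core_io.read_domain_table(config.domain_table)
                    if config.domain_table else {})
    profiles = []
    for rec in records:
        domains = domain_calls.get(rec.id)
        profiles.append(motifs.profile(rec, catalog=catalog,
                                       domains=domains))
    return records, profiles


def run_compare(config: PipelineConfig,
                pairs: list[tuple[str, str]]) -> list[dict]:
    """Superpose listed model pairs; one result row per pair.  A row-level
    error is recorded without aborting the remaining pairs."""
    rows = []
    for path_a, path_b in pairs:
        row = {"model_a": Path(path_a).stem, "model_b": Path(path_b).stem}
        try:
            model_a = core_io.read_pdb(path_a)
            model_b = core_io.read_pdb(path_b)
            sup = structure.superpose_models(model_a, model_b)
            row.update(n_pairs=sup.n_pairs, rmsd=round(sup.rmsd, 4),
                       mode=sup.mode)
        except Exception as exc:  # noqa: BLE001 - row-level error contract
            row["error"] = str(exc)
        rows.append(row)
    return rows


def run_full(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are present; returns the report dict.

    Stage order: profile -> identity matrix -> tree -> clades -> PCA ->
    synteny -> structures.  Missing optional inputs skip their stage with
    a logged notice.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "skipped": [],
                    "counts": {}}

    records, profiles = run_profile(config)
    report["counts"]["n_proteins"] = len(records)

    matrix = tree = assignments = None
    if len(records) >= 2:
        matrix = align.identity_matrix(records, _align_params(config))
    else:
        report["skipped"].append("identity_matrix")
        logger.info("skipping identity matrix: fewer than two proteins")
    if matrix is not None and len(records) >= 3:
        tree = phylo.nj_tree(matrix)
        exemplars = _load_exemplars(config, records)
        if exemplars:
            assignments = phylo.assign_clades(
                tree, profiles, exemplars, matrix,
                unassigned_ceiling=config.clade_ceiling)
            counts: dict[str, int] = {}
            for a in assignments:
                counts[a.clade] = counts.get(a.clade, 0) + 1
            report["counts"]["n_per_clade"] = counts
            summary = phylo.clade_summary(assignments, profiles)
            summary.to_csv(outdir / "clade_summary.tsv", sep="\t",
                           index=False)
        else:
            report["skipped"].append("clades")
            logger.info("skipping clade assignment: no exemplars")
        scores, explained = phylo.pca_identity(matrix, k=2)
        clade_of = {a.protein_id: a.clade for a in (assignments or [])}
        with open(outdir / "pca.tsv", "w") as fh:
            fh.write("id\tPC1\tPC2\tclade\n")
            for pid, (x, y) in zip(matrix.ids, scores):
                fh.write(f"{pid}\t{x:.6f}\t{y:.6f}\t"
                         f"{clade_of.get(pid, '')}\n")
        report["counts"]["pca_explained"] = [float(v) for v in explained]
    else:
        report["skipped"].extend(["tree", "clades", "pca"])

    clusters = None
    linkage = None
    if config.gff3:
        clusters, linkage = [], []
        for gff_path in config.gff3:
            features, contig_lengths = core_io.read_gff3(gff_path)
            clusters.extend(synteny.detect_clusters(
                features, max_gap_genes=config.max_gap_genes,
                max_gap_bp=config.max_gap_bp))
            linkage.extend(synteny.classify_linkage(
                features, window_genes=config.window_genes))
        report["counts"]["n_clusters_by_type"] = {}
        for call in clusters:
            t = call.cluster_type
            report["counts"]["n_clusters_by_type"][t] = \
                report["counts"]["n_clusters_by_type"].get(t, 0) + 1
        report["counts"]["n_linked"] = sum(
            1 for lc in linkage if lc.status == "linked")
        report["counts"]["n_unlinked"] = sum(
            1 for lc in linkage if lc.status == "unlinked")
        with open(outdir / "linkage.tsv", "w") as fh:
            fh.write("pilY1_tag\tstatus\tevidence\n")
            for lc in sorted(linkage, key=lambda c: c.pilY1_tag):
                ev = ",".join(f"{r}@{d:+d}" for r, d in lc.evidence)
                fh.write(f"{lc.pilY1_tag}\t{lc.status}\t{ev}\n")
    else:
        report["skipped"].append("synteny")
        logger.info("skipping synteny: no gff3 inputs")

    if config.structures:
        disulfides = {}
        with open(outdir / "disulfides.tsv", "w") as fh:
            fh.write("model\tres_i\tres_j\tsg_distance\n")
            for path in config.structures:
                model = core_io.read_pdb(path)
                pairs, count = structure.detect_disulfides(
                    model, sg_max=config.sg_max)
                disulfides[model.model_id] = count
                for p in pairs:
                    fh.write(f"{model.model_id}\t{p.res_i}\t{p.res_j}\t"
                             f"{p.sg_distance:.3f}\n")
        report["counts"]["n_disulfides_per_model"] = disulfides
    else:
        report["skipped"].append("structures")
        logger.info("skipping structures: no models configured")

    core_io.write_outputs(profiles, clusters, tree, assignments, outdir,
                          linkage=linkage)
    # merge pipeline report over the writer's summary
    with open(outdir / "report.json") as fh:
        base = json.load(fh)
    base.update(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(base, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return base
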
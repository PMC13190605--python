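"""Seeded generators for proteomes, genome annotations and coordinate models.

Every pipeline stage is exercised against data with a known ground truth:
clade-structured protein families whose cysteine medians, domain flags and
motif repertoires follow the nine PilY1 clades; GFF3 genomes with planted
minor-pilin operons, embedded-major arrangements, solitary pilY1 genes and
translational-coupling overlaps; and coordinate-model pairs related by a
known rigid transform with planted disulfide bridges.  Each generator
returns a manifest that fully determines the expected output of the
deterministic pipeline stages, and is byte-deterministic for a fixed seed.

Sequences are built from a clade-specific conserved core mutated per
protein at a rate that keeps within-clade identity high (>= ~70%) while
independent cores keep between-clade identity low (<= ~40%); the
background alphabet excludes cysteine so the planted per-protein cysteine
count is exact.  After planting, chance motif occurrences are scrubbed by
point mutation so the scanned motif set equals the manifest exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .core_io import GeneFeature, ProteinRecord, StructureModel
from .motifs import MOTIF_NAMES, MotifPattern, default_catalog, scan

#: background alphabet: the standard residues minus C (cysteines are planted)
BACKGROUND_AA = "ADEFGHIKLMNPQRSTVWY"

#: per-protein substitution rate applied to the clade core
MUTATION_RATE = 0.06


@dataclass
class CladeTemplate:
    """Study conditions for one clade: length and cysteine targets follow
    the clade medians, motif repertoires follow the reported trends
    (clades 1.1/1.2 predominantly carry calcium motif 1; 1.4a/1.4c/1.7
    mostly lack all three), and the N-terminal domain matches the clade
    architecture (DUF4114 for 1.1/1.2, vWFA for the 1.3-like clades,
    neither for 1.4a/1.4c; a beta-propeller always)."""

    clade: str
    length_median: int
    length_spread: int
    n_cys_median: int
    n_cys_spread: int
    motif_probs: dict[str, float]
    domain: str | None            # "DUF4114" | "vWFA" | None


def default_templates() -> list[CladeTemplate]:
    # cysteine medians per clade: 1.1:23 1.2:22 1.3:35 1.4a:21 1.4b:25
    # 1.4c:17 1.5:30 1.6:36 1.7:41; lengths: 1.4a shortest, 1.6/1.7 longest
    def probs(m1, m2, m3, midas, rgd):
        return {"motif1": m1, "motif2": m2, "motif3": m3,
                "MIDAS": midas, "RGD": rgd}

    return [
        CladeTemplate("1.1", 1250, 60, 23, 2, probs(.9, .15, .15, .3, .2),
                      "DUF4114"),
        CladeTemplate("1.2", 1200, 60, 22, 2, probs(.9, .15, .15, .3, .2),
                      "DUF4114"),
        CladeTemplate("1.3", 1350, 60, 35, 3, probs(.5, .3, .3, .7, .2),
                      "vWFA"),
        CladeTemplate("1.4a", 900, 50, 21, 2, probs(.05, .05, .05, .3, .2),
                      None),
        CladeTemplate("1.4b", 1100, 60, 25, 2, probs(.4, .3, .3, .7, .2),
                      "vWFA"),
        CladeTemplate("1.4c", 1000, 50, 17, 2, probs(.05, .05, .05, .2, .2),
                      None),
        CladeTemplate("1.5", 1450, 70, 30, 3, probs(.5, .3, .3, .7, .2),
                      "vWFA"),
        CladeTemplate("1.6", 1700, 80, 36, 3, probs(.5, .3, .3, .7, .2),
                      "vWFA"),
        CladeTemplate("1.7", 1650, 80, 41, 3, probs(.05, .05, .05, .7, .2),
                      "vWFA"),
    ]


def _sample_background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BACKGROUND_AA), size=n))


def _motif_instance(rng: np.random.Generator, pattern: MotifPattern) -> str:
    letters = []
    for tok in pattern.tokens:
        if tok is None:
            letters.append(str(rng.choice(list(BACKGROUND_AA))))
        else:
            letters.append(str(rng.choice(sorted(tok))))
    return "".join(letters)


def _scrub_chance_hits(seq: list[str], record_id: str, catalog,
                       planted: dict[str, list[int]],
                       protected: set[int],
                       rng: np.random.Generator,
                       max_rounds: int = 100) -> None:
    """Point-mutate away motif occurrences that were not planted, leaving
    planted windows and cysteine positions untouched."""
    for _ in range(max_rounds):
        rec = ProteinRecord(id=record_id, sequence="".join(seq))
        dirty = False
        unfixable = 0
        for name, pattern in catalog.items():
            for hit in scan(rec, pattern):
                if hit.start in planted.get(name, []):
                    continue
                # pick a fixed-token offset outside protected positions
                offsets = [i for i, tok in enumerate(pattern.tokens)
                           if tok is not None
                           and (hit.start - 1 + i) not in protected]
                if not offsets:
                    unfixable += 1  # chance hit buried in planted windows
                    continue
                off = int(rng.choice(offsets))
                pos = hit.start - 1 + off
                tok = pattern.tokens[off]
                choices = [a for a in BACKGROUND_AA if a not in tok]
                seq[pos] = str(rng.choice(choices))
                dirty = True
        if not dirty:
            if unfixable:
                raise RuntimeError(
                    f"{record_id}: {unfixable} chance motif hit(s) cannot "
                    "be scrubbed without touching planted windows")
            return
    raise RuntimeError(f"{record_id}: could not scrub chance motif hits "
                       f"after {max_rounds} rounds")


def generate_proteome(templates: list[CladeTemplate] | None = None,
                      n_per_clade: int = 12, seed: int = 0
                      ) -> tuple[list[ProteinRecord], dict]:
    """Generate a clade-structured proteome plus its ground-truth manifest.

    The first member of each clade carries ``ref_clade`` (a labelled
    exemplar).  Manifest keys: per-protein clade, planted motif start
    positions, exact cysteine count and domain annotations.
    """
    if templates is None:
        templates = default_templates()
    rng = np.random.default_rng(seed)
    catalog = default_catalog()
    records: list[ProteinRecord] = []
    manifest: dict = {"seed": int(seed), "n_per_clade": int(n_per_clade),
                      "proteins": {}}

    for tpl in templates:
        core = _sample_background(rng, tpl.length_median + 200)
        for k in range(n_per_clade):
            pid = f"{tpl.clade}_p{k + 1:02d}"
            for attempt in range(100):
                try:
                    seq, planted, n_cys, cys_pos = _build_protein(
                        tpl, pid, core, catalog, rng)
                    break
                except RuntimeError:
                    continue  # re-draw; rng state has advanced
            else:
                raise RuntimeError(
                    f"{pid}: generation failed after 100 retries")
            domains: list[tuple[str, int, int]] = []
            length = len(seq)
            if tpl.domain is not None:
                domains.append((tpl.domain, 30, min(330, length)))
            domains.append(("beta_propeller", max(1, length - 600),
                            length - 10))
            rec = ProteinRecord(
                id=pid, sequence="".join(seq),
                organism=f"synthetic clade {tpl.clade}",
                domains=domains,
                ref_clade=tpl.clade if k == 0 else None)
            records.append(rec)
            manifest["proteins"][pid] = {
                "clade": tpl.clade,
                "motifs": {m: sorted(v) for m, v in planted.items()},
                "n_cys": n_cys,
                "cys_positions": [i + 1 for i in cys_pos],
                "domains": [list(d) for d in domains],
                "exemplar": k == 0,
            }
    return records, manifest


def _build_protein(tpl: CladeTemplate, pid: str, core: str, catalog,
                   rng: np.random.Generator):
    """One attempt at building a clade member; raises RuntimeError when the
    chance-hit scrub cannot produce a sequence whose motif content equals
    the plants exactly."""
    length = int(tpl.length_median
                 + rng.integers(-tpl.length_spread, tpl.length_spread + 1))
    seq = list(core[:length])
    if length > len(core):
        seq += list(_sample_background(rng, length - len(core)))
    # per-protein divergence from the clade core
    n_mut = rng.binomial(length, MUTATION_RATE)
    for pos in rng.choice(length, size=n_mut, replace=False):
        current = seq[pos]
        choices = [a for a in BACKGROUND_AA if a != current]
        seq[pos] = str(rng.choice(choices))

    # plant motifs in non-overlapping windows
    planted: dict[str, list[int]] = {}
    protected: set[int] = set()
    margin = 20
    for name in MOTIF_NAMES:
        if rng.random() >= tpl.motif_probs.get(name, 0.0):
            continue
        pattern = catalog[name]
        width = pattern.core_length
        for _try in range(200):
            start0 = int(rng.integers(margin, length - width - margin))
            window = set(range(start0 - 1, start0 + width + 1))
            if window & protected:
                continue
            instance = _motif_instance(rng, pattern)
            seq[start0:start0 + width] = list(instance)
            planted.setdefault(name, []).append(start0 + 1)
            protected |= set(range(start0, start0 + width))
            break

    # exact cysteine budget outside motif windows
    n_cys = max(1, int(tpl.n_cys_median
                       + rng.integers(-tpl.n_cys_spread,
                                      tpl.n_cys_spread + 1)))
    free = [i for i in range(length) if i not in protected]
    if n_cys > len(free):
        raise RuntimeError(f"{pid}: cysteine budget exceeds free positions")
    cys_pos = sorted(int(i) for i in
                     rng.choice(free, size=n_cys, replace=False))
    for i in cys_pos:
        seq[i] = "C"
    protected |= set(cys_pos)

    _scrub_chance_hits(seq, pid, catalog, planted, protected, rng)
    return seq, planted, n_cys, cys_pos


# ---------------------------------------------------------------------------
# genome layouts

#: layout name -> ordered roles; "other*" marks the trailing accessory gene
GENOME_LAYOUTS = {
    "mx_cluster1": ["fimU", "pilV", "pilW", "pilX", "tfcP", "pilY1"],
    "mx_cluster2": ["fimU", "pilV", "pilW", "pilX", "pilY1"],
    "mx_cluster3": ["fimU", "pilV", "pilW", "pilX", "pilY1", "other*"],
    "anaeromyxobacter_embedded": [
        "pilQ", "pilP", "pilO", "pilN", "pilM",
        "fimU", "pilV", "pilW", "pilX", "pilY1",
        "pilB", "pilT", "pilC", "pilA"],
    "solitary_unlinked": ["pilY1"],
    "pilX_adjacent_partial": ["pilX", "pilY1"],
}

#: (upstream_role, downstream_role, overlap_bp) planted per layout
_LAYOUT_COUPLINGS = {
    "mx_cluster1": [("tfcP", "pilY1", 4)],
    "mx_cluster3": [("pilY1", "other*", 1)],
}

_EXPECTED_CLUSTER_TYPE = {
    "mx_cluster1": "minor_cluster",
    "mx_cluster2": "minor_cluster",
    "mx_cluster3": "minor_cluster",
    "anaeromyxobacter_embedded": "major_embedded_pilY1",
    "solitary_unlinked": "solitary_pilY1",
    "pilX_adjacent_partial": "solitary_pilY1",
}

_EXPECTED_LINKAGE = {
    "mx_cluster1": "linked", "mx_cluster2": "linked",
    "mx_cluster3": "linked", "anaeromyxobacter_embedded": "linked",
    "solitary_unlinked": "unlinked", "pilX_adjacent_partial": "linked",
}

_GENE_LENGTH = {"pilY1": 3600, "tfcP": 600, "fimU": 480, "pilV": 510,
                "pilW": 810, "pilX": 540, "pilQ": 2400, "pilP": 540,
                "pilO": 630, "pilN": 600, "pilM": 1080, "pilB": 1700,
                "pilT": 1040, "pilC": 1230, "pilA": 690, "other": 900}


def generate_genome(layouts: list[str], seed: int = 0
                    ) -> tuple[list[GeneFeature], dict[str, int], dict]:
    """Generate one annotated genome: one contig per requested layout.

    Returns features (sorted), contig lengths, and a manifest recording the
    expected cluster type, linkage status and coupling pairs per pilY1.
    """
    rng = np.random.default_rng(seed)
    features: list[GeneFeature] = []
    contig_lengths: dict[str, int] = {}
    manifest: dict = {"seed": int(seed), "pilY1": {}, "coupling_pairs": [],
                      "contigs": {}}
    for layout in layouts:
        if layout not in GENOME_LAYOUTS:
            raise ValueError(f"unknown layout {layout!r}; choose from "
                             f"{sorted(GENOME_LAYOUTS)}")
        contig = f"ctg_{layout}"
        roles = GENOME_LAYOUTS[layout]
        couplings = {(u, d): ov
                     for u, d, ov in _LAYOUT_COUPLINGS.get(layout, [])}
        pos = 5000 + int(rng.integers(0, 1000))
        # leading filler genes, far from the cluster
        feats: list[GeneFeature] = []
        tag_no = 1

        def add_gene(role_token: str, start: int) -> GeneFeature:
            nonlocal tag_no
            role = "other" if role_token.startswith("other") else role_token
            glen = _GENE_LENGTH[role] + int(rng.integers(-30, 31)) * 3
            f = GeneFeature(contig=contig, start=start,
                            end=start + glen - 1, strand="+",
                            locus_tag=f"{layout}_{tag_no:03d}", role=role)
            tag_no += 1
            feats.append(f)
            return f

        for _ in range(2):
            g = add_gene("other", pos)
            pos = g.end + 4000 + int(rng.integers(0, 500))

        prev_token = None
        prev_feat = None
        for token in roles:
            if prev_token is not None and (prev_token, token) in couplings:
                overlap = couplings[(prev_token, token)]
                start = prev_feat.end - overlap + 1
            elif prev_feat is None:
                start = pos
            else:
                start = prev_feat.end + 1 + 60 + int(rng.integers(0, 60))
            f = add_gene(token, start)
            if prev_token is not None and (prev_token, token) in couplings:
                manifest["coupling_pairs"].append(
                    [prev_feat.locus_tag, f.locus_tag])
            if f.role == "pilY1":
                manifest["pilY1"][f.locus_tag] = {
                    "layout": layout,
                    "cluster_type": _EXPECTED_CLUSTER_TYPE[layout],
                    "linkage": _EXPECTED_LINKAGE[layout],
                }
            prev_token, prev_feat = token, f

        pos = prev_feat.end + 4000 + int(rng.integers(0, 500))
        for _ in range(2):
            g = add_gene("other", pos)
            pos = g.end + 4000 + int(rng.integers(0, 500))

        contig_lengths[contig] = feats[-1].end + 5000
        manifest["contigs"][contig] = {"layout": layout,
                                       "length": contig_lengths[contig]}
        features.extend(feats)
    features.sort(key=lambda f: (f.contig, f.start))
    _validate_no_unplanned_overlap(features, manifest)
    return features, contig_lengths, manifest


def _validate_no_unplanned_overlap(features, manifest) -> None:
    planned = {tuple(p) for p in manifest["coupling_pairs"]}
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_contig.setdefault(f.contig, []).append(f)
    for feats in by_contig.values():
        for prev, nxt in zip(feats, feats[1:]):
            if nxt.start <= prev.end and \
                    (prev.locus_tag, nxt.locus_tag) not in planned:
                raise ValueError(
                    f"unplanned overlap {prev.locus_tag}/{nxt.locus_tag}")


def write_gff3(features: list[GeneFeature], contig_lengths: dict[str, int],
               path: str | Path) -> None:
    """Write features as GFF3 CDS rows with role carried in ``gene=``."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in sorted(contig_lengths):
            fh.write(f"##sequence-region {contig} 1 "
                     f"{contig_lengths[contig]}\n")
        for f in features:
            attrs = [f"ID=cds-{f.locus_tag}", f"locus_tag={f.locus_tag}"]
            if f.role != "other":
                attrs.append(f"gene={f.role}")
            fh.write("\t".join([
                f.contig, "pily_profiler_synth", "CDS", str(f.start),
                str(f.end), ".", f.strand, "0", ";".join(attrs)]) + "\n")


# ---------------------------------------------------------------------------
# coordinate models

def _self_avoiding_trace(rng: np.random.Generator, n_res: int,
                         step: float = 3.8, min_sep: float = 3.0
                         ) -> np.ndarray:
    coords = np.zeros((n_res, 3))
    for i in range(1, n_res):
        for _try in range(200):
            v = rng.normal(size=3)
            v *= step / np.linalg.norm(v)
            cand = coords[i - 1] + v
            if i < 2 or np.linalg.norm(coords[:i - 1] - cand,
                                       axis=1).min() >= min_sep:
                coords[i] = cand
                break
        else:
            coords[i] = coords[i - 1] + v  # accept a clash rather than stall
    return coords


def generate_structure_pair(n_res: int = 120, noise_sigma: float = 0.0,
                            transform_seed: int = 0, n_disulfides: int = 3,
                            n_lone_cys: int = 2
                            ) -> tuple[StructureModel, StructureModel, dict]:
    """Generate a CA-trace model, plant disulfide bridges, and a copy under
    a known rigid transform plus isotropic Gaussian coordinate noise.

    The manifest records the rotation, translation, noise sigma and the
    planted bridge residue pairs.
    """
    if n_res < 4:
        raise ValueError("n_res must be >= 4")
    rng = np.random.default_rng(transform_seed)
    ca = _self_avoiding_trace(rng, n_res)

    # choose disjoint bridge pairs, preferring spatially close CA pairs
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
    cands = [(i, j) for i in range(n_res) for j in range(i + 3, n_res)
             if 4.0 <= d[i, j] <= 8.0]
    rng.shuffle(cands)
    fallback = [(i, j) for i in range(n_res) for j in range(i + 3, n_res)]
    rng.shuffle(fallback)
    bridges: list[tuple[int, int]] = []
    used: set[int] = set()
    for pool in (cands, fallback):
        for i, j in pool:
            if len(bridges) == n_disulfides:
                break
            if i in used or j in used:
                continue
            bridges.append((i, j))
            used.update((i, j))
    bridges.sort()

    cys_res = set(used)
    sg: dict[int, np.ndarray] = {}
    for i, j in bridges:
        mid = 0.5 * (ca[i] + ca[j])
        u = ca[j] - ca[i]
        u /= np.linalg.norm(u)
        sg[i] = mid - 1.025 * u   # 2.05 A apart, the canonical S-S length
        sg[j] = mid + 1.025 * u
    # lone cysteines whose SG pairs with nothing
    lone = [i for i in range(n_res) if i not in used][:n_lone_cys]
    for i in lone:
        for _try in range(100):
            v = rng.normal(size=3)
            v *= 1.8 / np.linalg.norm(v)
            cand = ca[i] + v
            if all(np.linalg.norm(cand - s) > 4.0 for s in sg.values()):
                sg[i] = cand
                break
        cys_res.add(i)

    def build(coords_ca, coords_sg, model_id):
        atoms = []
        for r in range(n_res):
            res_name = "CYS" if r in cys_res else "ALA"
            x, y, z = coords_ca[r]
            atoms.append((r + 1, res_name, "CA", float(x), float(y),
                          float(z)))
            if r in coords_sg:
                x, y, z = coords_sg[r]
                atoms.append((r + 1, res_name, "SG", float(x), float(y),
                              float(z)))
        return StructureModel(model_id=model_id, atoms=atoms)

    model_a = build(ca, sg, "model_a")
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    ca_b = ca @ R.T + t
    sg_b = {i: R @ v + t for i, v in sg.items()}
    if noise_sigma > 0:
        ca_b = ca_b + rng.normal(scale=noise_sigma, size=ca_b.shape)
        sg_b = {i: v + rng.normal(scale=noise_sigma, size=3)
                for i, v in sg_b.items()}
    model_b = build(ca_b, sg_b, "model_b")
    manifest = {
        "seed": int(transform_seed), "n_res": int(n_res),
        "noise_sigma": float(noise_sigma),
        "rotation": R.tolist(), "translation": t.tolist(),
        "disulfides": [[i + 1, j + 1] for i, j in bridges],
        "lone_cys": [i + 1 for i in lone],
    }
    return model_a, model_b, manifest
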
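# Methods

This note documents the models, parameter choices and numerical
conventions behind `pily-profiler`, and what the synthetic-data tests do
and do not demonstrate about real data.

## Motif model

Motifs are degenerate patterns over the 20 amino-acid letters: fixed
residues, two-letter alternations (`D/N`, parenthesised or not) and `x`
wildcards.  The shipped catalog contains the three Ca²⁺-binding motifs
described for PilY1 proteins — motif 1 `Dx(D/N)xDGxxD` (9 positions),
motif 2 `DxDxNxxxD` (9), motif 3 `DxD/NxDxxxxxxD/E` (12) — plus `RGD`
and the MIDAS site.  The scanner reports **every** occurrence, including
overlaps; presence flags mean "at least one hit".  The ambiguity letter
`X` (to which U/B/Z/J/O are folded on input) never satisfies a fixed
residue but does satisfy a wildcard: an unknown residue cannot be
positive evidence for a motif.

The MIDAS site is discontinuous: a `DxSxS` core followed at a distance
by a Thr and an Asp.  Canonical vWFA MIDAS geometry places the Thr
roughly 6–40 residues and the Asp 7–80 residues downstream of the core
start, but published descriptions do not pin the spacing down.  We
therefore treat the contiguous core as necessary and sufficient for the
MIDAS flag, and annotate the Thr/Asp positions when they occur in those
windows (`T@6-40,D@7-80` in the catalog).  A catalog author can append
`!` to make a tail mandatory instead.  This avoids silently missing
MIDAS sites whose tail spacing falls outside our windows, at the cost of
a permissive flag.

Motifs are scanned over the full annotated sequence, signal peptide
included; restricting the scan to particular domains is left to the
caller via the domain table.  Cysteine counts are exact counts of `C`
over the full sequence.

## Pairwise identity and similarity

Percent identity and similarity between two proteins are computed from
one optimal affine-gap global alignment under EMBOSS-needle semantics:
EBLOSUM62 (shipped as a text matrix in NCBI format), gap open 10, gap
extend 0.5, end gaps free, and a gap of length *L* charged
`open + L·extend`.  The alignment length — the denominator of both
percentages — counts every column, terminal-gap columns included; a
column is *similar* when its substitution score is strictly positive
(gap columns never are).  Since all BLOSUM62 diagonal entries are
positive, identity ≤ similarity always.

The dynamic program is Biopython's `PairwiseAligner` (C kernel) with the
open score shifted by one extend to map needle's gap convention onto the
per-position one.  Where several alignments are co-optimal we keep the
aligner's first traceback, which is deterministic; identity values may
differ minutely between co-optimal tracebacks, so the traceback order is
part of the reproducibility contract.  Exhaustive enumeration over all
global alignments of short sequences is used as the correctness oracle
in the tests.

Region-restricted comparisons (e.g. β-propeller only) are supported via
optional 1-based ranges per record; the default is full length.

## Clade classification

Trees are built by neighbor joining (Saitou–Nei Q criterion) over
*d* = 100 − %identity.  The implementation is in-package because two
details are contractual: ties in Q are broken toward the lowest index
pair in the current working order, and negative branch lengths are
clamped to zero with the deficit moved to the sibling branch, keeping
the path length of the joined pair intact.  The root trifurcates
(unrooted topology).  NJ recovers the generating tree exactly on
additive inputs; this is verified over every 4- and 5-taxon topology.
This distance method deliberately replaces likelihood-based inference:
it is deterministic, fast at desk scale, and sufficient for clade
demarcation when clades are separated by large identity gaps; it is not
a substitute for ML phylogenetics on hard datasets.

Clade labels propagate from reference exemplars (≥ 1 per clade).  A
query inherits the clade of the smallest exemplar-spanning subtree
containing it; queries contained in no subtree — typical when a clade
has a single exemplar — or in several equally small ones fall back to
the nearest exemplar by matrix distance.  Only in that fallback, when
the subtrees conflict *and* the nearest distance exceeds a ceiling
(default *d* > 75, i.e. identity < 25%), is a query left `unassigned`.
Assignments are then checked against the expected clade architecture
(DUF4114 for clades 1.1/1.2; vWFA for 1.3, 1.4b, 1.5–1.7; neither for
1.4a/1.4c): an assignment whose domain flags deviate keeps its label but
is flagged inconsistent.

PCA treats the rows of the identity matrix as feature vectors,
column-centers them, and reports scores along the top-k right singular
axes with explained-variance fractions.  The exact featurization behind
published identity-based PCAs is rarely stated; matrix rows are the
assumption made here.  Sign convention: each component's
largest-magnitude loading is positive, making coordinates reproducible
up to input order.

## Synteny

Gene roles (pilY1, the minor pilins pilX/pilW/pilV/fimU, tfcP, and the
major-cluster core pilQ/P/O/N/M/B/T/C/A) are pipeline inputs, read from
`role=`/`gene=`/`product=` GFF3 attributes in that precedence; role
detection from sequence is out of scope.

* **Clusters** — role-bearing genes chain greedily: two join when at
  most `max_gap_genes = 2` non-role genes intervene *and* the intergenic
  span is ≤ `max_gap_bp = 3000`.  A run with ≥ 5 distinct core roles is
  a major cluster; pilY1 plus ≥ 2 minor pilins a minor cluster; both at
  once a pilY1-embedded major cluster (the Anaeromyxobacteraceae /
  Vulgatibacteraceae arrangement).  A run containing pilY1 that meets
  neither test — including a bare pilX–pilY1 pair — is reported as
  `solitary_pilY1`; its operon context is still visible in the linkage
  call.  Both thresholds are config-exposed; they were chosen to span
  observed operon layouts (≤ 1 intervening gene) with slack.
* **Linkage** — a pilY1 is `linked` iff any minor-pilin gene lies within
  `window_genes = 5` genes on the same contig, strand ignored (linkage
  in comparative work is positional, not transcriptional).  Published
  analyses rarely state their operational criterion; this window is the
  documented assumption here.
* **Translational coupling** — consecutive same-strand CDS with
  intergenic distance `g = next.start − prev.end − 1 ≤ 4` bp, covering
  the canonical 1-bp and 4-bp stop/start overlaps (`g ≤ 0` always
  qualifies).  Strand equality is required: co-orientation is necessary
  for coupled translation.
* **Contig edges** — a pilY1 starting or ending within 2,000 bp of a
  contig boundary is flagged as a possible assembly artifact; without a
  `##sequence-region` pragma the flag is undetermined and logged.

## Structure comparison

Superposition is the Kabsch algorithm on CA atoms paired by residue
index: centroid alignment, covariance SVD, reflection fixed by the sign
of the determinant (rotations only, det = +1).  The default uses all
pairs; an optional iterative outlier-rejection mode (5 cycles, 2.0 σ)
approximates viewers that trim divergent regions, and the mode used is
recorded in the output, because trimmed RMSDs are not comparable to
all-pair RMSDs.  Fewer than three pairs, or collinear coordinates,
are rejected as underdetermined.

Disulfide bridges are called from CYS SG–SG distances ≤ 2.5 Å (the
canonical S–S bond is ≈ 2.05 Å; the margin absorbs model noise), with
greedy matching by ascending distance so each cysteine joins at most one
bridge.  The threshold is config-exposed since predicted-model "bridges"
have no universal criterion.

## Synthetic data: what it emulates

The generator plants the statistical structure the pipeline is meant to
recover, with a manifest that fully determines expected output:

* **Proteome** — nine clade templates.  Cysteine-count medians per clade
  are 1.1: 23, 1.2: 22, 1.3: 35, 1.4a: 21, 1.4b: 25, 1.4c: 17, 1.5: 30,
  1.6: 36, 1.7: 41 (spread ± 2–3).  Lengths are realistic PilY1 sizes
  (900–1700 aa medians) ordered so clade 1.4a is shortest and 1.6/1.7
  longest; no published numeric medians exist for length, so these are
  the package's own defaults.  Motif repertoires follow the reported
  trends: clades 1.1/1.2 carry motif 1 with probability 0.9; clades
  1.4a, 1.4c and 1.7 carry each Ca²⁺ motif with probability 0.05; the
  MIDAS probability is high (0.7) in vWFA clades; RGD is 0.2 throughout.
  Each clade has a conserved core mutated per protein at rate 0.06,
  giving ≈ 80% within-clade identity; independent cores give ≈ 10–15%
  between-clade identity (well inside the ≥ 70% / ≤ 40% separation the
  classification tests assume).  The background alphabet excludes
  cysteine, so the planted per-protein cysteine count is exact, and
  chance motif occurrences are scrubbed by point mutation (never inside
  planted windows) so the scanned motif set equals the manifest exactly;
  a protein whose chance hits cannot be scrubbed is re-drawn, with an
  error after 100 attempts.
* **Genomes** — one contig per named layout: the three *M. xanthus*
  minor-pilin cluster arrangements (cluster 1 with the 4-bp tfcP–pilY1
  coupling overlap; cluster 3 with a trailing accessory gene coupled by
  a 1-bp overlap), the Anaeromyxobacter-style embedded-major layout, a
  solitary unlinked pilY1, and a partial pilX-adjacent layout.
  Intra-cluster gaps are 60–120 bp, filler genes sit ≥ 4 kb away, and
  any unplanned overlap is an error, so coupling calls are exactly the
  planted ones.
* **Structures** — a self-avoiding random CA trace (3.8 Å steps),
  disulfides planted as SG pairs 2.05 Å apart (preferring spatially
  close residues) plus lone cysteines as negative controls, and a second
  model under a known uniform-random rotation + translation with
  optional isotropic Gaussian noise.

All generators are byte-deterministic for a fixed seed.

**Limitations.**  The synthetic data contains no indel evolution, no
domain shuffling, no compositional bias, no annotation errors (split
genes), and clade separation far cleaner than hard real datasets; a
100% recovery there validates the machinery, not performance on
borderline clades.  Published reference values (motif coordinates on
*P. aeruginosa* PilY1, the 7–30 cysteine range over the 15-protein
reference panel, clade cysteine medians and motif prevalence over the
published 150-protein set) are asserted by dedicated tests that read
NCBI-fetched sequences from `data/reference/`; `scripts/fetch_reference.py`
downloads what is accession-addressable, while the 150-protein set and
its clade membership must be assembled from supplementary material.
Published model-vs-model RMSDs are not reproduction targets: they depend
on nondeterministic structure predictions and tool-specific outlier
rejection.

## Problem sizes

The acceptance script and end-to-end test run nine clades × twelve
proteins (108 sequences, 5,778 pairwise alignments), one genome per
layout, and 120-residue structure pairs; oracle checks use 1,000 random
200-mers (motifs), 100–200 short pairs (alignment enumeration), all 18
4-/5-taxon topologies (NJ), and 10,000 sampled rotations on 8-point
clouds (superposition).  These sizes keep the full run at a few minutes
on one core while exercising every code path at the study's scale.
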
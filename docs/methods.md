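# Methods

## Overview

`coevo` analyses residue coevolution within and between a G protein-coupled
receptor (GPCR) subfamily and the Gα subunits it signals through, using
statistical coupling analysis (SCA). The pipeline has five computational
stages — alignment preparation, SCA with sector extraction, sector
refinement, coupling-aware receptor–Gα concatenation with cross-sector
coupling, and amino-acid pattern classification — plus a synthetic-family
generator that provides ground-truthed inputs for every stage.

## Statistical coupling analysis

Let an alignment have positions *i* and symbols *a* over the fixed
21-letter alphabet `ARNDCQEGHILKMFPSTWYV-` (20 residues plus gap, indexed
in this order everywhere).

**Sequence weighting.** Each sequence *s* receives weight
w_s = 1/|{s′ : identity(s, s′) ≥ θ_id}| with θ_id = 0.8 by default;
identity is the fraction of matching symbols over the full alignment
length (gap-vs-gap counts as a match — simpler and documented; the
denominator choice is configurable in effect through θ_id). M_eff = Σ w_s.

**Frequencies.** Regularized single-site frequencies
f_i(a) = (1−λ)·(Σ_s w_s·[x_si = a])/M_eff + λ·q(a) with pseudocount
weight λ = 0.03; pairwise frequencies analogously with the product
background q(a)q(b) for i ≠ j. The diagonal blocks are set to
diag(f_i) exactly — a column paired with itself has no off-diagonal
mass — which keeps f2(i,i,a,a) = f1(i,a) exact.

**Background q.** Standard database amino-acid frequencies with the gap
symbol assigned 0.05 and the residue mass renormalized. Both λ and the
gap background are configurable.

**Conservation.** D_i = Σ_a f_i(a) ln(f_i(a)/q(a)) (nats), the
Kullback–Leibler divergence of the position from background; larger D
means more conserved. A residue-binarized variant D_i(a) and the
conservation-gradient weights φ_i(a) = ln[f(1−q)/((1−f)q)] are also
computed, the latter with f floored at λq and capped at 1−λ(1−q) so the
logarithms stay finite.

**Coupling matrix.** C_ij = ‖φ_i(a)·φ_j(b)·(f_ij(ab) − f_i(a)f_j(b))‖_F
(Frobenius norm over the 21×21 residue pairs). C is symmetric and
non-negative; the diagonal is kept in the matrix (simplest and
consistent) but carries no coevolution information — the randomized null
below has the identical diagonal, so the mode-retention step is not
affected by it.

**Noise cleaning.** Each of n_rand trials permutes every alignment column
independently (preserving composition, destroying inter-column
correlation), recomputes C and records its largest eigenvalue. The cutoff
is the `rand_quantile` quantile of these maxima (default: the maximum);
k★ is the number of real eigenvalues above it. The element-wise mean and
standard deviation of the randomized C are also recorded — they form the
per-pair noise null reused by refinement. n_rand defaults to 100; the
bundled experiments use 10–20 trials, which at their alignment sizes
leaves the cutoff stable while keeping runs at desk scale.

**Sector extraction.** The top k★ eigenvectors are rotated into
independent components (scikit-learn FastICA; a single retained mode is
used as-is), each flipped so its largest-magnitude loading is positive.
Per component, a location-scale t null is fitted robustly — location =
median, scale = 1.4826·MAD, tail index fitted on the inlier bulk
(|z| ≤ 3) only, since a straight t fit is badly distorted when a quarter
of the loadings are signal — and positions beyond the `ic_quantile`
(default 0.95) upper tail qualify. A position qualifying on several
components joins the one with the largest loading magnitude (ties: lower
component index); sectors below `min_size` = 5 positions are dropped.

**Conservation classes.** Sector KLD distributions are compared pairwise
with two-sided Mann–Whitney U tests (significance rendered with the
star convention, `****` for p ≤ 1e−4). A sector is labeled *conserved*
iff its median D exceeds every other sector's and all pairwise p ≤ 1e−4;
the others are *coevolved*.

## Sector refinement

Extraction by eigenvector tail can miss strongly coupled positions and
keep weakly coupled ones. Refinement scores every position by its mean
pairwise similarity to a sector's members and iterates admissions and
removals to a fixed point.

The similarity is deliberately **not** the raw coupling: the φ weights
make every coupling a highly conserved position participates in large,
whether or not any real covariation exists, so the raw mean coupling of
an independently conserved position to a coevolved sector is
systematically elevated. Two corrections are available:

* with a noise-cleaning null available (the default path), the
  similarity is the element-wise z of C against the column-permutation
  ensemble, (C − mean_rand)/sd_rand — genuine coevolution sits tens to
  hundreds of sigma above this null while conservation-inflated noise
  sits near zero;
* otherwise, the conservation-normalized coupling
  C_ij/√(C_ii·C_jj).

Scores are standardized against the non-member score distribution using
robust location/scale (median, Gaussian-consistent MAD), so missed
sector positions do not inflate their own reference. Admission requires
z ≥ z_add = 4 — with of order 10² candidate positions a 2σ cut would
admit the top of the background tail on every iteration — and members
with z < z_drop = 1.5 are dropped. Admissions precede removals within an
iteration, a dropped position is never re-admitted to the same sector
(this, with z_add ≥ z_drop, rules out oscillation), and iteration stops
at a fixed point or after max_iter = 10 rounds with a warning flag.
All three parameters are config-exposed and logged.

## Integrated receptor–Gα analysis

Receptor sequences are joined to Gα sequences family by family using a
primary-coupling table: each receptor sequence contributes one
concatenated row per primary-coupled Gα family of its subtype, so a
dually coupled subtype appears once with each family. Only primary
couplings are used. The Gα partner is the same-species sequence of the
required family; under the default `species-consensus` policy a missing
partner falls back to the family consensus sequence rather than dropping
the row (`species-strict` drops it with a warning). Receptor and Gα
column labels are namespaced `R:`/`G:` so the two numbering schemes
cannot collide, and per-row provenance makes the concatenation losslessly
decomposable.

The coupling matrix over the concatenated sector columns is computed with
the standard SCA formula but **without** noise cleaning or clustering —
the sectors are already defined, and the object of interest is the
receptor × Gα off-diagonal block of C, where inter-protein selectivity
signals appear.

## Amino-acid pattern classification

For one (receptor position, Gα position) pair, rows are split by coupled
Gα family into four groups (fixed order Gi/o, Gq/11, Gs, G12/13), and a
21 × 21 joint amino-acid frequency matrix is counted per family. Each
matrix is flattened row-major to a length-441 vector; the six pairwise
similarities between the four vectors are cosines (L2-normalized inner
products — bounded to [0,1] so the 0.6 threshold is meaningful across
cells; the raw dot product is available behind a flag). Thresholded
similarities define a graph on the four families, and its connected
components give the pattern class — one of the 15 set partitions of a
4-element set. Component closure is the only deterministic rule that
maps all 64 edge configurations onto the 15 partitions without arbitrary
tie-breaking (intransitive similarity A~B, B~C, A≁C lands in one block).
Families with no rows are flagged and classification proceeds on the
remainder.

## Synthetic families

The generator emulates the statistical structure of curated
subtype-labeled alignments without imitating real sequences. Default
shape: 13 receptor subtypes × 45 sequences (585 × 100 positions) and one
Gα sequence per family per species (180 × 60), over the four Gα families
with 16 emulated Gα genes (four per family). Column classes:

* **background** — i.i.d. from the 21-symbol background;
* **conserved** (10 per protein) — one dominant residue with probability
  0.95, the conventional strength of a strongly conserved family
  position;
* **coevolved** (20 receptor / 14 Gα) — the residue is a function of
  subtype (receptor) or gene (Gα) with a 5% flip rate. Each such column
  carries a small variant set (3 residues, subtypes partitioned among
  them) rather than one residue per subtype: subfamily-specific motif
  positions in real alignments show a few variants at intermediate
  frequency, and a 13-variant column would leave every residue near
  background frequency, where the φ weighting (correctly) assigns it
  almost no conservation signal;
* **selectivity** (4 + 4) — the residue is a function of the coupled Gα
  family's grouping block; the default grouping {Gi/o, G12/13} vs
  {Gq/11, Gs} mirrors the observed pattern dichotomy in which Gi- and
  G12-coupled patterns resemble each other. Receptor-side selectivity
  columns follow the subtype's first primary family.

Species tags guarantee every receptor sequence a same-species Gα partner
in every family. One subtype (R01) primarily couples to two families, so
concatenation duplicates its sequences. Gaps are injected uniformly at
1%. Everything is reproducible from the spec's seed, and a ground-truth
manifest records the planted sectors and selectivity assignments.

What the generator does **not** emulate: phylogenetic tree structure
(sequences are exchangeable within subtype), realistic per-family
sequence similarity gradients, indel patterns (gaps are uniform), or
linkage between structured columns beyond the planted classes. Passing
the recovery experiments therefore shows the pipeline detects the
planted statistical structure at realistic sizes and noise levels, not
that it reproduces results on any particular curated alignment.

## Experiment sizes and expectations

* **Null calibration** — 20 i.i.d. background alignments (200 × 50,
  20 randomization trials each): k★ ≤ 2 in ≥ 95% of runs (k★ = 0 in
  most).
* **Planted-sector recovery** — 20 seeds of the default 585 × 100
  family, 10 randomization trials: the best sector matches the planted
  20-position coevolved set with Jaccard ≥ 0.7 after refinement, and
  refinement never lowers the mean Jaccard. The extracted sector
  typically also contains the 4 selectivity positions — they genuinely
  covary with subtype — which caps the attainable Jaccard near
  20/24 ≈ 0.83.
* **Selectivity recovery** — the planted (receptor, Gα) selectivity cell
  ranks in the top 5% of the cross block and classifies to the planted
  family grouping; permuting Gα family annotations before pairing
  collapses the cell value and lowers the block median. The partition
  label of the planted cell survives the shuffle — rows are conditioned
  on the coupling table, so the receptor side alone still separates the
  blocks — which is why the negative control is asserted on the coupling
  values, not the labels.

## Numerical choices and degenerate inputs

Frequency normalizations hold to 1e−12 and the coupling matrix is
symmetrized against rounding asymmetry. All logarithms are in nats.
Alignments with ragged rows, label/column mismatches, empty
post-filtering results, unknown Gα family names, duplicate coupling
rows, zero-frequency pattern matrices and singleton sectors raise hard
errors; missing metadata, empty overlap sets, sub-minimum sectors in
conservation tests and subtypes absent from the coupling table degrade
with warnings. k★ = 0 is a valid outcome that yields no sectors. Gap
filtering iterates to a fixed point so that preprocessing is idempotent.

## Known limitations

* The refinement scheme (similarity measure, thresholds, iteration
  policy) is this package's own concrete instantiation of a
  post-extraction add/drop step; other instantiations are defensible.
* Pairing of individual receptor and Gα sequences in the concatenation
  is by species with a consensus fallback; real orthologue mapping is
  richer.
* The independent-component rotation uses FastICA; with a single
  retained mode no rotation is possible and the eigenvector is used
  directly.
* Conservation classes need at least two sectors; a lone sector stays
  `unassigned`.
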
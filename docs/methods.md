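# Methods

`panmag` studies a simple question with a controlled simulation: what does
the degraded quality of metagenome-assembled genomes (MAGs) — fragmentation
into contigs, incomplete sequence recovery, and contamination by foreign
fragments — do to bacterial pan-genome analysis, and how much of the damage
can analysis choices (gene-caller mode, core-gene threshold, paralog
splitting, mixing in complete genomes) repair?  Everything is measured
against a synthetic species whose gene families, coordinates and functional
categories are known exactly, so every loss or false recovery can be
audited against ground truth.

## The synthetic species

A species is a set of gene families.  Core families (default 200) occur in
every genome; accessory families (default 150) occur in a uniformly drawn
fraction of genomes (default prevalence 0.15–0.85, membership
`round(prevalence * n)`, round-half-to-even); each genome additionally
carries its own unique genes (default 15).  Every family has a random
ancestral open reading frame (ATG … stop, length a multiple of 3, default
300–1,500 nt) and a single-letter COG-style category.  A genome's copy of a
family is the ancestor with independent per-site substitutions at rate *d*
(`within_family_divergence`, default 0.01, substitution to one of the other
three bases uniformly).  Two copies then agree per site with probability

    E[identity] = 1/4 + 3/4 (1 - 4d/3)^2,

0.980 at d = 0.01 — far above any clustering threshold in use, while
unrelated genes score ~0.5–0.6 under the identity defined below.  Model
construction rejects any *d* for which this expectation does not exceed the
highest identity threshold to be tested.

Genes are laid out in a fixed order shared by all genomes (no rearrangement
simulation — the phenomena under study concern presence, not synteny) on a
circular chromosome, separated by per-genome random intergenic spacers, and
no gene spans the origin.  Strand is a family property.  A "genus partner"
species for inter-species contamination re-mutates every ancestor at
`genus_divergence` (default 0.30) before per-genome mutation, which pushes
partner-vs-resident identity to ~0.7, safely below the lowest clustering
threshold, and guarantees inter-species contaminants never merge into
resident clusters.

**Scale choice.**  The desk preset keeps 350 shared families (≈280 genes
per genome) but uses long intergenic spacers (8–12 kb) so the chromosome is
≈3 Mb.  The fragmentation mechanism is driven by the dimensionless ratio
(fragments × gene length / genome length) — the probability that a cut
lands inside a gene — not by gene count.  Long spacers therefore preserve
the cut-probability regime of real bacterial genomes under the published
fragment-count grid (50–400) while keeping clustering tractable on one CPU;
the cost is an unrealistically low coding density, which none of the
measured statistics depends on.

## MAG simulation

Three steps, in order, each with exact bookkeeping:

1. **Fragmentation.**  *k* cut positions drawn uniformly without
   replacement on the circle give exactly *k* contigs whose lengths sum to
   the genome length (grid 50/100/200/300/400; or a mean-fragment-length
   mode with k = round(genome/length)).  Contigs keep source orientation
   and record their exact source interval.
2. **Incompleteness.**  Whole contigs are removed in uniform-random order
   until the target fraction (1–5%) of the parent's bp is gone; only the
   last-removed contig is trimmed (the surplus is handed back from one
   random end), so the realized fraction is exact to 1 bp.  Removing whole
   contigs mirrors binning loss.
3. **Contamination.**  A random donor genome — same species, or the genus
   partner — is fragmented and its contigs appended until the target
   fraction (0.5–4%) of the parent's *pre-removal* size has been added;
   the last fragment is tail-trimmed, which makes contaminant sequence
   nested across increasing levels under a fixed seed (useful for
   monotonicity checks).  The fixed pre-removal denominator keeps levels
   auditable.  Donors are held out of the analyzed dataset by default.

Per-genome levels are either fixed or drawn from truncated normals with
configurable spread.  Mixed datasets replace `round(f% · n)` randomly chosen
parents by their paired MAGs; a parent never contributes both.

## Gene calling

Contigs carry provenance, so calling is a deterministic lift of the true
annotations — the surrogate isolates the one behavioural difference that
matters here: what a caller does at contig edges.  A gene fully inside a
contig is called in both modes.  A gene cut by an edge is *lost* in
`normal` mode (Prokka/Prodigal-style, as consumed by Roary/BPGA-like
pipelines) and *partially called* in `meta` mode (Prodigal metagenome mode,
the Anvi'o default) when the retained piece is at least
`max(min_partial_fraction × gene length, min_call_length)` — defaults 0.5
and 90 nt, plausible caller floors.  Pieces are trimmed to the annotated
reading frame (5'-intact pieces keep the start frame, 3'-intact pieces the
end frame).  Contaminant contigs are lifted against their donor's
annotations.  An optional `spurious_rate` emits a junk call per truncation
event (family sentinel `SPURIOUS`), modelling frame-shifted false
predictions; it defaults to 0 so the mechanism stays deterministic.
The all-or-nothing normal-mode rule is a deliberate modelling choice: it is
the simplest mechanism that reproduces the observed contrast (fragmentation
hurts normal-mode pipelines, not metagenome-mode ones).

## Clustering and classification

Identity between two sequences is matches / aligned columns of the best
end-free alignment under unit match score and zero mismatch/gap penalties,
with ties broken toward the fewest aligned columns and terminal overhangs
excluded from the length.  Excluding overhangs is essential: a partial call
is a codon-trimmed substring of a family member and must reach ~100%
identity to its full-length representative, as it does in real clustering
tools.  The objective is encoded in one integer (`matches · 2^20 −
columns`), so an off-the-shelf local-alignment DP maximises it exactly and
both matches and columns decode from the optimal score; production
clustering uses a k-mer-seeded banded version of the same DP (band 16),
exact whenever the optimal path stays in the band — always the case for
substitution-only sequences — and verified against the full DP in the test
suite.  `prefilter=False` forces the full DP everywhere.

`greedy_besthit` processes calls by decreasing length (then id); a call
joins the best-matching representative at or above the identity threshold
(default 90%), else founds a cluster whose representative it becomes.
`single_linkage` (connected components of the match graph) exists as the
oracle-friendly alternative.  Optional paralog splitting reproduces the
Roary-style artefact: a cluster with several members in one assembly is
re-seeded on that assembly's paralogs and every member joins its
highest-identity seed, recursively — so an intra-species contaminant copy of
a core gene splits the family into sub-clusters that no longer span all
assemblies, expelling it from the 100% core.

Clusters are classified against the presence/absence matrix: core at
`ceil(t·n/100)` assemblies (ceil implements "found in ≥ t% of genomes"
literally), soft-core ≥ 95%, shell ≥ 15%, cloud below 15%.  The bins are
configurable; a core threshold below the cloud bound is rejected.

## Evaluation statistics

* Core-count decay over fragment count x is summarised by ordinary least
  squares of ln y on x (`y = e^(ax+b)`), with adjusted R² =
  1 − (1−R²)(n−1)/(n−2) and a two-sided t-test on the slope.
* Recovery under a relaxed core threshold compares the simulated core set
  with the reference (complete-genome) core set at the same threshold:
  a simulated core cluster is a true positive if its representative matches
  any reference representative at ≥ the clustering identity threshold
  (`identity` mode; one documented knob governs clustering and matching) or
  shares the hidden family label (`oracle_labels` mode, valid on synthetic
  data only; the two must agree on divergence-separated data).  Recall
  divides by the reference core set, precision by the simulated one,
  F-score is their harmonic mean; 0/0 ratios are reported as missing, never
  as 0 or 1.
* Coverage of increased core genes: of the clusters the *reference* gains
  when relaxing the threshold from 100% to t, the fraction also gained by
  the simulated dataset (matched by the same rule).
* Replicate summaries report mean, median and sample SD (n−1).

## Trees and enrichment

The single-copy core families (exactly one member per assembly) are
concatenated into a positional alignment: the generator is
substitution-only, so members are placed by their offset within the gene
and missing ends become gaps; no real MSA is needed (a real-MSA hook would
be the extension point if indel evolution were added).  Distances are
p-distances with gaps excluded pairwise, or Jaccard distances on
accessory-gene presence.  Trees are built by neighbour joining (scikit-bio)
with taxa sorted for deterministic tie-breaking — a deliberate substitute
for maximum likelihood: on substitution-only synthetic data, topology
comparison gains nothing from ML, and NJ keeps the pipeline deterministic
and dependency-free.  Comparison metrics are the normalized
Robinson–Foulds distance (RF / 2(n−3) for fully resolved unrooted trees,
otherwise RF over the total bipartition count) and the fraction of the
first tree's non-trivial bipartitions shared by the second; both are
invariant to leaf order and rooting.

Enrichment of category c in a gene set (core / accessory / unique
clusters): with background fraction q of c among all categorized clusters
and k of the set's m categorized members in c, p = P[Binomial(m, q) ≥ k]
(upper tail, i.e. enrichment), Benjamini–Hochberg adjusted across
categories.  Uncategorized clusters (including `SPURIOUS`) are excluded
from both numerator and background.  The significance cutoff is a reporting
choice (default 0.05), not baked into the statistic.

**Null calibration.**  The calibration check shuffles category labels
independently of core status and requires the p-values to pass a
Kolmogorov–Smirnov uniformity test at α = 0.01 over 500 nulls.  Binomial
p-values are discrete, hence slightly conservative; to make the KS check
meaningful the calibration uses a large synthetic pan-genome (20,000
clusters, 2,000 core, two balanced categories), where the atom sizes
(~0.02) are well below the KS critical value.  Small category counts would
fail the test through discreteness alone, which is a property of exact
tail tests, not a miscalibration.

## Closed forms used as oracles

* Fragmentation loss (normal mode): a gene of length L survives k uniform
  circular cuts with probability C(G−(L−1), k)/C(G, k); the test suite
  verifies this by exhaustive enumeration on a toy genome and by Monte
  Carlo at desk scale.
* Incompleteness (F equal fragments, m removed): an interior gene survives
  with probability (F−m)/F; a boundary-spanning gene is lost.  The expected
  number of families retained in the 100% core is the sum over families of
  the product over genomes of these per-gene survival probabilities
  (boundary status is deterministic given the realized coordinates); the
  observed mean over ≥20 seeds must sit within 3 Monte-Carlo standard
  errors.

## Orchestration and reproducibility

`ExperimentConfig` (YAML-serialisable) holds the species model, grids,
personas (`roary_like` = normal calling + paralog split, `bpga_like` =
normal, `anvio_like` = metagenome mode), threshold grids, mixed fractions,
replicates and a master seed.  Per-stage seeds are derived by hashing
(master seed, stage, grid cell), so replicates are independent yet any
stage reproduces in isolation; identical configs give byte-identical
summaries.  `run_experiment` writes long-format TSVs per stage plus a
`summary.json` stamped with the config hash.  The `panmag` CLI exposes the
stages as subcommands (`simulate-species`, `simulate-mags`, `call-genes`,
`build-pangenome`, `evaluate`, `compare-trees`, `enrich`, `run-all`).

### Problem sizes

The default test and acceptance runs use the desk preset (20 genomes, 350
shared families, ≈3 Mb chromosomes); statistical checks use 5–20 seeded
replicates per condition and the full published level grids.  These sizes
were chosen so the whole assessment reruns from scratch in minutes on one
CPU while leaving the monotonicity and calibration statistics well clear of
their decision boundaries.

## What the generator does and does not emulate

It emulates: controlled family structure with realistic within/between
identity separation, single-copy genes, circular chromosomes, the
fragmentation/incompleteness/contamination process with exact accounting,
and caller edge behaviour.  It does not emulate: codon usage, GC skew,
indel evolution within genes, operons and rearrangements, mobile elements,
chimeric joins, reverse-complemented fragments, coverage-correlated binning
bias (real mis-binning is not uniform over the genome, so random removal
likely *overstates* core loss relative to real MAGs), or real read
assembly.  Conclusions transfer as mechanisms, not as effect sizes on any
particular real species.

## Known limitations

* The identity definition, while made exactly well-posed, is one of several
  schemes real tools use; absolute identity values below ~0.9 are not
  comparable across schemes (thresholds are, which is what the analyses
  use).
* The k-mer prefilter cannot propose joins between sequences that share no
  12-mer; at the divergences the generator produces this never occurs, but
  clustering arbitrary external sequences near a 80% threshold should use
  `prefilter=False`.
* Prevalence of accessory families is uniform and independent; real
  accessory-gene frequency spectra are U-shaped.
* The per-genome level distributions for `sampling="distribution"` are
  truncated normals with user-supplied spread, a stand-in for empirical
  MAG-quality catalogue distributions, which are not shipped.
* Because genomes are sampled i.i.d. from the family ancestors, the true
  phylogeny of a synthetic species is a star.  Reconstructed topologies are
  therefore noise-resolved and absolute nRF values against the original
  tree sit high (~0.8 at 20 taxa); only the *direction* of the degradation
  effect (more degradation → no smaller median nRF) is meaningful, which is
  what the tree-distortion check asserts.  Real species with clonal
  structure would show lower absolute distances.
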
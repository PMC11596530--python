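# Methods

`primertrace` analyses how a trained cellulolytic community (a "primer",
obtained by incubating soil with a cellulosic substrate) is assembled from
its source soil and substrate.  This note documents the models, conventions
and numerical choices behind each stage, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Origin classification

Every ASV detected in a primer community is classified by pooled
presence/absence in its source communities: present in both soil and
substrate → **Common**, soil only → **FromSoil**, substrate only →
**FromSubstrate**, neither → **Unique**.  Presence in a source group is the
group's summed reads over its replicates reaching `presence_min` (default 1
read) — the pooled reading is the more permissive of the per-replicate vs
pooled alternatives, and `presence_min` exposes the stricter choices.  The
four categories partition the primer's detected ASVs exactly, and read
totals are conserved through classification and summarisation (asserted in
tests).  An ASV is a **major** taxon when its summed primer reads strictly
exceed `major_threshold` (default 600); the boundary value 600 itself is
minor.

The interesting category is Unique: taxa that look like they appeared from
nowhere.  The working hypothesis is that most of them are real source taxa
whose reads dropped below the detection limit in the finite-depth source
observation.  The pipeline makes that hypothesis testable in two ways:
nearest-neighbour resolution (below) and the dropout experiment built into
the generator.

## Alignment and p-distance

Unique ASVs are resolved against the pooled soil + substrate reference
sequences by minimal p-distance under pairwise alignment.

* **Algorithm.** Needleman–Wunsch-style dynamic programming with *free
  terminal gaps* (semi-global / overlap alignment), linear gap cost.
  Amplicon variants may differ in trimmed length, and penalising terminal
  overhangs would inflate the distance between biologically identical
  variants.  Default scoring: match +1, mismatch −1, gap −2 — the simplest
  scheme whose optima are stable for near-identical sequences; configurable.
* **Determinism.** Traceback tie order is fixed (diagonal > up > left, fixed
  end-point preference), and the orientation is canonicalised to the
  lexicographic order of the two sequences, so `align(a, b)` and
  `align(b, a)` are exact mirror images even when several alignments share
  the optimal score.
* **p-distance.** Mismatching base–base columns divided by comparable
  columns; gap columns and columns containing an ambiguity code are
  excluded.  Zero comparable columns is an error, never a distance of 0.
* **Minimum coverage in nearest-neighbour search.**  The optimal free-end-gap
  alignment of two *unrelated* random amplicons is usually a short,
  near-perfect suffix–prefix overlap: measured on random 250-mers, roughly a
  fifth of pairs reach p-distance < 0.02 over a median of ~10 columns.  A
  raw minimal-p-distance search would therefore be dominated by such
  spurious overlaps.  `resolve_unique` only considers a reference eligible
  when its optimal alignment covers at least `min_coverage` (default 0.5) of
  the shorter sequence in comparable columns, falling back to the full pool
  (with a warning) if no reference qualifies.  With this rule, a variant a
  few substitutions away from its parent — whose alignment spans the whole
  amplicon — always outranks unrelated references.
* **Ties.** References whose distances are co-minimal (within 1e-12) are
  considered jointly.  The reported possible source is **Common** when the
  co-minimal set touches both pools (including a single reference present in
  both), otherwise Soil or Substrate; this matches the three-way source
  vocabulary without inventing a priority order.  The reported nearest id is
  the first co-minimal reference in pool order.

The per-source summary reports, for each of Common/Soil/Substrate: the
summed primer reads of the group's Unique ASVs and the mean, Q3 and maximum
of their distances.  Q3 is the 75th percentile with linear interpolation
between order statistics (no convention was prescribed; this is numpy's
default).  Distances are kept at full precision internally and rendered to
2 decimals (halves away from zero) only at the I/O layer.

## Synthetic community generator

The generator produces the study design in miniature with known ground
truth, since real denoised tables carry none.

* **Taxa and sequences.**  A species-rich soil (default 200 taxa) and a
  species-poor substrate (default 30), sharing `n_shared_taxa` (default 20)
  taxa.  Sequences are uniform-random DNA of `seq_length` (default 250 nt,
  the scale of a 16S v3–v4 amplicon), kept pairwise-separated at ≥ 5% of
  sites by rejection sampling so that nearest-neighbour truth is
  unambiguous.  Uniform-random DNA is deliberate: the distance logic does
  not depend on base composition, and realistic phylogenetic structure is a
  non-goal.
* **Abundances.**  Log-normal relative abundances (μ = 0, σ = 1.5), the
  standard neutral-ish rank-abundance model; no abundance model was
  prescribed.  Independent draws per community.
* **Observation.**  Multinomial sampling at `depth_source` /
  `depth_primer` reads per replicate (defaults 20,000, bracketing a reported
  mean depth of ~22,000 and minimum of ~10,000), 4 replicates per community.
* **Primer assembly.**  Each of `n_primer_taxa` (default 100) slots draws a
  category from the recruitment fractions (defaults: soil 0.65, substrate
  0.10, shared 0.15, novel 0.10 — soil-dominated, as observed for trained
  communities), then picks a taxon from that pool without replacement;
  category overflow beyond a pool's size is reassigned deterministically
  (soil-only, then shared, then substrate-only).  Novel variants mutate a
  random source parent (soil-biased 0.8/0.2, mirroring the observation that
  over three-quarters of unique taxa trace to soil) at `mutation_rate`
  (default 0.02) per base, always to a different base and conditioned on at
  least one substitution; the realised substitution fraction is recorded as
  the true parent distance.  The conditioning shifts the expected distance
  by ~1e-4 at the default rate — accounted for where tests compare against
  the binomial expectation.
* **Dropout.**  `subsample_observation` (identical machinery to `rarefy`)
  draws a without-replacement multivariate-hypergeometric subsample per
  sample; rare source taxa that fall to zero everywhere become undetected,
  converting truly-recruited taxa into apparent Unique ASVs — the mechanism
  the dropout experiment quantifies.
* **Determinism.**  All draws flow from one `numpy` `SeedSequence`; the
  primer stage uses a child stream of the same seed.  Identical parameters
  and seed give bit-identical tables, sequences and truth.

What the generator does **not** emulate: chimeras, PCR and sequencing bias,
phylogenetically realistic sequence evolution, compositional correlations
between communities, or fungal (ITS) data.  Passing tests therefore show
that the *pipeline logic* is correct under a clean mixing-and-dropout model,
not that real communities satisfy that model.

## Diversity kernels

* **Rarefaction** is without replacement (multivariate hypergeometric) to a
  common depth, default 10,000 reads; samples below depth raise an error
  naming the sample.  Rarefaction is applied before richness; whether to
  rarefy before beta-diversity is left an explicit choice (default: alpha
  only).
* **Observed ASVs**: count of taxa with ≥ 1 read.
* **Bray–Curtis**: Σ|aᵢ−bᵢ| / Σ(aᵢ+bᵢ); two all-zero vectors are an error.
* **PCoA**: classical scaling — square, double-center, eigendecompose.
  Axes are ordered by descending eigenvalue; negative eigenvalues (expected
  for Bray–Curtis input) are dropped from the explained-variance denominator
  and reported in the log, with no Cailliez/Lingoes correction by default;
  each axis's sign is fixed so its largest-magnitude loading is positive.
  Cross-checked against scikit-bio's implementation in the test suite.

## Efficiency statistics

* **Decomposition level** = 100 × (initial − final) / initial percent
  dry-mass loss of the applied substrate (default vessel: 10 g dry substrate
  + 1 g primer inoculum + 30 mL water; the substrate mass is the basis).
  No ash correction is applied — whether the published weight loss was
  ash-free is unstated — and apparent mass gains clamp to 0 with a warning.
* **Correlation screen**: pairwise Pearson |r| over the chemistry panel;
  parameters are linked when |r| exceeds the threshold (default 0.7) and
  reported as connected components; the decomposition level is the preferred
  representative.  Zero-variance parameters are excluded with a warning.
* **Rank-sum test**: two-sided Wilcoxon rank-sum (independent samples —
  treatments are separate vessels, so the paired signed-rank variant does
  not apply) for every treatment pair within a substrate.  The null is
  enumerated exactly (all C(n+m, n) rank assignments, midranks for ties;
  two-sided p = probability of a rank-sum at least as far from its null
  mean) when n+m ≤ 12, and otherwise uses the tie-corrected normal
  approximation via the Mann–Whitney U.  Stars: ** for p < 0.01, * for
  p < 0.05.  No multiplicity correction by default (the published pairwise
  stars are raw); Benjamini–Hochberg is available behind a flag.  Note the
  exact test is discrete: at balanced sizes 5–6 the largest attainable level
  below 0.05 is ≈ 0.032–0.041, while sizes (4, 8) attain ≈ 0.0485 — the
  calibration simulation uses (4, 8) for that reason.

## Problem sizes

Validation uses desk-scale configurations chosen to keep every check sharp:
200 + 30 taxa with 20 shared for classification experiments, ~100 novel
variants aggregated over six seeded runs for resolution fidelity, 20 seeds
for the dropout contrast, 2,000 replicates for rank-sum calibration and 100
seeded runs for the ordination structure check.  All-pairs alignment is
affordable at these pool sizes (a 250-nt alignment costs a few
milliseconds), so no k-mer prescreening heuristic is used.

## Known limitations

* PERMANOVA, taxonomic annotation, phylogenetic (UniFrac) metrics and
  abundance-weighted source apportionment (FEAST/SourceTracker-style) are
  out of scope.
* The possible-source label for ties spanning both pools ("Common") is one
  defensible reading of a three-way source vocabulary; an alternative
  priority-ordered rule would change only tie cases.
* p-distance excludes gap and ambiguous columns; conventions that count gap
  positions would give slightly larger distances on length-variant pairs.
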
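# Methods

This note documents the models, estimators and design choices behind
`phylochem`, the assumptions they rest on, and what the synthetic-data
tests do and do not establish about real data.

## Data model

The unit of observation is one compound × species occurrence: an opaque
structure key (InChIKey), an accepted species with genus/family/clade, the
per-structure descriptors MW (Da), XLogP, TPSA (Å²), Fsp³ ∈ [0, 1] and
C/N/O atom counts, and chemical-class labels. Occurrence data are
presence-only; all diversity and distance computations are therefore
incidence-based, with a compound's "abundance" within a family defined as
the number of that family's species containing it.

Missing numeric descriptors are represented as absent (NaN), never zero.
The C/O ratio is undefined (absent, record retained) for oxygen-free
compounds. Negative atom counts are rejected.

## Harmonization and consolidation

Taxonomic name matching is exact-string after whitespace collapsing and
case folding, against a user-supplied synonym backbone; fuzzy matching is
deliberately out of scope (resolving orthographic variants is the
backbone's job). The backbone's genus/family assignment is authoritative
for matched records — conflicting family assignments in the occurrence
table are overwritten. Unmatched or unresolved names are dropped and
counted; harmonization never invents records and is idempotent.
Consolidation keeps the first-seen record per (InChIKey, species) and logs
a warning if duplicate rows disagreed on descriptor values, because
per-structure metadata should be constant and disagreement indicates dirty
input rather than signal.

## Chemical-core filtration

Two sequential filters, promiscuity first:

1. A compound is removed everywhere if its family breadth exceeds
   `max_families` (default 6, **exclusive**: removal at > 6) or if it
   occurs in at least `max_species_frac` (default 0.20, inclusive) of all
   distinct species in the harmonized input. The comparator is exposed in
   `FilterConfig` because both conventions appear in the literature.
   Breadth is computed on the dataset as given; to reproduce a
   global-repository breadth, supply the full export rather than a subset.
2. Within each family, a compound needs `min_species_per_family` (default
   2) supporting species, or all its records in that family are removed. A
   compound can survive in one family and fall in another.

A compound that is both promiscuous and a family singleton is accounted
under promiscuity (the filters run in that order). Raising the support
threshold never grows the core; raising the breadth threshold never
shrinks it; occurrences are conserved across the three bins
(core + promiscuity-removed + support-removed). `build_core` is idempotent
on its own output.

Retention percentages are rounded half-up to 1 decimal and chemical
densities (core compounds / kept species) to 2 decimals, matching the
precision conventions of published accounting tables. Clade densities are
unweighted means of member-family densities computed before rounding.

## Diversity estimators

Hill numbers of order q ∈ {0, 1, 2} are computed from incidence
frequencies (`p_i = Y_i/U`); general q is unsupported by design. Sample
coverage uses the incidence Good–Turing estimator
`Ĉ = 1 − (Q1/U)·[(T−1)Q1/((T−1)Q1 + 2Q2)]`, which is 1 when there are no
unique incidences.

Coverage-standardized profiles interpolate expected richness at t ≤ T
sampling units via `Ŝ(t) = S_obs − Σ_i C(T−Y_i, t)/C(T, t)` (computed with
log-gamma for stability) and extrapolate beyond T with the Chao2 asymptote
(bias-corrected `Q1(Q1−1)/2` fallback when Q2 = 0). For q = 1, 2 at t ≤ T
the expected rarefied frequency spectrum
`E[Q_k(t)] = Σ_i C(Y_i,k)·C(T−Y_i,t−k)/C(T,t)` is plugged into the Hill
formulas; this reproduces `Ŝ(t)` exactly at q = 0 and matches exhaustive
subset enumeration (tested for T ≤ 6). For extrapolated t > T, q1 and q2
are held at their observed, near-asymptotic values and the profile row is
flagged — order-1/2 extrapolation machinery was judged not worth its
complexity for these data. Coverage at non-integer t is linearly
interpolated between integer-t values; extrapolation is capped at 2T and
families that cannot reach the target coverage within the cap are flagged
rather than extrapolated further.

The biosynthetic plasticity index is the Shannon entropy of a family's
chemical-class proportions; it is reported with log10 compound richness
and their Pearson correlation across families.

## β-diversity partitioning

Baselga's additive decomposition, both Jaccard (β_jac = β_jtu + β_jne) and
Sørensen (β_sor = β_sim + β_sne) families, is computed for family-POOLED
compound sets — one comparison per unordered family pair, since the
family is the unit of macroevolutionary comparison; species-level structure
lives in the ordination stage. Both families are always computed; the
Jaccard triple is the default reported. Identities hold to 1e−12 and both
implementations are cross-checked against explicit set arithmetic on
random pairs. The turnover ratio β_jtu/β_jac is undefined (NaN) for
identical sets.

Clade summaries group pairs as within-clade (per clade) or between-clade;
the Kruskal–Wallis test runs across the within-clade groups only, since
between-clade pairs mix lineage effects. Grouping is a reporting choice,
not baked into the partition code.

## Ordination and permutation statistics

Species are subsampled uniformly without replacement to at most
`n_max = 200` per family (no upsampling below the cap); the cap's adequacy
can be checked with `dispersion_stability`, which recomputes dispersion
across a grid of subsample sizes.

PCoA double-centers −½D² (Gower) and eigendecomposes; coordinates are
√λ-scaled on positive axes. Negative eigenvalues — expected for Jaccard
matrices — are reported, not corrected (no Cailliez/Lingoes). PERMANOVA
uses the standard one-factor sums of squares from the distance matrix with
free whole-label permutations and plus-one p-values
(`p = (1 + #{F* ≥ F})/(1 + n_perm)`), so p is never 0; ties on F (e.g.
permutations reproducing a perfect split) count as exceedances.
Dispersion (betadisper analogue) embeds units with positive- and
negative-eigenvalue axes kept separately; squared distances to the group
centroid subtract the imaginary-axis part and are floored at zero, the
standard treatment for non-Euclidean dissimilarities. Group comparison is
a permutation F on the distance-to-centroid values.

## Traits

The unit of analysis is the unique compound per clade (a compound in
several families of one clade counts once per clade); occurrence weighting
is available via `weighted=True` but not default, to avoid weighting
descriptor distributions by literature sampling depth. Standardization
uses sample (n−1) standard deviations throughout. Clade contrasts:
tie-corrected Kruskal–Wallis, pairwise two-sided rank-sum tests, and BH
correction applied within one descriptor's set of pairwise tests (the
"family" of hypotheses is the pairwise set for that descriptor, not all
descriptors jointly). Compact letter displays are derived greedily from
the adjusted significance matrix: groups share a letter iff not
significantly different.

## Drivers, networks, phylogenetic signal

Chemical-class profiles count distinct core compounds per unit per class;
unclassified compounds pool into an excludable column. Ward clustering
Hellinger-transforms the counts, z-scores columns (constant columns
dropped with a warning) and agglomerates under Ward.D2 (scipy's `ward` on
the transformed coordinates). Branch support is the ordinary bootstrap
probability over column-resampled replicates; multiscale (AU) correction
is intentionally not implemented — plain bootstrap probabilities answer
the same stability question with far less machinery, at the cost of a
known slight conservatism.

The random-forest stage (scikit-learn, default 2000 trees) predicts clade
from species-level profiles; importance is permutation-based accuracy
decrease (the mean-decrease-accuracy analogue), and out-of-bag accuracy is
reported. Per-family driver shares restrict a family's class counts to the
top-k drivers (default k = 25) and normalize to 100% per family — the
normalization is per family, which is one explicit choice among several
plausible ones.

Bipartite metrics apply log1p to the family × class counts. H₂′
standardizes the two-dimensional Shannon entropy by margin-constrained
extrema: with real-valued (not integer) fills, the maximum-entropy table
under fixed margins is the outer product of the margins, so
H₂max = H(rows) + H(cols) exactly; H₂min comes from greedy mass
concentration (repeatedly saturating the largest remaining row/column
margin pair). H₂′ = (H₂max − H₂)/(H₂max − H₂min) is clipped to [0, 1]; it
is exactly 0 for margin-independent matrices and 1 for equal-weight
diagonal matrices. Barber's bipartite modularity Q is maximized by greedy
label moves from `restarts` seeded random initializations with the
single-module partition (Q = 0) as a floor; exhaustive partition search is
used only as a test oracle (≤ 6 nodes).

The phenetic UPGMA tree is built from Jaccard distances between
family-pooled core compound sets (consistent with the β stage; class-profile
Euclidean distances can be substituted). Node heights are half the
agglomeration distances, so root-to-tip distances are equal (ultrametric)
and an ultrametric input matrix is reproduced exactly.

Blomberg's K uses the tree's shared-path covariance V (V_ij = root-to-MRCA
path length) with the GLS mean, standardized by the Brownian expectation
`(tr V − n/(1ᵀV⁻¹1))/(n−1)`; on a star phylogeny (V ∝ I) K = 1 identically.
Significance is a tip-permutation test with plus-one p-values. Brownian
traits simulated on a fixed tree give mean K ≈ 1 (calibrated over 1000
replicates on a 32-tip tree in the acceptance suite).

## Synthetic data: what it emulates, and what it does not

The generator plants, with one global seed (per-stage seeds derived by
hashing the stage name):

- a promiscuous background pool whose family breadth follows a shifted
  Poisson truncated to [2, n_families] (mean 8 by default, i.e. most
  background compounds exceed the >6-family threshold; a fixed-breadth
  override exists for exact-removal checks) — emulating a heavy-tailed
  diffuse background generated by low-specificity enzymes;
- per-family core compounds with species support ≥ 2 (shifted truncated
  Poisson, mean 3), per-family singletons, and compounds shared between
  family pairs (`shared_fraction`, default 0.02 of the per-family core,
  which puts cross-family overlap of the filtered core in the
  ~10–20% range);
- clade-shifted descriptor distributions whose default locations follow
  the empirical clade contrasts the pipeline is meant to resolve
  (lipophilic/nitrogen-rich vs hydrophilic/high-MW vs oxygen-rich
  regimes): normal XLogP, normal log10 MW, half-normal TPSA, clipped
  normal Fsp³, Poisson atom counts. Shared compounds draw descriptors from
  one member family's clade, chosen at random, and the generating clade of
  every compound is recorded in the ground truth — recovery tests compare
  recovered clade means against the exact planted mixture mean, so the
  check is calibrated (pure Monte-Carlo error) rather than biased by
  cross-clade sharing. Note the clipped Fsp³ mean differs slightly from
  its location parameter, so recovery checks use XLogP and TPSA;
- one diagnostic chemical class per family (allocation weight 0.35) and
  per clade (0.15) over a base of five ubiquitous classes;
- a synonym backbone (aliases for a `synonym_rate` fraction of species,
  plus orthographic variants and unresolvable names) and a corruption
  helper that swaps accepted names for aliases without changing row
  counts.

Separately, `plant_turnover_pairs` constructs independent set pairs whose
Jaccard turnover share hits a requested target exactly up to integer
rounding, by solving the partition identity for the exclusive-count ratio.

Default species pools mirror a 3-clade × 4-family design with realistic,
strongly unbalanced family sizes (48–3787 species). The test suite and the
acceptance script run a proportionally scaled design (12 families,
10–60 species each, 30 core compounds per family) so the whole suite
completes in well under a minute per stage; problem sizes are stated in
each test.

What passing these tests shows: the estimators implement their definitions
correctly (oracle and identity checks), permutation tests hold their
nominal level, and planted structure of the kinds listed above is
recovered. What they do not show: robustness to literature sampling bias
beyond the breadth distribution, to taxonomic error not representable as
backbone aliases, to descriptor measurement error, or to real biosynthetic
correlation structure between classes — none of which the generator
models. Quantities tied to a particular repository snapshot (absolute
occurrence counts, specific retention percentages, specific PERMANOVA R²)
are properties of the data, not the method, and are only checked at the
level of arithmetic on published accounting tables.

## Numerical conventions

- Rounding of reported percentages/densities: decimal half-up (not
  banker's), 1 and 2 decimals respectively.
- Combinatorial terms via log-gamma; `C(n, k) = 0` for n < k.
- Monte-Carlo p-values always use the plus-one rule.
- Ties in sorting importance tables are broken stably (mergesort).
- Degenerate inputs fail loudly: empty datasets, all-zero profile rows,
  constant traits for K, sd = 0 columns for z-scoring, singleton groups
  for PERMANOVA.

## Known limitations

- Exact H₂′ extrema are NP-hard in general; the greedy/analytic bounds
  used here are the field's standard practice but are heuristics for
  H₂min on adversarial margins.
- The greedy modularity optimizer can stall in local optima on large
  networks; restarts mitigate but do not guarantee optimality (exhaustive
  search verified only for tiny cases).
- Hill q = 1, 2 are not extrapolated beyond the observed sample size.
- PERMANOVA is one-factor with free permutations; no strata, nested
  designs or distance corrections.
- The UPGMA tree is phenetic: Blomberg's K on it measures conservation of
  traits along *chemical* affinity, which is an assumption to be aware of
  when interpreting it as phylogenetic signal.
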
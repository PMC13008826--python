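# phylochem

Phylometabolomic analysis of compound–taxon occurrence data: from raw
compound × species occurrence tables (e.g. exports of open natural-product
repositories such as LOTUS) to a curated **chemical core** and its
macroevolutionary structure across plant lineages.

The package is aimed at researchers in chemotaxonomy, chemical ecology and
plant macroevolution who want a tested, scriptable pipeline for questions
like: *is chemical divergence between lineages driven by metabolite
replacement (turnover) or by subset retention (nestedness)? Do clades occupy
distinct physicochemical neighborhoods? Which chemical classes diagnose
which lineages?*

## What it computes

**Chemical core curation.** Occurrence records are harmonized against a
taxonomic synonym backbone, consolidated to one record per
(InChIKey, species), and filtered in two steps: a *promiscuity filter*
removes compounds recorded in more than `max_families` families (default
&gt; 6) or in ≥ 20% of all species, and a *within-family support filter*
removes compounds found in only one species of a family. Per-family
retention, chemical density (core compounds per retained species) and
cross-family overlap are reported in an accounting table.

**Diversity.** Incidence-based Hill numbers per family — with incidence
frequency `Y_i` (number of species containing compound *i*), `U = Σ Y_i`
and `p_i = Y_i/U`:

    q = 0 : S_obs                     (richness)
    q = 1 : exp(−Σ p_i ln p_i)        (Shannon-effective)
    q = 2 : 1 / Σ p_i²                (Simpson-effective)

plus evenness `q1/q0`, and coverage-based rarefaction/extrapolation to a
target sample coverage (default Ĉ* = 0.95) so families with very different
species pools are comparable.

**β-diversity partitioning** (Baselga framework, Jaccard and Sørensen
families) for every unordered family pair:

    β_jac = (b+c)/(a+b+c),  β_jtu = 2·min(b,c)/(a+2·min(b,c)),  β_jne = β_jac − β_jtu

where `a` is the shared compound count and `b`, `c` the exclusive counts.
The *turnover ratio* `β_jtu/β_jac` quantifies the share of dissimilarity due
to replacement; summaries include clade groupings and a Kruskal–Wallis test.

**Ordination and dispersion.** Species-level Jaccard distance matrices on a
standardized subsample (default 200 species/family), PCoA with Gower
centering (negative eigenvalues reported), one-factor PERMANOVA
(999 permutations, plus-one p-values) and multivariate dispersion
(distance-to-centroid with the real/imaginary axis split).

**Traits.** Global z-scored hybrid chemical space (log10 MW × XLogP),
per-clade descriptor summaries (MW, Fsp³, XLogP, TPSA, N count, C/O) and
Kruskal–Wallis + BH-corrected pairwise rank-sum contrasts with compact
letter displays.

**Drivers and structure.** Random-forest classification of clades from
species-level chemical-class profiles with permutation importance;
Hellinger/Ward (ward.D2) clustering with bootstrap support; bipartite
family × class metrics (H₂′ specialization, Barber modularity *Q*); a
phenetic UPGMA tree from chemical distances; and Blomberg's *K* with a
tip-permutation test for phylogenetic signal in biosynthetic traits.

**Synthetic data.** `phylochem.synth` generates occurrence tables with a
known planted structure (promiscuous background pool, family-supported
cores, singletons, shared compounds, clade-shifted descriptors, diagnostic
classes, synonym backbones), so every stage is testable without downloads.

## Worked example

```python
from phylochem import synth, ingest, core_filter, beta, ordination

cfg = synth.SynthConfig(
    species_per_family=(30, 25, 12, 18, 20, 10, 22, 19, 60, 15, 40, 35),
    n_background_compounds=40, core_compounds_per_family=30,
    singletons_per_family=15, seed=1,
)
occ, truth = synth.generate_occurrences(cfg)
backbone = synth.generate_backbone(cfg, occ)
occ = synth.corrupt_species_names(occ, backbone, rate=0.3, seed=1)

dataset, report = ingest.harmonize_taxa(occ, backbone)
dataset = ingest.derive_elemental(ingest.consolidate_structures(dataset))
core, filt = core_filter.build_core(dataset)

parts = beta.pairwise_family_partitions(core)
summary = beta.turnover_summary(parts, core.clade_map())

sub = ordination.subsample_species(core, n_max=200, seed=1)
inc = sub.species_incidence()
fams = sub.records.drop_duplicates("species").set_index("species")["family"]
D = ordination.jaccard_distance_matrix(inc)
res = ordination.permanova(D, [fams[s] for s in inc.index], n_perm=999, seed=1)
```

printed output:

```
records in: 2601  (direct 2528, synonym 73, dropped 0)
core: 1642/2601 occurrences (63.1%), 30 promiscuous compounds removed
66 family pairs, mean turnover share 99.9% (Kruskal-Wallis across clades p = 0.138)
PERMANOVA (family): R2 = 0.12, p = 0.001
```

Reading: harmonization resolved all synonym aliases back to accepted names
(2601 records conserved); the two-step filter kept 63.1% of occurrences as
family-supported core chemistry; across all 66 family pairs virtually all
compositional dissimilarity is due to compound replacement rather than
nestedness, at a rate that does not differ among clades; and family identity
still explains a significant share of species-level chemical composition.

A full run (all stages, all output tables, a manifest) is one call:

```bash
phylochem simulate --seed 1 --out data/
phylochem init-config --out cfg.yaml   # then point it at data/
phylochem run-all --config cfg.yaml
```

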
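# Methods

This note documents the models, conventions and numerical choices behind
`digiprot`, in the order the pipeline runs.

## Coordinates, lengths, and the structural identity

GenBank convention throughout: 1-based, inclusive coordinates, so an exon
`a..b` has length `b − a + 1` nucleotides.  A complete CDS includes its stop
codon, while the annotated translation does not, so for any clean record

    cds_nt = 3 × (protein_aa + 1).

Protein length is taken from the `/translation` qualifier when present and
from CDS arithmetic (`cds_nt/3 − 1`) otherwise; the identity above makes the
two sources agree, and the QC stage flags records where they do not
(`translation_mismatch`).  Summed over a species this yields the exact
structural identity `mean_EN × mean_EL(pooled) = 3(mean_PL + 1)`, which the
test suite asserts to float tolerance on every synthetic proteome — it is
the arithmetic backbone of the exon-architecture analysis.

For `complement(...)` locations, exon spans are reported in translation
order (descending genomic coordinates); lengths are unaffected.

## Quality control

Records are excluded when they carry any of: partial-boundary markers
(`<`/`>` anywhere in the location), a translation not beginning with
methionine, a coding length not divisible by three, a translation length
inconsistent with the coding length, a `/pseudo` qualifier, or an
unsupported location (`order(...)`, cross-contig references, mixed
strands).  A species is retained only when at least `min_per_species`
(default 500) records survive.  The 500 threshold follows from the
lognormal shape of protein-length distributions: the relative standard
error of a sample mean is CV/√n with CV = √(exp(σ²) − 1), which at a
typical σ ≈ 0.8 and n = 500 is ≈ 4.2% — below that sample size, species
means and medians are too noisy to compare.  All CDS features are ingested;
splice isoforms are not collapsed (redundancy filtering has been shown to
affect these statistics only marginally, and the reference dataset was
likewise unfiltered).

## Summary conventions

* Mean exon number: total exons ÷ number of genes.
* Pooled mean exon length (default): total exonic nt ÷ total exons.
  A gene-first variant (average within gene, then across genes) is computed
  alongside, since some comparative datasets were historically summarised
  that way; the two coincide exactly when all genes have the same exon
  count.
* Group aggregation is computed at both levels and labelled: unweighted
  averages of species means (`species_means`) and recomputation over the
  union of records (`pooled_proteins`).  They coincide when species sample
  sizes are equal.
* Medians of even-sized samples: mean of the two central order statistics.
  Percentiles: type-7 linear interpolation (`numpy.percentile` default).
* Distribution fits: lognormal by closed-form MLE on logs (μ = mean of
  logs, σ = population SD of logs); gamma by iterative MLE with location
  fixed at 0 (scipy), reported as shape/rate.  Model choice by AIC with
  k = 2 for both; AIC = 2k − 2·loglik.

## Cross-lineage inference

Protein-length distributions are heavily right-skewed, so lineage
comparisons use rank statistics: a tie-corrected Kruskal–Wallis omnibus
test (χ² reference, g − 1 df), followed by pairwise two-sample
Kruskal–Wallis tests — on two groups this is the tie-corrected rank-sum
χ² test — with Benjamini–Hochberg adjustment over all g(g−1)/2 pairs at
α = 0.05.  The post-hoc letter display uses the insert-and-absorb
algorithm: start with one letter covering all groups; for each
significantly different pair sharing a letter, split that letter into two
copies each missing one endpoint; absorb any letter whose group set is a
subset of another's.  Two groups share a letter iff their adjusted p ≥ α.
Exhaustive checking against a brute-force minimal edge-clique-cover search
shows the algorithm returns a minimum-size labelling for every significance
pattern on up to five groups (beyond that minimality is not guaranteed,
matching standard practice).

Wilcoxon tests (paired signed-rank with zero-difference removal, unpaired
rank-sum) use exact p-values for n ≤ 25 without ties and the normal
approximation with continuity correction otherwise.

## The length hyperplane

Species-level mean protein length is regressed on mean exon number and mean
exon length by OLS, optionally with the EN×EL interaction.  Because of the
structural identity, the interaction coefficient is pinned near 1/3 and R²
near 1 whenever the summaries derive from CDS arithmetic; refitting on the
14 published lineage rows gives an interaction coefficient of ≈ 0.336 and
R² ≈ 0.999, and the published coefficients evaluated at each lineage's
(EN, EL) reproduce its mean protein length within 2.4% (worst case: the
Excavata group, whose single giant exons sit at the edge of the design).
Percentage contrasts between lineages are reported as integers, rounded
half away from zero, with the reference in the denominator (the "than"
operand: *A* is X% larger **than B** ⇒ 100(A−B)/B).

Domain-count tables are summarised as relative-frequency histograms, tail
fractions P(domains ≥ k), and the OLS slope of protein length on domain
count (aa added per additional domain).

## Independent contrasts

Cross-species regressions are confounded by shared ancestry, so the
exon-architecture regression is repeated on Felsenstein's independent
contrasts.  The implementation is from scratch on a minimal tree structure
(Newick parsing delegated to dendropy):

* **Midpoint rooting**: the root is placed halfway along the longest
  leaf-to-leaf path.  Ties are broken toward the lexicographically smallest
  endpoint pair, for determinism.  Total tree length is conserved; an
  already-midpoint-rooted tree is returned unchanged.
* **Zero-branch pruning**: leaves with zero-length terminal branches are
  removed (they make contrast standardization degenerate) and unary nodes
  suppressed with branch lengths summed.
* **Contrasts**: postorder; at each node, contrast (x_i − x_j)/√(v_i+v_j),
  ancestral value the 1/v-weighted mean, parent branch extended by
  v_i·v_j/(v_i+v_j).  A strictly bifurcating rooted tree is required;
  polytomies raise an error instructing resolution rather than being
  silently resolved, since zero-length resolution branches would conflict
  with the pruning policy.
* **Regression**: forced through the origin (contrast signs are
  arbitrary), with R² computed about zero.  When an interaction predictor
  is requested, the contrast of the per-species product EN×EL is used (the
  product of contrasts has no BM interpretation).
* Traits enter untransformed by default; a log-transform is available but
  off.

Correctness is checked two ways: slope agreement to 1e-8 with a brute-force
GLS oracle that inverts the full BM covariance matrix on trees of ≤ 8
leaves, and calibration of the BM simulator (contrast variance ≈ the
simulated rate; leaf variance ≈ rate × depth).  Slope recovery on 100-leaf
trees over 200 replicates returns the generating slope within ±0.05.  The
published contrast regression on the real 233-species rRNA tree (R² = 0.67,
exon number significant, exon length not) requires that external tree and
is not reproduced here; the package demonstrates the same qualitative
behaviour on simulated trees.

## Endosymbiotic dilution and orthologs

The dilution model is a count-weighted mixture: blending n₁ migrant
proteins of mean m₁ into n₂ host proteins of mean m₂ gives
(n₁m₁ + n₂m₂)/(n₁ + n₂), strictly between m₁ and m₂.  With the published
scenario (3,500 × 319 aa into 22,900 × 472 aa) the blend is 451.7 aa —
bounded well above the 436-aa Streptophyta mean, which is the arithmetic
refutation of the dilution hypothesis.  The ortholog comparison computes
mean(plant − cyanobacterium) over positionally paired lengths with a paired
Wilcoxon test; all-identical pairs are flagged degenerate rather than
raising.

Compartment summaries join protein lengths to GO-slim cellular-component
annotations (a protein annotated to several categories counts once in
each, as in the published tables whose column sums exceed the proteome
size), compute n/median/mean/SD per category, attach Kruskal–Wallis
letters, and order rows by descending median.

## Synthetic data

The generator is parameterised by lineage profiles tied to the published
group statistics.  Protein lengths are lognormal with σ = √(2 ln(mean/median))
and μ = ln(median), so a profile reproduces both printed statistics in
expectation.  Exon counts are 1 + Poisson(mean_EN − 1) — at least one exon,
the target mean, modest dispersion.  The coding length 3(L+1) nt is
partitioned uniformly at random into the drawn exon count; intron gaps are
uniform in [50, 500] nt and strands random, both cosmetic since only exon
arithmetic is consumed downstream.  Records are written as GenBank flat
files without sequence data (locations and `/translation` qualifiers carry
everything the pipeline reads).  Ortholog pairs draw cyanobacterial lengths
lognormal (σ = 0.6, arithmetic mean fixed at the requested base) and add a
Normal(shift, sd) plant offset floored at 1 aa.

What the generator does **not** emulate: real sequence content (codon
usage, splice signals), annotation errors, isoform structure, transposon
contamination, or phylogenetic correlation between species within a group.
Passing end-to-end tests therefore demonstrate that the pipeline's
arithmetic, statistics and plumbing are correct at realistic effect sizes
and sample sizes — not that the biological conclusions would survive those
real-data complications; those are exactly the artifacts the QC and
redundancy discussions above address.

## Problem sizes and determinism

Default test/acceptance scales, chosen to estimate each quantity with
comfortable margin: 2,000 replicates for the Kruskal–Wallis type-I
calibration (SE ≈ 0.5 pp at the 5% level); 200 Brownian replicates on
100-leaf trees for slope recovery; 1,339 ortholog pairs (the published set
size); and an end-to-end dataset of 2 lineages × 5 species × 2,000 genes
(per-species SE of the mean ≈ 2%, pooled ≈ 0.9%, against a 5% acceptance
band).  Every stochastic routine takes an explicit seed (or a seed derived
from the acceptance script's `--seed`); nothing touches global random
state, so identical inputs and seeds are bit-reproducible.

## Known limitations

* Real GenBank oddities beyond the QC taxonomy (trans-splicing, fuzzy
  `one-of` positions, joined records) are excluded, not modelled.
* The gamma fit fixes location at zero; distributions with a hard lower
  offset would need the three-parameter variant.
* The letter-display algorithm guarantees minimal letter counts only up to
  five groups (verified exhaustively); larger tables may use a letter more
  than strictly necessary.
* Midpoint rooting assumes a clock-like enough tree for the midpoint to be
  meaningful; no outgroup rooting is provided.
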
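# Methods

This note documents the models, estimators and design choices behind
lineage-scope, and what the synthetic panel does and does not emulate.

## Data model

Genotypes are unphased alternate-allele dosages {0, 1, 2} with a dedicated
missing sentinel, for diploid biallelic SNPs only. The intended organisms
are highly selfing, so heterozygosity is treated as a residual/QC signal,
never as phase-bearing information. Sites are kept sorted by
(chromosome, position, id); VCF positions are 1-based throughout, and the
only 0-based coordinates produced are half-open BED intervals in painting
tracks, following each format's convention. Swapping a site's ref and alt
alleles maps dosage d to 2 − d for non-missing calls.

## Synthetic panel

The generator produces the statistical structure the analysis assumes,
with ground truth for every planted feature.

**Lineage divergence.** Ancestral allele frequencies are Uniform(0.1, 0.9)
per site. Each lineage draws its frequency from the Balding–Nichols
distribution Beta(p(1−F)/F, (1−p)(1−F)/F) with F = `divergence_f`
(default 0.5, matching the deep L1–L2 split). This model is used because
pairwise F_ST between the daughter populations has expectation ≈ F,
which turns the divergence parameter into a recoverable quantity: the
acceptance checks require the Hudson estimate to land within ±0.05 of the
planted F across seeds.

**Inbred genotypes.** One allele is drawn from the lineage frequency and
duplicated (dosage 0/2); with probability `residual_het` (default 0.002)
the second allele is redrawn. Defaults for noise are `missing_rate` 0.02
and symmetric `error_rate` 0.001 (a flipped call moves to one of the other
two states uniformly); both are applied after all hybrids and planted
features, so the recorded truth stays clean.

**Substructure and geography.** Each lineage is split into two
subpopulations by a second Balding–Nichols round (`l1_substructure_f`
0.08, `l2_substructure_f` 0.05 — weaker than the main split, as observed
intra-lineage structure is). Passport geography is *correlated with* the
genetic substructure — a longitudinal east/west cline within L1 and an
altitudinal split (~150 m) within L2 — but isolation by distance is not
modeled genetically: coordinates are drawn per subpopulation, not per
individual kinship. Correlations of PC2/PC3 with geography therefore test
that PCA finds the planted substructure, not a continuous cline model.

**Derived (wheat-like) panel.** `wheat_founder_count` (4) haplotypes are
drawn from the simulated L2 samples; panel frequencies follow a further
Balding–Nichols bottleneck round around the founder frequencies. This
guarantees the derived panel carries no allele absent from L2 — so every
L1-private allele observed in it is a planted introgression. At
`wheat_introgression_sites` (10) L1-private sites, exactly
`wheat_introgression_carriers` (3) wheat lines receive the L1 allele;
`wheat_single_carrier_sites` (2) additional sites get exactly one carrier
as the negative control for the ≥ 2-carrier consensus rule.

**Hybrids.** Nine per default panel, mirroring a realistic mix: one F1
(one haplotype from each chosen parent, heterozygous wherever the parents
differ), one recombinant inbred line (per-chromosome 2-state Markov mosaic
over site order with expected `ril_breakpoints_per_chrom` = 2 switches,
fully homozygous), and a 7-member "hybrid lineage" sharing a single
mosaic prototype plus 20 fixed and 5 segregating group-exclusive alleles.
The prototype uses a much denser switch rate
(`hybrid_breakpoints_per_chrom` = 25): a lineage descended from a
hybridization event followed by intercrossing shows diffusely interleaved
private alleles, unlike the RIL's clean blocks, and the painting-clarity
statistic is designed to separate the two. Mosaics are simulated over site
order rather than genetic map distance because painting operates on site
order only.

All draws flow from one seeded generator, so a config is bit-reproducible.
What the simulator does **not** emulate: linkage disequilibrium beyond the
mosaic block structure, ascertainment bias of GBS discovery, allele-
frequency clines within subpopulations, and selection. Passing
parameter-recovery tests on this panel shows the estimators are correct
under the stated model, not that real GBS data meets the model.

## QC cascade

Order: site filters → allelic-tag test → sample filters → outgroup-private
removal, with per-stage dimensions logged. Defaults: site MAF ≥ 0.01,
site missingness ≤ 0.20, site heterozygosity ≤ 0.05 (a selfing panel),
sample missingness ≤ 0.80, sample heterozygosity ≤ 0.05. Samples are
removed when they exceed *either* threshold. MAF is allele-count based
(a het contributes one alternate allele).

The allelic-tag test asks whether a site's calls behave like one Mendelian
locus. If two paralogous tags were collapsed, samples carrying both
appear heterozygous and samples carrying neither appear missing, so the
2×2 table [[n_het, n_hom_ref], [n_hom_alt, n_missing]] shows an excess on
the het/missing diagonal. A site is flagged when the two-sided Fisher
exact p-value falls below alpha/n_sites (Bonferroni over the sites
entering the test, alpha = 0.001) **and** the odds ratio
(n_het·n_missing)/(n_hom_ref·n_hom_alt) exceeds 1 — the directionality
requirement keeps significantly *negatively* associated (well-behaved)
sites from being flagged. P-values are computed by direct hypergeometric
enumeration in log space (gammaln), summing outcomes with pmf ≤ the
observed pmf (relative tie tolerance 1e-9); the suite verifies agreement
with exact integer-arithmetic enumeration to 1e-10 on every table with
n ≤ 60.

Note the cascade is not idempotent in the strict sense on arbitrary data:
removing samples changes site statistics, so a re-run can remove further
borderline sites. Stage dimensions are logged so such effects are visible.

## Diversity and differentiation

Nei's gene diversity is h = 2f(1−f) per biallelic site (frequencies within
the subset, non-missing calls only), averaged over all retained sites —
including sites monomorphic in the subset, which contribute 0. This
panel-wide convention changes the scale relative to a polymorphic-only
average; both modes are available and the default is all-sites.

F_ST uses Hudson's estimator with ratio-of-sums averaging across sites,
chosen for robustness to unequal sample sizes and its clean expectation
under the simulation model; Weir–Cockerham is deliberately not the
default. Per-site terms use pairwise-complete data; sites lacking ≥ 2
allele calls in either group, or with zero denominator, are excluded from
that pair only. Estimates are reported unclamped, with a warning when
negative. One caveat: the sample-size correction assumes independent
allele draws, while inbred samples contribute two correlated alleles; the
resulting bias is O(1/N) and is absorbed by the ±0.05 recovery tolerance.

## Structure

The relationship matrix is the centered-crossproduct genomic relationship
over polymorphic sites, with missing dosages imputed at the site mean
(zero after centering). PCA is its eigendecomposition; reported scores
are eigenvectors scaled by √λ (raw eigenvectors are retained), eigenvector
signs are fixed deterministically, and variance fractions use the
positive part of the spectrum. Euclidean distances are pairwise-complete
with the m/m_obs rescaling used by R's `dist`; omitting the rescaling
would bias distances downward for high-missingness pairs. Neighbor
joining is the standard Saitou–Nei agglomeration on the Q criterion, with
ties broken by the smallest active index pair (evaluated on the upper
triangle only, since floating-point evaluation of Q is not exactly
symmetric) and negative branch lengths clamped to zero with a count kept
on the tree. Admixture-model fitting is intentionally out of scope:
hybrid evidence comes from PCA position plus private-allele
contributions, which identify the same samples independently.

## Lineage-private alleles

A site yields an allele private to lineage A iff that allele has frequency
0 in lineage B, strictly in (0,1) in A, and both lineages have ≥ 50%
non-missing calls there (`min_call_fraction` guards against missingness
artifacts; the threshold is configurable). Fixed inter-lineage
differences are excluded — they are diagnostic of the split, not of
within-lineage ancestry — and a config switch can re-include them for
sensitivity analysis.

Contributions are dosage-weighted (het = 1 copy) so an F1 lands at
~50/50; on inbred accessions this is indistinguishable from carrier
counting. The hybrid flag (minor-lineage share ≥ 0.10 with ≥ 100
informative sites) sits between pure-line noise (~0 under the error
model) and the weakest realistic hybrid signal (~30% minor contribution).
Painting clarity is 1 − switches/max(informative − 1, 1): 1.0 for a
single-block chromosome set, ~0.5 for random interleaving.

Parentage identity is the share of co-genotyped private sites where the
two genotypes share at least one allele (only opposite homozygotes
mismatch). On inbred data this equals dosage equality; for a het F1 it
correctly scores the true parents at 100%. The denominator uses
co-genotyped sites only. The consensus introgression rule assigns a
private site to the minor donor lineage (L1) only when ≥ `min_carriers`
(default 2) derived lines carry the allele — one carrier is treated as
error/convergence — and to L2 only when some derived line actually
carries the L2-private allele, so the summary percentages count carried
alleles rather than all private sites. Lowering `min_carriers` can only
add calls (monotone).

## Core selection

The M-strategy is realized as greedy maximal-coverage set cover over the
observed (site, allele) classes, extended with (trait, category) classes
when phenotypes are supplied; ties break lexicographically so selection is
reproducible. This is a documented surrogate for PowerCore's heuristic,
not a clone, and is benchmarked two ways: against random same-size subsets
(greedy must dominate) and against exhaustive optima on small panels via
the (1 − 1/e) submodular-cover guarantee. SNP classes are 2-state (allele
presence); a 3-state genotype mode is not provided because heterozygotes
in this material are residual. The reduction step formalizes
phenotype-guided manual curation as a quota-constrained weighted greedy:
score = new allele classes + w_pheno × new resistant-trait classes
(default w_pheno = 5; susceptible categories are neutral), subject to
per-group quotas, enabling L1-heavy MiniCore-style compositions. Capture
is the percentage of panel-segregating sites still segregating within the
subset, plus the subset's Nei index.

## Problem sizes

The default panel is 129 samples × 2,000 SNPs on 7 chromosomes — large
enough that every planted feature (9 hybrids, 10 introgression sites,
25 group-private sites, ~850 private alleles) is recovered with clear
margins, while the full test suite and the acceptance script each run in
well under a minute of CPU. F_ST recovery uses 100+100 samples × 5,000
sites per seed; exact-test validation enumerates all 2×2 tables up to
n = 60 in the suite (n = 40 in the acceptance script).
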
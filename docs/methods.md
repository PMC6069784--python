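# Methods

## The population model

`magicpop` simulates and analyses an 8-way MAGIC population of inbred
lines. Eight founders at crossing positions A–H are crossed in four fixed
pairs (A×B, C×D, E×F, G×H); single F1 plants are intercrossed into two
4-way crosses (ABCD, EFGH); 4-way plants are intercrossed — in both
directions — into 8-way seeds; each 8-way plant is selfed and its progeny
advanced by single-seed descent (SSD). The defaults mirror the modelled
study design: 141 8-way seeds from 18 4-way plants per side, ~15 F2 seeds
per 8-way plant, three selfing generations (F1 → F4), 910 retained lines.
Reciprocal 8-way crosses are genetically identical here (no cytoplasmic
effects are modelled); the reciprocal tag is kept only as pedigree
metadata.

Two analytic laws anchor the design and serve as test oracles:

- every line is expected to inherit **12.5%** of its genome from each
  founder;
- a locus, heterozygous by construction in the 8-way F1 (one origin from
  the ABCD side, one from EFGH), remains heterozygous with probability
  2⁻ᵍ after *g* selfing generations — 1/8 at F4.

### Meiosis

Chromosomes are represented as founder-origin segment lists in cM
(haplotype mosaics). Crossover counts per chromosome are Poisson with
mean L/100 and breakpoints are uniform — the Haldane model, without
interference. Crossover interference would shorten the tails of the
segment-length distribution but does not change any expectation the
package tests; the simpler model was chosen deliberately.

### Founder marker panel

`simulate_founder_alleles` draws each SNP's allele-frequency group (AFG:
the number of founders, 1–7, carrying the reference founder's allele)
from the observed per-AFG composition of a 7,584-SNP wheat MAGIC array
(3.4%, 7.0%, 11.6%, 11.1%, 17.3%, 20.9%, 28.7% for AFG 1–7). The
reference founder always carries its own allele, so AFG-1 SNPs are
private to it.

When a genetic map is supplied, carrier sets are locally persistent: a
SNP reuses its left neighbour's carrier set with probability
ρ·exp(−d/λ) (defaults ρ = 0.6, λ = 10 cM). This emulates the shared
founder haplotype blocks that give real marker panels their short-range
LD; without it, simulated r² between even fully linked SNPs is capped
near 0.1 because independent carrier partitions decorrelate the IBS
dosages. With persistence on, a simulated population at study scale
shows r² = 0.2 near 6 cM and a background (95th-percentile unlinked) r²
near 0.02, matching the behaviour such populations show in the field.
The marginal AFG composition is unchanged by the copying.

### Genotyping and trait

IBS dosage = copies of the reference-founder allele (2/1/0); residual
heterozygous loci give dosage 1. Genotyping noise defaults: 2% missing
calls, 0.5% spurious heterozygote calls — typical array behaviour after
QC. The trait model is

    y(line, year, rep) = μ + Σ a·x + Σ (aa/4)·x₁x₂ + Y + GY + ε,

with x = dosage − 1. An additive effect *a* is half the homozygous
contrast (Δ between lines fixed for the two alleles is 2a). The (aa/4)
scaling is chosen so that the two-locus homozygous class-mean contrast
(JJ+NN) − (JN+NJ) equals aa in expectation — i.e. the estimator used
downstream recovers the injected parameter exactly in the noiseless
case. Year effects, genotype-by-year and residual are independent
normals; with one replicate per year the last two are statistically
confounded (see variance components below).

### The unlinked-locus sampler

`sample_unlinked_population` draws genotypes from the exact single-locus
funnel law (one origin uniform on {A..D}, one on {E..H}, residual
heterozygosity 2⁻ᵍ) with every SNP independent. It exists because
calibration checks — chi-square p-value uniformity, null false-positive
rates of the scan — require independent markers, which mosaic-simulated
genomes deliberately are not.

## Genotype QC

Filters (strict inequalities, applied missing → het → MAF so removal
reasons are unambiguous): missing > 10%, heterozygous > 10%, MAF < 1%.
MAF is allele-based with heterozygotes contributing one allele each,
missing excluded. Mean imputation replaces each missing call with the
SNP's mean dosage; it preserves per-SNP means exactly and is only valid
after filtering (a fully missing SNP raises). Unmapped SNPs are placed at
the position of the mapped SNP maximising a 2×2 chi-square of homozygous
dosage classes, with a Bonferroni-corrected 0.05 floor across anchors
below which the SNP stays unassigned.

## Segregation distortion

The expected reference-allele frequency of an AFG-*k* SNP is *k*/8.
Observed allele counts (reference = Σ dosage over non-missing lines, out
of 2N alleles) are tested per SNP with a 1-df chi-square.

**Calibration.** The naive allele-count chi-square treats the 2N alleles
as independent; in an inbred population they are not (the two alleles of
a line are nearly always identical by descent), which inflates the
statistic by ≈ 1+F — measured type-I rates of 15–18% at nominal 5% for
F4 lines. The default `calibration="funnel"` therefore uses the exact
null dosage variance of the funnel design,

    Var(d) = (1−h)·4p(1−p) + h·[q_A(1−q_A) + q_B(1−q_B)],

where p = k/8, q_A and q_B are the carrier fractions on the two funnel
sides (recorded in the AFG table), and h, the residual origin
heterozygosity, is estimated genome-wide from observed heterozygote
counts. This makes the null p-value distribution uniform (verified by KS
at 2,000 independent SNPs; ≥ 1,500 lines are needed before the count
statistic's discreteness stops being visible to a KS test at that SNP
count). `calibration="count"` reproduces the uncorrected textbook
statistic for comparison with count-based oracles.

Bonferroni–Holm is applied genome-wide across all tested SNPs. SDRs are
maximal runs of ≥ 3 adjacent mapped SNPs with adjusted p below 0.01;
distortion direction is recorded per member but not required to be
uniform. Founder-specific selection events group significant AFG-1/7
SNPs by (chromosome, unique founder, direction of that founder's allele
change — inverted for AFG 7, where a reference-allele excess is a deficit
of the unique non-carrier's allele) and report groups with strictly more
than 10 SNPs.

A brute-force enumeration of double-homozygote removal (the dwarf
selection rule) shows that the allele-frequency deficit is *larger at the
rarer locus*: removing a class with allele frequency 1 shifts frequency
by f(1−p)/(1−f), decreasing in p. With ~10% of lines removed, a locus
whose dwarf allele sits in 4/8 founders loses 5.6 points and a 2/8 locus
loses 8.4 points; the tests assert this enumeration.

## Diversity and LD

Similarity is the simple-matching proportion over pairwise-complete SNPs
with states {0, 1, 2} compared exactly; PCA treats the similarity matrix
as data (lines × similarity-to-line variables, column-centered). LD is
the squared Pearson correlation of dosages. "Unlinked" means
inter-chromosomal; the background r² is the 95th percentile of unlinked
pairs (subsampled to 100,000 with a seeded RNG). The decay curve is a
degree-2 locally weighted polynomial regression (tricube weights, span
0.3 by default), written in-package because the available lowess
implementations are degree-1 only; the decay distance is the first
downward crossing of r² = 0.2, linearly interpolated on a 200-point grid.

## Phenotype analysis

Line means are arithmetic means over years (replicates averaged within
year first), which equals the least-squares mean under the balanced
fixed-genotype/random-year layout. Variance components come from
method-of-moments expected-mean-squares ANOVA on lines × years restricted
to lines observed in every year; negative solutions truncate to zero.
With one replicate per year, V_GY and V_R cannot be separated and the
interaction mean square estimates their pooled sum V_E; heritability is
then h² = V_G/(V_G + V_E/y). With r > 1 the full decomposition
h² = V_G/(V_G + V_GY/y + V_R/(y·r)) is used. The package does not
fabricate a V_GY/V_R split it cannot estimate.

Transgressive lines are counted against a least-significant-difference
criterion: a line is transgressive-tall when its mean exceeds the tallest
founder's by more than z₁₋α/₂·√(V_R/n₁ + V_R/n₂).

## GWAS

Line means are regressed on imputed dosages with forward/backward
stepwise selection ("Model-A": no kinship or structure covariate — the
funnel design produces no robust population structure, which the PCA
tests confirm). Forward steps add the smallest partial-F p ≤ 0.001;
backward steps drop any term whose partial p rises above 0.001; ties
break by map position then SNP id, making the fit deterministic.
Candidates whose residual norm falls below tolerance are treated as
collinear and skipped.

The scan repeats the fit over 20 × 5-fold cross-validation (seeded): the
detection count of a SNP is the number of the 100 training-set fits that
selected it. A SNP's validated R² is the mean, over fits that selected
it, of its semi-partial R² refit on the corresponding held-out fold —
this makes per-QTL R² values additive below the model's total R². Final
p-values come from one full-data stepwise fit, Bonferroni–Holm adjusted
**with the family of all scanned SNPs** (step-down factors m, m−1, …).
Adjusting only within the final model would be vacuous — every selected
SNP already has p ≤ 0.001, so Holm over the handful of selected terms
can never reject, and measured null false-positive rates reach 50% per
scan; the genome-wide family restores calibration (0/30 null scans with
an MTA) and matches the magnitude of corrected p-values such scans
report in practice. MTAs (detection ≥ 35 and adjusted p < 0.01) are
grouped into QTL by single linkage within 5 cM on a chromosome,
same-sign effects only; the representative SNP has the lowest adjusted p.
Reported effects are homozygous contrasts (mean of dosage-2 lines minus
dosage-0 lines).

## Epistasis

Single-marker prescreen keeps SNPs with p < 0.15. Every candidate pair
is fitted as y ~ x₁ + x₂ + x₁x₂ on centered dosages — the product term
keeps heterozygous and imputed lines in the test — with
Benjamini–Hochberg FDR across all pairs, significant at q ≤ 0.01. A
joint forward/backward selection over the significant product terms
(main effects always included; collinear main-effect families reduced to
one representative) removes LD-proxy duplicates. Interactions whose
endpoints co-locate within 7 cM (either orientation, single linkage)
merge, represented by the lowest FDR p.

The additive-by-additive effect uses hard homozygous classification
(dosage ≥ 1.5 / ≤ 0.5; intermediates excluded): aa = (JJ+NN) − (JN+NJ).
If exactly one mixed class is empty — the signature of double-dwarf
removal — the missing sum term is substituted by twice the other mixed
class's mean and the record is flagged; an empty homozygous class leaves
aa undefined. The explained epistatic variance of a pair is
100·SS(interaction)/SS(between the four classes) from the two-way
regression decomposition on classified lines.

## Study-scale test conditions

The acceptance-level tests run at sizes chosen to keep the full suite
within a few minutes while preserving the statistics being checked:

- neutral funnel population: 7,584 SNPs × 520 lines (the AFG-1 class then
  holds ~260 SNPs);
- calibration runs: 2,000 independent SNPs × 1,500 lines for p-value
  uniformity; 100 replicates of 1,000 SNPs × 400 lines for the null scan;
- parameter recovery: 840 mapped SNPs × 900 lines, two large loci
  (homozygous contrasts +12.8 and −14.9 cm) placed at balanced AFG-4
  carrier sets, interacting with aa = 13.7 cm, six small QTL (2–5 cm
  contrasts), noise calibrated to h² = 0.9 on a two-year line-mean basis.

The epistatic pair is placed *on* the two large-effect loci, mirroring
the architecture in which the two major height genes are also the
strongest interaction. Balanced (AFG-4) carrier sets at those loci are a
deliberate condition: with an unbalanced partner locus the marginal
homozygous contrast of a locus is 2a + (aa/2)·E[x_partner], so only a
centered partner makes the class-contrast estimator target the injected
contrast. Dwarf selection is off in the recovery run so all four
two-locus classes are populated (selection is precisely what empties a
mixed class and triggers the aa NA rule).

Monte-Carlo acceptance bands use chromosome-cluster standard errors:
per-SNP frequencies and per-line founder shares are dependent within a
population (linkage plus the 18-plants-per-side crossing bottleneck), so
per-chromosome means — approximately independent across the 21
chromosomes — provide the honest error scale. The acceptance script
additionally averages over independently seeded funnel replicates, whose
spread includes the bottleneck variance a single population cannot
reveal.

## What the simulator does not capture

Sequence-level variation (markers are abstract bi-allelic SNPs placed on
a uniform map), crossover interference, cytoplasmic or parent-of-origin
effects, genotyping batch structure, real founder haplotypes (the
persistence model is a one-parameter caricature of them), segregation
distortion of biological origin (only the dwarf-selection rule distorts),
and field-trial spatial structure. Passing tests therefore demonstrate
that the estimators recover what the model family injects at realistic
sizes and noise — not that any particular field dataset satisfies the
model's assumptions.
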
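# Methods

## Model and procedure

The pipeline treats a case–control cohort as two subpopulations of one
source population and asks, per biallelic site, how much allelic variance
separates them. The Weir–Cockerham method-of-moments estimator is used
exactly in its genotype-count form: with r = 2 groups of sizes n_i,
alt-allele frequencies p̃_i and observed heterozygote proportions h̃_i,

- n̄ = Σn_i/r, n_c = (r·n̄ − Σn_i²/(r·n̄))/(r−1)
- p̄ = Σn_i p̃_i/(r·n̄), s² = Σn_i(p̃_i−p̄)²/((r−1)n̄), h̄ = Σn_i h̃_i/(r·n̄)
- a = (n̄/n_c)[s² − (p̄(1−p̄) − ((r−1)/r)s² − h̄/4)/(n̄−1)]
- b = (n̄/(n̄−1))[p̄(1−p̄) − ((r−1)/r)s² − ((2n̄−1)/(4n̄))h̄]
- c = h̄/2, θ̂ = a/(a+b+c); multi-site weighting Σa/Σ(a+b+c).

The estimator is unbiased around 0 with a small negative bias under the
null (both groups drawn from one pool), which is why genome-wide weighted
θ̂ on a homogeneous cohort is typically slightly negative. Sites
monomorphic overall have θ̂ undefined and are dropped from distributions;
missing genotypes are dropped site-wise, never imputed. The test suite
cross-checks this implementation against an independent nested-ANOVA
derivation (allele observations nested in individuals nested in groups)
to 1e−12 on 10⁴ random sites.

Candidate selection flags autosomal sites with θ̂ ≥ 0.05 (inclusive;
configurable) and retains those whose alternate allele is more frequent in
cases. X-chromosome variants are removed before selection because male
hemizygosity breaks the diploid variance partition; they are kept in a
side report. The direction filter is deliberately orientated on the
alternate allele: orienting on "whichever allele is commoner in cases"
would by construction retain every flagged site and make the filter
vacuous.

Blocks are connected components of the genotype-r² graph (squared Pearson
correlation of dosage vectors over pairwise-complete samples) within one
gene, at r² ≥ 0.9. This composite-LD proxy is used instead of EM phasing
because the blocks this design targets are in near-perfect linkage, where
the dosage correlation and the haplotypic r² coincide; the threshold is
exposed because block delineation is genuinely a free choice. A block's
per-sample dosage is the median of member risk-allele dosages, rounding
even-count ties down (toward lower risk); a sample is missing when more
than half the members are missing. Components of size one are reported as
standalone SNPs and excluded from scoring.

The cumulative score is the sum of block dosages (1 per heterozygous,
2 per homozygous risk haplotype), so E[score] = 2·Σp exactly, by
linearity — no independence between blocks is needed. Missing block
dosages contribute 0 and flag the sample low-confidence. Association per
unit is allele-based 2×2 (2n chromosomes per group): this is the one
convention under which odds ratios reconstructed from published group
frequencies reproduce the published values. Fisher's exact p is two-sided
by probability ordering (scipy); the odds ratio has no continuity
correction and is ND when a cell is zero; genotype likelihood ratios are
ND when the control count is zero. No multiple-testing correction is
applied by default, matching the nominal-α design this pipeline
reproduces; a Benjamini–Hochberg step can be layered on by the caller.

Diagnostic evaluation dichotomizes at cutoff 6 (positive ⇔ score ≥ 6,
inferred from the convention that "below six" is the negative portion).
LR+ is computed from confusion counts rather than from rounded
sensitivity/specificity; with counts 42/63 and 3/32 this gives 7.11
exactly, whereas the rounded pair (0.67, 0.93) does not — counts win.
Post-test probability is Bayes on the odds scale; the prevalence-explained
fraction is positive-rate × post-test probability / prevalence.

## Distribution tests

Scores are tested for normality per group with Kolmogorov–Smirnov against
a normal using that group's estimated mean and SD. This is the desktop-
statistics convention and is approximate: estimating parameters from the
same sample makes the test conservative-in-distribution, and integer
scores introduce ties. The location comparison is a one-sided
Mann–Whitney U (cases > controls, the design's a-priori direction);
small tie-free samples use the exact U distribution and everything else
uses midranks with the normal approximation, tie correction and
continuity correction. Against an exhaustive permutation oracle the
exact path agrees to machine precision and the asymptotic path to a few
hundredths at n ≈ 10 with heavy ties — which is why the small-sample
exact path exists.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not sequencing reality. Defaults are the study conditions: 63 cases and
32 controls; eight autosomal risk-haplotype blocks with the published
per-group risk-allele frequencies, genes, hg38 member positions and rs
ids; the four standalone case-enriched SNPs; 200 background variants with
a Beta(0.8, 3) site-frequency spectrum shared by both groups (a
realistically skewed spectrum; the exact shape is a modelling choice);
missing rate 0 by default (rates up to ~10% are exercised in tests); and
an optional X-linked block whose case/control frequencies (0.30/0.12) are
a modelling choice producing divergence of the observed order, since only
a mean F_ST was published for it. Sex is assigned at the study's observed
male fractions (39/63, 15/32), and X-block males are hemizygous (dosage
coded 0/2).

Blocks are sampled at the block level — a latent per-individual dosage
~ Binomial(2, p_group), i.e. Hardy–Weinberg within each group — and
copied to every member SNP, making perfect LD exact rather than
approximate. Partial linkage keeps the latent dosage with probability
√r² and redraws independently otherwise, so the expected dosage
correlation is √r² and its square the target r² (verified by simulation).
Blocks are mutually independent; inter-block LD in the real cohort is
unknown and the score expectation does not depend on it. What the
generator does **not** emulate: read-level error, genotyping batch
effects, population stratification, coalescent allele-frequency
correlations, or recombination within blocks — so green tests show the
statistics and plumbing are right under the assumed model, not that the
biological findings replicate.

## Numerical and design choices

- Internal coordinates are 0-based half-open; VCF positions convert at
  the boundary. Promoter windows are the 1500 bp immediately upstream of
  the TSS, strand-aware, truncated at position 0 with a warning.
- Region classification precedence: UTR > exon > intron > promoter
  (UTRs are tabulated separately from the exons containing them);
  classification is per-gene and total (no hit → intergenic).
- The premature-stop rule: a stop escapes nonsense-mediated decay iff it
  lies in the last exon or ≤ 50 nt upstream of the final exon–exon
  junction; single-exon transcripts escape.
- The HWE exact test conditions on allele counts and sums Levene
  probabilities ≤ the observed configuration (with a 1e−12 relative
  guard against float equality); verified against full enumeration.
- Multi-allelic VCF records are split into biallelic records; for each
  alt, other alt alleles count as reference.
- ND is an explicit None end-to-end; TSV/JSON serialization keeps such
  cells empty/null rather than coercing to 0 or inf.
- `fisher_exact_2x2` returns p = 1 on a zero margin (every table with
  those margins is equally extreme).

## Problem sizes

End-to-end tests and the acceptance script simulate at 630/320 (the
study's arms scaled ×10), where block-frequency estimates are stable to
~0.02 and per-block odds-ratio log-SEs range 0.1–0.2; oracle suites run
10⁴ random sites for the F_ST cross-check and exhaustive enumeration up
to n ≈ 10 per group for rank tests. These sizes were chosen so each
statistical property is measured well inside its sampling noise while
the full suite stays quick to run.

## Known limitations

- Selection at θ̂ ≥ 0.05 is a hard cut on a noisy estimator: at the
  default design, a true block with expected θ̂ ≈ 0.05–0.06 is recovered
  in only a fraction of realizations. This is a property of the design
  being reproduced, not of the implementation; treat near-threshold
  blocks as unstable.
- Odds ratios for blocks with very low control frequency have log-SEs of
  ~0.2 even at the ×10 scale; single-run ORs for such blocks should be
  read with their confidence width in mind.
- The genotype-r² block definition has no recombination model; it will
  merge variant sets that are correlated for any reason, including
  genotyping artifacts.
- KS normality on integer scores is approximate (ties, estimated
  parameters); it is reported as descriptive, not inferential.
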
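# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Polarization

Four parsimony rules decide the ancestral allele of a focal polymorphism
from the outgroup call at the same reference coordinate:

1. outgroup absent or showing only the reference → reference ancestral;
2. outgroup alternate equal to the focal alternate → alternate ancestral
   (a homozygous shared alternate is folded into this rule);
3. heterozygous outgroup sharing exactly one allele with the focal
   ref/alt set → that shared allele ancestral;
4. no shared resolution — including an outgroup carrying *both* focal
   alleles — → masked (`N` in the ancestral reference, excluded downstream).

Multi-allelic focal records are decomposed into per-alt comparisons and
masked if the alts disagree — the conservative extension of rule 4. Indels
are not polarized (the analysis is SNP-based) and pass through unmasked.
No genotype-likelihood or probabilistic reconstruction is attempted; the
rules are deterministic and are tested against an exhaustive enumeration of
all ref/alt/outgroup allele combinations.

## F_ST

Per-site components are the Hudson estimator with the Bhatia et al.
finite-sample correction,

    num = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1),

computed from called genotypes (the sampling design is deep, ≥ 14×, so hard
calls are a faithful substitute for genotype-likelihood machinery; absolute
values from likelihood-based pipelines would differ slightly). Windows are
ratios of sums — Σnum/Σden — which is invariant to how sites are grouped
and avoids the instability of averaging per-site ratios. Windows are
anchored at coordinate 0 (10 kb / 5 kb step by default), terminal partial
windows are kept and flagged, and windows with fewer than 5 SNPs report a
missing value (the floor stabilizes ratios on sparse data). Small negative
values are a normal consequence of the unbiasedness correction.

Outlier regions merge windows above the threshold (0.5 by default);
overlapping or adjacent windows always merge, and the pipeline additionally
bridges sub-threshold interruptions up to one window long so that a single
SNP-poor window does not split a contiguous signal.

Genome-wide values exclude the Z chromosome by default: sex sampling is
uneven between populations and females carry one Z, which distorts
frequencies. The exclusion list generalizes to any chromosome, which also
reproduces the "re-analyse without the inversion chromosome" workflow.

PCA of the column-centred dosage matrix uses plain SVD; component signs are
fixed by forcing the largest-magnitude loading positive so coordinates are
reproducible. Missing dosages are mean-imputed per site.

## Inversion detection and genotyping

In a population where k of T sampled chromosomes carry a non-recombining
inverted haplotype, every SNP fixed on that haplotype has frequency exactly
k/T. The detector therefore works on the integer frequency lattice: it
requires complete-case sites (fixed T), takes each candidate lattice value
0 < k < T in turn, chains SNPs at that value allowing at most
`max_gap_snps` (default 10) off-modal SNPs between consecutive modal SNPs,
trims chain ends while the local modal density in a 25-site edge window is
below `min_modal_fraction`, and keeps chains with ≥ `min_modal_fraction`
(default 0.6) modal SNPs overall, ≥ `min_modal_snps` (default 10) of them,
and a span ≥ `min_span` (default 100 kb, matched to the desk-scale genome).
Runs at frequency 0 or 1 are ignored; fewer than 4 sampled chromosomes is
refused outright because the lattice is too coarse to be informative.
The thresholds are exposed because the detector itself is a package design
(the original workflow combined read-pair structural-variant calls with
visual inspection of frequency plots, neither of which is a reusable
algorithm); read-pair breakpoint evidence is out of scope and printed
breakpoints are treated as interval arithmetic only, with interval length
computed as end − start on 1-based breakpoints to match how such lengths
are conventionally reported.

Samples are genotyped by their carried-derived-allele fraction over the
tract's modal SNPs: < 0.25 ancestral homozygote, 0.25–0.75 heterozygote,
> 0.75 inverted homozygote — robust to sporadic genotyping error on long
tracts. Hemizygous samples are carrier/non-carrier at 0.5 and contribute a
single chromosome to the carrier tally. Samples missing more than half the
tract SNPs are set unknown and excluded from the frequency. Concordance
with a focal variant is the fraction of samples whose variant genotype
class matches their inversion class.

The r² profile is the squared Pearson correlation of genotype dosages
averaged over SNP pairs in nonoverlapping windows (50 bp by default, the
resolution used on dense real data; synthetic data are ~100× sparser, so
the packaged tests pass 50 kb through the same parameter).

## Population statistics

Degeneracy classes come from the standard nuclear codon table (table 1,
configurable): a CDS position is 4-fold if all substitutions preserve the
amino acid, 0-fold if none does, else "other". Genes whose joined CDS is
not a multiple of 3 or contains an internal stop are flagged and excluded.
Positions claimed by overlapping frames with conflicting classes collapse
to "other" for genome-wide statistics while remaining gene-specific for
per-gene statistics. Effects are resolved in CDS frame (strand-aware);
stop-loss requires a canonical stop reference codon ({TAA, TAG, TGA}) and a
non-stop alternate.

Per-gene pN is the nonsynonymous SNP count over the gene's 0-fold position
count and pS the synonymous count over the 4-fold count, using sites
segregating within the population; population values are medians across
genes (robust to outlier genes), with pN/pS reported only where pS > 0.
π uses the unbiased per-site heterozygosity 2p(1−p)·n/(n−1) averaged over
all class positions, and Tajima's D is the standard normalized difference
(π_total − S/a₁)/√(e₁S + e₂S(S−1)) with the usual constants, computed on
complete-case sites so n is fixed; D is reported as 0 and flagged when
S = 0, and n < 4 is refused. Between-species dN/dS and SFS-likelihood
estimators are out of scope.

## Anchoring

Votes are aggregated per (new scaffold, chromosome) weighted by aligned
bases; the raw count of contributing old scaffolds is reported alongside so
the simpler counting rule can be audited (base weighting is robust to
swarms of tiny fragments). The top chromosome wins; ties are ambiguous and
support below 10 kb is unassigned. When the runner-up exceeds 20 % of the
top's bases, the scaffold is either flagged `split_synteny` — if the two
chromosomes' intervals occupy disjoint halves under the best split point,
with less than 10 % of bases misplaced — or called ambiguous. Manual
overrides (e.g. cytogenetic evidence) are applied afterwards, flagged, and
keep the original call in provenance. Scaffold ordering within chromosomes
is not inferred.

## Expression specificity

SPM along a dimension is the category's mean expression divided by the sum
of category means; the linear proportion is the default (it matches the
"proportion of expression" definition and the 0.90 worked example), with
the squared variant available via `squared=True`. A gene is labelled with a
category when its SPM reaches 0.70, else unbiased; zero-expression genes
are unlabelled and excluded from counts. The stage dimension uses only
tissues sampled in all three stages (head, midgut, fat bodies) so stage
contrasts are not confounded by tissue availability; the sex dimension uses
only sexed libraries; gonad libraries split into ovary/testis tissue
categories by sex. Composition tests are Pearson χ² on the 2 × k
inside/outside table without continuity correction (df = k − 1); categories
absent from both margins are collapsed with a warning, and p-values are
reported raw (a handful of tests, no multiplicity correction by default).

The default condition grid (18 libraries over 3 stages × 7 tissues with
sexed gonads/adult antennae) is a package default reconstructing a typical
availability design; it is fully configurable through the design table.

## Synthetic data generator

The generator produces the *statistical structure* the analysis assumes,
not sequence evolution: no coalescent, no recombination graph, no read or
quality simulation, no mapping bias.

- **Background differentiation.** Balding–Nichols: ancestral derived-allele
  frequency p ~ Uniform(0.05, 0.95); population frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F). Independent draws give pairwise Hudson
  F_ST ≈ (F_i+F_j)/2, so per-population F is solved from the pair targets by
  non-negative least squares. Defaults target the neutral-site estimates of
  the study design: NC–KS 0.054, NC–AZ 0.081, KS–AZ 0.044 (solving to
  F = 0.091/0.017/0.071). Genotypes are binomial per chromosome; the
  calibration property (estimate within ±0.02 of target over ≥ 5000 neutral
  SNPs) is exercised in the tests.
- **Sampling design.** NC 12 diploids (all male), KS 4 (1 M / 3 F), AZ 8
  (6 M / 2 F); females are hemizygous on Z scaffolds. Scaffolds are
  desk-scale: 1 Mb autosomes and a 500 kb Z, with the chr12-analog
  inversion spanning half its scaffold (mirroring the ~56 % of the real
  chromosome) and the Z-analog inversion 200 kb.
- **Inversions.** Carrier chromosomes are assigned per sample from explicit
  genotype-class counts (AZ autosomal: 4 hom + 3 het = 11/16; AZ Z:
  5 hom + 1 het males + 2 carrier females = 13/14 — the single non-carrier
  chromosome is a heterozygous male by default; a non-carrier female would
  give the same 13/14). Marker SNPs (1.5/kb) are fixed on the inverted
  haplotype, so they sit at exactly k/T in the carrier population and 0
  elsewhere. Non-marker SNPs inside the interval follow a latent local
  haplotype group in *every* population (carrier status where the inversion
  segregates, a random binary label elsewhere) with an 0.8 linkage fraction
  and an 0.1 per-chromosome flip rate — this reproduces elevated r² inside
  the interval even in populations lacking the inversion, without creating
  a spurious modal tract there; in the carrier population, unlinked inside
  variation segregates only on non-carrier chromosomes, since the inverted
  haplotype is one shared haplotype.
- **Pseudogene.** 61 SNPs in a gene inside the autosomal inversion whose
  genotypes copy the inversion exactly, one of them converting the terminal
  TAA to TCA (a stop loss) — hence concordance 1.0 and frequency 11/16.
- **Polarization structure.** 25 % of background sites have the alternate
  allele ancestral (outgroup shares the alt; 15 % of those shown as
  heterozygous tri-allelic outgroup calls), 2 % carry a conflicting
  outgroup allele and are true masked sites. Inversion markers keep the
  reference ancestral, consistent with a reference individual lacking the
  inversion.
- **Selection signal.** Derived frequencies at 0-fold CDS positions are
  multiplied by a suppression factor (0.25 by default), giving π₀ < π₄ and
  a lower Tajima's D at 0-fold sites; setting the factor to 1 recovers
  drift-only π₀ ≈ π₄. The generator's frequency spectrum is
  common-allele-heavy (uniform ancestral frequencies), so absolute D values
  are positive; the D implementation itself is validated against a
  Monte-Carlo null with a 1/k spectrum.
- **Expression.** Gene class labels per dimension are drawn from
  configurable probabilities (genes inside the Z inversion draw from a
  sex-unbiased-enriched distribution, the seeded signal for the enrichment
  test); condition values are multiplicative weights (0.9 specificity
  share) with 10 % lognormal noise. Label recovery at the 0.70 threshold is
  ≥ 90 % per dimension — not 100 %, because tissue availability is
  asymmetric across stages, exactly as in real designs.
- **Seeding.** One integer seed fans out to named streams
  (reference/positions/frequencies/genotypes/outgroup/ancestry/latent/
  expression), so adding a component never shifts another's draws; fixture
  bundles are byte-identical across runs at a fixed seed.

What passing tests on this generator shows: the estimators and detectors
recover the quantities the generator encodes, at the study's sample sizes
and on the frequency lattice the design implies. What it does not show:
robustness to mapping artefacts, genotyping error beyond simple
missingness, recombinant inversion haplotypes, homoplasy in the outgroup,
or realistic site-frequency spectra.

## Pipeline

Stages exchange data through files in the run directory and are cached by
SHA-256 digests of inputs, parameters and outputs (plus the package
version). A rerun with unchanged inputs is a no-op with a byte-identical
report; deleting an output reruns its producing stage, and downstream
stages are reused when their input digests still match. The report gives
carrier frequencies as exact fractions alongside decimals (e.g.
"11/16 (0.6875)") because lattice fractions, not decimals, are the natural
units of the tract model.

Desk-scale problem sizes throughout (≈ 2300 SNPs, 24 samples, 2.5 Mb
genome; ≥ 5000 SNPs for calibration properties) keep the full suite and
the acceptance script to a couple of minutes on one CPU; they were chosen
as the smallest sizes at which the lattice structure, window scan and
composition tests are all well-posed.

## Known limitations

- Genome-wide F_ST on the default synthetic design is dominated by the
  inversions (they cover a sixth of the desk-scale genome, versus a few
  percent of a real genome), so the reported whole-genome values exceed the
  neutral background targets by construction; the calibration property is
  therefore stated over neutral sites.
- The anchoring module consumes an alignment summary; it does not compute
  whole-genome alignments.
- The effect annotator handles SNPs only, one gene model per transcript,
  and the detector assumes a single shared inverted haplotype (no nested or
  overlapping inversions).
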
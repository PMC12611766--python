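# Methods

## Data model

A duplex "call" is one (sample, site, alternate allele) observation with a
count of supporting double-strand-consensus molecules and the site's duplex
depth. One duplex molecule interrogates one haploid genome, so for sperm
the per-duplex-molecule mutation rate at a site equals the probability that
a randomly drawn cell is mutant there. All coordinates are 1-based
inclusive in memory; BED output is 0-based half-open.

## Synthetic cohorts

The generator emulates the statistical structure of deeply duplex-sequenced
bulk sperm rather than reads or lineages:

* **Geometry.** One chromosome; single-transcript genes laid out left to
  right with fixed exon/intron/intergenic lengths; CDS built from random
  sense codons (stop-free by construction); strand random per gene;
  essential splice sites are the terminal 2 bp of each intron.
* **Rates.** Per (site, alt, sample), mutant molecule counts are Poisson
  with mean `rate(context) x age x coverage x selection_fold`. The context
  rate is a strand-symmetric substitution-type weight (C>T and T>C
  dominated, an ageing-germline-like spectrum) times a CpG-transition
  multiplier linear in methylation, `1 + (F - 1) m` with `F = 6` at full
  methylation, normalized so the genome-averaged total equals
  `neutral_rate_per_bp_year` (default 1.67 / 2,861,326,455 per bp per
  year, the male-germline clock). Ages enter linearly with no intercept.
* **Methylation.** Per-CpG levels are a bimodal Beta mixture (70% high,
  ~0.9; 30% low, ~0.09), the shape of testis whole-genome bisulfite data;
  the value is attached to both strands of the dinucleotide.
* **Coverage.** Negative-binomial per base (gamma-Poisson, shape
  `dispersion`), independent across samples; `dispersion=inf` gives
  Poisson depth.
* **Selection.** A multiplicative fold on nonsynonymous rates: per driver
  gene a missense fold and a LOF fold (nonsense, essential splice,
  frameshift indels), plus per-site hotspot folds. Clonal structure is not
  simulated — at these rates and depths virtually every variant is a
  singleton, so counts are sufficient for every downstream estimator, and
  the tests confirm >=99% single-molecule support at study-scale settings.
* **Indels.** A single genome-wide rate (default 0.10/1.67 of the SNV
  rate), sizes uniform on 1-21 bp, insertions and deletions equiprobable;
  frameshifts in driver CDS receive the LOF fold.
* **Contamination.** Cross-sample germline alleles are spiked as
  `Binomial(coverage, alpha)` molecules at supplied genotype sites, with
  the contaminating donor's own library carrying them at
  heterozygous-like VAF — the signal the cohort-wide decontamination step
  keys on.
* **Scale.** The standard toy cohort (50 genes x 1,200 bp CDS, 50 samples,
  ~20,000 dx) concentrates a study-scale mutation yield onto a desk-scale
  territory: cumulative duplex coverage substitutes for exome breadth so
  per-gene counts match a deeply sequenced targeted panel. What passing
  tests on such cohorts show is that the estimators are calibrated and
  recover known truth under the generating model; they cannot show
  robustness to alignment artefacts, mapping bias, read-level errors or
  real clonal structure, none of which are simulated.

## The neutral mutation model (208 parameters)

Rates are fitted on putatively neutral calls — synonymous plus noncoding
SNVs — with per-base duplex coverage as exposure:

* 192 strand-specific trinucleotide substitution classes (64 trinucleotides
  x 3 alternates);
* the 8 CpG-transition classes (NCG C>T and CGN G>A) are substratified by
  the site's methylation level into three bins with edges at 1/3 and 2/3;
  the two non-reference bins carry one multiplicative coefficient per
  class — 16 methylation parameters, 208 in total.

Because the parameterization is saturated per stratum, the Poisson
log-linear coverage-offset fit has the closed form `rate = calls / summed
coverage` within each (class, bin) stratum; bins without neutral exposure
fall back to the class-pooled rate, and classes with no neutral exposure
drop out of expectations. Binned methylation was chosen over a continuous
log-linear term because it keeps the stated 16-parameter count
identifiable and matches the strongly bimodal methylation distribution;
with methylation disabled the model reduces exactly to the plain 192-class
fit. An optional pentanucleotide adjustment multiplies rates by
`(observed + k) / (expected + k)` per 5-mer stratum (`k = 5`,
empirical-Bayes shrinkage toward 1, off by default): desk-scale data
cannot identify a saturated 3,072-parameter 5-mer model.

The indel rate is a single genome-wide value fitted on noncoding indels
per noncoding duplex base pair.

## Selection inference

Per gene, observed counts `n` and model expectations `E` per impact class
(synonymous, missense, nonsense, essential splice, indel) enter a
penalized Poisson likelihood with a per-gene rate nuisance `t` under a
Gamma(theta, theta) prior, profiled in closed form
(`t = (n_fixed + theta) / (E_fixed + theta)`). Likelihood-ratio tests
compare free omega groups against neutrality: `p_mis` (1 dof), `p_trunc`
(nonsense + splice, 1 dof), `p_ind` (1 dof) and `p_gene` (all three
jointly, 3 dof), with chi-square reference distributions and
Benjamini-Hochberg q-values per test family. `theta` is the NB
overdispersion of synonymous counts across genes, kept only when it beats
the Poisson limit in a 1-dof LRT (otherwise the Poisson limit
`theta = inf`, which pins `t = 1`); this keeps gene tests calibrated when
there is no real gene-to-gene rate variation. Calibration is verified on
20 seeded neutral cohorts (global-omega CI coverage, zero q<0.1
discoveries, KS-uniform p-values).

Global and gene-set dN/dS use the two-Poisson model
`S ~ Poisson(t E_S)`, `N ~ Poisson(omega t E_N)` on aggregated counts with
`t` profiled out and a profile-likelihood 95% CI (chi-square 1-dof
cutoff); `1 - 1/omega` converts omega into the excess (driver) fraction of
observed nonsynonymous mutations, and the CI is propagated through the
same transform. Hotspot tests compute `lambda = rate x cohort coverage`
per site-alt and an upper Poisson tail `P(X >= observed)` on the number of
independent samples carrying the identical change; the FDR universe is
all covered site-alts with recurrence >= 1 (exome-wide mode) or a supplied
restricted list. Recurrence-bin enrichment compares observed calls with
summed expectations over the binned site-alt universe with exact Poisson
CIs; bins must partition the possible-substitution universe (assigning
bins from observed calls would condition on the very recurrence being
tested).

## Burdens, regressions, signatures

The corrected burden reweights per-class rates by full-genome
trinucleotide frequencies, `sum_c f_c n_c / L_c`, skipping uncovered
classes with renormalization; per-cell burdens multiply by 2,861,326,455
mappable haploid base pairs (doubled for diploid blood). Age regressions
fit `burden ~ age` with a per-individual random slope and no random
intercept by maximum likelihood (statsmodels MixedLM; the random-effect
column is scaled by the mean age for numerical conditioning and the
variance back-transformed). If every donor has a single sample or the
slope variance degenerates to zero, the fit falls back to OLS with a
logged note. 95% bands come from parametric bootstrap (default 1,000
replicates) over ages 14-84. Blood:sperm fold changes average per-bp
per-year rates within donor and tissue before the ratio.

Spectra use the standard 96 pyrimidine-collapsed channels; the normalized
spectrum multiplies each channel by the genome/covered-territory abundance
ratio of its trinucleotide. Signature exposures are non-negative least
squares against a catalog of probability vectors; the packaged catalog
(`data/synthetic_sbs_catalog.tsv`) contains synthetic SBS1/SBS5/SBS19-like
shapes (CpG-deamination-like, flat clock-like, and a third distinct
profile) — they are stand-ins constructed for this package, not the COSMIC
vectors, and exposure tests measure recovery of mixtures of this catalog.

## Cell fractions and disease burden

Observed class fractions are summed duplex VAFs per sample, reported as a
percentage of cells while the mean count is below 0.1 and as a mean count
above it (cells then often carry several class variants). Two expectation
conventions exist and are deliberately kept separate:

* `expected_class_fraction` sums `rate x site coverage x age_correction`
  over the class universe — an expected **call count**, exactly linear in
  coverage;
* `expected_cell_fraction` sums `rate x age_correction` over the *covered*
  universe — the exact expectation of the summed VAF, since coverage
  cancels between mutant molecules and depth. This is the quantity used
  wherever observed sum-of-VAF values are compared with the model
  (fraction-vs-age trends, the decomposition).

The per-sample age correction is the age-predicted burden from an
unweighted linear fit divided by the cohort mean rate. Fraction-vs-age
trends use a binomial GLM with freely estimated Pearson dispersion
(quasibinomial). The disease decomposition takes the cohort mean observed
disease fraction and splits it into the neutral-model expectation, the
driver-explained portion (observed minus expected sum-of-VAF of variants
labelled both likely-disease and likely-driver, floored at zero per
sample) and the unexplained remainder; the three parts sum to the total
by construction. ClinVar-style pathogenicity (including the guarded
conflicting-classifications rule), monoallelic "absent gene product"
disease genes, a damaging-score cutoff of 30 for missense, LOF-enrichment
flags from the gene tests (with an activating-override list) and hotspot
membership drive the labels; missing annotation tables yield missing
labels, never false. Phenotype associations are Gaussian GLMs
(`outcome ~ age + BMI + pack_years + drink_years`) with BH adjustment
across all coefficient tests performed.

## Numerical choices and degenerate inputs

* Ties and zeros: LRT statistics are floored at 0; classes with calls but
  no expectation are excluded from the likelihood with a warning; genes
  with zero total expectation are excluded from testing.
* Profile-CI root finding brackets outward from the MLE and uses Brent's
  method; `S = 0` or `N = 0` returns a degenerate CI rather than failing.
* QC thresholds are strict inequalities (`> 10` molecules, `VAF > 0.3`),
  masking is idempotent, and masked sites leave numerator and denominator
  of every downstream rate together.
* Contig-edge sites (within 2 bp) have no resolvable context and are
  excluded from the neutral universe; an edge variant raises an explicit
  error in context extraction.
* Determinism: every stochastic routine takes an explicit seed; the
  pipeline derives stage seeds from the run seed and stamps outputs with
  the seed and a configuration hash.

## Known limitations

No read-level simulation (alignment or consensus artefacts are out of
reach of these tests); no clonal lineage structure or twin correlation; one
transcript per gene and splice effects limited to the +-2 essential sites;
selection folds are age-constant; the signature catalog is synthetic; the
pentanucleotide adjustment is a shrunk post-hoc factor rather than a free
5-mer model. Test problem sizes (tens of kilobases at tens of thousands of
duplex depth) are chosen so per-gene mutation counts match a deeply
sequenced targeted panel while runs stay interactive.
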
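# Methods

This note documents the models and procedures implemented in `dtcprs`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not
show about real data.

## Scoring model

A trait's weight panel is a list of SNPs with effect allele, other
allele, effect size β (log odds ratio or linear-trait effect,
dimensionless), and effect-allele frequency per 1000 Genomes
super-population (AFR, AMR, EAS, EUR, SAS). Panels come in two modes:

* **TOP_SNP** — LD-clumped genome-wide-significant variants
  (p < 5·10⁻⁸); scored with analytic population scaling by default.
* **ALL_SNP** — genome-wide weights already shrunk for LD by an external
  method (e.g. LDpred); weight derivation is out of scope here, the
  weights are inputs.

Three quantities are computed per profile and trait:

1. raw sum `Σ β·x` over attained SNPs (the naive score);
2. zero-centered score `Σ β·x − f·2·β`, which has expectation 0 for a
   member of the scaling population under Hardy–Weinberg equilibrium;
3. Z-score = zero-centered score / SD_population.

**The analytic denominator.** `SD_population = sqrt(Σ β²·2f(1−f))` is the
score SD under Hardy–Weinberg and linkage equilibrium. No closed form is
"the" correct denominator for arbitrary LD; for LD-clumped top-SNP panels
the independence approximation is the unique analytic choice consistent
with the clumping, and the empirical alternative (below) matches it well
in practice. This was a genuinely open design point; the HWE+LE form was
chosen because it is exact for the generator used in testing, making
calibration testable (z-scores of a cohort drawn from the scaling
population must have mean ≈ 0, SD ≈ 1).

**Empirical scaling.** Alternatively a score is standardized against
previously computed scores of ancestry-matched profiles, using the sample
SD (n−1). A minimum reference size of 30 is enforced: SD estimates below
that are too unstable to define a Z-score presented to a person. The
floor is a package choice; nothing forces 30, but the value must be fixed
somewhere and small changes do not matter.

**Missing panel SNPs.** Three policies:

* `SKIP` — the SNP contributes nothing and no renormalization is applied.
  This deliberately mirrors naive raw-data scoring and is what the
  vendor-mask experiment uses.
* `FREQUENCY_FILL` — dosage := 2f (the population mean), flagged
  `frequency_filled`. For the *zero-centered* score a filled SNP
  contributes β·2f − f·2·β, which is exactly 0.0 in floating point
  (verified bit-for-bit in the tests), so FREQUENCY_FILL ≡ SKIP there;
  the policies differ only in the raw sum and the coverage accounting.
  It is a deliberately inferior stand-in for real imputation: it restores
  the score's *location*, never its person-specific information.
* `FAIL` — any gap is an error.

There is intentionally **no per-individual renormalization** by attained
variance; the whole point of the mixed-vendor experiment is to exhibit
the failure mode of scoring different attained SNP sets on one scale.
Z-scores are reported at full precision without winsorizing; percentile
display (Φ(z)·100) is a CLI formatting option only.

## Harmonization and QC

Alleles are aligned to the reference panel's {ref, alt}: direct match
first, reverse complement second; A/T and C/G site classes are rejected
unconditionally, because no strand metadata from consumer exports is
trustworthy across dozens of dialects, and a frequency-based resolution
would silently mis-align some fraction of sites. When a call and a panel
site share an rsid but disagree on position, the site is rejected — the
panel is the coordinate authority (all coordinates GRCh37; a
mismatched-build file is the caller's error, no liftover is attempted).

The QC gate retains a site iff MAF > 0.05, exact Hardy–Weinberg
p > 10⁻⁵, genotype yield > 0.95, and imputation INFO ≥ 0.9 when an INFO
column is supplied. The exclusion ledger records the *first* failing
criterion in that order. The HWE test is the plain two-sided exact test
(sum of heterozygote configurations with conditional probability ≤ the
observed one); mid-p is not used, as only a threshold — not a test
variant — is part of the pipeline contract. Cohort MAF is estimated from
genotype counts when ≥ 50 samples are called and otherwise taken from the
supplied panel frequency: single-profile uploads cannot estimate MAF.

## Ancestry assignment

Naive-Bayes over HWE genotype likelihoods: for each super-population,
`Σ log P(g | f_pop)` over non-missing autosomal reference sites, with
frequencies clamped to [10⁻⁴, 1−10⁻⁴] to keep fixed alleles finite;
argmax wins, ties break deterministically in the order AFR, AMR, EAS,
EUR, SAS. At least 100 informative sites are required. A PCA projection
would need external loadings; the likelihood classifier needs nothing
beyond the site table already required for harmonization and is fully
testable on synthetic frequencies. It offers no admixture proportions
and no within-continent resolution — for an admixed profile the label is
only "closest reference population".

## Evaluation statistics

* **Nagelkerke R²** — intercept-only and intercept+score logistic models
  fit by a self-contained IRLS (convergence: log-likelihood change
  < 10⁻¹⁰, ≤ 100 iterations; scores standardized internally, to which the
  statistic is invariant); R²_CS = 1 − exp(−(2/n)(ℓ₁−ℓ₀)) rescaled by
  1 − exp((2/n)ℓ₀). A fitted |coefficient| > 50 triggers a separation
  warning. The univariate score model is used throughout (no covariates).
* **AUC** — Mann–Whitney concordance from average ranks (ties take half
  credit).
* **Two-proportion carrier test** — pooled z-test *with* Yates continuity
  correction. The choice is a reconstruction: for carrier fractions 20/25
  vs 33/39 the corrected statistic gives p = 0.89 → 0.9 as published,
  whereas the uncorrected one gives ≈ 0.63.
* **Score correlation** — Pearson r over shared traits between two result
  sets, the statistic used to compare one person's files from two
  vendors.

## Synthetic cohorts

The generator emulates the structure of a genotyped case/control cohort
without any restricted data:

* effect sizes β ~ Normal(0, 0.1²); effect-allele frequencies uniform on
  [0.05, 0.95] (both per panel, identical across populations unless a
  logit-scale divergence SD is requested);
* dosages Binomial(2, f) per SNP — **linkage equilibrium by
  construction**, which makes the analytic SD exact;
* liability = a·G + e with G the zero-centered score, a chosen so
  Var(a·G) = h², e ~ Normal(0, 1−h²); case iff liability > Φ⁻¹(1−K).
* Default conditions for the experiments: prevalence K = 0.3, liability
  heritability h² = 0.4 (experiment) or 0.5 (calibration/recovery),
  cohorts of 2000 (experiment) or 5000 (recovery) individuals, panels of
  200–300 SNPs. Sizes were chosen so every sampling-based check sits well
  inside its tolerance at interactive runtimes.

What this does **not** model: LD between SNPs, ancestry-specific effect
sizes, genotyping error, case/control ascertainment, covariates. Passing
tests therefore show the *mechanics* of the pipeline are right — exact
centering, calibrated scaling, correct metric computation, and the
qualitative SNP-set degradation — not that any particular real-data R²
will be attained.

## The vendor SNP-set experiment

Vendor chips are random panel subsets (real chip manifests are
proprietary): each of three "vendors" covers a configurable fraction
(default 0.5) of the panel, optionally sharing a common backbone.
Conditions:

* **FULL** — complete dosages;
* **UNIFORM** — one vendor's mask applied to every individual, reported
  per vendor (mean across the three vendors is the summary);
* **MIXED** — each individual independently assigned a vendor with the
  live-user proportions (0.55, 0.30, 0.15), redrawn 100 times, mean ± SD.

Masked conditions are evaluated on the **naive un-centered weighted sum**
over attained SNPs. This is the score a raw-data tool that neither
imputes nor population-centers computes, and it is the mechanism of the
mixed-set collapse: each vendor's attained SNP set carries a different
offset `Σ_mask 2f·β`, so scores of individuals with different vendors are
not on a common scale. AUC and R² are invariant to any *shared* shift, so
the FULL and UNIFORM rows are unaffected by using the naive rather than
the centered score — in an idealized simulation with exactly known
frequencies the centered score is immune to mixing by construction, and
only the naive score exhibits the real-world failure.

Measured at the default conditions (20 replicates), FULL→UNIFORM roughly
halves the variance explained (R² 0.33 → 0.16) and MIXED collapses it
much further (→ 0.09), with the ordering FULL > UNIFORM > MIXED in 20/20
replicates. The collapse is substantial but bounded: with three
equal-coverage random half-masks the ratio of between-vendor offset
variance to within-vendor score variance is fixed near 1.74 (independent
of β scale, panel size, and cohort size), which caps how far the mixed
AUC can fall — about 0.65–0.66 against a full-data 0.80 here. A stronger
collapse would require more vendors, more divergent chip sizes, or
systematically positive effect sizes, none of which the default
conditions assume. The experiment is a structural analog of the
published comparison, not a numeric replication; acceptance of the
qualitative claim is ordering-based for exactly this reason.

**"Half-overlap" masks** in the cross-vendor reproducibility check are
masks sharing half the panel as a common backbone, each covering half of
the remainder (overall coverage 0.75). Two *independent* half-coverage
masks would share only a quarter of the panel and give score correlation
≈ overlap/coverage = 0.5; real vendor chips share most GWAS-relevant
content, and the backbone construction reflects that (measured r ≈ 0.83;
identical scores, r = 1.0, with complete coverage).

## Numerical choices and degenerate inputs

* HWE exact test: log-space enumeration with an inclusion tolerance of
  10⁻⁹ on the log-probability comparison, so exact ties (symmetric
  configurations) are included regardless of rounding; verified against
  exact integer-arithmetic enumeration for every table with n ≤ 200.
* All-missing profiles score 0 with an `EmptyOverlapWarning` rather than
  returning a number presented as informative; empty panels, zero
  variance, one-class label vectors, and sub-minimum reference cohorts
  raise typed errors (`ZeroVariancePanel`, `DegenerateInput`,
  `InsufficientReference`, `InsufficientSites`).
* Identity metadata: uniqueIDs are `id_` + 9 characters of `[0-9a-z]`,
  collision-checked against a caller-supplied registry; the source digest
  is a plain md5 of the upload bytes, so identical files map to one user.
* Haploid single-letter calls (X/Y/MT) are stored as homozygous pairs
  (PLINK convention) and counted; X/Y/MT never enter scoring, whose
  dosage model is diploid.
* Insertion/deletion genotype codes are rejected with a counted reason;
  scoring panels here are SNP-based.
* Duplicate rsid lines keep the first occurrence; later ones are counted
  as rejected.

## Known limitations

* No imputation: `FREQUENCY_FILL` restores score location only. The
  experiment quantifies exactly what is lost by not imputing.
* No LD in the generator, so all-SNP panels with dense LD are outside
  what the synthetic tests exercise.
* Ancestry labels are categorical; admixed profiles get a nearest-label
  call with no proportions.
* The dialect grammars are the representative common core of each vendor
  family, not an exhaustive catalog of historical chip versions.
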
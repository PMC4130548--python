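# Methods

## Setting and model

The package analyses case-control association in a founder population:
every sampled individual descends from a small founder pool through a
known multi-generation pedigree, so cases and controls are related and
the usual binomial variance of an allele-frequency contrast is wrong.
The analysis chain is (1) genotype CNVs in the cohort from two-channel
array-CGH data, quality-gated against sequencing read-depth copy
numbers; (2) select candidate variants by read-depth screens and
gene-disruptive filter cascades; (3) test association with a
relatedness-corrected allelic test, a rank-sum test for multi-allelic
copy numbers, stratified replication via Cochran–Mantel–Haenszel, and a
covariate-adjusted rare-variant set test.

## Array-CGH signal model and genotyping

A locus is summarized per sample by the medians of its probe-level
log2 ratios, test-channel intensities and reference-channel
intensities.  The theoretical log2 ratio of copy number c against a
CN_ref-copy reference is log2(max(c, ε)/CN_ref) with ε = 0.05 copies:
arrays saturate rather than report −∞ for homozygous deletions, and the
floor keeps the zero-copy state at a large but finite ≈ −5.3.

*Validation calling* requires |median log2| strictly greater than 0.5
(a heterozygous deletion sits at −1, a single-copy duplication at
+0.58).

*Hybridization QC.* The derivative log ratio spread is SD of successive
probe differences divided by √2; for white probe noise of SD σ it
estimates σ, so the 0.24 ceiling reads as a per-probe noise bound.  The
named metric is conventionally defined this way; on a targeted (non
copy-neutral) probe set the pipeline pools first differences within
loci so true copy-number steps at locus boundaries do not count as
noise.  Sample sex is inferred from the median X-chromosome log2 ratio
relative to a reference of known sex (copy ratio 1/2, 1 or 2) and
checked against the reported sex.  Hybridizations failing the DLR bound
are repeated up to two additional times (fresh signal draws in the
synthetic pipeline), with the attempt count recorded in the QC table;
samples still failing DLR, or failing sex concordance (a likely sample
mix-up, which a re-hybridization cannot repair), are excluded.

*rCV.* For each locus, rCV = CV(median test intensities)/CV(median
reference intensities) across samples; high values mean the test
channel varies while the reference channel is reproducible — a
polymorphic, well-performing locus.  Loci are kept when rCV > 1.4.  A
zero reference CV (no between-hybridization variation at all) is
pathological and reported as an infinite sentinel flagged for review
rather than a silent pass.  rCV is computed on the summaries as given;
any global intensity normalization upstream cancels because CV is
scale-free, which is also asserted as an invariant.

*Integer copy-number fitting.* Each sample is assigned the state
c ∈ [0, 8] whose theoretical log2 ratio is nearest its observed median;
`joint_fit` adds the intensity channel log2(median_test/median_ref),
which shares the same theoretical value.  A free per-locus log2 offset
(hybridization bias) is refined by a short assign/re-estimate loop,
initialized at zero so absolute anchoring defaults to the reference
copy number.  This deliberately reproduces the known failure mode of
log2-only genotyping: a constant offset of about half a state spacing
shifts every log2-only call by one state, while the intensity channel
keeps the joint fit anchored.  An earlier design sketch selected
contiguous state windows by BIC; the full-grid assignment with an
offset nuisance subsumes that search for the locus types in scope and
is simpler and deterministic.  A locus whose best assignment leaves an
RMS residual above 0.2 (data not sitting near any integer grid — e.g.
dynamic-range compression) is reported *unfittable*, a state rather
than an exception.  Note that strong compression can instead produce a
confident fit to wrong states; that is exactly what the read-depth gate
catches.

*Method gating.* Both methods' calls are correlated (Pearson) with
sequencing read-depth copy numbers over the overlapping samples; the
higher-r method is selected (ties prefer `joint_fit`, for
reproducibility) and the locus is rejected when the best r < 0.65 or r
is undefined.  Loci that resist integer states fall back to
intensity-calibrated continuous copy number: reference CN = median
reference intensity / single-copy intensity, test CN = reference CN ×
2^(median log2); the single-copy intensity is a parameter estimated in
practice from control loci of known copy number.

## Candidate selection and filter cascades

The read-depth screen compares study genomes to a reference panel per
locus: loci with all study copy numbers strictly inside (1.5, 2.5) are
non-variant; otherwise a locus is selected when both study groups shift
against the panel (rank-sum p ≤ 0.01 in one group and p < 0.1 in the
other, either assignment of the two thresholds, recorded), when either
group alone differs at p ≤ 0.01, or when any single study sample is a
|z| > 2 outlier against the panel distribution (panel mean and SD, not
robust estimators — matching the plain z-score definition).  The
both-groups rule is checked first; it is the most specific and would
otherwise be shadowed by the single-group rule.  Rank-sum p-values use
exact enumeration for small untied samples and the tie-corrected normal
approximation otherwise.

The gene-disruptive discovery filter keeps variants that are nonsense,
splice-site or frameshifting; carried by at least one case and no
sequenced control (missing genotypes count as non-carrier, with a
caveat flag in the audit log); and rare (< 0.05 in every annotated
panel) or absent from the known-variant database.  The set-inclusion
rule for the transcript-level test keeps, in `rare_conserved` mode,
nonsense and coding indels plus missense/splice variants with GERP
strictly above 3, all at panel AF < 0.05 in every continental panel,
and in `all_protein_altering` mode every protein-altering class; both
modes drop variants with more than 15% missing genotypes.  All
boundaries are strict (GERP = 3.0 and missingness = 16% are excluded;
missingness = 15% is kept); every exclusion carries a reason code.
Filters are pure, idempotent and order-independent where logically
independent.

## Association statistics

*Kinship-corrected allelic χ².*  With allele counts x_i ∈ {0,1,2},
case/control sizes n_A, n_U, contrast vector c_i = 1/n_A (cases),
−1/n_U (controls) and pooled frequency p̂, the statistic is
Δ²/Var̂(Δ) with Δ = cᵀx/2 and Var̂(Δ) = (p̂(1−p̂)/2)·cᵀ(2Φ)c, referred
to χ²₁.  Under gene dropping Cov(x_i, x_j) = 2p(1−p)·2φ_ij exactly, so
the quadratic form is the correct null variance for any fixed phenotype
configuration, and for Φ = I/2 the statistic equals the classical
allelic (pooled two-proportion) χ² identically.  The fuller MQLS
weighting of unaffected relatives is not implemented; the corrected χ²
is fully determined by the kinship matrix, which keeps the test exactly
reproducible from pedigree data alone.  Monomorphic variants return
p = 1 with a flag.

*Wilcoxon rank-sum* (multi-allelic copy numbers): exact p by full
enumeration over group assignments of midranks whenever the number of
splits is ≤ 200,000, else the tie-corrected normal approximation.
Two-sided means twice the smaller one-sided tail in both paths, so the
exact and approximate paths share a convention even when ties make the
permutation distribution asymmetric.

*CMH combination.*  The Mantel–Haenszel common odds ratio
Σ(a_k d_k/N_k)/Σ(b_k c_k/N_k) and a χ² with the score-type variance
r1·r2·c1·c2/N³ per stratum, no continuity correction.  The score-type
variance (N in place of the classical N−1) makes the single-stratum
statistic reduce *exactly* to the uncorrected Pearson χ², which is the
cleaner invariant; for replication-cohort sizes the two differ by under
0.5% and statsmodels' classical implementation is used as a
cross-check in the tests.  One-sided p-values halve the two-sided p
when the pooled OR points in the configured risk direction (deletion
enriched in cases).  Strata with a zero margin are dropped with a note;
zero-control-carrier strata at the per-stratum level produce an
explicit infinite-OR sentinel, with a Haldane–Anscombe 0.5 correction
available behind a flag but never applied silently.

*Set test.*  The null model is a logistic regression of case status on
covariates (global and transcript-local ancestry proportions in the
intended application).  With per-variant scores S = G̃ᵀ(y − μ̂), where
G̃ projects the covariates out of the genotypes in the
iteratively-reweighted metric, the statistic at mixing parameter ρ is
Q_ρ = (1−ρ)Σ_j w_j²S_j² + ρ(Σ_j w_j S_j)² — pure variance-component at
ρ = 0, pure burden at ρ = 1.  Per-ρ p-values come from the
moment-matched weighted-χ²-mixture approximation (four-cumulant
matching to a noncentral χ²), with eigenvalues of
M_ρ^{1/2} V M_ρ^{1/2}, V = G̃ᵀdiag(μ̂(1−μ̂))G̃.  The reported p is the
minimum over ρ ∈ {0, 0.25, 0.5, 1}, calibrated by permuting the
null-model residuals (999 seeded permutations), which charges the grid
search its proper multiplicity; a single-element grid returns the
analytic p (at ρ = 1 with one variant this equals the logistic score
test to machine precision, an identity the tests assert).  Variants are
weighted equally; missing genotypes are mean-imputed; Bonferroni
adjustment over transcripts × test modes is applied only in set-test
reports — all other p-values are reported nominal.

## Synthetic cohorts

The generators exist so every stage is testable without restricted
genotype data; their defaults are the package's study conditions.

*Pedigree*: founders in generation 0, random monogamous within-
generation pairing with Poisson offspring counts (mean 2 × offspring
rate per couple; default rate 3.0, i.e. ~6 children per couple,
reflecting the large sibships of high-fertility founder communities)
and avoidance of matings with kinship ≥ 1/4, letting inbreeding
accumulate through cousin lines as in a real closed population.
Kinship follows the standard recursion φ(i,i) = (1+φ(f,m))/2,
φ(i,j) = (φ(f,j)+φ(m,j))/2, validated against a gene-dropping IBD
estimator.

*Phenotype*: logistic model with intercept logit(prevalence) (default
0.25, matching a cohort with 164 diagnosed cases among 652 classified
individuals), per-allele log-odds log(OR) on the centered risk
genotype, and a kinship-structured familial liability
a ~ N(0, σ²·2Φ).  The default σ = 1.8 puts the liability-scale
heritability near 0.5, typical of asthma; it is what makes case status
cluster in families, the condition under which the naive χ² actually
inflates and the corrected test earns its keep.  With per-allele
OR = 1 the phenotype is independent of the tested genotype.

*aCGH signals*: per probe, log2 ratio = log2(max(CN, ε)/CN_ref) +
N(0, σ) and intensities scale·CN/2·exp(N(0, σ)) per channel; default
probe noise σ = 0.15, a mid-range value for two-color CGH, and
configurable since hybridization noise varies by platform and batch.
An optional constant log2 bias emulates dye/wash artifacts.  The model
has no probe-specific response, GC waves or segmental-duplication
cross-hybridization, so passing tests show correctness of the
genotyping logic, not robustness to every array pathology.

*Variant tables*: functional classes from a configurable mix, GERP ~
Normal(1, 2) (so a minority of missense variants clear the > 3 bar),
continental-panel AFs ~ Beta(0.2, 30) (mostly rare, occasionally
common), genotypes Binomial(2, f) with qualifying variants carrying
allele frequency 2e-4 in cases and a configurable control enrichment
(10× in the power scenario, mirroring an observed control-enriched
transcript with ~2.0% of controls vs ~0.23% of cases carrying).
Genotypes are missing independently at a configurable rate.

All generators draw from named RNG streams derived from one integer
seed (stream key = CRC32 of the component name), so outputs are
bit-reproducible and adding a generator never shifts existing draws.

## Calibration analyses and problem sizes

The scenario layer fixes the problem sizes used throughout the tests,
the analysis drivers and the acceptance script: 100 random draws for
the unrelated-limit reduction (agreement to 1e−10); 10,000 null
replicates on a three-generation, 16-founder pedigree for type-I
calibration; 200 samples × 20 loci × 10 probes at noise 0.1 for
integer-CN recovery (≥ 99% required); 500 locus pairs for rCV
discrimination; all group sizes up to 8 for the rank-sum enumeration
oracle; 2,000 phenotype permutations for set-test null calibration and
500 replicates at 800 cases / 500 controls for power under ten-fold
control enrichment.  These sizes make the full acceptance run complete
in minutes on a single core while keeping Monte-Carlo error well below
the decision margins.

## Known limitations

- The corrected χ² conditions on the phenotype configuration; it does
  not exploit unaffected relatives' phenotypes (full MQLS) and, like
  any score test, is approximate for very rare alleles in small
  pedigrees.
- The permutation-calibrated min-p has resolution 1/(B+1); p-values
  below ~0.001 at the default B = 999 are reported at that floor.
- Continuous copy-number estimation presumes a known single-copy
  intensity; mis-specification scales all copy numbers, which the
  read-depth correlation gate will flag but not repair.
- The aCGH simulator omits probe-level systematic structure (see
  above), and the pedigree simulator has no generation overlap,
  migration or non-paternity.
- Replication allele counts recovered from printed two-decimal
  frequencies are exact only where the rounding is unambiguous; the
  smallest cohort counts (1–2 alleles) carry rounding uncertainty.
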
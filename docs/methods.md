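# Methods notes

This note records the modelling choices, generator design, numerical
conventions and known limitations of `mqtlsmoke`.

## Study design emulated by the generator

The synthetic-data module (`mqtlsmoke.simulate`) emulates a two-panel
cross-sectional design nested in an older-adult screening cohort:

- panels of 581 (discovery) and 368 (validation) participants, drawn
  independently but sharing one set of SNPs, CpGs and generative
  effects;
- smoking prevalence (18 % current / 30 % former / 52 % never), ages
  ~61 ± 6.3 years (clipped to 50–75), pack-years ≈ 34.6 ± 18.2 for
  current and ≈ 21 ± 17 for former smokers, cessation ≈ 17 ± 11 years
  before recruitment, and lifestyle/comorbidity category frequencies
  matching such a cohort (majority overweight/obese, low activity, low
  alcohol; CVD ≈ 15 %, diabetes ≈ 16 %, cancer ≈ 6 %);
- ~150 candidate CpGs, each with a handful of array SNPs inside the
  ±50 kb cis window (default 9), spread across chromosomes at 1 Mb
  spacing so windows never overlap;
- ~12.4 years of mortality follow-up with administrative censoring at a
  fixed horizon.

### Genotypes

Loci live in LD blocks of `ld_block_size` (default 3).  All loci in a
block share one true MAF drawn uniformly from `maf_range` (default
0.05–0.5, deliberately wider than the post-QC MAF > 0.1 so the MAF
filter has work to do).  Haplotypes are generated by a copy scheme: the
first locus of a block is Bernoulli(MAF) per haplotype, each later
locus copies its left neighbour with probability `ld_rho` (default
0.8) and is redrawn otherwise.  Sharing the MAF within a block keeps
marginal frequencies exactly at HWE while adjacent-locus allelic
correlation ≈ `ld_rho` with geometric decay.  The contract is the
realized pairwise R², not the mechanism; no attempt is made at
haplotype-accurate population genetics.  Missing calls are masked in at
rate `missing_rate` (default 0.5 %, so binomial fluctuation pushes a few
SNPs per study over the 1 % exclusion boundary).

### Methylation

Beta-values are generated directly on the beta scale (the analysis
model's scale) and clipped to [0, 1]:

    beta_ij = clip01( sum_k p_ik w_jk + a_j G_ij + b_j s_i
                      + batch_B(i) + eps_ij )

with Dirichlet cell proportions p (default alpha mirrors whole-blood
leukocyte composition, granulocyte-dominated, K = 6), cell-type
profiles w_jk centred on the CpG's baseline, smoking code s (current 1,
former 0.5, never 0), batch intercepts N(0, 0.01) over 10 round-robin
batches, and noise sd 0.03 (a typical residual sd for variable 450K
probes).  A fraction `mqtl_fraction` (default 0.5, matching 70/150
CpGs with validated mQTLs) of CpGs receives exactly one causal SNP with
per-allele effect drawn from ±(0.02–0.15); every CpG receives a smoking
effect of magnitude 0.01–0.08, negative with probability 0.8 (smoking
predominantly demethylates these sites).  Logit-scale generation was
rejected in favour of fidelity to the analysis model.  No generative
parameters for methylation variance are published for this design;
defaults were chosen once for realistic pipeline power and are not
tuned against test outcomes.

Under the default configuration fewer than 1 % of entries are clipped;
clipped CpGs are the one place where the generative model is not exactly
linear, and exact-recovery tests skip them.

### Survival

Weibull proportional hazards (shape 1.2, scale 55 years) with true
log-hazards 0.08/year of age, 0.7 for current and 0.25 for former
smoking, censored administratively at 12.4 years — giving ≈ 15 % deaths,
as in the emulated design.

### What the generator does not emulate

Probe chemistry and detection p-values, genotype imputation
uncertainty, fine-scale LD and allele-frequency spectra, cell-type
shifts induced by smoking, and confounding between genotype and smoking
(population structure).  Passing tests therefore demonstrate the
statistical machinery — error control, power at the stated effect
sizes, and estimator correctness — not robustness to those artefacts of
real data.

## Analysis conventions

- **Coordinates** are 1-based inclusive throughout, including the
  BED-like manifest, to match published table positions (GRCh37).
- **Cis window**: same chromosome and `cpg_pos − 50 kb ≤ snp_pos ≤
  cpg_pos + 50 kb`, bounds inclusive; signed distance is
  `snp_pos − cpg_pos`.  CpGs with no SNP in the window are reported as
  dropped.
- **Minor allele** is defined within the loaded cohort; a VCF ALT allele
  with frequency > 0.5 is flipped at load; ties at exactly 0.5 keep file
  order.
- **QC order** is missingness → HWE → MAF → LD; the three marginal
  filters commute (tested), so order affects only the per-filter
  attribution.  Exclusion boundaries are inclusive on the exclusion
  side (≥ 1 % missing, MAF ≤ 0.1, HWE p < 1e-4 excluded).  The HWE test
  uses the combined panels' non-missing calls by default
  (`hwe_scope="per_panel"` available).
- **"Strongest SNP" ranking for LD pruning** is not pinned down by the
  published description; the default ranks by the marginal
  simple-regression p-value of the CpG's discovery-panel beta-values on
  the dosage (computed before pruning, deterministic, ties broken by
  position then id), with a MAF-based ranking available.  Pruning is
  greedy per CpG over that CpG's window.
- **SNP coding** is a single additive dosage term by default.  The
  published description says "categorical 0/1/2" yet reports single
  coefficients; additive coding reproduces single-coefficient output
  and is the QTL-mapping norm.  `snp_coding="categorical"` fits two
  genotype dummies and reports the joint Wald p.
- **Mixed model**: REML random-intercept fit via statsmodels `MixedLM`.
  Optimizers are tried in the order bfgs → lbfgs → powell because lbfgs
  can falsely report convergence on the σ_b = 0 boundary; total failure
  yields a flagged, untested pair.  A single batch degrades to OLS with
  a logged notice.  Wald z-tests per coefficient.
- **FDR families**: stage 1 over all tested pairs jointly; stage 2 over
  stage-1 survivors only (a `validation_fdr_scope="joint"` option
  refits all pairs).  Sign concordance between stages is recorded and
  reported, not enforced.
- **Attribution** pools both panels, restricts to current + never
  smokers, uses dominant carrier coding, and fits both models on the
  rows complete for the carrier-adjusted model so β₁ and β₂ come from
  identical samples.  Records with β₁ = 0 or β₁ not significant at 0.05
  are flagged and their percentage omitted.  Whether β₁/β₂ should come
  from pooled panels or validation only is not specified in the
  published design; pooled is implemented.
- **Interaction scan**: genotype as 3-level categorical
  (major-homozygote reference) with current-smoking × genotype
  products; empty genotype cells drop their contrast with a log notice;
  the per-pair p is the Bonferroni-adjusted minimum contrast p
  (collapsing multi-contrast interactions to one number is a design
  choice), BH-corrected across pairs.
- **Outcome scans**: smoking-indicator models exclude smoking-derived
  covariates and cell proportions (adjusting an indicator for smoking
  status would be circular; the published description is ambiguous
  here and the deviation is deliberate).  Binary contrasts use logistic
  regression (a linear-probability option exists for comparisons);
  continuous indicators use OLS among ever smokers.  Mortality uses Cox
  partial likelihood with Breslow ties (statsmodels `PHReg`),
  additionally adjusted for smoking status, pooled panels.  Degenerate
  fits (constant carrier, separation, zero events) are flagged records,
  never silent estimates.
- **Deconvolution** solves min ‖m − Rp‖² s.t. p ≥ 0, Σp ≤ 1 (inequality,
  not equality; the residual mass is reported) by SLSQP plus an exact
  KKT polish on the identified active set, which recovers noiseless
  mixtures to ~1e-15.  Downstream models use K−1 proportions to avoid
  collinearity with the intercept.
- **Degenerate designs**: category levels that are absent or universal
  in a subset produce constant dummy columns; these are dropped from
  the design rather than raising, mirroring how empty cells behave in
  standard regression software.  Remaining rank deficiency raises an
  error naming the collinear terms.

## Numerical conventions

- HWE exact test: two-sided, conditioning on allele counts, summing all
  heterozygote counts with conditional probability ≤ observed × (1 +
  1e-12); monomorphic sites return p = 1 with a log entry.  Verified
  exhaustively against an independent recurrence oracle for all
  configurations with n ≤ 50.
- LD R² is the squared Pearson correlation of dosages over
  pairwise-complete samples (composite LD from unphased genotypes);
  constant columns raise an undefined-LD error.
- Result TSVs format p/FDR columns in scientific notation (6
  significant digits; values as small as 1e-103 round-trip) and other
  floats to 6 significant digits; matrix TSVs use 12 significant digits
  so write→read round-trips agree to < 1e-9.  Reruns with the same
  config and seed are byte-identical.
- Every stochastic draw derives from one seeded generator tree
  (`SeedSequence([seed, stream])`), so panels, masking and noise are
  independently replayable.

## Problem sizes used by tests and the acceptance script

Unit and pipeline tests run a desk-scale study (10 CpGs × 6 SNPs,
150/100 samples) chosen to exercise every code path, including LD
pruning and the missingness filter, in seconds.  The acceptance script
runs the full design (150 CpGs × 9 SNPs, 581/368 samples), a
100-replicate null simulation of the two-stage design (50 pairs,
200/150 samples, single batch), a 20-seed power check at effect 0.05
beta-units and MAF 0.3 at panel sizes 581/368, and exhaustive oracle
sweeps (HWE n ≤ 40–50, 10⁴ BH vectors).  These sizes are the package's
own choices for a complete yet quick verification pass.

## Known limitations

- The batch variance component is estimated per pair; with 10 batches
  its sampling error is large (tested only to within 50 % of truth on
  average), which is inherent to the design, not the implementation.
- The two-stage FDR guarantee is checked under the global null; FDR
  under partial alternatives is inherited from BH theory, not
  simulated.
- Attribution percentages on synthetic data are small unless carrier
  status is confounded with smoking, because the generator plants no
  genotype-exposure dependence; the omitted-variable-bias identity is
  therefore verified on purpose-built confounded fixtures.
- No trans-mQTL search, imputation, probe-level preprocessing, or
  cause-specific mortality.
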
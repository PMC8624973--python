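# Methods

## Scope and model

The package implements the analysis chain for sex-stratified genetic studies
of steroid hormone levels and their causal downstream effects: per-study
association of log-transformed hormone traits on imputed genotype dosages;
fixed-effect meta-analysis across cohorts with heterogeneity-based filtering;
male-vs-female effect comparison under two-level hierarchical FDR; HLA
subtype dosage association with asymmetric LD between multi-allelic loci; and
two-sample Mendelian randomization with a mediation decomposition of the
hormone → CAD effect through obesity traits.

Hormone levels are modelled as log-normal: all association models regress the
natural log of the analyte on the expected allele dosage (0–2) plus
covariates, so effect sizes are per-allele changes in log concentration.
Covariates are age, log-BMI, and (in the combined stratum only) sex;
sex-stratified fits never carry a sex covariate. p-values at the single-study
level use the t reference with n − k − 1 degrees of freedom — equal to the
normal reference at study scale but exact for small fixtures; meta-level and
MR p-values are normal (Wald), the GWAS convention.

## Filters and thresholds

| parameter | default | role |
|---|---|---|
| `maf_min` | 0.01 | single-study MAF filter (exclusive) |
| `info_single_min` | 0.5 | single-study imputation info filter |
| `mac_min_exclusive` | 6 | exclude minor allele count ≤ 6 (expected-dosage MAC) |
| `af_dev_max` | 0.2 | study-vs-reference allele frequency deviation (strict >) |
| `i2_max_exclusive` | 0.9 | post-meta heterogeneity filter (I² ≥ 0.9 excluded) |
| `info_meta_min` | 0.8 | minimum per-study info at meta level (0.8 kept) |
| `weighted_maf_min` | 0.01 | sample-size-weighted MAF at meta level |
| `alpha_gw`, `alpha_suggestive` | 5×10⁻⁸, 5×10⁻⁶ | significance tiers (strict <) |
| `alpha_instrument` | 1×10⁻⁶ | liberal instrument pre-selection |
| `ld_prune_r2` | 0.1 | pairwise instrument pruning (keep r² < 0.1) |
| `gene_dist_kb` | 250 | biologically-plausible-gene radius |
| `explained_var_min` | 0.001 | "strong instrument" mode: 2p(1−p)β² threshold |
| `or_scale` | 1.81 | log-OR → liability-scale divisor |
| `fdr_alpha` | 0.05 | hierarchical FDR level |

Exclusions are recorded in ledgers with one reason per variant under a fixed
precedence (MAF, info, MAC, AF deviation, mismatch; at meta level
heterogeneity, info, weighted MAF), so ledgers are reproducible regardless of
input order.

## Allele harmonization

Records are aligned to a shared effect allele; a swapped record is flipped
(β := −β, EAF := 1 − EAF), and flipping is an involution. Strand complements
are accepted only when they align without an additional allele swap, because
complement-plus-swap cannot be distinguished from a different allele pair.
Palindromic variants (A/T, C/G) are flagged ambiguous — and excluded from
meta-analysis and instrument sets — when either record's EAF lies in
[0.4, 0.6], where frequency cannot resolve the strand; this window is the
package's choice of standard two-sample MR hygiene.

## Hierarchical FDR

Both multiple-testing layouts (variants-within-hormone for the interaction
scan; outcomes-within-exposure for MR) use one engine: families are screened
by Benjamini–Hochberg across their combined p-values, and hypotheses inside
the k selected of n families are called by within-family BH against
0.05·k/n. The family combiner is Simes (equivalently, the family's minimum
BH-adjusted p), with Bonferroni available as a switch; the two published
descriptions of the procedure coincide under this reading, which is why a
single engine serves both. With one family the procedure reduces exactly to
plain BH. Under a simulated global null (5 families × 10 hypotheses), the
proportion of replicates with any call stays at the nominal level.

## Mendelian randomization and mediation

Instrument selection takes, per locus, the best-associated SNP for which
outcome statistics exist, after the p cut-off, the optional
plausible-gene/strong-instrument restrictions, and greedy LD pruning by
ascending p. Sex-stratified MR uses stratum-matched exposure statistics; CAD
outcome statistics carry no strata, and the combined outcome table is reused
for stratified MR — a modelling assumption of the design, not a switch.

The ratio estimator's SE deliberately uses only the first delta term
(SE_out/|β_exp|): the neglected instrument-uncertainty term is second-order
for strong instruments, and the replicate experiments confirm nominal 95% CI
coverage under the default network. The indirect-effect SE is the first-order
delta form √(α²SE(β)² + β²SE(α)²); a "literal" unsquared variant
(α²SE(β) + β²SE(α)) is kept behind a mode flag for audit only, as it is
dimensionally inconsistent. Direct effects are τ − indirect with
root-sum-square SE, so additivity holds to machine precision and
SE(direct) ≥ max(SE(τ), SE(indirect)) always. Mediation verdicts:
"mediated" (indirect significant, direct not), "direct + indirect" (both),
"neither" otherwise, at nominal 0.05 on the Wald p-values.

## Synthetic data: what it emulates and what it does not

The generator encodes the study design as a causal network: instruments with
chosen EAFs and per-allele effects on log-hormone (optionally sex-multiplied),
a mediator trait M = α·log H + ε on top of a sex-specific anthropometric
baseline, and a continuous CAD liability Y = direct·log H + Σβ·M + ε with a
binary CAD label drawn from a logistic model of Y. The total effect
τ = direct + Σα·β is always derived, never stored. Defaults follow the
validated study conditions: two cohorts of n = 4000, log-trait noise SD 1,
three instruments with effects 0.15/0.12/0.10 at EAFs 0.30/0.25/0.40 (≈1% of
trait variance each — desk-scale power, chosen once for the fixture, not
realism), covariate slopes 0.005 (age) and 0.3 (log-BMI) on log-hormone, and
α = 0.06, β = 0.17 (SE 0.018), direct = −0.118 for the causal network.
Because BMI is both a hormone covariate and a candidate mediator, BMI is
dropped from the hormone covariate model whenever it is declared a mediator;
the default mediator is WHR.

Two summary-statistic modes exist and are cross-checked against each other:
`exact` simulates individuals and runs the association engine; `fast` draws
each per-study SNP effect from its asymptotic Normal(truth, σ²/(2p(1−p)n))
sampling distribution. The replicate experiments (CI coverage, verdict
recovery) use the fast mode; the stated problem sizes — 50 replicates for
coverage, 10,000 variants for the null-inflation check — are the package's
standard experiment sizes.

Not emulated: linkage disequilibrium beyond user-supplied pairwise r² tables,
population structure and relatedness, imputation error (info scores are 1 in
generated data), case-control ascertainment, and X-chromosome dosage
conventions. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the stated generative model,
not robustness to those real-data complications.

For HLA data, subjects draw two haplotypes from a joint two-locus frequency
table; subtype dosages are copy counts and per-sample probability scores are
corrupted downwards by a configurable noise level to exercise the ≥ 0.7 QC
threshold. The bundled frequency table is synthetic (labelled as such), shaped
like a coupled HLA-B × HLA-C pair with a rare haplotype.

## Numerical choices and degenerate inputs

- I² is floored at 0 when Q < k − 1, and a single study has Q = I² = 0 by
  definition (no heterogeneity information).
- Monomorphic dosages are skipped with a flag; constant vectors make dosage
  correlation undefined (NaN with a warning); a monomorphic locus makes
  asymmetric LD undefined (error).
- Logistic models use statsmodels' IRLS (tolerance 1e-8, max 50 iterations);
  complete separation is flagged and the estimate withheld rather than
  reported.
- β_exp = 0 makes the Wald ratio undefined and is flagged as a weak
  instrument; an empty instrument set yields "not computable", mirroring
  strata without usable instruments.
- The "rare in each study" HLA filter is read conservatively: a subtype below
  1% in any study is dropped (every retained subtype can support
  meta-analysis); the "all studies" reading is available via a switch.
- Instrument ties (equal exposure p) break by variant id; QC ledger order
  follows input order but kept-set membership is order-independent.

## Known limitations

- Fixed-effect meta only; no random-effects model, no MR-Egger or
  weighted-median estimators — the design uses ratio + IVW.
- LD for pruning must be supplied; the package computes none from reference
  panels.
- The HLA arm consumes externally estimated dosage/probability matrices; HLA
  imputation itself is out of scope, as are genotype calling, annotation, and
  expression-based association.
- Genomic inflation is computed over post-filter variants per phenotype and
  stratum; pre-filter λ would differ slightly.
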
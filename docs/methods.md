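# Methods

## Model

Log₂ expression for one cell type is modeled as

    Y = Xβ + Wα + ε,        Y: n samples × m genes

where `X` holds the factors of interest and `W` latent unwanted factors
(scan batch, RNA quality, and possibly factors correlated with disease
status). Three designs are used: `X = [G, P]` (risk-allele dosage and
case/control indicator) for cis-eQTL mapping, `X = [G, P, G×P]` for
genotype-by-phenotype interactions, and `X = [P]` for pure case/control
comparisons. `Z` holds nuisance covariates, by default a lone intercept.
The key identifying assumption is the existence of negative-control
genes — housekeeping genes assumed unassociated with every column of
`X` — which carry the same unwanted variation `Wα` as the test genes and
therefore reveal it.

Per SNP, samples missing that SNP's genotype call are dropped for that
SNP's fit only (listwise within SNP); no genotype imputation is done.

## Estimators

All fits first project `Y` and `X` onto the orthogonal complement of `Z`.

- **RUV-2** — SVD of the control columns; Ŵ = first k left singular
  vectors × singular values; OLS of `Y` on `[X, Ŵ]`. `k = 0` reduces
  exactly to OLS (asserted to 1e-12 in the tests).
- **RUV-4** — controls are additionally residualized on `X` before the
  SVD, giving loadings α̂_C; Ŵ is recovered by regressing the
  *unresidualized* controls on α̂_C. This protects the `X` signal from
  absorption into Ŵ at small k while still letting Ŵ span the
  `X`-correlated part of `W`.
- **RUV-inv / RUV-rinv** — generalized least squares with the control
  second-moment matrix `A = Y_C Y_Cᵀ` as noise proxy:

      β̂ = (Xᵀ A_ρ⁻¹ X)⁻¹ Xᵀ A_ρ⁻¹ Y,    A_ρ = A + ρI.

  RUV-inv is the ρ = 0 limit with the Moore–Penrose pseudo-inverse;
  RUV-rinv defaults to ρ = trace(A)/n (the mean eigenvalue), a one-unit
  shrink toward OLS; ρ → ∞ recovers OLS. Per-gene variances come from the
  whitened residuals with df = n − p − q. All solves go through a
  symmetric eigendecomposition of `A` (no explicit inverses); the
  whitening turns the GLS into an OLS on transformed data.

  Neither inverse method requires choosing a number of unwanted factors —
  the practical reason it is the pipeline default.

**Leave-one-out control statistics.** A control gene's own expression
vector is a summand of `A`, so the plain GLS systematically shrinks
control statistics relative to test-gene statistics; a calibration
anchored on the controls would then under-correct (observed as genotype
type-I error near 0.07 instead of 0.05). Each control gene's fit is
therefore recomputed with its own column removed from `A` via a
Sherman–Morrison rank-one downdate — controls and test genes then play by
identical rules. The downdate is vectorized over control genes and adds
negligible cost.

**Maximal-factor limit.** RUV-4 at k = n − p − q saturates the sample
space: the OLS residual is identically zero and no per-gene variance
exists on that path. At that boundary the implementation computes
variances through the control-GLS quadratic form, which is the limit in
which RUV-4 coincides with RUV-inv; the test suite verifies the two
independent algebraic routes (factor regression vs spectral whitening)
agree. For any k with df ≥ 1 the ordinary per-gene OLS variance is used;
note that t statistics at k close to the boundary are df-starved and
noisy, which is the usual argument against pushing factor counts high.

**Empirical variance calibration.** For each factor, ĉ = mean over
control genes of the squared raw t; calibrated t = raw t / √ĉ, with
two-sided p-values from the standard normal. Control-gene calibrated
statistics have mean square exactly 1 by construction, making the
controls an internal null reference. Calibration is scale-invariant and
requires ≥ 2 controls (a warning is issued below 30).

A caveat the package intentionally leaves visible: for the phenotype
coefficient every SNP fit shares essentially the same test, so the
calibration factor's sampling noise (driven by the number of control
genes) does not average out across SNPs; phenotype-coefficient type-I
error at a single simulated cohort therefore scatters more widely around
its nominal level than the genotype coefficient's does.

## Multiple testing

Benjamini–Hochberg step-up q-values (via statsmodels) are computed inside
explicit families, never mixed: the full enumerated cis-pair family of a
cell type (genotype, phenotype and interaction coefficients), the
detected-eQTL subset (a less stringent family for phenotype/interaction
effects among established eQTLs), the near-SNP gene family for `X = P`
scans, and the transcriptome-wide family. Cis pairs are SNP–gene pairs on
the same chromosome with |TSS − SNP| ≤ 500 kb, boundary inclusive, 1-based
coordinates, strand ignored.

## Conditional adjustment

For a significant risk-SNP/gene pair, every panel SNP within 500 kb of
the gene's TSS is fit with the two-factor model and the most significant
one (ties: nearer the TSS, then lexicographic) becomes the lead SNP. If
the lead is the risk SNP itself or in strong LD with it (r² > 0.8) the
pair is classed `lead_or_proxy`. Otherwise the model is refit with both
dosages, `Y = G_MS β_adj + G_sig β_sig + P β_P + …`, and the pair is
classed `attenuated_major` when the risk-SNP coefficient drops by more
than 70 % or changes sign, else `attenuated_minor`. The classification is
scale-invariant; near-collinear leads (r² ≥ 0.999) are forced to
`lead_or_proxy` with a warning. Fits restrict `Y` to the controls plus
the target gene, which leaves the estimates unchanged (only `A` and the
gene's own column enter) and keeps the local scan fast.

## Cross-normalization

Subtracting a fitted `Ŵα̂` estimated on all samples over-adjusts: each
sample's own noise leaks into its correction. The leave-one-out scheme
implemented here: for each sample, (1) fit the configured RUV estimator
on the remaining samples, (2) SVD the control columns of their residuals
to get factor loadings, (3) place the held-out sample in factor space by
regressing its centered control-gene values on the control loadings, and
(4) subtract its predicted unwanted component only. The held-out sample's
non-control values never influence its own adjustment, and `Xβ̂` is left
in the data. The factor count uses Horn's parallel analysis (eigenvalues
above the maximum eigenvalue of a column-permuted copy, fixed permutation
seed, computed once on the full-data residuals): under pure noise it
returns 0 and the adjustment is a no-op, which is what protects against
over-adjustment in clean data.

RLE statistics (per-gene-median-centered values, summarized per sample by
median and IQR) and SVD sample scores (gene-centered, deterministic sign
convention, variance fractions) provide the before/after batch
diagnostics.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any
particular dataset:

- **Genotypes.** Each base SNP is two independent Bernoulli(MAF)
  haplotypes per sample, hence HWE. LD pairs copy haplotypes with flip
  probability f solving r² = (1 − 2f)², which is exact at MAF 0.5 and
  slightly conservative at lower MAF (target 0.6 at MAF 0.3 realizes
  ≈ 0.55); partners sit within 40 kb. Loci are spaced 2 Mb apart (20 per
  chromosome) so cis windows of distinct loci never overlap and per-pair
  truth stays unambiguous. Missing calls default to 0.5 % to exercise
  call-rate filters.
- **Expression.** `Y = μ + Gβ_G + GPβ_GP + Pβ_P + Wα + ε` on the log₂
  scale directly (probe-level simulation is out of scope). Defaults,
  chosen once as field-realistic values: baseline μ ~ U(4, 12); per-gene
  noise SD σ ~ U(0.2, 0.4) log₂ units (typical residual spread of RMA
  expression summaries for expressed genes); MAF ~ U(0.05, 0.5) (risk
  panels hold common variants); k = 3 unwanted factors — a binary batch,
  a continuous quality score, and a factor correlated with phenotype at
  0.3 by default — with gene-loading SDs (0.4, 0.25, 0.25), batch
  dominant, loading on all genes including controls; 10 % of cis genes
  carry an anchor-SNP effect cycling through β_G ∈ {0.2 … 0.6} log₂ per
  allele. Control genes live on a SNP-free chromosome and carry no β of
  any kind. Cohort sizes default to 53 cases / 78 controls
  (`CohortConfig.study_default()` builds the five-cell-type layout with
  per-cell sample counts).
- **Truth table.** Planted pair effects, per-gene σ/μ/β_P/control flag,
  the realized `W` per cell type, and realized r² per LD pair. Scoring
  utilities in `evaluation.py` label scanned pairs causal / tagged
  (r² > 0.5 with a causal SNP of the same gene) / null, so LD shadows are
  counted as neither hits nor false positives in detection rates.

What the generator does *not* emulate: probe-level microarray noise,
genome-wide LD maps, population structure, relatedness, cell-type
deconvolution error. Passing tests therefore demonstrate the estimators'
statistical behavior under the assumed model, not robustness to every
artifact of real arrays.

## Numerical and design choices

- Seeds: a single integer seed fully determines a cohort; independent
  substreams (numpy `default_rng([stream, seed])`) cover genotypes, gene
  placement, effect assignment and per-cell-type expression. The CLI
  derives per-stage seeds from the run seed by a CRC32 of the stage name.
- LD grouping is single-linkage (connected components of the r² > 0.5
  graph) on pairwise-complete dosage correlations; undefined correlations
  (constant SNPs) contribute no edges and raise on direct calls rather
  than returning 0.
- HWE uses the 1-df asymptotic χ² test (the thresholds involved, p >
  0.002, are far from the regime where an exact test would differ
  materially); monomorphic SNPs return p = 1; underflowing p-values are
  clamped to the smallest positive float so p ∈ (0, 1] holds.
- Genomic inflation λ = median(allelic 2×2 χ²) / 0.454937; zero-margin
  SNP tables are skipped with a log notice.
- Degenerate inputs raise informative errors: rank-deficient `Z` names
  the collinear columns, singular `A` at ρ = 0 points to the ridge or
  pseudo-inverse mode, all-missing/constant dosage vectors are rejected
  as "undefined LD" distinct from r² = 0.
- Scan outputs are plain pandas DataFrames sorted deterministically;
  reruns of a fixed cohort + config are byte-identical, including file
  hashes in the `run-all` manifest.

## Known limitations

- Effect-size recovery at n ≈ 130 has an irreducible noise floor of about
  0.05 log₂ units per pair (σ/(sd(G)·√n), worst for low-MAF SNPs); the
  acceptance script reports the resulting truth–estimate correlation, and
  under the default generator settings that correlation is limited by
  this floor rather than by the unwanted-variation removal (an OLS fit
  given the true `W` performs essentially the same).
- The ridge default ρ = trace(A)/n is a heuristic; sensitivity to
  0.1–10× the default is part of the test suite's benchmark grid rather
  than an optimized constant.
- Cross-normalization is validated by its stated properties (batch
  decorrelation, signal retention, leave-one-out stability), not by
  equivalence to an external reference implementation.
- The phenotype-coefficient calibration caveat above: with a few hundred
  controls, per-cohort phenotype type-I error is accurate to roughly
  ±0.02 around the nominal 0.05 even when calibration is working as
  designed.
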
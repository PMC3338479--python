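# Methods

## Study design and trait coding

The package targets a four-group hippocampal expression design: control,
environmental enrichment, voluntary exercise, and fluoxetine, with seven
animals per group (28 samples). The *antidepressant trait* is coded 1 for
exercise and fluoxetine samples and 0 for control and enrichment, keeping
all 28 samples in every correlation test. This coding is what makes the
module–trait significances exact Student-t correlation tests at n = 28.

## Generative model (synthetic_data)

All quantities are log2 expression units. For gene *i* and sample *s*:

    x(i,s) = baseline(i) + Σ_m loading(i,m)·σ_mod·f(m,s)
             + effect(i, group(s)) + ε(i,s)

* `baseline(i) ~ U(4, 12)`, `ε ~ N(0, noise_sd²)` i.i.d.
* Module factors `f(m,s) = ρ_m·z_t(s) + √(1−ρ_m²)·e(m,s)` with `z_t` the
  standardized trait and `e ~ N(0,1)` independent across modules, so `ρ_m`
  (the *module trait loading*) is the expected factor–trait correlation.
  Member genes have loading 1, all others 0.
* Treatment effects for the DE set are drawn from a trivariate Gaussian
  over (fluoxetine, exercise, enrichment) with unit scale `effect_sd` and
  correlation matrix built from `rho_flx_ex` (0.49), `rho_flx_enr` (0.15)
  and `rho_ex_enr` (defaulting to `rho_flx_enr`; the matrix is checked for
  positive semi-definiteness and invalid combinations are rejected).
  Non-DE genes have exactly zero effects.
* Detection P-values: detected genes draw per-sample P ~ U(0, 0.05) with
  5% contamination from U(0, 1); undetected genes draw U(0, 1). Planted
  module and DE genes are always in the detected set; the rest of the set
  is drawn to hit `detect_rate` (0.487) exactly.
* The replication study (fluoxetine vs control, 7 + 7) re-draws baselines
  and noise and sets true effects `b = ρ·a + √(1−ρ²)·sd(a)·z` over the DE
  set (`ρ = replication_rho = 0.57`), zero elsewhere.

One `numpy.random.Generator` seeded from `config.seed` drives every draw
in a fixed documented order (baselines, noise, module residuals, effects,
detected mask, detection P-values), so identical configurations are
bit-identical; the replication generator derives its stream from the same
seed.

### Default scales, and why

`effect_sd = 1.2`, `noise_sd = 0.5`, `module_sd = 1.5` were fixed jointly
by two opposing requirements:

* **Ratio-correlation recovery.** A treatment log-ratio is estimated from
  7-vs-7 group means with variance `2·noise_sd²/7`; correlation estimates
  are attenuated by `effect_sd²/(effect_sd² + 2·noise_sd²/7)` per study
  (≈ 0.975 at the defaults). Estimated cross-treatment correlations must
  stay within ±0.07 of their generating values, which caps `noise_sd`
  relative to `effect_sd`.
* **Clean module recovery.** Chance alignment of DE genes' group-effect
  patterns creates genuine (truth-unassigned) co-expression; β = 14
  suppresses it only while single-sample DE profiles stay below
  |cor| ≈ 0.8. The per-sample noise must therefore be *large* relative to
  the per-sample effect pattern even while the 7-sample group means remain
  precise. `noise_sd = 0.5` with `effect_sd = 1.2` satisfies both; module
  amplitude 1.5 then gives within-module correlations ≈ 0.9, comfortably
  above the DE-gene background.

Typical planted effects of ±1.2 log2 units are large (≈ 2.3-fold), which
is deliberate: the DE set models the reliably-detected responders whose
signatures the concordance statistics compare. Module sizes
(200, 150, 120, 100) and loadings (0.85, 0.80, −0.80, −0.85) give two
trait-positive and two trait-negative modules, mirroring the module–trait
table the network stage reports.

The `SimulationConfig.null()` constructor removes *all* planted structure
(no DE genes, no modules). Zero-loading module factors are not null for
the ANOVA: within any one realization a random factor still shifts group
means and correlates member genes, visibly breaking KS uniformity of the
pooled P-values.

### What the generator does not emulate

Probe-level array artifacts, normalization residuals, batch effects,
heavy-tailed or intensity-dependent noise, correlated baseline structure
beyond the planted modules, and count-based (RNA-seq) sampling. Passing
recovery tests therefore shows the *pipeline logic* is sound under the
assumed Gaussian additive model, not that real arrays meet the model.

## Differential expression

* **Detection filter**: keep genes with detection P < 0.05 (strict) in
  ≥ 80% (inclusive) of all 28 samples jointly — not per group, matching a
  single study-wide expressed count.
* **ANOVA**: vectorized one-way fixed effects; genes with zero total
  variance take P = 1 and are flagged. With two groups F equals the
  squared pooled t (property-tested).
* **q-values**: Storey's procedure; π̂0 from the λ-grid 0.05…0.95 with a
  natural cubic spline read at λ = 0.95, clipped to [1/m, 1]; inputs with
  fewer than 38 P-values fall back to π̂0 = 1, and `mode="bh"` fixes
  π̂0 = 1 exactly (the small-instance oracle is brute-force BH).
* **Contrasts**: pooled-variance two-sample t vs control (equal group
  sizes by design); linear ratios `2^(Δ log2 mean)`; exact-zero
  log-ratios get direction 0 and are excluded from direction tables.

## Concordance

Ratio correlations are computed on log2 ratios. The 2×2 direction table
(reference up/down × concordant/discordant) is tested with a Pearson
chi-square with Yates continuity correction (1 df); Fisher's exact test
is available as a mode. Cross-study comparisons drop (and count) genes
absent from the replication data; the replication summary also reports a
binomial P for the concordant count. `correlation_pvalue` is strictly
decreasing in |r| and in n (property-tested).

## Network stage

Unsigned adjacency `|cor|^β`, β = 14 fixed; TOM per the standard
formula, oracle-checked against a triple loop at 1e-12. Average-linkage
clustering on 1 − TOM. The fixed-height cut runs at **0.90 × the maximum
merge height** (not higher): with a binary trait and strong loadings all
trait-linked module factors share the trait direction (pairwise factor
|cor| ≈ ρ_i·ρ_j), so in an unsigned network distinct trait modules merge
into one branch just below the dendrogram top; cutting at 0.90 separates
them while leaving noise genes unassigned (measured 10/10 default-seed
recovery at ARI ≥ 0.91 versus ~0.6 at 0.99). The cut fraction and minimum
module size (30) are parameters.

Eigengenes are first right-singular vectors of the per-gene standardized
module matrix, unit variance, sign aligned with the module mean profile
(required for determinism). Merging is iterative: the pair with the
highest eigengene correlation strictly above 0.8 merges (larger partner's
name wins; ties by name), eigengenes are recomputed, and the loop ends
when no pair exceeds the threshold — the post-condition is verified by an
exhaustive pair scan in tests. Final modules are renamed M1, M2, … by
size; WGCNA-style color aliases are cosmetic.

The scale-free fit statistic bins log10 connectivity into 10
equal-occupancy bins and regresses the log *density* (bin frequency over
bin width in log-k) on log mean connectivity — with equal-occupancy bins
the raw frequency is constant by construction and carries no signal. The
signed index −sign(slope)·R² is reported alongside R² and the slope.

Gene significance uses the signed correlation with the trait; the GS–MM
coupling per module uses absolute values of both.

## Numerical and scale choices

* Acceptance-scale simulations use ~5,000 genes (≈ 2,430 expressed, all
  entering the network after top-4,000 selection clamps) and 10 seeds per
  recovery statistic; each full network stage runs in ~2 s.
* Degenerate inputs (constant genes, zero margins, sub-minimum modules,
  |r| = 1) follow the documented conventions rather than raising, except
  where an error is the contract (constant trait, missing control, empty
  matrices).
* TSVs are tab-separated UTF-8 with '#' provenance comments (config hash
  and seed) and round-trip floats at full precision.

## Known limitations

* The fixed-height cut is a deliberate simplification of the dynamic
  tree-cut family; deeply nested or unequal-density modules may need the
  full dynamic hybrid variant, which is an extension point.
* Storey's smoother is evaluated at the spline boundary (λ = 0.95) and is
  noisy for a few hundred P-values; `mode="bh"` is conservative and exact.
* Module recovery at the default conditions succeeds in ~9/10 seeds, not
  uniformly: occasionally two same-sign trait modules merge through a
  sampled eigengene correlation above 0.8, which is the merge rule working
  as specified on genuinely entangled factors.
* The replication generator carries gene-level effects only; module
  factors do not replicate, so module genes dilute cross-study
  correlations if included in the readout set.
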
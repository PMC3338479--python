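# coexnet

Differential expression, cross-treatment concordance, and weighted gene
co-expression network analysis (WGCNA) for small multi-group transcriptomic
studies — with a synthetic-data generator that plants the structure the
analysis is meant to find.

## The scientific problem

Different antidepressant interventions — a drug (fluoxetine), voluntary
exercise, environmental enrichment — may act through shared molecular
pathways in the hippocampus. With only a handful of animals per group
(7 per group, 28 arrays), gene-by-gene testing of ~20k transcripts is
underpowered, so the analysis leans on three complementary strategies:

1. **Differential expression** on detected genes only: a gene is
   "expressed" when its detection-above-background P-value is < 0.05 in
   ≥ 80% of samples; expressed genes are tested with a one-way ANOVA
   across the four groups and called at Storey q ≤ 0.05.
2. **Concordance statistics**: if two interventions share a mechanism,
   their treatment-vs-control log2 ratio vectors correlate, their up/down
   calls agree, and an independent study's ratios reproduce the signature.
   Correlation P-values use the exact Student-t transform
   `t = r·√(n−2)/√(1−r²)`; 2×2 direction tables use a Yates-corrected
   chi-square (Fisher's exact as an alternative).
3. **Co-expression modules**: an unsigned weighted network `a_ij =
   |cor(x_i, x_j)|^β` (β = 14) is summarized by the topological overlap
   matrix (TOM); average-linkage clustering of 1 − TOM plus a fixed-height
   cut yields modules, merged when their eigengenes (first principal
   components) correlate above 0.8. Each module eigengene is correlated
   with the antidepressant trait (1 = exercise/fluoxetine, 0 = control/
   enrichment), and per-gene **gene significance** (cor with trait) is
   related to **module membership** (cor with the eigengene).

Because the package is exercised end-to-end on synthetic data, the
generator is first-class: it plants co-expression modules with known
trait loadings, differentially expressed genes with a known trivariate
effect-correlation structure across treatments (defaults 0.49
fluoxetine–exercise, 0.15 fluoxetine–enrichment), a matched replication
study (default cross-study effect correlation 0.57), and detection
P-values reproducing a ~49% expressed fraction. Every downstream claim is
tested against this ground truth.

## Worked example

```python
from coexnet import PipelineConfig, run_report
report = run_report(PipelineConfig(seed=1))
```

which (see `examples/05_full_report.py`) prints:

```
{
 "config_hash": "206831a0db5a",
 "expressed_fraction": 0.486,
 "n_significant_q05": 1090,
 "r_flx_ex_de": 0.499,
 "replication_r": 0.508,
 "n_modules": 4,
 "n_trait_modules_p05": 4
}
```

About half the simulated genes pass the detection filter (configured
rate 0.487); the fluoxetine and exercise log2-ratio vectors correlate at
0.499 over the planted DE set (generating value 0.49) while the
independent replication study reproduces the fluoxetine signature at
0.508 (generating value 0.57, attenuated by measurement noise on both
sides); and the network stage recovers all four planted modules, each
significantly associated with the trait with the correct sign. The
`examples/` directory has one short narrative script per capability.

A CLI mirrors the stages:

```sh
coexnet simulate --outdir sim --seed 1
coexnet de --expr sim/expression.tsv --detect sim/detection.tsv \
           --design sim/design.tsv --out de.tsv
coexnet network --expr sim/expression.tsv --design sim/design.tsv --out net/
coexnet report --outdir out --seed 1
```

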
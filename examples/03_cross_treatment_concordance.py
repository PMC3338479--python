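"""Concordance of treatment signatures across treatments and across studies.

Three readouts: the Pearson correlation of log2 expression ratios (with its
exact Student-t P-value), a 2x2 up/down direction table tested with a
Yates-corrected chi-square, and replication of the DE set in an
independent two-group study.
"""

from coexnet import (
    SimulationConfig,
    direction_concordance,
    generate_dataset,
    generate_replication,
    ratio_correlation,
    replication_summary,
    run_de,
)

config = SimulationConfig(seed=1)
expression, detection, design, truth = generate_dataset(config)
result, _ = run_de(expression, detection, design)
de_genes = truth.de_genes.intersection(result.gene_ids)

r, p = ratio_correlation(
    result.table["ratio_fluoxetine"], result.table["ratio_exercise"], de_genes
)
print(f"fluoxetine vs exercise ratio correlation (DE set): r={r:.3f} (p={p:.2e})")
r2, p2 = ratio_correlation(
    result.table["ratio_fluoxetine"], result.table["ratio_enrichment"], de_genes
)
print(f"fluoxetine vs enrichment:                          r={r2:.3f} (p={p2:.2e})")

# Direction agreement among strong fluoxetine responders (contrast P < 0.05)
responders = de_genes[result.table.loc[de_genes, "p_fluoxetine"] < 0.05]
dires = direction_concordance(
    result.table["dir_fluoxetine"].loc[responders],
    result.table["dir_exercise"].loc[responders],
)
print(f"direction table over {len(responders)} fluoxetine responders:\n{dires.table}")
print(f"Yates chi2={dires.chi2:.1f}, p={dires.p_table:.2e} "
      "(tests whether concordance differs between up- and down-genes)")
from scipy import stats  # noqa: E402

n_conc = int(dires.table["concordant"].sum())
print(f"overall concordant: {n_conc}/{dires.n} "
      f"(binomial p={stats.binomtest(n_conc, dires.n, 0.5).pvalue:.2e})")

rep_expr, rep_design = generate_replication(truth, config)
rep = replication_summary(result, rep_expr, rep_design, de_genes)
print(f"cross-study ratio correlation: r={rep.r:.3f} (p={rep.p_correlation:.2e})")
# The two antidepressant-like interventions agree far beyond the enrichment
# control (generating correlations 0.49 vs 0.15), and the independent
# replication tracks the original effects (generating correlation 0.57).
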
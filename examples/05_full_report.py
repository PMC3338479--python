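"""One-call end-to-end report over a simulated study.

Equivalent to the CLI's `coexnet report`; returns a JSON-serializable
summary of every stage plus the config hash and seed that produced it.
"""

import json

from coexnet import PipelineConfig, run_report

report = run_report(PipelineConfig(seed=1))

print(json.dumps({
    "config_hash": report["config_hash"],
    "expressed_fraction": round(report["diffexpr"]["expressed_fraction"], 3),
    "n_significant_q05": report["diffexpr"]["n_significant"],
    "r_flx_ex_de": round(
        report["concordance"]["fluoxetine_vs_exercise"]["r_de_genes"], 3
    ),
    "replication_r": round(report["concordance"]["replication"]["r"], 3),
    "n_modules": report["network"]["n_modules"],
    "n_trait_modules_p05": report["network"]["n_trait_modules_p05"],
}, indent=1))
# About half the genes are detected, the fluoxetine/exercise signatures
# correlate near the generating 0.49, the replication near 0.57, and the
# four planted modules appear with significant trait association.
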
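"""End-to-end report: simulate -> differential expression -> concordance ->
co-expression network, with a machine-readable JSON summary."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance as cc
from . import diffexpr as de
from . import network as nw
from .config import PipelineConfig
from .simulate import generate_dataset, generate_replication

log = logging.getLogger(__name__)

__all__ = ["run_report"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise StageError(name, exc) from exc

        return wrapper

    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig):
    sim = config.simulation
    if sim.seed != config.seed:
        import dataclasses

        sim = dataclasses.replace(sim, seed=config.seed)
    expr, det, design, truth = generate_dataset(sim)
    rep_expr, rep_design = generate_replication(truth, sim)
    return sim, expr, det, design, truth, rep_expr, rep_design


def run_report(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage on a simulated study and summarize the results.

    Returns (and optionally writes) a JSON-serializable report with the
    expressed fraction, DE counts, cross-treatment and cross-study
    concordance statistics, and the module/trait table, plus the config
    hash and seed that produced it.
    """
    sim, expr, det, design, truth, rep_expr, rep_design = _simulate(config)
    report: dict = {
        "config_hash": config.hash(),
        "seed": int(config.seed),
        "parameters": config.to_dict(),
    }

    # --- differential expression ------------------------------------------
    @_stage("diffexpr")
    def _de():
        return de.run_de(
            expr,
            det,
            design,
            alpha=config.alpha,
            min_frac=config.min_frac,
            qvalue_mode=config.qvalue_mode,
        )

    result, mask = _de()
    sig = result.significant(config.fdr)
    report["diffexpr"] = {
        "n_genes": int(len(expr)),
        "n_expressed": int(mask.sum()),
        "expressed_fraction": float(mask.mean()),
        "n_significant": int(len(sig)),
        "fdr": config.fdr,
    }

    # --- concordance -------------------------------------------------------
    @_stage("concordance")
    def _concord():
        de_genes = truth.de_genes.intersection(result.gene_ids)
        out = {}
        for pair, (a, b) in {
            "fluoxetine_vs_exercise": ("fluoxetine", "exercise"),
            "fluoxetine_vs_enrichment": ("fluoxetine", "enrichment"),
        }.items():
            if a not in result.treatments or b not in result.treatments:
                continue
            entry = {}
            r, p = cc.ratio_correlation(
                result.table[f"ratio_{a}"], result.table[f"ratio_{b}"]
            )
            entry["r_all_genes"] = r
            entry["p_all_genes"] = p
            if len(de_genes) >= 3:
                r, p = cc.ratio_correlation(
                    result.table[f"ratio_{a}"], result.table[f"ratio_{b}"], de_genes
                )
                entry["r_de_genes"] = r
                entry["p_de_genes"] = p
            out[pair] = entry
        dirs = cc.direction_concordance(
            result.table["dir_fluoxetine"].loc[
                sig if len(sig) >= 10 else de_genes
            ],
            result.table["dir_exercise"].loc[sig if len(sig) >= 10 else de_genes],
            mode=config.concordance_mode,
        )
        out["direction_fluoxetine_vs_exercise"] = dirs.to_dict()
        # Replication carries gene-level treatment effects only, so the
        # informative readout is the planted DE set (falling back to the
        # significant set when truth is degenerate).
        rep_set = de_genes if len(de_genes) >= 10 else sig
        if len(rep_set) >= 3:
            rep = cc.replication_summary(result, rep_expr, rep_design, rep_set)
            out["replication"] = rep.to_dict()
        return out

    report["concordance"] = _concord()

    # --- network -----------------------------------------------------------
    @_stage("network")
    def _network():
        expressed = expr.loc[mask]
        net, sub = nw.build_network(expressed, top_k=config.top_k_genes, beta=config.beta)
        raw = nw.cluster_and_cut(
            net.dissimilarity,
            net.gene_ids,
            min_module_size=config.min_module_size,
            cut_height_frac=config.cut_height_frac,
        )
        modules = nw.merge_close_modules(
            sub,
            raw.labels,
            threshold=config.merge_threshold,
            min_module_size=config.min_module_size,
        )
        trait = design.set_index("sample_id")["trait"]
        if modules.eigengenes.empty:
            return {"n_genes_in_network": int(len(net.gene_ids)), "modules": {}}, modules
        assoc = nw.gene_trait_statistics(sub, modules.labels, modules.eigengenes, trait)
        table = assoc.module_table.copy()
        table["var_explained"] = modules.var_explained
        colors = modules.color_aliases()
        mod_dict = {
            m: {
                "color": colors.get(m, m),
                **{
                    k: (float(v) if isinstance(v, (float, np.floating)) else int(v))
                    for k, v in row.items()
                },
            }
            for m, row in table.iterrows()
        }
        return (
            {
                "n_genes_in_network": int(len(net.gene_ids)),
                "n_modules": int(len(modules.eigengenes)),
                "n_unassigned": int((modules.labels == nw.UNASSIGNED).sum()),
                "n_trait_modules_p05": int((table["p_trait"] < 0.05).sum()),
                "modules": mod_dict,
            },
            modules,
        )

    net_report, modules = _network()
    report["network"] = net_report

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        from .io import write_design_tsv, write_matrix_tsv

        prov = {"config_hash": config.hash(), "seed": config.seed}
        write_matrix_tsv(expr, outdir / "expression.tsv", prov)
        write_matrix_tsv(det, outdir / "detection.tsv", prov)
        write_design_tsv(design, outdir / "design.tsv", prov)
        result.table.to_csv(outdir / "de_table.tsv", sep="\t")
        modules.labels.to_frame().to_csv(outdir / "modules.tsv", sep="\t")
    return report
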
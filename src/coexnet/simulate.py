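"""Synthetic four-group expression studies with planted structure.

The generator produces a gene x sample log2 expression matrix built from

    x(i, s) = baseline(i) + sum_m loading(i, m) * module_sd * f(m, s)
              + effect(i, group(s)) + noise(i, s)

where each module factor ``f(m, s) = rho_m * z_t(s) + sqrt(1 - rho_m^2) * e(m, s)``
mixes the standardized antidepressant-trait code ``z_t`` with an independent
standard-normal residual, so that ``rho_m`` is the expected correlation
between the module factor and the trait. Treatment effects for a designated
set of differentially expressed (DE) genes are drawn from a trivariate
Gaussian whose correlation matrix couples the fluoxetine, exercise and
enrichment effects; all other genes have zero treatment effect.

A matching detection-P matrix mimics an array platform's detection-above-
background call: detected genes draw per-sample P-values from U(0, 0.05)
with a small U(0, 1) contamination, undetected genes from U(0, 1).

Everything is driven by a single :class:`numpy.random.Generator` seeded from
``config.seed``, in a fixed documented order, so identical configurations
yield bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TRAIT_OF_GROUP, ConfigError, SimulationConfig

__all__ = ["SyntheticTruth", "generate_dataset", "generate_replication"]

#: Fraction of detection P-values for detected genes drawn from U(0,1)
#: instead of U(0, 0.05), emulating occasional detection failures.
DETECTION_CONTAMINATION = 0.05


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset.

    ``module_of_gene`` uses labels ``"M1", "M2", ...`` and ``"unassigned"``.
    Effects are log2 shifts relative to control and are zero outside the DE
    set. ``factor_scores`` holds the module factors f(m, s).
    """

    module_of_gene: pd.Series
    effect_flx: pd.Series
    effect_ex: pd.Series
    effect_enr: pd.Series
    factor_scores: pd.DataFrame
    expressed_mask: pd.Series
    seed_used: int

    @property
    def de_genes(self) -> pd.Index:
        return self.effect_flx.index[self.effect_flx != 0.0]

    def to_dict(self) -> dict:
        return {
            "module_of_gene": self.module_of_gene.to_dict(),
            "effect_flx": self.effect_flx.to_dict(),
            "effect_ex": self.effect_ex.to_dict(),
            "effect_enr": self.effect_enr.to_dict(),
            "factor_scores": {
                m: row.tolist() for m, row in self.factor_scores.iterrows()
            },
            "expressed_mask": {
                g: bool(v) for g, v in self.expressed_mask.items()
            },
            "seed_used": int(self.seed_used),
        }


def _design_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for g in config.groups:
        for i in range(config.n_per_group):
            rows.append((f"{g[:3]}_{i + 1}", g))
    df = pd.DataFrame(rows, columns=["sample_id", "group"])
    df["trait"] = df["group"].map(TRAIT_OF_GROUP).astype(int)
    return df


def _gene_ids(n: int) -> pd.Index:
    width = len(str(n))
    return pd.Index([f"g{str(i + 1).zfill(width)}" for i in range(n)], name="gene_id")


def _standardized_trait(trait: np.ndarray) -> np.ndarray:
    sd = trait.std()
    if sd == 0:
        raise ConfigError("trait code is constant across samples")
    return (trait - trait.mean()) / sd


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate one four-group study.

    Returns ``(expression, detection_p, design, truth)`` where expression and
    detection_p are gene x sample DataFrames sharing index/columns, and
    design has columns ``sample_id``, ``group``, ``trait``.
    """
    rng = np.random.default_rng(config.seed)
    design = _design_frame(config)
    sample_ids = design["sample_id"].to_numpy()
    groups = design["group"].to_numpy()
    trait = design["trait"].to_numpy(dtype=float)
    zt = _standardized_trait(trait)
    n_g, n_s, n_m = config.n_genes, config.n_samples, config.n_modules

    genes = _gene_ids(n_g)
    module_label = np.full(n_g, "unassigned", dtype=object)
    pos = 0
    module_members: list[np.ndarray] = []
    for m, size in enumerate(config.module_sizes):
        idx = np.arange(pos, pos + size)
        module_label[idx] = f"M{m + 1}"
        module_members.append(idx)
        pos += size
    de_idx = np.arange(pos, pos + config.n_de_genes)

    # Draw order is fixed: baselines, noise, module residuals, effects,
    # expressed mask, detection P-values.
    baseline = rng.uniform(4.0, 12.0, n_g)
    x = baseline[:, None] + rng.normal(0.0, config.noise_sd, (n_g, n_s))

    factors = np.zeros((n_m, n_s))
    for m, rho in enumerate(config.module_trait_loadings):
        resid = rng.normal(0.0, 1.0, n_s)
        factors[m] = rho * zt + np.sqrt(1.0 - rho**2) * resid
        x[module_members[m]] += config.module_sd * factors[m]

    effect = np.zeros((n_g, 3))  # columns: fluoxetine, exercise, enrichment
    if config.n_de_genes > 0:
        corr = config.effect_correlation_matrix()
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(3))
        effect[de_idx] = (rng.normal(0.0, 1.0, (config.n_de_genes, 3)) @ chol.T)
        effect[de_idx] *= config.effect_sd
    col_of_group = {"fluoxetine": 0, "exercise": 1, "enrichment": 2}
    for g, col in col_of_group.items():
        if g in config.groups:
            x[:, groups == g] += effect[:, col][:, None]

    # Expressed mask: planted module and DE genes are always detected; the
    # remainder of the detected set is drawn at random to hit detect_rate.
    n_expressed = int(round(config.detect_rate * n_g))
    forced = np.zeros(n_g, dtype=bool)
    for idx in [*module_members, de_idx]:
        forced[idx] = True
    if forced.sum() > n_expressed:
        raise ConfigError(
            "detect_rate too small to cover planted module and DE genes "
            f"({forced.sum()} forced > {n_expressed} detected)"
        )
    free = np.where(~forced)[0]
    extra = rng.choice(free, size=n_expressed - forced.sum(), replace=False)
    expressed = forced.copy()
    expressed[extra] = True

    det = rng.uniform(0.0, 1.0, (n_g, n_s))
    exp_rows = np.where(expressed)[0]
    clean = rng.random((len(exp_rows), n_s)) >= DETECTION_CONTAMINATION
    det_exp = rng.uniform(0.0, 0.05, (len(exp_rows), n_s))
    det[exp_rows] = np.where(clean, det_exp, det[exp_rows])

    expression = pd.DataFrame(x, index=genes, columns=sample_ids)
    detection = pd.DataFrame(det, index=genes, columns=sample_ids)
    truth = SyntheticTruth(
        module_of_gene=pd.Series(module_label, index=genes, name="module"),
        effect_flx=pd.Series(effect[:, 0], index=genes, name="effect_flx"),
        effect_ex=pd.Series(effect[:, 1], index=genes, name="effect_ex"),
        effect_enr=pd.Series(effect[:, 2], index=genes, name="effect_enr"),
        factor_scores=pd.DataFrame(
            factors, index=[f"M{m + 1}" for m in range(n_m)], columns=sample_ids
        ),
        expressed_mask=pd.Series(expressed, index=genes, name="expressed"),
        seed_used=int(config.seed),
    )
    return expression, detection, design, truth


def generate_replication(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an independent two-group (control vs fluoxetine) study whose
    true fluoxetine effects correlate with the original study's at
    ``config.replication_rho``.

    For DE genes the replication effect is
    ``b = rho * a + sqrt(1 - rho^2) * sd(a) * z`` with ``a`` the original
    effect vector and ``z`` standard normal, so corr(b, a) -> rho as the DE
    set grows; non-DE genes stay at zero effect. Returns
    ``(expression, design)``.
    """
    rho = config.replication_rho
    if not -1.0 < rho < 1.0:
        if abs(rho) == 1.0:
            pass  # exact copy/flip limit is allowed
        else:
            raise ConfigError(f"replication_rho={rho} outside [-1, 1]")
    rng = np.random.default_rng([int(truth.seed_used), 0x5EED])
    genes = truth.effect_flx.index
    n_g = len(genes)
    n_per = config.n_per_group
    sample_ids = [f"rep_con_{i + 1}" for i in range(n_per)] + [
        f"rep_flx_{i + 1}" for i in range(n_per)
    ]
    design = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": ["control"] * n_per + ["fluoxetine"] * n_per,
        }
    )
    design["trait"] = design["group"].map(TRAIT_OF_GROUP).astype(int)

    a = truth.effect_flx.to_numpy()
    de = a != 0.0
    b = np.zeros(n_g)
    if de.any():
        sd_a = a[de].std(ddof=1)
        z = rng.normal(0.0, 1.0, de.sum())
        b[de] = rho * a[de] + np.sqrt(max(0.0, 1.0 - rho**2)) * sd_a * z

    baseline = rng.uniform(4.0, 12.0, n_g)
    x = baseline[:, None] + rng.normal(0.0, config.noise_sd, (n_g, 2 * n_per))
    x[:, n_per:] += b[:, None]
    expression = pd.DataFrame(x, index=genes, columns=sample_ids)
    return expression, design
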
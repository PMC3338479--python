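"""Expression filtering, per-gene ANOVA, q-values, and treatment contrasts.

The analysis follows the classic microarray recipe for a small multi-group
design: keep genes detected above background in a sufficient fraction of
samples, test each kept gene with a one-way fixed-effects ANOVA across the
treatment groups, convert the P-value distribution to Storey q-values for
false-discovery-rate control, and summarize each treatment against control
with a linear-scale expression ratio and a pooled two-sample t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .config import ConfigError

log = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "filter_expressed",
    "anova_per_gene",
    "qvalues",
    "contrasts_vs_control",
    "run_de",
]


class DegenerateTestWarning(UserWarning):
    """A statistical test hit a degenerate input (e.g. zero total variance)."""


@dataclass
class DEResult:
    """Per-gene differential-expression summary.

    ``table`` columns: F, p_anova, q, ``mean_<group>`` per group,
    ``ratio_<treatment>`` (linear scale, treatment/control),
    ``p_<treatment>`` (pooled two-sample t vs control) and
    ``dir_<treatment>`` (sign of the log-ratio; 0 on exact ties).
    """

    table: pd.DataFrame
    control: str
    treatments: list[str]

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def significant(self, fdr: float = 0.05) -> pd.Index:
        return self.table.index[self.table["q"] <= fdr]

    def log2_ratio(self, treatment: str) -> pd.Series:
        return np.log2(self.table[f"ratio_{treatment}"])


def filter_expressed(
    detection: pd.DataFrame, alpha: float = 0.05, min_frac: float = 0.80
) -> pd.Series:
    """Detection-above-background filter.

    A gene is kept iff its detection P-value is strictly below ``alpha`` in
    at least ``min_frac`` of all samples (the fraction threshold is an
    inclusive >=, the P threshold a strict <).
    """
    if detection.size == 0:
        raise ValueError("empty detection matrix")
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1]")
    if not 0.0 < min_frac <= 1.0:
        raise ValueError(f"min_frac={min_frac} outside (0, 1]")
    vals = detection.to_numpy()
    if np.isnan(vals).any() or vals.min() < 0 or vals.max() > 1:
        raise ValueError("detection P-values must lie in [0, 1]")
    frac = (vals < alpha).mean(axis=1)
    return pd.Series(frac >= min_frac, index=detection.index, name="expressed")


def _group_indices(expr: pd.DataFrame, design: pd.DataFrame) -> dict[str, np.ndarray]:
    missing = set(expr.columns) - set(design["sample_id"])
    if missing:
        raise ValueError(f"samples missing from design: {sorted(missing)}")
    group_of = design.set_index("sample_id")["group"]
    cols = group_of.reindex(expr.columns)
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(cols):
        out[g] = np.where((cols == g).to_numpy())[0]
    for g, idx in out.items():
        if len(idx) < 2:
            raise ValueError(f"group '{g}' has fewer than 2 samples")
    return out


def anova_per_gene(expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Vectorized one-way fixed-effects ANOVA for every gene.

    F = (SSB/dfB) / (SSW/dfW) with P from the F distribution. Genes with
    zero between- and within-group variance take P = 1 by convention and are
    flagged in the ``degenerate`` column.
    """
    groups = _group_indices(expr, design)
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    x = expr.to_numpy(dtype=float)
    n = x.shape[1]
    grand = x.mean(axis=1)
    ssb = np.zeros(len(x))
    ssw = np.zeros(len(x))
    for idx in groups.values():
        xg = x[:, idx]
        mg = xg.mean(axis=1)
        ssb += len(idx) * (mg - grand) ** 2
        ssw += ((xg - mg[:, None]) ** 2).sum(axis=1)
    dfb = len(groups) - 1
    dfw = n - len(groups)
    if dfw <= 0:
        raise ValueError("no residual degrees of freedom")
    degenerate = (ssw == 0) & (ssb == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(f, dfb, dfw)
    # ssw == 0 with ssb > 0: infinitely strong separation, p -> 0.
    p[(ssw == 0) & (ssb > 0)] = 0.0
    f[degenerate] = np.nan
    p[degenerate] = 1.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) had zero total variance; P set to 1",
            DegenerateTestWarning,
            stacklevel=2,
        )
    return pd.DataFrame({"F": f, "p_anova": p}, index=expr.index)


def _pi0_smoother(p: np.ndarray, lambdas: np.ndarray) -> float:
    """Storey's pi0: natural cubic spline through pi0(lambda), read at the
    largest lambda."""
    m = len(p)
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    spline = interpolate.CubicSpline(lambdas, pi0_lam, bc_type="natural")
    pi0 = float(spline(lambdas[-1]))
    return min(max(pi0, 1.0 / m), 1.0)


def qvalues(p, mode: str = "smoother") -> np.ndarray:
    """Storey q-values for a vector of P-values.

    With ``mode="smoother"`` the null proportion pi0 is estimated on the
    lambda grid 0.05, 0.10, ..., 0.95 with a natural-cubic-spline smoother
    evaluated at lambda = 0.95 (clipped into (0, 1]); with ``mode="bh"``
    pi0 is fixed at 1, which reduces to Benjamini-Hochberg adjusted
    P-values. q(i) = min_{j: p_j >= p_i} pi0 * m * p_j / rank(j).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("P-values must lie in [0, 1]")
    m = len(p)
    if mode == "bh":
        pi0 = 1.0
    elif mode == "smoother":
        lambdas = np.arange(0.05, 0.96, 0.05)
        # The spline needs informative counts; tiny inputs fall back to pi0=1.
        if m < 2 * len(lambdas):
            pi0 = 1.0
        else:
            pi0 = _pi0_smoother(p, lambdas)
    else:
        raise ValueError(f"unknown qvalue mode: {mode!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def contrasts_vs_control(
    expr: pd.DataFrame, design: pd.DataFrame, control: str = "control"
) -> pd.DataFrame:
    """Treatment-vs-control summaries for every non-control group.

    For each treatment: linear expression ratio 2^(mean_t - mean_c) of the
    log2 group means, the sign of the log-ratio, and a pooled-variance
    two-sample t-test P-value against the control group.
    """
    groups = _group_indices(expr, design)
    if control not in groups:
        raise ValueError(f"control group '{control}' not present in design")
    x = expr.to_numpy(dtype=float)
    ci = groups[control]
    xc = x[:, ci]
    mc = xc.mean(axis=1)
    vc = xc.var(axis=1, ddof=1)
    out: dict[str, np.ndarray] = {}
    treatments = [g for g in groups if g != control]
    for g in treatments:
        ti = groups[g]
        xt = x[:, ti]
        mt = xt.mean(axis=1)
        vt = xt.var(axis=1, ddof=1)
        n1, n2 = len(ti), len(ci)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * vt + (n2 - 1) * vc) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        delta = mt - mc
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / se
        pt = 2.0 * stats.t.sf(np.abs(t), df)
        zero_se = se == 0
        if zero_se.any():
            pt[zero_se & (delta != 0)] = 0.0
            pt[zero_se & (delta == 0)] = 1.0
            warnings.warn(
                f"{int(zero_se.sum())} gene(s) with zero pooled variance in "
                f"contrast {g} vs {control}",
                DegenerateTestWarning,
                stacklevel=2,
            )
        out[f"ratio_{g}"] = np.exp2(delta)
        out[f"dir_{g}"] = np.sign(delta)
        out[f"p_{g}"] = pt
    for g, idx in groups.items():
        out[f"mean_{g}"] = x[:, idx].mean(axis=1)
    return pd.DataFrame(out, index=expr.index)


def run_de(
    expr: pd.DataFrame,
    detection: pd.DataFrame | None,
    design: pd.DataFrame,
    alpha: float = 0.05,
    min_frac: float = 0.80,
    qvalue_mode: str = "smoother",
    control: str = "control",
) -> tuple[DEResult, pd.Series]:
    """Full differential-expression stage: filter, ANOVA, q-values, contrasts.

    Returns the :class:`DEResult` over expressed genes and the boolean
    expressed mask over all input genes (all-True when ``detection`` is
    None).
    """
    if detection is not None:
        if not detection.index.equals(expr.index) or not detection.columns.equals(
            expr.columns
        ):
            raise ValueError("detection matrix not aligned with expression matrix")
        mask = filter_expressed(detection, alpha=alpha, min_frac=min_frac)
    else:
        mask = pd.Series(True, index=expr.index, name="expressed")
    kept = expr.loc[mask]
    if kept.empty:
        raise ValueError("no genes pass the detection filter")
    aov = anova_per_gene(kept, design)
    aov["q"] = qvalues(aov["p_anova"].to_numpy(), mode=qvalue_mode)
    con = contrasts_vs_control(kept, design, control=control)
    table = pd.concat([aov, con], axis=1)
    treatments = [c.removeprefix("ratio_") for c in con.columns if c.startswith("ratio_")]
    log.info(
        "DE stage: %d/%d genes expressed, %d significant at q<=0.05",
        mask.sum(),
        len(mask),
        int((table["q"] <= 0.05).sum()),
    )
    return DEResult(table=table, control=control, treatments=treatments), mask
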
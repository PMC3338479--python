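"""Agreement of differential-expression signatures across treatments/studies.

Three complementary readouts quantify whether two interventions (or two
independent studies) move the transcriptome the same way:

* the Pearson correlation of log2 expression ratios with its exact
  Student-t P-value,
* a 2x2 direction-concordance table (reference up/down x concordant/
  discordant in the other signature) tested with a Yates-corrected
  chi-square (or Fisher's exact test), and
* the overlap of a gene set with the top-k of a ranked list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ConcordanceResult",
    "correlation_pvalue",
    "direction_concordance",
    "ratio_correlation",
    "replication_summary",
    "top_k_overlap",
]


class DegenerateTableWarning(UserWarning):
    """A contingency table has a zero margin; the test is skipped."""


@dataclass
class ConcordanceResult:
    """Summary of agreement between two signatures.

    ``table`` rows are (up-in-reference, down-in-reference) and columns
    (concordant, discordant). ``chi2``/``p_table`` are NaN when a margin is
    zero and the test was skipped.
    """

    r: float = np.nan
    n: int = 0
    p_correlation: float = np.nan
    table: pd.DataFrame | None = None
    chi2: float = np.nan
    p_table: float = np.nan
    mean_ratio_up: float = np.nan
    mean_ratio_down: float = np.nan
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "r": float(self.r),
            "n": int(self.n),
            "p_correlation": float(self.p_correlation),
            "chi2": float(self.chi2),
            "p_table": float(self.p_table),
            "mean_ratio_up": float(self.mean_ratio_up),
            "mean_ratio_down": float(self.mean_ratio_down),
        }
        if self.table is not None:
            d["table"] = {
                str(row): {str(c): int(v) for c, v in r.items()}
                for row, r in self.table.iterrows()
            }
        d.update(self.extras)
        return d


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided P-value of a Pearson correlation under the null rho = 0.

    Uses the exact Student-t transform t = r * sqrt(n - 2) / sqrt(1 - r^2)
    with n - 2 degrees of freedom. |r| = 1 returns 0 by convention.
    """
    if n < 3:
        raise ValueError("correlation test needs n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation r={r} outside [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, n - 2))


def yates_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on a 2x2 table.

    chi2 = sum over cells of (max(|o - e| - 1/2, 0))^2 / e, 1 df.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    rows, cols, total = table.sum(1), table.sum(0), table.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in 2x2 table")
    expected = np.outer(rows, cols) / total
    chi2 = float(
        (np.clip(np.abs(table - expected) - 0.5, 0.0, None) ** 2 / expected).sum()
    )
    return chi2, float(stats.chi2.sf(chi2, 1))


def direction_concordance(
    ref_directions: pd.Series,
    other_directions: pd.Series,
    mode: str = "yates",
) -> ConcordanceResult:
    """Test whether up/down calls agree between two signatures.

    Genes with a zero direction in either input are excluded. The 2x2 table
    has rows (up, down) in the reference and columns (concordant,
    discordant). ``mode`` selects a Yates-corrected chi-square or Fisher's
    exact test; a zero margin skips the test but still returns the table.
    """
    if mode not in ("yates", "fisher"):
        raise ValueError(f"unknown concordance mode: {mode!r}")
    shared = ref_directions.index.intersection(other_directions.index)
    if len(shared) < len(ref_directions) or len(shared) < len(other_directions):
        log.info(
            "direction_concordance: %d unmatched gene IDs dropped",
            len(ref_directions) + len(other_directions) - 2 * len(shared),
        )
    a = np.sign(ref_directions.loc[shared].to_numpy(dtype=float))
    b = np.sign(other_directions.loc[shared].to_numpy(dtype=float))
    keep = (a != 0) & (b != 0)
    a, b = a[keep], b[keep]
    up, down = a > 0, a < 0
    conc = a == b
    table = pd.DataFrame(
        [
            [int((up & conc).sum()), int((up & ~conc).sum())],
            [int((down & conc).sum()), int((down & ~conc).sum())],
        ],
        index=pd.Index(["up", "down"], name="reference"),
        columns=["concordant", "discordant"],
    )
    res = ConcordanceResult(n=int(keep.sum()), table=table)
    t = table.to_numpy()
    if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
        warnings.warn(
            "zero margin in direction table; association test skipped",
            DegenerateTableWarning,
            stacklevel=2,
        )
        return res
    if mode == "yates":
        res.chi2, res.p_table = yates_chi2(t)
    else:
        res.p_table = float(stats.fisher_exact(t)[1])
    return res


def ratio_correlation(
    ratios_a: pd.Series, ratios_b: pd.Series, gene_subset=None
) -> tuple[float, float]:
    """Pearson correlation of two log2 ratio vectors over a gene subset,
    with its Student-t P-value. Inputs are linear-scale ratios."""
    if gene_subset is None:
        gene_subset = ratios_a.index.intersection(ratios_b.index)
    gene_subset = pd.Index(gene_subset)
    a = np.log2(ratios_a.loc[gene_subset].to_numpy(dtype=float))
    b = np.log2(ratios_b.loc[gene_subset].to_numpy(dtype=float))
    if len(a) < 3:
        raise ValueError("ratio correlation needs at least 3 genes")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant ratio vector; correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, correlation_pvalue(min(max(r, -1.0), 1.0), len(a))


def replication_summary(
    de_ref,
    expr_rep: pd.DataFrame,
    design_rep: pd.DataFrame,
    sig_set,
    treatment: str = "fluoxetine",
    control: str = "control",
) -> ConcordanceResult:
    """Cross-study replication of a significant gene set.

    Computes the replication study's linear expression ratios
    (treatment vs control group means on the log2 scale), counts how many
    reference up-genes replicate with ratio > 1 and down-genes with
    ratio < 1, the mean linear ratio per direction, and the correlation of
    log2 ratios over the significant set. Both a binomial and (when margins
    allow) a Yates chi-square P-value for the concordance counts are
    reported in ``extras``.
    """
    sig_set = pd.Index(sig_set)
    if len(sig_set) == 0:
        raise ValueError("empty significant gene set")
    shared = sig_set.intersection(expr_rep.index)
    dropped = len(sig_set) - len(shared)
    if dropped:
        log.info("replication_summary: %d gene(s) absent from replication data", dropped)
    group_of = design_rep.set_index("sample_id")["group"].reindex(expr_rep.columns)
    xt = expr_rep.loc[shared, (group_of == treatment).to_numpy()].mean(axis=1)
    xc = expr_rep.loc[shared, (group_of == control).to_numpy()].mean(axis=1)
    rep_ratio = np.exp2(xt - xc)

    ref_dir = np.sign(de_ref.log2_ratio(treatment).loc[shared])
    rep_dir = np.sign(np.log2(rep_ratio))
    res = direction_concordance(ref_dir, rep_dir)
    up = ref_dir > 0
    down = ref_dir < 0
    res.mean_ratio_up = float(rep_ratio[up].mean()) if up.any() else np.nan
    res.mean_ratio_down = float(rep_ratio[down].mean()) if down.any() else np.nan
    res.r, res.p_correlation = ratio_correlation(
        de_ref.table[f"ratio_{treatment}"], pd.Series(rep_ratio, index=shared), shared
    )
    n_conc = int(res.table.to_numpy()[:, 0].sum())
    n_tot = int(res.table.to_numpy().sum())
    res.extras["n_concordant"] = n_conc
    res.extras["p_binomial"] = float(stats.binomtest(n_conc, n_tot, 0.5).pvalue)
    res.extras["n_dropped"] = dropped
    return res


def top_k_overlap(gene_set, ranked, k: int = 100) -> int:
    """Size of the intersection of ``gene_set`` with the first ``k`` entries
    of a ranked gene list.

    ``ranked`` may be a sequence of gene IDs (already ordered) or a Series
    of scores indexed by gene ID, ranked ascending with ties broken by
    lexicographic gene ID (logged when ties straddle rank k).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if isinstance(ranked, pd.Series):
        df = ranked.rename("score").rename_axis("gene").reset_index()
        df = df.sort_values(["score", "gene"], kind="stable")
        if len(df) > k and df["score"].iloc[k - 1] == df["score"].iloc[k]:
            log.info("top_k_overlap: score ties at rank %d broken by gene ID", k)
        ids = df["gene"].tolist()
    else:
        ids = list(ranked)
    if len(ids) < k:
        raise ValueError(f"ranked list shorter than k={k}")
    return len(set(gene_set) & set(ids[:k]))
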
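"""Weighted gene co-expression network analysis (WGCNA-style).

The network is unsigned: gene-gene similarity is |Pearson correlation|
raised to a soft-threshold power beta (default 14), which suppresses weak
correlations and approximates scale-free topology without a hard cutoff.
Module detection runs on the topological overlap dissimilarity (1 - TOM)
with average-linkage hierarchical clustering and a fixed-height tree cut
subject to a minimum module size; modules are summarized by their
eigengene (first principal component of the standardized module
expression), merged when eigengenes are highly correlated, and related to
an external trait through eigengene-trait correlation, per-gene gene
significance (GS) and module membership (kME).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .concordance import correlation_pvalue

log = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "ModuleSet",
    "TraitAssociation",
    "select_variable_genes",
    "adjacency",
    "scale_free_fit",
    "topological_overlap",
    "cluster_and_cut",
    "module_eigengene",
    "merge_close_modules",
    "module_trait_association",
    "gene_trait_statistics",
    "build_network",
]

UNASSIGNED = "unassigned"

#: Cosmetic aliases for size-ranked module names, in the WGCNA color
#: tradition. Purely labels; M1 is always the largest module.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "lightgreen",
    "darkgrey", "royalblue",
)


class SmallModuleWarning(UserWarning):
    """Not enough genes for a requested module statistic."""


@dataclass
class GeneNetwork:
    """Soft-thresholded adjacency and topological overlap over a gene subset."""

    gene_ids: pd.Index
    beta: float
    adjacency: np.ndarray
    tom: np.ndarray

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.tom


@dataclass
class ModuleSet:
    """Module labels plus eigengene summaries.

    ``labels`` maps each gene to "M1", "M2", ... (size-ranked) or
    "unassigned"; ``eigengenes`` is modules x samples with unit-variance
    rows; ``var_explained`` is the fraction of standardized module variance
    captured by the eigengene.
    """

    labels: pd.Series
    min_module_size: int
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)
    var_explained: pd.Series = field(default_factory=pd.Series)
    merge_threshold: float = 0.8

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.eigengenes.index]

    def members(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    def sizes(self) -> pd.Series:
        counts = self.labels[self.labels != UNASSIGNED].value_counts()
        return counts.reindex(self.module_names).fillna(0).astype(int)

    def color_aliases(self) -> dict[str, str]:
        return {
            m: MODULE_COLORS[i] if i < len(MODULE_COLORS) else m
            for i, m in enumerate(self.module_names)
        }


@dataclass
class TraitAssociation:
    """Module- and gene-level trait statistics.

    ``module_table`` columns: n_genes, r_trait, p_trait, r_gsmm, p_gsmm.
    ``gene_table`` columns: module, gene_significance, module_membership.
    """

    module_table: pd.DataFrame
    gene_table: pd.DataFrame


def select_variable_genes(expr: pd.DataFrame, k: int = 4000) -> pd.Index:
    """The k genes with the largest sample variance, ties broken by gene ID
    order (stable and deterministic)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(expr):
        raise ValueError(f"k={k} exceeds number of genes ({len(expr)})")
    var = expr.var(axis=1, ddof=1)
    order = np.lexsort((expr.index.to_numpy(), -var.to_numpy()))
    return expr.index[order[:k]]


def adjacency(expr_subset: pd.DataFrame, beta: float = 14.0) -> np.ndarray:
    """Unsigned soft-threshold adjacency a(i,j) = |cor(x_i, x_j)|^beta with
    unit diagonal."""
    if expr_subset.shape[1] < 3:
        raise ValueError("adjacency needs at least 3 samples")
    sd = expr_subset.std(axis=1, ddof=1)
    const = sd[sd == 0]
    if len(const):
        raise ValueError(
            f"constant gene expression; cannot correlate: {list(const.index[:5])}"
        )
    cor = np.corrcoef(expr_subset.to_numpy(dtype=float))
    a = np.abs(np.clip(cor, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(
    expr_subset: pd.DataFrame, beta_grid, n_bins: int = 10
) -> pd.DataFrame:
    """Scale-free topology fit index across a grid of soft powers.

    For each beta, computes connectivities k_i = sum_{j != i} a(i, j), bins
    log10(k) into ``n_bins`` equal-occupancy bins, regresses log10
    frequency on log10 mean connectivity, and reports the regression R^2,
    the slope, and the conventional signed index -sign(slope) * R^2.
    Degenerate binning (all k equal) yields NaN and a flag.
    """
    beta_grid = list(beta_grid)
    if any(b <= 0 for b in beta_grid):
        raise ValueError("beta grid must be positive")
    rows = []
    for beta in beta_grid:
        a = adjacency(expr_subset, beta=beta)
        k = a.sum(axis=1) - 1.0
        rows.append({"beta": beta, **_fit_power_law(k, n_bins)})
    return pd.DataFrame(rows)


def _fit_power_law(k: np.ndarray, n_bins: int) -> dict:
    k = k[k > 0]
    if len(np.unique(np.round(k, 12))) < 3:
        return {"r_squared": np.nan, "slope": np.nan, "sft_index": np.nan,
                "degenerate": True}
    edges = np.quantile(k, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    mean_k, dens = [], []
    log_edges = np.log10(edges)
    for b in range(len(edges) - 1):
        sel = idx == b
        width = log_edges[b + 1] - log_edges[b]
        if sel.any() and width > 0:
            mean_k.append(k[sel].mean())
            # equal-occupancy bins carry their signal in the bin width:
            # regress the log *density* of log10(k), not the raw frequency
            dens.append(sel.mean() / width)
    if len(mean_k) < 3:
        return {"r_squared": np.nan, "slope": np.nan, "sft_index": np.nan,
                "degenerate": True}
    lx, ly = np.log10(mean_k), np.log10(dens)
    slope, intercept, r, _, _ = stats.linregress(lx, ly)
    return {
        "r_squared": float(r**2),
        "slope": float(slope),
        "sft_index": float(-np.sign(slope) * r**2),
        "degenerate": False,
    }


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    tom(i,j) = (l(i,j) + a(i,j)) / (min(k_i, k_j) + 1 - a(i,j)) for i != j,
    with l(i,j) = sum_{u != i,j} a(i,u) a(u,j) and k_i = sum_{u != i}
    a(i,u); tom(i,i) = 1. Genes sharing many strong neighbours overlap even
    when their direct adjacency is modest.
    """
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    a = adj.copy()
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    # (A @ A)[i, j] counts u = i and u = j, each contributing a(i, j).
    l_mat = a @ a - 2.0 * a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l_mat + a) / denom
    tom[denom == 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    return tom


def _tom_linkage(dissim: np.ndarray) -> np.ndarray:
    d = np.asarray(dissim, dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return linkage(squareform(d, checks=False), method="average")


def cluster_and_cut(
    dissim: np.ndarray,
    gene_ids: pd.Index,
    min_module_size: int = 30,
    cut_height_frac: float = 0.90,
) -> ModuleSet:
    """Average-linkage clustering of the TOM dissimilarity with a
    fixed-height cut.

    The dendrogram is cut at ``cut_height_frac`` times the maximum merge
    height; branches with at least ``min_module_size`` leaves become
    modules named "M1", "M2", ... by decreasing size (ties broken by the
    smallest member gene ID), everything else is "unassigned".
    """
    if len(gene_ids) != len(dissim):
        raise ValueError("gene_ids length does not match dissimilarity")
    labels = pd.Series(UNASSIGNED, index=gene_ids, name="module", dtype=object)
    if len(gene_ids) < min_module_size:
        warnings.warn(
            f"fewer genes ({len(gene_ids)}) than min_module_size "
            f"({min_module_size}); all unassigned",
            SmallModuleWarning,
            stacklevel=2,
        )
        return ModuleSet(labels=labels, min_module_size=min_module_size)
    z = _tom_linkage(dissim)
    height = cut_height_frac * z[:, 2].max()
    raw = fcluster(z, t=height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    kept = [
        (int(cnt), str(min(gene_ids[raw == c])), c)
        for c, cnt in sizes.items()
        if cnt >= min_module_size
    ]
    kept.sort(key=lambda t: (-t[0], t[1]))
    for rank, (_, _, c) in enumerate(kept, start=1):
        labels.iloc[np.where(raw == c)[0]] = f"M{rank}"
    log.info(
        "cluster_and_cut: %d modules (sizes %s), %d unassigned",
        len(kept),
        [t[0] for t in kept],
        int((labels == UNASSIGNED).sum()),
    )
    return ModuleSet(labels=labels, min_module_size=min_module_size)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def module_eigengene(
    expr_subset: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First-principal-component eigengene per module.

    Genes are standardized to zero mean / unit variance across samples; the
    eigengene is the first right-singular vector of the module's
    standardized gene x sample matrix, scaled to unit variance, with its
    sign fixed so it correlates non-negatively with the module's mean
    standardized profile. ``var_explained`` is the first squared singular
    value over the total.
    """
    labels = labels.reindex(expr_subset.index).fillna(UNASSIGNED)
    modules = sorted(set(labels) - {UNASSIGNED}, key=_module_sort_key)
    eig = {}
    var_exp = {}
    for m in modules:
        xs = _standardize(expr_subset.loc[labels == m].to_numpy(dtype=float))
        _, s, vt = np.linalg.svd(xs, full_matrices=False)
        e = vt[0]
        mean_profile = xs.mean(axis=0)
        if mean_profile.std() > 0 and np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        sd = e.std(ddof=1)
        eig[m] = e / sd if sd > 0 else e
        var_exp[m] = float(s[0] ** 2 / (s**2).sum())
    eigengenes = pd.DataFrame(eig, index=expr_subset.columns).T
    eigengenes.index.name = "module"
    return eigengenes, pd.Series(var_exp, name="var_explained")


def _module_sort_key(name: str):
    return (0, int(name[1:])) if name.startswith("M") and name[1:].isdigit() else (1, name)


def merge_close_modules(
    expr_subset: pd.DataFrame,
    labels: pd.Series,
    threshold: float = 0.8,
    min_module_size: int = 30,
) -> ModuleSet:
    """Iteratively merge the module pair with the highest eigengene
    correlation strictly above ``threshold``, recomputing eigengenes after
    each merge, until no pair exceeds it.

    The merged module keeps the name of the larger partner (ties broken by
    name). Final modules are renamed "M1", "M2", ... by decreasing size.
    """
    labels = labels.copy()
    while True:
        eigengenes, var_exp = module_eigengene(expr_subset, labels)
        mods = list(eigengenes.index)
        if len(mods) < 2:
            break
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                r = float(np.corrcoef(eigengenes.loc[mods[i]], eigengenes.loc[mods[j]])[0, 1])
                if r > threshold and (best is None or r > best[0]):
                    best = (r, mods[i], mods[j])
        if best is None:
            break
        _, a, b = best
        na, nb = (labels == a).sum(), (labels == b).sum()
        keep, drop = (a, b) if na > nb or (na == nb and str(a) < str(b)) else (b, a)
        log.info("merge_close_modules: merging %s into %s (r=%.3f)", drop, keep, best[0])
        labels[labels == drop] = keep
    # Rename by final size rank for deterministic output.
    sizes = labels[labels != UNASSIGNED].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], str(m)))
    rename = {old: f"M{i + 1}" for i, old in enumerate(order)}
    labels = labels.map(lambda m: rename.get(m, UNASSIGNED))
    eigengenes, var_exp = module_eigengene(expr_subset, labels)
    return ModuleSet(
        labels=labels,
        min_module_size=min_module_size,
        eigengenes=eigengenes,
        var_explained=var_exp,
        merge_threshold=threshold,
    )


def module_trait_association(
    eigengenes: pd.DataFrame, trait: pd.Series
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a numeric trait,
    with the Student-t correlation P-value (n = number of samples)."""
    t = trait.reindex(eigengenes.columns).to_numpy(dtype=float)
    if np.isnan(t).any():
        raise ValueError("trait missing for some samples")
    if t.std() == 0:
        raise ValueError("trait is constant across samples")
    rows = {}
    for m in eigengenes.index:
        r = float(np.corrcoef(eigengenes.loc[m].to_numpy(dtype=float), t)[0, 1])
        r = min(max(r, -1.0), 1.0)
        rows[m] = {"r_trait": r, "p_trait": correlation_pvalue(r, len(t))}
    out = pd.DataFrame(rows).T
    out.index.name = "module"
    return out


def gene_trait_statistics(
    expr_subset: pd.DataFrame,
    labels: pd.Series,
    eigengenes: pd.DataFrame,
    trait: pd.Series,
) -> TraitAssociation:
    """Gene significance, module membership, and their per-module coupling.

    GS(i) = cor(x_i, trait); MM(i) = cor(x_i, eigengene of gene i's module)
    (NaN for unassigned genes). Per module, r_gsmm = cor(|GS|, |MM|) over
    members, with its correlation P-value; modules with fewer than 3
    members get NaN and a warning.
    """
    labels = labels.reindex(expr_subset.index).fillna(UNASSIGNED)
    t = trait.reindex(expr_subset.columns).to_numpy(dtype=float)
    if t.std() == 0:
        raise ValueError("trait is constant across samples")
    x = expr_subset.to_numpy(dtype=float)
    xs = _standardize(x)
    zt = (t - t.mean()) / t.std()
    n = len(t)
    gs = np.clip((xs @ zt) / (np.linalg.norm(xs, axis=1) * np.linalg.norm(zt)), -1, 1)
    mm = np.full(len(x), np.nan)
    for m in eigengenes.index:
        e = eigengenes.loc[m].to_numpy(dtype=float)
        ez = (e - e.mean()) / np.linalg.norm(e - e.mean())
        sel = (labels == m).to_numpy()
        if sel.any():
            xm = xs[sel]
            mm[sel] = np.clip(
                (xm @ ez) / np.linalg.norm(xm, axis=1), -1, 1
            )
    gene_table = pd.DataFrame(
        {"module": labels, "gene_significance": gs, "module_membership": mm},
        index=expr_subset.index,
    )
    rows = {}
    trait_r = module_trait_association(eigengenes, trait)
    for m in eigengenes.index:
        members = gene_table[gene_table["module"] == m]
        row = {
            "n_genes": len(members),
            "r_trait": trait_r.loc[m, "r_trait"],
            "p_trait": trait_r.loc[m, "p_trait"],
        }
        if len(members) < 3:
            warnings.warn(
                f"module {m} has fewer than 3 genes; GS-MM correlation undefined",
                SmallModuleWarning,
                stacklevel=2,
            )
            row.update({"r_gsmm": np.nan, "p_gsmm": np.nan})
        else:
            ags = members["gene_significance"].abs().to_numpy()
            amm = members["module_membership"].abs().to_numpy()
            if ags.std() == 0 or amm.std() == 0:
                row.update({"r_gsmm": np.nan, "p_gsmm": np.nan})
            else:
                r = float(np.corrcoef(ags, amm)[0, 1])
                r = min(max(r, -1.0), 1.0)
                row.update({"r_gsmm": r, "p_gsmm": correlation_pvalue(r, len(members))})
        rows[m] = row
    module_table = pd.DataFrame(rows).T
    module_table.index.name = "module"
    module_table["n_genes"] = module_table["n_genes"].astype(int)
    return TraitAssociation(module_table=module_table, gene_table=gene_table)


def build_network(
    expr: pd.DataFrame,
    top_k: int = 4000,
    beta: float = 14.0,
) -> tuple[GeneNetwork, pd.DataFrame]:
    """Variable-gene selection plus adjacency and TOM in one call.

    ``top_k`` is clamped to the number of available genes. Returns the
    network and the expression submatrix over the selected genes.
    """
    k = min(top_k, len(expr))
    if k < top_k:
        log.info("build_network: only %d genes available; selecting all", k)
    genes = select_variable_genes(expr, k)
    sub = expr.loc[genes]
    adj = adjacency(sub, beta=beta)
    tom = topological_overlap(adj)
    return GeneNetwork(gene_ids=genes, beta=beta, adjacency=adj, tom=tom), sub
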
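"""Spatially biased transcriptome analysis.

The core procedure: cells carry a region label from photoactivated tagging
(e.g. tumor border vs whole tumor); genes upregulated in the tagged region
define a per-cell *region score* — the plain sum of their log-normalized
expression. Ranking cells by this score recovers a latent spatial axis, and
correlating every gene with the score (significance by permutation of the
score across cells) identifies smooth, opposing expression gradients along
that axis.

Supporting operations: log-normalization, variable-gene selection,
expression-bin-matched module scoring (and cell-cycle phase calls built on
it), cell-type composition tests, complete-linkage cell-type dendrograms
over Spearman correlation, and a binomial power calculation for detecting
rare populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .containers import CountMatrix, ExpressionMatrix
from .destats import adjust_pvalues
from .flow import fisher_exact

__all__ = [
    "lognormalize",
    "select_variable_genes",
    "region_score",
    "correlate_with_score",
    "permutation_test",
    "select_correlated_genes",
    "score_and_correlate",
    "ScoreResult",
    "ModuleScoreConfig",
    "module_score",
    "cell_cycle_phase",
    "composition_tests",
    "cluster_cell_types",
    "dendrogram_to_newick",
    "rare_cell_power",
]


def lognormalize(counts: CountMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """Log-normalize counts: e = ln(1 + scale * x / T_cell).

    T_cell is the cell's total UMI count; zero counts stay exactly zero.
    Cells with zero totals are an error (they cannot be normalized).
    """
    totals = counts.cell_totals()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total counts cannot be normalized: "
            f"{list(counts.cells[zero[:5]])}"
        )
    x = counts.matrix.tocsc().astype(float)
    for j in range(x.shape[1]):  # scale column data in place
        sl = slice(x.indptr[j], x.indptr[j + 1])
        x.data[sl] = np.log1p(scale * x.data[sl] / totals[j])
    return ExpressionMatrix(x.tocsr(), counts.genes, counts.cells,
                            scale=scale, cell_totals=totals)


def select_variable_genes(expr: ExpressionMatrix,
                          min_mean: float = 0.1) -> list:
    """Genes with mean log-normalized expression strictly above min_mean,
    ranked by dispersion (variance / mean) descending."""
    X = expr.matrix
    means = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = np.maximum(sq - means ** 2, 0.0)
    keep = means > min_mean
    if not keep.any():
        warnings.warn("no gene passes the variable-gene mean threshold")
        return []
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(means > 0, var / means, 0.0)
    idx = np.flatnonzero(keep)
    order = idx[np.argsort(-dispersion[idx], kind="stable")]
    return list(expr.genes[order])


def _resolve_gene_set(expr: ExpressionMatrix, gene_set) -> np.ndarray:
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    known = set(expr.genes)
    missing = [g for g in gene_set if g not in known]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) not in the matrix were "
                      f"dropped: {missing[:5]}")
    present = [g for g in gene_set if g in known]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    return expr.gene_index(present)


def region_score(expr: ExpressionMatrix, gene_set,
                 standardize: bool = False) -> pd.Series:
    """Per-cell region score: the sum of the set's log-normalized expression.

    ``standardize=True`` z-scores each gene across cells before summing
    (opt-in variant; the default is the plain unweighted sum).
    """
    rows = _resolve_gene_set(expr, gene_set)
    sub = expr.matrix[rows]
    if standardize:
        dense = np.asarray(sub.todense())
        sd = dense.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        dense = (dense - dense.mean(axis=1, keepdims=True)) / sd
        scores = dense.sum(axis=0)
    else:
        scores = np.asarray(sub.sum(axis=0)).ravel()
    return pd.Series(scores, index=expr.cells, name="region_score")


def _standardize_rows(X: np.ndarray):
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    flagged = (sd.ravel() == 0)
    sd[sd == 0] = 1.0
    return (X - mean) / sd, flagged


def correlate_with_score(expr: ExpressionMatrix, score) -> pd.DataFrame:
    """Pearson correlation of every gene with the per-cell score.

    Genes with zero variance get r = 0 and ``zero_variance = True``; a
    constant score is an error.
    """
    s = np.asarray(score, dtype=float)
    if expr.n_cells < 3:
        raise ValueError("need at least 3 cells")
    if s.shape != (expr.n_cells,) or not np.all(np.isfinite(s)):
        raise ValueError("score must be one finite value per cell")
    if s.std() == 0:
        raise ValueError("score is constant across cells")
    X = expr.to_dense()
    Z, flagged = _standardize_rows(X)
    z_s = (s - s.mean()) / s.std()
    r = Z @ z_s / expr.n_cells
    r[flagged] = 0.0
    return pd.DataFrame({"r": np.clip(r, -1.0, 1.0),
                         "zero_variance": flagged},
                        index=pd.Index(expr.genes, name="gene"))


def permutation_test(expr: ExpressionMatrix, score, n_perm: int = 999,
                     seed: int = 0) -> pd.DataFrame:
    """Permutation null for gene-score Pearson correlations.

    The score vector is shuffled across cells ``n_perm`` times and every
    gene's correlation recomputed; the two-sided p-value per gene is
    (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1), so the smallest attainable
    p is 1 / (n_perm + 1). Returns a DataFrame with r, p and flags.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for usable resolution")
    obs = correlate_with_score(expr, score)
    s = np.asarray(score, dtype=float)
    rng = np.random.default_rng(seed)
    X = expr.to_dense()
    Z, flagged = _standardize_rows(X)
    z_s = (s - s.mean()) / s.std()
    perms = np.empty((expr.n_cells, n_perm))
    for j in range(n_perm):
        perms[:, j] = rng.permutation(z_s)
    r_perm = np.abs(Z @ perms / expr.n_cells)      # genes x perms
    r_obs = np.abs(obs["r"].to_numpy())
    exceed = (r_perm >= (r_obs[:, None] - 1e-12)).sum(axis=1)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[flagged] = 1.0
    out = obs.copy()
    out["p"] = p
    out.attrs["n_permutations"] = n_perm
    out.attrs["seed"] = seed
    return out


def select_correlated_genes(result: pd.DataFrame, alpha: float = 0.05):
    """Split significant genes by correlation sign.

    ``result`` needs columns r and p (as returned by
    :func:`permutation_test`). Returns ``(negative_genes, positive_genes)``.
    """
    sig = result["p"] < alpha
    negative = list(result.index[sig & (result["r"] < 0)])
    positive = list(result.index[sig & (result["r"] > 0)])
    return negative, positive


@dataclass
class ScoreResult:
    """Region score plus gene-score correlation results."""

    score: pd.Series
    gene_set: list
    correlations: pd.DataFrame  # columns r, p, zero_variance
    n_permutations: int
    seed: int

    def ranked_cells(self) -> pd.Series:
        return self.score.sort_values(ascending=False)


def score_and_correlate(expr: ExpressionMatrix, gene_set,
                        n_perm: int = 999, seed: int = 0) -> ScoreResult:
    """Region score + permutation-tested gene-score correlations."""
    score = region_score(expr, gene_set)
    corr = permutation_test(expr, score.to_numpy(), n_perm=n_perm, seed=seed)
    return ScoreResult(score=score, gene_set=list(gene_set),
                       correlations=corr, n_permutations=n_perm, seed=seed)


@dataclass
class ModuleScoreConfig:
    """Expression-bin-matched control settings for module scoring."""

    n_bins: int = 24
    ctrl_genes_per_bin: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 1 or self.ctrl_genes_per_bin < 1:
            raise ValueError("n_bins and ctrl_genes_per_bin must be positive")


def module_score(expr: ExpressionMatrix, gene_set,
                 cfg: ModuleScoreConfig | None = None) -> pd.Series:
    """Gene-module score with expression-matched controls.

    Per cell: mean log-normalized expression over the gene set minus the
    mean over control genes. Genes are binned into ``n_bins`` bins of
    average expression; for each member gene, ``ctrl_genes_per_bin``
    controls are sampled (seeded, without replacement) from its bin,
    excluding the set itself.
    """
    cfg = cfg or ModuleScoreConfig()
    rows = _resolve_gene_set(expr, gene_set)
    if len(rows) >= expr.n_genes:
        raise ValueError("gene set covers the whole matrix; no control pool")
    rng = np.random.default_rng(cfg.seed)
    means = expr.gene_means()
    n_bins = min(cfg.n_bins, expr.n_genes)
    bins = pd.qcut(pd.Series(means).rank(method="first"), n_bins,
                   labels=False).to_numpy()
    in_set = np.zeros(expr.n_genes, dtype=bool)
    in_set[rows] = True
    ctrl_rows = []
    for g in rows:
        pool = np.flatnonzero((bins == bins[g]) & ~in_set)
        if pool.size == 0:
            raise ValueError("a module gene's expression bin has no "
                             "control candidates")
        take = min(cfg.ctrl_genes_per_bin, pool.size)
        ctrl_rows.append(rng.choice(pool, size=take, replace=False))
    ctrl_rows = np.concatenate(ctrl_rows)
    X = expr.matrix
    set_mean = np.asarray(X[rows].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(X[ctrl_rows].mean(axis=0)).ravel()
    return pd.Series(set_mean - ctrl_mean, index=expr.cells,
                     name="module_score")


def cell_cycle_phase(expr: ExpressionMatrix, s_genes, g2m_genes,
                     cfg: ModuleScoreConfig | None = None) -> pd.DataFrame:
    """Cell-cycle phase calls from S and G2/M module scores.

    A cell with both scores <= 0 is G0/1; otherwise the larger score wins.
    Returns a DataFrame with s_score, g2m_score and phase.
    """
    cfg = cfg or ModuleScoreConfig()
    known = set(expr.genes)
    if not (set(s_genes) & known) or not (set(g2m_genes) & known):
        raise ValueError("S and G2/M gene lists must each overlap the matrix")
    s_score = module_score(expr, [g for g in s_genes if g in known], cfg)
    g2m_cfg = ModuleScoreConfig(cfg.n_bins, cfg.ctrl_genes_per_bin,
                                cfg.seed + 1)
    g2m_score = module_score(expr, [g for g in g2m_genes if g in known],
                             g2m_cfg)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0), "G0/1",
        np.where(s_score > g2m_score, "S", "G2/M"),
    )
    return pd.DataFrame({"s_score": s_score, "g2m_score": g2m_score,
                         "phase": phase}, index=expr.cells)


def composition_tests(table: pd.DataFrame, mode: str = "fisher_per_type_bh",
                      pool_zero_margins: bool = False):
    """Cell-type composition tests across conditions.

    ``table`` is a cell-type x condition count table. Modes:

    * ``"fisher_per_type_bh"`` (2 conditions): per type, a 2x2 exact test
      of type-vs-rest against condition A-vs-B, BH-corrected across types.
      Returns a DataFrame with odds_ratio, p and p_adj.
    * ``"chisq_global"``: Pearson chi-square (no continuity correction) on
      the full table. Returns ``(statistic, p, dof)``. Zero-margin rows or
      columns make expected counts zero — warned about, and dropped when
      ``pool_zero_margins`` is set.
    """
    t = table.to_numpy(dtype=float)
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold non-negative integer counts")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 conditions")

    if mode == "fisher_per_type_bh":
        if table.shape[1] != 2:
            raise ValueError("fisher_per_type_bh requires exactly 2 conditions")
        col_tot = t.sum(axis=0)
        rows = []
        for i, cell_type in enumerate(table.index):
            a, b = t[i]
            sub = [[a, b], [col_tot[0] - a, col_tot[1] - b]]
            odds, p = fisher_exact(sub)
            rows.append((cell_type, odds, p))
        out = pd.DataFrame(rows, columns=["cell_type", "odds_ratio", "p"]
                           ).set_index("cell_type")
        out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method="bh")
        return out

    if mode == "chisq_global":
        work = table.copy()
        zero_rows = work.sum(axis=1) == 0
        zero_cols = work.sum(axis=0) == 0
        if zero_rows.any() or zero_cols.any():
            warnings.warn("zero-margin categories give zero expected counts")
            if pool_zero_margins:
                work = work.loc[~zero_rows, ~zero_cols]
        stat, p, dof, _ = stats.chi2_contingency(work.to_numpy(),
                                                 correction=False)
        return float(stat), float(p), int(dof)

    raise ValueError("mode must be 'fisher_per_type_bh' or 'chisq_global'")


def cluster_cell_types(expr: ExpressionMatrix, clusters, de_genes):
    """Complete-linkage dendrogram of cell types over Spearman correlation.

    Mean expression profiles per cluster are computed over ``de_genes``;
    the pairwise distance is 1 - Spearman rho; agglomeration is complete
    linkage. Returns ``(linkage_matrix, type_labels)``.
    """
    rows = _resolve_gene_set(expr, de_genes)
    clusters = np.asarray(clusters)
    labels = sorted(pd.unique(clusters), key=str)
    if len(labels) < 2:
        raise ValueError("need at least 2 cell types")
    profiles = np.column_stack([
        np.asarray(expr.matrix[rows][:, clusters == lbl].mean(axis=1)).ravel()
        for lbl in labels
    ])
    for j, lbl in enumerate(labels):
        if profiles[:, j].std() == 0:
            raise ValueError(f"cell type {lbl!r} has a zero-variance profile")
    rho = stats.spearmanr(profiles).statistic
    if np.isscalar(rho):  # spearmanr returns a scalar for 2 columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
    dist = np.clip(1.0 - rho, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    return z, [str(lbl) for lbl in labels]


def dendrogram_to_newick(linkage_matrix, labels) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch lengths."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage_matrix, labels)
    return str(tree).strip()


@dataclass
class RarePowerQuery:
    """Power query: frequency f, sample size n, minimum cells k."""

    f: float
    n: int
    k: int

    def __post_init__(self):
        if not 0 < self.f <= 1:
            raise ValueError("f must be in (0, 1]")
        if self.k < 0 or self.n < self.k:
            raise ValueError("need 0 <= k <= n")


def rare_cell_power(f: float, n: int, k: int) -> float:
    """Probability of sampling at least k cells of a population at
    frequency f among n cells: P(X >= k), X ~ Binomial(n, f)."""
    q = RarePowerQuery(f, n, k)
    if q.k == 0:
        return 1.0
    return float(stats.binom.sf(q.k - 1, q.n, q.f))
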
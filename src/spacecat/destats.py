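"""Differential-expression statistics for single-cell data.

The centrepiece is the bimodal likelihood-ratio test: log-normalized
single-cell expression of a gene is modeled as a mixture of a point mass at
zero (probability 1 - pi) and a Gaussian on the positive values
(mu, sigma^2). Detection fraction and positive-component moments have
closed-form MLEs, so the likelihood ratio between per-group and pooled fits
is cheap, and the statistic is referred to a chi-square null.

Also here: rank-sum DE with an exact small-sample path, Cohen's d,
multiple-testing correction and cell quality filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QCThresholds",
    "qc_filter",
    "bimod_lrt",
    "wilcoxon_de",
    "cohens_d",
    "adjust_pvalues",
    "find_markers",
]

VARIANCE_FLOOR = 1e-8
#: conventional minimum aligned reads per cell for full-length (Smart-Seq2)
#: libraries; UMI-based protocols filter on detected genes instead
SMARTSEQ2_MIN_READS = 100_000


@dataclass
class QCThresholds:
    """Cell quality thresholds.

    min_genes_per_cell: cells detecting fewer unique genes are removed
    (strictly-below rule: a cell at exactly the threshold is retained).
    min_reads_per_cell: total-count filter for read-based libraries; 0
    disables it (UMI default). variable_gene_min_mean: strict lower bound
    on mean log-normalized expression for variable-gene selection.
    """

    min_genes_per_cell: int = 200
    min_reads_per_cell: int = 0
    variable_gene_min_mean: float = 0.1

    def __post_init__(self):
        if min(self.min_genes_per_cell, self.min_reads_per_cell) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.variable_gene_min_mean < 0:
            raise ValueError("variable_gene_min_mean must be non-negative")


def qc_filter(counts, thresholds: QCThresholds | None = None):
    """Remove cells below quality thresholds.

    Returns ``(filtered CountMatrix, report DataFrame)`` where the report
    lists every input cell with its metrics, whether it was retained, and
    the reason for removal.
    """
    thresholds = thresholds or QCThresholds()
    genes_per_cell = counts.genes_per_cell()
    totals = counts.cell_totals()
    keep = genes_per_cell >= thresholds.min_genes_per_cell
    reasons = np.where(keep, "", f"<{thresholds.min_genes_per_cell} unique genes")
    if thresholds.min_reads_per_cell > 0:
        low_reads = totals < thresholds.min_reads_per_cell
        reasons = np.where(
            keep & low_reads,
            f"<{thresholds.min_reads_per_cell} total counts", reasons
        )
        keep &= ~low_reads
    report = pd.DataFrame(
        {
            "n_genes_detected": genes_per_cell,
            "total_counts": totals,
            "retained": keep,
            "reason": reasons,
        },
        index=pd.Index(counts.cells, name="cell"),
    )
    if not keep.any():
        warnings.warn("qc_filter removed every cell")
    return counts.subset_cells(keep), report


def _zero_inflated_loglik(x: np.ndarray, axis=-1):
    """Per-row MLE log-likelihood of the point-mass + Gaussian mixture.

    Returns (loglik, n_pos, positive-value sum of squares about the mean).
    """
    x = np.asarray(x, dtype=float)
    pos = x > 0
    n = x.shape[axis]
    n1 = pos.sum(axis=axis)
    n0 = n - n1
    s1 = np.where(pos, x, 0.0).sum(axis=axis)
    s2 = np.where(pos, x * x, 0.0).sum(axis=axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(n1 > 0, s1 / np.maximum(n1, 1), 0.0)
    ss = np.maximum(s2 - n1 * mu ** 2, 0.0)
    sigma2 = np.maximum(np.where(n1 > 0, ss / np.maximum(n1, 1), 0.0),
                        VARIANCE_FLOOR)
    ll = (xlogy(n0, np.where(n > 0, n0 / n, 1.0))
          + xlogy(n1, np.where(n > 0, n1 / n, 1.0))
          - 0.5 * n1 * np.log(2 * np.pi * sigma2)
          - ss / (2 * sigma2))
    return ll, n1, ss


def _bimod_lrt_arrays(x_a: np.ndarray, x_b: np.ndarray,
                      variance: str = "per_group"):
    """Vectorized bimodal LRT over rows of two matrices (genes x cells)."""
    x_a = np.atleast_2d(np.asarray(x_a, dtype=float))
    x_b = np.atleast_2d(np.asarray(x_b, dtype=float))
    pooled = np.concatenate([x_a, x_b], axis=1)
    ll_pool, _, _ = _zero_inflated_loglik(pooled)

    if variance == "per_group":
        ll_a, _, _ = _zero_inflated_loglik(x_a)
        ll_b, _, _ = _zero_inflated_loglik(x_b)
        ll_alt = ll_a + ll_b
        df = 3
    elif variance == "pooled":
        lla, n1a, ssa = _zero_inflated_loglik(x_a)
        llb, n1b, ssb = _zero_inflated_loglik(x_b)
        n1 = n1a + n1b
        sigma2 = np.maximum(
            np.where(n1 > 0, (ssa + ssb) / np.maximum(n1, 1), 0.0),
            VARIANCE_FLOOR,
        )
        ll_alt = np.zeros_like(lla)
        for x in (x_a, x_b):
            pos = x > 0
            n = x.shape[1]
            k1 = pos.sum(axis=1)
            k0 = n - k1
            s1 = np.where(pos, x, 0.0).sum(axis=1)
            s2 = np.where(pos, x * x, 0.0).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                mu = np.where(k1 > 0, s1 / np.maximum(k1, 1), 0.0)
            ss = np.maximum(s2 - k1 * mu ** 2, 0.0)
            ll_alt += (xlogy(k0, k0 / n) + xlogy(k1, k1 / n)
                       - 0.5 * k1 * np.log(2 * np.pi * sigma2)
                       - ss / (2 * sigma2))
        df = 2
    else:
        raise ValueError("variance must be 'per_group' or 'pooled'")

    lr = np.maximum(2.0 * (ll_alt - ll_pool), 0.0)
    # all-zero in both groups: no information, null by construction
    degenerate = ((x_a > 0).sum(axis=1) + (x_b > 0).sum(axis=1)) == 0
    lr = np.where(degenerate, 0.0, lr)
    p = stats.chi2.sf(lr, df)
    p = np.where(lr == 0.0, 1.0, p)
    return lr, p


def bimod_lrt(x_a, x_b, variance: str = "per_group"):
    """Bimodal likelihood-ratio test between two expression vectors.

    Each group is a point mass at zero plus a Gaussian on positives; the
    statistic is 2 (LL_a + LL_b - LL_pooled) against chi-square with df = 3
    (per-group pi, mu, sigma^2 — the default) or df = 2 when the positive
    variance is shared across groups (``variance="pooled"``).
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.size < 2 or x_b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    lr, p = _bimod_lrt_arrays(x_a[None, :], x_b[None, :], variance=variance)
    return float(lr[0]), float(p[0])


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _u_statistic(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    return ranks_a.sum() - n_a * (n_a + 1) / 2.0


def wilcoxon_de(x_a, x_b, exact_max_n: int = 12):
    """Two-sided Mann-Whitney / Wilcoxon rank-sum test.

    Uses exhaustive enumeration of group assignments (handling ties through
    midranks) when the combined sample size is <= ``exact_max_n``; otherwise
    the tie-corrected normal approximation. Returns ``(U_a, p)``.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    n_a, n_b = len(x_a), len(x_b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x_a, x_b])
    ranks = _midranks(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a, n_b)
    mean_u = n_a * n_b / 2.0

    if n_a + n_b <= exact_max_n:
        dev_obs = abs(u_obs - mean_u)
        count = 0
        total = comb(n_a + n_b, n_a)
        for idx in combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks[list(idx)], n_a, n_b)
            if abs(u - mean_u) >= dev_obs - 1e-12:
                count += 1
        return float(u_obs), count / total

    tie_term = 0.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n_a + n_b
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    var_u = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return float(u_obs), 1.0
    z = (u_obs - mean_u) / np.sqrt(var_u)
    return float(u_obs), float(2 * stats.norm.sf(abs(z)))


def cohens_d(x_a, x_b):
    """Cohen's d: mean difference over the pooled standard deviation.

    Pooling weights the group variances by (n - 1). A zero pooled SD gives
    signed infinity (0 when the means also agree), with a warning.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if len(x_a) < 2 or len(x_b) < 2:
        raise ValueError("each group needs at least 2 values")
    n_a, n_b = len(x_a), len(x_b)
    diff = x_a.mean() - x_b.mean()
    pooled_var = (((n_a - 1) * x_a.var(ddof=1) + (n_b - 1) * x_b.var(ddof=1))
                  / (n_a + n_b - 2))
    if pooled_var == 0:
        warnings.warn("zero pooled standard deviation in Cohen's d")
        if diff == 0:
            return 0.0
        return np.inf if diff > 0 else -np.inf
    return float(diff / np.sqrt(pooled_var))


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Multiple-testing correction, preserving input order.

    ``method`` is "bonferroni" (min(1, m p)) or "bh" (Benjamini-Hochberg
    step-up with enforced monotonicity).
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError("method must be 'bonferroni' or 'bh'")
    return multipletests(p, method=key)[1]


def find_markers(expr, clusters, test: str = "wilcoxon", alpha: float = 0.001,
                 min_genes_required: int = 25,
                 correction: str = "bonferroni") -> dict:
    """One-vs-rest differential expression per cluster.

    ``expr`` is an :class:`~spacecat.containers.ExpressionMatrix`;
    ``clusters`` a per-cell label vector. For each cluster, every gene is
    tested cluster-vs-rest with the chosen test ("wilcoxon" or "bimod"),
    p-values are corrected, and the log fold change (difference of mean
    log-normalized expression) gives direction. Returns a dict mapping
    cluster label to a result DataFrame; each frame's ``.attrs`` carries
    ``n_upregulated`` and a ``passes_min_genes`` flag (the convention that
    a well-supported cell type shows > ``min_genes_required`` significantly
    upregulated genes). Clusters with fewer than 2 cells are skipped with a
    warning.
    """
    clusters = np.asarray(clusters)
    labels = pd.unique(clusters)
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters")
    X = expr.to_dense()
    results = {}
    for lbl in labels:
        in_c = clusters == lbl
        if in_c.sum() < 2:
            warnings.warn(f"cluster {lbl!r} has fewer than 2 cells; skipped")
            continue
        xa, xb = X[:, in_c], X[:, ~in_c]
        if test == "bimod":
            stat, p = _bimod_lrt_arrays(xa, xb)
        elif test == "wilcoxon":
            res = stats.mannwhitneyu(xa, xb, axis=1, method="asymptotic",
                                     use_continuity=False)
            stat, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
            p = np.nan_to_num(p, nan=1.0)
        else:
            raise ValueError("test must be 'wilcoxon' or 'bimod'")
        lfc = xa.mean(axis=1) - xb.mean(axis=1)
        p_adj = adjust_pvalues(np.clip(p, 0, 1), method=correction)
        frame = pd.DataFrame(
            {
                "gene": expr.genes,
                "statistic": stat,
                "p": p,
                "p_adj": p_adj,
                "effect": lfc,
                "direction": np.where(lfc > 0, "up", "down"),
                "n_a": int(in_c.sum()),
                "n_b": int((~in_c).sum()),
            }
        ).sort_values("p_adj", kind="stable").reset_index(drop=True)
        n_up = int(((frame["p_adj"] < alpha) & (frame["effect"] > 0)).sum())
        frame.attrs["n_upregulated"] = n_up
        frame.attrs["passes_min_genes"] = n_up > min_genes_required
        results[lbl] = frame
    return results
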
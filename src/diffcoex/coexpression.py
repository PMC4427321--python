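"""Per-condition Spearman co-expression networks.

For each pair of genes the Spearman rank correlation r_ij and its
two-sided p-value are computed; p-values are Bonferroni-corrected over the
m(m-1)/2 tested pairs and thresholded at tau to give the sparse
co-expression matrix C (C_ij = r_ij if the adjusted p-value is below tau,
else 0).

P-values use the t-distribution approximation on the rank correlation,
t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom — standard for
n >= ~10 and safe at RNA-Seq cohort sizes.  Genes constant within a
condition have no defined rank correlation; they are retained in the
matrix (so gene indexing stays aligned across conditions) with r = 0 and
p = 1 for every pair they touch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoexpressionNetwork",
    "spearman_pair",
    "build_coexpression_network",
    "write_network_edges",
    "read_network_edges",
]


def spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman correlation of two sample vectors with its two-sided p-value.

    Ties are handled by average ranks.  A constant vector has no defined
    rank correlation: (nan, 1.0) is returned and treated as non-significant
    downstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), 1.0
    res = stats.spearmanr(x, y)
    r = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(p):  # |r| == 1 edge case
        p = 0.0 if abs(r) == 1.0 else 1.0
    return r, p


@dataclass
class CoexpressionNetwork:
    """Dense symmetric Spearman network for one condition of one study."""

    genes: list[str]
    r: np.ndarray        # (m, m), diagonal 1; 0 on degenerate pairs
    p_raw: np.ndarray    # (m, m) two-sided p-values, diagonal 0
    p_adj: np.ndarray    # Bonferroni over m(m-1)/2 pairs, capped at 1
    n_samples: int
    tau: float
    degenerate: np.ndarray  # (m,) bool, True for constant genes

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_tests(self) -> int:
        m = self.n_genes
        return m * (m - 1) // 2

    @property
    def C(self) -> np.ndarray:
        """Thresholded matrix: r where the adjusted p-value < tau, else 0."""
        mask = self.p_adj < self.tau
        np.fill_diagonal(mask, False)
        return np.where(mask, self.r, 0.0)


def _rank_correlation_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman correlation matrix of the rows of X, plus degeneracy mask."""
    ranks = stats.rankdata(X, axis=1)
    sd = ranks.std(axis=1)
    degenerate = sd == 0
    safe = ranks.copy()
    # stand-in unit-variance rows so corrcoef stays finite; overwritten below
    safe[degenerate] = np.arange(X.shape[1])
    r = np.corrcoef(safe)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0), degenerate


def build_coexpression_network(
    X: np.ndarray,
    tau: float,
    genes: list[str] | None = None,
) -> CoexpressionNetwork:
    """Build the Spearman co-expression network of a genes x samples matrix.

    All m(m-1)/2 pairs are computed; the Bonferroni family is the set of
    tested pairs for this condition.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if m < 2:
        raise ValueError("need at least 2 genes")
    if n < 4:
        raise ValueError("need at least 4 samples")
    if genes is None:
        genes = [f"g{i}" for i in range(m)]
    if len(genes) != m:
        raise ValueError("gene list length does not match matrix")

    r, degenerate = _rank_correlation_matrix(X)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p_raw = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p_raw[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p_raw, 0.0)
    p_raw[degenerate, :] = 1.0
    p_raw[:, degenerate] = 1.0

    n_tests = m * (m - 1) // 2
    p_adj = np.minimum(1.0, p_raw * n_tests)
    np.fill_diagonal(p_adj, 0.0)

    return CoexpressionNetwork(
        genes=list(genes),
        r=r,
        p_raw=p_raw,
        p_adj=p_adj,
        n_samples=n,
        tau=tau,
        degenerate=degenerate,
    )


def write_network_edges(net: CoexpressionNetwork, path: str | Path) -> None:
    """Write the upper triangle as a long-form edge list TSV."""
    iu, ju = np.triu_indices(net.n_genes, k=1)
    df = pd.DataFrame(
        {
            "gene_a": [net.genes[i] for i in iu],
            "gene_b": [net.genes[j] for j in ju],
            "r": net.r[iu, ju],
            "p_raw": net.p_raw[iu, ju],
            "p_adj": net.p_adj[iu, ju],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_network_edges(
    path: str | Path, n_samples: int, tau: float
) -> CoexpressionNetwork:
    """Rebuild a dense network from an edge-list TSV (inverse of the writer)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    genes: list[str] = []
    for g in pd.concat([df["gene_a"], df["gene_b"]]):
        if g not in genes:
            genes.append(g)
    idx = {g: i for i, g in enumerate(genes)}
    m = len(genes)
    r = np.eye(m)
    p_raw = np.zeros((m, m))
    p_adj = np.zeros((m, m))
    for row in df.itertuples(index=False):
        i, j = idx[row.gene_a], idx[row.gene_b]
        r[i, j] = r[j, i] = row.r
        p_raw[i, j] = p_raw[j, i] = row.p_raw
        p_adj[i, j] = p_adj[j, i] = row.p_adj
    degenerate = np.zeros(m, dtype=bool)
    return CoexpressionNetwork(genes, r, p_raw, p_adj, n_samples, tau, degenerate)
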
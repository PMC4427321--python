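"""Cross-study integration of differential co-expression networks.

Stages: (1) stack the per-study matrices D into a concatenated (k*m x m)
matrix whose columns — one per gene — hold that gene's differential
profile across all studies, and run PCA with genes as observations;
(2) count, per gene pair, in how many studies the pair is differentially
co-expressed and retain recurrent pairs; (3) compare the distribution of
the (ungated) delta_z statistic between pairs backed by a known binary
interaction and all other pairs; (4) quantify "noisier" co-expression of
a single gene pair by fitting a line per condition and comparing residual
variances with the Brown-Forsythe (median-centered Levene) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .differential import DifferentialNetwork
from .io import InteractionList

logger = logging.getLogger("diffcoex")

__all__ = [
    "ConcatenatedDC",
    "concat_and_pca",
    "PanCanRecurrence",
    "pancan_recurrence",
    "interaction_class_comparison",
    "residual_variance_test",
]


def _shared_universe(dnets: list[DifferentialNetwork]) -> list[str]:
    """Ordered intersection of the studies' gene lists."""
    shared = set(dnets[0].genes)
    for d in dnets[1:]:
        shared &= set(d.genes)
    if not shared:
        raise ValueError("gene-universe intersection across studies is empty")
    return [g for g in dnets[0].genes if g in shared]


def _reindexed_D(dnet: DifferentialNetwork, genes: list[str]) -> np.ndarray:
    order = [dnet.genes.index(g) for g in genes]
    return dnet.D[np.ix_(order, order)]


@dataclass
class ConcatenatedDC:
    """Stacked differential matrix with its PCA decomposition."""

    genes: list[str]
    study_names: list[str]
    D_C: np.ndarray               # (k*m, m), row blocks ordered by study
    variance_fractions: np.ndarray
    loadings: pd.DataFrame        # per-gene coordinates on the components


def concat_and_pca(
    dnets: list[DifferentialNetwork],
    n_components: int = 2,
    study_names: list[str] | None = None,
) -> ConcatenatedDC:
    """Stack the studies' D matrices and decompose with PCA.

    Columns of the stacked matrix are the observations (one per gene);
    they are mean-centered but not scaled before the decomposition.
    """
    if len(dnets) < 2:
        raise ValueError("need at least 2 studies")
    if study_names is None:
        study_names = [f"study{i}" for i in range(len(dnets))]
    genes = _shared_universe(dnets)
    blocks = [_reindexed_D(d, genes) for d in dnets]
    D_C = np.vstack(blocks)

    X = D_C.T  # genes as observations
    n_components = min(n_components, min(X.shape) - 1)
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    loadings = pd.DataFrame(
        coords,
        index=pd.Index(genes, name="gene"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return ConcatenatedDC(
        genes=genes,
        study_names=list(study_names),
        D_C=D_C,
        variance_fractions=pca.explained_variance_ratio_,
        loadings=loadings,
    )


@dataclass
class PanCanRecurrence:
    """Gene pairs differentially co-expressed in several studies."""

    pair_counts: pd.DataFrame     # gene_a, gene_b, n_studies, studies
    recurrent_pairs: list[tuple[str, str]]
    recurrent_genes: list[str]
    min_studies: int


def pancan_recurrence(
    dnets: list[DifferentialNetwork],
    min_studies: int = 3,
    study_names: list[str] | None = None,
) -> PanCanRecurrence:
    """Retain pairs differentially co-expressed in >= min_studies studies."""
    if len(dnets) < min_studies:
        raise ValueError("fewer studies supplied than min_studies")
    if study_names is None:
        study_names = [f"study{i}" for i in range(len(dnets))]
    genes = _shared_universe(dnets)
    m = len(genes)
    sig = np.zeros((len(dnets), m, m), dtype=bool)
    for k, d in enumerate(dnets):
        sig[k] = _reindexed_D(d, genes) != 0

    counts = sig.sum(axis=0)
    iu, ju = np.triu_indices(m, k=1)
    keep = counts[iu, ju] > 0
    rows = []
    for i, j in zip(iu[keep], ju[keep]):
        hit = [study_names[k] for k in range(len(dnets)) if sig[k, i, j]]
        rows.append(
            {
                "gene_a": genes[i],
                "gene_b": genes[j],
                "n_studies": len(hit),
                "studies": ",".join(hit),
            }
        )
    pair_counts = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "n_studies", "studies"]
    )
    rec = pair_counts[pair_counts["n_studies"] >= min_studies]
    recurrent_pairs = list(zip(rec["gene_a"], rec["gene_b"]))
    recurrent_genes = sorted({g for pair in recurrent_pairs for g in pair})
    return PanCanRecurrence(pair_counts, recurrent_pairs, recurrent_genes, min_studies)


def interaction_class_comparison(
    dnet: DifferentialNetwork, interactions: InteractionList
) -> pd.DataFrame:
    """Two-sample t-test of delta_z between interaction-backed pairs and the rest.

    Uses the ungated delta_z of all pairs.  Classes with fewer than 2
    member pairs are skipped with a warning.
    """
    m = dnet.n_genes
    idx = {g: i for i, g in enumerate(dnet.genes)}
    iu, ju = np.triu_indices(m, k=1)
    dz = dnet.delta_z[iu, ju]

    rows = []
    for itype, pairs in interactions.pairs.items():
        member = np.zeros((m, m), dtype=bool)
        for pair in pairs:
            a, b = tuple(pair)
            if a in idx and b in idx:
                member[idx[a], idx[b]] = member[idx[b], idx[a]] = True
        in_class = member[iu, ju]
        if in_class.sum() < 2 or (~in_class).sum() < 2:
            logger.warning("interaction class %r has <2 usable pairs; skipped", itype)
            continue
        res = stats.ttest_ind(dz[in_class], dz[~in_class], equal_var=False)
        rows.append(
            {
                "interaction_type": itype,
                "n_class": int(in_class.sum()),
                "n_other": int((~in_class).sum()),
                "mean_class": float(dz[in_class].mean()),
                "mean_other": float(dz[~in_class].mean()),
                "t_stat": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "interaction_type",
            "n_class",
            "n_other",
            "mean_class",
            "mean_other",
            "t_stat",
            "p_value",
        ],
    )


def residual_variance_test(
    pair_expr_T: tuple[np.ndarray, np.ndarray],
    pair_expr_N: tuple[np.ndarray, np.ndarray],
) -> tuple[float, float, float]:
    """Is the co-expression of one gene pair noisier in tumor?

    Fits an ordinary least-squares line y ~ x within each condition and
    compares the two residual sets with the median-centered
    (Brown-Forsythe) Levene test.  Returns (var_T, var_N, levene_p).
    """
    resids = []
    for x, y in (pair_expr_T, pair_expr_N):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 3 or x.size != y.size:
            raise ValueError("need >= 3 paired samples per condition")
        if np.ptp(x) == 0:
            raise ValueError("constant x: line fit is degenerate")
        slope, intercept = np.polyfit(x, y, 1)
        resids.append(y - (slope * x + intercept))
    var_T = float(np.var(resids[0], ddof=2))
    var_N = float(np.var(resids[1], ddof=2))
    levene_p = float(stats.levene(resids[0], resids[1], center="median").pvalue)
    return var_T, var_N, levene_p
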
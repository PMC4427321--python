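"""Gene-level and pathway-level aggregation of the differential network.

Per gene i:

* S0_i — the number of differentially co-expressed pairs (nonzero entries
  of row i of D);
* S_i  — a Fisher's-method style weighted count, -sum(ln p_hat_z) over
  gene i's differentially co-expressed pairs (the tests are not
  independent, so S is a ranking score, not a formal test statistic);
* S_cat_i / S_comp_i — how many of those pairs are known
  catalysis-precedes / in-complex-with interactions;
* gain_count_i — how many of those pairs are more strongly co-expressed
  (by |r|) in tumor than in normal;
* log2_ratio_i — log2 of (mean tumor + c)/(mean normal + c), a simple
  differential-expression effect size used to contrast DC with DE.

Per pathway: E = sum of member-gene S0, normalized by pathway size;
pathways with fewer than five member genes are excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DifferentialNetwork
from .io import ExpressionStudy, GeneSetCollection, InteractionList

logger = logging.getLogger("diffcoex")

__all__ = [
    "gene_scores",
    "annotate_interaction_scores",
    "tumor_gain_scores",
    "pathway_scores",
    "de_dc_comparison",
    "study_specific_hubs",
]

#: adjusted p-values of exactly 0 are floored here before the log
_P_FLOOR = np.finfo(float).tiny


def gene_scores(dnet: DifferentialNetwork) -> pd.DataFrame:
    """Per-gene S0 (pair count) and S (weighted sum of -ln adjusted p).

    The sum in S runs over the pairs that pass the full significance gate
    (the pairs counted by S0), using Bonferroni-adjusted p-values.
    """
    sig = dnet.D != 0
    S0 = sig.sum(axis=1)
    p = dnet.pz_adj.copy()
    if np.any((p == 0) & sig):
        logger.warning("adjusted p-values of 0 floored at %.3g before log", _P_FLOOR)
    p = np.maximum(p, _P_FLOOR)
    S = np.where(sig, -np.log(p), 0.0).sum(axis=1)
    return pd.DataFrame({"S0": S0.astype(int), "S": S}, index=pd.Index(dnet.genes, name="gene"))


def annotate_interaction_scores(
    dnet: DifferentialNetwork,
    interactions: InteractionList,
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Add S_cat and S_comp: differential pairs backed by known interactions."""
    if scores is None:
        scores = gene_scores(dnet)
    scores = scores.copy()
    idx = {g: i for i, g in enumerate(dnet.genes)}
    sig = dnet.D != 0
    for col, itype in (("S_cat", "catalysis_precedes"), ("S_comp", "in_complex_with")):
        counts = np.zeros(dnet.n_genes, dtype=int)
        n_missing = 0
        for pair in interactions.pairs[itype]:
            a, b = tuple(pair)
            if a not in idx or b not in idx:
                n_missing += 1
                continue
            i, j = idx[a], idx[b]
            if sig[i, j]:
                counts[i] += 1
                counts[j] += 1
        if n_missing:
            logger.info(
                "%d %s pairs involve genes absent from the network; ignored",
                n_missing,
                itype,
            )
        scores[col] = counts
    return scores


def tumor_gain_scores(
    dnet: DifferentialNetwork, scores: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Count, per gene, differential pairs with higher |r| in tumor."""
    if scores is None:
        scores = gene_scores(dnet)
    scores = scores.copy()
    gained = (dnet.D != 0) & (np.abs(dnet.net_T.r) > np.abs(dnet.net_N.r))
    scores["gain_count"] = gained.sum(axis=1).astype(int)
    return scores


def pathway_scores(
    scores: pd.DataFrame,
    pathways: GeneSetCollection,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Pathway score E = sum of member S0; normalized E_hat = E / n_genes.

    Pathway sets are intersected with the score table's gene universe and
    pathways with fewer than *min_genes* members after intersection are
    excluded.
    """
    restricted = pathways.restrict(scores.index)
    rows = []
    for name, members in restricted.sets.items():
        members = sorted(members)
        if len(members) < min_genes:
            continue
        E = int(scores.loc[members, "S0"].sum())
        rows.append({"pathway": name, "E": E, "n_genes": len(members), "E_hat": E / len(members)})
    return pd.DataFrame(rows, columns=["pathway", "E", "n_genes", "E_hat"]).set_index("pathway")


def de_dc_comparison(
    study: ExpressionStudy,
    scores: pd.DataFrame,
    sd_mult: float = 2.0,
    fc_cut: float = 0.2,
    pseudocount: float = 1.0,
    log2_ratio: pd.Series | None = None,
) -> tuple[float, list[str], pd.DataFrame]:
    """Contrast differential expression with differential co-expression.

    Returns (rho, dc_not_de, table): the Spearman correlation between
    |log2 ratio| and S0, the genes whose S0 exceeds the study mean by
    ``sd_mult`` standard deviations yet whose absolute log2 ratio is
    below ``fc_cut``, and the per-gene table.  An externally computed
    ``log2_ratio`` column (e.g. from a dedicated DE fit) may be supplied
    in place of the built-in ratio of condition means.
    """
    genes = list(scores.index)
    if log2_ratio is None:
        order = [study.genes.index(g) for g in genes]
        mean_T = study.tumor[order].mean(axis=1)
        mean_N = study.normal[order].mean(axis=1)
        log2_ratio = pd.Series(
            np.log2((mean_T + pseudocount) / (mean_N + pseudocount)), index=genes
        )
    else:
        log2_ratio = log2_ratio.reindex(genes)

    table = scores.copy()
    table["log2_ratio"] = log2_ratio

    S0 = table["S0"].to_numpy(dtype=float)
    abs_fc = np.abs(table["log2_ratio"].to_numpy())
    if np.ptp(S0) == 0 or np.ptp(abs_fc) == 0:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(abs_fc, S0).statistic)

    cut = S0.mean() + sd_mult * S0.std()
    dc_not_de = [
        g for g, s0, fc in zip(genes, S0, abs_fc) if s0 > cut and fc < fc_cut
    ]
    table["de_flag"] = abs_fc >= fc_cut
    return rho, dc_not_de, table


def study_specific_hubs(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    sd_mult: float = 2.0,
) -> tuple[list[str], list[str], list[str]]:
    """Split hub genes into study-specific and shared sets.

    A gene is A-specific when its S0 in study A exceeds the A mean by
    ``sd_mult`` standard deviations while its S0 in study B is exactly 0
    (and symmetrically for B); "shared" genes are above threshold in
    both.  Mean and SD include all genes (zeros included).
    """
    common = scores_a.index.intersection(scores_b.index)
    if len(common) == 0:
        raise ValueError("score tables share no genes")
    a = scores_a.loc[common, "S0"].to_numpy(dtype=float)
    b = scores_b.loc[common, "S0"].to_numpy(dtype=float)
    cut_a = a.mean() + sd_mult * a.std()
    cut_b = b.mean() + sd_mult * b.std()
    a_only = [g for g, x, y in zip(common, a, b) if x > cut_a and y == 0]
    b_only = [g for g, x, y in zip(common, a, b) if y > cut_b and x == 0]
    shared = [g for g, x, y in zip(common, a, b) if x > cut_a and y > cut_b]
    return a_only, b_only, shared
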
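"""Enrichment of differential co-expression among a regulator's targets.

For a motif with m target genes present in the network there are
t = m(m-1)/2 possible edges among the targets.  With e observed
differential co-expression edges in that sub-network and a background
edge probability p (the network-wide fraction of differentially
co-expressed pairs at the same threshold), the enrichment p-value is the
binomial upper tail P(X >= e), X ~ Binomial(t, p), Bonferroni-corrected
over the motifs tested.  Only highly significant edges are counted: the
default edge-calling threshold is 1e-10 on the adjusted change p-value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DifferentialNetwork
from .io import GeneSetCollection

logger = logging.getLogger("diffcoex")

__all__ = ["edge_density", "binomial_tail", "tf_enrichment"]


def _edge_mask(dnet: DifferentialNetwork, tau_edge: float) -> np.ndarray:
    """Pairs called differential at tau_edge (change test + condition gate)."""
    return dnet.gate(tau_z=tau_edge)


def edge_density(dnet: DifferentialNetwork, tau_edge: float) -> float:
    """Fraction of all gene pairs that are differential edges at tau_edge."""
    mask = _edge_mask(dnet, tau_edge)
    m = dnet.n_genes
    iu, ju = np.triu_indices(m, k=1)
    return float(mask[iu, ju].mean())


def binomial_tail(e: int, t: int, p: float) -> float:
    """P(X >= e) for X ~ Binomial(t, p), via the survival function."""
    if not 0 <= e <= t:
        raise ValueError("need 0 <= e <= t")
    if not 0.0 <= p <= 1.0:
        raise ValueError("need 0 <= p <= 1")
    if e == 0:
        return 1.0
    return float(stats.binom.sf(e - 1, t, p))


def tf_enrichment(
    dnet: DifferentialNetwork,
    motifs: GeneSetCollection,
    tau_edge: float = 1e-10,
) -> pd.DataFrame:
    """Binomial enrichment test for every motif's target sub-network.

    Motif target sets are intersected with the network's gene universe;
    motifs with fewer than 2 surviving targets are skipped.  Edges are
    counted among targets only.  The Bonferroni factor is the number of
    motifs actually tested.
    """
    restricted = motifs.restrict(dnet.genes)
    mask = _edge_mask(dnet, tau_edge)
    p_bg = edge_density(dnet, tau_edge)
    idx = {g: i for i, g in enumerate(dnet.genes)}

    rows = []
    for name, members in restricted.sets.items():
        ids = sorted(idx[g] for g in members)
        m = len(ids)
        if m < 2:
            logger.info("motif %r has %d target(s) in the universe; skipped", name, m)
            continue
        sub = mask[np.ix_(ids, ids)]
        t = m * (m - 1) // 2
        e = int(np.triu(sub, k=1).sum())
        rows.append(
            {
                "motif": name,
                "m": m,
                "t": t,
                "e": e,
                "p_background": p_bg,
                "p_value": binomial_tail(e, t, p_bg),
            }
        )
    df = pd.DataFrame(rows, columns=["motif", "m", "t", "e", "p_background", "p_value"])
    if len(df):
        df["p_adj"] = np.minimum(1.0, df["p_value"] * len(df))
        df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df.set_index("motif")
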
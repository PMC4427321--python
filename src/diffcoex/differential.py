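"""The differential co-expression statistic and its permutation null.

The sampling variance of a correlation coefficient depends on the
population value (Var(r) is proportional to (1-rho^2)^2), so raw
differences of correlations cannot be compared directly.  The Fisher
transform z = atanh(r) stabilizes the variance at approximately 1/(N-3),
after which the standardized difference

    delta_z = (z_T - z_N) / sqrt(1/(N_T-3) + 1/(N_N-3))

is approximately standard normal under the null of equal population
correlations, giving a two-sided Z-test per gene pair.  After Bonferroni
correction, a pair enters the differential matrix D only if (1) its
correlation change is significant and (2) the pair was significantly
correlated in at least one condition; the stored effect size is
delta_r = r_T - r_N.

A label-permutation null is also provided: condition labels are shuffled
over the pooled samples (preserving group sizes) and the per-pair maxima
of |delta_r| and |delta_z| over all permutations are recorded; a pair
"exceeds" the null when its real |delta_r| AND |delta_z| are both larger
than every permuted value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import CoexpressionNetwork, _rank_correlation_matrix
from .io import ExpressionStudy

logger = logging.getLogger("diffcoex")

__all__ = [
    "fisher_z",
    "delta_z_test",
    "DifferentialNetwork",
    "build_differential_network",
    "PermutationNull",
    "permutation_null",
    "write_differential_edges",
]

#: |r| is clamped to 1 - _CLAMP_EPS before the transform; degenerate
#: perfect correlations in toy data must not produce infinities.
_CLAMP_EPS = 1e-15


def fisher_z(r):
    """Fisher r-to-z transform, z = 0.5 * log((1+r)/(1-r)).

    Accepts scalars or arrays; |r| >= 1 - 1e-15 is clamped before the
    transform so the singularity at |r| = 1 is never reached.
    """
    r = np.clip(np.asarray(r, dtype=float), -(1.0 - _CLAMP_EPS), 1.0 - _CLAMP_EPS)
    out = np.arctanh(r)
    return out if out.ndim else float(out)


def delta_z_test(r_T, r_N, n_T: int, n_N: int):
    """Z-test for a difference of two correlation coefficients.

    Returns (delta_z, p_two_sided).  Inputs may be scalars or arrays of
    matching shape.  Requires n > 3 in both groups (Fisher variance
    1/(N-3) must be positive).
    """
    if n_T <= 3 or n_N <= 3:
        raise ValueError("both sample sizes must exceed 3")
    se = np.sqrt(1.0 / (n_T - 3) + 1.0 / (n_N - 3))
    dz = (fisher_z(r_T) - fisher_z(r_N)) / se
    p = 2.0 * stats.norm.sf(np.abs(dz))
    if np.ndim(dz) == 0:
        return float(dz), float(p)
    return dz, p


@dataclass
class DifferentialNetwork:
    """Matrix D of significant co-expression changes between conditions."""

    genes: list[str]
    delta_r: np.ndarray   # r_T - r_N, all pairs
    delta_z: np.ndarray   # standardized difference, all pairs
    pz_raw: np.ndarray    # two-sided normal p-values
    pz_adj: np.ndarray    # Bonferroni over m(m-1)/2 pairs
    D: np.ndarray         # gated: delta_r where significant, else 0
    tau: float
    net_T: CoexpressionNetwork
    net_N: CoexpressionNetwork

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gate(self, tau_z: float | None = None, tau_cond: float | None = None) -> np.ndarray:
        """Boolean mask of pairs passing the significance gate.

        A pair passes iff its adjusted change p-value is below ``tau_z``
        AND it was significantly correlated in tumor or normal at
        ``tau_cond``.  Both default to the network's tau.
        """
        if tau_z is None:
            tau_z = self.tau
        if tau_cond is None:
            tau_cond = self.tau
        mask = (self.pz_adj < tau_z) & (
            (self.net_T.p_adj < tau_cond) | (self.net_N.p_adj < tau_cond)
        )
        np.fill_diagonal(mask, False)
        return mask

    def nnz_pairs(self) -> int:
        """Number of differentially co-expressed pairs (upper triangle)."""
        return int(np.count_nonzero(np.triu(self.D, k=1)))


def build_differential_network(
    net_T: CoexpressionNetwork, net_N: CoexpressionNetwork, tau: float
) -> DifferentialNetwork:
    """Compare two per-condition networks pair by pair.

    Both networks must be on the identical gene list and ordering.  Pairs
    touching a gene that is degenerate (constant) in either condition are
    forced non-significant.
    """
    if net_T.genes != net_N.genes:
        raise ValueError("gene lists of the two networks differ")
    m = net_T.n_genes
    delta_r = net_T.r - net_N.r
    dz, pz = delta_z_test(net_T.r, net_N.r, net_T.n_samples, net_N.n_samples)

    bad = net_T.degenerate | net_N.degenerate
    pz[bad, :] = 1.0
    pz[:, bad] = 1.0
    np.fill_diagonal(pz, 1.0)

    n_tests = m * (m - 1) // 2
    pz_adj = np.minimum(1.0, pz * n_tests)

    dnet = DifferentialNetwork(
        genes=list(net_T.genes),
        delta_r=delta_r,
        delta_z=dz,
        pz_raw=pz,
        pz_adj=pz_adj,
        D=np.zeros((m, m)),
        tau=tau,
        net_T=net_T,
        net_N=net_N,
    )
    dnet.D = np.where(dnet.gate(), delta_r, 0.0)
    return dnet


def differential_network_from_study(
    study: ExpressionStudy, tau: float
) -> DifferentialNetwork:
    """Convenience: build both condition networks and compare them."""
    from .coexpression import build_coexpression_network

    net_T = build_coexpression_network(study.tumor, tau, study.genes)
    net_N = build_coexpression_network(study.normal, tau, study.genes)
    return build_differential_network(net_T, net_N, tau)


@dataclass
class PermutationNull:
    """Label-permutation null distribution for |delta_r| and |delta_z|."""

    n_perm: int
    max_abs_dr: np.ndarray   # (m, m) per-pair max over permutations
    max_abs_dz: np.ndarray
    exceeds: np.ndarray      # (m, m) bool: real exceeds both maxima

    @property
    def exceedance_fraction(self) -> float:
        m = self.exceeds.shape[0]
        iu, ju = np.triu_indices(m, k=1)
        return float(self.exceeds[iu, ju].mean())


def permutation_null(
    study: ExpressionStudy, n_perm: int, seed: int
) -> PermutationNull:
    """Shuffle condition labels and recompute delta_r / delta_z each time.

    Permutations reassign the pooled samples to groups of the original
    sizes; each permutation recomputes both Spearman matrices.  A pair's
    exceedance flag is set when the real |delta_r| and |delta_z| are both
    strictly larger than the corresponding maxima over all permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    logger.info("permutation null: n_perm=%d seed=%d", n_perm, seed)

    pooled = np.hstack([study.tumor, study.normal])
    n_T = study.n_tumor
    n_tot = pooled.shape[1]
    se = np.sqrt(1.0 / (n_T - 3) + 1.0 / (study.n_normal - 3))

    def _delta(mat: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        r_T, _ = _rank_correlation_matrix(mat[:, order[:n_T]])
        r_N, _ = _rank_correlation_matrix(mat[:, order[n_T:]])
        dr = r_T - r_N
        dz = (fisher_z(r_T) - fisher_z(r_N)) / se
        return np.abs(dr), np.abs(dz)

    real_dr, real_dz = _delta(pooled, np.arange(n_tot))

    max_dr = np.zeros_like(real_dr)
    max_dz = np.zeros_like(real_dz)
    for _ in range(n_perm):
        order = rng.permutation(n_tot)
        dr, dz = _delta(pooled, order)
        np.maximum(max_dr, dr, out=max_dr)
        np.maximum(max_dz, dz, out=max_dz)

    exceeds = (real_dr > max_dr) & (real_dz > max_dz)
    np.fill_diagonal(exceeds, False)
    return PermutationNull(n_perm, max_dr, max_dz, exceeds)


def write_differential_edges(dnet: DifferentialNetwork, path) -> None:
    """Write the central pipeline artifact: one row per gene pair."""
    iu, ju = np.triu_indices(dnet.n_genes, k=1)
    df = pd.DataFrame(
        {
            "gene_a": [dnet.genes[i] for i in iu],
            "gene_b": [dnet.genes[j] for j in ju],
            "r_T": dnet.net_T.r[iu, ju],
            "r_N": dnet.net_N.r[iu, ju],
            "delta_r": dnet.delta_r[iu, ju],
            "delta_z": dnet.delta_z[iu, ju],
            "pz_raw": dnet.pz_raw[iu, ju],
            "pz_adj": dnet.pz_adj[iu, ju],
            "D": dnet.D[iu, ju],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
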
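import numpy as np
import pytest

from diffcoex.coexpression import CoexpressionNetwork
from diffcoex.differential import build_differential_network
from diffcoex.io import ExpressionStudy
from diffcoex.synthetic import SyntheticScenario, generate_study


@pytest.fixture
def small_study() -> ExpressionStudy:
    """Deterministic 6-gene study with one decoupled and one null pair."""
    scn = SyntheticScenario(
        n_genes=6,
        n_tumor=60,
        n_normal=40,
        seed=42,
        decoupled_pairs=[(0, 1, 0.9)],
        null_pairs=[(2, 3, 0.5)],
    )
    study, _ = generate_study(scn)
    return study


def make_networks(r_T, r_N, p_T, p_N, n_T=200, n_N=100, tau=0.01):
    """Hand-built condition networks with prescribed adjusted p-values."""
    m = r_T.shape[0]
    genes = [f"g{i}" for i in range(m)]
    zeros = np.zeros(m, dtype=bool)

    def net(r, p_adj, n):
        return CoexpressionNetwork(
            genes=genes,
            r=r,
            p_raw=p_adj.copy(),
            p_adj=p_adj,
            n_samples=n,
            tau=tau,
            degenerate=zeros,
        )

    return net(r_T, p_T, n_T), net(r_N, p_N, n_N)


@pytest.fixture
def gate_dnet():
    """3-gene differential network exercising both halves of the gate.

    Pair (0,1): strong change, significant in normal -> should be in D.
    Pair (0,2): strong change but insignificant in both conditions.
    Pair (1,2): no change, significant in both conditions.
    """
    r_T = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.8], [0.0, 0.8, 1.0]])
    r_N = np.array([[1.0, 0.9, 0.7], [0.9, 1.0, 0.8], [0.7, 0.8, 1.0]])
    sig = 1e-6
    insig = 0.5
    p_T = np.array([[0.0, insig, insig], [insig, 0.0, sig], [insig, sig, 0.0]])
    p_N = np.array([[0.0, sig, 0.3], [sig, 0.0, sig], [0.3, sig, 0.0]])
    net_T, net_N = make_networks(r_T, r_N, p_T, p_N)
    return build_differential_network(net_T, net_N, tau=0.01)
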
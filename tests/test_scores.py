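"""Gene scores (S0, S, interaction counts, tumor-gain) and pathway scores."""

import numpy as np
import pandas as pd
import pytest

from diffcoex.differential import build_differential_network
from diffcoex.io import GeneSetCollection, InteractionList
from diffcoex.scores import (
    annotate_interaction_scores,
    de_dc_comparison,
    gene_scores,
    pathway_scores,
    study_specific_hubs,
    tumor_gain_scores,
)
from diffcoex.synthetic import SyntheticScenario, generate_study

from conftest import make_networks


def _hand_built_dnet():
    """4 genes; gene 0 in two significant pairs with p_adj 1e-2 and 1e-4."""
    m = 4
    r_T = np.eye(m)
    r_N = np.eye(m)
    # strong normal-only correlations for pairs (0,1) and (0,2)
    for i, j, rho in [(0, 1, 0.9), (0, 2, 0.8)]:
        r_N[i, j] = r_N[j, i] = rho
    sig = 1e-8
    p_T = np.full((m, m), 0.9)
    p_N = np.full((m, m), 0.9)
    np.fill_diagonal(p_T, 0.0)
    np.fill_diagonal(p_N, 0.0)
    for i, j in [(0, 1), (0, 2)]:
        p_N[i, j] = p_N[j, i] = sig
    dnet = build_differential_network(*make_networks(r_T, r_N, p_T, p_N), tau=0.01)
    # pin the adjusted change p-values to the worked example
    dnet.pz_adj[0, 1] = dnet.pz_adj[1, 0] = 1e-2 * (1 - 1e-12)
    dnet.pz_adj[0, 2] = dnet.pz_adj[2, 0] = 1e-4
    dnet.D = np.where(dnet.gate(), dnet.delta_r, 0.0)
    return dnet


class TestGeneScores:
    def test_weighted_sum_hand_example(self):
        dnet = _hand_built_dnet()
        tab = gene_scores(dnet)
        assert tab.loc["g0", "S0"] == 2
        # S = -(ln 1e-2 + ln 1e-4) = 6 ln 10
        assert tab.loc["g0", "S"] == pytest.approx(6 * np.log(10), rel=1e-9)
        assert tab.loc["g3", "S0"] == 0
        assert tab.loc["g3", "S"] == 0.0

    def test_zero_iff_empty_row(self):
        dnet = _hand_built_dnet()
        tab = gene_scores(dnet)
        assert ((tab["S"] == 0) == (tab["S0"] == 0)).all()
        assert (tab["S"] >= 0).all()

    def test_handshake_identity(self, small_study):
        from diffcoex.differential import differential_network_from_study

        dnet = differential_network_from_study(small_study, 0.01)
        tab = gene_scores(dnet)
        assert tab["S0"].sum() == 2 * dnet.nnz_pairs()


class TestInteractionScores:
    def test_partner_counting(self):
        dnet = _hand_built_dnet()  # D edges: (0,1), (0,2)
        inter = InteractionList()
        inter.add("g0", "g1", "in_complex_with")
        inter.add("g0", "g3", "in_complex_with")      # not a D edge
        inter.add("g0", "g2", "catalysis_precedes")
        inter.add("gX", "g0", "catalysis_precedes")   # absent gene, ignored
        tab = annotate_interaction_scores(dnet, inter)
        assert tab.loc["g0", "S_comp"] == 1
        assert tab.loc["g1", "S_comp"] == 1
        assert tab.loc["g0", "S_cat"] == 1
        assert tab.loc["g3", "S_comp"] == 0
        assert (tab["S_cat"] <= tab["S0"]).all()
        assert (tab["S_comp"] <= tab["S0"]).all()

    def test_no_interactions_all_zero(self):
        dnet = _hand_built_dnet()
        tab = annotate_interaction_scores(dnet, InteractionList())
        assert (tab["S_cat"] == 0).all()
        assert (tab["S_comp"] == 0).all()


class TestTumorGain:
    def test_loss_pairs_do_not_count(self):
        dnet = _hand_built_dnet()  # both D edges are losses (|r_T| < |r_N|)
        tab = tumor_gain_scores(dnet)
        assert (tab["gain_count"] == 0).all()

    def test_gained_pair_counts_both_members(self):
        m = 3
        r_T, r_N = np.eye(m), np.eye(m)
        r_T[0, 1] = r_T[1, 0] = 0.8
        r_N[0, 1] = r_N[1, 0] = 0.1
        sig, ins = 1e-8, 0.9
        p_T = np.full((m, m), ins)
        p_N = np.full((m, m), ins)
        p_T[0, 1] = p_T[1, 0] = sig
        dnet = build_differential_network(*make_networks(r_T, r_N, p_T, p_N), tau=0.01)
        assert dnet.D[0, 1] > 0
        tab = tumor_gain_scores(dnet)
        assert tab.loc["g0", "gain_count"] == 1
        assert tab.loc["g1", "gain_count"] == 1
        assert tab.loc["g2", "gain_count"] == 0

    def test_planted_gains_recovered(self):
        hits = 0
        reps = 30
        for rep in range(reps):
            scn = SyntheticScenario(
                n_genes=15,
                seed=7000 + rep,
                gained_pairs=[(0, 1, 0.85)],
            )
            study, _ = generate_study(scn)
            from diffcoex.differential import differential_network_from_study

            dnet = differential_network_from_study(study, 0.01)
            tab = tumor_gain_scores(dnet)
            top = tab["gain_count"].sort_values(ascending=False)
            hits += set(top.index[:2]) == {"g000", "g001"} and top.iloc[0] > 0
        assert hits >= int(0.9 * reps)


class TestPathwayScores:
    def _scores(self, s0_values):
        genes = [f"g{i}" for i in range(len(s0_values))]
        return pd.DataFrame(
            {"S0": s0_values, "S": np.zeros(len(s0_values))},
            index=pd.Index(genes, name="gene"),
        )

    def test_direct_sum_and_normalization(self):
        scores = self._scores([2, 0, 1, 0, 3])
        pw = GeneSetCollection({"p1": {"g0", "g1", "g2", "g3", "g4"}}, "pathway")
        tab = pathway_scores(scores, pw)
        assert tab.loc["p1", "E"] == 6
        assert tab.loc["p1", "E_hat"] == pytest.approx(1.2)

    def test_small_pathways_excluded(self):
        scores = self._scores([1, 1, 1, 1, 1])
        pw = GeneSetCollection({"small": {"g0", "g1", "g2", "g3"}}, "pathway")
        assert len(pathway_scores(scores, pw)) == 0

    def test_all_zero_scores(self):
        scores = self._scores([0] * 6)
        pw = GeneSetCollection({"p": {f"g{i}" for i in range(6)}}, "pathway")
        tab = pathway_scores(scores, pw)
        assert tab.loc["p", "E"] == 0
        assert tab.loc["p", "E_hat"] == 0.0

    def test_duplicate_members_do_not_inflate(self):
        # GMT dedup happens at parse time; sets are already unique, so E_hat
        # is invariant to how often a gene was listed upstream.
        scores = self._scores([2, 2, 2, 2, 2])
        pw = GeneSetCollection({"p": {"g0", "g1", "g2", "g3", "g4"}}, "pathway")
        tab = pathway_scores(scores, pw)
        assert tab.loc["p", "E_hat"] == pytest.approx(2.0)


class TestDeDcComparison:
    def test_flat_expression_gives_zero_ratio(self):
        scn = SyntheticScenario(n_genes=8, n_tumor=40, n_normal=40, seed=3)
        study, _ = generate_study(scn)
        study.normal = study.tumor.copy()  # identical condition means
        from diffcoex.differential import differential_network_from_study

        dnet = differential_network_from_study(study, 0.01)
        tab = gene_scores(dnet)
        tab.loc["g000", "S0"] = 50  # force one extreme hub
        rho, dc_not_de, table = de_dc_comparison(study, tab)
        assert np.allclose(table["log2_ratio"], 0.0)
        assert "g000" in dc_not_de

    def test_infinite_threshold_empty(self, small_study):
        from diffcoex.differential import differential_network_from_study

        dnet = differential_network_from_study(small_study, 0.01)
        tab = gene_scores(dnet)
        _, dc_not_de, _ = de_dc_comparison(small_study, tab, sd_mult=np.inf)
        assert dc_not_de == []

    def test_planted_dc_not_de_recovered(self):
        """Genes rewired between conditions but with identical margins land
        in the DC-not-DE list.  A large cohort keeps the mean-ratio noise
        well below the 0.2 fold-change cut."""
        hits = 0
        reps = 25
        planted = {"g000", "g001", "g002", "g003"}
        for rep in range(reps):
            scn = SyntheticScenario(
                n_genes=30,
                n_tumor=800,
                n_normal=400,
                seed=8000 + rep,
                dc_not_de_genes=[0, 1, 2, 3],
                dc_not_de_rho=0.9,
            )
            study, gt = generate_study(scn)
            from diffcoex.differential import differential_network_from_study

            dnet = differential_network_from_study(study, 0.01)
            tab = gene_scores(dnet)
            _, dc_not_de, _ = de_dc_comparison(study, tab)
            hits += planted <= set(dc_not_de)
        assert hits >= int(0.9 * reps)


class TestStudySpecificHubs:
    def _table(self, s0):
        return pd.DataFrame(
            {"S0": s0}, index=pd.Index([f"g{i}" for i in range(len(s0))], name="gene")
        )

    def test_rule_application(self):
        a = self._table([50, 2, 2, 2, 2, 2, 0, 8])
        b = self._table([0, 2, 2, 2, 2, 2, 30, 8])
        a_only, b_only, shared = study_specific_hubs(a, b, sd_mult=2)
        assert a_only == ["g0"]
        assert b_only == ["g6"]
        assert "g7" not in a_only and "g7" not in b_only

    def test_nonzero_other_study_excluded(self):
        a = self._table([50, 2, 2, 2, 2, 2])
        b = self._table([1, 2, 2, 2, 2, 2])  # S0=1, not 0, in the other study
        a_only, _, _ = study_specific_hubs(a, b, sd_mult=2)
        assert a_only == []

    def test_disjoint_universes_error(self):
        a = self._table([1, 2])
        b = pd.DataFrame({"S0": [1]}, index=pd.Index(["x9"], name="gene"))
        with pytest.raises(ValueError):
            study_specific_hubs(a, b)
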
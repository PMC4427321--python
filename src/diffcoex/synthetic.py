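"""Synthetic paired tumor/normal expression data with planted structure.

The generator uses a Gaussian copula: latent multivariate-normal variables
carry a block correlation structure that differs between conditions, and a
strictly increasing map to a non-negative scale (exponential by default)
produces skewed, RSEM-like values.  Because Spearman statistics depend
only on ranks, the monotone map preserves the planted rank-correlation
structure exactly; a latent (Pearson) correlation rho corresponds to a
Spearman correlation of (6/pi) * arcsin(rho/2).

Plantable elements: null pairs (equal correlation in both conditions),
decoupled pairs (correlated in normal only), gained pairs (correlated in
tumor only), a hub gene losing a one-factor module of partners, TF-motif
target modules (equicorrelated in normal only), differentially expressed
genes (tumor mean shift, structure preserved), and genes differentially
co-expressed without being differentially expressed (structure rewired,
margins identical).  Default sample sizes mirror the smallest cohort in
the published manifest (103 tumor / 49 normal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .io import ExpressionStudy, GeneSetCollection

__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "latent_to_spearman",
    "generate_study",
    "generate_pancan",
    "decoupled_recovery_scenario",
    "regulon_scenario",
    "pancan_scenarios",
]


def latent_to_spearman(rho: float) -> float:
    """Spearman correlation implied by a latent Gaussian correlation."""
    return float(6.0 / np.pi * np.arcsin(rho / 2.0))


@dataclass
class SyntheticScenario:
    """Recipe for one paired tumor/normal dataset with known structure.

    Planted elements must use disjoint gene indices; every unplanted gene
    is independent of all others in both conditions.
    """

    n_genes: int
    n_tumor: int = 103
    n_normal: int = 49
    seed: int = 0
    null_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    decoupled_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    gained_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    hub: tuple[int, list[int], float] | None = None
    tf_modules: dict[str, tuple[list[int], float]] = field(default_factory=dict)
    de_genes: dict[int, float] = field(default_factory=dict)  # gene -> log2 shift
    dc_not_de_genes: list[int] = field(default_factory=list)
    dc_not_de_rho: float = 0.8
    noise_sd: float = 0.0
    value_transform: Callable[[np.ndarray], np.ndarray] = np.exp
    study_name: str = "synthetic"

    def _blocks(self) -> list[tuple[str, list[int]]]:
        blocks: list[tuple[str, list[int]]] = []
        for i, j, rho in self.null_pairs:
            blocks.append((f"null_pair({i},{j},rho={rho})", [i, j]))
        for i, j, rho in self.decoupled_pairs:
            blocks.append((f"decoupled_pair({i},{j},rho={rho})", [i, j]))
        for i, j, rho in self.gained_pairs:
            blocks.append((f"gained_pair({i},{j},rho={rho})", [i, j]))
        if self.hub is not None:
            h, partners, rho = self.hub
            blocks.append((f"hub({h},rho={rho})", [h, *partners]))
        for name, (targets, rho) in self.tf_modules.items():
            blocks.append((f"tf_module({name},rho={rho})", list(targets)))
        if self.dc_not_de_genes:
            blocks.append(("dc_not_de_block", list(self.dc_not_de_genes)))
        return blocks

    def validate(self) -> None:
        used: set[int] = set()
        for name, idxs in self._blocks():
            if any(not 0 <= i < self.n_genes for i in idxs):
                raise ValueError(f"{name}: gene index out of range")
            if len(set(idxs)) != len(idxs) or used & set(idxs):
                raise ValueError(f"{name}: planted gene sets must be disjoint")
            used |= set(idxs)
        for group in (self.null_pairs, self.decoupled_pairs, self.gained_pairs):
            for i, j, rho in group:
                if not -1.0 < rho < 1.0:
                    raise ValueError(f"pair ({i},{j}): rho={rho} outside (-1, 1)")
        for name, (targets, rho) in self.tf_modules.items():
            k = len(targets)
            if k >= 2 and rho <= -1.0 / (k - 1):
                raise ValueError(
                    f"tf_module({name}): equicorrelation {rho} with {k} targets "
                    "is not positive definite"
                )
        if self.hub is not None and not -1.0 < self.hub[2] < 1.0:
            raise ValueError("hub: rho outside (-1, 1)")


@dataclass
class GroundTruth:
    """Planted labels a test can score the pipeline against."""

    pairs: list[dict]            # kind, i, j, rho_T, rho_N, should_be_in_D, sign
    hub_gene: int | None
    hub_partners: list[int]
    enriched_motifs: list[str]
    de_genes: list[int]
    dc_not_de_genes: list[int]

    def pairs_of_kind(self, kind: str) -> list[dict]:
        return [p for p in self.pairs if p["kind"] == kind]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


def _condition_correlation(scn: SyntheticScenario, condition: str) -> np.ndarray:
    sigma = np.eye(scn.n_genes)

    def put(i: int, j: int, rho: float) -> None:
        sigma[i, j] = sigma[j, i] = rho

    for i, j, rho in scn.null_pairs:
        put(i, j, rho)
    for i, j, rho in scn.decoupled_pairs:
        if condition == "normal":
            put(i, j, rho)
    for i, j, rho in scn.gained_pairs:
        if condition == "tumor":
            put(i, j, rho)
    if scn.hub is not None and condition == "normal":
        h, partners, rho = scn.hub
        for p in partners:
            put(h, p, rho)
        for a in partners:  # one-factor structure: partners share the hub factor
            for b in partners:
                if a != b:
                    put(a, b, rho * rho)
    if condition == "normal":
        for _name, (targets, rho) in scn.tf_modules.items():
            for a in targets:
                for b in targets:
                    if a != b:
                        put(a, b, rho)
        dd = scn.dc_not_de_genes
        for a in dd:
            for b in dd:
                if a != b:
                    put(a, b, scn.dc_not_de_rho)
    return sigma


def _sample_condition(
    scn: SyntheticScenario,
    sigma: np.ndarray,
    n: int,
    rng: np.random.Generator,
    tumor: bool,
) -> np.ndarray:
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as err:  # disjointness makes this unreachable
        raise ValueError(f"planted correlation matrix not positive definite: {err}")
    latent = L @ rng.standard_normal((scn.n_genes, n))
    if scn.noise_sd > 0:
        latent = latent + scn.noise_sd * rng.standard_normal(latent.shape)
    if tumor:
        for g, shift in scn.de_genes.items():
            latent[g] += shift * np.log(2.0)
    return scn.value_transform(latent)


def generate_study(scn: SyntheticScenario) -> tuple[ExpressionStudy, GroundTruth]:
    """Draw one paired dataset; deterministic given the scenario seed."""
    scn.validate()
    rng = np.random.default_rng(scn.seed)
    tumor = _sample_condition(scn, _condition_correlation(scn, "tumor"), scn.n_tumor, rng, True)
    normal = _sample_condition(scn, _condition_correlation(scn, "normal"), scn.n_normal, rng, False)

    genes = [f"g{i:03d}" for i in range(scn.n_genes)]
    study = ExpressionStudy(
        study_name=scn.study_name,
        genes=genes,
        tumor=tumor,
        normal=normal,
        sample_ids={
            "tumor": [f"T{i:04d}" for i in range(scn.n_tumor)],
            "normal": [f"N{i:04d}" for i in range(scn.n_normal)],
        },
    )

    pairs = []
    for i, j, rho in scn.null_pairs:
        pairs.append(dict(kind="null", i=i, j=j, rho_T=rho, rho_N=rho,
                          should_be_in_D=False, sign=0))
    for i, j, rho in scn.decoupled_pairs:
        pairs.append(dict(kind="decoupled", i=i, j=j, rho_T=0.0, rho_N=rho,
                          should_be_in_D=True, sign=-int(np.sign(rho))))
    for i, j, rho in scn.gained_pairs:
        pairs.append(dict(kind="gained", i=i, j=j, rho_T=rho, rho_N=0.0,
                          should_be_in_D=True, sign=int(np.sign(rho))))
    gt = GroundTruth(
        pairs=pairs,
        hub_gene=scn.hub[0] if scn.hub else None,
        hub_partners=list(scn.hub[1]) if scn.hub else [],
        enriched_motifs=list(scn.tf_modules),
        de_genes=sorted(scn.de_genes),
        dc_not_de_genes=list(scn.dc_not_de_genes),
    )
    return study, gt


def motif_collection(scn: SyntheticScenario, extra: dict[str, list[int]] | None = None
                     ) -> GeneSetCollection:
    """Gene-set collection holding the scenario's TF modules (plus decoys)."""
    sets = {
        name: {f"g{i:03d}" for i in targets}
        for name, (targets, _rho) in scn.tf_modules.items()
    }
    if extra:
        for name, targets in extra.items():
            sets[name] = {f"g{i:03d}" for i in targets}
    return GeneSetCollection(sets=sets, kind="tf_motif")


def generate_pancan(
    scenarios: list[SyntheticScenario],
    shared_pairs: list[tuple[int, int, float, list[int]]],
) -> list[tuple[ExpressionStudy, GroundTruth]]:
    """Generate several studies with recurrent decoupled pairs.

    ``shared_pairs`` rows are (i, j, rho_normal, study_indices): the pair
    is planted as decoupled in exactly those studies and left independent
    elsewhere.  All scenarios must share the gene universe size.
    """
    if len({s.n_genes for s in scenarios}) != 1:
        raise ValueError("all scenarios must share one gene universe")
    out = []
    for k, scn in enumerate(scenarios):
        planted = list(scn.decoupled_pairs)
        for i, j, rho, studies in shared_pairs:
            if k in studies:
                planted = planted + [(i, j, rho)]
        scn_k = SyntheticScenario(
            **{**scn.__dict__, "decoupled_pairs": planted}
        )
        out.append(generate_study(scn_k))
    return out


# ---------------------------------------------------------------------------
# Canonical study-condition scenarios reused by the test-suite and the
# acceptance script.  Parameters are fixed here, once.
# ---------------------------------------------------------------------------

def decoupled_recovery_scenario(seed: int) -> SyntheticScenario:
    """20 genes; three decoupled pairs (rho_N=0.8), two null pairs at 0.5."""
    return SyntheticScenario(
        n_genes=20,
        seed=seed,
        decoupled_pairs=[(0, 1, 0.8), (2, 3, 0.8), (4, 5, 0.8)],
        null_pairs=[(6, 7, 0.5), (8, 9, 0.5)],
    )


def regulon_scenario(seed: int) -> tuple[SyntheticScenario, GeneSetCollection]:
    """One planted regulon among decoy motifs.

    40 genes; the motif's 8 targets are tightly co-expressed
    (latent rho 0.9) in normal tissue only — a regulatory program lost in
    tumors.  Five decoy motifs draw 8 structureless genes each.
    """
    scn = SyntheticScenario(
        n_genes=40,
        seed=seed,
        tf_modules={"TF_PLANTED": (list(range(8)), 0.9)},
    )
    decoys = {
        "TF_DECOY0": list(range(8, 16)),
        "TF_DECOY1": list(range(16, 24)),
        "TF_DECOY2": list(range(24, 32)),
        "TF_DECOY3": list(range(32, 40)),
        "TF_DECOY4": [10, 13, 17, 21, 25, 29, 33, 37],
    }
    return scn, motif_collection(scn, extra=decoys)


def pancan_scenarios(
    seed: int,
) -> tuple[list[SyntheticScenario], list[tuple[int, int, float, list[int]]]]:
    """Seven studies, 24 shared genes; two recurrent decoupled pairs
    planted in five studies, one pair planted in a single study."""
    rng = np.random.default_rng(seed)
    scenarios = [
        SyntheticScenario(
            n_genes=24,
            seed=int(rng.integers(2**31 - 1)),
            study_name=f"S{k}",
        )
        for k in range(7)
    ]
    shared = [
        (0, 1, 0.9, [0, 1, 2, 3, 4]),
        (2, 3, 0.9, [1, 2, 3, 4, 5]),
        (4, 5, 0.9, [6]),
    ]
    return scenarios, shared
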
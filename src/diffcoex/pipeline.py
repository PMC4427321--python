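"""End-to-end orchestration with a config file and reproducible seeds.

All defaults are the published analysis' printed values: tau = 1e-2 for
per-study networks, tau = 1e-4 for the PanCan stage, 1e-10 for
enrichment edge calling, hub/DE thresholds of 2 SD and 0.2 absolute log2
ratio, pathways of at least 5 genes, recurrence in at least 3 studies,
and 10000 label permutations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .coexpression import build_coexpression_network, write_network_edges
from .differential import (
    build_differential_network,
    permutation_null,
    write_differential_edges,
)
from .enrichment import tf_enrichment
from .io import ExpressionStudy, GeneSetCollection, InteractionList
from .pancan import concat_and_pca, interaction_class_comparison, pancan_recurrence
from .scores import (
    annotate_interaction_scores,
    de_dc_comparison,
    gene_scores,
    pathway_scores,
    tumor_gain_scores,
)

logger = logging.getLogger("diffcoex")

__all__ = ["PipelineConfig", "run_study", "run_pancan"]


@dataclass
class PipelineConfig:
    tau: float = 1e-2
    tau_pancan: float = 1e-4
    tau_edge: float = 1e-10
    sd_mult: float = 2.0
    fc_cut: float = 0.2
    min_pathway_size: int = 5
    min_studies: int = 3
    n_perm: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau", "tau_pancan", "tau_edge"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _run_log(outdir: Path, config: PipelineConfig, extra: dict) -> None:
    payload = {"version": __version__, "config": asdict(config), **extra}
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(payload, fh, indent=1)


def run_study(
    config: PipelineConfig,
    study: ExpressionStudy,
    outdir: str | Path,
    pathways: GeneSetCollection | None = None,
    motifs: GeneSetCollection | None = None,
    interactions: InteractionList | None = None,
    run_permutations: bool = False,
) -> dict:
    """Run every per-study stage and write its artifacts to *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run_study %s: tau=%g seed=%d", study.study_name, config.tau, config.seed)

    net_T = build_coexpression_network(study.tumor, config.tau, study.genes)
    net_N = build_coexpression_network(study.normal, config.tau, study.genes)
    write_network_edges(net_T, outdir / "coexpression_tumor.tsv")
    write_network_edges(net_N, outdir / "coexpression_normal.tsv")

    dnet = build_differential_network(net_T, net_N, config.tau)
    write_differential_edges(dnet, outdir / "differential_network.tsv")

    scores = gene_scores(dnet)
    if interactions is not None:
        scores = annotate_interaction_scores(dnet, interactions, scores)
    scores = tumor_gain_scores(dnet, scores)
    rho, dc_not_de, scores = de_dc_comparison(
        study, scores, sd_mult=config.sd_mult, fc_cut=config.fc_cut
    )
    scores.to_csv(outdir / "gene_scores.tsv", sep="\t", float_format="%.17g")

    bundle: dict = {
        "study": study,
        "dnet": dnet,
        "scores": scores,
        "de_dc_rho": rho,
        "dc_not_de": dc_not_de,
    }
    if pathways is not None:
        ptab = pathway_scores(scores, pathways, min_genes=config.min_pathway_size)
        ptab.to_csv(outdir / "pathway_scores.tsv", sep="\t", float_format="%.17g")
        bundle["pathway_scores"] = ptab
    if motifs is not None:
        etab = tf_enrichment(dnet, motifs, tau_edge=config.tau_edge)
        etab.to_csv(outdir / "tf_enrichment.tsv", sep="\t", float_format="%.17g")
        bundle["tf_enrichment"] = etab
    if run_permutations:
        null = permutation_null(study, config.n_perm, config.seed)
        bundle["permutation_null"] = null
        with open(outdir / "permutation_null.json", "w") as fh:
            json.dump(
                {"n_perm": null.n_perm, "exceedance_fraction": null.exceedance_fraction},
                fh,
                indent=1,
            )
    _run_log(
        outdir,
        config,
        {
            "study": study.study_name,
            "n_tumor": study.n_tumor,
            "n_normal": study.n_normal,
            "n_genes": len(study.genes),
            "n_differential_pairs": dnet.nnz_pairs(),
            "de_dc_rho": None if rho != rho else rho,
        },
    )
    return bundle


def run_pancan(
    config: PipelineConfig,
    bundles: list[dict],
    outdir: str | Path,
    interactions: InteractionList | None = None,
) -> dict:
    """Cross-study stage over per-study bundles built at tau_pancan."""
    if len(bundles) < 2:
        raise ValueError("need at least 2 study bundles")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = [b["study"].study_name for b in bundles]
    dnets = [b["dnet"] for b in bundles]

    rec = pancan_recurrence(dnets, min_studies=config.min_studies, study_names=names)
    rec.pair_counts.to_csv(outdir / "recurrent_pairs.tsv", sep="\t", index=False)

    cdc = concat_and_pca(dnets, n_components=2, study_names=names)
    cdc.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t", float_format="%.17g")

    out: dict = {"recurrence": rec, "pca": cdc}
    if interactions is not None:
        rows = []
        for name, dnet in zip(names, dnets):
            tab = interaction_class_comparison(dnet, interactions)
            tab.insert(0, "study", name)
            rows.append(tab)
        import pandas as pd

        cmp_tab = pd.concat(rows, ignore_index=True) if rows else None
        if cmp_tab is not None:
            cmp_tab.to_csv(outdir / "interaction_class_tests.tsv", sep="\t", index=False)
            out["class_comparison"] = cmp_tab
    _run_log(
        outdir,
        config,
        {
            "studies": names,
            "n_recurrent_pairs": len(rec.recurrent_pairs),
            "n_recurrent_genes": len(rec.recurrent_genes),
            "variance_fractions": [float(v) for v in cdc.variance_fractions],
        },
    )
    return out
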
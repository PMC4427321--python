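"""Readers, writers and domain containers for the pipeline's file formats.

Expression matrices are plain TSV (header row = sample IDs, first column =
gene ID), condition labels a two-column TSV, gene sets GMT, binary
interactions a SIF-style three-column TSV, and the study manifest a CSV
mirroring the published cohort table.  Expression values are accepted as
already-normalized non-negative reals (RSEM scale); no re-normalization is
performed.  Gene identifiers are opaque strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("diffcoex")

CONDITIONS = ("tumor", "normal")
INTERACTION_TYPES = ("in_complex_with", "catalysis_precedes")

#: Fisher variance 1/(N-3) requires N > 3 in each condition.
MIN_SAMPLES_PER_CONDITION = 4


class FormatError(ValueError):
    """A file violated the expected schema."""


@dataclass
class ExpressionStudy:
    """One study: a gene x sample expression matrix per condition.

    Both condition matrices share the same gene list and ordering; values
    are non-negative reals on a normalized scale.
    """

    study_name: str
    genes: list[str]
    tumor: np.ndarray
    normal: np.ndarray
    sample_ids: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        m = len(self.genes)
        if len(set(self.genes)) != m:
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise FormatError(f"duplicate gene IDs: {dupes}")
        for cond in CONDITIONS:
            mat = getattr(self, cond)
            ids = self.sample_ids[cond]
            if mat.shape != (m, len(ids)):
                raise FormatError(
                    f"{cond} matrix shape {mat.shape} does not match "
                    f"{m} genes x {len(ids)} samples"
                )
            if mat.shape[1] < MIN_SAMPLES_PER_CONDITION:
                raise FormatError(
                    f"{cond} has {mat.shape[1]} samples; at least "
                    f"{MIN_SAMPLES_PER_CONDITION} required for the Fisher "
                    "variance 1/(N-3)"
                )
            if np.any(mat < 0):
                raise FormatError(f"negative expression value in {cond} matrix")
        all_ids = self.sample_ids["tumor"] + self.sample_ids["normal"]
        if len(set(all_ids)) != len(all_ids):
            raise FormatError("duplicate sample IDs")

    @property
    def n_tumor(self) -> int:
        return self.tumor.shape[1]

    @property
    def n_normal(self) -> int:
        return self.normal.shape[1]

    def condition(self, name: str) -> np.ndarray:
        if name not in CONDITIONS:
            raise KeyError(name)
        return getattr(self, name)


@dataclass
class StudyManifest:
    """Cohort bookkeeping: per-study tumor/normal sample counts."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"study_name", "n_tumor", "n_normal"}
        missing = required - set(self.rows.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        if self.rows["study_name"].duplicated().any():
            raise FormatError("duplicate study names in manifest")
        for col in ("n_tumor", "n_normal"):
            if (self.rows[col] <= 0).any():
                raise FormatError(f"manifest column {col} must be strictly positive")

    @property
    def total_tumor(self) -> int:
        return int(self.rows["n_tumor"].sum())

    @property
    def total_normal(self) -> int:
        return int(self.rows["n_normal"].sum())


@dataclass
class GeneSetCollection:
    """Named gene sets: metabolic pathways or TF-motif target sets."""

    sets: dict[str, set[str]]
    kind: str  # "pathway" or "tf_motif"

    def __post_init__(self) -> None:
        if self.kind not in ("pathway", "tf_motif"):
            raise ValueError(f"unknown gene-set kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with *universe*; drop sets that become empty."""
        uni = set(universe)
        out: dict[str, set[str]] = {}
        for name, members in self.sets.items():
            kept = members & uni
            if kept:
                out[name] = kept
            else:
                logger.warning(
                    "gene set %r shares no genes with the universe; dropped", name
                )
        return GeneSetCollection(out, self.kind)


@dataclass
class InteractionList:
    """Unordered binary interaction pairs keyed by interaction class."""

    pairs: dict[str, set[frozenset]] = field(
        default_factory=lambda: {t: set() for t in INTERACTION_TYPES}
    )

    def add(self, gene_a: str, gene_b: str, interaction_type: str) -> None:
        if interaction_type not in INTERACTION_TYPES:
            raise FormatError(
                f"unknown interaction type {interaction_type!r}; "
                f"accepted: {list(INTERACTION_TYPES)}"
            )
        if gene_a == gene_b:
            return  # self-pairs carry no co-expression information
        self.pairs[interaction_type].add(frozenset((gene_a, gene_b)))

    def n_pairs(self, interaction_type: str | None = None) -> int:
        if interaction_type is None:
            return sum(len(s) for s in self.pairs.values())
        return len(self.pairs[interaction_type])


def read_expression_matrix(
    path: str | Path, condition_labels: Mapping[str, str], study_name: str = "study"
) -> ExpressionStudy:
    """Read a gene x sample TSV and partition columns by condition.

    Every sample in the file must appear in *condition_labels* with value
    ``tumor`` or ``normal``.  Gene order is preserved from the file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"duplicate gene IDs in {path}: {dupes}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            raise FormatError(
                f"non-numeric value at gene {bad[0]!r}, sample {col!r} in {path}"
            )
    unlabeled = [s for s in df.columns if s not in condition_labels]
    if unlabeled:
        raise FormatError(f"samples without a condition label: {unlabeled}")
    bad_cond = {s: c for s, c in condition_labels.items() if c not in CONDITIONS}
    if bad_cond:
        raise FormatError(f"conditions must be in {CONDITIONS}: {bad_cond}")
    cols = {c: [s for s in df.columns if condition_labels[s] == c] for c in CONDITIONS}
    return ExpressionStudy(
        study_name=study_name,
        genes=[str(g) for g in df.index],
        tumor=df[cols["tumor"]].to_numpy(dtype=float),
        normal=df[cols["normal"]].to_numpy(dtype=float),
        sample_ids={c: cols[c] for c in CONDITIONS},
    )


def write_expression_matrix(study: ExpressionStudy, path: str | Path) -> None:
    """Write the concatenated (tumor then normal) matrix as TSV."""
    df = pd.DataFrame(
        np.hstack([study.tumor, study.normal]),
        index=pd.Index(study.genes, name="gene"),
        columns=study.sample_ids["tumor"] + study.sample_ids["normal"],
    )
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_condition_labels(study: ExpressionStudy, path: str | Path) -> None:
    rows = [(s, c) for c in CONDITIONS for s in study.sample_ids[c]]
    pd.DataFrame(rows, columns=["sample_id", "condition"]).to_csv(
        path, sep="\t", index=False
    )


def read_condition_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "condition"]:
        raise FormatError(
            f"label file {path} must have columns sample_id, condition"
        )
    return dict(zip(df["sample_id"], df["condition"]))


def load_manifest(path: str | Path) -> StudyManifest:
    """Load the study manifest (CSV or TSV) listing per-study sample counts."""
    df = pd.read_csv(path, sep=None, engine="python")
    return StudyManifest(rows=df)


def packaged_manifest_path() -> Path:
    """Path of the bundled seven-study TCGA cohort manifest."""
    return Path(__file__).parent / "data" / "tcga_manifest.csv"


def read_gene_sets(path: str | Path, kind: str) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description, >=1 gene"
                )
            name, _desc, *genes = fields
            members = {g for g in genes if g}
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    if not sets:
        raise FormatError(f"GMT file {path} contains no gene sets")
    return GeneSetCollection(sets=sets, kind=kind)


def read_interactions(path: str | Path) -> InteractionList:
    """Parse a SIF-style TSV of (gene_a, interaction_type, gene_b) rows."""
    out = InteractionList()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            a, itype, b = fields
            if a == b:
                n_self += 1
                continue
            out.add(a, b, itype)
    if n_self:
        logger.info("dropped %d self-pairs from %s", n_self, path)
    return out
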
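"""Readers and writers for the plain-text formats the pipeline consumes.

All tabular inputs are TSV with a header; gene sets are GMT; the
functional-interaction network is a three-column SIF-style table
(gene_a, edge_type, gene_b).  Validation is strict: structural problems
raise :class:`FormatError`, recoverable oddities (unknown consequence
strings, empty target sets) are logged and handled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import CONSEQUENCE_VOCABULARY

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "MutationRecord",
    "GermlineVariant",
    "DomainAnnotation",
    "GeneSampleMatrix",
    "DriverGene",
    "TargetAnnotation",
    "InteractionNetwork",
    "ALLOWED_EDGE_TYPES",
    "read_mutations",
    "write_mutations",
    "read_germline",
    "write_germline",
    "read_domains",
    "write_domains",
    "read_drivers",
    "write_drivers",
    "read_gene_sample_matrix",
    "write_gene_sample_matrix",
    "read_genesets_gmt",
    "write_genesets_gmt",
    "merge_target_sources",
    "read_network_sif",
    "write_network_sif",
]

#: functional-interaction edge types retained for partner search
ALLOWED_EDGE_TYPES = frozenset(
    {
        "in-complex-with",
        "interacts-with",
        "neighbor-of",
        "controls-phosphorylation-of",
        "controls-state-change-of",
    }
)


class FormatError(ValueError):
    """A structural problem in an input file."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation mapped to a 1-based amino-acid position."""

    sample_id: str
    gene: str
    protein_pos: int
    consequence: str

    def __post_init__(self) -> None:
        if self.protein_pos < 1:
            raise ValueError(f"protein_pos must be >= 1, got {self.protein_pos}")
        if self.consequence not in CONSEQUENCE_VOCABULARY:
            raise ValueError(f"unknown consequence {self.consequence!r}")


@dataclass(frozen=True)
class GermlineVariant:
    """One germline variant at a 1-based amino-acid position."""

    gene: str
    protein_pos: int
    allele_freq: float

    def __post_init__(self) -> None:
        if self.protein_pos < 1:
            raise ValueError(f"protein_pos must be >= 1, got {self.protein_pos}")
        if not (0.0 < self.allele_freq <= 1.0):
            raise ValueError(f"allele_freq must be in (0, 1], got {self.allele_freq}")


@dataclass(frozen=True)
class DomainAnnotation:
    """A protein domain with 1-based inclusive amino-acid bounds."""

    gene: str
    domain_id: str
    domain_name: str
    start_aa: int
    end_aa: int
    source_db: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValueError(
                f"invalid domain bounds [{self.start_aa}, {self.end_aa}] on {self.gene}"
            )

    @property
    def length_aa(self) -> int:
        return self.end_aa - self.start_aa + 1

    def contains(self, pos: int) -> bool:
        return self.start_aa <= pos <= self.end_aa


@dataclass(frozen=True)
class DriverGene:
    """A driver gene, its tumor types, and its mode of action."""

    gene: str
    tumor_types: frozenset
    mode_of_action: str  # Act | LoF | Undetermined
    is_tf: bool = False

    def __post_init__(self) -> None:
        if not self.tumor_types:
            raise ValueError(f"driver {self.gene} has no tumor types")
        if self.mode_of_action not in ("Act", "LoF", "Undetermined"):
            raise ValueError(f"unknown mode_of_action {self.mode_of_action!r}")

    @property
    def effective_mode(self) -> str:
        """Undetermined drivers are treated as Act for every calling rule."""
        return "Act" if self.mode_of_action == "Undetermined" else self.mode_of_action


@dataclass(frozen=True)
class TargetAnnotation:
    """Annotated targets of one TF, with the source databases recorded."""

    tf: str
    targets: frozenset
    sources: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"TF {self.tf} has an empty target set")


class GeneSampleMatrix:
    """A gene x sample matrix of expression (RPKM) or continuous CNA values."""

    KINDS = ("expression_rpkm", "cna_continuous")

    def __init__(self, df: pd.DataFrame, kind: str):
        if kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {kind!r}")
        if df.index.duplicated().any():
            raise FormatError("duplicate gene ids in matrix")
        if df.columns.duplicated().any():
            raise FormatError("duplicate sample ids in matrix")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise FormatError("matrix contains missing values")
        if kind == "expression_rpkm" and (values < 0).any():
            raise FormatError("expression matrix contains negative values")
        self.df = df.astype(float)
        self.kind = kind

    @property
    def genes(self) -> list:
        return list(self.df.index)

    @property
    def samples(self) -> list:
        return list(self.df.columns)

    def row(self, gene: str) -> pd.Series:
        return self.df.loc[gene]

    def subset_samples(self, samples: Sequence[str]) -> "GeneSampleMatrix":
        return GeneSampleMatrix(self.df[list(samples)], self.kind)


class InteractionNetwork:
    """An undirected functional-interaction network with typed edges."""

    def __init__(self, edges: Iterable[tuple]):
        stored: dict = {}
        for a, b, edge_type in edges:
            if a == b:
                continue  # self-loops carry no partner information
            key = frozenset((a, b))
            stored.setdefault(key, set()).add(edge_type)
        self._edges = stored

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, pair: tuple) -> bool:
        return frozenset(pair) in self._edges

    def neighbors(self, gene: str) -> set:
        out = set()
        for key in self._edges:
            if gene in key:
                out |= key - {gene}
        return out

    def edge_list(self) -> list:
        out = []
        for key, types in sorted(self._edges.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(key)
            for t in sorted(types):
                out.append((a, b, t))
        return out


# ---------------------------------------------------------------------------
# tabular readers / writers


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a somatic mutation table (columns: sample, gene, protein_pos,
    consequence).  Consequences outside the vocabulary become ``other``."""
    df = _read_tsv(path, ["sample", "gene", "protein_pos", "consequence"])
    records = []
    for row in df.itertuples(index=False):
        try:
            pos = int(row.protein_pos)
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path}: non-integer protein_pos {row.protein_pos!r}"
            ) from exc
        consequence = row.consequence
        if consequence not in CONSEQUENCE_VOCABULARY:
            logger.warning(
                "unknown consequence %r on %s:%s mapped to 'other'",
                consequence,
                row.gene,
                pos,
            )
            consequence = "other"
        records.append(MutationRecord(row.sample, row.gene, pos, consequence))
    return records


def write_mutations(records: Sequence[MutationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.sample_id, r.gene, r.protein_pos, r.consequence) for r in records],
        columns=["sample", "gene", "protein_pos", "consequence"],
    ).to_csv(path, sep="\t", index=False)


def read_germline(path: str | Path) -> list[GermlineVariant]:
    df = _read_tsv(path, ["gene", "protein_pos", "allele_freq"])
    out = []
    for row in df.itertuples(index=False):
        try:
            pos = int(row.protein_pos)
            af = float(row.allele_freq)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed germline row {row!r}") from exc
        out.append(GermlineVariant(row.gene, pos, af))
    return out


def write_germline(variants: Sequence[GermlineVariant], path: str | Path) -> None:
    pd.DataFrame(
        [(v.gene, v.protein_pos, repr(v.allele_freq)) for v in variants],
        columns=["gene", "protein_pos", "allele_freq"],
    ).to_csv(path, sep="\t", index=False)


def read_domains(path: str | Path) -> list[DomainAnnotation]:
    df = _read_tsv(path, ["gene", "domain_id", "domain_name", "start_aa", "end_aa"])
    out = []
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start_aa), int(row.end_aa)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed domain row {row!r}") from exc
        source = getattr(row, "source_db", "") or ""
        out.append(DomainAnnotation(row.gene, row.domain_id, row.domain_name, start, end, source))
    return out


def write_domains(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(d.gene, d.domain_id, d.domain_name, d.start_aa, d.end_aa, d.source_db) for d in domains],
        columns=["gene", "domain_id", "domain_name", "start_aa", "end_aa", "source_db"],
    ).to_csv(path, sep="\t", index=False)


def read_drivers(path: str | Path) -> list[DriverGene]:
    """Driver catalog TSV: gene, tumor_types (comma-separated), mode_of_action,
    is_tf (0/1)."""
    df = _read_tsv(path, ["gene", "tumor_types", "mode_of_action", "is_tf"])
    out = []
    for row in df.itertuples(index=False):
        tumor_types = frozenset(t for t in str(row.tumor_types).split(",") if t)
        out.append(
            DriverGene(row.gene, tumor_types, row.mode_of_action, str(row.is_tf) == "1")
        )
    return out


def write_drivers(drivers: Sequence[DriverGene], path: str | Path) -> None:
    pd.DataFrame(
        [
            (d.gene, ",".join(sorted(d.tumor_types)), d.mode_of_action, int(d.is_tf))
            for d in drivers
        ],
        columns=["gene", "tumor_types", "mode_of_action", "is_tf"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_sample_matrix(path: str | Path, kind: str) -> GeneSampleMatrix:
    """Read a TSV matrix: first column gene id, remaining columns samples."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: matrix has no sample columns")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix values") from exc
    try:
        return GeneSampleMatrix(df, kind)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_gene_sample_matrix(matrix: GeneSampleMatrix, path: str | Path) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="gene")


def read_genesets_gmt(path: str | Path) -> list[TargetAnnotation]:
    """Read a GMT file; one line per (TF, source) pair.

    GMT column 1 is the TF name, column 2 the source database, columns
    3+ the target genes.  (A dedicated parser is used because the
    description column, which carries the source, must be kept.)
    """
    path = Path(path)
    seen = set()
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line with fewer than 3 fields")
            name, source = parts[0], parts[1]
            if (name, source) in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r} / {source!r}")
            seen.add((name, source))
            members = frozenset(g for g in parts[2:] if g)
            if not members:
                logger.warning("gene set %s (%s) is empty; skipped", name, source)
                continue
            out.append(TargetAnnotation(name, members, frozenset({source})))
    return out


def write_genesets_gmt(annotations: Sequence[TargetAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            for source in sorted(ann.sources) or [""]:
                fh.write("\t".join([ann.tf, source, *sorted(ann.targets)]) + "\n")


def merge_target_sources(annotations: Sequence[TargetAnnotation]) -> dict:
    """Union targets per TF across sources; TFs left empty are dropped
    with a warning.  Returns ``{tf: TargetAnnotation}``."""
    by_tf: dict = {}
    for ann in annotations:
        if ann.tf in by_tf:
            prev = by_tf[ann.tf]
            by_tf[ann.tf] = TargetAnnotation(
                ann.tf, prev.targets | ann.targets, prev.sources | ann.sources
            )
        else:
            by_tf[ann.tf] = ann
    for tf in [t for t, a in by_tf.items() if not a.targets]:
        logger.warning("TF %s has no targets after merging; excluded", tf)
        del by_tf[tf]
    return by_tf


def read_network_sif(
    path: str | Path, allowed_types: Iterable[str] = ALLOWED_EDGE_TYPES
) -> InteractionNetwork:
    """Read a three-column (gene_a, edge_type, gene_b) network table,
    keeping only edges of the allowed types; storage is undirected."""
    path = Path(path)
    allowed = set(allowed_types)
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            a, edge_type, b = parts
            if edge_type in allowed:
                edges.append((a, b, edge_type))
    return InteractionNetwork(edges)


def write_network_sif(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, t in network.edge_list():
            fh.write(f"{a}\t{t}\t{b}\n")
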
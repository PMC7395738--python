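"""Readers, writers and signature-integrity QC for the pipeline's file formats.

Formats handled: tab-separated expression matrices (genes x samples), GMT
gene-set libraries (Broad dialect), PPI edge lists (two-column TSV or SIF
``A pp B``), two-column signature tables (gene, coefficient) and plain-text
gene lists (one symbol per line).

Gene symbols are normalised to uppercase everywhere on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StudyCategory",
    "ExpressionStudy",
    "StudyMetadata",
    "GeneSetLibrary",
    "PPINetwork",
    "QCReport",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_ppi",
    "write_ppi",
    "read_gene_list",
    "write_gene_list",
    "read_signature_table",
    "write_signature_table",
    "validate_signature_metadata",
]


class StudyCategory(str, Enum):
    """The three comparison groups a study can belong to."""

    CANCER_VS_NORMAL = "cancer_vs_normal"
    GENE_PERTURBATION = "gene_perturbation"
    DRUG_PERTURBATION = "drug_perturbation"


@dataclass
class ExpressionStudy:
    """One study's log2-scale expression matrix with case/control labels.

    Invariants enforced at construction: case and control sample sets are
    disjoint and non-empty, gene symbols are unique after uppercasing, the
    matrix shape matches the gene/sample lists, and all values are finite.
    """

    study_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    case_samples: list[str]
    control_samples: list[str]
    category: StudyCategory = StudyCategory.CANCER_VS_NORMAL

    def __post_init__(self) -> None:
        self.genes = [g.upper() for g in self.genes]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.study_id}: duplicate gene symbols after uppercasing")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"{self.study_id}: matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        overlap = set(self.case_samples) & set(self.control_samples)
        if overlap:
            raise ValueError(f"{self.study_id}: samples in both groups: {sorted(overlap)}")
        if not self.case_samples or not self.control_samples:
            raise ValueError(f"{self.study_id}: both sample groups must be non-empty")
        missing = (set(self.case_samples) | set(self.control_samples)) - set(self.samples)
        if missing:
            raise ValueError(f"{self.study_id}: sample IDs not in matrix: {sorted(missing)}")
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.study_id}: matrix contains non-finite values")
        self.category = StudyCategory(self.category)

    @property
    def case_indices(self) -> list[int]:
        pos = {s: i for i, s in enumerate(self.samples)}
        return [pos[s] for s in self.case_samples]

    @property
    def control_indices(self) -> list[int]:
        pos = {s: i for i, s in enumerate(self.samples)}
        return [pos[s] for s in self.control_samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class StudyMetadata:
    """Unvalidated study metadata, for QC of signatures before construction.

    Unlike :class:`ExpressionStudy`, no invariants are enforced, so studies
    that would be rejected by the integrity rules (e.g. a sample listed in
    both groups) can still be screened and reported.
    """

    study_id: str
    genes: Sequence[str]
    case_samples: Sequence[str]
    control_samples: Sequence[str]


@dataclass
class GeneSetLibrary:
    """A named collection of gene sets (TF targets, kinase substrates, GO, KEGG, drugs)."""

    name: str
    terms: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for term, genes in self.terms.items():
            gs = frozenset(g.upper() for g in genes if g)
            if not gs:
                raise ValueError(f"library {self.name}: term {term!r} is empty")
            clean[term] = gs
        self.terms = clean

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class PPINetwork:
    """Undirected simple protein-protein interaction network."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    @classmethod
    def build(cls, nodes: Iterable[str], edges: Iterable[tuple[str, str]]) -> "PPINetwork":
        """Normalise: uppercase symbols, drop self-loops, dedupe reversed edges.

        Nodes isolated after self-loop removal are retained.
        """
        node_set = {n.upper() for n in nodes}
        edge_set: set[tuple[str, str]] = set()
        for a, b in edges:
            a, b = a.upper(), b.upper()
            node_set.add(a)
            node_set.add(b)
            if a == b:
                continue
            edge_set.add((a, b) if a < b else (b, a))
        return cls(frozenset(node_set), frozenset(edge_set))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class QCReport:
    """Signature-integrity report: overlapping sample groups reject a study,
    symbols absent from the valid-symbol list are dropped and counted."""

    study_id: str
    status: str  # "accepted" | "rejected"
    overlapping_samples: list[str] = field(default_factory=list)
    invalid_symbols: list[str] = field(default_factory=list)
    n_genes_total: int = 0
    n_genes_retained: int = 0

    def to_row(self) -> dict:
        return {
            "study": self.study_id,
            "status": self.status,
            "overlapping_samples": ",".join(self.overlapping_samples),
            "n_invalid_symbols": len(self.invalid_symbols),
            "n_genes_total": self.n_genes_total,
            "n_genes_retained": self.n_genes_retained,
        }


def read_expression_matrix(
    path: str | Path,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    study_id: str,
    category: StudyCategory = StudyCategory.CANCER_VS_NORMAL,
    log2_transform: bool = False,
) -> ExpressionStudy:
    """Read a tab-separated genes x samples matrix into an :class:`ExpressionStudy`.

    The first column holds gene symbols, the header row sample IDs. Symbols
    are uppercased; duplicate rows are collapsed by arithmetic mean. With
    ``log2_transform=True``, ``log2(x + 1)`` is applied (for raw-scale input).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip().str.upper()

    header = list(raw.columns)
    for sid in list(case_ids) + list(control_ids):
        if sid not in header:
            raise ValueError(f"{path.name}: sample ID {sid!r} not found in header")

    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path.name}: non-numeric value {raw.iat[r, c]!r} at gene "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path.name}: missing value at gene {raw.index[r]!r}, sample {raw.columns[c]!r}")

    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.info("%s: collapsing %d duplicate gene rows by mean", path.name, n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()
    if log2_transform:
        numeric = np.log2(numeric + 1.0)

    return ExpressionStudy(
        study_id=study_id,
        genes=list(numeric.index),
        samples=list(numeric.columns),
        values=numeric.to_numpy(dtype=float),
        case_samples=list(case_ids),
        control_samples=list(control_ids),
        category=category,
    )


def write_expression_matrix(study: ExpressionStudy, path: str | Path) -> None:
    study.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT library: ``term <TAB> description <TAB> gene1 <TAB> gene2 ...``.

    Genes are uppercased and de-duplicated per term; terms whose gene fields
    are all blank are dropped with a warning. A line with fewer than three
    fields is an error.
    """
    path = Path(path)
    terms: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path.name}:{lineno}: GMT line has {len(fields)} fields (need >=3)")
            term = fields[0].strip()
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                logger.warning("%s:%d: term %r has no genes, dropped", path.name, lineno, term)
                continue
            terms[term] = genes
    return GeneSetLibrary(name=name or path.stem, terms=terms)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(library.terms):
            genes = "\t".join(sorted(library.terms[term]))
            fh.write(f"{term}\t{library.name}\t{genes}\n")


def read_ppi(path: str | Path) -> PPINetwork:
    """Read a PPI edge list: two whitespace-separated columns, or SIF ``A pp B``.

    Single-token lines denote isolated nodes; self-loops are removed and
    duplicate/reversed edges deduplicated. Lines with more than three tokens
    raise an error naming the line number.
    """
    path = Path(path)
    nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) == 1:  # isolated node
                nodes.add(tokens[0].upper())
                continue
            if len(tokens) == 2:
                a, b = tokens
            elif len(tokens) == 3:  # SIF: source relation target
                a, _, b = tokens
            else:
                raise ValueError(f"{path.name}:{lineno}: malformed edge line ({len(tokens)} tokens)")
            nodes.update((a.upper(), b.upper()))
            edges.append((a, b))
    return PPINetwork.build(nodes, edges)


def write_ppi(network: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")
        covered = {n for e in network.edges for n in e}
        for n in sorted(network.nodes - covered):  # isolated nodes, one token per line
            fh.write(f"{n}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_signature_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (gene, coefficient) TSV into an ordered mapping."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str).str.upper(), df.iloc[:, 1].astype(float)))


def write_signature_table(scores: Mapping[str, float], path: str | Path) -> None:
    df = pd.DataFrame({"gene": list(scores), "coefficient": [scores[g] for g in scores]})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def validate_signature_metadata(
    study: ExpressionStudy | StudyMetadata, valid_symbols: set[str]
) -> QCReport:
    """Signature-integrity QC.

    A study is rejected when any sample ID appears in both the case and the
    control group. Gene symbols absent from ``valid_symbols`` (e.g. an HGNC
    snapshot) are listed as dropped; the study itself remains accepted.
    """
    if not valid_symbols:
        raise ValueError("valid_symbols must be non-empty")
    valid_upper = {s.upper() for s in valid_symbols}
    genes = [g.upper() for g in study.genes]
    overlap = sorted(set(study.case_samples) & set(study.control_samples))
    invalid = sorted(g for g in genes if g not in valid_upper)
    status = "rejected" if overlap else "accepted"
    return QCReport(
        study_id=study.study_id,
        status=status,
        overlapping_samples=overlap,
        invalid_symbols=invalid,
        n_genes_total=len(genes),
        n_genes_retained=len(genes) - len(invalid),
    )
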
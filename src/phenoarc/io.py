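"""Core data model and parsers/writers for every file format the tool touches.

The central container is :class:`PhenoDataset`: a gene x phenotype x time
tensor of scores parsed from a whitespace-delimited file with one row per
(gene, phenotype) pair followed by one numeric value per time point.
Annotation networks (an enrichment table plus an interaction pair list,
both strictly tab-separated) and per-time-point bar series have their own
small containers.

Time points are labeled 1..n for display but indexed 0-based in every
programmatic interface of this package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataValueError, DuplicateRecordError, FormatError

logger = logging.getLogger(__name__)

#: token that marks a missing score in dataset files
MISSING_TOKEN = "NA"


@dataclass
class PhenoDataset:
    """Gene x phenotype x time scores.

    Parameters
    ----------
    genes, phenotypes
        Ordered, duplicate-free identifier lists.  Order is the first
        occurrence in the source file and is preserved everywhere.
    n_timepoints
        Number of score columns (the time course length ``n``).
    values
        Mapping ``(gene, phenotype) -> float array`` of length
        ``n_timepoints``; missing scores are ``nan``.  Pairs absent from
        the mapping are treated as entirely missing.
    """

    genes: list[str]
    phenotypes: list[str]
    n_timepoints: int
    values: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        if self.n_timepoints < 1:
            raise DataValueError("n_timepoints must be >= 1")
        if len(set(self.genes)) != len(self.genes):
            raise DataValueError("duplicate gene identifiers")
        if len(set(self.phenotypes)) != len(self.phenotypes):
            raise DataValueError("duplicate phenotype labels")
        for key, vec in self.values.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.n_timepoints,):
                raise DataValueError(
                    f"value vector for {key} has length {vec.size}, "
                    f"expected {self.n_timepoints}"
                )
            self.values[key] = vec

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotypes)

    def to_array(self) -> np.ndarray:
        """Dense ``(n_genes, n_phenotypes, n_timepoints)`` array, nan = missing."""
        arr = np.full((self.n_genes, self.n_phenotypes, self.n_timepoints), np.nan)
        gi = {g: i for i, g in enumerate(self.genes)}
        pi = {p: i for i, p in enumerate(self.phenotypes)}
        for (g, p), vec in self.values.items():
            arr[gi[g], pi[p], :] = vec
        return arr

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenoDataset):
            return NotImplemented
        if (
            self.genes != other.genes
            or self.phenotypes != other.phenotypes
            or self.n_timepoints != other.n_timepoints
            or set(self.values) != set(other.values)
        ):
            return False
        return all(
            np.array_equal(self.values[k], other.values[k], equal_nan=True)
            for k in self.values
        )


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    description: str
    p_value: float
    members: frozenset[str]


@dataclass
class AnnotationNetwork:
    """Enrichment terms plus term-term interaction edges (e.g. a GO network)."""

    terms: dict[str, AnnotationTerm]
    edges: set[frozenset[str]] = field(default_factory=set)

    @property
    def term_ids(self) -> list[str]:
        return list(self.terms)


@dataclass
class BarSeries:
    """One auxiliary value per time point, overlaid in the 3D arc view."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise FormatError("bar series must be one-dimensional")


# ---------------------------------------------------------------------------
# parsers


def parse_dataset(text: str, missing_token: str = MISSING_TOKEN) -> PhenoDataset:
    """Parse the whitespace-delimited dataset dialect.

    Column 1 is the gene name, column 2 the phenotype, the remaining
    columns are one score per time point.  Fields are separated by any run
    of spaces/tabs.  ``missing_token`` (default ``"NA"``) maps to nan.

    Raises
    ------
    FormatError
        Empty input, rows with fewer than 3 fields, or ragged rows (the
        message names the offending 1-based line).
    DuplicateRecordError
        A (gene, phenotype) pair occurring twice.
    DataValueError
        A non-numeric score other than the missing token.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty dataset text")

    genes: list[str] = []
    phenotypes: list[str] = []
    values: dict[tuple[str, str], np.ndarray] = {}
    n_fields: int | None = None

    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if len(fields) < 3:
            raise FormatError(
                f"line {lineno}: expected >= 3 whitespace-separated fields, "
                f"got {len(fields)}"
            )
        if n_fields is None:
            n_fields = len(fields)
        elif len(fields) != n_fields:
            raise FormatError(
                f"line {lineno}: ragged row ({len(fields)} fields, "
                f"expected {n_fields})"
            )
        gene, phenotype = fields[0], fields[1]
        key = (gene, phenotype)
        if key in values:
            raise DuplicateRecordError(
                f"line {lineno}: duplicate record for gene {gene!r}, "
                f"phenotype {phenotype!r}"
            )
        vec = np.empty(len(fields) - 2)
        for j, tok in enumerate(fields[2:]):
            if tok == missing_token:
                vec[j] = np.nan
            else:
                try:
                    vec[j] = float(tok)
                except ValueError:
                    raise DataValueError(
                        f"line {lineno}: non-numeric value {tok!r}"
                    ) from None
        if gene not in genes:
            genes.append(gene)
        if phenotype not in phenotypes:
            phenotypes.append(phenotype)
        values[key] = vec

    assert n_fields is not None
    return PhenoDataset(genes, phenotypes, n_fields - 2, values)


def parse_annotation_network(
    enrichment_text: str, interaction_text: str
) -> AnnotationNetwork:
    """Parse the tab-separated enrichment table and interaction pair list.

    Enrichment rows: ``term_id<TAB>description<TAB>p_value<TAB>g1|g2|...``.
    Interaction rows: ``term_a<TAB>term_b``.  An edge naming an absent term
    is dropped with a logged warning, never silently.
    """
    terms: dict[str, AnnotationTerm] = {}
    for lineno, line in enumerate(enrichment_text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 4:
            raise FormatError(
                f"enrichment line {lineno}: expected 4 tab-separated fields, "
                f"got {len(fields)}"
            )
        term_id, description, p_str, gene_str = fields
        try:
            p_value = float(p_str)
        except ValueError:
            raise DataValueError(
                f"enrichment line {lineno}: non-numeric p-value {p_str!r}"
            ) from None
        if not 0.0 <= p_value <= 1.0:
            raise DataValueError(
                f"enrichment line {lineno}: p-value {p_value} outside [0, 1]"
            )
        members = frozenset(g for g in gene_str.split("|") if g)
        if not members:
            raise FormatError(f"enrichment line {lineno}: empty gene list")
        terms[term_id] = AnnotationTerm(term_id, description, p_value, members)

    edges: set[frozenset[str]] = set()
    for lineno, line in enumerate(interaction_text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"interaction line {lineno}: expected 2 tab-separated fields, "
                f"got {len(fields)}"
            )
        a, b = fields
        if a not in terms or b not in terms:
            logger.warning(
                "interaction line %d: edge (%s, %s) references an unknown "
                "term; dropped",
                lineno,
                a,
                b,
            )
            continue
        if a != b:
            edges.add(frozenset((a, b)))
    return AnnotationNetwork(terms, edges)


def parse_barseries(text: str, n_timepoints: int, label: str = "bars") -> BarSeries:
    """Parse a whitespace-separated list of one value per time point."""
    tokens = text.split()
    if len(tokens) != n_timepoints:
        raise FormatError(
            f"bar series has {len(tokens)} values, expected {n_timepoints}"
        )
    try:
        values = np.array([float(t) for t in tokens])
    except ValueError:
        raise DataValueError("bar series contains a non-numeric value") from None
    return BarSeries(label, values)


# ---------------------------------------------------------------------------
# writers


def _fmt(v: float) -> str:
    if math.isnan(v):
        return MISSING_TOKEN
    return repr(float(v))


def write_dataset(dataset: PhenoDataset) -> str:
    """Serialize a dataset so that ``parse_dataset(write_dataset(d)) == d``.

    Rows are emitted in first-occurrence order of their (gene, phenotype)
    keys, which reproduces the gene and phenotype orderings on re-parse.
    """
    lines = []
    for (gene, phenotype), vec in dataset.values.items():
        lines.append(" ".join([gene, phenotype, *(_fmt(v) for v in vec)]))
    return "\n".join(lines) + "\n"


CONNECTIONS_HEADER = "source\ttarget\tt_source\tt_target\tweight\tgenes"


def write_connections_tsv(connections) -> str:
    """TSV with columns source, target, t_source, t_target, weight, genes.

    Gene sets are "|"-joined and sorted; rows are sorted by
    (t_source, t_target, source, target) for deterministic output.
    """
    rows = [CONNECTIONS_HEADER]
    for rec in sorted(
        connections.records,
        key=lambda r: (r.t_source, r.t_target, r.source, r.target),
    ):
        rows.append(
            "\t".join(
                [
                    rec.source,
                    rec.target,
                    str(rec.t_source),
                    str(rec.t_target),
                    str(rec.weight),
                    "|".join(sorted(rec.genes)),
                ]
            )
        )
    return "\n".join(rows) + "\n"


def read_connections_tsv(text: str):
    """Inverse of :func:`write_connections_tsv` (directedness not recorded:
    records with equal times are read back as undirected, lagged ones as
    directed, matching how the derivation functions emit them)."""
    from .events import Connection, ConnectionSet

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != CONNECTIONS_HEADER:
        raise FormatError("connection TSV must start with the standard header")
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 6:
            raise FormatError(f"connections line {lineno}: expected 6 fields")
        src, tgt, ts, tt, _w, genes = fields
        t_source, t_target = int(ts), int(tt)
        records.append(
            Connection(
                source=src,
                target=tgt,
                t_source=t_source,
                t_target=t_target,
                genes=frozenset(g for g in genes.split("|") if g),
                directed=t_target != t_source,
            )
        )
    phenos: list[str] = []
    for rec in records:
        for p in (rec.source, rec.target):
            if p not in phenos:
                phenos.append(p)
    n_t = 1 + max((r.t_target for r in records), default=0)
    return ConnectionSet(records=records, phenotypes=phenos, n_timepoints=n_t)


def write_edge_list(network) -> str:
    """Edge-list TSV for a gene network: ``a<TAB>b<TAB>weight`` with sorted
    endpoints and sorted rows; node attributes (role, first_phenotype) go
    in the companion table from :func:`write_node_table`."""
    rows = []
    for u, v, data in network.edges(data=True):
        a, b = sorted((u, v))
        rows.append(f"{a}\t{b}\t{data.get('weight', 1)}")
    return "\n".join(sorted(rows)) + ("\n" if rows else "")


def write_node_table(network) -> str:
    """Node annotation TSV: node, role, first_phenotype (empty if unset)."""
    rows = ["node\trole\tfirst_phenotype"]
    for node in sorted(network.nodes):
        data = network.nodes[node]
        rows.append(
            f"{node}\t{data.get('role', '')}\t{data.get('first_phenotype', '')}"
        )
    return "\n".join(rows) + "\n"


def write_layout_tsv(layout: dict[str, tuple[float, float]]) -> str:
    """Layout TSV: node, x, y."""
    rows = ["node\tx\ty"]
    for node in sorted(layout):
        x, y = layout[node]
        rows.append(f"{node}\t{x:.6f}\t{y:.6f}")
    return "\n".join(rows) + "\n"
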
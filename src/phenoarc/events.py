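"""Event gating and derivation of timed, weighted phenotype connections.

A gene-phenotype-time triple is an *event* when its score passes the
per-phenotype threshold interval.  Connections (the arcs of the
visualizations) link two phenotypes at times ``t`` and ``t + x`` whenever
gene events co-occur at those endpoints; their weight is the number of
genes involved.  If no thresholds are set every phenotype passes
everywhere, so all phenotypes appear interconnected — gating for
outstanding gene behavior (e.g. lowly/highly expressed, via quartiles) is
what makes the arc pattern informative.

Transitions are a second arc flavor: per gene, the *prominent* (maximally
scored) phenotype is tracked over time, and a change of prominence between
consecutive time points yields a directed arc colored by the phenotype
transitioned into.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataValueError, UnknownEntityError
from .io import PhenoDataset


@dataclass
class ThresholdSpec:
    """Per-phenotype inclusive score interval ``[lo, hi]``.

    Phenotypes without an explicit entry default to ``(-inf, +inf)``, i.e.
    every observed value passes.  Missing values never pass.
    """

    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise DataValueError(
                    f"threshold for {p!r}: lo={lo} exceeds hi={hi}"
                )

    def interval(self, phenotype: str) -> tuple[float, float]:
        return self.intervals.get(phenotype, (-np.inf, np.inf))

    def validate_for(self, dataset: PhenoDataset) -> None:
        unknown = set(self.intervals) - set(dataset.phenotypes)
        if unknown:
            raise UnknownEntityError(
                f"thresholds reference unknown phenotypes: {sorted(unknown)}"
            )


@dataclass
class EventMask:
    """Boolean (gene, phenotype, time) tensor of threshold-passing events."""

    genes: list[str]
    phenotypes: list[str]
    array: np.ndarray  # bool, shape (n_genes, n_phenotypes, n_timepoints)

    @property
    def n_timepoints(self) -> int:
        return self.array.shape[2]

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise UnknownEntityError(f"unknown gene {gene!r}") from None


@dataclass(frozen=True)
class Connection:
    """One arc: a weighted, timed link between two phenotypes.

    ``t_target >= t_source`` always; for undirected records (lag 0) the
    endpoint pair is stored in canonical sorted order.  The weight is the
    size of the gene set; empty connections are never stored.
    """

    source: str
    target: str
    t_source: int
    t_target: int
    genes: frozenset[str]
    directed: bool

    def __post_init__(self) -> None:
        if self.t_target < self.t_source:
            raise DataValueError("t_target must be >= t_source")
        if not self.genes:
            raise DataValueError("connections must carry at least one gene")
        if not self.directed and self.source > self.target:
            raise DataValueError(
                "undirected connections must store endpoints in sorted order"
            )

    @property
    def weight(self) -> int:
        return len(self.genes)

    @property
    def lag(self) -> int:
        return self.t_target - self.t_source


@dataclass
class ConnectionSet:
    """A collection of arcs plus the phenotype/time universe they live in."""

    records: list[Connection]
    phenotypes: list[str]
    n_timepoints: int
    genes_universe: frozenset[str] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def total_weight(self) -> int:
        return sum(r.weight for r in self.records)

    def at_time(self, t: int, cumulative: bool = False) -> list[Connection]:
        """Records ending at time ``t`` (or at any time up to ``t``)."""
        if cumulative:
            return [r for r in self.records if r.t_target <= t]
        return [r for r in self.records if r.t_target == t]


@dataclass
class ProminenceProfile:
    """Per gene, the prominent (arg-max) phenotype at each time, or None."""

    genes: list[str]
    phenotypes: list[str]
    entries: dict[str, tuple[str | None, ...]]

    @property
    def n_timepoints(self) -> int:
        return len(next(iter(self.entries.values())))


# ---------------------------------------------------------------------------
# gating


def build_mask(dataset: PhenoDataset, thresholds: ThresholdSpec | None = None) -> EventMask:
    """Mark every (gene, phenotype, time) whose score lies in its interval.

    Intervals are inclusive at both ends; with default thresholds every
    observed (non-missing) value passes.
    """
    thresholds = thresholds or ThresholdSpec()
    thresholds.validate_for(dataset)
    arr = dataset.to_array()
    mask = np.zeros(arr.shape, dtype=bool)
    for j, p in enumerate(dataset.phenotypes):
        lo, hi = thresholds.interval(p)
        col = arr[:, j, :]
        with np.errstate(invalid="ignore"):
            mask[:, j, :] = ~np.isnan(col) & (col >= lo) & (col <= hi)
    return EventMask(list(dataset.genes), list(dataset.phenotypes), mask)


def quartile_thresholds(dataset: PhenoDataset, side: str) -> ThresholdSpec:
    """Quartile gating: per phenotype, pool all non-missing values across
    genes and times; ``side="lower"`` admits values ``<= Q1``, ``"upper"``
    admits ``>= Q3``.  Quartiles use the linear-interpolation percentile
    definition (value at fractional rank ``q * (n - 1)``)."""
    if side not in ("lower", "upper"):
        raise DataValueError(f"side must be 'lower' or 'upper', got {side!r}")
    arr = dataset.to_array()
    intervals: dict[str, tuple[float, float]] = {}
    for j, p in enumerate(dataset.phenotypes):
        pooled = arr[:, j, :].ravel()
        pooled = pooled[~np.isnan(pooled)]
        if pooled.size == 0:
            raise DataValueError(f"phenotype {p!r} has no observed values")
        if side == "lower":
            q1 = float(np.percentile(pooled, 25, method="linear"))
            intervals[p] = (-np.inf, q1)
        else:
            q3 = float(np.percentile(pooled, 75, method="linear"))
            intervals[p] = (q3, np.inf)
    return ThresholdSpec(intervals)


# ---------------------------------------------------------------------------
# connection derivation


def derive_cooccurrence(mask: EventMask, lags: set[int] | None = None) -> ConnectionSet:
    """Connect phenotype p at time t with phenotype q at time t+x whenever a
    gene has events at both endpoints, for each lag x in ``lags``.

    Lag-0 records are undirected (each unordered pair counted once, stored
    in canonical order); positive-lag records are directed p -> q.  Weights
    aggregate genes per (p, q, t, t+x).
    """
    if lags is None:
        lags = {0}
    n = mask.n_timepoints
    for x in lags:
        if not 0 <= x < n:
            raise DataValueError(f"lag {x} outside the valid range 0..{n - 1}")

    arr = mask.array
    P = len(mask.phenotypes)
    buckets: dict[tuple[str, str, int, int, bool], set[str]] = {}
    for x in sorted(lags):
        for t in range(n - x):
            a = arr[:, :, t]          # events at t
            b = arr[:, :, t + x]      # events at t + x
            for pi in range(P):
                for qi in range(P):
                    if pi == qi:
                        continue
                    if x == 0 and pi > qi:
                        continue  # unordered pair counted once
                    joint = a[:, pi] & b[:, qi]
                    if not joint.any():
                        continue
                    genes = {mask.genes[gi] for gi in np.nonzero(joint)[0]}
                    p, q = mask.phenotypes[pi], mask.phenotypes[qi]
                    if x == 0:
                        p, q = sorted((p, q))
                    key = (p, q, t, t + x, x > 0)
                    buckets.setdefault(key, set()).update(genes)
    records = [
        Connection(p, q, t0, t1, frozenset(genes), directed)
        for (p, q, t0, t1, directed), genes in buckets.items()
    ]
    records.sort(key=lambda r: (r.t_source, r.t_target, r.source, r.target))
    return ConnectionSet(
        records,
        list(mask.phenotypes),
        n,
        genes_universe=frozenset(mask.genes),
    )


def derive_prominence(
    dataset: PhenoDataset, thresholds: ThresholdSpec | None = None
) -> ProminenceProfile:
    """Per gene and time point, the maximally scored phenotype.

    If ``thresholds`` are given only passing values compete; if none passes
    (or all values are missing) the entry is None.  Ties are broken by
    phenotype input order (first wins).
    """
    arr = dataset.to_array()
    if thresholds is not None:
        passing = build_mask(dataset, thresholds).array
    else:
        passing = ~np.isnan(arr)
    entries: dict[str, tuple[str | None, ...]] = {}
    for gi, gene in enumerate(dataset.genes):
        row: list[str | None] = []
        for t in range(dataset.n_timepoints):
            vals = arr[gi, :, t]
            ok = passing[gi, :, t]
            if not ok.any():
                row.append(None)
                continue
            masked = np.where(ok, vals, -np.inf)
            row.append(dataset.phenotypes[int(np.argmax(masked))])
        entries[gene] = tuple(row)
    return ProminenceProfile(list(dataset.genes), list(dataset.phenotypes), entries)


def derive_transitions(
    profile: ProminenceProfile, include_self: bool = False
) -> ConnectionSet:
    """Directed arcs for changes of the prominent phenotype between
    consecutive time points.

    A None entry breaks the chain (no arc across a gap).  Unchanged
    prominence emits nothing unless ``include_self`` is set.  The arc's
    display color keys on the target phenotype — the phenotype the cells
    transition into.
    """
    buckets: dict[tuple[str, str, int], set[str]] = {}
    for gene, seq in profile.entries.items():
        for t in range(len(seq) - 1):
            a, b = seq[t], seq[t + 1]
            if a is None or b is None:
                continue
            if a == b and not include_self:
                continue
            buckets.setdefault((a, b, t), set()).add(gene)
    records = [
        Connection(a, b, t, t + 1, frozenset(genes), directed=True)
        for (a, b, t), genes in buckets.items()
    ]
    records.sort(key=lambda r: (r.t_source, r.source, r.target))
    return ConnectionSet(
        records,
        list(profile.phenotypes),
        profile.n_timepoints,
        genes_universe=frozenset(profile.genes),
    )


# ---------------------------------------------------------------------------
# filtering and pair analytics


def filter_connections(
    connections: ConnectionSet,
    gene_subset: set[str] | None = None,
    phenotype_subset: set[str] | None = None,
    time_window: tuple[int, int] | None = None,
    max_lag: int | None = None,
) -> ConnectionSet:
    """Restrict a connection set.

    ``gene_subset`` intersects gene sets (records left empty are dropped);
    ``phenotype_subset`` uses touch semantics (source *or* target in the
    subset, matching "transitions to and from" a phenotype of interest);
    ``time_window = (lo, hi)`` keeps records with ``lo <= t_source`` and
    ``t_target <= hi``; ``max_lag`` bounds ``t_target - t_source``.
    """
    if gene_subset is not None and connections.genes_universe is not None:
        unknown = set(gene_subset) - connections.genes_universe
        if unknown:
            raise UnknownEntityError(f"unknown genes: {sorted(unknown)}")
    if phenotype_subset is not None:
        unknown = set(phenotype_subset) - set(connections.phenotypes)
        if unknown:
            raise UnknownEntityError(f"unknown phenotypes: {sorted(unknown)}")

    kept: list[Connection] = []
    for rec in connections.records:
        if phenotype_subset is not None and not (
            rec.source in phenotype_subset or rec.target in phenotype_subset
        ):
            continue
        if time_window is not None:
            lo, hi = time_window
            if rec.t_source < lo or rec.t_target > hi:
                continue
        if max_lag is not None and rec.lag > max_lag:
            continue
        if gene_subset is not None:
            genes = rec.genes & frozenset(gene_subset)
            if not genes:
                continue
            rec = replace(rec, genes=genes)
        kept.append(rec)
    return ConnectionSet(
        kept,
        list(connections.phenotypes),
        connections.n_timepoints,
        genes_universe=connections.genes_universe,
    )


def pair_specific_genes(
    connections: ConnectionSet, t: int | None = None
) -> dict[tuple[str, str], set[str]]:
    """Genes unique to one phenotype pair's connection.

    Records are grouped by unordered endpoint pair, at time ``t``
    (``t_source == t``) or globally when ``t`` is None; a gene is specific
    to a pair when it appears in that pair's gene set and in no other
    pair's at the same scope.
    """
    pooled: dict[tuple[str, str], set[str]] = {}
    for rec in connections.records:
        if t is not None and rec.t_source != t:
            continue
        key = tuple(sorted((rec.source, rec.target)))
        pooled.setdefault(key, set()).update(rec.genes)
    specific: dict[tuple[str, str], set[str]] = {}
    for pair, genes in pooled.items():
        others: set[str] = set()
        for other_pair, other_genes in pooled.items():
            if other_pair != pair:
                others |= other_genes
        specific[pair] = genes - others
    return specific
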
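"""Gene networks derived from gated events and prominence profiles.

Two constructions are provided.  The per-time co-phenotype network links
two genes when they pass the threshold for at least one common phenotype
at that time point, weighting the edge by the number of shared passing
phenotypes; it is recomputed for each time point, and a hard cap refuses
networks of 500 nodes or more.  The synchronous network links genes whose
entire prominence profiles are identical — cliques of genes that run
through the exact same phenotypic succession, candidates for involvement
in closely related processes.

Networks are plain :class:`networkx.Graph` objects with ``weight`` edge
attributes and optional ``first_phenotype`` / ``role`` node attributes.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .errors import CapacityError, DataValueError
from .events import EventMask, ProminenceProfile
from .io import AnnotationNetwork

#: networks at or above this node count are refused (display/perf envelope)
NODE_CAP = 500


def cophenotype_network(mask: EventMask, t: int, force_large: bool = False) -> nx.Graph:
    """Gene network at time ``t``: nodes are genes with at least one passing
    phenotype, edges join genes sharing >= 1 passing phenotype, edge weight
    is the number of shared passing phenotypes.

    Raises :class:`CapacityError` when the node count reaches ``NODE_CAP``
    (500) unless ``force_large`` is set.
    """
    if not 0 <= t < mask.n_timepoints:
        raise DataValueError(f"time point {t} out of range 0..{mask.n_timepoints - 1}")
    at_t = mask.array[:, :, t]  # genes x phenotypes
    active = np.nonzero(at_t.any(axis=1))[0]
    if len(active) >= NODE_CAP and not force_large:
        raise CapacityError(
            f"co-phenotype network at t={t} would have {len(active)} nodes; "
            f"only networks with fewer than {NODE_CAP} nodes are generated"
        )
    g = nx.Graph()
    g.add_nodes_from(mask.genes[i] for i in active)
    sub = at_t[active].astype(int)
    shared = sub @ sub.T  # pairwise shared-phenotype counts
    for a in range(len(active)):
        for b in range(a + 1, len(active)):
            w = int(shared[a, b])
            if w >= 1:
                g.add_edge(mask.genes[active[a]], mask.genes[active[b]], weight=w)
    return g


def synchronous_network(profiles: ProminenceProfile) -> nx.Graph:
    """Link genes whose full prominence sequences are identical (including
    the placement of None entries).  Only genes with at least one partner
    appear; each node carries ``first_phenotype`` — its first non-None
    profile entry."""
    groups: dict[tuple[str | None, ...], list[str]] = {}
    for gene, seq in profiles.entries.items():
        groups.setdefault(seq, []).append(gene)
    g = nx.Graph()
    for seq, genes in groups.items():
        if len(genes) < 2:
            continue
        first = next((p for p in seq if p is not None), None)
        for gene in genes:
            g.add_node(gene, first_phenotype=first)
        for a in range(len(genes)):
            for b in range(a + 1, len(genes)):
                g.add_edge(genes[a], genes[b], weight=1)
    return g


def core_variable_split(networks: list[nx.Graph]) -> dict[str, str]:
    """Classify genes across a per-time-point network series: ``core`` if
    present as a node at every time point, ``variable`` otherwise."""
    if not networks:
        raise DataValueError("at least one network is required")
    all_nodes: set[str] = set().union(*(set(g.nodes) for g in networks))
    core = set(networks[0].nodes)
    for g in networks[1:]:
        core &= set(g.nodes)
    return {n: ("core" if n in core else "variable") for n in all_nodes}


def annotate_roles(networks: list[nx.Graph]) -> None:
    """Write the core/variable split back onto each network's nodes."""
    roles = core_variable_split(networks)
    for g in networks:
        for n in g.nodes:
            g.nodes[n]["role"] = roles[n]


def force_layout(
    network: nx.Graph, seed: int = 0, iterations: int = 100
) -> dict[str, tuple[float, float]]:
    """Deterministic force-directed (spring) layout scaled to the unit
    square.  A single node sits at (0.5, 0.5); degenerate axes collapse to
    0.5."""
    if network.number_of_nodes() == 0:
        raise DataValueError("cannot lay out an empty network")
    if network.number_of_nodes() == 1:
        return {next(iter(network.nodes)): (0.5, 0.5)}
    pos = nx.spring_layout(network, seed=seed, iterations=iterations)
    coords = np.array([pos[n] for n in network.nodes])
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    out: dict[str, tuple[float, float]] = {}
    for n in network.nodes:
        x, y = (np.asarray(pos[n]) - lo) / span
        if hi[0] == lo[0]:
            x = 0.5
        if hi[1] == lo[1]:
            y = 0.5
        out[n] = (float(x), float(y))
    return out


def go_highlight(
    annotation: AnnotationNetwork,
    active_genes: set[str],
    dataset_genes: set[str] | None = None,
) -> tuple[set[str], dict[str, int]]:
    """Highlight terms whose member genes intersect the currently active
    genes, and size every term by how many of its members occur in the
    dataset (node size is drawn proportional to this count).

    Returns ``(highlighted term ids, term id -> size)``.
    """
    if dataset_genes is None:
        dataset_genes = set(active_genes)
    highlighted: set[str] = set()
    sizes: dict[str, int] = {}
    for term_id, term in annotation.terms.items():
        sizes[term_id] = len(term.members & dataset_genes)
        if term.members & active_genes:
            highlighted.add(term_id)
    return highlighted, sizes
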
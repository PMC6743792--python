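"""Signed directed regulatory networks: construction, I/O, and topology statistics.

A network is a :class:`SignedDiGraph` — a :class:`networkx.DiGraph` whose every
edge carries a ``sign`` attribute in ``{+1, -1}`` (+1 activation, -1
inhibition).  Networks come from KGML (KEGG XML), GraphML, or SIF files, or are
generated synthetically for benchmarking.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

ACTIVATION = 1
INHIBITION = -1

#: KGML relation subtypes that carry a usable sign.
_KGML_SIGN = {
    "activation": ACTIVATION,
    "expression": ACTIVATION,
    "inhibition": INHIBITION,
    "repression": INHIBITION,
}


class NetworkError(ValueError):
    """Raised for malformed or inconsistent network inputs."""


class SignedDiGraph(nx.DiGraph):
    """Directed graph whose edges carry a ``sign`` attribute in {+1, -1}.

    Node identifiers are strings (gene symbols).  Optional graph attributes
    ``pathway_id`` and ``name`` identify the source pathway.
    """

    def add_signed_edge(self, source: str, target: str, sign: int) -> None:
        if sign not in (ACTIVATION, INHIBITION):
            raise NetworkError(f"edge sign must be +1 or -1, got {sign!r}")
        if source == target:
            logger.warning("self-loop on node %r", source)
        self.add_edge(source, target, sign=int(sign))

    def edge_sign(self, source: str, target: str) -> int:
        return self[source][target]["sign"]

    def signed_edges(self) -> set[tuple[str, str, int]]:
        """All edges as ``(source, target, sign)`` triples."""
        return {(u, v, d["sign"]) for u, v, d in self.edges(data=True)}

    def source_nodes(self) -> list[str]:
        """Nodes with in-degree zero, in sorted order."""
        return sorted(n for n in self.nodes if self.in_degree(n) == 0)

    def validate(self) -> None:
        for u, v, d in self.edges(data=True):
            if d.get("sign") not in (ACTIVATION, INHIBITION):
                raise NetworkError(f"edge ({u!r}, {v!r}) missing a valid sign")


# ---------------------------------------------------------------------------
# KGML
# ---------------------------------------------------------------------------


def _entry_label(entry: ET.Element) -> str:
    """Human-readable identifier for a KGML entry.

    Prefers the first token of the graphics name (the display symbol KEGG
    shows), falling back to the first token of the entry name attribute.
    """
    graphics = entry.find("graphics")
    if graphics is not None and graphics.get("name"):
        return graphics.get("name").split(",")[0].strip()
    return entry.get("name", "").split()[0]


def parse_kgml(source: str | Path, keep_compounds: bool = True) -> SignedDiGraph:
    """Parse a KGML (KEGG XML) pathway document into a signed graph.

    Gene and (optionally) compound entries become nodes; ``relation``
    elements with activation/expression subtypes become +1 edges and
    inhibition/repression subtypes -1 edges.  Relations without a signed
    subtype are dropped with a warning.  Group entries are expanded: edges to
    or from a group are duplicated to every member.

    Parameters
    ----------
    source
        Path to a KGML file, or a KGML document as a string.
    keep_compounds
        If False, compound entries are discarded along with their relations.
    """
    text = str(source)
    if "<" not in text:
        text = Path(source).read_text()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise NetworkError(f"malformed KGML XML: {exc}") from exc

    labels: dict[str, str] = {}      # entry id -> node label
    aliases: dict[str, list[str]] = {}
    groups: dict[str, list[str]] = {}  # group entry id -> member entry ids
    n_gene_entries = 0

    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if etype == "group":
            groups[eid] = [c.get("id") for c in entry.findall("component")]
            continue
        if etype == "gene":
            n_gene_entries += 1
        elif etype == "compound":
            if not keep_compounds:
                continue
        else:
            continue
        labels[eid] = _entry_label(entry)
        aliases[eid] = entry.get("name", "").split()

    if n_gene_entries == 0:
        raise NetworkError("KGML document contains no gene entries")

    g = SignedDiGraph(
        pathway_id=root.get("name", ""), name=root.get("title", "")
    )
    for eid, label in labels.items():
        g.add_node(label, aliases=" ".join(aliases[eid]))

    def expand(eid: str) -> list[str]:
        if eid in groups:
            return [labels[m] for m in groups[eid] if m in labels]
        if eid in labels:
            return [labels[eid]]
        return []

    for rel in root.findall("relation"):
        subtype_names = [s.get("name") for s in rel.findall("subtype")]
        signs = {_KGML_SIGN[s] for s in subtype_names if s in _KGML_SIGN}
        if not signs:
            logger.warning(
                "dropping unsigned relation %s -> %s (subtypes: %s)",
                rel.get("entry1"), rel.get("entry2"), subtype_names or "none",
            )
            continue
        # a relation annotated both ways is contradictory; keep activation
        sign = ACTIVATION if ACTIVATION in signs else INHIBITION
        for src in expand(rel.get("entry1")):
            for tgt in expand(rel.get("entry2")):
                g.add_signed_edge(src, tgt, sign)
    return g


# ---------------------------------------------------------------------------
# GraphML / SIF
# ---------------------------------------------------------------------------

_SIGNAL_TO_SIGN = {"a": ACTIVATION, "i": INHIBITION}
_SIGN_TO_SIGNAL = {ACTIVATION: "a", INHIBITION: "i"}


def read_graph(path: str | Path, format: str | None = None) -> SignedDiGraph:
    """Read a signed network from GraphML or SIF.

    GraphML edges carry the sign in a ``signal`` attribute (``a``/``i``);
    a missing attribute defaults to activation with a warning.  Undirected
    GraphML graphs and bidirectional edges are expanded into two directed
    edges.  SIF lines are ``source <a|i> target``.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "graphml":
        raw = nx.read_graphml(path)
        g = SignedDiGraph(**raw.graph)
        g.add_nodes_from(raw.nodes(data=True))
        directed = raw.is_directed()
        for u, v, d in raw.edges(data=True):
            if u not in raw or v not in raw:  # pragma: no cover - nx guards this
                raise NetworkError(f"dangling edge endpoint in ({u}, {v})")
            signal = d.get("signal")
            if signal is None:
                logger.warning("edge (%s, %s) missing 'signal'; assuming activation", u, v)
                sign = ACTIVATION
            elif signal in _SIGNAL_TO_SIGN:
                sign = _SIGNAL_TO_SIGN[signal]
            else:
                raise NetworkError(f"edge ({u}, {v}) has unknown signal {signal!r}")
            g.add_signed_edge(str(u), str(v), sign)
            if not directed:
                g.add_signed_edge(str(v), str(u), sign)
        return g
    if format == "sif":
        g = SignedDiGraph()
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3:
                raise NetworkError(f"{path}:{lineno}: expected 'src <a|i> tgt', got {line!r}")
            src, interaction, tgt = fields
            if interaction not in _SIGNAL_TO_SIGN:
                raise NetworkError(f"{path}:{lineno}: unknown interaction {interaction!r}")
            g.add_signed_edge(src, tgt, _SIGNAL_TO_SIGN[interaction])
        return g
    raise NetworkError(f"unknown network format {format!r}")


def write_graph(g: SignedDiGraph, path: str | Path, format: str | None = None) -> None:
    """Write a signed network to GraphML (``signal`` edge attribute) or SIF."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "graphml":
        out = nx.DiGraph(**{k: v for k, v in g.graph.items()})
        out.add_nodes_from(g.nodes(data=True))
        for u, v, d in g.edges(data=True):
            attrs = {k: v for k, v in d.items() if k != "sign"}
            out.add_edge(u, v, signal=_SIGN_TO_SIGNAL[d["sign"]], **attrs)
        nx.write_graphml(out, path)
    elif format == "sif":
        lines = [
            f"{u} {_SIGN_TO_SIGNAL[d['sign']]} {v}"
            for u, v, d in sorted(g.edges(data=True))
        ]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise NetworkError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# Topology statistics
# ---------------------------------------------------------------------------


def ancestors(g: SignedDiGraph, node: str) -> set[str]:
    """Nodes from which ``node`` is reachable, including ``node`` itself."""
    if node not in g:
        raise NetworkError(f"unknown node {node!r}")
    return nx.ancestors(g, node) | {node}


def total_ancestor_overlap(g: SignedDiGraph, node: str) -> int:
    """Sum of shared-ancestor counts over pairs of distinct regulators of ``node``.

    Ancestor sets are self-inclusive; nodes with in-degree <= 1 score 0.
    """
    if node not in g:
        raise NetworkError(f"unknown node {node!r}")
    regs = [u for u in g.predecessors(node) if u != node]
    anc = {u: ancestors(g, u) for u in regs}
    return sum(len(anc[u] & anc[v]) for u, v in combinations(regs, 2))


def longest_shortest_path(g: SignedDiGraph) -> int:
    """Maximum over reachable ordered node pairs of the directed shortest-path length."""
    if len(g) == 0:
        raise NetworkError("empty graph")
    best = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        longest = max(lengths.values(), default=0)
        best = max(best, longest)
    return best


# ---------------------------------------------------------------------------
# Synthetic networks
# ---------------------------------------------------------------------------


def generate_random_network(
    n_nodes: int,
    max_indegree: int = 3,
    p_inhibitory: float = 0.2,
    seed: int | np.random.Generator | None = None,
    p_source: float = 0.2,
) -> SignedDiGraph:
    """Generate a connected random signed DAG for benchmarking.

    Nodes are named ``g000 .. g{n-1}``.  The first node in a random
    topological order is a guaranteed source (in-degree 0) and each later
    node is an additional source with probability ``p_source`` (curated
    pathways typically have several receptor-like entry nodes); every other
    node receives 1..``max_indegree`` regulators drawn from earlier nodes.
    The graph is weakly connected and acyclic.  Edge signs are -1 with
    probability ``p_inhibitory``.
    """
    if n_nodes < 2:
        raise NetworkError("n_nodes must be >= 2")
    if not 1 <= max_indegree <= 3:
        raise NetworkError("max_indegree must be in 1..3")
    if not 0.0 <= p_inhibitory <= 1.0:
        raise NetworkError("p_inhibitory must be in [0, 1]")
    if not 0.0 <= p_source < 1.0:
        raise NetworkError("p_source must be in [0, 1)")
    rng = np.random.default_rng(seed)
    names = [f"g{i:03d}" for i in range(n_nodes)]
    order = list(rng.permutation(names))
    g = SignedDiGraph(name=f"random-{n_nodes}")
    g.add_nodes_from(names)

    def draw_sign() -> int:
        return INHIBITION if rng.random() < p_inhibitory else ACTIVATION

    sources = [order[0]]
    for i, node in enumerate(order[1:], start=1):
        if i < n_nodes - 1 and rng.random() < p_source:
            sources.append(node)
            continue
        k = int(rng.integers(1, min(max_indegree, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        for p in parents:
            g.add_signed_edge(order[int(p)], node, draw_sign())
    # keep the graph weakly connected: each stray component donates one of
    # its sources an edge into the main component; acyclicity is preserved
    # because the joined components share no edges.  When every candidate
    # target is at the in-degree cap, a parent is swapped out — preferring
    # parents that stay connected through other edges
    for _ in range(n_nodes):
        comps = sorted(nx.weakly_connected_components(g),
                       key=lambda c: order[0] not in c)
        if len(comps) == 1:
            break
        main, comp = set(comps[0]), comps[1]
        s = sorted(n for n in comp if g.in_degree(n) == 0)[0]
        under_cap = sorted(n for n in main if g.in_degree(n) < max_indegree)
        if under_cap:
            target = under_cap[int(rng.integers(len(under_cap)))]
        else:
            full = sorted(n for n in main if g.in_degree(n) > 0)
            target = full[int(rng.integers(len(full)))]
            preds = sorted(g.predecessors(target))
            safe = [p for p in preds if g.out_degree(p) > 1 or g.in_degree(p) > 0]
            old = (safe or preds)[int(rng.integers(len(safe or preds)))]
            g.remove_edge(old, target)
        g.add_signed_edge(s, target, draw_sign())
    if not nx.is_weakly_connected(g):  # pragma: no cover - safety net
        raise NetworkError("failed to build a connected network; try another seed")
    return g


def add_false_edges(
    g: SignedDiGraph,
    multiple: float,
    seed: int | np.random.Generator | None = None,
    p_inhibitory: float = 0.2,
) -> SignedDiGraph:
    """Return a copy of ``g`` with ``round(multiple * |E|)`` spurious edges added.

    New edges are sampled uniformly from the non-existing ordered pairs
    (excluding self-loops) with random signs; existing edges are untouched.
    """
    if multiple < 0:
        raise NetworkError("multiple must be >= 0")
    rng = np.random.default_rng(seed)
    n_new = round(multiple * g.number_of_edges())
    nodes = sorted(g.nodes)
    existing = set(g.edges)
    candidates = [
        (u, v) for u in nodes for v in nodes if u != v and (u, v) not in existing
    ]
    if n_new > len(candidates):
        raise NetworkError(
            f"cannot add {n_new} edges: only {len(candidates)} non-edges available"
        )
    out = g.copy()
    out.__class__ = SignedDiGraph
    idx = rng.choice(len(candidates), size=n_new, replace=False)
    for i in idx:
        u, v = candidates[int(i)]
        sign = INHIBITION if rng.random() < p_inhibitory else ACTIVATION
        out.add_signed_edge(u, v, sign)
    return out
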
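"""Directed weighted pathway-network data model, file I/O and summaries.

A :class:`PathwayNetwork` is a validated, directed graph whose nodes are the
molecular species of a signalling pathway (proteins, small molecules, or
terminal events) and whose arrows point downstream.  Edge weights are
dimensionless path costs: the unperturbed network carries a uniform weight
(default 10) on every edge, and inhibiting a protein raises the weight of its
outgoing edges.  Supported serialisations are a plain edge-list TSV, the
Cytoscape SIF dialect, and GraphML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from pathflux.errors import ConfigurationError, NetworkParseError, ValidationError

DEFAULT_WEIGHT = 10.0
WEIGHT_FLOOR = 10.0
WEIGHT_CAP = 99999.0

NODE_KINDS = ("protein", "small_molecule", "event")


@dataclass(frozen=True)
class NodeRecord:
    """One pathway species: a stable id, a display label, and a kind."""

    id: str
    label: str = ""
    kind: str = "protein"

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValidationError(
                f"node {self.id!r}: kind {self.kind!r} not one of {NODE_KINDS}"
            )
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass
class PathwayNetwork:
    """Directed weighted pathway graph with an optional explicit exit set.

    ``graph`` is a :class:`networkx.DiGraph` whose nodes carry ``label`` and
    ``kind`` attributes and whose edges carry a positive ``weight``.
    ``exit_nodes`` may be empty, in which case :func:`detect_exits` falls back
    to the sinks (out-degree 0 nodes).
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    exit_nodes: frozenset[str] = frozenset()
    weight_floor: float = WEIGHT_FLOOR
    weight_cap: float = WEIGHT_CAP

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        nodes: Iterable[NodeRecord | str],
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        exit_nodes: Iterable[str] = (),
        default_weight: float = DEFAULT_WEIGHT,
        weight_floor: float = WEIGHT_FLOOR,
        weight_cap: float = WEIGHT_CAP,
    ) -> "PathwayNetwork":
        g = nx.DiGraph()
        for n in nodes:
            rec = NodeRecord(n) if isinstance(n, str) else n
            if rec.id in g:
                raise ValidationError(f"duplicate node id {rec.id!r}")
            g.add_node(rec.id, label=rec.label, kind=rec.kind)
        for e in edges:
            u, v = e[0], e[1]
            w = float(e[2]) if len(e) > 2 else float(default_weight)
            for endpoint in (u, v):
                if endpoint not in g:
                    raise ValidationError(f"edge {u!r}->{v!r}: unknown node {endpoint!r}")
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            if g.has_edge(u, v):
                raise ValidationError(f"duplicate edge {u!r}->{v!r}")
            g.add_edge(u, v, weight=w)
        net = cls(
            graph=g,
            exit_nodes=frozenset(exit_nodes),
            weight_floor=weight_floor,
            weight_cap=weight_cap,
        )
        net.validate()
        return net

    # -- invariants --------------------------------------------------------

    def validate(self) -> "PathwayNetwork":
        for u, v, data in self.graph.edges(data=True):
            w = data.get("weight")
            if w is None or not math.isfinite(w) or w <= 0:
                raise ValidationError(f"edge {u!r}->{v!r}: nonpositive weight {w!r}")
            if not (self.weight_floor <= w <= self.weight_cap):
                raise ValidationError(
                    f"edge {u!r}->{v!r}: weight {w} outside "
                    f"[{self.weight_floor}, {self.weight_cap}]"
                )
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
        missing = self.exit_nodes - set(self.graph)
        if missing:
            raise ValidationError(f"exit nodes not in network: {sorted(missing)}")
        return self

    # -- views ---------------------------------------------------------------

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def node_record(self, node_id: str) -> NodeRecord:
        data = self.graph.nodes[node_id]
        return NodeRecord(node_id, data.get("label", node_id), data.get("kind", "protein"))

    def weights(self) -> dict[tuple[str, str], float]:
        return {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}

    def copy(self) -> "PathwayNetwork":
        return PathwayNetwork(
            graph=self.graph.copy(),
            exit_nodes=self.exit_nodes,
            weight_floor=self.weight_floor,
            weight_cap=self.weight_cap,
        )

    def with_weights(self, weights: Mapping[tuple[str, str], float]) -> "PathwayNetwork":
        """Return a copy whose edge weights are replaced by ``weights``."""
        out = self.copy()
        for (u, v), w in weights.items():
            if not out.graph.has_edge(u, v):
                raise ValidationError(f"no edge {u!r}->{v!r} to reweight")
            out.graph[u][v]["weight"] = float(w)
        return out.validate()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayNetwork):
            return NotImplemented
        return (
            set(self.graph.nodes) == set(other.graph.nodes)
            and all(
                self.node_record(n) == other.node_record(n) for n in self.graph.nodes
            )
            and self.weights() == other.weights()
            and self.exit_nodes == other.exit_nodes
        )


@dataclass(frozen=True)
class NetworkSummary:
    """Topological headline numbers of a pathway network.

    ``average_degree`` is 2E/N (each edge touches two nodes);
    ``average_shortest_path_length`` is the mean hop count over the ordered
    node pairs with a finite directed distance, computed on the unweighted
    view of the graph (NaN when no pair is reachable).
    """

    node_count: int
    edge_count: int
    average_degree: float
    average_shortest_path_length: float


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FORMATS = ("tsv", "sif", "graphml")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    if suffix in ("txt", "edges"):
        return "tsv"
    raise ConfigurationError(f"cannot infer network format from {path.name!r}")


def read_network(
    path: str | Path,
    format: str | None = None,
    default_weight: float = DEFAULT_WEIGHT,
) -> PathwayNetwork:
    """Read a pathway network from ``path``.

    TSV dialect: one edge per line as ``source<TAB>target[<TAB>weight]``;
    ``#`` starts a comment; directive lines ``%node <id> <kind> [label]`` and
    ``%exit <id>`` declare node kinds and explicit exits.  SIF dialect:
    ``source<TAB>interaction<TAB>target`` (interaction label ignored, weights
    default).  GraphML: ``weight`` edge attribute, ``kind``/``label`` node
    attributes, optional ``exits`` graph attribute (comma-separated ids).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ConfigurationError(f"unknown network format {fmt!r}")
    if not path.exists():
        raise NetworkParseError(f"{path}: no such file")
    if fmt == "graphml":
        return _read_graphml(path)
    return _read_edgelist(path, sif=(fmt == "sif"), default_weight=default_weight)


def _read_edgelist(path: Path, sif: bool, default_weight: float) -> PathwayNetwork:
    nodes: dict[str, NodeRecord] = {}
    edges: list[tuple[str, str, float]] = []
    seen: set[tuple[str, str]] = set()
    exits: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("%"):
            parts = line.split()
            if parts[0] == "%exit" and len(parts) == 2:
                exits.append(parts[1])
            elif parts[0] == "%node" and len(parts) >= 3:
                node_id, kind = parts[1], parts[2]
                label = " ".join(parts[3:]) or node_id
                try:
                    nodes[node_id] = NodeRecord(node_id, label, kind)
                except ValidationError as exc:
                    raise NetworkParseError(f"{path}:{lineno}: {exc}") from exc
            else:
                raise NetworkParseError(f"{path}:{lineno}: bad directive {line!r}")
            continue
        fields = line.split("\t")
        if sif:
            if len(fields) != 3:
                raise NetworkParseError(
                    f"{path}:{lineno}: SIF line needs 3 fields, got {len(fields)}"
                )
            u, _, v = fields
            w = default_weight
        else:
            if len(fields) not in (2, 3):
                raise NetworkParseError(
                    f"{path}:{lineno}: expected source<TAB>target[<TAB>weight]"
                )
            u, v = fields[0], fields[1]
            try:
                w = float(fields[2]) if len(fields) == 3 else default_weight
            except ValueError as exc:
                raise NetworkParseError(
                    f"{path}:{lineno}: bad weight {fields[2]!r}"
                ) from exc
        if u == v:
            raise NetworkParseError(f"{path}:{lineno}: self-loop on {u!r}")
        if (u, v) in seen:
            raise NetworkParseError(f"{path}:{lineno}: duplicate edge {u!r}->{v!r}")
        seen.add((u, v))
        for endpoint in (u, v):
            nodes.setdefault(endpoint, NodeRecord(endpoint))
        edges.append((u, v, w))
    for x in exits:
        if x not in nodes:
            raise NetworkParseError(f"{path}: %exit references unknown node {x!r}")
    try:
        return PathwayNetwork.from_records(nodes.values(), edges, exits)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _read_graphml(path: Path) -> PathwayNetwork:
    g = nx.read_graphml(path)
    if not g.is_directed():
        raise NetworkParseError(f"{path}: GraphML graph must be directed")
    nodes = [
        NodeRecord(str(n), d.get("label", str(n)), d.get("kind", "protein"))
        for n, d in g.nodes(data=True)
    ]
    edges = [
        (str(u), str(v), float(d.get("weight", DEFAULT_WEIGHT)))
        for u, v, d in g.edges(data=True)
    ]
    exits_attr = g.graph.get("exits", "")
    exits = [x for x in str(exits_attr).split(",") if x]
    return PathwayNetwork.from_records(nodes, edges, exits)


def write_network(net: PathwayNetwork, path: str | Path, format: str | None = None) -> None:
    """Serialise ``net`` so that :func:`read_network` round-trips it.

    SIF cannot carry weights, kinds or exit directives; writing SIF is only
    lossless for default-weight networks without explicit exits.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    net.validate()
    if fmt == "graphml":
        g = net.graph.copy()
        g.graph["exits"] = ",".join(sorted(net.exit_nodes))
        nx.write_graphml(g, path)
        return
    lines: list[str] = []
    if fmt == "tsv":
        for n in sorted(net.graph.nodes):
            rec = net.node_record(n)
            lines.append(f"%node {rec.id} {rec.kind} {rec.label}")
        for x in sorted(net.exit_nodes):
            lines.append(f"%exit {x}")
        for u, v in sorted(net.graph.edges):
            w = net.graph[u][v]["weight"]
            lines.append(f"{u}\t{v}\t{w!r}")
    elif fmt == "sif":
        for u, v in sorted(net.graph.edges):
            lines.append(f"{u}\tactivates\t{v}")
        isolated = sorted(n for n in net.graph.nodes if net.graph.degree(n) == 0)
        lines.extend(isolated)
    else:
        raise ConfigurationError(f"unknown network format {fmt!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize(net: PathwayNetwork) -> NetworkSummary:
    """Node/edge counts, average degree 2E/N, and mean directed hop distance.

    The hop distance is taken on the unweighted view of the graph (topology
    before any perturbation) and averaged over the ordered pairs (i, j),
    i != j, with a finite directed path; NaN when there is none.
    """
    n = net.node_count
    if n < 1:
        raise ValidationError("summary of an empty network")
    e = net.edge_count
    avg_degree = 2.0 * e / n
    total = 0
    pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(net.graph):
        total += sum(dists.values())  # d(i,i)=0 contributes nothing
        pairs += len(dists) - 1
    aspl = total / pairs if pairs else float("nan")
    return NetworkSummary(n, e, avg_degree, aspl)


def detect_exits(net: PathwayNetwork) -> frozenset[str]:
    """The explicit exit set if declared, else the sinks (out-degree 0).

    The exit nodes are where network flux terminates — the pathway's final
    biological event.  Raises :class:`ConfigurationError` when the network
    has neither an explicit exit set nor any sink.
    """
    if net.exit_nodes:
        return frozenset(net.exit_nodes)
    sinks = frozenset(n for n in net.graph.nodes if net.graph.out_degree(n) == 0)
    if not sinks:
        raise ConfigurationError(
            "network has no sink and no explicit exit set; declare exits "
            "(%exit directive or exit_nodes) to compute network flux"
        )
    return sinks
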
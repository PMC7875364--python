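"""Weighted-graph data model and file formats.

The graph is the context in which node subsets are scored: nodes are
molecular variables (metabolites, transcripts), edges carry co-perturbation
strength. Two weight conventions coexist:

* ``signed`` -- partial correlations as produced by the network learner;
  edge sign encodes direction of co-perturbation.
* ``diffusion`` -- nonnegative weights used by the probability walker;
  obtained from signed graphs by taking absolute values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "WeightedGraph",
    "NodeSubset",
    "GraphFormatError",
    "GraphValidationError",
    "read_graph",
    "write_graph",
    "to_diffusion_weights",
    "permute_node_labels",
]

SIGNED = "signed"
DIFFUSION = "diffusion"


class GraphFormatError(ValueError):
    """Raised when an input file cannot be parsed in the named dialect."""


class GraphValidationError(ValueError):
    """Raised when a graph violates the weighted-graph invariants."""


@dataclass(frozen=True)
class WeightedGraph:
    """An undirected weighted graph over named nodes.

    Parameters
    ----------
    node_names
        Ordered, unique node labels; their order fixes row/column order of
        ``adjacency`` and is the deterministic tie-break everywhere else.
    adjacency
        Symmetric ``N x N`` float matrix with zero diagonal.
    weight_convention
        ``"signed"`` or ``"diffusion"`` (nonnegative weights).
    """

    node_names: tuple[str, ...]
    adjacency: np.ndarray
    weight_convention: str = SIGNED

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_names", tuple(self.node_names))
        adj = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", adj)
        validate_graph(self)
        adj.setflags(write=False)

    # -- convenience -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.node_names)}

    def degree(self, node: str) -> float:
        i = self.index[node]
        return float(np.abs(self.adjacency[i]).sum())

    def edges(self) -> list[tuple[str, str, float]]:
        """Upper-triangle nonzero edges as (u, v, weight)."""
        iu, jv = np.nonzero(np.triu(self.adjacency, k=1))
        return [
            (self.node_names[i], self.node_names[j], float(self.adjacency[i, j]))
            for i, j in zip(iu.tolist(), jv.tolist())
        ]


@dataclass(frozen=True)
class NodeSubset:
    """A set S of node names to be scored against a companion graph."""

    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) < 1:
            raise GraphValidationError("node subset must contain at least one node")

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)

    def validate_against(self, g: WeightedGraph) -> None:
        unknown = self.members - set(g.node_names)
        if unknown:
            raise GraphValidationError(
                f"subset members absent from graph: {sorted(unknown)}"
            )


def validate_graph(g: WeightedGraph) -> None:
    """Assert the shared weighted-graph invariants; raise on violation."""
    names = g.node_names
    if len(names) == 0:
        raise GraphValidationError("graph has no nodes")
    if len(set(names)) != len(names):
        raise GraphValidationError("node names are not unique")
    if any(not isinstance(n, str) or n == "" for n in names):
        raise GraphValidationError("node names must be non-empty strings")
    adj = g.adjacency
    n = len(names)
    if adj.shape != (n, n):
        raise GraphValidationError(
            f"adjacency shape {adj.shape} does not match {n} node names"
        )
    if not np.all(np.isfinite(adj)):
        raise GraphValidationError("adjacency contains non-finite entries")
    if not np.allclose(adj, adj.T, atol=1e-12, rtol=0.0):
        raise GraphValidationError("adjacency is not symmetric")
    if np.any(np.diagonal(adj) != 0.0):
        raise GraphValidationError("adjacency diagonal must be exactly zero (no self-loops)")
    if g.weight_convention not in (SIGNED, DIFFUSION):
        raise GraphValidationError(
            f"unknown weight convention {g.weight_convention!r}"
        )
    if g.weight_convention == DIFFUSION and np.any(adj < 0.0):
        raise GraphValidationError("diffusion-convention graph has negative weights")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

EDGE_LIST = "edge_list"
GRAPHML = "graphml"
ADJACENCY_CSV = "adjacency_csv"


def read_graph(
    path: str | Path,
    format: str = EDGE_LIST,
    node_names: list[str] | None = None,
    weight_convention: str = SIGNED,
) -> WeightedGraph:
    """Read a weighted undirected graph.

    Formats: ``edge_list`` (3 tab-separated columns ``node_a  node_b  weight``,
    no header), ``graphml``, ``adjacency_csv`` (square matrix; first row and
    first column are node names). ``node_names`` optionally supplies the full
    node universe for edge lists (isolated nodes cannot otherwise appear).
    """
    path = Path(path)
    if format == EDGE_LIST:
        return _read_edge_list(path, node_names, weight_convention)
    if format == GRAPHML:
        return _read_graphml(path, weight_convention)
    if format == ADJACENCY_CSV:
        return _read_adjacency_csv(path, weight_convention)
    raise ValueError(f"unknown graph format {format!r}")


def _read_edge_list(
    path: Path, node_names: list[str] | None, weight_convention: str
) -> WeightedGraph:
    seen: dict[tuple[str, str], float] = {}
    order: list[str] = list(node_names or [])
    known = set(order)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            a, b, wtxt = parts
            try:
                w = float(wtxt)
            except ValueError as exc:
                raise GraphFormatError(
                    f"{path}:{lineno}: weight {wtxt!r} is not a number"
                ) from exc
            if a == b:
                raise GraphValidationError(f"{path}:{lineno}: self-loop on {a!r}")
            for name in (a, b):
                if name not in known:
                    known.add(name)
                    order.append(name)
            key = (min(a, b), max(a, b))
            if key in seen and seen[key] != w:
                raise GraphValidationError(
                    f"{path}:{lineno}: edge {a}-{b} given twice with unequal weights"
                    f" ({seen[key]} vs {w})"
                )
            seen[key] = w
    if not order:
        raise GraphFormatError(f"{path}: empty edge list and no node list given")
    idx = {name: i for i, name in enumerate(order)}
    adj = np.zeros((len(order), len(order)))
    for (a, b), w in seen.items():
        adj[idx[a], idx[b]] = w
        adj[idx[b], idx[a]] = w
    return WeightedGraph(tuple(order), adj, weight_convention)


def _read_graphml(path: Path, weight_convention: str) -> WeightedGraph:
    try:
        gx = nx.read_graphml(path)
    except Exception as exc:  # pragma: no cover - networkx error text varies
        raise GraphFormatError(f"{path}: not parseable as GraphML: {exc}") from exc
    if gx.is_directed():
        gx = gx.to_undirected()
    names = tuple(str(n) for n in gx.nodes())
    idx = {n: i for i, n in enumerate(names)}
    adj = np.zeros((len(names), len(names)))
    for u, v, data in gx.edges(data=True):
        if u == v:
            raise GraphValidationError(f"{path}: self-loop on {u!r}")
        w = float(data.get("weight", 1.0))
        adj[idx[str(u)], idx[str(v)]] = w
        adj[idx[str(v)], idx[str(u)]] = w
    return WeightedGraph(names, adj, weight_convention)


def _read_adjacency_csv(path: Path, weight_convention: str) -> WeightedGraph:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise GraphFormatError(f"{path}: empty file")
    header = rows[0][1:]
    n = len(header)
    if len(rows) != n + 1:
        raise GraphFormatError(
            f"{path}: {n} columns in header but {len(rows) - 1} data rows"
        )
    adj = np.zeros((n, n))
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != n + 1:
            raise GraphFormatError(
                f"{path}: line {r}: expected {n + 1} fields, got {len(row)}"
            )
        if row[0] != header[r - 2]:
            raise GraphFormatError(
                f"{path}: line {r}: row label {row[0]!r} does not match header"
                f" {header[r - 2]!r}"
            )
        try:
            adj[r - 2] = [float(x) for x in row[1:]]
        except ValueError as exc:
            raise GraphFormatError(f"{path}: line {r}: non-numeric entry") from exc
    return WeightedGraph(tuple(header), adj, weight_convention)


def write_graph(g: WeightedGraph, path: str | Path, format: str = EDGE_LIST) -> None:
    """Write a graph; writers mirror readers (edge lists at 12 sig. digits)."""
    path = Path(path)
    if format == EDGE_LIST:
        with open(path, "w") as fh:
            for u, v, w in g.edges():
                fh.write(f"{u}\t{v}\t{w:.12g}\n")
    elif format == GRAPHML:
        gx = nx.Graph()
        gx.add_nodes_from(g.node_names)
        for u, v, w in g.edges():
            gx.add_edge(u, v, weight=w)
        nx.write_graphml(gx, path)
    elif format == ADJACENCY_CSV:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([""] + list(g.node_names))
            for i, name in enumerate(g.node_names):
                writer.writerow([name] + [f"{x:.12g}" for x in g.adjacency[i]])
    else:
        raise ValueError(f"unknown graph format {format!r}")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def to_diffusion_weights(g: WeightedGraph) -> WeightedGraph:
    """Copy of ``g`` with absolute-value weights, for the probability walker.

    Diffusion splits probability proportionally by edge weight, which is
    ill-defined for signed partial correlations; magnitude encodes
    co-perturbation strength, so |w| is used. Sign is kept on the original
    graph for reporting.
    """
    if g.weight_convention == DIFFUSION:
        return g
    return WeightedGraph(g.node_names, np.abs(g.adjacency), DIFFUSION)


def permute_node_labels(g: WeightedGraph, rng_seed: int) -> WeightedGraph:
    """Shuffle node labels over an unchanged adjacency (seeded).

    This is the label-permutation negative control: the permuted graph has
    the same degree-sequence multiset and edge-weight multiset, but labels
    no longer sit on their learned positions.
    """
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(g.n_nodes)
    new_names = tuple(g.node_names[i] for i in perm)
    # adjacency values stay in place; only the labelling moves
    return WeightedGraph(new_names, g.adjacency.copy(), g.weight_convention)
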
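"""Probability diffusion and the diffusion-guided network walker.

Two pieces:

* :func:`diffuse_probability` spreads a probability mass ``p1`` from the
  node the walker currently stands on. Unvisited neighbors inherit shares
  proportional to edge weight; when a share's half exceeds ``threshold_diff``
  the half is diffused onward recursively (the neighbor being treated as
  visited for the remainder of that one diffusion call). A node with no
  unvisited neighbors spreads its mass uniformly over *all* unvisited nodes,
  so disconnected graphs still diffuse.

* :func:`rank_nodes` runs the walker: from each seed in the subset S it
  repeatedly diffuses from the current node, steps to the unvisited node of
  maximal accumulated probability, and stops once every member of S has been
  visited or ``num_misses`` consecutive non-members have been stepped on.

The walker's step sequence depends only on the graph and the seed -- the
subset S enters only through the stopping rule -- so the full visit ordering
from each seed can be computed once and reused for every subset
(:class:`RankingEngine`). This is what makes exhaustive enumeration over
many subsets affordable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import DIFFUSION, NodeSubset, WeightedGraph, to_diffusion_weights

__all__ = [
    "DiffusionState",
    "NodeRankings",
    "RankingEngine",
    "diffuse_probability",
    "rank_nodes",
    "default_num_misses",
    "DEFAULT_P1",
    "DEFAULT_THRESHOLD_DIFF",
]

DEFAULT_P1 = 1.0
DEFAULT_THRESHOLD_DIFF = 0.01


def default_num_misses(n_nodes: int) -> int:
    """ceil(log2 N): past that many consecutive misses the bitstring has
    already spent as many bits as one fixed-length node code, so continuing
    the walk cannot compress."""
    return max(1, math.ceil(math.log2(max(n_nodes, 2))))


@dataclass
class DiffusionState:
    """Per-node probability scores plus the walker's visited list.

    ``discarded`` accumulates mass lost at dead ends (a recursion reaching a
    node when every node of the graph is already visited); outside that case
    one diffusion call deposits exactly ``p1`` onto ``probs``.
    """

    probs: dict[str, float]
    visited: list[str] = field(default_factory=list)
    discarded: float = 0.0

    @classmethod
    def fresh(cls, g: WeightedGraph, start: str) -> "DiffusionState":
        return cls(probs={n: 0.0 for n in g.node_names}, visited=[start])

    def validate_against(self, g: WeightedGraph) -> None:
        if set(self.probs) != set(g.node_names):
            raise ValueError("probability map keys do not match graph nodes")
        if any(v < 0 for v in self.probs.values()):
            raise ValueError("negative probability score")
        if len(set(self.visited)) != len(self.visited):
            raise ValueError("visited list contains duplicates")


@dataclass(frozen=True)
class NodeRankings:
    """Per-seed visit sequences and the walker parameters that produced them."""

    walks: dict[str, tuple[str, ...]]
    p1: float
    threshold_diff: float
    num_misses: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": {
                "p1": self.p1,
                "threshold_diff": self.threshold_diff,
                "num_misses": self.num_misses,
            },
            "walks": {seed: list(walk) for seed, walk in self.walks.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "NodeRankings":
        payload = json.loads(Path(path).read_text())
        p = payload["params"]
        return cls(
            walks={s: tuple(w) for s, w in payload["walks"].items()},
            p1=p["p1"],
            threshold_diff=p["threshold_diff"],
            num_misses=p["num_misses"],
        )


# ---------------------------------------------------------------------------
# Probability diffusion
# ---------------------------------------------------------------------------

def diffuse_probability(
    p1: float,
    threshold_diff: float,
    start_node: str,
    state: DiffusionState,
    g: WeightedGraph,
) -> DiffusionState:
    """One diffusion call from ``start_node``; returns a new state.

    The caller's visited list is untouched: recursion marks nodes visited
    only for the duration of this call, otherwise diffusion-touched nodes
    could never be stepped to by the walker.
    """
    if p1 < 0:
        raise ValueError(f"p1 must be nonnegative, got {p1}")
    if threshold_diff <= 0:
        raise ValueError(f"threshold_diff must be positive, got {threshold_diff}")
    if start_node not in state.probs:
        raise KeyError(f"start node {start_node!r} not in graph")
    gd = g if g.weight_convention == DIFFUSION else to_diffusion_weights(g)
    idx = gd.index
    adj = gd.adjacency
    n = gd.n_nodes
    probs = np.array([state.probs[name] for name in gd.node_names])
    visited = np.zeros(n, dtype=bool)
    for name in state.visited:
        visited[idx[name]] = True

    discarded = _diffuse(
        p1, threshold_diff, idx[start_node], probs, visited, adj, n
    )
    new_probs = {name: float(probs[i]) for i, name in enumerate(gd.node_names)}
    return DiffusionState(
        probs=new_probs,
        visited=list(state.visited),
        discarded=state.discarded + discarded,
    )


def _diffuse(
    p1: float,
    threshold_diff: float,
    sn: int,
    probs: np.ndarray,
    visited: np.ndarray,
    adj: np.ndarray,
    n: int,
) -> float:
    """Recursive kernel; mutates probs/visited in place, returns mass
    discarded at dead ends."""
    weights = adj[sn]
    unvisited_nb = np.nonzero((weights > 0) & ~visited)[0]
    discarded = 0.0
    if unvisited_nb.size > 0:
        total_w = float(weights[unvisited_nb].sum())
        for i in unvisited_nb.tolist():
            inherited = p1 * float(weights[i]) / total_w
            probs[i] += inherited
            if inherited / 2.0 > threshold_diff:
                probs[i] -= inherited / 2.0
                visited[i] = True
                discarded += _diffuse(
                    inherited / 2.0, threshold_diff, i, probs, visited, adj, n
                )
    else:
        unvisited = np.nonzero(~visited)[0]
        if unvisited.size > 0:
            probs[unvisited] += p1 / unvisited.size
        else:
            discarded += p1  # dead end: nowhere left to deposit
    return discarded


# ---------------------------------------------------------------------------
# Diffusion-guided walker
# ---------------------------------------------------------------------------

class RankingEngine:
    """Caches the full (subset-independent) visit ordering from each seed.

    The walker's next step is a pure function of the graph and its visit
    history, so the complete ordering from a seed serves every subset and
    every ``num_misses``; subset-specific walks are cheap truncations.
    """

    def __init__(
        self,
        g: WeightedGraph,
        p1: float = DEFAULT_P1,
        threshold_diff: float = DEFAULT_THRESHOLD_DIFF,
        reset_probs_each_step: bool = False,
    ):
        if p1 < 0:
            raise ValueError(f"p1 must be nonnegative, got {p1}")
        if threshold_diff <= 0:
            raise ValueError(f"threshold_diff must be positive, got {threshold_diff}")
        gd = to_diffusion_weights(g)
        self.graph = gd
        self.p1 = p1
        self.threshold_diff = threshold_diff
        # default: probabilities accumulate across steps, so the walk is
        # guided by diffusion from all previously encountered nodes; the
        # alternative reading (fresh diffusion per step) stays available
        self.reset_probs_each_step = reset_probs_each_step
        self._adj = gd.adjacency
        self._names = gd.node_names
        self._idx = gd.index
        self._orders: dict[str, tuple[str, ...]] = {}

    def full_order(self, seed: str) -> tuple[str, ...]:
        """Complete visit ordering (length N) of the walker started at seed."""
        if seed not in self._idx:
            raise KeyError(f"seed {seed!r} not in graph")
        cached = self._orders.get(seed)
        if cached is not None:
            return cached
        n = len(self._names)
        probs = np.zeros(n)
        visited = np.zeros(n, dtype=bool)
        order = [self._idx[seed]]
        visited[self._idx[seed]] = True
        current = self._idx[seed]
        while len(order) < n:
            if self.reset_probs_each_step:
                probs = np.zeros(n)
            # diffusion sees the walk's visited list; its own marks are
            # call-local (copy), so touched nodes remain steppable
            _diffuse(
                self.p1,
                self.threshold_diff,
                current,
                probs,
                visited.copy(),
                self._adj,
                n,
            )
            # probs accumulate across steps; visited nodes are excluded from
            # the argmax and zeroed when stepped on (ties: node-name order)
            masked = np.where(visited, -np.inf, probs)
            current = int(np.argmax(masked))
            visited[current] = True
            probs[current] = 0.0
            order.append(current)
        walk = tuple(self._names[i] for i in order)
        self._orders[seed] = walk
        return walk

    def walk(self, seed: str, subset: frozenset[str] | set[str], num_misses: int) -> tuple[str, ...]:
        """Subset-specific walk: the full ordering truncated at the stopping
        rule (all of S visited, or ``num_misses`` consecutive misses)."""
        if num_misses < 1:
            raise ValueError(f"num_misses must be >= 1, got {num_misses}")
        order = self.full_order(seed)
        remaining = set(subset)
        remaining.discard(seed)
        if not remaining:
            return (seed,)
        misses = 0
        for pos in range(1, len(order)):
            node = order[pos]
            if node in remaining:
                remaining.remove(node)
                misses = 0
                if not remaining:
                    return order[: pos + 1]
            else:
                misses += 1
                if misses >= num_misses:
                    return order[: pos + 1]
        return order


def rank_nodes(
    g: WeightedGraph,
    s: NodeSubset,
    num_misses: int | None = None,
    p1: float = DEFAULT_P1,
    threshold_diff: float = DEFAULT_THRESHOLD_DIFF,
    engine: RankingEngine | None = None,
) -> NodeRankings:
    """Run the diffusion-guided walker from every member of S.

    Pass a shared :class:`RankingEngine` to reuse visit orderings across
    many subsets of the same graph.
    """
    s.validate_against(g)
    if engine is None:
        engine = RankingEngine(g, p1=p1, threshold_diff=threshold_diff)
    if num_misses is None:
        num_misses = default_num_misses(g.n_nodes)
    if num_misses < 1:
        raise ValueError(f"num_misses must be >= 1, got {num_misses}")
    walks = {
        seed: engine.walk(seed, s.members, num_misses)
        for seed in s.sorted_members()
    }
    return NodeRankings(
        walks=walks,
        p1=engine.p1,
        threshold_diff=engine.threshold_diff,
        num_misses=num_misses,
    )
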
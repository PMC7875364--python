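"""Seeded generators for synthetic networks and case/control profiles.

Two generators cover every input class the validation experiments need:

* random weighted networks at a stated connectedness (fraction of the
  N(N-1)/2 possible edges present), for the power/conservativeness studies;
* case/control profile matrices with an implanted single-factor covariance
  module mimicking an enzyme deficiency: substrate features load positively
  and product features negatively on a per-sample latent factor, so
  substrates co-vary positively with each other and negatively with
  products -- the structure a disease-specific partial-correlation learner
  should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import DIFFUSION, WeightedGraph
from .learning import ProfileMatrix

__all__ = [
    "FixtureSpec",
    "generate_random_network",
    "generate_profiles",
    "random_sparse_precision",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for the synthetic generators.

    Network side: ``n_nodes``, ``connectedness`` (fraction of possible
    edges), ``weight_range`` (uniform weights on (low, high], low >= 0 for
    diffusion graphs). Profile side: ``n_features``, per-class sample
    counts, the planted substrate/product feature sets and the factor
    loading ``effect_size`` (default 2.0: strong enough that module
    recovery succeeds at n = 100 per class).
    """

    n_nodes: int = 50
    connectedness: float = 0.1
    weight_range: tuple[float, float] = (0.01, 1.0)
    rng_seed: int = 0
    n_features: int = 30
    n_disease: int = 100
    n_control: int = 100
    substrates: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    effect_size: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.connectedness <= 1.0):
            raise ValueError(f"connectedness must be in [0,1], got {self.connectedness}")
        if self.weight_range[0] < 0:
            raise ValueError("weight_range low bound must be >= 0 for diffusion graphs")
        if set(self.substrates) & set(self.products):
            raise ValueError("substrate and product sets must be disjoint")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_random_network(spec: FixtureSpec) -> WeightedGraph:
    """Random network with an exact edge count.

    Exactly ``round_half_up(connectedness * N(N-1)/2)`` distinct undirected
    edges are sampled uniformly without replacement; weights are uniform on
    ``weight_range`` (left-open). The graph may be disconnected -- the
    walker's uniform fallback handles isolated components.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_nodes
    names = tuple(f"n{i:03d}" for i in range(n))
    possible = n * (n - 1) // 2
    n_edges = _round_half_up(spec.connectedness * possible)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    chosen = rng.choice(possible, size=n_edges, replace=False)
    lo, hi = spec.weight_range
    adj = np.zeros((n, n))
    for c in chosen.tolist():
        i, j = pairs[c]
        w = hi - rng.random() * (hi - lo)  # uniform on (lo, hi]
        adj[i, j] = adj[j, i] = w
    return WeightedGraph(names, adj, DIFFUSION)


def generate_profiles(spec: FixtureSpec) -> ProfileMatrix:
    """Case/control feature-by-sample matrix with a planted latent module.

    Controls are i.i.d. standard normal per feature. Each disease sample
    draws a latent factor l ~ N(0,1); substrate features receive
    ``+effect_size * l``, product features ``-effect_size * l``, off-module
    features are untouched. Under this model the substrate-substrate
    correlation tends to effect^2 / (1 + effect^2) and substrate-product
    correlation to its negative.
    """
    if not (set(spec.substrates) or set(spec.products)):
        pass  # a pure-null fixture is legitimate (effect plays no role)
    rng = np.random.default_rng(spec.rng_seed)
    features = [f"f{i:03d}" for i in range(spec.n_features)]
    known = set(features)
    missing = [f for f in (*spec.substrates, *spec.products) if f not in known]
    if missing:
        raise ValueError(f"module features outside the feature universe: {missing}")
    n_total = spec.n_disease + spec.n_control
    values = rng.standard_normal((spec.n_features, n_total))
    sub_idx = [features.index(f) for f in spec.substrates]
    prod_idx = [features.index(f) for f in spec.products]
    latent = rng.standard_normal(spec.n_disease)
    for i in sub_idx:
        values[i, : spec.n_disease] += spec.effect_size * latent
    for i in prod_idx:
        values[i, : spec.n_disease] -= spec.effect_size * latent
    samples = [f"case{i:03d}" for i in range(spec.n_disease)] + [
        f"ctrl{i:03d}" for i in range(spec.n_control)
    ]
    labels = ["disease"] * spec.n_disease + ["control"] * spec.n_control
    return ProfileMatrix(
        feature_names=tuple(features),
        sample_names=tuple(samples),
        values=values,
        class_labels=tuple(labels),
        scale="zscore",
    )


def random_sparse_precision(
    p: int, density: float = 0.1, rng_seed: int = 0, strength: float = 0.4
) -> np.ndarray:
    """Random sparse positive-definite precision matrix.

    Off-diagonal entries are placed on a uniform random support (fraction
    ``density`` of the p(p-1)/2 pairs) with magnitude ``strength`` and
    random sign; the diagonal is then lifted to make the matrix strictly
    diagonally dominant (hence positive definite). Used as ground truth in
    edge-support recovery simulations.
    """
    rng = np.random.default_rng(rng_seed)
    theta = np.zeros((p, p))
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    n_edges = int(round(density * len(pairs)))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    for c in chosen.tolist():
        i, j = pairs[c]
        w = strength * rng.choice([-1.0, 1.0])
        theta[i, j] = theta[j, i] = w
    np.fill_diagonal(theta, np.abs(theta).sum(axis=1) + 1.0)
    return theta
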
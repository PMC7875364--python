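"""Compression-based scoring of node subsets.

A subset S of a graph with N nodes can always be written down with the
uniform "null" code in ``I0 = log2 C(N, k)`` bits. The alternative code
exploits connectedness: one member (the seed) is spelled out in ``log2 N``
bits, the walker's visit order is then annotated with one membership bit per
step (the bitstring B, F ones), and members the walk never reached are
spelled out in ``log2 N`` bits each:

    IA = (|S| - F) * log2 N + |B|

By the algorithmic-significance argument, achieving ``d = I0 - IA`` bits of
compression under the null has probability below ``2^-d``, so
``min(1, 2^-d)`` is a p-value upper bound -- no permutation testing needed.
The bound is meaningful only while the code is (sub-)uniquely decodable,
which the Kraft--McMillan sum test exercises on small graphs.

Code lengths are kept real-valued (log2 N is not ceiled), making bits
continuous; the implied sub-probabilities still satisfy Kraft.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .diffusion import NodeRankings
from .graph import NodeSubset

__all__ = [
    "SubsetEncoding",
    "CTDResult",
    "null_encoding_length",
    "encode_subset",
    "p_value_bound",
    "bits_threshold",
    "find_best_subset",
    "adjust_fdr",
]

LOG2E = math.log2(math.e)


def null_encoding_length(N: int, k: int) -> float:
    """log2 C(N, k): bits to name one size-k subset under the uniform code."""
    if not (1 <= k <= N):
        raise ValueError(f"need 1 <= k <= N, got k={k}, N={N}")
    if N <= 10_000:
        # exact integer binomial: keeps k=1 and k=N code lengths exact
        return math.log2(math.comb(N, k))
    # log-gamma for scales where the exact binomial gets expensive
    return float(
        (gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1)) * LOG2E
    )


def p_value_bound(d: float) -> float:
    """Upper bound min(1, 2^-d) on the p-value of d bits of compression."""
    if not math.isfinite(d):
        raise ValueError(f"d must be finite, got {d}")
    return min(1.0, 2.0 ** (-d))


def bits_threshold(alpha: float) -> float:
    """Bits of compression needed for significance at level alpha: -log2(alpha)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return -math.log2(alpha)


@dataclass(frozen=True)
class SubsetEncoding:
    """The alternative-code description of one subset from one seed."""

    seed: str
    bitstring: str
    F: int
    I0: float
    IA: float
    d: float
    p_bound: float
    found_nodes: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "bitstring": self.bitstring,
            "F": self.F,
            "I0_bits": self.I0,
            "IA_bits": self.IA,
            "d_bits": self.d,
            "p_bound": self.p_bound,
            "found_nodes": list(self.found_nodes),
        }


@dataclass(frozen=True)
class CTDResult:
    """Full scoring of a subset: all per-seed encodings, the best one, and
    the optimal highly connected sub-subset with its own score."""

    subset: tuple[str, ...]
    encodings: tuple[SubsetEncoding, ...]
    best: SubsetEncoding
    optimal_subset: tuple[str, ...]
    optimal_encoding: SubsetEncoding
    params: dict

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "subset": list(self.subset),
            "best": self.best.to_dict(),
            "optimal_subset": list(self.optimal_subset),
            "optimal": self.optimal_encoding.to_dict(),
            "per_seed": [e.to_dict() for e in self.encodings],
            "params": self.params,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _encode_one_walk(
    walk: tuple[str, ...], members: frozenset[str], N: int, k: int
) -> SubsetEncoding:
    seed = walk[0]
    bits = []
    found = []
    for node in walk[1:]:
        if node in members:
            bits.append("1")
            found.append(node)
        else:
            bits.append("0")
    B = "".join(bits)
    F = len(found)
    IA = (k - F) * math.log2(N) + len(B)
    I0 = null_encoding_length(N, k)
    d = I0 - IA
    return SubsetEncoding(
        seed=seed,
        bitstring=B,
        F=F,
        I0=I0,
        IA=IA,
        d=d,
        p_bound=p_value_bound(d),
        found_nodes=tuple(found),
    )


def encode_subset(
    s: NodeSubset, rankings: NodeRankings, N: int
) -> list[SubsetEncoding]:
    """Encode S from every seed; the minimal-IA encoding is the score.

    The walk from a seed is annotated with one bit per post-seed step
    (1 = member of S). A walk stopped by the miss limit ends in a zero run,
    which stays in |B|: the decoder finds the block boundary by counting
    that same shared run length. A walk stopped because all of S was found
    ends at its final '1'.
    """
    members = s.members
    k = s.size
    if k > N / 5:
        warnings.warn(
            f"subset size {k} is not small relative to N={N}; "
            "p-value bounds are only valid for k << N",
            stacklevel=2,
        )
    missing = sorted(m for m in members if m not in rankings.walks)
    if missing:
        raise ValueError(
            f"no walk available for seeds {missing}; run rank_nodes first"
        )
    encodings = [
        _encode_one_walk(rankings.walks[seed], members, N, k)
        for seed in sorted(members)
    ]
    return encodings


def best_encoding(encodings: list[SubsetEncoding]) -> SubsetEncoding:
    """Minimal-IA encoding; ties broken by seed name order."""
    return min(encodings, key=lambda e: (e.IA, e.seed))


def find_best_subset(
    s: NodeSubset,
    rankings: NodeRankings,
    N: int,
    params: dict | None = None,
) -> CTDResult:
    """Score S and locate its most significant highly connected sub-subset.

    Candidates are, per seed walk, {seed} plus the first j found nodes
    (j = 1..F): the bitstring truncated at its j-th '1' with the null length
    for a size-(j+1) subset. The candidate minimizing the p-value bound
    wins; ties go to the smaller subset, then node-name order.
    """
    encodings = encode_subset(s, rankings, N)
    best = best_encoding(encodings)
    k = s.size

    if k == 1:
        warnings.warn("singleton subset: no connectedness to score", stacklevel=2)
        trivial = encodings[0]
        return CTDResult(
            subset=tuple(s.sorted_members()),
            encodings=tuple(encodings),
            best=best,
            optimal_subset=tuple(s.sorted_members()),
            optimal_encoding=trivial,
            params=params or {},
        )

    candidates: list[tuple[float, int, tuple[str, ...], SubsetEncoding]] = []
    for enc in encodings:
        walk = rankings.walks[enc.seed]
        ones = 0
        found: list[str] = []
        for pos, node in enumerate(walk[1:], start=1):
            if node not in s.members:
                continue
            ones += 1
            found.append(node)
            sub_size = ones + 1  # seed + found prefix
            B_len = pos  # bitstring truncated at the j-th '1'
            IA = math.log2(N) + B_len  # only the seed is fixed-length coded
            I0 = null_encoding_length(N, sub_size)
            d = I0 - IA
            sub_nodes = tuple(sorted([enc.seed] + found))
            cand_enc = SubsetEncoding(
                seed=enc.seed,
                bitstring=enc.bitstring[:B_len],
                F=ones,
                I0=I0,
                IA=IA,
                d=d,
                p_bound=p_value_bound(d),
                found_nodes=tuple(found),
            )
            candidates.append((cand_enc.p_bound, sub_size, sub_nodes, cand_enc))

    if not candidates:
        # no walk ever found a second member: fall back to the full subset
        return CTDResult(
            subset=tuple(s.sorted_members()),
            encodings=tuple(encodings),
            best=best,
            optimal_subset=tuple(s.sorted_members()),
            optimal_encoding=best,
            params=params or {},
        )
    p, size, nodes, enc = min(candidates, key=lambda c: (c[0], c[1], c[2]))
    return CTDResult(
        subset=tuple(s.sorted_members()),
        encodings=tuple(encodings),
        best=best,
        optimal_subset=nodes,
        optimal_encoding=enc,
        params=params or {},
    )


def adjust_fdr(p_bounds: list[float]) -> list[float]:
    """Benjamini--Hochberg step-up adjustment (order-preserving)."""
    if len(p_bounds) == 0:
        return []
    if any(not (0.0 < p <= 1.0) for p in p_bounds):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p_bounds, method="fdr_bh")
    return [float(p) for p in adjusted]
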
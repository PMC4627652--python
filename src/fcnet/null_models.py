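"""Degree-preserving random networks and efficiency normalization.

Small-worldness in the efficiency formalism is judged against degree-matched
random graphs: E_loc(real)/E_loc(random) > 1 with E_glob(real)/E_glob(random)
close to 1.  Nulls are built by Markov-chain double-edge swaps, which preserve
the degree sequence exactly; connectedness is not enforced because the
efficiency formalism handles disconnection gracefully.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_metrics import GlobalMetrics, global_efficiency, local_efficiency
from .net_build import BinaryNetwork

__all__ = [
    "NullEnsemble",
    "rewire_degree_preserving",
    "null_efficiencies",
    "normalize",
]

DEFAULT_SWAP_FACTOR = 10


def _swap_loop(adjb, edges, picks, flips):
    """Sequential double-edge-swap chain; adjb and edges are updated in place.

    Returns the number of accepted swaps.  Kept free of Python objects so it
    can be JIT-compiled.
    """
    accepted = 0
    for t in range(picks.shape[0]):
        e1 = picks[t, 0]
        e2 = picks[t, 1]
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if flips[t]:
            c, d = d, c
        if a == d or c == b:
            continue
        if adjb[a, d] or adjb[c, b]:
            continue
        adjb[a, b] = adjb[b, a] = False
        adjb[c, d] = adjb[d, c] = False
        adjb[a, d] = adjb[d, a] = True
        adjb[c, b] = adjb[b, c] = True
        if a < d:
            edges[e1, 0], edges[e1, 1] = a, d
        else:
            edges[e1, 0], edges[e1, 1] = d, a
        if c < b:
            edges[e2, 0], edges[e2, 1] = c, b
        else:
            edges[e2, 0], edges[e2, 1] = b, c
        accepted += 1
    return accepted


try:  # JIT the chain when numba is available; semantics are identical
    from numba import njit

    _swap_loop = njit(cache=False)(_swap_loop)
except ImportError:  # pragma: no cover
    pass


@dataclass
class NullEnsemble:
    """Mean efficiencies over a seeded ensemble of rewired graphs."""

    source_sparsity: float
    n_random: int
    mean_e_glob_random: float
    mean_e_loc_random: float
    rng_seed: int | None = None


def rewire_degree_preserving(
    net: BinaryNetwork,
    n_swaps: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> BinaryNetwork:
    """Randomize a graph by repeated double-edge swaps.

    Picks two edges (a,b), (c,d) uniformly and rewires to (a,d), (c,b) unless
    that would create a self-loop or duplicate edge (such attempts are
    skipped).  The degree sequence, node count and edge count are preserved
    exactly.  Default attempt budget is 10x the edge count, a standard mixing
    heuristic for this chain.
    """
    adj = net.adjacency.copy()
    iu, ju = np.nonzero(np.triu(adj, k=1))
    n_edges = iu.size
    if n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    if n_swaps is None:
        n_swaps = DEFAULT_SWAP_FACTOR * n_edges
    rng = np.random.default_rng(seed)
    edges = np.stack([iu, ju], axis=1).astype(np.int64)
    picks = rng.integers(0, n_edges, size=(n_swaps, 2))
    flips = rng.integers(0, 2, size=n_swaps).astype(bool)
    adjb = adj.astype(bool)
    _swap_loop(adjb, edges, picks, flips)
    return BinaryNetwork(adjacency=adjb.astype(np.uint8), sparsity=net.sparsity)


def null_efficiencies(
    net: BinaryNetwork,
    n_random: int = 100,
    seed: int | np.random.SeedSequence | None = None,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
) -> NullEnsemble:
    """Mean global/local efficiency over n_random independently rewired graphs.

    Each null draws its own child stream from the master seed, so the whole
    ensemble is reproducible bit-exactly and safe to parallelize.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_random)
    n_swaps = swap_factor * net.n_edges
    eg = np.empty(n_random)
    el = np.empty(n_random)
    for i, child in enumerate(children):
        null = rewire_degree_preserving(net, n_swaps=n_swaps, seed=child)
        eg[i] = global_efficiency(null)
        el[i] = local_efficiency(null)
    return NullEnsemble(
        source_sparsity=net.sparsity,
        n_random=n_random,
        mean_e_glob_random=float(eg.mean()),
        mean_e_loc_random=float(el.mean()),
        rng_seed=ss.entropy if isinstance(ss.entropy, int) else None,
    )


def normalize(real: GlobalMetrics, null: NullEnsemble) -> GlobalMetrics:
    """Divide real efficiencies by the null-ensemble means."""
    if null.mean_e_glob_random <= 0 or null.mean_e_loc_random <= 0:
        raise ValueError("null ensemble mean efficiency is zero; network degenerate")
    return GlobalMetrics(
        e_glob=real.e_glob,
        e_loc=real.e_loc,
        e_glob_norm=real.e_glob / null.mean_e_glob_random,
        e_loc_norm=real.e_loc / null.mean_e_loc_random,
    )
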
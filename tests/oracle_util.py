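"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions, by direct enumeration,
without reusing the package's incremental or vectorised code paths.  The
only package types used are the graph containers.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np

from mcse.network_io import PPINetwork


def random_ppi(rng: np.random.Generator, n: int, p: float) -> PPINetwork:
    """G(n, p) random graph over string vertex IDs (isolated vertices kept)."""
    net = PPINetwork()
    names = [f"v{i:02d}" for i in range(n)]
    for v in names:
        net.add_vertex(v)
    for u, v in combinations(names, 2):
        if rng.random() < p:
            net.add_edge(u, v)
    return net


def brute_ecv(net: PPINetwork, u: str, v: str) -> float:
    """ECV by literal term-by-term evaluation of the definition."""
    nu = net.neighbors(u)
    nv = net.neighbors(v)
    common = nu & nv
    num = sum(net.base_weight(u, k) for k in common) * sum(
        net.base_weight(v, k) for k in common
    )
    den = sum(net.base_weight(u, s) for s in nu) * sum(
        net.base_weight(v, t) for t in nv
    )
    return num / den


def brute_ecv_unweighted(net: PPINetwork, u: str, v: str) -> float:
    """|I(u,v)|^2 / (deg(u)*deg(v)) — valid when all base weights are 1."""
    common = net.neighbors(u) & net.neighbors(v)
    return len(common) ** 2 / (net.degree(u) * net.degree(v))


def brute_f(v: str, H: set[str], weight_of) -> float:
    """Cluster property by summing weight_of(v, u) over all u in H adjacent."""
    return sum(weight_of(v, u) for u in H)


def brute_lambda(net: PPINetwork, H: set[str], weight_fn) -> float:
    """lambda(H) by summing per-vertex weighted in/out degrees directly.

    ``weight_fn(u, v)`` returns the weight to use for an existing edge.
    """
    in_sum = 0.0
    out_sum = 0.0
    for v in H:
        for u in net.neighbors(v):
            w = weight_fn(v, u)
            if u in H:
                in_sum += w
            else:
                out_sum += w
    if out_sum == 0:
        return math.inf
    return in_sum / out_sum


def brute_density(net: PPINetwork, H: set[str]) -> float:
    """Induced edge density by pair enumeration."""
    members = sorted(H)
    m = sum(1 for a, b in combinations(members, 2) if net.has_edge(a, b))
    n = len(members)
    return 2 * m / (n * (n - 1))


def simulate_expansion(net: PPINetwork, weight_fn, seed_edge: tuple[str, str],
                       lambda_th: float, covered: set[str]):
    """From-scratch re-simulation of one seed expansion.

    Recomputes the cluster property of every outside vertex and lambda(H)
    from the definitions at every step (no incremental state).  Returns
    ``(status, members, final_lambda)`` with status "output"/"abandoned".
    """
    H = set(seed_edge)
    while True:
        if len(H & covered) > len(H) / 2:
            return "abandoned", frozenset(H), None
        lam = brute_lambda(net, H, weight_fn)
        if lam >= lambda_th:
            return "output", frozenset(H), lam
        candidates = {}
        for v in sorted(net.vertices - H):
            f = sum(weight_fn(v, u) for u in net.neighbors(v) if u in H)
            if f > 0:
                candidates[v] = f
        if not candidates:
            return "output", frozenset(H), math.inf
        best_f = max(candidates.values())
        chosen = min(v for v, f in candidates.items() if f == best_f)
        H.add(chosen)


def nx_graph(net: PPINetwork) -> nx.Graph:
    return net.graph
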
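"""λ-module seed expansion: the core complex-detection algorithm.

Each seed edge is grown greedily into a *λ-module*.  For a vertex set H,

    λ(H) = Σ_{v∈H} d_in(v, H)  /  Σ_{v∈H} d_out(v, H)

where d_in sums the weights of v's edges to other members of H (so every
internal edge is counted from both ends) and d_out sums the weights of
v's edges leaving H.  A subgraph with no outgoing edges has λ = +∞.  H is
a λ-module for threshold λ_th when λ(H) ≥ λ_th: densely connected inside
relative to its boundary.  Small λ_th stops expansion early (small, tight
complexes); large λ_th grows the same seeds into larger supercomplexes,
which is what produces the hierarchy across thresholds.

Growth adds, one at a time, the outside vertex with the highest *cluster
property* f(v, H) — the summed weight of its edges into H — restricting
candidates to f > 0 so every intermediate set stays connected.  The λ test
runs before each growth step, starting at the 2-vertex seed, so a pair
whose boundary is already weak enough can be emitted as a complex.

Overlap control: before the λ test (on the seed pair and after every
addition) the cluster is abandoned if strictly more than half of its
vertices already belong to previously output complexes.  Abandoned
clusters mark nothing and do not prune the seed queue.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

from .network_io import PPINetwork, ProteinList
from .seeding import SeedEdge, SeedQueue, prune_queue, select_seeds
from .weighting import DEFAULT_ALPHA, WeightedPPINetwork, build_weighted_network

logger = logging.getLogger("mcse")

__all__ = [
    "Cluster",
    "ComplexSet",
    "cluster_property",
    "lambda_value",
    "expand_seed",
    "mcse",
]


@dataclass(frozen=True)
class Cluster:
    """One expansion outcome: an output complex or an abandoned cluster."""

    members: frozenset[str]
    seed: SeedEdge
    final_lambda: float | None  # λ at emission (may be math.inf); None if abandoned
    status: str  # "output" | "abandoned"

    def sorted_members(self) -> list[str]:
        return sorted(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ComplexSet:
    """Ordered output of one run at a single λ_th, with its configuration."""

    complexes: list[Cluster]
    lambda_th: float
    alpha: float = DEFAULT_ALPHA
    strategy: str = "union"
    rng_seed: int | None = None
    unweighted_expansion: bool = False

    def member_sets(self) -> list[set[str]]:
        return [set(c.members) for c in self.complexes]

    def covered_vertices(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c.members
        return out

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)


def cluster_property(
    v: str, H: Iterable[str], wnet: WeightedPPINetwork, use_base: bool = False
) -> float:
    """f(v, H): summed weight of edges between outside vertex v and H."""
    members = set(H)
    if v in members:
        raise ValueError(f"cluster_property requires v not in H (v={v!r})")
    net = wnet.network
    return sum(
        wnet.edge_weight(v, u, base=use_base)
        for u in net.neighbors(v)
        if u in members
    )


def lambda_value(
    H: Iterable[str], wnet: WeightedPPINetwork, use_base: bool = False
) -> float:
    """λ(H) = total weighted in-degree / total weighted out-degree.

    Returns ``math.inf`` when H has no outgoing edges.  Requires |H| ≥ 2.
    """
    members = set(H)
    if len(members) < 2:
        raise ValueError("lambda_value requires at least 2 vertices")
    net = wnet.network
    in_sum = 0.0
    out_sum = 0.0
    for v in members:
        for u in net.neighbors(v):
            w = wnet.edge_weight(v, u, base=use_base)
            if u in members:
                in_sum += w
            else:
                out_sum += w
    if out_sum == 0.0:
        return math.inf
    return in_sum / out_sum


def expand_seed(
    seed: SeedEdge,
    wnet: WeightedPPINetwork,
    lambda_th: float,
    covered: Iterable[str] = (),
    use_base: bool = False,
) -> Cluster:
    """Grow one seed edge into a λ-module (or abandon it).

    Maintains the λ numerator/denominator and the frontier cluster
    properties incrementally; ties in f are broken toward the
    lexicographically smallest vertex ID (logged when actually broken).
    """
    if lambda_th <= 0:
        raise ValueError(f"lambda_th must be > 0, got {lambda_th}")
    covered = set(covered)
    net = wnet.network
    a, b = seed.edge
    H: set[str] = {a, b}

    w_ab = wnet.edge_weight(a, b, base=use_base)
    in_sum = 2.0 * w_ab
    out_sum = 0.0
    frontier: dict[str, float] = {}
    for v in (a, b):
        for u in net.neighbors(v):
            if u in H:
                continue
            w = wnet.edge_weight(v, u, base=use_base)
            out_sum += w
            frontier[u] = frontier.get(u, 0.0) + w
    n_covered = len(H & covered)

    while True:
        if n_covered > len(H) / 2:
            return Cluster(members=frozenset(H), seed=seed,
                           final_lambda=None, status="abandoned")
        lam = math.inf if out_sum <= 0.0 else in_sum / out_sum
        if lam >= lambda_th:
            return Cluster(members=frozenset(H), seed=seed,
                           final_lambda=lam, status="output")
        if not frontier:
            # connected component exhausted: no outside neighbour remains
            return Cluster(members=frozenset(H), seed=seed,
                           final_lambda=math.inf, status="output")
        best_f = max(frontier.values())
        best = [v for v, f in frontier.items() if f == best_f]
        if len(best) > 1:
            logger.debug(
                "tie in cluster property f=%.6g among %s; choosing %s",
                best_f, sorted(best), min(best),
            )
        chosen = min(best)

        # incremental update for adding `chosen`
        H.add(chosen)
        del frontier[chosen]
        if chosen in covered:
            n_covered += 1
        for u in net.neighbors(chosen):
            w = wnet.edge_weight(chosen, u, base=use_base)
            if u in H:
                in_sum += 2.0 * w
                out_sum -= w
            else:
                out_sum += w
                frontier[u] = frontier.get(u, 0.0) + w


def mcse(
    network: PPINetwork,
    essentials: ProteinList | Iterable[str] = (),
    lambda_th: float = 0.5,
    alpha: float = DEFAULT_ALPHA,
    strategy: str = "union",
    rng_seed: int | None = None,
    unweighted_expansion: bool = False,
) -> ComplexSet:
    """Run the full pipeline: weight, seed, expand, output.

    Stages: (1) re-weight the network by the ECV transform; (2) build the
    seed queue from high-weight and essential edges; (3) repeatedly pop
    the head seed and expand it against the vertices covered by complexes
    already output; (4) after each output complex, mark its members and
    drop queue entries touching them.

    ``unweighted_expansion=True`` keeps the weighted seed queue but runs
    f and λ on base weights (the expansion-ablation mode).
    """
    wnet = build_weighted_network(network, alpha=alpha)
    queue = select_seeds(wnet, essentials, strategy=strategy, rng_seed=rng_seed)
    covered: set[str] = set()
    out: list[Cluster] = []
    entries = list(queue.entries)
    n_abandoned = 0
    while entries:
        seed = entries.pop(0)
        cluster = expand_seed(seed, wnet, lambda_th, covered,
                              use_base=unweighted_expansion)
        if cluster.status == "output":
            out.append(cluster)
            covered |= cluster.members
            entries = prune_queue(
                SeedQueue(entries=entries, strategy=strategy), covered
            ).entries
        else:
            n_abandoned += 1
    logger.info(
        "mcse: %d complexes output, %d expansions abandoned (lambda_th=%g)",
        len(out), n_abandoned, lambda_th,
    )
    return ComplexSet(
        complexes=out,
        lambda_th=lambda_th,
        alpha=alpha,
        strategy=strategy,
        rng_seed=rng_seed,
        unweighted_expansion=unweighted_expansion,
    )
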
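"""Edge clustering value (ECV) and the derived edge-weight transform.

The ECV of an edge <u, v> measures how strongly the edge is embedded in a
locally dense neighbourhood.  With base weights w and common-neighbour set
I(u,v) = N(u) ∩ N(v):

    ECV(u, v) = (Σ_{k∈I} w(u,k) · Σ_{k∈I} w(v,k))
                / (Σ_{s∈N(u)} w(u,s) · Σ_{t∈N(v)} w(v,t))

On an unweighted network this reduces to |I|² / (deg(u)·deg(v)) and always
lies in [0, 1].  N(u) is the full neighbour set of u, so v ∈ N(u): only the
denominator is affected since I never contains an endpoint in a simple
graph.  Edges in dense complexes have high ECV; bridges have ECV 0.

Each edge is then re-weighted as

    w'(u, v) = α + (1 − α) · ECV(u, v) / ECV_avg

where ECV_avg is the arithmetic mean ECV over all edges and α ∈ [0, 1) is
the floor weight given to edges with ECV = 0 (default 0.2).  A direct
algebraic consequence is that the mean of w' over all edges is exactly 1,
which is what makes "weight ≥ mean weight" a stable seed criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .network_io import PPINetwork, canonical_edge

logger = logging.getLogger("mcse")

__all__ = ["WeightedPPINetwork", "compute_ecv", "build_weighted_network"]

DEFAULT_ALPHA = 0.2


def compute_ecv(network: PPINetwork, edge: tuple[str, str]) -> float:
    """Edge clustering value of one edge, using base weights.

    Raises ``KeyError`` if the edge is not in the network.  The result is
    in [0, 1]: every common-neighbour term in the numerator also appears in
    the corresponding full-neighbour sum of the denominator.
    """
    u, v = edge
    if not network.has_edge(u, v):
        raise KeyError(f"edge ({u}, {v}) not in network")
    nu = network.neighbors(u)
    nv = network.neighbors(v)
    common = nu & nv
    if not common:
        return 0.0
    num_u = sum(network.base_weight(u, k) for k in common)
    num_v = sum(network.base_weight(v, k) for k in common)
    den_u = sum(network.base_weight(u, s) for s in nu)
    den_v = sum(network.base_weight(v, t) for t in nv)
    return (num_u * num_v) / (den_u * den_v)


@dataclass
class WeightedPPINetwork:
    """A PPI network re-weighted by the ECV transform.

    Carries the original network (base weights intact), per-edge ECV, the
    network ECV average, α, and the transformed per-edge weight.  The
    transformed weights drive seed selection and, unless an ablation mode
    says otherwise, greedy expansion and the λ statistic.
    """

    network: PPINetwork
    alpha: float
    ecv: dict[tuple[str, str], float]
    ecv_avg: float
    weights: dict[tuple[str, str], float] = field(repr=False)

    def edge_ecv(self, u: str, v: str) -> float:
        return self.ecv[canonical_edge(u, v)]

    def edge_weight(self, u: str, v: str, base: bool = False) -> float:
        """Transformed weight of an edge; ``base=True`` returns the input weight."""
        if base:
            return self.network.base_weight(u, v)
        return self.weights[canonical_edge(u, v)]

    def mean_weight(self) -> float:
        return sum(self.weights.values()) / len(self.weights)


def build_weighted_network(
    network: PPINetwork, alpha: float = DEFAULT_ALPHA
) -> WeightedPPINetwork:
    """Compute ECV for every edge and apply the weight transform.

    Raises ``ValueError`` on an empty edge set or α outside [0, 1).  If
    every edge has ECV 0 (e.g. a tree: no edge closes a triangle) the
    transform is undefined; all weights are set to 1.0 and a warning is
    logged, preserving the mean-weight-1 property.
    """
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if network.n_edges == 0:
        raise ValueError("no edges: cannot weight an empty network")

    ecv = {e: compute_ecv(network, e) for e in network.edges()}
    ecv_avg = sum(ecv.values()) / len(ecv)
    if ecv_avg == 0.0:
        logger.warning(
            "degenerate network: every edge has ECV 0; all weights set to 1.0"
        )
        weights = {e: 1.0 for e in ecv}
    else:
        scale = (1.0 - alpha) / ecv_avg
        weights = {e: alpha + scale * val for e, val in ecv.items()}
    return WeightedPPINetwork(
        network=network, alpha=alpha, ecv=ecv, ecv_avg=ecv_avg, weights=weights
    )
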
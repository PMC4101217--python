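"""Seed-edge selection and queue maintenance.

Two complementary signals mark an interaction as a promising expansion
seed: a transformed weight at or above the network mean (topology — the
edge sits in a locally dense region), and *essentiality* (biology — an
essential PPI is an interaction both of whose proteins are essential).
The default strategy takes the union of both sets; the single-signal and
random strategies exist as ablations.

The queue is sorted nonincreasing by weight, essential edges first among
ties (high-weight edges are empirically the stronger complex predictor of
the two signals), with a final lexicographic tie-break on the canonical
edge so output order is platform-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network_io import ProteinList
from .weighting import WeightedPPINetwork

logger = logging.getLogger("mcse")

__all__ = ["SeedEdge", "SeedQueue", "STRATEGIES", "select_seeds", "prune_queue"]

STRATEGIES = ("union", "ecv_only", "essential_only", "random")


@dataclass(frozen=True)
class SeedEdge:
    edge: tuple[str, str]  # canonical (sorted) pair
    weight: float
    essential: bool


@dataclass
class SeedQueue:
    """Ordered, duplicate-free list of seed edges for one run."""

    entries: list[SeedEdge]
    strategy: str

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def _sort_key(s: SeedEdge) -> tuple:
    # nonincreasing weight; essential first among equal weights; then edge label
    return (-s.weight, not s.essential, s.edge)


def select_seeds(
    wnet: WeightedPPINetwork,
    essentials: ProteinList | Iterable[str] = (),
    strategy: str = "union",
    rng_seed: int | None = None,
) -> SeedQueue:
    """Build the seed queue for one run.

    Strategies
    ----------
    union
        Edges with weight ≥ mean weight, plus all essential PPIs (default).
    ecv_only
        The weight-threshold set only.
    essential_only
        Essential PPIs only.
    random
        A uniform sample, without replacement, of as many edges as the
        union strategy would select; requires ``rng_seed``.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    ess_set = essentials.as_set() if isinstance(essentials, ProteinList) else set(essentials)
    # "weight not less than the average": the average is exactly 1 in exact
    # arithmetic but the summed mean drifts by a few ulps, which would
    # arbitrarily drop edges sitting exactly at the average; a 1e-9
    # absolute slack (weights are O(1)) absorbs that without admitting any
    # genuinely below-average edge
    mean_w = wnet.mean_weight() - 1e-9

    all_edges = sorted(wnet.weights)
    high = [e for e in all_edges if wnet.weights[e] >= mean_w]
    ess = [e for e in all_edges if e[0] in ess_set and e[1] in ess_set]

    if strategy == "ecv_only":
        chosen = high
    elif strategy == "essential_only":
        chosen = ess
    elif strategy == "union":
        chosen = sorted(set(high) | set(ess))
    else:  # random
        if rng_seed is None:
            raise ValueError("strategy='random' requires rng_seed for reproducibility")
        n = len(set(high) | set(ess))
        rng = np.random.default_rng(rng_seed)
        idx = rng.choice(len(all_edges), size=min(n, len(all_edges)), replace=False)
        chosen = [all_edges[i] for i in sorted(idx)]

    entries = [
        SeedEdge(edge=e, weight=wnet.weights[e],
                 essential=(e[0] in ess_set and e[1] in ess_set))
        for e in chosen
    ]
    entries.sort(key=_sort_key)
    logger.info("selected %d seed edges (strategy=%s)", len(entries), strategy)
    return SeedQueue(entries=entries, strategy=strategy)


def prune_queue(queue: SeedQueue, marked: Sequence[str] | set[str]) -> SeedQueue:
    """Drop every entry with at least one endpoint in ``marked``.

    ``marked`` is the union of vertices of all complexes output so far.
    Relative order of surviving entries is preserved.
    """
    marked = set(marked)
    kept = [s for s in queue.entries
            if s.edge[0] not in marked and s.edge[1] not in marked]
    return SeedQueue(entries=kept, strategy=queue.strategy)
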
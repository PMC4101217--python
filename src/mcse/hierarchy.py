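"""Multi-threshold runs and the containment forest across λ layers.

Running the detector independently at an increasing ladder of λ_th values
produces layers of complexes: low thresholds stop expansion early (many
small complexes), high thresholds let the same seeds grow into larger
supercomplexes.  Complexes in adjacent layers are then linked by a
containment coefficient |child ∩ parent| / |child|: a child at the lower
threshold links to every parent at the next threshold that contains at
least ``link_threshold`` of its members (default 0.5).  When no parent
reaches the threshold, the best-overlapping parent is still recorded,
flagged as below threshold, so every child's strongest attachment is
visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .expansion import ComplexSet, mcse
from .network_io import PPINetwork, ProteinList
from .weighting import DEFAULT_ALPHA

logger = logging.getLogger("mcse")

__all__ = ["DEFAULT_LAMBDA_LADDER", "Link", "Hierarchy",
           "containment_links", "run_hierarchy"]

#: The standard threshold ladder spanning tight cores to supercomplexes.
DEFAULT_LAMBDA_LADDER = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class Link:
    """Containment link from a child complex to a parent in the next layer."""

    child_lambda: float
    parent_lambda: float
    child_index: int  # position in the child layer's ComplexSet
    parent_index: int
    containment: float  # |child ∩ parent| / |child|, in (0, 1]
    meets_threshold: bool


@dataclass
class Hierarchy:
    """Per-λ_th layers plus containment links between adjacent layers."""

    layers: dict[float, ComplexSet]
    links: list[Link]
    link_threshold: float

    @property
    def lambdas(self) -> list[float]:
        return sorted(self.layers)

    def layer_links(self, child_lambda: float, parent_lambda: float) -> list[Link]:
        return [l for l in self.links
                if l.child_lambda == child_lambda
                and l.parent_lambda == parent_lambda]


def containment_links(
    child_sets: Sequence[set[str]],
    parent_sets: Sequence[set[str]],
    threshold: float = 0.5,
) -> list[tuple[int, int, float, bool]]:
    """Containment links between two complex lists.

    Returns ``(child_index, parent_index, containment, meets_threshold)``
    tuples: one per parent whose containment of the child reaches
    ``threshold``, plus the argmax parent (flagged False) when no parent
    does but some overlap exists.  Disjoint children produce no link.
    """
    out: list[tuple[int, int, float, bool]] = []
    for ci, child in enumerate(child_sets):
        if not child:
            continue
        scores = [len(child & parent) / len(child) for parent in parent_sets]
        hit = False
        for pi, s in enumerate(scores):
            if s >= threshold and s > 0:
                out.append((ci, pi, s, True))
                hit = True
        if not hit and scores:
            best = max(range(len(scores)), key=lambda i: (scores[i], -i))
            if scores[best] > 0:
                out.append((ci, best, scores[best], False))
    return out


def run_hierarchy(
    network: PPINetwork,
    essentials: ProteinList | Iterable[str] = (),
    lambdas: Sequence[float] = DEFAULT_LAMBDA_LADDER,
    alpha: float = DEFAULT_ALPHA,
    strategy: str = "union",
    rng_seed: int | None = None,
    link_threshold: float = 0.5,
    unweighted_expansion: bool = False,
) -> Hierarchy:
    """Detect complexes at every λ_th in ``lambdas`` and link adjacent layers.

    Each layer is an independent full run (fresh weighting and seed
    queue); links are only computed between consecutive thresholds.
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise ValueError("empty lambda ladder")
    if any(l <= 0 for l in lambdas):
        raise ValueError("all lambda_th values must be > 0")
    if any(b <= a for a, b in zip(lambdas, lambdas[1:])):
        raise ValueError("lambda ladder must be strictly increasing")

    layers = {
        lam: mcse(network, essentials, lambda_th=lam, alpha=alpha,
                  strategy=strategy, rng_seed=rng_seed,
                  unweighted_expansion=unweighted_expansion)
        for lam in lambdas
    }
    links: list[Link] = []
    for child_lam, parent_lam in zip(lambdas, lambdas[1:]):
        raw = containment_links(
            layers[child_lam].member_sets(),
            layers[parent_lam].member_sets(),
            threshold=link_threshold,
        )
        links.extend(
            Link(child_lambda=child_lam, parent_lambda=parent_lam,
                 child_index=ci, parent_index=pi,
                 containment=s, meets_threshold=ok)
            for ci, pi, s, ok in raw
        )
    logger.info("hierarchy: %d layers, %d links", len(layers), len(links))
    return Hierarchy(layers=layers, links=links, link_threshold=link_threshold)


def render_tree(h: Hierarchy) -> str:
    """Indented-text rendering of the containment forest, top layer first."""
    lambdas = h.lambdas
    lines: list[str] = []

    def children_of(parent_lam: float, parent_idx: int,
                    child_lam: float) -> list[Link]:
        return [l for l in h.layer_links(child_lam, parent_lam)
                if l.parent_index == parent_idx and l.meets_threshold]

    def walk(lam_pos: int, idx: int, depth: int) -> None:
        lam = lambdas[lam_pos]
        c = h.layers[lam].complexes[idx]
        lines.append("  " * depth
                     + f"[λ={lam:g}] #{idx + 1} ({len(c)} proteins)")
        if lam_pos == 0:
            return
        for link in children_of(lam, idx, lambdas[lam_pos - 1]):
            walk(lam_pos - 1, link.child_index, depth + 1)

    top = len(lambdas) - 1
    for idx in range(len(h.layers[lambdas[top]])):
        walk(top, idx, 0)
    return "\n".join(lines)
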
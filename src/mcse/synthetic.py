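"""Synthetic PPI networks with planted complexes, and hand-checked fixtures.

``generate_planted`` emulates the features of a curated PPI dataset that
the detector depends on: a sparse background, planted dense subgraphs of
tunable density standing in for protein complexes, controlled vertex
sharing between consecutive complexes (so the overlap-abandonment rule is
exercised), and an essential-protein subset enriched inside complexes the
way essentiality is enriched in real complex membership.  It makes no
attempt to reproduce a scale-free degree distribution.

``worked_fixtures`` returns tiny graphs whose ECV/weight/λ tables were
computed by hand (values embedded as exact fractions); they anchor the
numeric tests of the weighting, seeding and expansion modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Any

import numpy as np

from .network_io import ComplexSetFile, PPINetwork, ProteinList

__all__ = ["PlantedNetwork", "generate_planted", "WorkedFixture", "worked_fixtures"]

#: fraction of background (non-complex) vertices labelled essential
BACKGROUND_ESSENTIAL_FRAC = 0.05


@dataclass
class PlantedNetwork:
    """A generated network together with its ground truth and parameters."""

    network: PPINetwork
    truth: ComplexSetFile
    essentials: ProteinList
    params: dict[str, Any]
    rng_seed: int


def generate_planted(
    n_complexes: int = 10,
    size_range: tuple[int, int] = (5, 8),
    p_in: float = 0.9,
    p_out: float = 0.02,
    overlap_frac: float = 0.3,
    essential_frac: float = 0.5,
    n_background: int = 50,
    rng_seed: int | None = None,
) -> PlantedNetwork:
    """Plant dense complexes in a sparse random background.

    Each of the ``n_complexes`` planted vertex sets has a size drawn
    uniformly from ``size_range``; with probability ``overlap_frac`` a
    complex shares one vertex with the previous complex.  Pairs inside a
    complex are connected with probability ``p_in`` (plus a spanning path
    so every truth complex is connected); every other pair — across
    complexes, to or within the ``n_background`` extra vertices — is
    connected with probability ``p_out``.  ``essential_frac`` of each
    complex's members, plus a small background fraction, are labelled
    essential.
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError(f"need 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    if not 0 <= overlap_frac < 1:
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    if not 0 <= essential_frac <= 1:
        raise ValueError(f"essential_frac must be in [0, 1], got {essential_frac}")
    if size_range[0] < 2 or size_range[1] < size_range[0]:
        raise ValueError(f"invalid size_range {size_range}")
    if n_complexes < 0 or n_background < 0:
        raise ValueError("counts must be nonnegative")
    if rng_seed is None:
        raise ValueError("rng_seed is required for reproducible generation")
    rng = np.random.default_rng(rng_seed)

    counter = 0

    def new_vertex() -> str:
        nonlocal counter
        v = f"P{counter:04d}"
        counter += 1
        return v

    complexes: list[list[str]] = []
    for i in range(n_complexes):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members: list[str] = []
        if i > 0 and rng.random() < overlap_frac:
            members.append(complexes[-1][int(rng.integers(len(complexes[-1])))])
        while len(members) < size:
            members.append(new_vertex())
        complexes.append(members)

    background = [new_vertex() for _ in range(n_background)]
    all_vertices = sorted({v for c in complexes for v in c} | set(background))

    net = PPINetwork()
    for v in all_vertices:
        net.add_vertex(v)

    intra_pairs: set[tuple[str, str]] = set()
    for members in complexes:
        # spanning path in a random order guarantees truth connectivity
        order = list(members)
        rng.shuffle(order)
        for u, v in zip(order, order[1:]):
            pair = (u, v) if u <= v else (v, u)
            intra_pairs.add(pair)
            if not net.has_edge(*pair):
                net.add_edge(*pair)
        for u, v in combinations(sorted(members), 2):
            pair = (u, v)
            intra_pairs.add(pair)
            if not net.has_edge(*pair) and rng.random() < p_in:
                net.add_edge(*pair)

    if p_out > 0:
        for u, v in combinations(all_vertices, 2):
            if (u, v) in intra_pairs or net.has_edge(u, v):
                continue
            if rng.random() < p_out:
                net.add_edge(u, v)

    essential_ids: list[str] = []
    seen: set[str] = set()
    for members in complexes:
        k = int(round(essential_frac * len(members)))
        pool = sorted(members)
        chosen = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        for idx in sorted(chosen):
            if pool[idx] not in seen:
                seen.add(pool[idx])
                essential_ids.append(pool[idx])
    if background:
        k = int(round(BACKGROUND_ESSENTIAL_FRAC * len(background)))
        chosen = rng.choice(len(background), size=k, replace=False)
        for idx in sorted(chosen):
            if background[idx] not in seen:
                seen.add(background[idx])
                essential_ids.append(background[idx])

    truth = ComplexSetFile(
        complexes=[set(c) for c in complexes],
        labels=[f"T{i + 1}" for i in range(len(complexes))],
    )
    params = dict(
        n_complexes=n_complexes, size_range=tuple(size_range), p_in=p_in,
        p_out=p_out, overlap_frac=overlap_frac, essential_frac=essential_frac,
        n_background=n_background, rng_seed=rng_seed,
    )
    return PlantedNetwork(
        network=net, truth=truth,
        essentials=ProteinList(essential_ids),
        params=params, rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# hand-checked fixtures


@dataclass
class WorkedFixture:
    """A toy graph with hand-computed ECV/weight/λ expectations.

    ``ecv`` and ``weights_alpha02`` (α = 0.2) map canonical edges to exact
    values; ``lambda_examples`` maps vertex subsets to the λ value on base
    (unit) weights.  These tables are derivations, not measurements: they
    were worked out on paper from the definitions and serve as oracles.
    """

    name: str
    network: PPINetwork
    ecv: dict[tuple[str, str], Fraction]
    ecv_avg: Fraction
    weights_alpha02: dict[tuple[str, str], Fraction]
    lambda_examples: dict[frozenset[str], float] = field(default_factory=dict)
    notes: str = ""


def _fixture(name, edges, ecv, lambda_examples=None, notes=""):
    net = PPINetwork.from_edges(edges)
    ecv = {tuple(sorted(e)): Fraction(v) for e, v in ecv.items()}
    avg = sum(ecv.values(), Fraction(0)) / len(ecv)
    if avg == 0:
        weights = {e: Fraction(1) for e in ecv}
    else:
        weights = {e: Fraction(1, 5) + Fraction(4, 5) * v / avg
                   for e, v in ecv.items()}
    return WorkedFixture(
        name=name, network=net, ecv=ecv, ecv_avg=avg,
        weights_alpha02=weights,
        lambda_examples={frozenset(k): v for k, v in (lambda_examples or {}).items()},
        notes=notes,
    )


def worked_fixtures() -> dict[str, WorkedFixture]:
    """Library of hand-checked toy graphs; stable across calls."""
    fixtures = {}

    f = Fraction
    fixtures["K3"] = _fixture(
        "K3",
        [("a", "b"), ("a", "c"), ("b", "c")],
        {("a", "b"): f(1, 4), ("a", "c"): f(1, 4), ("b", "c"): f(1, 4)},
        lambda_examples={("a", "b", "c"): float("inf")},
        notes="triangle: every edge has one common neighbour, degrees 2,2",
    )

    k4_edges = [("a", "b"), ("a", "c"), ("a", "d"),
                ("b", "c"), ("b", "d"), ("c", "d")]
    fixtures["K4"] = _fixture(
        "K4",
        k4_edges,
        {e: f(4, 9) for e in k4_edges},
        lambda_examples={
            ("a", "b"): 2 / 4,        # in 2, out 4
            ("a", "b", "c"): 6 / 3,   # in 6, out 3
        },
        notes="clique of 4: |I|=2, degrees 3,3 for every edge",
    )

    fixtures["path3"] = _fixture(
        "path3",
        [("a", "b"), ("b", "c")],
        {("a", "b"): 0, ("b", "c"): 0},
        lambda_examples={("a", "b"): 2 / 1},
        notes="path a-b-c: no triangles, degenerate ECV_avg=0, unit weights",
    )

    fixtures["two_triangles"] = _fixture(
        "two_triangles",
        [("a", "b"), ("a", "c"), ("b", "c"),
         ("d", "e"), ("d", "f"), ("e", "f")],
        {e: f(1, 4) for e in
         [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f")]},
        lambda_examples={
            ("a", "b", "c"): float("inf"),
            ("a", "b"): 2 / 2,  # in 2, out a-c and b-c
        },
        notes="two disjoint triangles; all weights 1 after transform",
    )

    fixtures["bridged_triangles"] = _fixture(
        "bridged_triangles",
        [("a", "b"), ("a", "c"), ("b", "c"),
         ("c", "d"),
         ("d", "e"), ("d", "f"), ("e", "f")],
        {("a", "b"): f(1, 4), ("a", "c"): f(1, 6), ("b", "c"): f(1, 6),
         ("c", "d"): 0,
         ("d", "e"): f(1, 6), ("d", "f"): f(1, 6), ("e", "f"): f(1, 4)},
        lambda_examples={
            ("a", "b", "c"): 6 / 1,  # in 6, out: the bridge c-d
            ("d", "e", "f"): 6 / 1,
        },
        notes="triangles abc and def joined by bridge c-d; ECV_avg = 1/6",
    )

    fixtures["square_diag_pendant"] = _fixture(
        "square_diag_pendant",
        [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d"),
         ("a", "c"), ("d", "e")],
        {("a", "b"): f(1, 6), ("b", "c"): f(1, 6),
         ("c", "d"): f(1, 9), ("a", "d"): f(1, 9),
         ("a", "c"): f(4, 9), ("d", "e"): 0},
        notes=(
            "square a-b-c-d-a with diagonal a-c and pendant d-e; "
            "ECV_avg = 1/6; at α=0.2 only a-c (7/3), a-b (1) and b-c (1) "
            "reach the mean weight 1"
        ),
    )

    return fixtures
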
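"""Evaluation of a predicted complex set against a reference catalogue.

A predicted complex Ic and a reference complex Kc match when their overlap
score

    OS(Ic, Kc) = |V_Ic ∩ V_Kc|² / (|V_Ic| · |V_Kc|)

reaches a threshold (0.2 by convention).  From the matches:

* specificity Sp — fraction of predicted complexes matched by some
  reference complex;
* sensitivity Sn — fraction of reference complexes matched by some
  predicted complex (size-sensitive: it grows with the number of
  predictions, so treat it with care when comparing methods that output
  very different numbers of complexes);
* F-score — harmonic mean 2·Sp·Sn / (Sp + Sn).

Set-level summaries cover complex count, mean size, induced-subgraph edge
density (mean and minimum), and the overlapping rate Σ|C_i| / |∪C_i| (= 1
iff the complexes are pairwise disjoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .network_io import ComplexSetFile, PPINetwork

__all__ = [
    "EvalReport",
    "SetSummary",
    "overlap_score",
    "match_stats",
    "overlapping_rate",
    "density",
    "summarize",
]


def _as_sets(obj) -> list[set[str]]:
    """Accept a ComplexSetFile, a ComplexSet, or an iterable of sets."""
    if isinstance(obj, ComplexSetFile):
        return [set(c) for c in obj.complexes]
    if hasattr(obj, "member_sets"):
        return obj.member_sets()
    return [set(c) for c in obj]


def overlap_score(a: Iterable[str], b: Iterable[str]) -> float:
    """OS(A, B) = |A∩B|² / (|A|·|B|); symmetric, in [0, 1]."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap_score requires nonempty sets")
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


@dataclass
class EvalReport:
    os_threshold: float
    specificity: float
    sensitivity: float
    f_score: float
    # per predicted complex: (predicted index, best reference index, best OS)
    matches: list[tuple[int, int, float]] = field(default_factory=list)


def match_stats(predicted, known, os_threshold: float = 0.2) -> EvalReport:
    """Specificity, sensitivity and F-score at one overlap-score threshold."""
    pred = _as_sets(predicted)
    ref = _as_sets(known)
    if not pred or not ref:
        raise ValueError("match_stats requires nonempty predicted and known sets")
    if not 0 < os_threshold <= 1:
        raise ValueError(f"os_threshold must be in (0, 1], got {os_threshold}")

    matches: list[tuple[int, int, float]] = []
    n_pred_matched = 0
    ref_matched = [False] * len(ref)
    for i, p in enumerate(pred):
        best_j, best_os = -1, 0.0
        for j, k in enumerate(ref):
            os_ = overlap_score(p, k)
            if os_ > best_os:
                best_j, best_os = j, os_
            if os_ >= os_threshold:
                ref_matched[j] = True
        if best_os >= os_threshold:
            n_pred_matched += 1
            matches.append((i, best_j, best_os))

    sp = n_pred_matched / len(pred)
    sn = sum(ref_matched) / len(ref)
    f = 2 * sp * sn / (sp + sn) if sp + sn > 0 else 0.0
    return EvalReport(os_threshold=os_threshold, specificity=sp,
                      sensitivity=sn, f_score=f, matches=matches)


def overlapping_rate(cset) -> float:
    """Σ|C_i| / |∪C_i| over a nonempty complex set; ≥ 1 always."""
    sets = _as_sets(cset)
    if not sets:
        raise ValueError("overlapping_rate requires a nonempty complex set")
    union: set[str] = set()
    total = 0
    for c in sets:
        total += len(c)
        union |= c
    return total / len(union)


def density(members: Iterable[str], network: PPINetwork) -> float:
    """Induced-subgraph edge density 2m / (n·(n−1)); requires n ≥ 2."""
    members = set(members)
    n = len(members)
    if n < 2:
        raise ValueError("density requires at least 2 vertices")
    m = network.induced_edge_count(members)
    return 2.0 * m / (n * (n - 1))


@dataclass
class SetSummary:
    n_complexes: int
    mean_size: float
    mean_density: float
    min_density: float
    overlapping_rate: float


def summarize(cset, network: PPINetwork) -> SetSummary:
    """Set-level characteristics of one detected complex set."""
    sets = _as_sets(cset)
    if not sets:
        raise ValueError("summarize requires a nonempty complex set")
    sizes = [len(c) for c in sets]
    dens = [density(c, network) for c in sets]
    return SetSummary(
        n_complexes=len(sets),
        mean_size=sum(sizes) / len(sizes),
        mean_density=sum(dens) / len(dens),
        min_density=min(dens),
        overlapping_rate=overlapping_rate(sets),
    )
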
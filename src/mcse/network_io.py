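"""Input/output for PPI networks, protein lists and complex-set files.

A protein-protein interaction (PPI) network is stored as an undirected
simple graph whose vertices are opaque, case-sensitive protein identifier
strings.  Each edge carries a positive *base weight* (1.0 for unweighted
input); downstream weighting replaces these with topology-derived weights
but the base weights remain the input to the edge-clustering statistic.

File formats are deliberately minimal plain text:

* edge list  -- whitespace/tab separated, two ID columns and an optional
  numeric weight column; ``#`` starts a comment line;
* protein list -- one ID per line, ``#`` comments allowed;
* complex set -- one complex per line, members whitespace-separated, with
  an optional leading ``label:`` token.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger("mcse")

__all__ = [
    "ParseError",
    "PPINetwork",
    "ProteinList",
    "ComplexSetFile",
    "canonical_edge",
    "load_network",
    "write_network",
    "load_protein_list",
    "write_protein_list",
    "load_complex_set",
    "write_complex_set",
]


class ParseError(ValueError):
    """Raised for malformed input lines; the message names the line number."""


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered representation of an edge: lexicographically sorted.

    All edge dictionaries in the package are keyed this way so that the
    order of endpoints in the input file never affects results.
    """
    return (u, v) if u <= v else (v, u)


class PPINetwork:
    """Undirected simple PPI graph with positive per-edge base weights.

    Thin wrapper over :class:`networkx.Graph` that enforces the simple-graph
    invariants (no self-loops, no duplicate edges, positive weights) and
    exposes edges in canonical (sorted-pair) form.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = graph if graph is not None else nx.Graph()

    # -- construction -----------------------------------------------------

    def add_vertex(self, v: str) -> None:
        self._g.add_node(v)

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if u == v:
            raise ValueError(f"self-loop {u!r} not allowed")
        if weight <= 0:
            raise ValueError(f"non-positive base weight {weight} on edge ({u}, {v})")
        self._g.add_edge(u, v, weight=float(weight))

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str] | tuple[str, str, float]]
    ) -> "PPINetwork":
        net = cls()
        for e in edges:
            net.add_edge(*e)
        return net

    # -- queries ----------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def vertices(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str]]:
        """Iterate edges as canonical (sorted) pairs."""
        for u, v in self._g.edges:
            yield canonical_edge(u, v)

    def has_vertex(self, v: str) -> bool:
        return v in self._g

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def base_weight(self, u: str, v: str) -> float:
        try:
            return self._g[u][v]["weight"]
        except KeyError:
            raise KeyError(f"edge ({u}, {v}) not in network") from None

    def neighbors(self, v: str) -> set[str]:
        return set(self._g[v])

    def degree(self, v: str) -> int:
        return self._g.degree(v)

    def induced_edge_count(self, members: Iterable[str]) -> int:
        """Number of edges of the subgraph induced by ``members``."""
        return self._g.subgraph(members).number_of_edges()

    def is_connected_subset(self, members: Iterable[str]) -> bool:
        sub = self._g.subgraph(members)
        return sub.number_of_nodes() > 0 and nx.is_connected(sub)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        if self.vertices != other.vertices:
            return False
        mine = {e: self.base_weight(*e) for e in self.edges()}
        theirs = {e: other.base_weight(*e) for e in other.edges()}
        return mine == theirs

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PPINetwork({self.n_vertices} vertices, {self.n_edges} edges)"


@dataclass
class ProteinList:
    """Order-preserving, duplicate-free list of protein IDs."""

    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        unique = []
        for pid in self.ids:
            if pid not in seen:
                seen.add(pid)
                unique.append(pid)
        self.ids = unique
        self._set = seen

    def __contains__(self, pid: str) -> bool:
        return pid in self._set

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def as_set(self) -> set[str]:
        return set(self._set)


@dataclass
class ComplexSetFile:
    """An ordered collection of complexes (vertex sets) with optional labels."""

    complexes: list[set[str]] = field(default_factory=list)
    labels: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [None] * len(self.complexes)
        if len(self.labels) != len(self.complexes):
            raise ValueError("labels and complexes length mismatch")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[set[str]]:
        return iter(self.complexes)


# ---------------------------------------------------------------------------
# readers / writers


def load_network(path: str | Path, weighted: bool = False) -> PPINetwork:
    """Read an edge-list file into a cleaned :class:`PPINetwork`.

    Cleaning removes self-loops and collapses duplicate unordered pairs
    (the first occurrence's weight is kept; a conflicting later weight is
    logged).  Counts of dropped records are logged at INFO level.

    Parameters
    ----------
    path:
        Two-column (plus optional weight column) whitespace-separated file.
    weighted:
        If true, a third numeric column is required on every edge line and
        used as the base weight; otherwise all base weights are 1.0.
    """
    net = PPINetwork()
    n_self_loops = 0
    n_duplicates = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected at least two columns, got {len(parts)}"
                )
            u, v = parts[0], parts[1]
            if weighted:
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: missing weight column")
                try:
                    w = float(parts[2])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                    ) from None
                if w <= 0:
                    raise ParseError(f"{path}:{lineno}: non-positive weight {w}")
            else:
                w = 1.0
            if u == v:
                n_self_loops += 1
                continue
            if net.has_edge(u, v):
                n_duplicates += 1
                if weighted and net.base_weight(u, v) != w:
                    logger.warning(
                        "%s:%d: duplicate edge (%s, %s) with conflicting weight "
                        "%g; keeping first weight %g",
                        path, lineno, u, v, w, net.base_weight(u, v),
                    )
                continue
            net.add_edge(u, v, weight=w)
    logger.info(
        "loaded %s: %d proteins, %d interactions (dropped %d self-loops, "
        "%d duplicates)",
        path, net.n_vertices, net.n_edges, n_self_loops, n_duplicates,
    )
    return net


def write_network(
    net: PPINetwork,
    path: str | Path,
    header: Iterable[str] = (),
    extra_columns: dict[tuple[str, str], list[float]] | None = None,
) -> None:
    """Write an edge list (canonical pair + base weight) as TSV.

    ``extra_columns`` maps canonical edges to additional numeric columns
    appended after the weight (used by the CLI to emit ECV alongside the
    transformed weight).  Isolated vertices are not representable in an
    edge list and are dropped.
    """
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for e in sorted(net.edges()):
            cols = [e[0], e[1], f"{net.base_weight(*e):g}"]
            if extra_columns is not None:
                cols.extend(f"{x:.6g}" for x in extra_columns[e])
            fh.write("\t".join(cols) + "\n")


def load_protein_list(path: str | Path) -> ProteinList:
    """Read a one-ID-per-line protein list, deduplicated, order preserved."""
    ids: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line.split()[0])
    return ProteinList(ids)


def write_protein_list(plist: ProteinList, path: str | Path,
                       header: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for pid in plist:
            fh.write(pid + "\n")


def load_complex_set(path: str | Path, strict: bool = False) -> ComplexSetFile:
    """Read a complex-set file: one complex per line, optional ``label:`` prefix.

    Lines with fewer than two members are skipped with a warning by
    default; ``strict=True`` turns them into a :class:`ParseError`.
    """
    complexes: list[set[str]] = []
    labels: list[str | None] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            # '#' opens a comment, except that labels like "#12:" are
            # legitimate complex names (the run command emits them)
            if line.startswith("#") and not re.match(r"^#\S*:", line):
                continue
            label: str | None = None
            first, _, rest = line.partition(":")
            if rest and " " not in first.strip() and "\t" not in first.strip():
                label = first.strip()
                line = rest
            members = set(line.split())
            if len(members) < 2:
                msg = f"{path}:{lineno}: complex with fewer than 2 members"
                if strict:
                    raise ParseError(msg)
                logger.warning("%s; skipped", msg)
                continue
            complexes.append(members)
            labels.append(label)
    return ComplexSetFile(complexes, labels)


def write_complex_set(cset: ComplexSetFile, path: str | Path,
                      header: Iterable[str] = ()) -> None:
    """Write a complex set; members sorted so output is deterministic."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for label, members in zip(cset.labels, cset.complexes):
            prefix = f"{label}: " if label else ""
            fh.write(prefix + " ".join(sorted(members)) + "\n")
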
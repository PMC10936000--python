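"""Interpretive Structural Modeling: from expert adjacency to factor hierarchy.

Warfield's ISM procedure turns a binary direct-influence matrix R (entry
(i, j) = 1 iff factor Si directly affects Sj) into a layered hierarchy:

1. the reachability matrix M = (R + I)^lambda under Boolean arithmetic,
   where lambda is the first power at which the matrix stabilizes;
2. per-factor reachable sets R(Si) (row of M), antecedent sets A(Si)
   (column of M) and common sets T(Si) = R(Si) n A(Si);
3. iterative level extraction: factors with R(Si) n A(Si) = R(Si) form the
   next (shallowest remaining) level and are deleted, until none remain.

Level 1 — extracted first — is the *surface* level of most direct
influences; the deepest level holds the root drivers (*bottom*).  The
hierarchy digraph keeps direct cross-level links after transitive
reduction, plus the mutual links inside each strongly connected group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


class AdjacencyValidationError(ValueError):
    """The supplied adjacency matrix is not a valid 0/1 square matrix."""


@dataclass(frozen=True)
class FactorSystem:
    """Ordered factor labels with optional human-readable names."""

    labels: tuple[str, ...]
    names: dict[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) == 0:
            raise ValueError("at least one factor required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("factor labels must be unique")

    @property
    def k(self) -> int:
        return len(self.labels)

    def name_of(self, label: str) -> str:
        if self.names and label in self.names:
            return self.names[label]
        return label


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Validated binary direct-influence matrix with zero diagonal."""

    entries: np.ndarray

    @property
    def k(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class ReachabilityMatrix:
    """Transitive-reflexive Boolean closure of an adjacency matrix."""

    entries: np.ndarray

    @property
    def k(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class FactorSets:
    """Reachable, antecedent and common sets per factor, in label order."""

    labels: tuple[str, ...]
    reachable: dict[str, frozenset]
    antecedent: dict[str, frozenset]
    common: dict[str, frozenset]


@dataclass(frozen=True)
class LevelPartition:
    """Ordered disjoint levels; level 1 (index 0) is the surface."""

    levels: tuple[frozenset, ...]

    @property
    def level_of(self) -> dict[str, int]:
        return {lab: i + 1 for i, level in enumerate(self.levels) for lab in level}

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class HierarchyGraph:
    """Level-annotated digraph of retained influence links."""

    system: FactorSystem
    partition: LevelPartition
    edges: tuple[tuple[str, str], ...]
    groups: tuple[frozenset, ...]


def validate_adjacency(entries) -> AdjacencyMatrix:
    """Validate a square 0/1 matrix; diagonal 1s are coerced to 0 with a log.

    Self-influence is carried by the identity during closure, so a 1 on the
    diagonal is redundant rather than wrong.
    """
    A = np.asarray(entries)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise AdjacencyValidationError(f"adjacency must be square, got shape {A.shape}")
    bad = ~np.isin(A, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise AdjacencyValidationError(
            f"non-binary entry {A[i, j]!r} at position ({i}, {j})"
        )
    A = A.astype(int)
    if np.diag(A).any():
        logger.info("coercing %d diagonal 1s to 0", int(np.diag(A).sum()))
        np.fill_diagonal(A, 0)
    return AdjacencyMatrix(entries=A)


def reachability_closure(R: AdjacencyMatrix) -> ReachabilityMatrix:
    """Boolean closure M = (R + I)^lambda, by repeated Boolean squaring.

    Stabilizes in at most k - 1 squarings since path lengths double.
    """
    B = (R.entries | np.eye(R.k, dtype=int)).astype(bool)
    while True:
        nxt = B @ B  # boolean matrix product
        if np.array_equal(nxt, B):
            break
        B = nxt
    return ReachabilityMatrix(entries=B.astype(int))


def factor_sets(M: ReachabilityMatrix, labels) -> FactorSets:
    """Read reachable/antecedent/common sets off the reachability matrix."""
    labels = tuple(labels)
    if len(labels) != M.k:
        raise ValueError("label count must match matrix dimension")
    E = M.entries
    reachable = {
        labels[i]: frozenset(labels[j] for j in range(M.k) if E[i, j])
        for i in range(M.k)
    }
    antecedent = {
        labels[i]: frozenset(labels[j] for j in range(M.k) if E[j, i])
        for i in range(M.k)
    }
    common = {lab: reachable[lab] & antecedent[lab] for lab in labels}
    return FactorSets(
        labels=labels, reachable=reachable, antecedent=antecedent, common=common
    )


def partition_levels(M: ReachabilityMatrix, labels) -> LevelPartition:
    """Iterative level extraction on the reachability matrix.

    At each round the factors of the current submatrix whose reachable set
    is contained in their antecedent set (R n A = R) form the next level
    and are deleted.  A true reachability matrix always yields at least one
    extractable factor per round; a round extracting nothing means the
    input was not a closure and raises.
    """
    labels = tuple(labels)
    if len(labels) != M.k:
        raise ValueError("label count must match matrix dimension")
    E = M.entries
    remaining = list(range(M.k))
    levels: list[frozenset] = []
    while remaining:
        extracted = []
        for i in remaining:
            reach = {j for j in remaining if E[i, j]}
            ante = {j for j in remaining if E[j, i]}
            if reach & ante == reach:
                extracted.append(i)
        if not extracted:
            raise ValueError(
                "no extractable factor: matrix is not a valid reachability closure"
            )
        levels.append(frozenset(labels[i] for i in extracted))
        remaining = [i for i in remaining if i not in set(extracted)]
    return LevelPartition(levels=tuple(levels))


def strongly_connected_groups(M: ReachabilityMatrix, labels) -> list[frozenset]:
    """Groups of mutually reachable factors (M(i,j) = M(j,i) = 1).

    On a reachability matrix mutual reachability is an equivalence
    relation, so the groups partition the labels.  Order follows first
    appearance in label order.
    """
    labels = tuple(labels)
    E = M.entries
    mutual = (E & E.T).astype(bool)
    seen: set[int] = set()
    groups: list[frozenset] = []
    for i in range(M.k):
        if i in seen:
            continue
        members = {j for j in range(M.k) if mutual[i, j]}
        seen |= members
        groups.append(frozenset(labels[j] for j in members))
    return groups


def build_hierarchy(
    R: AdjacencyMatrix, partition: LevelPartition, system: FactorSystem
) -> HierarchyGraph:
    """Assemble the drawable hierarchy digraph.

    Cross-level edges are direct adjacency links from a strictly deeper
    factor group to a shallower one, after transitive reduction on the
    condensation (an edge implied through an intermediate group is
    dropped).  Within-level edges are the adjacency links inside one
    strongly connected group, kept as drawn.
    """
    labels = system.labels
    if R.k != system.k:
        raise ValueError("adjacency dimension must match factor system")
    covered = frozenset().union(*partition.levels) if partition.levels else frozenset()
    if covered != frozenset(labels):
        raise ValueError("partition does not cover the factor system")
    M = reachability_closure(R)
    if partition_levels(M, labels) != partition:
        raise ValueError("partition is not the level partition of R's closure")

    groups = strongly_connected_groups(M, labels)
    group_of = {lab: gi for gi, grp in enumerate(groups) for lab in grp}
    # condensed adjacency between groups
    g = len(groups)
    cond = np.zeros((g, g), dtype=bool)
    idx = {lab: i for i, lab in enumerate(labels)}
    for a in labels:
        for b in labels:
            if R.entries[idx[a], idx[b]] and group_of[a] != group_of[b]:
                cond[group_of[a], group_of[b]] = True
    # transitive reduction of the condensation (a DAG): drop (u,v) when some
    # direct successor w of u reaches v
    reach = reachability_closure(AdjacencyMatrix(entries=cond.astype(int))).entries
    keep = cond.copy()
    for u in range(g):
        for v in range(g):
            if not cond[u, v]:
                continue
            for w in range(g):
                if w not in (u, v) and cond[u, w] and reach[w, v]:
                    keep[u, v] = False
                    break

    edges: list[tuple[str, str]] = []
    for a in labels:
        for b in labels:
            if not R.entries[idx[a], idx[b]]:
                continue
            ga, gb = group_of[a], group_of[b]
            if ga == gb:
                edges.append((a, b))  # mutual link within a group
            elif keep[ga, gb]:
                edges.append((a, b))
    return HierarchyGraph(
        system=system, partition=partition, edges=tuple(edges), groups=tuple(groups)
    )


def export_graph(graph: HierarchyGraph) -> str:
    """Render the hierarchy as DOT text, one same-rank subgraph per level."""
    lines = ["digraph hierarchy {", "  rankdir=BT;"]
    level_of = graph.partition.level_of
    for li, level in enumerate(graph.partition.levels, start=1):
        members = sorted(level)
        lines.append(f"  subgraph level_{li} {{")
        lines.append("    rank=same;")
        for lab in members:
            name = graph.system.name_of(lab)
            lines.append(f'    "{lab}" [label="{lab}\\n{name}", level={li}];')
        lines.append("  }")
    for src, dst in sorted(graph.edges):
        style = " [constraint=false]" if level_of[src] == level_of[dst] else ""
        lines.append(f'  "{src}" -> "{dst}"{style};')
    lines.append("}")
    return "\n".join(lines) + "\n"


def load_adjacency_csv(path) -> tuple[list[str], np.ndarray]:
    """Read a 0/1 adjacency CSV with a header row of factor labels."""
    import pandas as pd

    frame = pd.read_csv(path, index_col=0)
    labels = list(frame.columns)
    return labels, frame.to_numpy()
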
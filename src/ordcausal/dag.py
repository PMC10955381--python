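"""Causal DAG representation, d-separation and adjustment-set checking.

Graphs here are tiny (well under ten nodes), so everything is done by
explicit path enumeration.  That keeps each rule visible in the code and
lets the test suite compare against an independent moralization-based
oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Tuple

__all__ = [
    "CausalDag",
    "AdjustmentQuery",
    "build_survey_dag",
    "d_separated",
    "backdoor_valid",
    "enumerate_minimal_adjustment_sets",
    "read_edge_list",
    "write_edge_list",
]

Edge = Tuple[str, str]


class DagError(ValueError):
    """Raised for structurally invalid graphs or malformed queries."""


@dataclass(frozen=True)
class CausalDag:
    """A directed acyclic graph over named variables.

    Parameters
    ----------
    nodes : frozenset of str
        Variable names.
    edges : frozenset of (parent, child) pairs
        Directed edges; both endpoints must be members of ``nodes``.
    unobserved : frozenset of str
        Subset of ``nodes`` flagged as latent (never measurable, never
        admissible in a conditioning set).
    """

    nodes: FrozenSet[str]
    edges: FrozenSet[Edge]
    unobserved: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(self.edges))
        object.__setattr__(self, "unobserved", frozenset(self.unobserved))
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise DagError(f"edge ({a}, {b}) has an endpoint outside nodes")
        if not self.unobserved <= self.nodes:
            raise DagError("unobserved contains names not in nodes")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn's algorithm; leftover nodes mean a directed cycle.
        indeg = {n: 0 for n in self.nodes}
        for _, b in self.edges:
            indeg[b] += 1
        frontier = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while frontier:
            n = frontier.pop()
            seen += 1
            for c in self.children(n):
                indeg[c] -= 1
                if indeg[c] == 0:
                    frontier.append(c)
        if seen != len(self.nodes):
            raise DagError("edge set contains a directed cycle")

    @property
    def observed(self) -> FrozenSet[str]:
        return self.nodes - self.unobserved

    def parents(self, node: str) -> FrozenSet[str]:
        return frozenset(a for a, b in self.edges if b == node)

    def children(self, node: str) -> FrozenSet[str]:
        return frozenset(b for a, b in self.edges if a == node)

    def descendants(self, node: str) -> FrozenSet[str]:
        """All nodes reachable from ``node`` by a directed path (exclusive)."""
        out: set[str] = set()
        stack = [node]
        while stack:
            for c in self.children(stack.pop()):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return frozenset(out)

    def require_nodes(self, names: Iterable[str]) -> None:
        unknown = set(names) - self.nodes
        if unknown:
            raise DagError(f"unknown node name(s): {sorted(unknown)}")


@dataclass(frozen=True)
class AdjustmentQuery:
    """An exposure/outcome pair plus a candidate conditioning set."""

    exposure: str
    outcome: str
    conditioning_set: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "conditioning_set", frozenset(self.conditioning_set)
        )
        if self.exposure == self.outcome:
            raise DagError("exposure and outcome must differ")
        if {self.exposure, self.outcome} & self.conditioning_set:
            raise DagError("conditioning set may not contain exposure or outcome")


# ---------------------------------------------------------------------------
# The default survey DAG
# ---------------------------------------------------------------------------

_DEFAULT_EDGES: frozenset[Edge] = frozenset(
    {
        ("Sex", "Education"),
        ("Age", "Education"),
        ("Sex", "Religiosity"),
        ("Age", "Religiosity"),
        ("Sex", "FoodInsecurity"),
        ("Age", "FoodInsecurity"),
        ("Education", "Children"),
        ("Children", "FoodInsecurity"),
        ("Children", "Religiosity"),
        ("Education", "FoodInsecurity"),
        ("Education", "Religiosity"),
        ("FoodInsecurity", "Religiosity"),
    }
)


def build_survey_dag(
    include_education_type: bool = False,
    education_type_causes_food_security: bool = False,
) -> CausalDag:
    """Construct the default causal graph for the cross-site survey.

    Observed nodes: Sex, Age, Education (years), Children, FoodInsecurity,
    Religiosity.  Optionally adds a latent ``EducationType`` node acting on
    religiosity alone, or — under the pessimistic scenario — on food
    insecurity as well, turning it into an unmeasured common cause.
    """
    nodes = {"Sex", "Age", "Education", "Children", "FoodInsecurity", "Religiosity"}
    edges = set(_DEFAULT_EDGES)
    unobserved: set[str] = set()
    if include_education_type:
        nodes.add("EducationType")
        unobserved.add("EducationType")
        edges.add(("EducationType", "Religiosity"))
        if education_type_causes_food_security:
            edges.add(("EducationType", "FoodInsecurity"))
    elif education_type_causes_food_security:
        raise DagError(
            "education_type_causes_food_security requires include_education_type"
        )
    return CausalDag(frozenset(nodes), frozenset(edges), frozenset(unobserved))


# Backwards-compatible alias used in early revisions of the CLI.
build_paper_dag = build_survey_dag


# ---------------------------------------------------------------------------
# d-separation by path enumeration
# ---------------------------------------------------------------------------

def _undirected_paths(dag: CausalDag, x: str, y: str):
    """Yield all simple paths x..y as lists of (node, arrived_by_incoming).

    Each step records the traversed edge's orientation so collider status
    of intermediate nodes can be read off directly.
    """
    adjacency: dict[str, list[tuple[str, bool]]] = {n: [] for n in dag.nodes}
    for a, b in dag.edges:
        adjacency[a].append((b, True))   # a -> b : arrive at b via incoming edge
        adjacency[b].append((a, False))  # traverse against the arrow

    path: list[tuple[str, bool]] = [(x, False)]
    on_path = {x}

    def walk(node: str):
        for nxt, incoming in adjacency[node]:
            if nxt in on_path:
                continue
            path.append((nxt, incoming))
            if nxt == y:
                yield list(path)
            else:
                on_path.add(nxt)
                yield from walk(nxt)
                on_path.remove(nxt)
            path.pop()

    yield from walk(x)


def _path_active(dag: CausalDag, path, z: frozenset[str]) -> bool:
    """A path is active given z iff every intermediate node passes the
    chain/fork/collider rules."""
    for i in range(1, len(path) - 1):
        node, arrived_incoming = path[i]
        _, next_incoming = path[i + 1]
        is_collider = arrived_incoming and not next_incoming
        if is_collider:
            opened = node in z or bool(dag.descendants(node) & z)
            if not opened:
                return False
        else:
            if node in z:
                return False
    return True


def d_separated(dag: CausalDag, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """True iff every path between x and y is blocked given z."""
    z = frozenset(z)
    dag.require_nodes([x, y, *z])
    if x == y:
        raise DagError("x and y must differ")
    if x in z or y in z:
        raise DagError("x and y may not be members of z")
    return not any(
        _path_active(dag, p, z) for p in _undirected_paths(dag, x, y)
    )


# ---------------------------------------------------------------------------
# Adjustment validity
# ---------------------------------------------------------------------------

def _directed_causal_path(path) -> bool:
    """True iff every step of the path follows an arrow forward."""
    return all(incoming for _, incoming in path[1:])


def backdoor_valid(dag: CausalDag, query: AdjustmentQuery) -> bool:
    """Check whether the conditioning set identifies the exposure effect.

    The conditioning set is valid when every *non-causal* path from
    exposure to outcome (any path that is not a forward-directed causal
    chain) is blocked given the set, under the usual chain/fork/collider
    opening rules.  Conditioning on a mediator is permitted — it shifts the
    estimand to a controlled direct effect — but conditioning that opens a
    collider path (e.g. through a common effect of the exposure and a
    latent cause of the outcome) invalidates the set.
    """
    z = query.conditioning_set
    dag.require_nodes([query.exposure, query.outcome, *z])
    latent = z & dag.unobserved
    if latent:
        raise DagError(f"latent node(s) in conditioning set: {sorted(latent)}")
    for path in _undirected_paths(dag, query.exposure, query.outcome):
        if _directed_causal_path(path):
            continue
        if _path_active(dag, path, z):
            return False
    return True


def enumerate_minimal_adjustment_sets(
    dag: CausalDag, exposure: str, outcome: str
) -> list[frozenset[str]]:
    """All minimal observed conditioning sets valid for exposure -> outcome.

    Brute force over subsets of observed non-descendants of the exposure,
    which suffices at these graph sizes.  Results are sorted by size then
    lexicographically; a returned set has no valid proper subset.
    """
    if exposure == outcome:
        raise DagError("exposure and outcome must differ")
    dag.require_nodes([exposure, outcome])
    candidates = sorted(
        dag.observed - {exposure, outcome} - dag.descendants(exposure)
    )
    valid: list[frozenset[str]] = []
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            s = frozenset(combo)
            if any(v <= s for v in valid):
                continue  # superset of an already-minimal set
            if backdoor_valid(dag, AdjustmentQuery(exposure, outcome, s)):
                valid.append(s)
    return sorted(valid, key=lambda s: (len(s), sorted(s)))


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------

def write_edge_list(dag: CausalDag, path) -> None:
    """Write the DAG as one ``parent -> child`` line per edge, with a
    ``# latent:`` header naming unobserved nodes."""
    lines = []
    if dag.unobserved:
        lines.append("# latent: " + " ".join(sorted(dag.unobserved)))
    isolated = dag.nodes - {n for e in dag.edges for n in e}
    for n in sorted(isolated):
        lines.append(f"# node: {n}")
    for a, b in sorted(dag.edges):
        lines.append(f"{a} -> {b}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_edge_list(path) -> CausalDag:
    """Parse the plain-text edge-list format written by :func:`write_edge_list`."""
    nodes: set[str] = set()
    edges: set[Edge] = set()
    unobserved: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("latent:"):
                    unobserved.update(body[len("latent:"):].split())
                elif body.startswith("node:"):
                    nodes.update(body[len("node:"):].split())
                continue
            if "->" not in line:
                raise DagError(f"malformed edge line: {line!r}")
            a, b = (part.strip() for part in line.split("->", 1))
            if not a or not b:
                raise DagError(f"malformed edge line: {line!r}")
            nodes.update((a, b))
            edges.add((a, b))
    nodes.update(unobserved)
    return CausalDag(frozenset(nodes), frozenset(edges), frozenset(unobserved))
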
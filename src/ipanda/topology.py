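"""Pathway graphs, module collapse, walk counting and topological weights.

A pathway is a directed signed graph whose nodes are *gene units*: individual
genes, native multi-gene nodes, or collapsed coexpression modules.  The
topological weight of a unit is its share of independent start->end walks
through the graph, normalized to the pathway maximum:

    w_ip^T = N_ip / max_j N_jp

where N_ip counts the simple (node-repetition-free) walks from any zero
in-degree unit to any zero out-degree unit that pass through unit i.  Loops
are forbidden: a unit may appear at most once per walk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger("ipanda")

ACTIVATION = "activation"
INHIBITION = "inhibition"


class ComplexityError(RuntimeError):
    """Raised when simple-walk enumeration exceeds the configured budget."""


class SchemaError(ValueError):
    """Raised for malformed pathway-topology input."""


@dataclass(frozen=True)
class PathwayUnit:
    """One node of a pathway graph: a gene, a native gene set, or a module."""

    unit_id: str
    genes: tuple[str, ...]
    sign: int  # +1 activator of the pathway, -1 inhibitor
    kind: str = "gene"  # "gene" | "module"

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise SchemaError(
                f"unit {self.unit_id!r}: sign must be +1 or -1, got {self.sign!r}"
            )
        if not self.genes:
            raise SchemaError(f"unit {self.unit_id!r} has no member genes")


@dataclass
class PathwayGraph:
    """Directed signed graph of gene units for one pathway."""

    pathway_id: str
    units: dict[str, PathwayUnit]
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for src, dst, etype in self.edges:
            for end in (src, dst):
                if end not in self.units:
                    raise SchemaError(
                        f"pathway {self.pathway_id!r}: edge references "
                        f"undeclared unit {end!r}"
                    )
            if etype not in (ACTIVATION, INHIBITION):
                raise SchemaError(
                    f"pathway {self.pathway_id!r}: bad edge type {etype!r}"
                )

    @property
    def genes(self) -> set[str]:
        return {g for u in self.units.values() for g in u.genes}

    @property
    def size(self) -> int:
        """N_i: number of unique member genes."""
        return len(self.genes)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(pathway_id=self.pathway_id)
        for uid, unit in self.units.items():
            g.add_node(uid, genes=unit.genes, sign=unit.sign, kind=unit.kind)
        for src, dst, etype in self.edges:
            if src != dst:  # self-edges carry no walk information
                g.add_edge(src, dst, type=etype)
        return g


@dataclass
class PathwayDatabase:
    """A named collection of pathway graphs with unique identifiers."""

    pathways: list[PathwayGraph]
    name: str = "pathways"
    version: str = "0"

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate pathway identifiers in database")
        for p in self.pathways:
            if not p.units:
                raise SchemaError(f"pathway {p.pathway_id!r} has no nodes")

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: str) -> PathwayGraph:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return out


@dataclass
class WalkCounts:
    pathway_id: str
    counts: dict[str, int]
    n_complete_walks: int


@dataclass
class TopologicalWeights:
    pathway_id: str
    weights: dict[str, float]


# ---------------------------------------------------------------------------
# Module collapse
# ---------------------------------------------------------------------------

def collapse_modules(graph: PathwayGraph, modules) -> PathwayGraph:
    """Contract nodes sharing a coexpression module into single unit nodes.

    All nodes whose member genes intersect the same module (chains of shared
    membership are followed transitively) become one unit carrying the union
    of member genes and of incident edges; self-edges are dropped.  The
    collapsed unit takes the majority sign of the contracted nodes; an exact
    tie splits the module into per-sign sub-units, since a unit must carry a
    single activation sign.  Pathways containing no module gene are returned
    unchanged.
    """
    if modules is None or not getattr(modules, "modules", None):
        return graph

    gene_to_module = modules.assignment
    # union-find over node ids keyed by shared module membership
    parent = {uid: uid for uid in graph.units}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    module_nodes: dict[str, list[str]] = {}
    for uid, unit in graph.units.items():
        for g in unit.genes:
            mid = gene_to_module.get(g)
            if mid is not None:
                module_nodes.setdefault(mid, []).append(uid)
    touched = False
    for nodes in module_nodes.values():
        for other in nodes[1:]:
            union(nodes[0], other)
            touched = True
    if not touched:
        return graph

    groups: dict[str, list[str]] = {}
    for uid in graph.units:
        groups.setdefault(find(uid), []).append(uid)

    # split multi-node groups on sign ties
    new_units: dict[str, PathwayUnit] = {}
    node_to_new: dict[str, str] = {}
    for root, members in sorted(groups.items()):
        if len(members) == 1:
            uid = members[0]
            new_units[uid] = graph.units[uid]
            node_to_new[uid] = uid
            continue
        members = sorted(members)
        pos = [m for m in members if graph.units[m].sign > 0]
        neg = [m for m in members if graph.units[m].sign < 0]
        if len(pos) == len(neg):
            subgroups = [(pos, +1), (neg, -1)]
        else:
            sign = +1 if len(pos) > len(neg) else -1
            subgroups = [(members, sign)]
        for sub, sign in subgroups:
            if not sub:
                continue
            if len(sub) == 1:
                uid = sub[0]
                new_units[uid] = graph.units[uid]
                node_to_new[uid] = uid
                continue
            uid = "+".join(sub)
            genes = tuple(
                sorted({g for m in sub for g in graph.units[m].genes})
            )
            new_units[uid] = PathwayUnit(uid, genes, sign, kind="module")
            for m in sub:
                node_to_new[m] = uid

    new_edges: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    for src, dst, etype in graph.edges:
        ns, nd = node_to_new[src], node_to_new[dst]
        if ns == nd:
            continue
        if (ns, nd) not in seen:
            seen.add((ns, nd))
            new_edges.append((ns, nd, etype))
    return PathwayGraph(graph.pathway_id, new_units, new_edges)


# ---------------------------------------------------------------------------
# Walk counting
# ---------------------------------------------------------------------------

def count_walks(graph: PathwayGraph, max_walks: int = 10**6) -> WalkCounts:
    """Count simple start->end walks through each unit of a pathway.

    Starts are units with zero incoming edges, ends are units with zero
    outgoing edges; an isolated unit is both and lies on exactly one walk
    (itself).  On acyclic graphs a dynamic program (walks into a unit times
    walks out of it) is used; cyclic graphs fall back to depth-first
    enumeration with a visited set, so a unit never repeats within a walk.

    Raises :class:`ComplexityError` when the number of complete walks exceeds
    ``max_walks``.
    """
    if not graph.units:
        raise ValueError(f"pathway {graph.pathway_id!r} is empty")
    if max_walks < 1:
        raise ValueError("max_walks must be >= 1")
    g = graph.to_networkx()
    starts = [n for n in g if g.in_degree(n) == 0]
    ends = [n for n in g if g.out_degree(n) == 0]
    if nx.is_directed_acyclic_graph(g):
        counts, total = _count_walks_dag(g, starts, ends)
    else:
        counts, total = _count_walks_dfs(g, starts, ends, max_walks)
    if total > max_walks:
        raise ComplexityError(
            f"pathway {graph.pathway_id!r}: {total} start->end walks exceed "
            f"max_walks={max_walks}; simplify the graph or collapse modules"
        )
    return WalkCounts(graph.pathway_id, counts, total)


def _count_walks_dag(
    g: nx.DiGraph, starts: list[str], ends: list[str]
) -> tuple[dict[str, int], int]:
    order = list(nx.topological_sort(g))
    into = {n: 0 for n in g}
    for s in starts:
        into[s] = 1
    for n in order:
        for succ in g.successors(n):
            into[succ] += into[n]
    out = {n: 0 for n in g}
    for e in ends:
        out[e] = 1
    for n in reversed(order):
        for pred in g.predecessors(n):
            out[pred] += out[n]
    counts = {n: into[n] * out[n] for n in g}
    total = sum(into[e] for e in ends)
    return counts, total


def _count_walks_dfs(
    g: nx.DiGraph, starts: list[str], ends: list[str], max_walks: int
) -> tuple[dict[str, int], int]:
    counts = {n: 0 for n in g}
    end_set = set(ends)
    total = 0
    path: list[str] = []
    on_path: set[str] = set()

    def visit(node: str) -> None:
        nonlocal total
        path.append(node)
        on_path.add(node)
        if node in end_set:
            total += 1
            if total > max_walks:
                raise ComplexityError(
                    f"more than {max_walks} start->end walks; "
                    "simplify the graph or collapse modules"
                )
            for n in path:
                counts[n] += 1
        for succ in g.successors(node):
            if succ not in on_path:
                visit(succ)
        path.pop()
        on_path.discard(node)

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, len(g) * 10 + 1000))
    try:
        for s in starts:
            visit(s)
    finally:
        sys.setrecursionlimit(old_limit)
    return counts, total


def topological_weights(counts: WalkCounts) -> TopologicalWeights:
    """Normalize walk counts to the pathway maximum: w_ip^T = N_ip / max N_jp.

    When no complete start->end walk exists (e.g. every unit sits on a cycle)
    all weights fall back to 1 and a warning is logged, so the pathway scores
    as if topology were uninformative.
    """
    max_count = max(counts.counts.values(), default=0)
    if max_count == 0:
        logger.warning(
            "pathway %s has no complete start->end walk; "
            "topological weights set to 1",
            counts.pathway_id,
        )
        return TopologicalWeights(
            counts.pathway_id, {u: 1.0 for u in counts.counts}
        )
    return TopologicalWeights(
        counts.pathway_id,
        {u: n / max_count for u, n in counts.counts.items()},
    )
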
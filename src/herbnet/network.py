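"""Compound-target and compound-target-pathology networks.

A C-T network is an undirected, unweighted bipartite graph between
prescription compounds and disease-associated protein targets (official
gene symbols, uppercased). The P-T-D extension annotates targets with
pathology categories (inflammation, apoptosis, coagulation, ...),
many-to-many. Only degree-style statistics are computed: per-node degree,
node/edge counts, mean compound degree and max target degree.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import UndefinedFractionError, ValidationError

__all__ = [
    "CTNetwork",
    "PTDNetwork",
    "NodeMetrics",
    "DEFAULT_PATHOLOGY_CATEGORIES",
    "build_ct_network",
    "annotate_pathology",
    "category_fraction",
    "export_network",
    "import_edge_tsv",
]

#: pathology vocabulary of the intracerebral-hemorrhage application; extensible
DEFAULT_PATHOLOGY_CATEGORIES = (
    "inflammation",
    "apoptosis",
    "proliferation/differentiation",
    "oxidative stress",
    "blood-brain-barrier",
    "neurotransmitter",
    "calcium overload",
    "coagulation",
)


def normalize_symbol(symbol: str) -> str:
    """Official-symbol convention: strip whitespace, uppercase."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class NodeMetrics:
    """Network-level degree bookkeeping."""

    n_compounds: int
    n_targets: int
    n_edges: int
    mean_compound_degree: float
    max_target_degree: int

    @property
    def n_nodes(self) -> int:
        return self.n_compounds + self.n_targets


class CTNetwork:
    """Undirected bipartite compound-target network.

    Compounds and targets live in disjoint namespaces (node attribute
    ``kind``); duplicate edges collapse to one.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        self._check()

    def _check(self) -> None:
        for u, v in self.graph.edges:
            ku, kv = self.graph.nodes[u]["kind"], self.graph.nodes[v]["kind"]
            if {ku, kv} != {"compound", "target"}:
                raise ValidationError(f"edge ({u}, {v}) is not compound-target")

    @property
    def compounds(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "compound")

    @property
    def targets(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "target")

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edges as (compound, target) pairs."""
        out = set()
        for u, v in self.graph.edges:
            if self.graph.nodes[u]["kind"] == "compound":
                out.add((u, v))
            else:
                out.add((v, u))
        return out

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def compound_degrees(self) -> dict[str, int]:
        return {c: self.graph.degree[c] for c in self.compounds}

    def target_degrees(self) -> dict[str, int]:
        return {t: self.graph.degree[t] for t in self.targets}

    def metrics(self) -> NodeMetrics:
        nc, nt, ne = len(self.compounds), len(self.targets), self.graph.number_of_edges()
        return NodeMetrics(
            n_compounds=nc,
            n_targets=nt,
            n_edges=ne,
            mean_compound_degree=ne / nc if nc else 0.0,
            max_target_degree=max((self.graph.degree[t] for t in self.targets), default=0),
        )

    def restrict_to_compounds(self, keep: Iterable[str]) -> "CTNetwork":
        """Subnetwork induced by a compound subset; isolated targets drop."""
        keep = set(keep)
        g = nx.Graph()
        for c, t in self.edges:
            if c in keep:
                g.add_node(c, kind="compound")
                g.add_node(t, kind="target")
                g.add_edge(c, t)
        return CTNetwork(g)


class PTDNetwork(CTNetwork):
    """C-T network over potential compounds plus pathology-category annotation."""

    def __init__(self, graph: nx.Graph, categories: Mapping[str, frozenset[str]]):
        super().__init__(graph)
        self.categories = {t: frozenset(c) for t, c in categories.items()}

    def category_counts(self) -> dict[str, int]:
        """Targets per category; a target in two categories counts in both."""
        counts = {}
        for cats in self.categories.values():
            for c in cats:
                counts[c] = counts.get(c, 0) + 1
        return counts

    def category_fractions(self) -> dict[str, float]:
        """Per-category percent of targets, rounded half-up to 2 decimals."""
        total = len(self.targets)
        if total == 0:
            return {}
        return {c: category_fraction(k, total) for c, k in self.category_counts().items()}

    def uncategorized_targets(self) -> list[str]:
        return [t for t in self.targets if not self.categories.get(t)]


def build_ct_network(edges: Iterable[tuple[str, str]]) -> CTNetwork:
    """Build a C-T network from (compound id, target symbol) pairs.

    Target symbols are normalized (uppercase, stripped); duplicate pairs
    collapse. An empty edge list yields an empty network.
    """
    g = nx.Graph()
    for i, row in enumerate(edges):
        try:
            compound, target = row
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"edge row {i + 1} malformed: {row!r}") from exc
        compound = str(compound).strip()
        target = normalize_symbol(target)
        if not compound or not target:
            raise ValidationError(f"edge row {i + 1} has an empty endpoint: {row!r}")
        g.add_node(compound, kind="compound")
        g.add_node(target, kind="target")
        g.add_edge(compound, target)
    return CTNetwork(g)


def annotate_pathology(
    net: CTNetwork,
    category_map: Mapping[str, Iterable[str]],
    vocabulary: Iterable[str] = DEFAULT_PATHOLOGY_CATEGORIES,
) -> PTDNetwork:
    """Attach pathology categories to the network's targets.

    ``category_map`` maps target symbol -> category name(s); assignments to
    targets absent from the network raise a single warning with a count,
    never an error. Category names must come from ``vocabulary``.
    """
    vocab = set(vocabulary)
    present = set(net.targets)
    categories: dict[str, set[str]] = {t: set() for t in present}
    absent = 0
    for target, cats in category_map.items():
        cats = [cats] if isinstance(cats, str) else list(cats)
        for c in cats:
            if c not in vocab:
                raise ValidationError(f"category {c!r} not in declared vocabulary")
        t = normalize_symbol(target)
        if t not in present:
            absent += 1
            continue
        categories[t].update(cats)
    if absent:
        warnings.warn(
            f"{absent} category assignment(s) refer to targets absent from the network",
            stacklevel=2,
        )
    return PTDNetwork(net.graph.copy(), {t: frozenset(c) for t, c in categories.items()})


def category_fraction(count: int, total: int) -> float:
    """100*count/total as percent, rounded half-up to 2 decimals."""
    if total == 0:
        raise UndefinedFractionError("fraction undefined for total = 0")
    if not 0 <= count <= total:
        raise ValidationError(f"count {count} outside [0, {total}]")
    frac = decimal.Decimal(100 * count) / decimal.Decimal(total)
    return float(frac.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


def export_network(net: CTNetwork, path, format: str = "tsv") -> None:
    """Write a network as SIF, GraphML or edge-list TSV.

    SIF rows are ``compound interacts target``; GraphML carries the node
    ``kind`` and (for annotated networks) a ``categories`` attribute;
    the edge TSV round-trips exactly through :func:`import_edge_tsv`.
    """
    fmt = format.lower()
    edges = sorted(net.edges)
    if fmt == "sif":
        with open(path, "w") as fh:
            for c, t in edges:
                fh.write(f"{c}\tinteracts\t{t}\n")
    elif fmt == "graphml":
        g = net.graph.copy()
        if isinstance(net, PTDNetwork):
            for t, cats in net.categories.items():
                g.nodes[t]["categories"] = "|".join(sorted(cats))
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        pd.DataFrame(edges, columns=["compound", "target"]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {format!r}; expected sif, graphml or tsv")


def import_edge_tsv(path) -> CTNetwork:
    """Read an edge-list TSV (columns compound, target) back into a network."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"compound", "target"} <= set(df.columns):
        raise ValidationError("edge TSV must have 'compound' and 'target' columns")
    return build_ct_network(df[["compound", "target"]].itertuples(index=False, name=None))
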
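"""Hypergeometric over-representation analysis with kappa term grouping.

Given a query gene list (e.g. the targets of a prescription's potential
compounds) and a catalog of named gene sets (e.g. REACTOME pathways) over a
universe of N genes, each term is tested with the upper-tail hypergeometric
probability P(X >= k) of observing at least the realized overlap k between
the query (size n) and the term (size K). P-values are adjusted with
Benjamini-Hochberg by default. Significant terms are then grouped by Cohen's
kappa agreement of their gene memberships: pairs with kappa at or above a
threshold (default 0.4) are linked, connected components become functional
groups, and each group's leading term is its most significant member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyQueryError, UndefinedKappaError, ValidationError
from .network import normalize_symbol

__all__ = [
    "GeneSetCatalog",
    "EnrichmentResults",
    "hypergeometric_p",
    "run_ora",
    "kappa_score",
    "group_terms",
    "read_gmt",
    "write_gmt",
]

DEFAULT_KAPPA_THRESHOLD = 0.4


@dataclass
class GeneSetCatalog:
    """Named gene sets over a declared universe.

    ``universe_size`` may exceed the union of the terms (the annotation
    source usually covers more genes than any one catalog slice).
    """

    terms: dict[str, frozenset[str]]
    universe_size: int
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {
            str(name): frozenset(normalize_symbol(g) for g in genes)
            for name, genes in self.terms.items()
        }
        for name, genes in self.terms.items():
            if not genes:
                raise ValidationError(f"term {name!r} is empty")
        union = set().union(*self.terms.values()) if self.terms else set()
        if self.universe_size < len(union):
            raise ValidationError(
                f"universe size {self.universe_size} smaller than union of terms ({len(union)})"
            )

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path, universe_size: int | None = None) -> GeneSetCatalog:
    """Read a GMT file (term <tab> description <tab> genes...).

    When ``universe_size`` is omitted, the union of all term genes is used.
    """
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = frozenset(normalize_symbol(g) for g in parts[2:] if g.strip())
            descriptions[parts[0]] = parts[1]
    if universe_size is None:
        universe_size = len(set().union(*terms.values())) if terms else 0
    return GeneSetCatalog(terms, universe_size, descriptions)


def write_gmt(catalog: GeneSetCatalog, path) -> None:
    with open(path, "w") as fh:
        for name, genes in catalog.terms.items():
            desc = catalog.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail p = P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k``: realized overlap, ``K``: term size, ``n``: query size,
    ``N``: universe size. p lies in (0, 1]; k = 0 gives exactly 1.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValidationError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    # sf(k-1) = P(X >= k); exact, no 1-cdf cancellation
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def kappa_score(term_a: Iterable[str], term_b: Iterable[str], N: int) -> float:
    """Cohen's kappa of two gene sets' membership over a universe of N genes.

    Built from the 2x2 table (a = |A∩B|, b = |A\\B|, c = |B\\A|,
    d = N - |A∪B|): observed agreement (a+d)/N against chance agreement
    from the marginals. Symmetric; 1 for identical proper subsets, -1 for
    complementary halves of the universe.
    """
    A, B = set(term_a), set(term_b)
    if N <= 0:
        raise ValidationError("universe size must be positive")
    if len(A | B) > N:
        raise ValidationError("term union exceeds the universe")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = N - len(A | B)
    po = (a + d) / N
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / N**2
    if pe == 1.0:
        raise UndefinedKappaError(
            "expected agreement is 1 (both sets empty or both equal to the universe)"
        )
    return (po - pe) / (1 - pe)


@dataclass
class EnrichmentResults:
    """Per-term ORA results, sorted by p, with optional kappa grouping.

    ``table`` columns: term, K (term size), k (overlap), n (query size),
    N (universe), p, q, and after :meth:`group` also group and leading.
    """

    table: pd.DataFrame
    query: frozenset[str]
    catalog: GeneSetCatalog
    alpha: float = 0.05
    adjustment: str = "fdr_bh"
    term_graph: nx.Graph | None = None
    kappa_threshold: float | None = None

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = self.alpha if alpha is None else alpha
        return self.table[self.table["q"] <= alpha].reset_index(drop=True)

    def group(self, kappa_threshold: float = DEFAULT_KAPPA_THRESHOLD) -> "EnrichmentResults":
        """Assign kappa-component groups to significant terms (in place)."""
        graph, assignment, leading = group_terms(
            self.significant(), self.catalog, kappa_threshold
        )
        self.term_graph = graph
        self.kappa_threshold = kappa_threshold
        self.table["group"] = self.table["term"].map(assignment).astype("Int64")
        self.table["leading"] = self.table["term"].isin(leading)
        return self

    def summary(self, top: int = 10) -> str:
        lines = [
            "Over-representation analysis",
            f"  query genes: {len(self.query)}   catalog terms: {len(self.catalog)}   "
            f"universe: {self.catalog.universe_size}",
            f"  adjustment: {self.adjustment}   alpha: {self.alpha}   "
            f"significant terms: {len(self.significant())}",
        ]
        if self.kappa_threshold is not None:
            n_groups = self.table["group"].nunique(dropna=True)
            lines.append(f"  kappa threshold: {self.kappa_threshold}   groups: {n_groups}")
        with pd.option_context("display.width", 120):
            lines.append(self.table.head(top).to_string(index=False))
        return "\n".join(lines)


def run_ora(
    query: Iterable[str],
    catalog: GeneSetCatalog,
    alpha: float = 0.05,
    adjustment: str = "fdr_bh",
) -> EnrichmentResults:
    """Test every catalog term for over-representation in the query.

    Query symbols are normalized and deduplicated; symbols outside the
    catalog's terms are kept in the query size n (they are part of the
    drawn sample). Only terms with overlap k >= 1 are reported, sorted by
    p ascending. ``adjustment`` is any statsmodels multipletests method.
    """
    q = {normalize_symbol(g) for g in query if str(g).strip()}
    if not q:
        raise EmptyQueryError("query gene list is empty after normalization")
    n, N = len(q), catalog.universe_size
    if n > N:
        raise ValidationError(f"query size {n} exceeds universe size {N}")
    rows = []
    for name, genes in catalog.terms.items():
        k = len(q & genes)
        if k == 0:
            continue
        rows.append((name, len(genes), k, hypergeometric_p(k, len(genes), n, N)))
    table = pd.DataFrame(rows, columns=["term", "K", "k", "p"])
    if len(table):
        table = table.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
        table["q"] = multipletests(table["p"].to_numpy(), method=adjustment)[1]
    else:
        table["q"] = pd.Series(dtype=float)
    table.insert(3, "n", n)
    table.insert(4, "N", N)
    return EnrichmentResults(table=table, query=frozenset(q), catalog=catalog,
                             alpha=alpha, adjustment=adjustment)


def group_terms(
    results: pd.DataFrame,
    catalog: GeneSetCatalog | Mapping[str, frozenset[str]],
    kappa_threshold: float = DEFAULT_KAPPA_THRESHOLD,
) -> tuple[nx.Graph, dict[str, int], set[str]]:
    """Group terms whose gene memberships agree (kappa >= threshold).

    Nodes are the supplied terms; edges carry the kappa weight; connected
    components are the groups, numbered by their best (lowest) p. The
    leading term of each group is its smallest-p member, ties broken by
    larger overlap k then lexicographic term name.

    Returns (term graph, {term: group id}, {leading terms}).
    """
    terms = results["term"].tolist()
    sets = catalog.terms if isinstance(catalog, GeneSetCatalog) else catalog
    N = catalog.universe_size if isinstance(catalog, GeneSetCatalog) else None
    if N is None:
        N = len(set().union(*sets.values())) if sets else 0
    graph = nx.Graph()
    graph.add_nodes_from(terms)
    for i, ta in enumerate(terms):
        for tb in terms[i + 1 :]:
            kap = kappa_score(sets[ta], sets[tb], N)
            if kap >= kappa_threshold:
                graph.add_edge(ta, tb, kappa=kap)
    rank = {
        row.term: (row.p, -row.k, row.term) for row in results.itertuples()
    }
    components = [sorted(c, key=lambda t: rank[t]) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: rank[c[0]])
    assignment = {t: gid for gid, comp in enumerate(components, start=1) for t in comp}
    leading = {comp[0] for comp in components}
    return graph, assignment, leading
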
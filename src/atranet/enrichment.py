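"""Hypergeometric term enrichment and the kappa-agreement term network.

Enriched terms are connected when the chance-corrected agreement (Cohen's
kappa) of their gene memberships reaches a threshold; connected components
of that graph are the functional groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

ENRICH_COLUMNS = ["term", "name", "k", "K", "n", "N", "p", "fdr"]


@dataclass
class TermNetwork:
    graph: nx.Graph
    groups: list[set[str]] = field(default_factory=list)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"term_a": a, "term_b": b, "kappa": d["kappa"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["term_a", "term_b", "kappa"])


def hypergeometric_enrich(
    signature: Iterable[str],
    annotations: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Right-tail hypergeometric enrichment of the signature in each term.

    ``p = sum_{i>=k} C(K,i) C(N-K,n-i) / C(N,n)`` with N the universe size,
    K the term size (within the universe), n the signature size and k the
    overlap.  BH adjustment across all tested terms.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    signature = set(signature) & universe
    rows = []
    for term in annotations:
        name, members = annotations.sets[term]
        members_u = set(members) & universe
        if not members_u:
            continue
        k = len(signature & members_u)
        K = len(members_u)
        n = len(signature)
        N = len(universe)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term": term, "name": name, "k": k, "K": K, "n": n, "N": N, "p": p}
        )
    result = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    if len(result):
        _, fdr, _, _ = multipletests(result["p"], method="fdr_bh")
        result["fdr"] = fdr
    else:
        result["fdr"] = []
    return result.sort_values("p", kind="stable").reset_index(drop=True)


def kappa_statistic(
    term_a: Iterable[str], term_b: Iterable[str], universe: Iterable[str]
) -> float:
    """Cohen's kappa of two terms' gene memberships over the universe."""
    universe = set(universe)
    a = set(term_a) & universe
    b = set(term_b) & universe
    if not a or not b:
        raise ValueError("both terms must be non-empty within the universe")
    N = len(universe)
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = N - both - only_a - only_b
    po = (both + neither) / N
    pe = (len(a) * len(b) + (N - len(a)) * (N - len(b))) / (N * N)
    if pe >= 1.0:  # both terms cover the whole universe
        return 1.0
    return (po - pe) / (1.0 - pe)


def build_term_network(
    results: pd.DataFrame,
    annotations: GeneSetCollection,
    kappa_min: float = 0.4,
    universe: Iterable[str] | None = None,
) -> TermNetwork:
    """Link enriched terms whose membership kappa reaches ``kappa_min``.

    The agreement universe defaults to all genes annotated to at least one
    tested term.  Groups are the connected components of the term graph.
    """
    terms = list(results["term"])
    if universe is None:
        universe = set()
        for t in terms:
            universe |= set(annotations.members(t))
    universe = set(universe)
    g = nx.Graph()
    g.add_nodes_from(terms)
    for a, b in combinations(terms, 2):
        kappa = kappa_statistic(
            annotations.members(a), annotations.members(b), universe
        )
        if kappa >= kappa_min:
            g.add_edge(a, b, kappa=kappa)
    groups = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    return TermNetwork(graph=g, groups=[set(c) for c in groups])
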
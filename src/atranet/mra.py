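"""Master-regulator analysis and common-network assembly.

A TF is called a master regulator (MR) when its regulon is enriched in
the differentiation signature by a one-sided Fisher exact test at BH
FDR < 5%.  MRs shared by every cell line are the common MRs; their
edges, present in every line's network, targeting signature genes and
supported by a TF binding site overlapping the target's promoter, form
the common regulatory network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval
from .netinf import Network

log = logging.getLogger("atranet")

MR_COLUMNS = [
    "tf",
    "overlap",
    "regulon_size",
    "signature_size",
    "universe_size",
    "odds_ratio",
    "p",
    "fdr",
    "is_mr",
]


@dataclass
class CommonNetwork:
    regulators: set[str]
    targets: set[str]
    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["regulator", "target"])
    )

    def __post_init__(self) -> None:
        if len(self.edges):
            linked = set(self.edges["regulator"])
            orphan = self.regulators - linked
            if orphan:
                raise ValueError(f"regulators without retained edges: {sorted(orphan)}")


def fisher_regulon_enrichment(
    regulon: Iterable[str],
    signature: Iterable[str],
    universe: Iterable[str],
    tf: str = "",
) -> dict:
    """One-sided (enrichment) Fisher exact test on the 2x2 membership table.

    The right-tail p equals the hypergeometric tail
    ``sum_{i>=k} C(K,i) C(N-K,n-i) / C(N,n)`` with K the regulon size,
    n the signature size, N the universe size and k the overlap.
    """
    universe = set(universe)
    regulon = set(regulon) & universe
    signature = set(signature) & universe
    N, K, n = len(universe), len(regulon), len(signature)
    k = len(regulon & signature)
    if K == 0:
        return {
            "tf": tf,
            "overlap": 0,
            "regulon_size": 0,
            "signature_size": n,
            "universe_size": N,
            "odds_ratio": np.nan,
            "p": 1.0,
            "fdr": np.nan,
            "is_mr": False,
        }
    p = float(hypergeom.sf(k - 1, N, K, n))
    a, b, c, d = k, K - k, n - k, N - K - (n - k)
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return {
        "tf": tf,
        "overlap": k,
        "regulon_size": K,
        "signature_size": n,
        "universe_size": N,
        "odds_ratio": odds,
        "p": p,
        "fdr": np.nan,
        "is_mr": False,
    }


def mra_table(
    regulons: Mapping[str, Iterable[str]],
    signature: Iterable[str],
    universe: Iterable[str],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment for every TF, BH-adjusted; ``is_mr`` iff fdr < fdr_max."""
    rows = [
        fisher_regulon_enrichment(targets, signature, universe, tf=tf)
        for tf, targets in sorted(regulons.items())
    ]
    table = pd.DataFrame(rows, columns=MR_COLUMNS)
    if len(table):
        _, fdr, _, _ = multipletests(table["p"], method="fdr_bh")
        table["fdr"] = fdr
        table["is_mr"] = table["fdr"] < fdr_max
    return table


def common_mrs(per_line_mr_sets: Sequence[Iterable[str]]) -> set[str]:
    """Strict intersection of per-cell-line MR sets."""
    if len(per_line_mr_sets) < 2:
        raise ValueError("need MR sets from at least two cell lines")
    sets = [set(s) for s in per_line_mr_sets]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def filter_by_promoter_binding(
    edges: pd.DataFrame,
    promoters: Mapping[str, GenomicInterval],
    tfbs: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Keep edges whose TF has >=1 binding site overlapping (>=1 bp, same
    chromosome, strand-agnostic) the target's promoter interval.

    Targets without a promoter record drop their edges (logged).
    """
    keep = []
    for _, row in edges.iterrows():
        target, reg = row["target"], row["regulator"]
        promoter = promoters.get(target)
        if promoter is None:
            log.info("edge %s->%s dropped: no promoter record", reg, target)
            keep.append(False)
            continue
        sites = tfbs.get(reg, ())
        keep.append(any(site.overlaps(promoter) for site in sites))
    return edges[np.array(keep, dtype=bool)].reset_index(drop=True)


def assemble_common_network(
    per_line_networks: Sequence[Network],
    common_mr_set: Iterable[str],
    signature: Iterable[str],
    promoters: Mapping[str, GenomicInterval] | None = None,
    tfbs: Mapping[str, Sequence[GenomicInterval]] | None = None,
    mode: str = "edges",
) -> CommonNetwork:
    """Intersect per-line networks into the common regulatory network.

    ``mode="edges"`` (default) keeps regulator->target edges present in
    every line's network; ``mode="nodes"`` relaxes to edges whose regulator
    and target both appear (in those roles) in every line.  Edges are then
    restricted to common MRs regulating signature genes and, when promoter
    and binding-site records are supplied, to TF-promoter overlaps.
    """
    if len(per_line_networks) < 2:
        raise ValueError("need networks from at least two cell lines")
    common_mr_set = set(common_mr_set)
    signature = set(signature)
    if mode == "edges":
        shared = per_line_networks[0].edge_set()
        for net in per_line_networks[1:]:
            shared &= net.edge_set()
    elif mode == "nodes":
        regs = set.intersection(
            *[set(net.edges["regulator"]) for net in per_line_networks]
        )
        tgts = set.intersection(
            *[set(net.edges["target"]) for net in per_line_networks]
        )
        shared = {
            e
            for net in per_line_networks
            for e in net.edge_set()
            if e[0] in regs and e[1] in tgts
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows = [
        {"regulator": r, "target": t}
        for r, t in sorted(shared)
        if r in common_mr_set and t in signature
    ]
    edges = pd.DataFrame(rows, columns=["regulator", "target"])
    if promoters is not None and tfbs is not None:
        edges = filter_by_promoter_binding(edges, promoters, tfbs)
    return CommonNetwork(
        regulators=set(edges["regulator"]),
        targets=set(edges["target"]),
        edges=edges,
    )


def extract_subnetwork(
    network: CommonNetwork, category: Iterable[str]
) -> CommonNetwork:
    """Restrict targets to a gene category, keeping regulators with >=1 edge."""
    category = set(category)
    edges = network.edges[network.edges["target"].isin(category)].reset_index(
        drop=True
    )
    return CommonNetwork(
        regulators=set(edges["regulator"]),
        targets=set(edges["target"]),
        edges=edges,
    )
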
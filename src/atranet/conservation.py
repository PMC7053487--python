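"""Homolog conservation: pairwise distances, NJ tree, relative position.

Distances between aligned homologous sequences use the Kimura
two-parameter model, which separates transition (P) and transversion
(Q) fractions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)   [substitutions/site]

Trees are built with the Saitou-Nei neighbour-joining algorithm (ties
broken towards the lexicographically smallest taxon pair, negative
branch lengths clamped to zero and flagged).  The position of each
species' homolog relative to the anchor gene is classified as inside /
upstream / downstream / distal, strand-relative to the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np

from .io import GenomicInterval

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
VALID = PURINES | PYRIMIDINES


class SaturationError(ValueError):
    """Observed divergence too high for the distance model."""


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    Columns where either sequence holds a gap or ambiguous base are
    excluded pairwise.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a = seq_a.upper()
    b = seq_b.upper()
    n = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in VALID or y not in VALID:
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        raise ValueError("no comparable (ungapped, unambiguous) sites")
    P = transitions / n
    Q = transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"divergence saturated (P={P:.3f}, Q={Q:.3f})"
        )
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.taxa)
        if self.d.shape != (k, k):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(self.d) != 0).any():
            raise ValueError("diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")

    @classmethod
    def from_alignment(cls, seqs: dict[str, str]) -> "DistanceMatrix":
        taxa = list(seqs)
        k = len(taxa)
        d = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                d[i, j] = d[j, i] = k2p_distance(seqs[taxa[i]], seqs[taxa[j]])
        return cls(taxa=taxa, d=d)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """Unrooted tree as newick text plus bookkeeping."""

    newick: str
    taxa: list[str]
    clamped_branches: int = 0
    notes: list[str] = field(default_factory=list)

    def to_biopython(self):
        from Bio import Phylo

        return Phylo.read(StringIO(self.newick), "newick")


def _fmt(length: float) -> str:
    return f"{length:.10f}".rstrip("0").rstrip(".") or "0"


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    Joins minimise the Q criterion; exact ties pick the pair whose sorted
    (lexicographically smallest member leaf) labels are smallest.  The
    final three nodes are resolved with the three-point formula, giving
    an unrooted tree with a trifurcating root.  Negative branch lengths
    are clamped to zero and counted in ``clamped_branches``.
    """
    k = len(dm.taxa)
    if k < 3:
        raise ValueError("need at least three taxa")
    # active nodes: newick fragment, smallest contained leaf name
    nodes: list[tuple[str, str]] = [(t, t) for t in dm.taxa]
    D = dm.d.astype(float).copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(q, np.inf)
        q_min = q.min()
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                if q[i, j] <= q_min + 1e-12:
                    key = tuple(sorted((nodes[i][1], nodes[j][1])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        li = clamp(0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2)))
        lj = clamp(D[i, j] - (0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))))
        newick = f"({nodes[i][0]}:{_fmt(li)},{nodes[j][0]}:{_fmt(lj)})"
        mini = min(nodes[i][1], nodes[j][1])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [m for m in range(r) if m not in (i, j)]
        D = np.vstack([D[keep][:, keep], d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[m] for m in keep] + [(newick, mini)]

    # final trifurcation via the three-point formula
    (na, ma), (nb, mb), (nc, mc) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = clamp(0.5 * (dab + dac - dbc))
    lb = clamp(0.5 * (dab + dbc - dac))
    lc = clamp(0.5 * (dac + dbc - dab))
    order = sorted(
        [(ma, na, la), (mb, nb, lb), (mc, nc, lc)], key=lambda t: t[0]
    )
    inner = ",".join(f"{frag}:{_fmt(ln)}" for _, frag, ln in order)
    newick = f"({inner});"
    notes = []
    if clamped:
        notes.append(f"{clamped} negative branch length(s) clamped to 0")
    return PhyloTree(
        newick=newick, taxa=list(dm.taxa), clamped_branches=clamped, notes=notes
    )


# ---------------------------------------------------------------------------
# relative position
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PositionCall:
    species: str
    position_class: str  # inside | upstream | downstream | distal
    distance_bp: int | None  # signed, strand-relative (negative = upstream)


def classify_position(
    hit: GenomicInterval,
    gene: GenomicInterval,
    distal_cutoff: int = 500_000,
    species: str = "",
) -> PositionCall:
    """Classify a homolog hit relative to the anchor gene.

    ``inside`` means >=1 bp overlap with the gene body; otherwise the hit
    is upstream or downstream relative to the gene's strand, or ``distal``
    when it lies on another chromosome or beyond ``distal_cutoff`` bp from
    the nearest gene boundary.  ``distance_bp`` is the signed gap to the
    nearest boundary (negative upstream), None on another chromosome.
    """
    if hit.chrom != gene.chrom:
        return PositionCall(species=species, position_class="distal", distance_bp=None)
    if hit.overlaps(gene):
        return PositionCall(species=species, position_class="inside", distance_bp=0)
    if hit.end <= gene.start:
        gap = gene.start - hit.end
        before = True
    else:
        gap = hit.start - gene.end
        before = False
    minus = gene.strand == "-"
    upstream = before != minus  # 5' side, strand-relative
    signed = -gap if upstream else gap
    if gap > distal_cutoff:
        return PositionCall(
            species=species, position_class="distal", distance_bp=signed
        )
    return PositionCall(
        species=species,
        position_class="upstream" if upstream else "downstream",
        distance_bp=signed,
    )
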
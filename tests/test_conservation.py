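import numpy as np
import pytest
from hypothesis import given, strategies as st

from atranet.conservation import (
    DistanceMatrix,
    SaturationError,
    classify_position,
    k2p_distance,
    nj_tree,
)
from atranet.io import GenomicInterval


def random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths; returns the
    leaf-to-leaf path-distance matrix and the set of non-trivial splits."""
    # start from a star over 3 leaves and repeatedly attach new leaves
    next_node = [n_taxa]  # internal node ids
    edges = {}  # node -> (parent, length)

    def new_len():
        return float(rng.uniform(0.05, 1.0))

    # adjacency with branch lengths
    adj = {i: {} for i in range(3)}

    def connect(a, b, ln):
        adj.setdefault(a, {})[b] = ln
        adj.setdefault(b, {})[a] = ln

    center = next_node[0]
    next_node[0] += 1
    for leaf in range(3):
        connect(center, leaf, new_len())
    for leaf in range(3, n_taxa):
        # split a random existing edge and hang the new leaf off it
        a = rng.choice([n for n in adj if adj[n]])
        b = rng.choice(list(adj[a]))
        ln = adj[a].pop(b)
        adj[b].pop(a)
        mid = next_node[0]
        next_node[0] += 1
        f = rng.uniform(0.2, 0.8)
        connect(a, mid, ln * f)
        connect(mid, b, ln * (1 - f))
        connect(mid, leaf, new_len())
    # all-pairs leaf distances by BFS
    import collections

    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        queue = collections.deque([src])
        while queue:
            u = queue.popleft()
            for v, ln in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + ln
                    queue.append(v)
        for dst in range(n_taxa):
            d[src, dst] = dist[dst]
    splits = set()
    leaves = set(range(n_taxa))

    def leafset(u, parent):
        out = set()
        stack = [(u, parent)]
        while stack:
            x, p = stack.pop()
            if x < n_taxa:
                out.add(x)
            for y in adj[x]:
                if y != p:
                    stack.append((y, x))
        return out

    taxa = [str(i) for i in range(n_taxa)]
    for u in adj:
        for v in adj[u]:
            if u < v:
                side = leafset(u, v)
                if 1 < len(side) < n_taxa - 1:
                    splits.add(canonical_split(frozenset(map(str, side)), taxa))
    return d, splits


def canonical_split(side, taxa):
    """Represent a split by whichever side holds the smallest taxon."""
    side = frozenset(side)
    comp = frozenset(taxa) - side
    return side if min(side) < min(comp) else comp


def newick_splits(newick, taxa):
    """Non-trivial splits of a newick string, via biopython."""
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(newick), "newick")
    n = len(taxa)
    splits = set()
    for clade in tree.get_nonterminals():
        names = {t.name for t in clade.get_terminals()}
        if 1 < len(names) < n - 1:
            splits.add(canonical_split(frozenset(names), taxa))
        comp = set(taxa) - names
        if 1 < len(comp) < n - 1:
            splits.add(canonical_split(frozenset(comp), taxa))
    return splits


class TestK2P:
    def test_identical_sequences_distance_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_for_known_fractions(self):
        # 20 sites: 2 transitions (A<->G), 1 transversion (A<->C)
        a = "A" * 20
        b = "G" * 2 + "C" * 1 + "A" * 17
        P, Q = 0.1, 0.05
        expected = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
        assert k2p_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_gap_only_overlap_is_error(self):
        with pytest.raises(ValueError):
            k2p_distance("--N-", "AC-G")

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("AAAA" * 5, "GGGG" * 5)

    def test_gapped_columns_excluded_pairwise(self):
        assert k2p_distance("ACGT-A", "ACGTTA") == 0.0


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            taxa=["a", "b", "c"],
            d=np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]]),
        )
        tree = nj_tree(dm)
        # la = (dab+dac-dbc)/2 etc.
        assert "a:0.1" in tree.newick
        assert "b:0.2" in tree.newick
        assert "c:0.4" in tree.newick

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree: ((a:0.1,b:0.2):0.05,(c:0.3,d:0.4))
        taxa = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0.0, 0.3, 0.45, 0.55],
                [0.3, 0.0, 0.55, 0.65],
                [0.45, 0.55, 0.0, 0.7],
                [0.55, 0.65, 0.7, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(taxa=taxa, d=d))
        splits = newick_splits(tree.newick, taxa)
        # the single non-trivial split: {a,b} vs {c,d}
        assert splits == {frozenset({"a", "b"})}
        bio = tree.to_biopython()
        assert bio.distance("a", "b") == pytest.approx(0.3, abs=1e-9)
        assert bio.distance("a", "d") == pytest.approx(0.55, abs=1e-9)
        assert bio.distance("c", "d") == pytest.approx(0.7, abs=1e-9)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_recovers_random_additive_trees(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for rep in range(10):
            d, true_splits = random_additive_tree(n_taxa, rng)
            taxa = [str(i) for i in range(n_taxa)]
            tree = nj_tree(DistanceMatrix(taxa=taxa, d=d))
            assert newick_splits(tree.newick, taxa) == true_splits

    def test_topology_agrees_with_skbio(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(0)
        d, _ = random_additive_tree(6, rng)
        # perturb slightly so it is not exactly additive
        noise = rng.normal(scale=0.01, size=d.shape)
        d = d + noise + noise.T
        np.fill_diagonal(d, 0.0)
        d = np.abs((d + d.T) / 2)
        taxa = [str(i) for i in range(6)]
        ours = nj_tree(DistanceMatrix(taxa=taxa, d=d))
        theirs = sk_nj(SkDM(d, ids=taxa))
        sk_splits = set()
        for node in theirs.non_tips():
            names = frozenset(t.name for t in node.tips())
            if 1 < len(names) < 5:
                sk_splits.add(canonical_split(names, taxa))
            comp = frozenset(taxa) - names
            if 1 < len(comp) < 5:
                sk_splits.add(canonical_split(comp, taxa))
        assert newick_splits(ours.newick, taxa) == sk_splits

    def test_newick_round_trips(self):
        dm = DistanceMatrix(
            taxa=["a", "b", "c", "d"],
            d=np.array(
                [
                    [0.0, 0.2, 0.5, 0.6],
                    [0.2, 0.0, 0.5, 0.6],
                    [0.5, 0.5, 0.0, 0.3],
                    [0.6, 0.6, 0.3, 0.0],
                ]
            ),
        )
        tree = nj_tree(dm)
        bio = tree.to_biopython()
        assert {t.name for t in bio.get_terminals()} == set(dm.taxa)

    def test_negative_branch_clamped_and_noted(self):
        # triangle violation (dbc > dab + dac) forces a negative branch
        d = np.array(
            [
                [0.0, 0.2, 0.2],
                [0.2, 0.0, 0.9],
                [0.2, 0.9, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(taxa=list("abc"), d=d))
        assert tree.clamped_branches > 0
        assert tree.notes
        assert ":-" not in tree.newick

    def test_graded_divergence_groups_close_clade(self, homolog_fixture):
        fx = homolog_fixture
        dm = DistanceMatrix.from_alignment(fx.alignment)
        tree = nj_tree(dm)
        taxa = list(fx.alignment)
        splits = newick_splits(tree.newick, taxa)
        assert canonical_split(frozenset({"human", "orangutan", "monkey"}), taxa) in splits

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(taxa=["a", "b"], d=np.zeros((2, 2))))


class TestClassifyPosition:
    GENE = GenomicInterval("chr9", 1_000_000, 1_350_000, "NTRK2", "+")

    def test_overlap_is_inside(self):
        hit = GenomicInterval("chr9", 1_349_900, 1_350_100, "h")
        assert classify_position(hit, self.GENE).position_class == "inside"

    def test_five_prime_hit_is_upstream(self):
        hit = GenomicInterval("chr9", 990_000, 990_118, "h")
        call = classify_position(hit, self.GENE)
        assert call.position_class == "upstream"
        assert call.distance_bp == -(1_000_000 - 990_118)

    def test_minus_strand_gene_flips_orientation(self):
        gene = GenomicInterval("chr9", 1_000_000, 1_350_000, "NTRK2", "-")
        hit = GenomicInterval("chr9", 1_360_000, 1_360_118, "h")
        assert classify_position(hit, gene).position_class == "upstream"

    def test_other_chromosome_is_distal(self):
        hit = GenomicInterval("chr8", 1_000_000, 1_000_118, "h")
        call = classify_position(hit, self.GENE)
        assert call.position_class == "distal"
        assert call.distance_bp is None

    def test_beyond_cutoff_is_distal(self):
        hit = GenomicInterval("chr9", 2_000_000, 2_000_118, "h")
        assert (
            classify_position(hit, self.GENE, distal_cutoff=500_000).position_class
            == "distal"
        )

    @given(st.integers(0, 10_000_000))
    def test_translation_invariant(self, shift):
        hit = GenomicInterval("chr9", 1_360_000, 1_360_118, "h")
        a = classify_position(hit, self.GENE)
        b = classify_position(
            GenomicInterval("chr9", hit.start + shift, hit.end + shift, "h"),
            GenomicInterval(
                "chr9", self.GENE.start + shift, self.GENE.end + shift, "NTRK2", "+"
            ),
        )
        assert (a.position_class, a.distance_bp) == (b.position_class, b.distance_bp)

    def test_fixture_realises_five_species_pattern(self, homolog_fixture):
        fx = homolog_fixture
        got = {
            s: classify_position(fx.hits[s], fx.anchors[s], species=s).position_class
            for s in fx.hits
        }
        assert got == fx.classes
        assert sorted(got.values()) == sorted(
            ["inside", "downstream", "downstream", "upstream", "distal"]
        )
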
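import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import fisher_exact

from atranet.enrichment import hypergeometric_enrich
from atranet.fixtures import assayed_genes, load_common_network, load_qpcr_primers
from atranet.io import GeneSetCollection, GenomicInterval
from atranet.mra import (
    CommonNetwork,
    assemble_common_network,
    common_mrs,
    extract_subnetwork,
    filter_by_promoter_binding,
    fisher_regulon_enrichment,
    mra_table,
)
from atranet.netinf import Network

from .oracles import hypergeom_tail, intervals_overlap


def _network(pairs):
    return Network(
        edges=pd.DataFrame(
            [{"regulator": r, "target": t, "mi": 0.5, "support": 1.0} for r, t in pairs]
        )
    )


class TestFisherEnrichment:
    def test_matches_tail_sum_oracle(self):
        universe = [f"g{i}" for i in range(200)]
        regulon = universe[:10]
        signature = universe[2:22]
        res = fisher_regulon_enrichment(regulon, signature, universe)
        k = len(set(regulon) & set(signature))
        assert k == 8
        assert res["p"] == pytest.approx(hypergeom_tail(k, 200, 10, 20), rel=1e-12)

    def test_matches_scipy_fisher_one_sided(self):
        universe = [f"g{i}" for i in range(60)]
        regulon = universe[:12]
        signature = universe[6:24]
        res = fisher_regulon_enrichment(regulon, signature, universe)
        k = len(set(regulon) & set(signature))
        table = [
            [k, len(regulon) - k],
            [len(signature) - k, 60 - len(regulon) - (len(signature) - k)],
        ]
        _, p = fisher_exact(table, alternative="greater")
        assert res["p"] == pytest.approx(p, rel=1e-9)

    def test_agrees_with_hypergeometric_enrichment_module(self):
        universe = [f"g{i}" for i in range(80)]
        regulon = universe[:15]
        signature = universe[5:30]
        res = fisher_regulon_enrichment(regulon, signature, universe)
        ann = GeneSetCollection(sets={"R": ("R", list(regulon))})
        other = hypergeometric_enrich(signature, ann, universe)
        assert res["p"] == pytest.approx(other.loc[0, "p"], abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        res = fisher_regulon_enrichment(universe[:10], universe[20:30], universe)
        assert res["p"] == pytest.approx(1.0)

    def test_empty_regulon_not_mr(self):
        universe = [f"g{i}" for i in range(50)]
        res = fisher_regulon_enrichment([], universe[:10], universe)
        assert res["p"] == 1.0 and not res["is_mr"]

    def test_mr_flag_follows_fdr_threshold(self):
        universe = [f"g{i}" for i in range(300)]
        signature = set(universe[:40])
        regulons = {
            "strong": universe[:15],                 # fully inside the signature
            "null1": universe[100:115],
            "null2": universe[150:165],
        }
        table = mra_table(regulons, signature, universe, fdr_max=0.05)
        by_tf = table.set_index("tf")
        assert bool(by_tf.loc["strong", "is_mr"])
        assert (table["is_mr"] == (table["fdr"] < 0.05)).all()


class TestCommonMRs:
    def test_intersection(self):
        assert common_mrs([{"A", "B"}, {"B", "C"}, {"B"}]) == {"B"}

    def test_disjoint_sets_empty(self):
        assert common_mrs([{"A"}, {"B"}]) == set()

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            common_mrs([{"A"}])


class TestPromoterFilter:
    def _edges(self, pairs):
        return pd.DataFrame([{"regulator": r, "target": t} for r, t in pairs])

    def test_site_inside_promoter_kept(self):
        edges = self._edges([("TF", "G")])
        promoters = {"G": GenomicInterval("chr1", 0, 2500, "G")}
        tfbs = {"TF": [GenomicInterval("chr1", 100, 110, "TF")]}
        assert len(filter_by_promoter_binding(edges, promoters, tfbs)) == 1

    def test_site_on_other_chromosome_dropped(self):
        edges = self._edges([("TF", "G")])
        promoters = {"G": GenomicInterval("chr1", 0, 2500, "G")}
        tfbs = {"TF": [GenomicInterval("chr2", 100, 110, "TF")]}
        assert len(filter_by_promoter_binding(edges, promoters, tfbs)) == 0

    def test_missing_promoter_record_drops_edge(self):
        edges = self._edges([("TF", "G")])
        assert len(filter_by_promoter_binding(edges, {}, {"TF": []})) == 0

    def test_matches_bruteforce_overlap_oracle(self):
        rng = np.random.default_rng(7)
        kept_pkg, kept_oracle = [], []
        for i in range(1000):
            chrom_a = f"chr{rng.integers(1, 3)}"
            chrom_b = f"chr{rng.integers(1, 3)}"
            a0 = int(rng.integers(0, 1500))
            b0 = int(rng.integers(0, 1500))
            a1 = a0 + int(rng.integers(1, 400))
            b1 = b0 + int(rng.integers(1, 400))
            edges = self._edges([("TF", "G")])
            promoters = {"G": GenomicInterval(chrom_a, a0, a1, "G")}
            tfbs = {"TF": [GenomicInterval(chrom_b, b0, b1, "TF")]}
            kept_pkg.append(len(filter_by_promoter_binding(edges, promoters, tfbs)) == 1)
            kept_oracle.append(intervals_overlap(chrom_a, a0, a1, chrom_b, b0, b1))
        assert kept_pkg == kept_oracle

    def test_idempotent(self):
        edges = self._edges([("TF", "G"), ("TF", "H")])
        promoters = {
            "G": GenomicInterval("chr1", 0, 2500, "G"),
            "H": GenomicInterval("chr1", 5000, 7500, "H"),
        }
        tfbs = {"TF": [GenomicInterval("chr1", 100, 110, "TF")]}
        once = filter_by_promoter_binding(edges, promoters, tfbs)
        twice = filter_by_promoter_binding(once, promoters, tfbs)
        assert once.equals(twice)


class TestAssembleCommonNetwork:
    def test_edge_in_two_of_three_lines_excluded(self):
        nets = [
            _network([("A", "x"), ("A", "y")]),
            _network([("A", "x"), ("A", "y")]),
            _network([("A", "x")]),
        ]
        common = assemble_common_network(nets, {"A"}, {"x", "y"})
        assert set(common.edges.itertuples(index=False, name=None)) == {("A", "x")}

    def test_order_invariant(self):
        nets = [
            _network([("A", "x"), ("B", "y")]),
            _network([("A", "x"), ("B", "y"), ("B", "z")]),
            _network([("A", "x"), ("B", "y")]),
        ]
        args = ({"A", "B"}, {"x", "y", "z"})
        a = assemble_common_network(nets, *args)
        b = assemble_common_network(list(reversed(nets)), *args)
        assert a.edges.equals(b.edges)

    def test_regulators_must_have_edges(self):
        with pytest.raises(ValueError):
            CommonNetwork(
                regulators={"A", "B"},
                targets={"x"},
                edges=pd.DataFrame([{"regulator": "A", "target": "x"}]),
            )


class TestExtractSubnetwork:
    def _common(self):
        edges = pd.DataFrame(
            [
                {"regulator": "A", "target": "x"},
                {"regulator": "A", "target": "y"},
                {"regulator": "B", "target": "y"},
            ]
        )
        return CommonNetwork(regulators={"A", "B"}, targets={"x", "y"}, edges=edges)

    def test_full_category_is_identity(self):
        net = self._common()
        sub = extract_subnetwork(net, {"x", "y"})
        assert sub.edges.equals(net.edges)

    def test_disjoint_category_gives_empty(self):
        sub = extract_subnetwork(self._common(), {"z"})
        assert len(sub.edges) == 0 and sub.regulators == set()

    @given(st.sets(st.sampled_from(["x", "y", "z"])))
    def test_target_count_matches_category_overlap(self, category):
        sub = extract_subnetwork(self._common(), category)
        assert sub.targets == category & {"x", "y"}


class TestPublishedFixtures:
    def test_common_network_counts(self):
        net = load_common_network()
        assert len(net.regulators) == 10
        assert len(net.targets) == 71

    def test_primer_panel_assayed_count(self):
        assert len(assayed_genes()) == 19
        primers = load_qpcr_primers()
        assert set(primers.columns) == {"gene", "role", "forward", "reverse"}
        assert (primers["role"] == "reference").sum() == 1
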
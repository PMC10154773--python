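"""Contact assembly, categorization, distances and summary statistics."""

import numpy as np
import pytest

from proxilig.clustering import PointCluster
from proxilig.contacts import (
    Contact,
    GeneIndex,
    assemble_contacts,
    categorize,
    contact_distance,
    read_contact_table,
    summarize,
    write_contact_table,
)
from proxilig.io_formats import GeneModel
from proxilig.junctions import LigationJunction, LigationPoint


def _junction(jid, kind, pos_a, pos_b, reads, chrom_a="chr1", chrom_b="chr1"):
    return LigationJunction(
        id=jid, kind=kind,
        point_a=LigationPoint(chrom_a, pos_a, "donor"),
        point_b=LigationPoint(chrom_b, pos_b, "acceptor"),
        read_ids=set(reads),
    )


@pytest.fixture
def two_clusters():
    return {
        "C1": PointCluster("C1", "chr1", 95, 105, (100,)),
        "C2": PointCluster("C2", "chr1", 995, 1005, (1000,)),
    }


class TestAssemble:
    def test_read_support_unions_disjoint_reads(self, two_clusters):
        j1 = _junction("j1", "neo", 100, 1000, ["r1"])
        j2 = _junction("j2", "neo", 100, 1000, ["r2"])
        assignment = {
            ("j1", "a"): "C1", ("j1", "b"): "C2",
            ("j2", "a"): "C1", ("j2", "b"): "C2",
        }
        contacts, n_self = assemble_contacts([j1, j2], assignment, two_clusters)
        assert n_self == 0
        (c,) = contacts
        assert c.r == 2
        assert (c.cluster_a, c.cluster_b) == ("C1", "C2")

    def test_shared_read_counted_once(self, two_clusters):
        j1 = _junction("j1", "neo", 100, 1000, ["r1"])
        j2 = _junction("j2", "chimeric", 100, 1000, ["r1"])
        assignment = {
            ("j1", "a"): "C1", ("j1", "b"): "C2",
            ("j2", "a"): "C1", ("j2", "b"): "C2",
        }
        (c,), _ = assemble_contacts([j1, j2], assignment, two_clusters)
        assert c.r == 1
        assert c.kinds == frozenset({"neo", "chimeric"})

    def test_self_contact_dropped_and_counted(self, two_clusters):
        j1 = _junction("j1", "neo", 100, 103, ["r1"])
        assignment = {("j1", "a"): "C1", ("j1", "b"): "C1"}
        contacts, n_self = assemble_contacts([j1], assignment, two_clusters)
        assert contacts == []
        assert n_self == 1

    def test_junction_conservation(self, two_clusters):
        junctions = [
            _junction("j1", "neo", 100, 1000, ["r1"]),
            _junction("j2", "neo", 100, 1000, ["r2"]),
            _junction("j3", "neo", 100, 103, ["r3"]),  # self
        ]
        assignment = {
            ("j1", "a"): "C1", ("j1", "b"): "C2",
            ("j2", "a"): "C1", ("j2", "b"): "C2",
            ("j3", "a"): "C1", ("j3", "b"): "C1",
        }
        contacts, n_self = assemble_contacts(junctions, assignment,
                                             two_clusters)
        linking = sum(len(c.junction_ids) for c in contacts)
        assert linking + n_self == len(junctions)


class TestCategorize:
    genes = GeneIndex([
        GeneModel("G1", "chr1", 50, 2000, "+"),
        GeneModel("G2", "chr1", 5000, 9000, "+"),
    ])

    def _contact(self, clusters):
        return Contact(
            cluster_a="A", cluster_b="B", r=1, kinds=frozenset({"neo"}),
            junction_ids=("j1",),
        )

    def test_both_in_common_gene(self):
        clusters = {
            "A": PointCluster("A", "chr1", 95, 105, (100,)),
            "B": PointCluster("B", "chr1", 995, 1005, (1000,)),
        }
        assert categorize(self._contact(clusters), clusters, self.genes) == \
            "intragenic"

    def test_same_chromosome_different_genes_is_cis(self):
        clusters = {
            "A": PointCluster("A", "chr1", 95, 105, (100,)),
            "B": PointCluster("B", "chr1", 5995, 6005, (6000,)),
        }
        assert categorize(self._contact(clusters), clusters, self.genes) == "cis"

    def test_different_chromosomes_is_trans(self):
        clusters = {
            "A": PointCluster("A", "chr1", 95, 105, (100,)),
            "B": PointCluster("B", "chr7", 995, 1005, (1000,)),
        }
        assert categorize(self._contact(clusters), clusters, self.genes) == \
            "trans"


class TestDistance:
    def test_midpoint_distance(self, two_clusters):
        c = Contact("C1", "C2", r=3, kinds=frozenset({"neo"}),
                    junction_ids=("j1",))
        assert contact_distance(c, two_clusters) == 900.0

    def test_equal_midpoints_floored_at_one(self):
        clusters = {
            "C1": PointCluster("C1", "chr1", 95, 105, (100,)),
            "C2": PointCluster("C2", "chr1", 90, 110, (95, 105)),
        }
        c = Contact("C1", "C2", r=1, kinds=frozenset({"neo"}),
                    junction_ids=("j1",))
        assert contact_distance(c, clusters) == 1.0

    def test_trans_contact_rejected(self):
        clusters = {
            "C1": PointCluster("C1", "chr1", 95, 105, (100,)),
            "C2": PointCluster("C2", "chr7", 95, 105, (100,)),
        }
        c = Contact("C1", "C2", r=1, kinds=frozenset({"neo"}),
                    junction_ids=("j1",))
        with pytest.raises(ValueError):
            contact_distance(c, clusters)


class TestSummarize:
    def _clusters(self):
        return {
            "C1": PointCluster("C1", "chr1", 95, 105, (100,)),
            "C2": PointCluster("C2", "chr1", 995, 1005, (1000,)),
        }

    def test_mean_log2_read_support(self):
        clusters = self._clusters()
        contacts = [
            Contact("C1", "C2", r=1, kinds=frozenset({"neo"}),
                    junction_ids=("j1",), category="intragenic", d=900.0),
            Contact("C1", "C2", r=2, kinds=frozenset({"neo"}),
                    junction_ids=("j2",), category="intragenic", d=900.0),
        ]
        stats = summarize(contacts, clusters)
        assert stats.loc["intragenic", "n"] == 2
        assert stats.loc["intragenic", "log2_r_mean"] == pytest.approx(0.5)
        assert stats.loc["intragenic", "s_mean"] == pytest.approx(10.0)

    def test_single_contact_sd_undefined(self):
        clusters = self._clusters()
        contacts = [
            Contact("C1", "C2", r=2, kinds=frozenset({"neo"}),
                    junction_ids=("j1",), category="cis", d=900.0),
        ]
        stats = summarize(contacts, clusters)
        assert np.isnan(stats.loc["cis", "log2_r_sd"])
        assert np.isnan(stats.loc["cis", "log2_d_sd"])

    def test_empty_category_row_present_with_zero_n(self):
        stats = summarize([], {})
        assert list(stats.index) == ["intragenic", "cis", "trans"]
        assert (stats["n"] == 0).all()
        assert np.isnan(stats.loc["trans", "log2_d_mean"])


def test_category_partition_on_fixture(fixture_data):
    from conftest import call_contacts
    paths, _ = fixture_data
    res = call_contacts(paths)
    counts = {"intragenic": 0, "cis": 0, "trans": 0}
    for c in res["contacts"]:
        counts[c.category] += 1
    assert sum(counts.values()) == len(res["contacts"])


def test_contact_table_round_trip(tmp_path, fixture_data):
    from conftest import call_contacts
    paths, _ = fixture_data
    res = call_contacts(paths)
    p = tmp_path / "contacts.tsv"
    write_contact_table(res["contacts"], p)
    assert read_contact_table(p) == res["contacts"]
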
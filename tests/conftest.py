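import pytest

from proxilig import clustering, contacts as cm, io_formats, junctions
from proxilig.clustering import ClusterConfig
from proxilig.simulate import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def fixture_data(tmp_path_factory):
    """Default synthetic fixture: (paths, truth)."""
    outdir = tmp_path_factory.mktemp("fixture")
    return generate_fixture(FixtureConfig(seed=11), outdir)


def call_contacts(paths, delta=10, annotation_only=False, unique_only=True):
    """Run the library pipeline on fixture paths; return a results dict."""
    control = (
        None if annotation_only
        else [io_formats.read_sj_table(paths["control_sj"])]
    )
    annotation = io_formats.read_sj_table(paths["annotation_sj"])
    known = junctions.build_known_set(control, annotation)
    neo = junctions.neo_junctions_from_alignments(
        io_formats.read_sam_splits(paths["sam"]), known,
        unique_only=unique_only,
    )
    chim = junctions.chimeric_to_ligation(
        io_formats.read_chimeric_table(paths["chimeric"])
    )
    all_junctions = neo + chim
    cluster_list, assignment = clustering.cluster_junction_points(
        all_junctions, ClusterConfig(delta=delta)
    )
    clusters = {c.id: c for c in cluster_list}
    contact_list, n_self = cm.assemble_contacts(
        all_junctions, assignment, clusters
    )
    genes = cm.GeneIndex(
        io_formats.read_gene_models(paths["genes_gtf"], "gtf")
    )
    cm.annotate_contacts(contact_list, clusters, genes)
    return {
        "neo": neo,
        "chimeric": chim,
        "junctions": all_junctions,
        "clusters": clusters,
        "assignment": assignment,
        "contacts": contact_list,
        "n_self": n_self,
        "genes": genes,
    }
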